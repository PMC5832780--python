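"""Sequence/interval containers, FASTA/BED/GFF readers and interval arithmetic.

Coordinates are 0-based, half-open (BED convention) throughout the package.
All DNA-side storage uses T; queries given as RNA (with U) are normalised on
input.  The genome-assembly label of any coordinate is carried as opaque
metadata and never interpreted.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaError(ValueError):
    """Malformed or unacceptable FASTA input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval [start, end) on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Shared-base test; strand-blind."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass
class HaplotypeSequence:
    """A named nucleotide sequence, optionally anchored to genome coordinates.

    ``origin`` maps local offset 0 to ``origin.start`` on ``origin.chrom``;
    it is opaque metadata (no assembly is assumed).
    """

    name: str
    seq: str
    origin: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"sequence {self.name!r} is empty")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.name!r} contains illegal characters: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def normalize_seq(raw: str, *, name: str = "<seq>") -> str:
    """Uppercase, map U->T, and validate against the DNA alphabet."""
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise FastaError(
            f"record {name!r} contains illegal characters: {sorted(bad)}"
        )
    return seq


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    up = seq.upper()
    bad = set(up) - DNA_ALPHABET
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    return up.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[HaplotypeSequence]:
    """Read a FASTA file into HaplotypeSequence records.

    Sequences are uppercased and U is mapped to T.  Record order is
    preserved.  Raises :class:`FastaError` for an empty file, duplicate
    record names, or characters outside {A,C,G,T,N,U}.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records: list[HaplotypeSequence] = []
    seen: set[str] = set()
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise FastaError(f"duplicate record name {rec.id!r} in {path}")
            seen.add(rec.id)
            seq = normalize_seq(str(rec.seq), name=rec.id)
            if not seq:
                raise FastaError(f"record {rec.id!r} in {path} is empty")
            records.append(HaplotypeSequence(name=rec.id, seq=seq))
    if not records:
        raise FastaError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[HaplotypeSequence], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED / GFF
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BedRecord:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "+"

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


def read_bed(path: str | Path) -> list[BedRecord]:
    """Read a BED3/BED6 file (comment lines starting with '#' skipped)."""
    out: list[BedRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            strand = parts[5] if len(parts) > 5 else "+"
            out.append(BedRecord(chrom, start, end, name, score, strand))
    return out


def write_bed(records: Sequence[BedRecord], path: str | Path) -> None:
    """Write BED6 rows in deterministic (chrom, start, end, name) order."""
    ordered = sorted(records, key=lambda r: (r.chrom, r.start, r.end, r.name))
    with open(path, "w") as fh:
        for r in ordered:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score:g}\t"
                f"{r.strand}\n"
            )


def read_exons(path: str | Path) -> list[GenomicInterval]:
    """Read exon intervals from a BED file or a GFF3/GTF file.

    For GFF3/GTF input only rows whose feature type is ``exon`` are used;
    GFF coordinates (1-based inclusive) are converted to 0-based half-open.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3", ".gtf"):
        out = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 8 or parts[2].lower() != "exon":
                    continue
                strand = parts[6] if parts[6] in ("+", "-") else "+"
                out.append(
                    GenomicInterval(parts[0], int(parts[3]) - 1, int(parts[4]),
                                    strand)
                )
        return out
    return [r.interval for r in read_bed(path)]


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def merge_intervals(
    intervals: Iterable[GenomicInterval], *, stranded: bool = False
) -> list[GenomicInterval]:
    """Union of intervals: sorted, pairwise-disjoint per chromosome.

    Merging is strand-blind by default (merged spans carry strand '+');
    with ``stranded=True`` intervals merge only within a strand.
    """
    def key(iv: GenomicInterval):
        return (iv.chrom, iv.strand) if stranded else (iv.chrom,)

    groups: dict[tuple, list[GenomicInterval]] = {}
    for iv in intervals:
        groups.setdefault(key(iv), []).append(iv)

    merged: list[GenomicInterval] = []
    for k in sorted(groups):
        ivs = sorted(groups[k], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        strand = ivs[0].strand if stranded else "+"
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(ivs[0].chrom, cur_start, cur_end,
                                              strand))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(ivs[0].chrom, cur_start, cur_end, strand))
    merged.sort(key=lambda iv: (iv.chrom, iv.start, iv.end, iv.strand))
    return merged


def to_rna(seq: str) -> str:
    """DNA-side string rendered RNA-side (T -> U) for display."""
    return seq.upper().replace("T", "U")
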