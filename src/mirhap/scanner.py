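"""Sliding-window hairpin scan: stages 1-4 of the discovery funnel.

Every window of 58-110 bp (1 bp stride, both strands, reported 5'->3') is
folded; windows below the MFE cutoff whose structure is a linear hairpin
(by the configured strictness) survive, and surviving windows are merged
into an atlas of candidate pre-miRNA loci after exon exclusion.

Implementation note: the banded DP tables of :class:`~mirhap.folding.engine.
FoldTables` depend only on the subsequence, so one table fill per strand
serves every window; per-start exterior passes then price all window
lengths at that start in O(L^2).  That makes stride-1 scans of kilobase
haplotypes take seconds instead of hours.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from .core_io import GenomicInterval, HaplotypeSequence, merge_intervals, revcomp
from .folding import EnergyParams, FoldResult, Topology, classify_topology
from .folding.engine import INF, FoldTables


@dataclass
class ScanConfig:
    """Parameters of the window scan.

    Defaults are the published operating point: window lengths 58-110 bp
    (the 5th-95th percentiles of annotated human pre-miRNA lengths), MFE
    strictly below -20 kcal/mol (the 5th percentile of annotated pre-miRNA
    MFE), both strands, stride 1.
    """

    min_len: int = 58
    max_len: int = 110
    stride: int = 1
    mfe_cutoff: float = -20.0
    #: "lt" keeps mfe < cutoff (the operational reading: "MFE >= -20 ...
    #: removed"); "le" admits equality.
    mfe_comparator: str = "lt"
    both_strands: bool = True
    prescreen: bool = True
    prescreen_threshold: int | None = None  # None: derive from EnergyParams
    reject_bulges: bool = True
    reject_multiloops: bool = True
    reject_internal_loops: bool = False
    require_single_hairpin: bool = True

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.mfe_comparator not in ("lt", "le"):
            raise ValueError("mfe_comparator must be 'lt' or 'le'")

    def mfe_passes(self, mfe: float) -> bool:
        return mfe < self.mfe_cutoff if self.mfe_comparator == "lt" \
            else mfe <= self.mfe_cutoff

    def topology_passes(self, topo: Topology) -> bool:
        if self.require_single_hairpin and topo.n_hairpin_loops != 1:
            return False
        if self.reject_multiloops and topo.n_multiloops > 0:
            return False
        if self.reject_bulges and topo.n_bulges > 0:
            return False
        if self.reject_internal_loops and topo.n_internal_loops > 0:
            return False
        return topo.n_pairs > 0


@dataclass
class HairpinWindow:
    """One candidate window with its fold, topology and filter verdict."""

    interval: GenomicInterval
    seq: str
    fold: FoldResult
    topology: Topology
    passed_filters: bool = True
    triage_score: float | None = None


@dataclass
class CandidateLocus:
    """A merged atlas entry: a genomic span holding >=1 passing window."""

    interval: GenomicInterval
    n_windows: int
    best_mfe: float


@dataclass
class ScanStats:
    """Per-stage funnel counts of one scan."""

    windows_enumerated: int = 0
    prescreen_passed: int = 0
    folded: int = 0
    mfe_passed: int = 0
    topology_passed: int = 0


# ---------------------------------------------------------------------------
# window enumeration
# ---------------------------------------------------------------------------

def enumerate_windows(
    hap: HaplotypeSequence, config: ScanConfig
) -> Iterator[tuple[GenomicInterval, str]]:
    """Yield (interval, window sequence 5'->3') in (start, length, strand) order.

    Reverse-strand windows carry the reverse complement of the forward
    slice.  A sequence shorter than ``min_len`` yields nothing.
    """
    n = len(hap.seq)
    chrom = hap.name
    strands = ("+", "-") if config.both_strands else ("+",)
    for start in range(0, n - config.min_len + 1, config.stride):
        for length in range(config.min_len, min(config.max_len, n - start) + 1):
            fwd = hap.seq[start : start + length]
            for strand in strands:
                win = fwd if strand == "+" else revcomp(fwd)
                yield GenomicInterval(chrom, start, start + length, strand), win


def count_windows(seq_len: int, config: ScanConfig) -> int:
    total = 0
    for start in range(0, seq_len - config.min_len + 1, config.stride):
        total += max(0, min(config.max_len, seq_len - start) - config.min_len + 1)
    return total * (2 if config.both_strands else 1)


# ---------------------------------------------------------------------------
# prescreen
# ---------------------------------------------------------------------------

def prescreen(window_seq: str, threshold: int,
              params: EnergyParams | None = None) -> bool:
    """Cheap conservative gate: maximum possible pair count >= threshold.

    The maximum pair count over all nested structures (Nussinov) upper-bounds
    the pair count of any structure, and
    :meth:`EnergyParams.conservative_pair_threshold` converts the MFE cutoff
    into a pair count no passing structure can be below, so a window rejected
    here can never fold below the cutoff.  ``threshold <= 0`` disables the
    screen (all pass).
    """
    if threshold <= 0:
        return True
    tables = FoldTables(window_seq, params)
    nuss = tables.nussinov()
    return int(nuss[0, len(window_seq) - 1]) >= threshold


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _scan_strand(
    seq: str,
    chrom: str,
    strand: str,
    config: ScanConfig,
    params: EnergyParams,
    stats: ScanStats,
) -> list[HairpinWindow]:
    """Scan one oriented sequence; map hits back to forward coordinates."""
    n = len(seq)
    if n < config.min_len:
        return []
    cap = config.max_len - 1
    tables = FoldTables(seq, params, cap=cap)
    nuss = tables.nussinov() if config.prescreen else None
    thr = config.prescreen_threshold
    if thr is None:
        thr = params.conservative_pair_threshold(config.mfe_cutoff)

    out: list[HairpinWindow] = []
    cutoff_deci_ok = config.mfe_passes
    for s in range(0, n - config.min_len + 1, config.stride):
        max_l = min(config.max_len, n - s)
        We, _ = tables.window_mfe_profile(s, max_l)
        for length in range(config.min_len, max_l + 1):
            stats.windows_enumerated += 1
            if config.prescreen:
                if int(nuss[s, length - 1]) < thr:
                    continue  # never folded
            stats.prescreen_passed += 1
            stats.folded += 1
            mfe = We[length] / 10.0
            if not cutoff_deci_ok(mfe):
                continue
            stats.mfe_passed += 1
            structure = tables.traceback(s, s + length)
            topo = classify_topology(structure)
            if not config.topology_passes(topo):
                continue
            stats.topology_passed += 1
            if strand == "+":
                iv = GenomicInterval(chrom, s, s + length, "+")
            else:
                iv = GenomicInterval(chrom, n - (s + length), n - s, "-")
            fold = FoldResult(seq[s : s + length], structure, mfe, "reference")
            out.append(HairpinWindow(iv, seq[s : s + length], fold, topo))
    return out


def scan_sequence(
    hap: HaplotypeSequence,
    config: ScanConfig | None = None,
    params: EnergyParams | None = None,
    stats: ScanStats | None = None,
) -> list[HairpinWindow]:
    """Windows passing the MFE and topology filters, both strands.

    Returned windows are deduplicated by (interval, strand) and sorted by
    (start, end, strand).
    """
    config = config or ScanConfig()
    params = params or EnergyParams.default()
    stats = stats if stats is not None else ScanStats()
    if len(hap.seq) < config.min_len:
        return []
    hits = _scan_strand(hap.seq, hap.name, "+", config, params, stats)
    if config.both_strands:
        hits += _scan_strand(revcomp(hap.seq), hap.name, "-", config, params,
                             stats)
    seen: set[tuple] = set()
    unique: list[HairpinWindow] = []
    for w in sorted(hits, key=lambda w: (w.interval.start, w.interval.end,
                                         w.interval.strand)):
        key = (w.interval.start, w.interval.end, w.interval.strand)
        if key not in seen:
            seen.add(key)
            unique.append(w)
    return unique


# ---------------------------------------------------------------------------
# exon exclusion and atlas
# ---------------------------------------------------------------------------

def exclude_exons(entries: Iterable, exons: list[GenomicInterval]) -> list:
    """Drop every entry sharing >=1 base with any exon interval (strand-blind).

    Works on anything with an ``interval`` attribute (HairpinWindow,
    CandidateLocus) or on bare GenomicIntervals.
    """
    merged_exons = merge_intervals(exons) if exons else []
    out = []
    for entry in entries:
        iv = entry.interval if hasattr(entry, "interval") else entry
        if not any(iv.overlaps(e) for e in merged_exons):
            out.append(entry)
    return out


def build_atlas(windows: list[HairpinWindow]) -> list[CandidateLocus]:
    """Merge passing windows into disjoint, sorted candidate loci.

    Merging is strand-blind; each locus records how many windows merged
    into it and the best (lowest) window MFE.
    """
    if not windows:
        return []
    merged = merge_intervals(w.interval for w in windows)
    loci = []
    for span in merged:
        members = [w for w in windows if w.interval.overlaps(span)]
        loci.append(
            CandidateLocus(span, n_windows=len(members),
                           best_mfe=min(w.fold.mfe for w in members))
        )
    return loci
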