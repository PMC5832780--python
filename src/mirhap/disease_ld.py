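"""Disease-SNP linkage-disequilibrium analysis of miRNA loci.

LD blocks are built from externally supplied pairwise proxy tables (index
rsid, proxy rsid, position, r²): the block of an index SNP spans the index
and every proxy with r² >= 0.9 (configurable).  Blocks are intersected
with miRNA loci to tabulate which miRNAs lie in LD with disease-associated
SNPs, and mature miRNAs are flagged when they contain a common SNP
(MAF >= cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .core_io import GenomicInterval

DEFAULT_R2_MIN = 0.9


@dataclass
class DiseaseSNP:
    rsid: str
    chrom: str
    pos: int  # 0-based
    phenotypes: list[str] = field(default_factory=list)
    maf: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"{self.rsid}: MAF must lie in [0, 0.5]")


@dataclass
class LDBlock:
    index_rsid: str
    interval: GenomicInterval
    members: dict[str, float] = field(default_factory=dict)  # rsid -> r2


def read_snp_table(path) -> list[DiseaseSNP]:
    """TSV columns: rsid, chrom, pos, maf, phenotypes (';'-separated)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        phen = str(r.get("phenotypes", "")) if pd.notna(r.get("phenotypes")) else ""
        out.append(DiseaseSNP(
            rsid=str(r["rsid"]), chrom=str(r["chrom"]), pos=int(r["pos"]),
            phenotypes=[p for p in phen.split(";") if p],
            maf=float(r.get("maf", 0.0)),
        ))
    return out


def build_ld_blocks(
    proxies: pd.DataFrame,
    snps: list[DiseaseSNP],
    r2_min: float = DEFAULT_R2_MIN,
) -> list[LDBlock]:
    """One block per disease SNP: [min, max+1) over index + qualifying proxies.

    Proxies with r² < ``r2_min`` are excluded; an index with no qualifying
    proxy yields a 1-bp block at its own position.  Every index rsid in the
    proxy table must be present in ``snps``.
    """
    by_rsid = {s.rsid: s for s in snps}
    unknown = set(proxies["index_rsid"]) - set(by_rsid) if len(proxies) else set()
    if unknown:
        raise ValueError(f"proxy table references unknown index SNPs: "
                         f"{sorted(unknown)}")
    blocks = []
    for snp in snps:
        rows = proxies[proxies["index_rsid"] == snp.rsid] if len(proxies) \
            else proxies
        members: dict[str, float] = {}
        positions = [snp.pos]
        for _, r in rows.iterrows():
            if float(r["r2"]) >= r2_min:
                members[str(r["proxy_rsid"])] = float(r["r2"])
                positions.append(int(r["pos"]))
        blocks.append(LDBlock(
            index_rsid=snp.rsid,
            interval=GenomicInterval(snp.chrom, min(positions),
                                     max(positions) + 1),
            members=members,
        ))
    return blocks


def intersect_mirna_ld(
    mirna_loci: list[tuple[str, GenomicInterval]],
    blocks: list[LDBlock],
) -> pd.DataFrame:
    """One row per (miRNA, block) sharing >=1 base; strand-blind.

    Columns: mirna_id, index_rsid, mirna_start, mirna_end, block_start,
    block_end.
    """
    trees: dict[str, IntervalTree] = {}
    for bi, b in enumerate(blocks):
        trees.setdefault(b.interval.chrom, IntervalTree()).addi(
            b.interval.start, b.interval.end, bi
        )
    rows = []
    for mid, iv in mirna_loci:
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(iv.start, iv.end),
                          key=lambda h: (h.begin, h.end, h.data)):
            b = blocks[hit.data]
            rows.append({
                "mirna_id": mid, "index_rsid": b.index_rsid,
                "mirna_start": iv.start, "mirna_end": iv.end,
                "block_start": b.interval.start, "block_end": b.interval.end,
            })
    return pd.DataFrame(
        rows, columns=["mirna_id", "index_rsid", "mirna_start", "mirna_end",
                       "block_start", "block_end"],
    )


def _norm_phenotype(label: str) -> str:
    return " ".join(label.lower().split())


def summarize_disease(
    associations: pd.DataFrame, snps: list[DiseaseSNP]
) -> tuple[int, int, int]:
    """(n miRNAs in LD, n unique SNPs, n unique phenotypes).

    SNPs deduplicate by rsid; phenotypes by case-folded, whitespace-
    normalised label.  Row order of the association table is irrelevant.
    """
    if associations.empty:
        return (0, 0, 0)
    by_rsid = {s.rsid: s for s in snps}
    n_mirna = associations["mirna_id"].nunique()
    rsids = set(associations["index_rsid"])
    phenotypes = {
        _norm_phenotype(p)
        for rsid in rsids
        for p in by_rsid[rsid].phenotypes
        if p.strip()
    }
    return (int(n_mirna), len(rsids), len(phenotypes))


def common_snp_overlap(
    mirnas: list[tuple[str, GenomicInterval]],
    snps: list[DiseaseSNP],
    maf_min: float,
) -> tuple[dict[str, bool], int]:
    """Flag miRNAs containing >=1 SNP with MAF >= maf_min (inclusive).

    A SNP is "within" a miRNA when its position lies in [start, end).
    Returns (per-miRNA flags, flagged count).
    """
    common = [s for s in snps if s.maf >= maf_min]
    flags = {}
    for mid, iv in mirnas:
        flags[mid] = any(
            iv.contains_point(s.chrom, s.pos) for s in common
        )
    return flags, sum(flags.values())
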