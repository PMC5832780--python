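"""Functional-evidence calls: Ago CLIP read support and Dicer dependence.

Ago support: a mature miRNA is supported when reads containing its exact,
ungapped sequence total at least 500 across the CLIP-seq datasets (the
aggregation rule — sum across datasets vs. required in each — is
configurable, sum being the default reading).

Dicer dependence: ΔCt = Ct(target) - Ct(normalizer) per sample; a
two-sided pooled-variance t-test compares silencing vs control ΔCt, and a
miRNA is called Dicer dependent when p <= 0.05 AND expression goes down on
silencing (mean ΔCt higher under silencing).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from Bio import SeqIO

from .core_io import normalize_seq, revcomp

logger = logging.getLogger(__name__)

DEFAULT_SUPPORT_THRESHOLD = 500


@dataclass
class AgoSupport:
    """Exact-read support counts for one mature miRNA."""

    mirna_id: str
    per_dataset: dict[str, int]
    threshold: int = DEFAULT_SUPPORT_THRESHOLD
    mode: str = "sum"  # "sum" across datasets | "per_dataset" (each must pass)

    @property
    def total(self) -> int:
        return sum(self.per_dataset.values())

    @property
    def supported(self) -> bool:
        if not self.per_dataset:
            return False
        if self.mode == "per_dataset":
            return all(c >= self.threshold for c in self.per_dataset.values())
        return self.total >= self.threshold


def _iter_fastq(path: str | Path):
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    skipped = 0
    with opener(path, "rt") as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                yield str(rec.seq)
        except ValueError as exc:
            skipped += 1
            logger.warning("skipping unreadable FASTQ tail in %s: %s", path, exc)
    if skipped:
        logger.warning("%s: %d unreadable records skipped", path, skipped)


def count_read_support(
    mirna_id: str,
    mirna_seq: str,
    datasets: dict[str, str | Path],
    threshold: int = DEFAULT_SUPPORT_THRESHOLD,
    both_strands: bool = False,
    mode: str = "sum",
) -> AgoSupport:
    """Count reads containing the exact mature sequence, per dataset.

    Matching is sense-strand by default (CLIP reads are sense);
    ``both_strands=True`` also counts reverse-complement occurrences.
    A read equal to the sequence itself counts (substring includes identity).
    """
    q = normalize_seq(mirna_seq, name=mirna_id)
    if len(q) < 16:
        raise ValueError(f"{mirna_id}: mature sequence shorter than 16 nt")
    rc = revcomp(q)
    counts: dict[str, int] = {}
    for name, path in datasets.items():
        c = 0
        for read in _iter_fastq(path):
            read = read.upper().replace("U", "T")
            if q in read or (both_strands and rc in read):
                c += 1
        counts[name] = c
    return AgoSupport(mirna_id, counts, threshold=threshold, mode=mode)


def flag_supported(supports: list[AgoSupport],
                   threshold: int = DEFAULT_SUPPORT_THRESHOLD) -> dict[str, bool]:
    """Apply the >=threshold rule (under each support's aggregation mode)."""
    out = {}
    for s in supports:
        s.threshold = threshold
        out[s.mirna_id] = s.supported
    return out


# ---------------------------------------------------------------------------
# Dicer dependence from qPCR Ct tables
# ---------------------------------------------------------------------------

@dataclass
class DicerCall:
    """ΔΔCt silencing call for one miRNA."""

    mirna_id: str
    mean_dct_control: float
    mean_dct_silenced: float
    ddct: float
    fold_change: float
    p_value: float
    dependent: bool


def dicer_dependence_test(
    ct_table: pd.DataFrame,
    normalizer: str = "ACTB",
    silenced_condition: str = "silenced",
    control_condition: str = "control",
    alpha: float = 0.05,
    comparator: str = "le",
) -> list[DicerCall]:
    """Per-miRNA Dicer-dependence calls from a long-format Ct table.

    ``ct_table`` columns: sample, condition, target, ct.  ΔCt is computed
    per sample against the named normalizer; conditions are compared with a
    two-sided pooled-variance t-test.  A miRNA is dependent iff the p-value
    passes ``alpha`` (comparator "le": p <= alpha; "lt": p < alpha) and the
    silenced-condition mean ΔCt exceeds the control mean (expression down).
    Samples missing the normalizer Ct are skipped with a warning; a
    zero-effect / undefined test is never significant.
    """
    required = {"sample", "condition", "target", "ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"ct table lacks columns: {sorted(missing)}")

    norm = ct_table[ct_table["target"] == normalizer]
    norm_ct = norm.set_index("sample")["ct"].to_dict()

    calls: list[DicerCall] = []
    targets = [t for t in ct_table["target"].unique() if t != normalizer]
    for target in targets:
        rows = ct_table[ct_table["target"] == target]
        dct: dict[str, list[float]] = {silenced_condition: [],
                                       control_condition: []}
        skip = False
        for _, row in rows.iterrows():
            if row["sample"] not in norm_ct:
                logger.warning(
                    "%s: sample %s lacks normalizer %s Ct; miRNA skipped",
                    target, row["sample"], normalizer,
                )
                skip = True
                break
            if row["condition"] in dct:
                dct[row["condition"]].append(row["ct"] - norm_ct[row["sample"]])
        if skip:
            continue
        sil = np.asarray(dct[silenced_condition])
        ctl = np.asarray(dct[control_condition])
        if len(sil) < 2 or len(ctl) < 2:
            logger.warning("%s: fewer than 2 replicates per condition; skipped",
                           target)
            continue
        if np.ptp(sil) == 0 and np.ptp(ctl) == 0 and sil.mean() == ctl.mean():
            p = 1.0  # identical data: no evidence
        else:
            p = float(sps.ttest_ind(sil, ctl, equal_var=True).pvalue)
            if np.isnan(p):
                p = 1.0
        ddct = float(sil.mean() - ctl.mean())
        sig = p <= alpha if comparator == "le" else p < alpha
        calls.append(
            DicerCall(
                mirna_id=target,
                mean_dct_control=float(ctl.mean()),
                mean_dct_silenced=float(sil.mean()),
                ddct=ddct,
                fold_change=float(2.0 ** (-ddct)),
                p_value=p,
                dependent=bool(sig and sil.mean() > ctl.mean()),
            )
        )
    return calls
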