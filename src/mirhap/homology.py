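"""Semi-global pairwise alignment of mature miRNAs against a catalog.

Semi-global (overlap) Needleman-Wunsch: a global alignment whose terminal
gaps on either sequence are free, suited to short sequences that may
overlap end-to-end.  Default scoring is +5 match / -4 mismatch with a
linear gap penalty of 8 (the three values are configurable since only the
algorithm, not its parameters, is fixed by convention).  U and T are
identical for scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ScoringScheme:
    match: float = 5.0
    mismatch: float = -4.0
    gap: float = 8.0  # subtracted per gap position

    def __post_init__(self) -> None:
        if self.gap < 0:
            raise ValueError("gap penalty must be >= 0")

    def sub(self, a: str, b: str) -> float:
        if a == "N" or b == "N":
            return self.mismatch
        return self.match if a == b else self.mismatch


@dataclass
class AlignmentResult:
    score: float
    aligned_query: str
    aligned_subject: str

    @property
    def identity(self) -> float:
        """Fraction of identical symbols over aligned columns."""
        cols = len(self.aligned_query)
        if cols == 0:
            return 0.0
        same = sum(
            1 for x, y in zip(self.aligned_query, self.aligned_subject)
            if x == y and x != "-"
        )
        return same / cols


def _norm(seq: str) -> str:
    return seq.upper().replace("T", "U")


def semiglobal_align(a: str, b: str,
                     scheme: ScoringScheme | None = None) -> AlignmentResult:
    """Best-scoring alignment of a vs b with free terminal gaps.

    Deterministic traceback: ties prefer diagonal, then up (gap in b),
    then left (gap in a).
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    scheme = scheme or ScoringScheme()
    qa, qb = _norm(a), _norm(b)
    n, m = len(qa), len(qb)
    H = np.zeros((n + 1, m + 1))
    # free leading gaps: first row/col zero
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            H[i, j] = max(
                H[i - 1, j - 1] + scheme.sub(qa[i - 1], qb[j - 1]),
                H[i - 1, j] - scheme.gap,
                H[i, j - 1] - scheme.gap,
            )
    # free trailing gaps: best cell on the last row or column
    best_i, best_j = n, m
    best = H[n, m]
    for i in range(n + 1):
        if H[i, m] > best:
            best, best_i, best_j = H[i, m], i, m
    for j in range(m + 1):
        if H[n, j] > best:
            best, best_i, best_j = H[n, j], n, j

    # traceback from (best_i, best_j) to a leading edge
    out_a: list[str] = []
    out_b: list[str] = []
    # trailing free gaps
    for i in range(n, best_i, -1):
        out_a.append(qa[i - 1])
        out_b.append("-")
    for j in range(m, best_j, -1):
        out_a.append("-")
        out_b.append(qb[j - 1])
    i, j = best_i, best_j
    while i > 0 and j > 0:
        if H[i, j] == H[i - 1, j - 1] + scheme.sub(qa[i - 1], qb[j - 1]):
            out_a.append(qa[i - 1])
            out_b.append(qb[j - 1])
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] - scheme.gap:
            out_a.append(qa[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(qb[j - 1])
            j -= 1
    # leading free gaps
    while i > 0:
        out_a.append(qa[i - 1])
        out_b.append("-")
        i -= 1
    while j > 0:
        out_a.append("-")
        out_b.append(qb[j - 1])
        j -= 1
    return AlignmentResult(float(best), "".join(reversed(out_a)),
                           "".join(reversed(out_b)))


def best_annotated_matches(
    novel_seq: str,
    catalog: list[tuple[str, str]],
    scheme: ScoringScheme | None = None,
) -> list[tuple[str, AlignmentResult]]:
    """All catalog entries achieving the maximal alignment score.

    Every tie is reported, in catalog input order.
    """
    if not catalog:
        raise ValueError("catalog is empty")
    scheme = scheme or ScoringScheme()
    results = [(cid, semiglobal_align(novel_seq, cseq, scheme))
               for cid, cseq in catalog]
    top = max(r.score for _, r in results)
    return [(cid, r) for cid, r in results if r.score == top]
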