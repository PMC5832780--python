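"""Reference minimum-free-energy folding engine.

A Zuker-style dynamic program over the loop-decomposition energy model of
:mod:`.params`: V(i,j) is the best energy of the subsequence [i..j] with
(i,j) paired, with helper matrices M / M1 for multiloop decomposition and a
per-window exterior pass.  No pseudoknots; N never pairs; minimum hairpin
loop 3.

Determinism / tie-breaking: the DP minimises the lexicographic objective
(energy, -pair count), so among equal-energy structures one with the most
pairs is returned; remaining ties are resolved by a fixed traceback case
order (hairpin, then interior loops by increasing unpaired counts, then
multiloop splits left-to-right; exterior prefers leaving a base unpaired).

All matrices are banded on the span (j - i <= cap), which is what makes the
sliding-window scan cheap: V/M/M1 depend only on the subsequence [i..j], so
one fill of the banded tables serves every window of a haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .params import CompiledParams, EnergyParams, encode

INF = CompiledParams.INF


@dataclass
class FoldResult:
    """A sequence, its predicted structure, and the engine that produced it."""

    seq: str
    structure: str
    mfe: float
    engine: str

    @property
    def n_pairs(self) -> int:
        return self.structure.count("(")


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _fill_tables(codes, cap, min_loop, max_interior, ptab, stack, hairpin,
                 bulge, internal, ml_a, ml_b, ml_c):
    """Fill banded V/M/M1 (energy) and parallel pair-count tables."""
    n = codes.shape[0]
    V = np.full((n, cap + 1), INF, dtype=np.int64)
    Vp = np.zeros((n, cap + 1), dtype=np.int64)
    M = np.full((n, cap + 1), INF, dtype=np.int64)
    Mp = np.zeros((n, cap + 1), dtype=np.int64)
    M1 = np.full((n, cap + 1), INF, dtype=np.int64)
    M1p = np.zeros((n, cap + 1), dtype=np.int64)

    for d in range(1, cap + 1):
        for i in range(0, n - d):
            j = i + d
            # ----- V: (i, j) paired -------------------------------------
            pt = ptab[codes[i], codes[j]]
            if pt >= 0 and d - 1 >= min_loop:
                bE = hairpin[d - 1]
                bP = 1
                # stack / bulge / internal loop with inner pair (k, l)
                for u1 in range(0, max_interior + 1):
                    k = i + 1 + u1
                    if k >= j - 1:
                        break
                    for u2 in range(0, max_interior + 1 - u1):
                        l = j - 1 - u2
                        if l <= k:
                            break
                        vin = V[k, l - k]
                        if vin >= INF:
                            continue
                        if u1 == 0 and u2 == 0:
                            inner_rev = ptab[codes[l], codes[k]]
                            cost = stack[pt, inner_rev]
                        elif u1 == 0 or u2 == 0:
                            cost = bulge[u1 + u2]
                        else:
                            cost = internal[u1 + u2]
                        e = vin + cost
                        p = Vp[k, l - k] + 1
                        if e < bE or (e == bE and p > bP):
                            bE, bP = e, p
                # multiloop closed by (i, j): >= 2 branches inside
                for k in range(i + 2, j - 1):
                    m = M[i + 1, k - 1 - (i + 1)]
                    if m >= INF:
                        continue
                    m1 = M1[k, j - 1 - k]
                    if m1 >= INF:
                        continue
                    e = ml_a + ml_b + m + m1
                    p = Mp[i + 1, k - 1 - (i + 1)] + M1p[k, j - 1 - k] + 1
                    if e < bE or (e == bE and p > bP):
                        bE, bP = e, p
                if bE < INF:
                    V[i, d] = bE
                    Vp[i, d] = bP

            # ----- M1: one branch starting at i, trailing unpaired ------
            bE = INF
            bP = 0
            if d >= 1 and M1[i, d - 1] < INF:
                e = M1[i, d - 1] + ml_c
                p = M1p[i, d - 1]
                if e < bE or (e == bE and p > bP):
                    bE, bP = e, p
            if V[i, d] < INF:
                e = V[i, d] + ml_b
                p = Vp[i, d]
                if e < bE or (e == bE and p > bP):
                    bE, bP = e, p
            if bE < INF:
                M1[i, d] = bE
                M1p[i, d] = bP

            # ----- M: >= 1 branch, unpaired charged ml_c each -----------
            bE = INF
            bP = 0
            if M[i, d - 1] < INF:
                e = M[i, d - 1] + ml_c
                p = Mp[i, d - 1]
                if e < bE or (e == bE and p > bP):
                    bE, bP = e, p
            if M[i + 1, d - 1] < INF:
                e = M[i + 1, d - 1] + ml_c
                p = Mp[i + 1, d - 1]
                if e < bE or (e == bE and p > bP):
                    bE, bP = e, p
            if V[i, d] < INF:
                e = V[i, d] + ml_b
                p = Vp[i, d]
                if e < bE or (e == bE and p > bP):
                    bE, bP = e, p
            for k in range(i + 1, j + 1):
                left = M[i, k - 1 - i]
                if left >= INF:
                    continue
                right = M1[k, j - k]
                if right >= INF:
                    continue
                e = left + right
                p = Mp[i, k - 1 - i] + M1p[k, j - k]
                if e < bE or (e == bE and p > bP):
                    bE, bP = e, p
            if bE < INF:
                M[i, d] = bE
                Mp[i, d] = bP

    return V, Vp, M, Mp, M1, M1p

# single-base cells for M/M1 with d=0 are INF by construction (no branch of
# span 0 exists); the d-1 lookups above therefore need d >= 1, which holds.


@njit(cache=True)
def _window_energies(V, Vp, s, max_len, cap):
    """Exterior-loop DP: best (energy, pairs) for every prefix [s, s+t)."""
    We = np.zeros(max_len + 1, dtype=np.int64)
    Wp = np.zeros(max_len + 1, dtype=np.int64)
    for t in range(1, max_len + 1):
        bE = We[t - 1]
        bP = Wp[t - 1]
        for i_rel in range(0, t - 1):
            d = t - 1 - i_rel
            if d > cap:
                continue
            v = V[s + i_rel, d]
            if v >= INF:
                continue
            e = We[i_rel] + v
            p = Wp[i_rel] + Vp[s + i_rel, d]
            if e < bE or (e == bE and p > bP):
                bE, bP = e, p
        We[t] = bE
        Wp[t] = bP
    return We, Wp


@njit(cache=True)
def _nussinov_band(codes, cap, min_loop, ptab):
    """Banded maximum-pair-count (Nussinov) table; prescreen upper bound."""
    n = codes.shape[0]
    N = np.zeros((n, cap + 1), dtype=np.int64)
    for d in range(1, cap + 1):
        for i in range(0, n - d):
            j = i + d
            best = N[i + 1, d - 1]
            if N[i, d - 1] > best:
                best = N[i, d - 1]
            if d - 1 >= min_loop and ptab[codes[i], codes[j]] >= 0:
                cand = 1 + (N[i + 1, d - 2] if d >= 2 else 0)
                if cand > best:
                    best = cand
            for k in range(i + 1, j):
                cand = N[i, k - i] + N[k + 1, j - k - 1]
                if cand > best:
                    best = cand
            N[i, d] = best
    return N


# ---------------------------------------------------------------------------
# Shared-table folding interface
# ---------------------------------------------------------------------------

class FoldTables:
    """Banded DP tables for one sequence; serves any window [s, e)."""

    def __init__(self, seq: str, params: EnergyParams | None = None,
                 cap: int | None = None):
        self.seq = seq
        self.params = params or EnergyParams.default()
        n = len(seq)
        self.cap = min(cap if cap is not None else max(n - 1, 1), max(n - 1, 1))
        self.cp = self.params.compiled(max(self.cap, 3))
        self.codes = encode(seq)
        cp = self.cp
        self.V, self.Vp, self.M, self.Mp, self.M1, self.M1p = _fill_tables(
            self.codes, self.cap, cp.min_loop, cp.max_interior, cp.ptab,
            cp.stack, cp.hairpin, cp.bulge, cp.internal,
            cp.ml_a, cp.ml_b, cp.ml_c,
        )

    # -- window-level queries --------------------------------------------
    def window_mfe_profile(self, s: int, max_len: int):
        """(energy, pairs) in deci-kcal ints for all window lengths at start s."""
        max_len = min(max_len, len(self.seq) - s)
        return _window_energies(self.V, self.Vp, s, max_len, self.cap)

    def window_mfe(self, s: int, e: int) -> float:
        We, _ = self.window_mfe_profile(s, e - s)
        return We[e - s] / 10.0

    def traceback(self, s: int, e: int) -> str:
        """Deterministic optimal structure for window [s, e)."""
        cp = self.cp
        V, Vp, M, Mp, M1, M1p = self.V, self.Vp, self.M, self.Mp, self.M1, self.M1p
        codes = self.codes
        We, Wp = self.window_mfe_profile(s, e - s)
        out = ["."] * (e - s)
        tasks: list[tuple] = [("W", e - s)]
        while tasks:
            task = tasks.pop()
            kind = task[0]
            if kind == "W":
                t = task[1]
                if t == 0:
                    continue
                if We[t] == We[t - 1] and Wp[t] == Wp[t - 1]:
                    tasks.append(("W", t - 1))
                    continue
                found = False
                for i_rel in range(0, t - 1):
                    d = t - 1 - i_rel
                    if d > self.cap or V[s + i_rel, d] >= INF:
                        continue
                    if (We[i_rel] + V[s + i_rel, d] == We[t]
                            and Wp[i_rel] + Vp[s + i_rel, d] == Wp[t]):
                        tasks.append(("W", i_rel))
                        tasks.append(("V", s + i_rel, s + t - 1))
                        found = True
                        break
                if not found:  # pragma: no cover - DP consistency guard
                    raise RuntimeError("traceback failed in exterior loop")
            elif kind == "V":
                i, j = task[1], task[2]
                d = j - i
                out[i - s] = "("
                out[j - s] = ")"
                e0, p0 = V[i, d], Vp[i, d]
                pt = cp.ptab[codes[i], codes[j]]
                if (d - 1 >= cp.min_loop and cp.hairpin[d - 1] == e0
                        and p0 == 1):
                    continue
                found = False
                for u1 in range(0, cp.max_interior + 1):
                    k = i + 1 + u1
                    if k >= j - 1:
                        break
                    for u2 in range(0, cp.max_interior + 1 - u1):
                        l = j - 1 - u2
                        if l <= k:
                            break
                        if V[k, l - k] >= INF:
                            continue
                        if u1 == 0 and u2 == 0:
                            cost = cp.stack[pt, cp.ptab[codes[l], codes[k]]]
                        elif u1 == 0 or u2 == 0:
                            cost = cp.bulge[u1 + u2]
                        else:
                            cost = cp.internal[u1 + u2]
                        if (V[k, l - k] + cost == e0
                                and Vp[k, l - k] + 1 == p0):
                            tasks.append(("V", k, l))
                            found = True
                            break
                    if found:
                        break
                if found:
                    continue
                for k in range(i + 2, j - 1):
                    m = M[i + 1, k - 1 - (i + 1)]
                    m1 = M1[k, j - 1 - k]
                    if m >= INF or m1 >= INF:
                        continue
                    if (cp.ml_a + cp.ml_b + m + m1 == e0
                            and Mp[i + 1, k - 1 - (i + 1)] + M1p[k, j - 1 - k] + 1 == p0):
                        tasks.append(("M", i + 1, k - 1))
                        tasks.append(("M1", k, j - 1))
                        found = True
                        break
                if not found:  # pragma: no cover
                    raise RuntimeError(f"traceback failed at V({i},{j})")
            elif kind == "M":
                i, j = task[1], task[2]
                d = j - i
                e0, p0 = M[i, d], Mp[i, d]
                if d >= 1 and M[i, d - 1] < INF and M[i, d - 1] + cp.ml_c == e0 \
                        and Mp[i, d - 1] == p0:
                    tasks.append(("M", i, j - 1))
                    continue
                if d >= 1 and M[i + 1, d - 1] < INF \
                        and M[i + 1, d - 1] + cp.ml_c == e0 \
                        and Mp[i + 1, d - 1] == p0:
                    tasks.append(("M", i + 1, j))
                    continue
                if V[i, d] < INF and V[i, d] + cp.ml_b == e0 and Vp[i, d] == p0:
                    tasks.append(("V", i, j))
                    continue
                found = False
                for k in range(i + 1, j + 1):
                    left, right = M[i, k - 1 - i], M1[k, j - k]
                    if left >= INF or right >= INF:
                        continue
                    if left + right == e0 and Mp[i, k - 1 - i] + M1p[k, j - k] == p0:
                        tasks.append(("M", i, k - 1))
                        tasks.append(("M1", k, j))
                        found = True
                        break
                if not found:  # pragma: no cover
                    raise RuntimeError(f"traceback failed at M({i},{j})")
            else:  # M1
                i, j = task[1], task[2]
                d = j - i
                e0, p0 = M1[i, d], M1p[i, d]
                if d >= 1 and M1[i, d - 1] < INF \
                        and M1[i, d - 1] + cp.ml_c == e0 and M1p[i, d - 1] == p0:
                    tasks.append(("M1", i, j - 1))
                    continue
                if V[i, d] < INF and V[i, d] + cp.ml_b == e0 and Vp[i, d] == p0:
                    tasks.append(("V", i, j))
                    continue
                raise RuntimeError(f"traceback failed at M1({i},{j})")  # pragma: no cover
        return "".join(out)

    def fold_window(self, s: int, e: int, engine_name: str = "reference") -> FoldResult:
        mfe = self.window_mfe(s, e)
        structure = self.traceback(s, e)
        return FoldResult(self.seq[s:e], structure, mfe, engine_name)

    def nussinov(self):
        cp = self.cp
        return _nussinov_band(self.codes, self.cap, cp.min_loop, cp.ptab)


def fold_mfe(seq: str, params: EnergyParams | None = None,
             engine: str = "reference") -> FoldResult:
    """Fold one sequence and return its MFE structure.

    ``engine`` selects the self-contained reference DP (``"reference"``) or
    the external folder adapter (``"vienna"``/``"external"``).
    """
    if not seq:
        raise ValueError("cannot fold an empty sequence")
    if engine == "reference":
        tables = FoldTables(seq, params)
        return tables.fold_window(0, len(seq))
    if engine in ("vienna", "external"):
        from .vienna import fold_vienna
        return fold_vienna(seq)
    raise ValueError(f"unknown folding engine {engine!r}")
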