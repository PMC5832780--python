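"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive (enumeration, per-base masks,
recursion) and shares no code path with the implementations it checks.
"""

from __future__ import annotations

from functools import lru_cache


# ---------------------------------------------------------------------------
# structure enumeration (folding oracle)
# ---------------------------------------------------------------------------

def enumerate_structures(n: int, min_loop: int = 3) -> list[str]:
    """All pseudoknot-free dot-bracket strings of length n (hairpin >= min_loop)."""

    @lru_cache(maxsize=None)
    def gen(length: int) -> tuple[str, ...]:
        if length <= 0:
            return ("",)
        out = []
        for rest in gen(length - 1):
            out.append("." + rest)
        # first position paired with position k (0-based), k >= min_loop + 1
        for k in range(min_loop + 1, length):
            for inner in gen(k - 1):
                for rest in gen(length - k - 1):
                    out.append("(" + inner + ")" + rest)
        return tuple(out)

    return list(gen(n))


def brute_force_mfe(seq: str, score_fn) -> tuple[float, int]:
    """(lowest energy, max pairs among minima) over all enumerable structures.

    ``score_fn(structure) -> float`` must raise ValueError for structures
    the model cannot score (non-canonical pairs); those are skipped.
    """
    best = 0.0
    best_pairs = 0
    for st in enumerate_structures(len(seq)):
        if "(" not in st:
            e, p = 0.0, 0
        else:
            try:
                e = score_fn(st)
            except ValueError:
                continue
            p = st.count("(")
        if e < best or (e == best and p > best_pairs):
            best, best_pairs = e, p
    return best, best_pairs


# ---------------------------------------------------------------------------
# recursive loop decomposition (topology oracle)
# ---------------------------------------------------------------------------

def stack_pair_table(structure: str) -> list[int | None]:
    """Push/pop pairing oracle."""
    out: list[int | None] = [None] * len(structure)
    stack = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            out[i], out[j] = j, i
    return out


def recursive_loop_counts(structure: str) -> dict[str, int]:
    """Count loop classes by plain recursion over enclosed regions."""
    table = stack_pair_table(structure)
    counts = {"hairpin": 0, "bulge": 0, "internal": 0, "multi": 0, "stack": 0}

    def branches_in(lo: int, hi: int) -> list[tuple[int, int]]:
        res = []
        k = lo
        while k <= hi:
            if table[k] is not None and table[k] > k:
                res.append((k, table[k]))
                k = table[k] + 1
            else:
                k += 1
        return res

    def visit(i: int, j: int) -> None:
        kids = branches_in(i + 1, j - 1)
        if not kids:
            counts["hairpin"] += 1
        elif len(kids) == 1:
            (k, l) = kids[0]
            left, right = k - i - 1, j - l - 1
            if left == 0 and right == 0:
                counts["stack"] += 1
            elif left == 0 or right == 0:
                counts["bulge"] += 1
            else:
                counts["internal"] += 1
        else:
            counts["multi"] += 1
        for (k, l) in kids:
            visit(k, l)

    for (k, l) in branches_in(0, len(structure) - 1):
        visit(k, l)
    return counts


def random_balanced_structure(n: int, rng, p_open: float = 0.3,
                              min_loop: int = 3) -> str:
    """A random balanced dot-bracket string with legal hairpin sizes."""
    while True:
        chars = []
        open_stack: list[int] = []
        for i in range(n):
            r = rng.random()
            can_close = open_stack and (i - open_stack[-1] - 1) >= min_loop
            if r < p_open and (n - i) > len(open_stack) + min_loop + 1:
                open_stack.append(i)
                chars.append("(")
            elif can_close and r < 0.6:
                open_stack.pop()
                chars.append(")")
            else:
                chars.append(".")
        if not open_stack:
            return "".join(chars)


# ---------------------------------------------------------------------------
# exhaustive alignment enumeration (homology oracle)
# ---------------------------------------------------------------------------

def enumerate_alignments(a: str, b: str):
    """All global alignments (as aligned string pairs) of two short strings."""
    out = []

    def rec(i: int, j: int, ra: str, rb: str) -> None:
        if i == len(a) and j == len(b):
            out.append((ra, rb))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, ra + a[i], rb + b[j])
        if i < len(a):
            rec(i + 1, j, ra + a[i], rb + "-")
        if j < len(b):
            rec(i, j + 1, ra + "-", rb + b[j])
    rec(0, 0, "", "")
    return out


def best_semiglobal_score(a: str, b: str, match=5.0, mismatch=-4.0,
                          gap=8.0) -> float:
    """Max semi-global score by scoring every enumerated alignment.

    Terminal gap runs (on either end of either sequence) are free.
    """
    a = a.upper().replace("T", "U")
    b = b.upper().replace("T", "U")

    def gap_type(ca: str, cb: str) -> int:
        # 0 = substitution column, 1 = gap in b, 2 = gap in a
        if ca == "-":
            return 2
        if cb == "-":
            return 1
        return 0

    best = None
    for ra, rb in enumerate_alignments(a, b):
        n = len(ra)
        # a free terminal run must be a uniform gap type on one end (an
        # alignment path enters/leaves the DP matrix on one edge only)
        lo = 0
        t0 = gap_type(ra[0], rb[0])
        if t0:
            while lo < n and gap_type(ra[lo], rb[lo]) == t0:
                lo += 1
        hi = n
        if hi > lo:
            t1 = gap_type(ra[-1], rb[-1])
            if t1:
                while hi > lo and gap_type(ra[hi - 1], rb[hi - 1]) == t1:
                    hi -= 1
        score = 0.0
        for k in range(lo, hi):
            if ra[k] == "-" or rb[k] == "-":
                score -= gap
            elif ra[k] == rb[k]:
                score += match
            else:
                score += mismatch
        if best is None or score > best:
            best = score
    return best


# ---------------------------------------------------------------------------
# per-base mask union (interval oracle)
# ---------------------------------------------------------------------------

def mask_union(intervals, size: int):
    """Boolean per-base coverage mask of [0, size)."""
    mask = [False] * size
    for iv in intervals:
        for p in range(iv.start, min(iv.end, size)):
            mask[p] = True
    return mask


def mask_to_intervals(mask) -> list[tuple[int, int]]:
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(mask)))
    return out
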