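"""Dot-bracket parsing and standard loop decomposition.

For each closing pair, the enclosed branch count k and the unpaired runs
determine the loop class: k=0 is a hairpin loop; k=1 with unpaired bases on
exactly one side is a bulge; k=1 with unpaired bases on both sides is an
internal loop (k=1 with none is a stacked pair); k>=2 is a multiloop.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class StructureError(ValueError):
    """Unbalanced or illegal dot-bracket string."""


def pair_table(structure: str) -> list[int | None]:
    """Map each position to its pairing partner (None when unpaired).

    Raises :class:`StructureError` with the first offending index for an
    unbalanced or illegal character.
    """
    stack: list[int] = []
    table: list[int | None] = [None] * len(structure)
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unmatched ')' at index {i}")
            j = stack.pop()
            table[i], table[j] = j, i
        elif ch != ".":
            raise StructureError(f"illegal character {ch!r} at index {i}")
    if stack:
        raise StructureError(f"unmatched '(' at index {stack[-1]}")
    return table


@dataclass
class Loop:
    kind: str            # hairpin | stack | bulge | internal | multi | exterior
    closing: tuple[int, int] | None
    branches: list[tuple[int, int]]
    unpaired: int


@dataclass
class Topology:
    """Loop-decomposition summary of a dot-bracket structure."""

    n_hairpin_loops: int
    n_bulges: int
    n_internal_loops: int
    n_multiloops: int
    n_pairs: int
    is_linear_hairpin: bool
    loops: list[Loop] = field(default_factory=list, repr=False)


def _children(table: list[int | None], i: int, j: int) -> tuple[list[tuple[int, int]], int]:
    """Branches directly enclosed by (i, j) and the unpaired count between them."""
    branches: list[tuple[int, int]] = []
    unpaired = 0
    k = i + 1
    while k < j:
        p = table[k]
        if p is None:
            unpaired += 1
            k += 1
        else:
            branches.append((k, p))
            k = p + 1
    return branches, unpaired


def classify_topology(structure: str) -> Topology:
    """Standard loop decomposition of a balanced dot-bracket string.

    ``is_linear_hairpin`` is True for the characteristic pre-miRNA shape:
    exactly one hairpin loop, no multiloop and no bulge (internal loops are
    permitted; stricter settings are applied by the scanner's filter flags).
    """
    table = pair_table(structure)
    n = len(structure)

    loops: list[Loop] = []
    n_hp = n_bulge = n_int = n_multi = 0

    ext_branches, ext_unpaired = _children(table, -1, n)
    loops.append(Loop("exterior", None, ext_branches, ext_unpaired))

    n_pairs = sum(1 for p in table if p is not None) // 2
    for i, p in enumerate(table):
        if p is None or p < i:
            continue
        j = p
        branches, unpaired = _children(table, i, j)
        if len(branches) == 0:
            kind = "hairpin"
            n_hp += 1
        elif len(branches) == 1:
            (k, l) = branches[0]
            left, right = k - i - 1, j - l - 1
            if left == 0 and right == 0:
                kind = "stack"
            elif left == 0 or right == 0:
                kind = "bulge"
                n_bulge += 1
            else:
                kind = "internal"
                n_int += 1
        else:
            kind = "multi"
            n_multi += 1
        loops.append(Loop(kind, (i, j), branches, unpaired))

    linear = n_hp == 1 and n_multi == 0 and n_bulge == 0
    return Topology(
        n_hairpin_loops=n_hp,
        n_bulges=n_bulge,
        n_internal_loops=n_int,
        n_multiloops=n_multi,
        n_pairs=n_pairs,
        is_linear_hairpin=linear,
        loops=loops,
    )
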