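"""Nearest-neighbour energy parameters for the reference folding engine.

The model is the standard loop-decomposition free-energy model at 37 °C:
the energy of a (pseudoknot-free) structure is the sum, over every closing
base pair, of the energy of the loop that pair closes —

* stacked pair            : tabulated pair-on-pair stacking free energy,
* hairpin loop            : size-dependent initiation penalty,
* bulge loop              : size-dependent initiation penalty,
* internal loop           : size-dependent initiation penalty (size = total
                            unpaired on both sides; no asymmetry term),
* multiloop (k >= 2 arms) : affine penalty a + b*(k+1) + c*unpaired.

Loop penalties beyond the tabulated sizes are extrapolated with the usual
Jacobson-Stockmayer term  1.75 * RT * ln(size / size_max).  Energies are
stored internally as integers in units of 0.1 kcal/mol (deci-kcal), which
keeps the dynamic program exact.

The stacking values are the widely published nearest-neighbour RNA stacking
free energies; loop initiations are rounded versions of the standard
tables.  They live in this one module (and can be overridden from a YAML
file) precisely so users can swap parameter sets; no claim is made that the
reference engine reproduces any particular external folder's energies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

RT_37 = 0.616  # kcal/mol at 37 degC

#: base codes used throughout the engine
BASES = "ACGU"
N_CODE = 4

#: canonical pair codes (order matters: indexes the stacking matrix)
PAIR_ORDER = ("CG", "GC", "GU", "UG", "AU", "UA")

# Pair-on-pair stacking free energies, kcal/mol.  Entry [p][q] is read with
# p = the outer (closing) pair 5'a...b3' and q = the *reversed* inner pair
# (d, c) for inner pair c-d; with that convention the matrix is symmetric.
_STACK = {
    "CG": {"CG": -2.4, "GC": -3.3, "GU": -2.1, "UG": -1.4, "AU": -2.1, "UA": -2.1},
    "GC": {"CG": -3.3, "GC": -3.4, "GU": -2.5, "UG": -1.5, "AU": -2.2, "UA": -2.4},
    "GU": {"CG": -2.1, "GC": -2.5, "GU": 1.3, "UG": -0.5, "AU": -1.4, "UA": -1.3},
    "UG": {"CG": -1.4, "GC": -1.5, "GU": -0.5, "UG": 0.3, "AU": -0.6, "UA": -1.0},
    "AU": {"CG": -2.1, "GC": -2.2, "GU": -1.4, "UG": -0.6, "AU": -1.1, "UA": -0.9},
    "UA": {"CG": -2.1, "GC": -2.4, "GU": -1.3, "UG": -1.0, "AU": -0.9, "UA": -1.3},
}

_HAIRPIN = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
_BULGE = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
_INTERNAL = {2: 1.5, 3: 1.6, 4: 1.7, 5: 1.8, 6: 2.0}


@dataclass
class EnergyParams:
    """Tunable parameter set of the reference engine (kcal/mol)."""

    stack: dict = field(default_factory=lambda: {
        p: dict(q) for p, q in _STACK.items()
    })
    hairpin_init: dict = field(default_factory=lambda: dict(_HAIRPIN))
    bulge_init: dict = field(default_factory=lambda: dict(_BULGE))
    internal_init: dict = field(default_factory=lambda: dict(_INTERNAL))
    multiloop_offset: float = 3.4
    multiloop_per_branch: float = 0.4
    multiloop_per_unpaired: float = 0.0
    min_hairpin_loop: int = 3
    max_interior_unpaired: int = 30

    def __post_init__(self) -> None:
        if self.min_hairpin_loop < 3:
            raise ValueError("min_hairpin_loop must be >= 3")
        for tbl in (self.hairpin_init, self.bulge_init, self.internal_init):
            if any(v < 0 for v in tbl.values()):
                raise ValueError("loop initiation penalties must be >= 0")
        for p in ("CG", "GC", "AU", "UA"):
            for q in ("CG", "GC", "AU", "UA"):
                if self.stack[p][q] > 0:
                    raise ValueError(
                        f"canonical stack {p}/{q} must be <= 0 kcal/mol"
                    )

    # -- serialisation ----------------------------------------------------
    @classmethod
    def default(cls) -> "EnergyParams":
        return cls()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EnergyParams":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "stack": self.stack,
            "hairpin_init": self.hairpin_init,
            "bulge_init": self.bulge_init,
            "internal_init": self.internal_init,
            "multiloop_offset": self.multiloop_offset,
            "multiloop_per_branch": self.multiloop_per_branch,
            "multiloop_per_unpaired": self.multiloop_per_unpaired,
            "min_hairpin_loop": self.min_hairpin_loop,
            "max_interior_unpaired": self.max_interior_unpaired,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    # -- derived quantities ----------------------------------------------
    @property
    def min_stack(self) -> float:
        """Most favourable (most negative) single stacking energy."""
        return min(min(row.values()) for row in self.stack.values())

    @property
    def min_hairpin_init(self) -> float:
        return min(self.hairpin_init.values())

    def conservative_pair_threshold(self, mfe_cutoff: float) -> int:
        """Smallest pair count any structure below ``mfe_cutoff`` can have.

        Every loop energy in the model is >= ``min_stack`` and any structure
        with at least one pair contains a hairpin loop costing at least
        ``min_hairpin_init``, so  E >= min_hairpin_init + (n_pairs - 1) *
        min_stack.  Solving E < cutoff for n_pairs gives a bound that a
        maximum-pairing (Nussinov) pre-screen may safely enforce: a window
        whose maximum possible pair count is below it can never fold below
        the cutoff.
        """
        need = (-mfe_cutoff + self.min_hairpin_init) / (-self.min_stack)
        return int(math.floor(need)) + 1 + 1  # strict inequality, +closing

    def compiled(self, max_size: int) -> "CompiledParams":
        return CompiledParams(self, max_size)


def _extrapolate(table: dict[int, float], size: int) -> float:
    mx = max(table)
    if size <= mx:
        return table[size] if size in table else math.inf
    return table[mx] + 1.75 * RT_37 * math.log(size / mx)


class CompiledParams:
    """Integer (deci-kcal) numpy views of an EnergyParams, for the DP kernels."""

    INF = 10 ** 7

    def __init__(self, params: EnergyParams, max_size: int):
        self.params = params
        self.min_loop = params.min_hairpin_loop
        self.max_interior = params.max_interior_unpaired
        self.ml_a = round(params.multiloop_offset * 10)
        self.ml_b = round(params.multiloop_per_branch * 10)
        self.ml_c = round(params.multiloop_per_unpaired * 10)

        # pair-type lookup: ptab[a,b] = pair code or -1
        self.ptab = np.full((5, 5), -1, dtype=np.int64)
        for idx, pq in enumerate(PAIR_ORDER):
            a, b = BASES.index(pq[0]), BASES.index(pq[1])
            self.ptab[a, b] = idx

        self.stack = np.full((6, 6), self.INF, dtype=np.int64)
        for i, p in enumerate(PAIR_ORDER):
            for j, q in enumerate(PAIR_ORDER):
                self.stack[i, j] = round(params.stack[p][q] * 10)

        size = max(max_size, 3)
        self.hairpin = np.full(size + 1, self.INF, dtype=np.int64)
        for u in range(self.min_loop, size + 1):
            self.hairpin[u] = round(_extrapolate(params.hairpin_init, u) * 10)
        self.bulge = np.full(size + 1, self.INF, dtype=np.int64)
        for u in range(1, size + 1):
            self.bulge[u] = round(_extrapolate(params.bulge_init, u) * 10)
        self.internal = np.full(size + 1, self.INF, dtype=np.int64)
        for u in range(2, size + 1):
            self.internal[u] = round(_extrapolate(params.internal_init, u) * 10)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA/RNA string as base codes (A=0, C=1, G=2, U/T=3, N=4)."""
    out = np.empty(len(seq), dtype=np.int64)
    up = seq.upper()
    for i, ch in enumerate(up):
        if ch in ("T", "U"):
            out[i] = 3
        elif ch == "A":
            out[i] = 0
        elif ch == "C":
            out[i] = 1
        elif ch == "G":
            out[i] = 2
        elif ch == "N":
            out[i] = N_CODE
        else:
            raise ValueError(f"illegal nucleotide {ch!r} at position {i}")
    return out
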