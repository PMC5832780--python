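"""Standalone loop-decomposition scoring of a given structure.

Independent of the dynamic program: decomposes the dot-bracket string into
loops and sums the model energies.  Used both to annotate arbitrary
structures and, in the test suite, to verify that the engine's reported MFE
equals the energy of the structure it returns.
"""

from __future__ import annotations

from .params import EnergyParams, encode
from .topology import classify_topology


def score_structure(seq: str, structure: str,
                    params: EnergyParams | None = None) -> float:
    """Free energy (kcal/mol) of ``structure`` on ``seq`` under the model.

    Raises ValueError if the structure pairs bases the model cannot pair
    (non-canonical pair, a pair involving N, or a hairpin loop shorter than
    the model minimum).
    """
    if len(seq) != len(structure):
        raise ValueError("sequence and structure lengths differ")
    params = params or EnergyParams.default()
    # compiled tables are cached per parameter object (size rounded up)
    size = max(len(seq), 3)
    cache = getattr(params, "_compiled_cache", None)
    if cache is None or cache.hairpin.shape[0] <= size:
        cache = params.compiled(max(size, 256))
        params._compiled_cache = cache
    cp = cache
    codes = encode(seq)
    topo = classify_topology(structure)

    total = 0  # deci-kcal
    for loop in topo.loops:
        if loop.closing is None:
            continue  # exterior loop is free
        i, j = loop.closing
        pt = cp.ptab[codes[i], codes[j]]
        if pt < 0:
            raise ValueError(f"pair ({i},{j}) is not pairable under the model")
        if loop.kind == "hairpin":
            u = j - i - 1
            if u < cp.min_loop:
                raise ValueError(f"hairpin loop at ({i},{j}) below minimum size")
            total += int(cp.hairpin[u])
        elif loop.kind == "stack":
            k, l = loop.branches[0]
            inner_rev = cp.ptab[codes[l], codes[k]]
            if inner_rev < 0:
                raise ValueError(f"pair ({k},{l}) is not pairable under the model")
            total += int(cp.stack[pt, inner_rev])
        elif loop.kind == "bulge":
            total += int(cp.bulge[loop.unpaired])
        elif loop.kind == "internal":
            total += int(cp.internal[loop.unpaired])
        else:  # multi
            k = len(loop.branches)
            total += cp.ml_a + cp.ml_b * (k + 1) + cp.ml_c * loop.unpaired
    return total / 10.0
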