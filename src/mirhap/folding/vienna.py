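"""Adapter for the external ``RNAfold`` executable.

Runs the tool at its defaults (37 °C) in batch mode over stdin.  This is
the engine used to reproduce published MFE values; it is optional, and the
rest of the package is fully functional without it.
"""

from __future__ import annotations

import re
import shutil
import subprocess

from .engine import FoldResult

_OUT_RE = re.compile(r"^([().]+)\s+\(\s*(-?\d+(?:\.\d+)?)\)\s*$")


def vienna_available() -> bool:
    return shutil.which("RNAfold") is not None


def fold_vienna_many(seqs: list[str]) -> list[FoldResult]:
    """Fold many sequences with one RNAfold process."""
    if not vienna_available():
        raise FileNotFoundError(
            "RNAfold executable not found on PATH; the external engine is "
            "unavailable (use engine='reference')"
        )
    rna = [s.upper().replace("T", "U") for s in seqs]
    proc = subprocess.run(
        ["RNAfold", "--noPS"],
        input="\n".join(rna) + "\n",
        capture_output=True,
        text=True,
        check=True,
    )
    lines = [ln for ln in proc.stdout.splitlines() if ln.strip()]
    results: list[FoldResult] = []
    for idx, seq in enumerate(seqs):
        m = _OUT_RE.match(lines[2 * idx + 1])
        if m is None:
            raise RuntimeError(
                f"unparseable RNAfold output line: {lines[2 * idx + 1]!r}"
            )
        results.append(FoldResult(seq, m.group(1), float(m.group(2)), "vienna"))
    return results


def fold_vienna(seq: str) -> FoldResult:
    return fold_vienna_many([seq])[0]
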