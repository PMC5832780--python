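"""Trainable hairpin-candidate classifier (funnel stage 5).

Stands in for the published boosting tool with the same stage contract:
train on labelled hairpin windows, score candidates in [0, 1], keep at a
threshold.  Features are computed from sequence + predicted structure only,
so scores are invariant to genomic coordinates.  An adapter seam
(:func:`export_candidates` / :func:`import_scores`) lets an external
classifier replace the built-in model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import cross_val_score

from .folding.topology import classify_topology, pair_table
from .scanner import HairpinWindow

_DINUCS = [a + b for a in "ACGT" for b in "ACGT"]

#: documented feature order
FEATURE_NAMES: list[str] = [
    "length",
    "gc_fraction",
    "mfe",
    "mfe_per_nt",
    "n_pairs",
    "pairing_fraction",
    "longest_helix",
    "terminal_loop_size",
    "stem_asymmetry",
] + [f"dinuc_{d}" for d in _DINUCS]


def _longest_helix(structure: str) -> int:
    """Longest run of directly stacked pairs."""
    table = pair_table(structure)
    best = run = 0
    prev = None
    for i, p in enumerate(table):
        if p is not None and p > i:
            if prev is not None and prev == (i - 1, p + 1):
                run += 1
            else:
                run = 1
            prev = (i, p)
            best = max(best, run)
    return best


def extract_features(window: HairpinWindow) -> np.ndarray:
    """Deterministic numeric feature vector (order = FEATURE_NAMES)."""
    seq = window.seq.upper().replace("U", "T")
    n = len(seq)
    structure = window.fold.structure
    topo = window.topology if window.topology is not None \
        else classify_topology(structure)
    gc = (seq.count("G") + seq.count("C")) / n
    n_pairs = topo.n_pairs
    # terminal loop: size of the (first) hairpin loop, 0 if none
    term = 0
    for loop in topo.loops:
        if loop.kind == "hairpin":
            term = loop.unpaired
            break
    # unpaired excess of the 5' arm vs the 3' arm around the first hairpin loop
    table = pair_table(structure)
    paired_pos = [i for i, p in enumerate(table) if p is not None]
    if paired_pos:
        mid = (paired_pos[0] + paired_pos[-1]) // 2
        up5 = sum(1 for i in range(paired_pos[0], mid + 1) if table[i] is None)
        up3 = sum(1 for i in range(mid + 1, paired_pos[-1] + 1) if table[i] is None)
        asym = abs(up5 - up3)
    else:
        asym = 0
    counts = {d: 0 for d in _DINUCS}
    for i in range(n - 1):
        d = seq[i : i + 2]
        if d in counts:
            counts[d] += 1
    denom = max(n - 1, 1)
    vec = [
        float(n),
        gc,
        window.fold.mfe,
        window.fold.mfe / n,
        float(n_pairs),
        2.0 * n_pairs / n,
        float(_longest_helix(structure)),
        float(term),
        float(asym),
    ] + [counts[d] / denom for d in _DINUCS]
    return np.asarray(vec, dtype=float)


def feature_matrix(windows: list[HairpinWindow]) -> np.ndarray:
    if not windows:
        return np.empty((0, len(FEATURE_NAMES)))
    return np.vstack([extract_features(w) for w in windows])


@dataclass
class TriageModel:
    """A fitted candidate classifier plus its decision threshold."""

    kind: str
    estimator: object
    threshold: float = 0.5
    n_pos: int = 0
    n_neg: int = 0
    seed: int = 0
    cv_accuracy: float | None = None
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))
    version: str = "1"

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "TriageModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise ValueError(f"{path} does not contain a TriageModel")
        return model


def train_triage(
    pos: list[HairpinWindow],
    neg: list[HairpinWindow],
    seed: int = 0,
    threshold: float = 0.5,
    cv_folds: int = 5,
) -> TriageModel:
    """Fit the candidate classifier on labelled windows.

    Requires >=10 examples per class; reports stratified cross-validated
    accuracy; reproducible for a fixed seed.
    """
    if len(pos) < 10 or len(neg) < 10:
        raise ValueError("need at least 10 positive and 10 negative windows")
    X = np.vstack([feature_matrix(pos), feature_matrix(neg)])
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    if len(np.unique(y)) < 2:  # pragma: no cover - guarded above
        raise ValueError("degenerate single-class training input")
    est = GradientBoostingClassifier(random_state=seed)
    cv = float(np.mean(cross_val_score(est, X, y, cv=cv_folds)))
    est.fit(X, y)
    return TriageModel(
        kind="gradient_boosting",
        estimator=est,
        threshold=threshold,
        n_pos=len(pos),
        n_neg=len(neg),
        seed=seed,
        cv_accuracy=cv,
    )


def apply_triage(
    model: TriageModel, candidates: list[HairpinWindow]
) -> list[HairpinWindow]:
    """Annotate candidates with scores; keep those at or above the threshold.

    Returns the kept windows; every input window gets ``triage_score`` and
    ``passed_filters`` set.  A threshold of 0 keeps everything.
    """
    if not candidates:
        return []
    if model.feature_names != FEATURE_NAMES:
        raise ValueError("triage model feature schema does not match")
    X = feature_matrix(candidates)
    scores = model.estimator.predict_proba(X)[:, 1]
    kept = []
    for w, s in zip(candidates, scores):
        w.triage_score = float(s)
        w.passed_filters = bool(s >= model.threshold)
        if w.passed_filters:
            kept.append(w)
    return kept


# ---------------------------------------------------------------------------
# adapter seam for an external classifier
# ---------------------------------------------------------------------------

def export_candidates(candidates: list[HairpinWindow], path: str | Path) -> None:
    """Write candidates as TSV (id, interval, seq, structure, mfe) for an
    external classifier."""
    with open(path, "w") as fh:
        fh.write("id\tchrom\tstart\tend\tstrand\tseq\tstructure\tmfe\n")
        for i, w in enumerate(candidates):
            iv = w.interval
            fh.write(
                f"w{i}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t"
                f"{w.seq}\t{w.fold.structure}\t{w.fold.mfe}\n"
            )


def import_scores(
    candidates: list[HairpinWindow], path: str | Path, threshold: float = 0.5
) -> list[HairpinWindow]:
    """Attach externally computed scores (TSV: id<TAB>score, ids as exported)."""
    scores: dict[int, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("id"):
                continue
            wid, score = line.split("\t")[:2]
            scores[int(wid.lstrip("w"))] = float(score)
    kept = []
    for i, w in enumerate(candidates):
        w.triage_score = scores.get(i)
        w.passed_filters = w.triage_score is not None and w.triage_score >= threshold
        if w.passed_filters:
            kept.append(w)
    return kept
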