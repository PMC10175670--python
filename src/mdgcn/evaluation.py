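"""Cross-validation folds, metrics, and fold aggregation.

Known positive associations are shuffled and partitioned into k
near-equal test parts; negatives are sampled uniformly without
replacement from the zero cells, disjoint between the train and test
roles, at a 1:1 ratio with the positives of each role.

Metrics per fold: AUC (rank statistic with tie correction), AUPR (step
interpolation, i.e. average precision), and thresholded MCC, F1 and
Precision at 0.5 on the sigmoid scores. Precision is reported as
TP / (TP + FP); recall is reported alongside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    f1_score,
    matthews_corrcoef,
    precision_score,
    recall_score,
    roc_auc_score,
)

from .types import AssociationMatrix, FoldReport

__all__ = [
    "FoldSplit",
    "CVSummary",
    "make_folds",
    "compute_metrics",
    "aggregate",
    "rank_candidates",
]

METRICS = ("auc", "aupr", "mcc", "f1", "precision", "recall")


@dataclass
class FoldSplit:
    """Index pairs for one fold; all arrays are (k, 2) of (m_idx, d_idx)."""

    fold_index: int
    train_pos: np.ndarray
    test_pos: np.ndarray
    train_neg: np.ndarray
    test_neg: np.ndarray
    seed: int


@dataclass
class CVSummary:
    """Per-fold reports plus per-metric aggregates."""

    folds: list[FoldReport]
    mean: dict[str, float]
    sd_sample: dict[str, float]
    sd_population: dict[str, float]
    provenance: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "folds": [f.as_dict() for f in self.folds],
            "mean": self.mean,
            "sd_sample": self.sd_sample,
            "sd_population": self.sd_population,
            "provenance": self.provenance,
        }


def make_folds(a: AssociationMatrix, k: int, seed: int) -> list[FoldSplit]:
    """k-fold split of the positives with balanced negative sampling.

    Test positives partition the positive set; each fold draws
    ``|test_pos| + |train_pos|`` distinct negatives (zero cells) and
    assigns them disjointly to the test and train roles.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    pos = a.positive_pairs()
    n_pos = len(pos)
    if n_pos < k:
        raise ValueError(f"cannot make {k} folds from {n_pos} positives")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_pos)
    parts = np.array_split(order, k)

    zero_rows, zero_cols = np.nonzero(a.values == 0)
    zeros = np.column_stack([zero_rows, zero_cols]).astype(np.int64)

    folds = []
    for i, part in enumerate(parts):
        test_mask = np.zeros(n_pos, dtype=bool)
        test_mask[part] = True
        test_pos = pos[test_mask]
        train_pos = pos[~test_mask]
        need = len(test_pos) + len(train_pos)
        if need > len(zeros):
            raise ValueError("not enough zero cells for balanced negative sampling")
        pick = rng.choice(len(zeros), size=need, replace=False)
        neg = zeros[pick]
        folds.append(
            FoldSplit(
                fold_index=i,
                train_pos=train_pos,
                test_pos=test_pos,
                train_neg=neg[len(test_pos):],
                test_neg=neg[: len(test_pos)],
                seed=seed,
            )
        )
    return folds


def compute_metrics(scores, labels, threshold: float = 0.5) -> FoldReport:
    """Full metric bundle on a scored pair set."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present for AUC/AUPR")
    pred = (scores >= threshold).astype(int)
    return FoldReport(
        auc=float(roc_auc_score(labels, scores)),
        aupr=float(average_precision_score(labels, scores)),
        mcc=float(matthews_corrcoef(labels, pred)),
        f1=float(f1_score(labels, pred, zero_division=0)),
        precision=float(precision_score(labels, pred, zero_division=0)),
        recall=float(recall_score(labels, pred, zero_division=0)),
    )


def aggregate(reports: list[FoldReport]) -> CVSummary:
    """Arithmetic mean plus sample and population SD for every metric."""
    if not reports:
        raise ValueError("need at least one fold report")
    mean, sd_s, sd_p = {}, {}, {}
    for m in METRICS:
        vals = np.array([getattr(r, m) for r in reports], dtype=float)
        mean[m] = float(vals.mean())
        sd_p[m] = float(vals.std(ddof=0))
        sd_s[m] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return CVSummary(folds=list(reports), mean=mean, sd_sample=sd_s, sd_population=sd_p)


def rank_candidates(
    score_matrix: np.ndarray,
    a: AssociationMatrix,
    anchor: str,
    candidates,
    top_k: int | None = None,
    threshold: float = 0.5,
) -> list[dict]:
    """Rank candidate partners of one anchor node by predicted score.

    ``anchor`` may be a miRNA id (candidates are diseases) or a disease
    id (candidates are miRNAs). Returns descending-score records with a
    thresholded verdict; ties break on candidate id for determinism.
    """
    candidates = [str(c) for c in candidates]
    if anchor in a.mirna_ids:
        i = a.mirna_index(anchor)
        scores = {c: float(score_matrix[i, a.disease_index(c)]) for c in candidates}
    elif anchor in a.disease_ids:
        j = a.disease_index(anchor)
        scores = {c: float(score_matrix[a.mirna_index(c), j]) for c in candidates}
    else:
        raise KeyError(f"unknown anchor id: {anchor!r}")
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_k is not None:
        ranked = ranked[:top_k]
    return [
        {"id": c, "score": s, "predicted": int(s >= threshold)} for c, s in ranked
    ]
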