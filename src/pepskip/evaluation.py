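"""Performance evaluation: SE/SP/ACC/MCC, jackknife and k-fold validation,
ROC/AUC, and the tree-count sweep.

The four metrics follow the usual binary-predictor definitions:

    SE  = TP / (TP + FN) * 100
    SP  = TN / (TN + FP) * 100
    ACC = (TP + TN) / (TP + TN + FP + FN) * 100
    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))

SE/SP/ACC are percentages; MCC lives on [-1, 1]. Cross-validated metrics
are pooled: held-out predictions from all folds are merged into a single
confusion matrix before scoring. Pooling is the only coherent choice for
the jackknife (leave-one-out) protocol, whose folds contain one sample
each, and it is applied uniformly so that the jackknife is exactly k-fold
with k equal to the dataset size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .dataset import LabeledDataset
from .features import SkipGramConfig, featurize_dataset
from .model import DEFAULT_TREES, ForestModel

#: Default tree-count sweep: 10, 20, ..., 500.
DEFAULT_SWEEP: tuple[int, ...] = tuple(range(10, 501, 10))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, truth: Sequence[int],
                         predicted: Sequence[int]) -> "ConfusionCounts":
        t = np.asarray(list(truth), dtype=int)
        p = np.asarray(list(predicted), dtype=int)
        if t.shape != p.shape:
            raise ValueError("truth and prediction lengths differ")
        return cls(
            tp=int(np.sum((t == 1) & (p == 1))),
            tn=int(np.sum((t == 0) & (p == 0))),
            fp=int(np.sum((t == 0) & (p == 1))),
            fn=int(np.sum((t == 1) & (p == 0))),
        )


@dataclass
class MetricsReport:
    """SE/SP/ACC as percentages, MCC on [-1, 1], optional AUC on [0, 1].

    ``se``/``sp`` are None when the corresponding class is absent;
    ``mcc_degenerate`` flags an MCC forced to 0 by a zero denominator factor.
    """

    se: float | None
    sp: float | None
    acc: float
    mcc: float
    auc: float | None = None
    mcc_degenerate: bool = False
    counts: ConfusionCounts | None = None

    def to_text(self) -> str:
        def fmt(x, suffix=""):
            return "n/a" if x is None else f"{x:.4g}{suffix}"

        lines = [
            f"SE\t{fmt(self.se, '%')}",
            f"SP\t{fmt(self.sp, '%')}",
            f"ACC\t{fmt(self.acc, '%')}",
            f"MCC\t{self.mcc:.4f}" + (" (degenerate)" if self.mcc_degenerate else ""),
        ]
        if self.auc is not None:
            lines.append(f"AUC\t{self.auc:.4f}")
        return "\n".join(lines) + "\n"


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Metrics from pooled confusion counts; see module docstring for
    formulas and degenerate-denominator handling."""
    se = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) else None
    sp = 100.0 * c.tn / (c.tn + c.fp) if (c.tn + c.fp) else None
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    acc = 100.0 * (c.tp + c.tn) / c.total
    denom = (
        (c.tp + c.fn) * (c.tp + c.fp) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        mcc, degenerate = 0.0, True
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
        degenerate = False
    return MetricsReport(se=se, sp=sp, acc=acc, mcc=mcc,
                         mcc_degenerate=degenerate, counts=c)


def roc_auc(scores: Sequence[float], labels: Sequence[int]
            ) -> tuple[float, pd.DataFrame]:
    """Trapezoidal AUC over the full threshold sweep, plus curve points.

    Equivalent to the Mann-Whitney statistic normalized by
    (positives x negatives), with ties counting 1/2.
    """
    y = np.asarray(list(labels), dtype=int)
    s = np.asarray(list(scores), dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, pd.DataFrame({"fpr": fpr, "tpr": tpr})


def _fold_assignment(labels: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Stratified fold index per sample: within each class, a seeded shuffle
    dealt round-robin, so per-fold class counts differ by at most one."""
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(labels), dtype=int)
    for cls in (1, 0):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % folds
    return assignment


@dataclass
class CVResult:
    metrics: MetricsReport
    predictions: pd.DataFrame  # id, truth, predicted, score, fold
    roc_points: pd.DataFrame


def cross_validate_matrix(
    features: pd.DataFrame,
    labels: Sequence[int],
    t: int = DEFAULT_TREES,
    folds: int | None = None,
    seed: int = 0,
    max_features: int | float | str = "sqrt",
) -> CVResult:
    """Stratified cross-validation on a pre-computed feature matrix.

    ``folds=None`` (or ``folds == n``) is the jackknife: each sample is
    held out once and predicted by a model trained on the rest. Per-fold
    model seeds derive from the master seed plus the fold index.
    """
    y = np.asarray(list(labels), dtype=int)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 samples")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    folds = n if folds is None else folds
    if folds < 2:
        raise ValueError(f"folds must be >= 2, got {folds}")
    if folds > n:
        raise ValueError(f"folds={folds} exceeds dataset size {n}")

    assignment = _fold_assignment(y, folds, seed)
    predicted = np.empty(n, dtype=int)
    scores = np.empty(n, dtype=float)
    for f in range(folds):
        held = assignment == f
        if not held.any():
            continue
        y_train = y[~held]
        if len(np.unique(y_train)) < 2:
            raise RuntimeError(
                f"fold {f}: training split lost a class "
                f"(positives={int(y_train.sum())}, n={len(y_train)})"
            )
        model = ForestModel.train(
            features.loc[~held], y_train, t=t, seed=seed + f,
            max_features=max_features,
        )
        frac = model.vote_fraction(features.loc[held])
        scores[held] = frac
        predicted[held] = (frac > 0.5).astype(int)

    counts = ConfusionCounts.from_predictions(y, predicted)
    metrics = compute_metrics(counts)
    metrics.auc, roc_points = roc_auc(scores, y)
    table = pd.DataFrame(
        {
            "id": list(features.index),
            "truth": y,
            "predicted": predicted,
            "score": scores,
            "fold": assignment,
        }
    )
    return CVResult(metrics=metrics, predictions=table, roc_points=roc_points)


def kfold(ds: LabeledDataset, cfg: SkipGramConfig | None = None,
          t: int = DEFAULT_TREES, folds: int = 10, seed: int = 0) -> CVResult:
    """Stratified k-fold cross-validation with pooled confusion counts."""
    features = featurize_dataset(ds.peptides, cfg)
    return cross_validate_matrix(features, ds.labels, t=t, folds=folds,
                                 seed=seed)


def jackknife(ds: LabeledDataset, cfg: SkipGramConfig | None = None,
              t: int = DEFAULT_TREES, seed: int = 0) -> CVResult:
    """Leave-one-out validation: each peptide is predicted by a model
    trained on all the others. Identical to ``kfold`` with folds = n."""
    return kfold(ds, cfg, t=t, folds=len(ds), seed=seed)


def tree_sweep(
    ds: LabeledDataset,
    cfg: SkipGramConfig | None = None,
    t_values: Sequence[int] = DEFAULT_SWEEP,
    seed: int = 0,
    folds: int | None = None,
) -> tuple[pd.DataFrame, int]:
    """Evaluate a range of tree counts; returns the per-t metric table and
    the recommended t (highest ACC, ties broken toward smaller t)."""
    if not t_values:
        raise ValueError("t_values must be non-empty")
    features = featurize_dataset(ds.peptides, cfg)
    rows = []
    for t in t_values:
        res = cross_validate_matrix(features, ds.labels, t=t, folds=folds,
                                    seed=seed)
        m = res.metrics
        rows.append({"t": t, "SE": m.se, "SP": m.sp, "ACC": m.acc,
                     "MCC": m.mcc, "AUC": m.auc})
    table = pd.DataFrame(rows)
    best = int(table.sort_values(["ACC", "t"], ascending=[False, True])
               .iloc[0]["t"])
    return table, best
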