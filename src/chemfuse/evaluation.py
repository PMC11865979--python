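"""Classification metrics, stratified k-fold evaluation and timing reports.

Metrics follow the usual conventions for small forensic panels: precision,
recall, F1 and overall accuracy from integer confusion counts, with
degenerate denominators mapped to 0 (not NaN) and logged so that reports
aggregate cleanly.  Cross-validation is stratified -- by analyte label, and
within a single-analyte (one-class) corpus by concentration level -- with
every preprocessing and model fit confined to the training folds.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .core import LabelledDataset, ValidationError

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "metrics",
    "MetricsReport",
    "kfold_evaluate",
    "timing_report",
    "spread_across_concentrations",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """Nonnegative confusion counts for one target analyte."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValidationError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            tp=self.tp + other.tp, fp=self.fp + other.fp,
            tn=self.tn + other.tn, fn=self.fn + other.fn,
        )


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    f1: float
    accuracy: float


def metrics(c: ConfusionCounts) -> Metrics:
    """P = tp/(tp+fp), R = tp/(tp+fn), F1 = 2PR/(P+R), acc = (tp+tn)/total.

    Degenerate denominators yield 0 with a logged note rather than NaN.
    """
    if c.total == 0:
        raise ValidationError("cannot compute metrics from empty counts")

    def _ratio(num, den, name):
        if den == 0:
            logger.warning("metrics: %s has zero denominator; reporting 0", name)
            return 0.0
        return num / den

    precision = _ratio(c.tp, c.tp + c.fp, "precision")
    recall = _ratio(c.tp, c.tp + c.fn, "recall")
    f1 = _ratio(2 * precision * recall, precision + recall, "f1")
    accuracy = (c.tp + c.tn) / c.total
    return Metrics(precision=precision, recall=recall, f1=f1, accuracy=accuracy)


@dataclass(frozen=True)
class MetricsReport:
    """Aggregated cross-validation outcome for one pipeline."""

    per_analyte: dict
    counts: ConfusionCounts
    accuracy: float
    k: int
    seed: int
    fold_assignments: np.ndarray
    decision_values: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "k": self.k,
            "seed": self.seed,
            "counts": {"tp": self.counts.tp, "fp": self.counts.fp,
                       "tn": self.counts.tn, "fn": self.counts.fn},
            "per_analyte": {
                a: {"precision": m.precision, "recall": m.recall, "f1": m.f1}
                for a, m in self.per_analyte.items()
            },
            "fold_assignments": self.fold_assignments.tolist(),
        }


def _strat_keys(dataset: LabelledDataset) -> np.ndarray:
    labels = dataset.labels.astype(str)
    conc = dataset.concentrations
    if np.unique(labels).size == 1 and np.all(np.isfinite(conc)):
        # one-class corpus: stratify by concentration level instead
        return np.array([f"{l}|{c:g}" for l, c in zip(labels, conc)], dtype=object)
    return labels


def kfold_evaluate(
    dataset: LabelledDataset,
    pipeline_factory,
    k: int = 5,
    seed: int = 0,
) -> MetricsReport:
    """Stratified k-fold cross-validation of a fusion pipeline.

    ``pipeline_factory()`` must return a fresh unfitted pipeline carrying the
    target ``analyte``; all preprocessing/PCA/model fitting happens inside
    the training folds.  ``k == n_samples`` requests leave-one-out.
    Deterministic for a given seed, including fold assignment.
    """
    n = dataset.n_samples
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > n:
        raise ValidationError(f"k={k} exceeds n_samples={n}")
    keys = _strat_keys(dataset)
    if k == n:
        splitter = KFold(n_splits=k)
        split_iter = splitter.split(np.zeros(n))
    else:
        _, counts = np.unique(keys, return_counts=True)
        if counts.min() < k:
            raise ValidationError(
                f"smallest stratum has {counts.min()} samples < k={k}; choose a smaller k"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(n), keys)

    fold_of = np.full(n, -1, dtype=int)
    positives = np.zeros(n, dtype=bool)
    decisions = {}
    for fold, (train_idx, test_idx) in enumerate(split_iter):
        fold_of[test_idx] = fold
        pipeline = pipeline_factory()
        pipeline.fit(dataset.subset(train_idx))
        pos, evidence = pipeline.predict(dataset.subset(test_idx))
        positives[test_idx] = np.asarray(pos, dtype=bool)
        for key, values in evidence.items():
            if isinstance(values, np.ndarray) and values.shape == (test_idx.size,):
                decisions.setdefault(key, np.full(n, np.nan))[test_idx] = values

    analyte = pipeline.analyte
    is_target = dataset.labels.astype(str) == analyte
    counts = ConfusionCounts(
        tp=int(np.sum(positives & is_target)),
        fp=int(np.sum(positives & ~is_target)),
        tn=int(np.sum(~positives & ~is_target)),
        fn=int(np.sum(~positives & is_target)),
    )
    m = metrics(counts)
    logger.info(
        "kfold_evaluate: analyte=%s k=%d seed=%d accuracy=%.4f counts=%s",
        analyte, k, seed, m.accuracy, counts,
    )
    return MetricsReport(
        per_analyte={analyte: m},
        counts=counts,
        accuracy=m.accuracy,
        k=k,
        seed=seed,
        fold_assignments=fold_of,
        decision_values=decisions,
    )


def timing_report(pipeline_factory, dataset: LabelledDataset, test_fraction: float = 0.2,
                  seed: int = 0) -> dict:
    """Wall-clock fit/predict seconds, for information only (hardware-bound).

    Prediction time is measured on held-out rows only.
    """
    n = dataset.n_samples
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = max(1, int(round(test_fraction * n)))
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    pipeline = pipeline_factory()
    t0 = time.perf_counter()
    pipeline.fit(dataset.subset(train_idx))
    t1 = time.perf_counter()
    pipeline.predict(dataset.subset(test_idx))
    t2 = time.perf_counter()
    return {"fit_seconds": t1 - t0, "predict_seconds": t2 - t1,
            "n_train": int(train_idx.size), "n_test": int(test_idx.size)}


def spread_across_concentrations(values, concentrations) -> float:
    """max - min of the per-concentration mean of a decision-value vector."""
    values = np.asarray(values, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    if values.size != conc.size or values.size == 0:
        raise ValidationError("values and concentrations must align and be nonempty")
    keep = np.isfinite(values)
    means = [values[keep & (conc == c)].mean() for c in np.unique(conc[keep])]
    return float(np.max(means) - np.min(means))
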