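"""Confusion counts, classification metrics, stratified k-fold
cross-validation, and the depth x augmentation-factor sweep.

The positive class is HFO. Augmentation, when requested, is applied inside
each training fold only: virtual samples are generated from the fold's
training portion and can never appear in a test fold (the leakage guard
asserts this in every cell). ``global_augment=True`` reproduces the riskier
variant in which the full dataset is augmented once before splitting; the
guard still keeps virtual samples out of the test folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .augment import AugmentConfig, balanced_augment
from .data import HFO, NC, SegmentDataset

METRIC_NAMES = ("accuracy", "precision", "sensitivity", "specificity", "f_score")


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.FP + other.FP,
            self.TN + other.TN, self.FN + other.FN,
        )


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f_score: float
    #: set when any denominator was zero and the metric was reported as 0
    degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """TP/FP/TN/FN with HFO as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    t = y_true == HFO
    p = y_pred == HFO
    return ConfusionCounts(
        TP=int(np.sum(t & p)),
        FP=int(np.sum(~t & p)),
        TN=int(np.sum(~t & ~p)),
        FN=int(np.sum(t & ~p)),
    )


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    return (num / den, False) if den > 0 else (0.0, True)


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, sensitivity, specificity and F-score.

    F is the harmonic mean of precision and sensitivity. Division-by-zero
    cases return 0 with the ``degenerate`` flag set (and a warning).
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics of an empty evaluation")
    acc = (c.TP + c.TN) / c.total
    prec, d1 = _safe_div(c.TP, c.TP + c.FP)
    sens, d2 = _safe_div(c.TP, c.TP + c.FN)
    spec, d3 = _safe_div(c.TN, c.TN + c.FP)
    f, d4 = _safe_div(2.0 * prec * sens, prec + sens)
    degenerate = d1 or d2 or d3 or d4
    if degenerate:
        warnings.warn("zero denominator in metric computation; reported as 0",
                      stacklevel=2)
    return MetricsReport(acc, prec, sens, spec, f, degenerate)


def f_score(precision: float, sensitivity: float) -> float:
    """Harmonic mean F = 2 p s / (p + s); 0 when both are 0."""
    if precision + sensitivity == 0:
        return 0.0
    return 2.0 * precision * sensitivity / (precision + sensitivity)


@dataclass
class CVResult:
    k: int
    fold_counts: list[ConfusionCounts]
    aggregate: ConfusionCounts
    metrics: MetricsReport
    seed: int
    fold_test_sources: list[np.ndarray] = field(default_factory=list)


def kfold_cv(
    data: SegmentDataset,
    model_factory,
    k: int = 5,
    augment_cfg: AugmentConfig | None = None,
    seed: int = 0,
    global_augment: bool = False,
) -> CVResult:
    """Stratified k-fold cross-validation with leakage-safe augmentation.

    ``model_factory(seed)`` must return a fresh detector exposing
    ``fit(X, y)`` and ``predict(X)``. Per fold, the training portion is
    (optionally) augmented, the model trained from scratch, and the untouched
    test fold scored; the aggregate confusion matrix is the elementwise sum
    over folds and the metrics come from the aggregate.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = {c: int(np.sum(data.y == c)) for c in (HFO, NC)}
    small = [c for c, n in counts.items() if n < k]
    if small:
        raise ValueError(f"class(es) {small} have fewer than k={k} samples")
    if np.any(data.source == "virtual"):
        raise ValueError("evaluation data must not contain virtual samples")

    if global_augment and augment_cfg is not None and augment_cfg.factor > 0:
        augmented_pool = balanced_augment(data, augment_cfg)
    else:
        augmented_pool = None

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_counts: list[ConfusionCounts] = []
    fold_sources: list[np.ndarray] = []
    for fold, (tr_idx, te_idx) in enumerate(skf.split(data.X, data.y)):
        test = data.subset(te_idx)
        # leakage guard: no virtual sample is ever evaluated
        assert not np.any(test.source == "virtual"), "virtual sample in test fold"
        if augmented_pool is not None:
            real_part = augmented_pool.subset(np.arange(len(data)))
            keep = np.ones(len(data), dtype=bool)
            keep[te_idx] = False
            train_ds = SegmentDataset.concat(
                [real_part.subset(np.flatnonzero(keep)),
                 augmented_pool.subset(np.arange(len(data), len(augmented_pool)))]
            )
        else:
            train_ds = data.subset(tr_idx)
            if augment_cfg is not None and augment_cfg.factor > 0:
                fold_cfg = AugmentConfig(
                    factor=augment_cfg.factor,
                    k_neighbors=augment_cfg.k_neighbors,
                    bins=augment_cfg.bins,
                    imbalance_threshold=augment_cfg.imbalance_threshold,
                    seed=augment_cfg.seed + 1000 * fold,
                )
                train_ds = balanced_augment(train_ds, fold_cfg)
        model = model_factory(seed + fold)
        model.fit(train_ds.X, train_ds.y)
        pred = model.predict(test.X)
        fold_counts.append(confusion_counts((test.y == HFO).astype(int), pred))
        fold_sources.append(test.source)
    aggregate = sum(fold_counts, ConfusionCounts())
    return CVResult(k, fold_counts, aggregate, compute_metrics(aggregate), seed,
                    fold_sources)


@dataclass
class SweepGrid:
    """Results table over (model, depth N, augmentation factor) cells."""

    table: pd.DataFrame

    def cell(self, depth: int, factor: float) -> pd.Series:
        m = (self.table["N"] == depth) & (self.table["factor"] == factor)
        return self.table[m].iloc[0]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SweepGrid":
        return cls(pd.read_csv(path, sep="\t"))


def depth_augmentation_sweep(
    data: SegmentDataset,
    depths=(1, 2, 4, 10, 20, 40),
    factors=(0, 1, 5, 10, 20, 40),
    model_factory=None,
    k: int = 5,
    seed: int = 0,
    model_name: str = "attention",
) -> SweepGrid:
    """One cross-validation per (depth, factor) cell.

    ``model_factory(depth, seed)`` must return a fresh detector for the given
    number of stacked layers; defaults to the attention model with the
    package's default configuration. Cell seeds are deterministic offsets of
    the base seed. Every cell runs the leakage guard of :func:`kfold_cv`.
    """
    if not depths or not factors:
        raise ValueError("depths and factors must be nonempty")
    if model_factory is None:
        from .baselines import make_model

        def model_factory(depth, s):
            return make_model(model_name, seed=s, n_layers=depth)

    rows = []
    for i, depth in enumerate(depths):
        for j, factor in enumerate(factors):
            cell_seed = seed + 10000 * i + 100 * j
            aug = AugmentConfig(factor=factor, seed=cell_seed) if factor > 0 else None
            res = kfold_cv(
                data,
                lambda s, depth=depth: model_factory(depth, s),
                k=k,
                augment_cfg=aug,
                seed=cell_seed,
            )
            for src in res.fold_test_sources:
                assert not np.any(src == "virtual"), "leakage guard failed"
            c = res.aggregate
            rows.append(
                {
                    "model": model_name,
                    "N": depth,
                    "factor": factor,
                    "k": k,
                    "TP": c.TP,
                    "FP": c.FP,
                    "TN": c.TN,
                    "FN": c.FN,
                    **res.metrics.as_dict(),
                    "seed": cell_seed,
                }
            )
    return SweepGrid(pd.DataFrame(rows))
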