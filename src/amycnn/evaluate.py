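"""Model evaluation: stratified k-fold CV, confusion metrics, tri-plane
majority voting and external-test assessment.

Per-fold metrics are accuracy, sensitivity (true-positive rate among
amyloid-positive scans) and specificity (true-negative rate among
amyloid-negative scans), reported as percentages and aggregated across
folds as mean +/- SD. The three axis networks' predictions can be combined
by majority hard voting (2 of 3 binary votes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace
from typing import Sequence

import numpy as np

from .cnn import CNNConfig, TrainedModel, build_model, dataset_to_arrays, train
from .dataprep import AugmentParams, Dataset, augment, oversample_minority

logger = logging.getLogger(__name__)


@dataclass
class FoldAssignment:
    """Partition of scan_ids into k stratified folds."""

    k: int
    fold_index: dict[str, int]
    rng_seed: int = 0

    def fold_ids(self, fold: int) -> list[str]:
        return [sid for sid, f in self.fold_index.items() if f == fold]


@dataclass
class Metrics:
    """Confusion-matrix counts and derived percentages.

    A metric whose denominator is zero (e.g. sensitivity with no positive
    scans) is ``None`` ("undefined") rather than 0 or 100.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float | None:
        return 100.0 * (self.tp + self.tn) / self.n if self.n else None

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return 100.0 * self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return 100.0 * self.tn / d if d else None

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


@dataclass
class CVResult:
    """Per-fold metrics plus mean/SD aggregation and validation probabilities."""

    fold_metrics: list[Metrics]
    probabilities: dict[str, float]  # scan_id -> held-out probability
    fold_of: dict[str, int]
    models: list[TrainedModel] = field(default_factory=list)
    axis: str = ""

    def _agg(self, name: str) -> tuple[float | None, float | None]:
        vals = [getattr(m, name) for m in self.fold_metrics]
        defined = [v for v in vals if v is not None]
        if len(defined) < len(vals):
            logger.warning(
                "%s undefined in %d fold(s); excluded from the mean",
                name, len(vals) - len(defined))
        if not defined:
            return None, None
        mean = float(np.mean(defined))
        sd = float(np.std(defined, ddof=1)) if len(defined) > 1 else 0.0
        return mean, sd

    @property
    def mean_accuracy(self) -> float | None:
        return self._agg("accuracy")[0]

    @property
    def sd_accuracy(self) -> float | None:
        return self._agg("accuracy")[1]

    @property
    def mean_sensitivity(self) -> float | None:
        return self._agg("sensitivity")[0]

    @property
    def sd_sensitivity(self) -> float | None:
        return self._agg("sensitivity")[1]

    @property
    def mean_specificity(self) -> float | None:
        return self._agg("specificity")[0]

    @property
    def sd_specificity(self) -> float | None:
        return self._agg("specificity")[1]

    def summary(self) -> dict:
        return {
            "axis": self.axis,
            "folds": [m.as_dict() for m in self.fold_metrics],
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "mean_sensitivity": self.mean_sensitivity,
            "sd_sensitivity": self.sd_sensitivity,
            "mean_specificity": self.mean_specificity,
            "sd_specificity": self.sd_specificity,
        }


def stratified_kfold(labels: dict[str, int], k: int = 5,
                     rng_seed: int = 0) -> FoldAssignment:
    """Stratified partition of scan_ids into k folds.

    Each fold's class counts differ by at most 1 from proportional, and the
    leftover scans of each class (count % k) are placed in the currently
    smallest folds, so fold totals also differ by at most 1 whenever the
    class remainders allow it.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(rng_seed)
    ids = list(labels.keys())
    classes = sorted({int(v) for v in labels.values()})
    for cls in classes:
        if sum(1 for sid in ids if labels[sid] == cls) < k:
            raise ValueError(f"class {cls} has fewer than k={k} members")

    fold_index: dict[str, int] = {}
    totals = np.zeros(k, dtype=int)
    for cls in classes:
        members = [sid for sid in ids if labels[sid] == cls]
        order = rng.permutation(len(members))
        members = [members[i] for i in order]
        base, rem = divmod(len(members), k)
        # folds receiving one extra scan of this class: the currently
        # smallest folds (ties by fold index), to keep totals balanced
        extra_folds = np.argsort(totals, kind="stable")[:rem]
        sizes = np.full(k, base, dtype=int)
        sizes[extra_folds] += 1
        pos = 0
        for fold in range(k):
            for sid in members[pos:pos + sizes[fold]]:
                fold_index[sid] = fold
            pos += sizes[fold]
        totals += sizes
    return FoldAssignment(k=k, fold_index=fold_index, rng_seed=rng_seed)


def confusion_metrics(predicted: Sequence[int], true: Sequence[int]) -> Metrics:
    """Confusion-matrix counts for binary labels (1 = amyloid positive)."""
    pred = np.asarray(predicted).astype(int)
    y = np.asarray(true).astype(int)
    if pred.shape != y.shape:
        raise ValueError("predicted and true label vectors differ in length")
    return Metrics(
        tp=int(np.sum((pred == 1) & (y == 1))),
        fp=int(np.sum((pred == 1) & (y == 0))),
        tn=int(np.sum((pred == 0) & (y == 0))),
        fn=int(np.sum((pred == 0) & (y == 1))),
    )


def majority_vote(p_axial: float, p_coronal: float, p_sagittal: float,
                  threshold: float = 0.5) -> int:
    """Majority hard vote of the three per-axis probabilities."""
    probs = (p_axial, p_coronal, p_sagittal)
    for p in probs:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} outside [0, 1]")
    votes = sum(int(p >= threshold) for p in probs)
    return int(votes >= 2)


def _subset(ds: Dataset, ids: set[str]) -> Dataset:
    return Dataset(items=[(s, l) for s, l in ds.items if s.scan_id in ids])


def run_cv(
    dataset: Dataset,
    axis: str,
    cnn_config: CNNConfig,
    folds: FoldAssignment,
    augment_params: AugmentParams | None = None,
    keep_models: bool = True,
) -> CVResult:
    """Stratified k-fold cross-validation of one decomposition's CNN.

    For each fold: the training portion (the other k-1 folds) is balanced
    by minority oversampling, optionally augmented per epoch, and a fresh
    model is trained; the held-out fold is evaluated untouched. Fold
    metrics are aggregated as mean +/- SD.
    """
    ids_in_ds = {s.scan_id for s, _ in dataset.items}
    if ids_in_ds != set(folds.fold_index):
        raise ValueError("fold assignment does not match dataset scan_ids")
    input_shape = None
    fold_metrics: list[Metrics] = []
    probabilities: dict[str, float] = {}
    models: list[TrainedModel] = []

    for fold in range(folds.k):
        val_ids = set(folds.fold_ids(fold))
        train_ds = _subset(dataset, ids_in_ds - val_ids)
        val_ds = _subset(dataset, val_ids)
        fold_seed = cnn_config.rng_seed + 1000 * fold
        balanced = oversample_minority(train_ds, rng_seed=fold_seed + 1)

        if input_shape is None:
            planes = dataset.items[0][0].planes
            input_shape = (planes.shape[1], planes.shape[2], planes.shape[0])
        cfg = dc_replace(cnn_config, rng_seed=fold_seed)
        model = build_model(input_shape, cfg, axis=axis)

        augment_fn = None
        if augment_params is not None:
            base = augment_params

            def augment_fn(stack, i, epoch, _base=base, _fs=fold_seed):
                seed = (_base.rng_seed + _fs + 7919 * epoch + 104729 * i) \
                    % (2**31 - 1)
                return augment(stack, dc_replace(_base, rng_seed=seed))

        train(model, balanced, val_ds, cfg, augment_fn=augment_fn)

        x_val, y_val = dataset_to_arrays(val_ds)
        p_val = model.predict_proba(x_val)
        pred = (p_val >= cfg.decision_threshold).astype(int)
        fold_metrics.append(confusion_metrics(pred, y_val.astype(int)))
        for (stack, _), p in zip(val_ds.items, p_val):
            probabilities[stack.scan_id] = float(p)
        if keep_models:
            models.append(model)

    return CVResult(
        fold_metrics=fold_metrics,
        probabilities=probabilities,
        fold_of=dict(folds.fold_index),
        models=models,
        axis=axis,
    )


def select_best_axis(results: dict[str, CVResult]) -> str:
    """Axis with the highest mean CV accuracy; ties broken by mean
    sensitivity, then mean specificity."""
    def key(axis: str):
        r = results[axis]
        return (
            r.mean_accuracy if r.mean_accuracy is not None else -1.0,
            r.mean_sensitivity if r.mean_sensitivity is not None else -1.0,
            r.mean_specificity if r.mean_specificity is not None else -1.0,
        )
    return max(results, key=key)


def evaluate_external(
    models: Sequence[TrainedModel] | TrainedModel,
    test_ds: Dataset,
    threshold: float = 0.5,
) -> tuple[Metrics, dict[str, float]]:
    """Evaluate on an independent test set.

    When several fold models are given, the per-scan probability is their
    ensemble mean; a single model is used as-is. Returns the confusion
    metrics and the per-scan probabilities.
    """
    if isinstance(models, TrainedModel):
        models = [models]
    if len(test_ds) == 0:
        raise ValueError("test dataset is empty")
    x, y = dataset_to_arrays(test_ds)
    probs = np.mean([m.predict_proba(x) for m in models], axis=0)
    pred = (probs >= threshold).astype(int)
    metrics = confusion_metrics(pred, y.astype(int))
    per_scan = {
        stack.scan_id: float(p) for (stack, _), p in zip(test_ds.items, probs)
    }
    return metrics, per_scan
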