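"""Metrics, stratified cross-validation and the synthetic noisy benchmark.

Three training regimes are compared under identical model and training
hyperparameters:

* ``baseline`` — train on the original fold data only;
* ``tda`` — traditional data augmentation: train on the original data plus
  every augmented sample, no filtering;
* ``assf`` — the uncertainty-aware selection loop, which trains on the
  original data plus only the selected subset of augmented samples.

Evaluation is stratified k-fold: the encoder (including mRMR) is fitted on
each training split only, augmentation happens strictly inside the training
fold, and the held-out fold is scored with dropout switched off.  The noisy
benchmark additionally flips the inherited label of a fraction of augmented
samples and measures how many of these corrupted samples the selection loop
excludes.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import statistics
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import assf as assf_mod
from .assf import AssfConfig, IterationReport
from .augmentation import (
    AugmentedSample,
    PerturbationSpec,
    augmented_matrix,
    build_augmented_set,
)
from .descriptors import IndexTable, as_matrix, encode_dataset, fit_encoder
from .predictor import init_model, predict_proba, train_model
from .sequence_io import LabeledDataset, generate_synthetic_dataset

logger = logging.getLogger(__name__)

METHODS = ("baseline", "tda", "assf")


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; the positive class is the anticancer peptide."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


@dataclasses.dataclass
class MetricsReport:
    accuracy: float
    specificity: float
    f1: float
    mcc: float
    counts: ConfusionCounts
    method: str | None = None
    fold: int | None = None

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "specificity": self.specificity,
            "f1": self.f1,
            "mcc": self.mcc,
        }


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy, specificity, F1 and MCC from confusion counts.

    Degenerate denominators map to 0: specificity is 0 when TN+FP = 0, F1 is
    0 when 2TP+FP+FN = 0, and MCC is 0 when any factor of its denominator is 0.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    if counts.total == 0:
        raise ValueError("cannot compute metrics on zero samples")
    accuracy = (tp + tn) / counts.total
    specificity = tn / (tn + fp) if (tn + fp) > 0 else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    return MetricsReport(accuracy, specificity, f1, mcc, counts)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FoldDetail:
    """Audit record of one cross-validation fold."""

    fold: int
    train_ids: list[str]
    test_ids: list[str]
    metrics: MetricsReport
    da_source_ids: list[str] = dataclasses.field(default_factory=list)
    n_augmented: int = 0
    n_selected: int = 0
    n_flipped: int = 0
    n_flipped_selected: int = 0
    iteration_reports: list[IterationReport] = dataclasses.field(default_factory=list)

    @property
    def flipped_exclusion_rate(self) -> float | None:
        if self.n_flipped == 0:
            return None
        return 1.0 - self.n_flipped_selected / self.n_flipped


@dataclasses.dataclass
class CrossValResult:
    """Per-fold and aggregated metrics for one method."""

    method: str
    folds: list[FoldDetail]

    @property
    def mean_metrics(self) -> dict[str, float]:
        keys = ("accuracy", "specificity", "f1", "mcc")
        return {
            k: float(np.mean([f.metrics.as_dict()[k] for f in self.folds]))
            for k in keys
        }

    @property
    def pooled_metrics(self) -> MetricsReport:
        counts = self.folds[0].metrics.counts
        for f in self.folds[1:]:
            counts = counts + f.metrics.counts
        report = compute_metrics(counts)
        report.method = self.method
        return report

    @property
    def flipped_exclusion_rate(self) -> float | None:
        """Pooled over folds: fraction of label-flipped augmented samples
        absent from the final selection."""
        flipped = sum(f.n_flipped for f in self.folds)
        if flipped == 0:
            return None
        kept = sum(f.n_flipped_selected for f in self.folds)
        return 1.0 - kept / flipped

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.folds:
            for metric, value in f.metrics.as_dict().items():
                rows.append(
                    {"method": self.method, "fold": f.fold,
                     "metric": metric, "value": value}
                )
        return pd.DataFrame(rows)


def _derive_seed(seed: int, *salts: int) -> int:
    out = seed % (2**31)
    for s in salts:
        out = (out * 1_000_003 + s + 1) % (2**31)
    return out


def _flip_labels(
    da: list[AugmentedSample], flip_fraction: float, seed: int
) -> list[int]:
    """Flip the inherited label of a random fraction of *da* in place;
    returns the flipped indices."""
    if flip_fraction == 0.0 or not da:
        return []
    rng = np.random.default_rng(seed)
    n_flip = int(round(flip_fraction * len(da)))
    idx = rng.choice(len(da), size=n_flip, replace=False)
    for i in idx:
        da[i].label = 1 - da[i].label
    return [int(i) for i in idx]


def cross_validate(
    data: LabeledDataset,
    method: str,
    cfg: AssfConfig,
    spec: PerturbationSpec | None = None,
    folds: int = 5,
    seed: int = 0,
    table: IndexTable | None = None,
    n_aaif: int = 50,
    flip_fraction: float = 0.0,
) -> CrossValResult:
    """Stratified k-fold evaluation of one training regime.

    Per fold: the encoder (including mRMR) is fitted on the training split
    only; both splits are encoded with it; augmentation (for ``tda`` and
    ``assf``) draws exclusively from training-fold vectors; the held-out
    fold is scored with dropout off.  All seeds derive from *seed* and the
    fold number, so identical calls are bit-reproducible.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if method != "baseline" and spec is None:
        raise ValueError(f"method {method!r} requires a PerturbationSpec")
    labels = data.labels
    if min(np.bincount(labels, minlength=2)) < folds:
        raise ValueError(f"need at least {folds} samples per class")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    details: list[FoldDetail] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        fold_seed = _derive_seed(seed, fold)
        train_set = data.subset(train_idx)
        test_set = data.subset(test_idx)
        state = fit_encoder(train_set, table=table, n_aaif=n_aaif)
        train_vecs = encode_dataset(train_set, state)
        test_vecs = encode_dataset(test_set, state)
        X_train, y_train = as_matrix(train_vecs), train_set.labels
        X_test, y_test = as_matrix(test_vecs), test_set.labels

        model_cfg = dataclasses.replace(cfg.model, seed=_derive_seed(fold_seed, 1))
        train_cfg = dataclasses.replace(cfg.train, seed=_derive_seed(fold_seed, 2))
        fold_cfg = dataclasses.replace(cfg, model=model_cfg, train=train_cfg)

        da: list[AugmentedSample] = []
        flipped_idx: list[int] = []
        n_selected = 0
        n_flipped_selected = 0
        iteration_reports: list[IterationReport] = []
        if method == "baseline":
            model = train_model(init_model(model_cfg), X_train, y_train, train_cfg)
        else:
            fold_spec = dataclasses.replace(spec, seed=_derive_seed(fold_seed, 3))
            da = build_augmented_set(train_vecs, y_train, fold_spec)
            flipped_idx = _flip_labels(da, flip_fraction, _derive_seed(fold_seed, 4))
            if method == "tda":
                X = np.vstack([X_train, augmented_matrix(da)])
                y = np.concatenate([y_train, [s.label for s in da]])
                model = train_model(init_model(model_cfg), X, y, train_cfg)
            else:
                model, ds, iteration_reports = assf_mod.assf_train(
                    X_train, y_train, da, fold_cfg
                )
                selected_ids = {id(s) for s in ds}
                n_selected = len(ds)
                n_flipped_selected = sum(
                    1 for i in flipped_idx if id(da[i]) in selected_ids
                )

        y_pred = predict_proba(model, X_test, dropout_active=False).argmax(axis=1)
        metrics = compute_metrics(ConfusionCounts.from_predictions(y_test, y_pred))
        metrics.method = method
        metrics.fold = fold
        details.append(
            FoldDetail(
                fold=fold,
                train_ids=[r.id for r in train_set],
                test_ids=[r.id for r in test_set],
                metrics=metrics,
                da_source_ids=[s.source_id for s in da],
                n_augmented=len(da),
                n_selected=n_selected,
                n_flipped=len(flipped_idx),
                n_flipped_selected=n_flipped_selected,
                iteration_reports=iteration_reports,
            )
        )
        logger.info(
            "%s fold %d: acc=%.4f sp=%.4f f1=%.4f mcc=%.4f",
            method, fold, metrics.accuracy, metrics.specificity,
            metrics.f1, metrics.mcc,
        )
    return CrossValResult(method=method, folds=details)


# ---------------------------------------------------------------------------
# Synthetic noisy benchmark
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class BenchmarkResult:
    """Median-over-seeds comparison of the three regimes under label noise."""

    per_seed: dict[str, list[CrossValResult]]   # method -> one result per seed
    seeds: list[int]
    flip_fraction: float

    def median_metric(self, method: str, metric: str) -> float:
        values = [
            r.mean_metrics[metric] for r in self.per_seed[method]
        ]
        return float(statistics.median(values))

    @property
    def median_flipped_exclusion_rate(self) -> float | None:
        rates = [
            r.flipped_exclusion_rate
            for r in self.per_seed.get("assf", [])
            if r.flipped_exclusion_rate is not None
        ]
        return float(statistics.median(rates)) if rates else None

    @property
    def median_selection_rate(self) -> float:
        rates = []
        for r in self.per_seed.get("assf", []):
            total_da = sum(f.n_augmented for f in r.folds)
            total_ds = sum(f.n_selected for f in r.folds)
            rates.append(total_ds / total_da if total_da else 0.0)
        return float(statistics.median(rates)) if rates else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for method, results in self.per_seed.items():
            for seed, result in zip(self.seeds, results):
                for metric, value in result.mean_metrics.items():
                    rows.append(
                        {"method": method, "seed": seed,
                         "metric": metric, "value": value}
                    )
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        frame = self.to_frame()
        return (
            frame.groupby(["method", "metric"])["value"]
            .median()
            .unstack("metric")
            .reset_index()
        )


def run_noisy_benchmark(
    cfg: AssfConfig,
    spec: PerturbationSpec,
    flip_fraction: float = 0.3,
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    n_pos: int = 100,
    n_neg: int = 100,
    class_bias: float = 0.9,
    length_range: tuple[int, int] = (10, 40),
    folds: int = 5,
    table: IndexTable | None = None,
    methods: Sequence[str] = METHODS,
) -> BenchmarkResult:
    """Compare baseline / TDA / ASSF on synthetic data with corrupted labels.

    For each seed a fresh composition-separable dataset is generated, the
    three regimes are cross-validated on it, and a *flip_fraction* of the
    augmented samples have their inherited label flipped before training (for
    ``tda`` and ``assf``).  Reported quantities are medians over seeds; the
    flipped-sample exclusion rate measures how many corrupted samples the
    selection loop kept out of its final subset.
    """
    per_seed: dict[str, list[CrossValResult]] = {m: [] for m in methods}
    for seed in seeds:
        dataset = generate_synthetic_dataset(
            n_pos=n_pos, n_neg=n_neg, length_range=length_range,
            class_bias=class_bias, seed=seed,
        )
        for method in methods:
            result = cross_validate(
                dataset, method, cfg, spec=spec, folds=folds, seed=seed,
                table=table, flip_fraction=0.0 if method == "baseline" else flip_fraction,
            )
            per_seed[method].append(result)
    return BenchmarkResult(
        per_seed=per_seed, seeds=list(seeds), flip_fraction=flip_fraction
    )
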