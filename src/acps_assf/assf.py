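"""Uncertainty-aware augmented-sample selection.

Augmented samples are cheap but noisy: a perturbed vector can land on the
wrong side of the decision boundary, and training on it teaches the model the
wrong thing.  The framework scores every augmented sample with Monte-Carlo
dropout — T stochastic forward passes of a model trained on trusted data —
and keeps only samples that are simultaneously

* low-uncertainty: the sample standard deviation (divisor T-1) of the
  predicted probability at the pseudo-label class is strictly below λ,
* high-confidence: the mean predicted probability at that class is strictly
  above γ (γ > 0.5, so the confident class is the argmax), and
* label-consistent: the pseudo-label (argmax of the mean probability) equals
  the label inherited from the source vector.

The selected subset Ds is merged with the original training set Do and the
model is retrained from a fresh initialization; scoring and selection are
repeated for I iterations, recomputing Ds from the full augmented set each
time.  The loop is fully seeded and reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np

from .augmentation import AugmentedSample, augmented_matrix
from .predictor import (
    MLPModel,
    ModelConfig,
    TrainConfig,
    init_model,
    mc_dropout_passes,
    train_model,
)

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class SelectionThresholds:
    """λ (uncertainty, strict upper bound) and γ (confidence, strict lower
    bound, in (0.5, 1)).  λ = 0 is permitted and disables selection outright,
    since uncertainties are non-negative and the bound is strict."""

    lambda_: float = 0.03
    gamma: float = 0.8

    def __post_init__(self) -> None:
        if not self.lambda_ >= 0:
            raise ValueError("lambda_ must be >= 0")
        if not 0.5 < self.gamma < 1.0:
            raise ValueError("gamma must lie in (0.5, 1)")


@dataclasses.dataclass
class AssfConfig:
    """All framework hyperparameters in one place."""

    thresholds: SelectionThresholds = dataclasses.field(
        default_factory=SelectionThresholds
    )
    T: int = 10                  # stochastic forward passes
    iterations: int = 10         # selection iterations I
    model: ModelConfig = dataclasses.field(default_factory=ModelConfig)
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.T < 2:
            raise ValueError("T must be >= 2")


@dataclasses.dataclass
class IterationReport:
    """Per-iteration audit record of the selection loop."""

    iteration: int
    n_selected: int
    n_selected_pos: int
    n_selected_neg: int
    n_rejected: int

    @property
    def selection_rate(self) -> float:
        total = self.n_selected + self.n_rejected
        return self.n_selected / total if total else 0.0


def summarize_passes(probs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reduce (n, T, 2) MC-dropout outputs to (pseudo_label, confidence,
    uncertainty) arrays.

    The pseudo-label is the argmax of the per-class mean probability (ties
    toward class 0); confidence is the mean and uncertainty the sample
    standard deviation (divisor T-1) of the probability at that class.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 3 or probs.shape[1] < 2:
        raise ValueError("expected an (n, T>=2, C) array of pass probabilities")
    mean = probs.mean(axis=1)                     # (n, C)
    std = probs.std(axis=1, ddof=1)               # (n, C)
    # identical passes (e.g. dropout rate 0) must give u = 0 exactly, not
    # mean-subtraction rounding dust
    std = np.where(probs.max(axis=1) == probs.min(axis=1), 0.0, std)
    pseudo = mean.argmax(axis=1)                  # argmax ties -> class 0
    rows = np.arange(len(mean))
    return pseudo, mean[rows, pseudo], std[rows, pseudo]


def score_augmented(
    model: MLPModel,
    da: Sequence[AugmentedSample],
    T: int,
    seed: int = 0,
) -> list[AugmentedSample]:
    """Fill pseudo_label, confidence and uncertainty on every sample of *da*.

    Scores are recomputed in place (samples are mutated and returned).
    """
    if not da:
        return []
    passes = mc_dropout_passes(model, augmented_matrix(da), T=T, seed=seed)
    pseudo, conf, unc = summarize_passes(passes)
    for s, p, c, u in zip(da, pseudo, conf, unc):
        s.pseudo_label = int(p)
        s.confidence = float(c)
        s.uncertainty = float(u)
    return list(da)


def select_samples(
    da: Sequence[AugmentedSample],
    thresholds: SelectionThresholds,
) -> list[AugmentedSample]:
    """Apply the three-part selection rule, preserving input order.

    A sample is kept iff uncertainty < λ (strict) and confidence > γ (strict)
    and its pseudo-label equals its inherited label.
    """
    for s in da:
        if not s.scored:
            raise RuntimeError(f"sample from {s.source_id!r} has not been scored")
    return [
        s
        for s in da
        if s.uncertainty < thresholds.lambda_
        and s.confidence > thresholds.gamma
        and s.pseudo_label == s.label
    ]


def assf_train(
    X_train: np.ndarray,
    y_train: np.ndarray,
    da: Sequence[AugmentedSample],
    cfg: AssfConfig,
) -> tuple[MLPModel, list[AugmentedSample], list[IterationReport]]:
    """Run the iterative selection loop.

    Each iteration re-initializes the model (seed derived deterministically
    from the model seed and the iteration number), trains E epochs on the
    original data merged with the previous iteration's selection, scores the
    full augmented set with T MC-dropout passes and recomputes the selection.
    Returns the final model, the final selected subset and the per-iteration
    reports.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    if len(X_train) == 0:
        raise ValueError("original training set is empty")
    if len(da) == 0:
        raise ValueError("augmented set is empty")

    ds: list[AugmentedSample] = []
    reports: list[IterationReport] = []
    model: MLPModel | None = None
    for iteration in range(1, cfg.iterations + 1):
        model_seed = (cfg.model.seed * 1_000_003 + iteration) % (2**31)
        model = init_model(dataclasses.replace(cfg.model, seed=model_seed))
        if iteration == 1 or not ds:
            X, y = X_train, y_train
        else:
            X = np.vstack([X_train, augmented_matrix(ds)])
            y = np.concatenate([y_train, [s.label for s in ds]])
        tcfg = dataclasses.replace(
            cfg.train, seed=(cfg.train.seed * 1_000_003 + iteration) % (2**31)
        )
        train_model(model, X, y, tcfg)
        score_seed = (cfg.model.seed * 2_000_003 + iteration) % (2**31)
        score_augmented(model, da, T=cfg.T, seed=score_seed)
        ds = select_samples(da, cfg.thresholds)
        n_pos = sum(1 for s in ds if s.label == 1)
        report = IterationReport(
            iteration=iteration,
            n_selected=len(ds),
            n_selected_pos=n_pos,
            n_selected_neg=len(ds) - n_pos,
            n_rejected=len(da) - len(ds),
        )
        reports.append(report)
        logger.info(
            "iteration %d: |Ds|=%d (%d pos / %d neg), rejected %d",
            iteration, report.n_selected, report.n_selected_pos,
            report.n_selected_neg, report.n_rejected,
        )
    assert model is not None
    return model, ds, reports


def export_selection_tsv(ds: Sequence[AugmentedSample], path) -> None:
    """Write the audited selection: source_id, label, y', confidence, uncertainty."""
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["source_id", "label", "pseudo_label", "confidence", "uncertainty"])
        for s in ds:
            writer.writerow([s.source_id, s.label, s.pseudo_label,
                             f"{s.confidence:.6f}", f"{s.uncertainty:.6f}"])
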