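"""Feature-space data augmentation by masked multiplicative perturbation.

New samples are generated directly in descriptor space:

    x_a = x_o * V * omega + x_o        (elementwise)

where ``x_o`` is a training vector drawn uniformly at random (with
replacement), ``V`` is a 400-coordinate vector whose first 180 coordinates
(the discrete BPF and OPE position codes) are zero and whose remaining 220
coordinates are fresh uniform draws on [0, 1], and ``omega`` scales the
perturbation.  The multiplicative form preserves zeros and signs, and bounds
the relative change of every coordinate by ``omega``.  Each augmented sample
inherits the label of its source vector; pseudo-label, confidence and
uncertainty are attached later by the selection framework.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .descriptors import FeatureVector, as_matrix


@dataclasses.dataclass
class PerturbationSpec:
    """Parameters of the augmentation step.

    omega : float
        Perturbation factor in [0, 1]; the relative change of any perturbed
        coordinate is at most omega.
    ratio : int
        Number of augmented samples generated per original training sample
        (the N/R parameter); must be >= 1.
    mask : np.ndarray
        0/1 vector, zero exactly on the BPF+OPE coordinates (first 180),
        one on the remaining 220.
    seed : int
        Seed for source selection and the uniform draws.
    """

    omega: float = 0.006
    ratio: int = 2
    mask: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError("omega must lie in [0, 1]")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=float)
            if not set(np.unique(self.mask)) <= {0.0, 1.0}:
                raise ValueError("mask must be 0/1-valued")

    def resolved_mask(self, width: int) -> np.ndarray:
        if self.mask is None:
            mask = np.ones(width)
            mask[:180] = 0.0
            return mask
        if len(self.mask) != width:
            raise ValueError(
                f"mask width {len(self.mask)} != vector width {width}"
            )
        return self.mask


@dataclasses.dataclass
class AugmentedSample:
    """A perturbed feature vector with its inherited label.

    ``pseudo_label``, ``confidence`` and ``uncertainty`` stay None until the
    sample is scored by MC-dropout inference.
    """

    values: np.ndarray
    label: int
    source_id: str
    pseudo_label: int | None = None
    confidence: float | None = None
    uncertainty: float | None = None

    @property
    def scored(self) -> bool:
        return self.pseudo_label is not None


def perturb(
    source: FeatureVector,
    spec: PerturbationSpec,
    draw: np.ndarray,
    label: int,
) -> AugmentedSample:
    """Apply one masked multiplicative perturbation to *source*.

    *draw* must be a uniform [0,1] vector of the same width as the source
    vector; the effective perturbation vector is ``V = mask * draw``.
    """
    x = source.values
    draw = np.asarray(draw, dtype=float)
    if draw.shape != x.shape:
        raise ValueError(f"draw shape {draw.shape} != vector shape {x.shape}")
    if draw.min() < 0.0 or draw.max() > 1.0:
        raise ValueError("draw coordinates must lie in [0, 1]")
    v = spec.resolved_mask(len(x)) * draw
    return AugmentedSample(values=x * v * spec.omega + x, label=label,
                           source_id=source.source_id)


def build_augmented_set(
    train_vectors: Sequence[FeatureVector],
    labels: Sequence[int],
    spec: PerturbationSpec,
) -> list[AugmentedSample]:
    """Generate ``ratio * len(train_vectors)`` augmented samples.

    Source vectors are drawn uniformly at random with replacement from the
    training collection; every augmented sample uses a fresh uniform draw.
    Deterministic given ``spec.seed``.
    """
    if len(train_vectors) == 0:
        raise ValueError("training collection is empty")
    if len(train_vectors) != len(labels):
        raise ValueError("labels must align with train_vectors")
    if spec.ratio < 1:
        raise ValueError("ratio (N/R) must be a positive integer")
    rng = np.random.default_rng(spec.seed)
    n_out = spec.ratio * len(train_vectors)
    picks = rng.integers(0, len(train_vectors), size=n_out)
    out: list[AugmentedSample] = []
    for i in picks:
        draw = rng.uniform(0.0, 1.0, size=len(train_vectors[i].values))
        out.append(perturb(train_vectors[i], spec, draw, int(labels[i])))
    return out


def augmented_matrix(samples: Sequence[AugmentedSample]) -> np.ndarray:
    return np.stack([s.values for s in samples])


def export_augmented_tsv(samples: Sequence[AugmentedSample], path) -> None:
    """Write (source_id, label, values...) rows for inspection."""
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        for s in samples:
            writer.writerow([s.source_id, s.label, *s.values.tolist()])
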