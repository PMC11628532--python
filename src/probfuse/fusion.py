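"""Probability-level ensemble fusion: simple and weighted averaging.

Fusion acts on predicted class probabilities (never logits): the fused
matrix is the convex combination ``sum_k w_k * P_k`` of the per-model
row-stochastic matrices, so it is itself row-stochastic.  Hard labels are
the per-row argmax of the fused matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io import LabelVector, ModelBundle, ProbabilityMatrix

#: tolerance on |sum(weights) - 1| for a valid weight vector.
SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class WeightVector:
    """K non-negative fusion weights on the probability simplex.

    For two models these are the mixing coefficients often written
    (alpha, beta) with alpha + beta = 1.  Weights are validated, never
    silently renormalized: constructing an off-simplex vector raises.
    """

    weights: np.ndarray
    model_names: tuple[str, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "model_names", tuple(map(str, self.model_names)))
        if w.ndim != 1 or w.size == 0:
            raise ValidationError("weights must be a non-empty 1-D vector")
        if len(self.model_names) != w.size:
            raise ValidationError(
                f"{len(self.model_names)} model names for {w.size} weights"
            )
        if not np.all(np.isfinite(w)):
            raise ValidationError("non-finite weight")
        if w.min() < -SIMPLEX_TOL or w.max() > 1.0 + SIMPLEX_TOL:
            raise ValidationError(f"weights must lie in [0, 1], got {w}")
        if abs(w.sum() - 1.0) > SIMPLEX_TOL:
            raise ValidationError(
                f"weights must sum to 1 within {SIMPLEX_TOL}, got sum {w.sum()!r}"
            )

    def __len__(self) -> int:
        return int(self.weights.size)

    @classmethod
    def equal(cls, model_names) -> "WeightVector":
        names = tuple(model_names)
        k = len(names)
        return cls(np.full(k, 1.0 / k), names)


def weighted_average(bundle: ModelBundle, w: WeightVector) -> ProbabilityMatrix:
    """Fuse the bundle's matrices with the given simplex weights.

    ``w.model_names`` must match the bundle's model order exactly; fusion
    refuses to reorder weights because a silent mismatch would corrupt
    results without any numeric symptom.
    """
    if w.model_names != bundle.model_names:
        raise ValidationError(
            f"weight names {w.model_names} do not match bundle models "
            f"{bundle.model_names}"
        )
    fused = np.tensordot(w.weights, bundle.stacked(), axes=(0, 0))
    # exact simplex weights on row-stochastic inputs keep rows summing to 1
    return ProbabilityMatrix(fused, bundle.class_names, bundle.sample_ids)


def simple_average(bundle: ModelBundle) -> ProbabilityMatrix:
    """Entrywise mean of the K matrices (weighted_average with equal weights)."""
    return weighted_average(bundle, WeightVector.equal(bundle.model_names))


def predict(matrix: ProbabilityMatrix) -> LabelVector:
    """Hard labels: per-row argmax, ties broken by lowest class index."""
    return LabelVector(np.argmax(matrix.values, axis=1), matrix.n_classes)
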