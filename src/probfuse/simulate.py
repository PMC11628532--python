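"""Synthetic softmax-output generator for ensembles of imperfect classifiers.

The generator emulates the test-time outputs of K trained multi-class
classifiers without any images or models.  For each sample a true label
is drawn from the class priors; for each model a Bernoulli "correct"
event fires with that model's target accuracy.  Error correlation between
models is introduced by a shared latent draw: with probability
``error_correlation`` all models reuse one uniform variate for the
correct/incorrect decision (so equally accurate models then succeed and
fail on exactly the same samples), otherwise each model draws its own.
On an incorrect event the intended (argmax) class is drawn from a
per-model confusion-bias distribution over the wrong classes.

The emitted row is a Dirichlet draw concentrated on the intended class:
concentration ``sharpness`` there and 1 on every other class, giving
realistic soft, row-stochastic outputs whose argmax matches the intended
class with probability approaching 1 as sharpness grows.  Erroneous rows
use ``error_sharpness`` instead (default: a lower value), reflecting the
well-documented behaviour of trained softmax classifiers, whose maximum
probability is systematically lower on misclassified inputs.  That
confidence asymmetry is what lets probability averaging outvote a
confidently-wrong model with a moderately-confident correct one — the
regime in which ensemble fusion genuinely helps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .io import LabelVector, ModelBundle, ProbabilityMatrix


def _shift_bias(n_classes: int, shift: int) -> np.ndarray:
    """Confusion bias sending every error from class c to class (c+shift) % C."""
    bias = np.zeros((n_classes, n_classes))
    for c in range(n_classes):
        bias[c, (c + shift) % n_classes] = 1.0
    return bias


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic ensemble scenario.

    ``model_accuracies`` are the target argmax accuracies (strictly
    between 0 and 1; values at or below chance 1/C are allowed but give
    uninformative models).  ``sharpness`` is the Dirichlet concentration
    placed on the intended class of a correct row; ``error_sharpness``
    (default ``sharpness / 8``, clipped to at least 2) plays the same role
    for erroneous rows.  ``confusion_bias`` may be one C x C row-stochastic
    matrix shared by all models or one per model; rows give the wrong-class
    distribution and must place no mass on the diagonal.  The default class
    count of 44 mirrors a fine-grained medical-imaging label space; tests
    use smaller C for speed.
    """

    n_samples: int
    model_accuracies: tuple[float, ...]
    n_classes: int = 44
    class_priors: tuple[float, ...] | None = None
    sharpness: float = 50.0
    error_sharpness: float | None = None
    error_correlation: float = 0.0
    confusion_bias: np.ndarray | Sequence[np.ndarray] | None = None
    model_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if self.n_classes < 2:
            raise ValidationError("n_classes must be >= 2")
        accs = tuple(float(a) for a in self.model_accuracies)
        object.__setattr__(self, "model_accuracies", accs)
        if len(accs) < 1:
            raise ValidationError("need at least one model accuracy")
        if any(not 0.0 < a < 1.0 for a in accs):
            raise ValidationError(f"model accuracies must lie in (0, 1), got {accs}")
        if self.class_priors is not None:
            priors = np.asarray(self.class_priors, dtype=float)
            if priors.shape != (self.n_classes,) or priors.min() < 0:
                raise ValidationError("class_priors must be C non-negative reals")
            if abs(priors.sum() - 1.0) > 1e-9:
                raise ValidationError("class_priors must sum to 1")
            object.__setattr__(self, "class_priors", tuple(priors))
        if self.sharpness <= 0:
            raise ValidationError("sharpness must be positive")
        if self.error_sharpness is not None and self.error_sharpness <= 0:
            raise ValidationError("error_sharpness must be positive")
        if not 0.0 <= self.error_correlation <= 1.0:
            raise ValidationError("error_correlation must be in [0, 1]")
        if self.model_names is not None:
            names = tuple(map(str, self.model_names))
            if len(names) != len(accs):
                raise ValidationError("one model name per accuracy required")
            object.__setattr__(self, "model_names", names)
        if self.confusion_bias is not None:
            object.__setattr__(
                self, "confusion_bias", self._validated_biases(self.confusion_bias)
            )

    def _validated_biases(self, bias) -> tuple[np.ndarray, ...]:
        arr = np.asarray(bias, dtype=float) if not isinstance(bias, (list, tuple)) else None
        if arr is not None and arr.ndim == 2:
            biases = [arr] * len(self.model_accuracies)
        else:
            biases = [np.asarray(b, dtype=float) for b in bias]
            if len(biases) != len(self.model_accuracies):
                raise ValidationError("need one confusion_bias per model (or one shared)")
        out = []
        for b in biases:
            if b.shape != (self.n_classes, self.n_classes) or b.min() < 0:
                raise ValidationError("confusion_bias must be C x C non-negative")
            if np.abs(b.sum(axis=1) - 1.0).max() > 1e-9:
                raise ValidationError("confusion_bias rows must sum to 1")
            if np.abs(np.diag(b)).max() > 0:
                raise ValidationError("confusion_bias must place no mass on the true class")
            out.append(b)
        return tuple(out)

    @property
    def n_models(self) -> int:
        return len(self.model_accuracies)

    def resolved_error_sharpness(self) -> float:
        if self.error_sharpness is not None:
            return float(self.error_sharpness)
        return max(self.sharpness / 8.0, 2.0)


def _draw_from_rows(rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One categorical draw per row of a row-stochastic matrix (inverse CDF)."""
    cdf = np.cumsum(rows, axis=1)
    u = rng.random(rows.shape[0])
    return (u[:, None] > cdf).sum(axis=1).clip(0, rows.shape[1] - 1)


def simulate(config: ScenarioConfig, seed: int | None = None) -> ModelBundle:
    """Generate a fully reproducible synthetic bundle for the scenario.

    ``seed`` overrides ``config.seed`` when given.  The bundle carries the
    true labels, so it can be fed directly to evaluation, fusion, and
    weight optimization.
    """
    if config.n_models < 2:
        raise ValidationError("a bundle needs >= 2 models; give >= 2 accuracies")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, c, k = config.n_samples, config.n_classes, config.n_models

    priors = (
        np.full(c, 1.0 / c)
        if config.class_priors is None
        else np.asarray(config.class_priors)
    )
    y_true = rng.choice(c, size=n, p=priors)

    shared_event = rng.random(n) < config.error_correlation
    u_shared = rng.random(n)

    uniform_wrong = (np.ones((c, c)) - np.eye(c)) / (c - 1)
    biases = (
        config.confusion_bias
        if config.confusion_bias is not None
        else (uniform_wrong,) * k
    )

    kappa = config.sharpness
    kappa_err = config.resolved_error_sharpness()
    names = config.model_names or tuple(f"model_{i + 1}" for i in range(k))
    ids = tuple(f"s{i:05d}" for i in range(n))
    class_names = tuple(f"class_{j}" for j in range(c))

    matrices = []
    for m in range(k):
        u_own = rng.random(n)
        u = np.where(shared_event, u_shared, u_own)
        correct = u < config.model_accuracies[m]
        intended = y_true.copy()
        wrong = ~correct
        if wrong.any():
            intended[wrong] = _draw_from_rows(biases[m][y_true[wrong]], rng)
        conc = np.ones((n, c))
        conc[np.arange(n), intended] = np.where(correct, kappa, kappa_err)
        gammas = rng.standard_gamma(conc)
        values = gammas / gammas.sum(axis=1, keepdims=True)
        matrices.append(ProbabilityMatrix(values, class_names, ids))

    return ModelBundle(tuple(matrices), LabelVector(y_true, c), names)


def scenario_s1(seed: int = 0) -> ScenarioConfig:
    """Canonical complementary-error fixture: two equally good models, disjoint mistakes.

    Two models of accuracy 0.80 on N=500 samples over C=5 classes, with
    independent errors (correlation 0) routed to disjoint wrong classes
    (model 1 confuses c with c+1 mod 5, model 2 with c+2 mod 5), sharpness
    50 on correct rows and 6 on erroneous rows.  The disjoint confusions
    plus the confidence asymmetry make an interior fusion weight strictly
    better than either model alone.
    """
    return ScenarioConfig(
        n_samples=500,
        n_classes=5,
        model_accuracies=(0.80, 0.80),
        sharpness=50.0,
        error_sharpness=6.0,
        error_correlation=0.0,
        confusion_bias=(_shift_bias(5, 1), _shift_bias(5, 2)),
        seed=seed,
    )


def scenario_random_pair(seed: int, n_samples: int = 500, n_classes: int = 5) -> ScenarioConfig:
    """Randomized two-model scenario family for stress-testing the optimizer.

    Accuracies are drawn uniformly from (0.55, 0.95), correct-row
    sharpness from (20, 100), erroneous-row sharpness from (3, 10), and
    error correlation from (0, 0.5); errors are routed to disjoint wrong
    classes as in :func:`scenario_s1`.  Every draw is a realistic,
    possibly asymmetric ensemble instance, fully determined by ``seed``.
    """
    rng = np.random.default_rng(seed)
    accuracies = tuple(rng.uniform(0.55, 0.95, size=2))
    return ScenarioConfig(
        n_samples=n_samples,
        n_classes=n_classes,
        model_accuracies=accuracies,
        sharpness=float(rng.uniform(20.0, 100.0)),
        error_sharpness=float(rng.uniform(3.0, 10.0)),
        error_correlation=float(rng.uniform(0.0, 0.5)),
        confusion_bias=(_shift_bias(n_classes, 1), _shift_bias(n_classes, 2)),
        seed=seed,
    )


def scenario_perfect_vs_random(seed: int = 0) -> ScenarioConfig:
    """Boundary fixture: a near-perfect confident model paired with a near-chance one.

    Model 1 has accuracy 0.99999 (virtually always correct on an N=500
    instance) and model 2 is barely above chance at 0.22 for C=5; both
    emit very sharp rows (concentration 1e4).  The optimal fusion puts
    essentially all weight on model 1.
    """
    return ScenarioConfig(
        n_samples=500,
        n_classes=5,
        model_accuracies=(0.99999, 0.22),
        sharpness=1e4,
        error_sharpness=1e4,
        error_correlation=0.0,
        seed=seed,
    )
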