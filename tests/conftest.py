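import numpy as np
import pytest

from probfuse import LabelVector, ModelBundle, ProbabilityMatrix


def make_matrix(rows, class_names=None, sample_ids=None):
    """Build a ProbabilityMatrix from a nested list of probabilities."""
    values = np.asarray(rows, dtype=float)
    n, c = values.shape
    if class_names is None:
        class_names = tuple(f"class_{j}" for j in range(c))
    if sample_ids is None:
        sample_ids = tuple(f"s{i}" for i in range(n))
    return ProbabilityMatrix(values, class_names, sample_ids)


def make_bundle(per_model_rows, labels=None):
    """Bundle K models given as lists of rows, with optional true labels."""
    matrices = tuple(make_matrix(rows) for rows in per_model_rows)
    names = tuple(f"model_{k + 1}" for k in range(len(matrices)))
    lv = None
    if labels is not None:
        lv = LabelVector(np.asarray(labels, dtype=int), matrices[0].n_classes)
    return ModelBundle(matrices, lv, names)


def random_bundle(rng, n=20, c=4, k=3, with_labels=True):
    """Random row-stochastic bundle for fuzz tests."""
    matrices = []
    ids = tuple(f"s{i}" for i in range(n))
    classes = tuple(f"class_{j}" for j in range(c))
    for _ in range(k):
        values = rng.dirichlet(np.ones(c), size=n)
        matrices.append(ProbabilityMatrix(values, classes, ids))
    labels = LabelVector(rng.integers(0, c, size=n), c) if with_labels else None
    return ModelBundle(tuple(matrices), labels, tuple(f"model_{i + 1}" for i in range(k)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_bundle():
    """Two 3-class models on 4 samples with known disagreements."""
    a = [[0.7, 0.2, 0.1], [0.1, 0.8, 0.1], [0.3, 0.3, 0.4], [0.6, 0.3, 0.1]]
    b = [[0.2, 0.6, 0.2], [0.1, 0.7, 0.2], [0.1, 0.2, 0.7], [0.5, 0.4, 0.1]]
    return make_bundle([a, b], labels=[0, 1, 2, 0])
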