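"""Reading, validating, and writing classifier probability outputs.

The on-disk dialect is deliberately plain: a probability matrix is a CSV
file whose first column is ``sample_id`` and whose remaining columns are
class probabilities, one header row naming the classes.  Ground-truth
labels travel either as a two-column ``sample_id,label`` CSV or as a bare
one-integer-per-line file (implicit row-number ids).  Everything else in
the package works on the validated in-memory containers defined here.
"""

from __future__ import annotations

import io as _stdio
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError

#: acceptable |row sum - 1| on ingest without explicit renormalization;
#: softmax outputs serialized at low precision routinely drift this much.
ROW_SUM_INGEST_TOL = 1e-3

#: strict internal tolerance enforced after normalization.
ROW_SUM_TOL = 1e-6


@dataclass(frozen=True)
class ProbabilityMatrix:
    """One model's predicted class probabilities, N samples x C classes.

    Rows are probability vectors: entries in [0, 1], each row summing to 1
    within :data:`ROW_SUM_TOL`.  ``class_names`` fixes the column order and
    ``sample_ids`` the row order; alignment between models is by these ids,
    never by position.
    """

    values: np.ndarray
    class_names: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "class_names", tuple(map(str, self.class_names)))
        object.__setattr__(self, "sample_ids", tuple(map(str, self.sample_ids)))
        if values.ndim != 2:
            raise ValidationError(f"probability matrix must be 2-D, got ndim={values.ndim}")
        n, c = values.shape
        if n < 1:
            raise ValidationError("probability matrix needs at least one sample")
        if c < 2:
            raise ValidationError(f"probability matrix needs >= 2 classes, got {c}")
        if len(self.class_names) != c:
            raise ValidationError(
                f"{len(self.class_names)} class names for {c} columns"
            )
        if len(self.sample_ids) != n:
            raise ValidationError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if not np.all(np.isfinite(values)):
            raise ValidationError("non-finite probability entries")
        if values.min() < 0.0 or values.max() > 1.0 + 1e-12:
            raise ValidationError("probability entries must lie in [0, 1]")
        row_sums = values.sum(axis=1)
        worst = np.abs(row_sums - 1.0).max()
        if worst > ROW_SUM_TOL:
            raise ValidationError(
                f"row sums deviate from 1 by up to {worst:.3g} (tolerance {ROW_SUM_TOL})"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_classes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.class_names))
        df.insert(0, "sample_id", list(self.sample_ids))
        return df

    def reordered(self, sample_ids: Sequence[str]) -> "ProbabilityMatrix":
        """Return a copy with rows permuted into the given sample-id order."""
        index = {sid: i for i, sid in enumerate(self.sample_ids)}
        missing = [sid for sid in sample_ids if sid not in index]
        if missing:
            raise ValidationError(f"sample ids absent from matrix: {missing[:5]}")
        if len(sample_ids) != self.n_samples:
            raise ValidationError(
                f"requested {len(sample_ids)} rows from a {self.n_samples}-row matrix"
            )
        perm = np.array([index[sid] for sid in sample_ids])
        return ProbabilityMatrix(self.values[perm], self.class_names, tuple(sample_ids))


@dataclass(frozen=True)
class LabelVector:
    """N integer class labels in [0, n_classes)."""

    labels: np.ndarray
    n_classes: int

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 1 or labels.size == 0:
            raise ValidationError("labels must be a non-empty 1-D sequence")
        if not np.issubdtype(labels.dtype, np.integer):
            as_int = labels.astype(int)
            if not np.array_equal(as_int, labels):
                raise ValidationError("labels must be integers")
            labels = as_int
        object.__setattr__(self, "labels", labels)
        if self.n_classes < 2:
            raise ValidationError("n_classes must be >= 2")
        if labels.min() < 0 or labels.max() >= self.n_classes:
            raise ValidationError(
                f"labels must lie in [0, {self.n_classes}), "
                f"got range [{labels.min()}, {labels.max()}]"
            )

    def __len__(self) -> int:
        return int(self.labels.size)


@dataclass(frozen=True)
class ModelBundle:
    """K aligned probability matrices plus (optionally) ground-truth labels.

    All matrices share class order, sample-id order, and shape, so fusion
    can operate positionally.  ``labels`` may be ``None`` for pure fusion;
    evaluation and weight optimization require it.
    """

    matrices: tuple[ProbabilityMatrix, ...]
    labels: LabelVector | None
    model_names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrices", tuple(self.matrices))
        object.__setattr__(self, "model_names", tuple(map(str, self.model_names)))
        if len(self.matrices) < 2:
            raise ValidationError("a bundle needs >= 2 models")
        if len(self.model_names) != len(self.matrices):
            raise ValidationError("one model name per matrix required")
        if len(set(self.model_names)) != len(self.model_names):
            raise ValidationError("duplicate model names")
        ref = self.matrices[0]
        for name, m in zip(self.model_names[1:], self.matrices[1:]):
            if m.class_names != ref.class_names:
                raise ValidationError(f"class names of {name!r} differ from first model")
            if m.sample_ids != ref.sample_ids:
                raise ValidationError(f"sample ids of {name!r} differ from first model")
        if self.labels is not None:
            if len(self.labels) != ref.n_samples:
                raise ValidationError(
                    f"{len(self.labels)} labels for {ref.n_samples} samples"
                )
            if self.labels.n_classes != ref.n_classes:
                raise ValidationError(
                    f"labels declare {self.labels.n_classes} classes, "
                    f"matrices have {ref.n_classes}"
                )

    @property
    def n_models(self) -> int:
        return len(self.matrices)

    @property
    def n_samples(self) -> int:
        return self.matrices[0].n_samples

    @property
    def n_classes(self) -> int:
        return self.matrices[0].n_classes

    @property
    def class_names(self) -> tuple[str, ...]:
        return self.matrices[0].class_names

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return self.matrices[0].sample_ids

    def stacked(self) -> np.ndarray:
        """(K, N, C) array view of the matrices for vectorized fusion."""
        return np.stack([m.values for m in self.matrices])

    def subset(self, indices: np.ndarray) -> "ModelBundle":
        """Bundle restricted to the given sample positions (e.g. a holdout split)."""
        ids = tuple(self.sample_ids[i] for i in indices)
        mats = tuple(
            ProbabilityMatrix(m.values[indices], m.class_names, ids)
            for m in self.matrices
        )
        labels = None
        if self.labels is not None:
            labels = LabelVector(self.labels.labels[indices], self.labels.n_classes)
        return ModelBundle(mats, labels, self.model_names)


def read_probability_matrix(path: str | os.PathLike, renormalize: bool = False) -> ProbabilityMatrix:
    """Read one model's probability matrix from CSV.

    Without ``renormalize``, row sums must already be within
    :data:`ROW_SUM_INGEST_TOL` of 1; with it, any strictly positive row sum
    is accepted.  In both cases rows are divided by their sums so the
    returned matrix meets the strict internal tolerance.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such probability matrix file: {path}")
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 3:
        raise FormatError(
            f"{path}: expected a sample_id column plus >= 2 class columns"
        )
    if df.columns[0] != "sample_id":
        raise FormatError(
            f"{path}: first column must be named 'sample_id', got {df.columns[0]!r}"
        )
    try:
        values = df.iloc[:, 1:].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric probability cell ({exc})") from exc
    if not np.all(np.isfinite(values)):
        raise FormatError(f"{path}: non-finite probability cell")
    if values.min() < 0:
        raise FormatError(f"{path}: negative probability entry {values.min():.3g}")
    row_sums = values.sum(axis=1)
    if renormalize:
        bad = np.flatnonzero(row_sums <= 0)
        if bad.size:
            raise FormatError(f"{path}: row {bad[0]} sums to 0, cannot renormalize")
    else:
        dev = np.abs(row_sums - 1.0)
        bad = np.flatnonzero(dev > ROW_SUM_INGEST_TOL)
        if bad.size:
            raise FormatError(
                f"{path}: row {bad[0]} sums to {row_sums[bad[0]]:.6g}, outside "
                f"[1-{ROW_SUM_INGEST_TOL}, 1+{ROW_SUM_INGEST_TOL}] "
                "(pass renormalize to accept)"
            )
    values = values / row_sums[:, None]
    return ProbabilityMatrix(
        values,
        tuple(df.columns[1:]),
        tuple(df.iloc[:, 0].astype(str)),
    )


def read_labels(path: str | os.PathLike) -> tuple[tuple[str, ...] | None, np.ndarray]:
    """Read ground-truth labels.

    Returns ``(sample_ids, labels)``; ``sample_ids`` is ``None`` for the
    bare one-label-per-line format, where ids are implicit row numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such labels file: {path}")
    text = path.read_text()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty labels file")
    first = [tok.strip() for tok in lines[0].split(",")]
    if first == ["sample_id", "label"]:
        df = pd.read_csv(_stdio.StringIO(text), dtype={"sample_id": str})
        try:
            labels = df["label"].to_numpy(dtype=int)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: non-integer label ({exc})") from exc
        return tuple(df["sample_id"].astype(str)), labels
    if len(first) == 1:
        try:
            labels = np.array([int(ln) for ln in lines])
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer label line ({exc})") from exc
        return None, labels
    raise FormatError(
        f"{path}: expected 'sample_id,label' header or one integer per line"
    )


def assemble_bundle(
    matrix_paths: Sequence[str | os.PathLike],
    labels_path: str | os.PathLike | None = None,
    renormalize: bool = False,
) -> ModelBundle:
    """Read >= 2 probability matrices (and optional labels) into an aligned bundle.

    Model names come from the file stems.  With an id-bearing labels file,
    every matrix is re-ordered by sample id to the labels order; a bare
    labels file requires all matrices to already agree on row order.
    """
    if len(matrix_paths) < 2:
        raise ValidationError(f"need >= 2 matrix paths, got {len(matrix_paths)}")
    names = []
    for p in matrix_paths:
        stem = Path(p).stem
        name = stem
        k = 2
        while name in names:  # disambiguate identical stems from different dirs
            name = f"{stem}_{k}"
            k += 1
        names.append(name)
    matrices = [read_probability_matrix(p, renormalize=renormalize) for p in matrix_paths]

    ref = matrices[0]
    for name, m in zip(names[1:], matrices[1:]):
        if m.class_names != ref.class_names:
            raise ValidationError(
                f"class names of {name!r} differ from {names[0]!r}: "
                f"{m.class_names} vs {ref.class_names}"
            )

    labels_vec = None
    if labels_path is not None:
        label_ids, labels = read_labels(labels_path)
        if label_ids is not None:
            matrices = [m.reordered(label_ids) for m in matrices]
        else:
            if len(labels) != ref.n_samples:
                raise ValidationError(
                    f"{len(labels)} labels for {ref.n_samples} samples"
                )
            for name, m in zip(names[1:], matrices[1:]):
                if m.sample_ids != ref.sample_ids:
                    raise ValidationError(
                        f"bare labels file requires identical row order, but "
                        f"{name!r} disagrees with {names[0]!r}; use sample_id,label"
                    )
        labels_vec = LabelVector(labels, ref.n_classes)
    else:
        # align all matrices to the first one's row order
        matrices = [matrices[0]] + [m.reordered(ref.sample_ids) for m in matrices[1:]]

    return ModelBundle(tuple(matrices), labels_vec, tuple(names))


def write_matrix(matrix: ProbabilityMatrix, path: str | os.PathLike) -> None:
    """Write a probability matrix in the package CSV dialect at full precision."""
    df = matrix.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")


def write_weights(weights, path: str | os.PathLike) -> None:
    """Write fusion weights as ``model_name,weight`` CSV lines."""
    names = list(weights.model_names)
    vals = np.asarray(weights.weights, dtype=float)
    if len(names) == 0:
        raise ValidationError("cannot write an empty weight vector")
    lines = ["model_name,weight"]
    lines += [f"{n},{float(v)!r}" for n, v in zip(names, vals)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_weights(path: str | os.PathLike):
    """Read a ``model_name,weight`` CSV written by :func:`write_weights`."""
    from .fusion import WeightVector

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such weights file: {path}")
    df = pd.read_csv(path, dtype={"model_name": str})
    if list(df.columns) != ["model_name", "weight"]:
        raise FormatError(f"{path}: expected header 'model_name,weight'")
    return WeightVector(
        df["weight"].to_numpy(dtype=float), tuple(df["model_name"].astype(str))
    )


def write_report(report, path: str | os.PathLike) -> None:
    """Serialize an evaluation report as YAML key-value text at full precision."""
    with open(path, "w") as fh:
        yaml.safe_dump(report.to_dict(), fh, sort_keys=False)


def read_report(path: str | os.PathLike) -> dict:
    """Read back a YAML report written by :func:`write_report`."""
    with open(path) as fh:
        return yaml.safe_load(fh)
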