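"""Multi-class evaluation metrics from one-vs-rest confusion counts.

Per class c the predictions are reduced to a binary problem (c vs rest),
giving counts TP, FP, FN, TN with TP+FP+FN+TN = N.  From these:

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = TP / (TP + 0.5 * (FN + FP))

(the last is algebraically 2PR/(P+R) whenever P+R > 0).  Per-class values
are aggregated across classes by macro (unweighted mean), weighted
(support-weighted mean, the default — it makes aggregated recall coincide
with overall accuracy for single-label data), or micro (metrics of the
pooled counts) averaging.  Any 0/0 ratio is defined as 0 with a logged
warning: with many classes, empty predicted or true classes are routine
and must not abort a fitness evaluation.

Top-k accuracy is the fraction of samples whose true class is among the k
highest-probability classes, probability ties broken by lowest class index
(consistent with :func:`probfuse.fusion.predict`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io import LabelVector, ProbabilityMatrix

logger = logging.getLogger(__name__)

AGGREGATION_SCHEMES = ("micro", "macro", "weighted")


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class one-vs-rest confusion counts over N samples."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            arr = np.asarray(getattr(self, name), dtype=int)
            object.__setattr__(self, name, arr)
            if arr.ndim != 1 or (arr < 0).any():
                raise ValidationError(f"{name} must be 1-D non-negative counts")
        totals = self.tp + self.fp + self.fn + self.tn
        if len(set(totals.tolist())) > 1:
            raise ValidationError("TP+FP+FN+TN must equal N for every class")

    @property
    def n_classes(self) -> int:
        return int(self.tp.size)

    @property
    def n_samples(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.fn[0] + self.tn[0])

    @property
    def support(self) -> np.ndarray:
        """Number of ground-truth samples per class."""
        return self.tp + self.fn


def _as_labels(y) -> np.ndarray:
    if isinstance(y, LabelVector):
        return y.labels
    return np.asarray(y, dtype=int)


def confusion_counts(y_true, y_pred, n_classes: int | None = None) -> ConfusionCounts:
    """One-vs-rest TP/FP/FN/TN for each of the C classes."""
    yt, yp = _as_labels(y_true), _as_labels(y_pred)
    if yt.shape != yp.shape:
        raise ValidationError(f"length mismatch: {yt.size} true vs {yp.size} predicted")
    if yt.size == 0:
        raise ValidationError("empty label vectors")
    if n_classes is None:
        candidates = [int(yt.max()) + 1, int(yp.max()) + 1]
        if isinstance(y_true, LabelVector):
            candidates.append(y_true.n_classes)
        if isinstance(y_pred, LabelVector):
            candidates.append(y_pred.n_classes)
        n_classes = max(candidates)
    if yt.min() < 0 or yp.min() < 0 or yt.max() >= n_classes or yp.max() >= n_classes:
        raise ValidationError(f"labels out of range [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (yt, yp), 1)
    tp = np.diag(cm)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = yt.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def _safe_div(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    zero = den == 0
    if np.any(zero):
        logger.warning(
            "%s undefined (0/0) for %d class(es); reporting 0 by convention",
            what,
            int(np.count_nonzero(zero)),
        )
    out = np.zeros_like(num, dtype=float)
    np.divide(num, den, out=out, where=~zero)
    return out


def class_metrics(counts: ConfusionCounts) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class (precision, recall, F1); 0/0 cases return 0."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    f1 = _safe_div(tp, tp + 0.5 * (fn + fp), "F1")
    return precision, recall, f1


def overall_accuracy(y_true, y_pred) -> float:
    """Fraction of samples with matching predicted and true label."""
    yt, yp = _as_labels(y_true), _as_labels(y_pred)
    if yt.shape != yp.shape:
        raise ValidationError(f"length mismatch: {yt.size} true vs {yp.size} predicted")
    if yt.size == 0:
        raise ValidationError("empty label vectors")
    return float(np.mean(yt == yp))


def aggregate(counts: ConfusionCounts, scheme: str = "weighted") -> tuple[float, float, float]:
    """Aggregate per-class precision/recall/F1 across classes.

    ``macro``: unweighted mean; ``weighted``: support-weighted mean;
    ``micro``: precision/recall/F1 of the pooled one-vs-rest counts (all
    three coincide with accuracy for single-label multi-class data).
    """
    if scheme not in AGGREGATION_SCHEMES:
        raise ValidationError(f"unknown aggregation scheme {scheme!r}")
    if scheme == "micro":
        tp, fp, fn = counts.tp.sum(), counts.fp.sum(), counts.fn.sum()
        p = _safe_div(np.array(tp), np.array(tp + fp), "micro precision").item()
        r = _safe_div(np.array(tp), np.array(tp + fn), "micro recall").item()
        f = _safe_div(np.array(tp, dtype=float), np.array(tp + 0.5 * (fn + fp)), "micro F1").item()
        return p, r, f
    precision, recall, f1 = class_metrics(counts)
    if scheme == "macro":
        return float(precision.mean()), float(recall.mean()), float(f1.mean())
    support = counts.support
    total = support.sum()
    if total == 0:
        raise ValidationError("cannot support-weight with zero total support")
    w = support / total
    return float(w @ precision), float(w @ recall), float(w @ f1)


def top_k_accuracy(matrix: ProbabilityMatrix, y_true, k: int) -> float:
    """Fraction of samples whose true class ranks among the top k probabilities."""
    if not 1 <= k <= matrix.n_classes:
        raise ValidationError(f"k must be in [1, {matrix.n_classes}], got {k}")
    yt = _as_labels(y_true)
    if yt.size != matrix.n_samples:
        raise ValidationError(f"{yt.size} labels for {matrix.n_samples} rows")
    # stable sort on negated values: equal probabilities keep ascending class order
    order = np.argsort(-matrix.values, axis=1, kind="stable")
    hits = (order[:, :k] == yt[:, None]).any(axis=1)
    return float(hits.mean())


@dataclass(frozen=True)
class EvaluationReport:
    """Full evaluation of one probability matrix against ground truth."""

    accuracy: float
    per_class: dict
    aggregated: dict
    top_k: dict
    class_names: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "accuracy": float(self.accuracy),
            "aggregated": {
                scheme: {m: float(v) for m, v in vals.items()}
                for scheme, vals in self.aggregated.items()
            },
            "top_k": {f"top_{k}": float(v) for k, v in sorted(self.top_k.items())},
            "per_class": {
                name: {m: (float(v) if m != "support" else int(v)) for m, v in vals.items()}
                for name, vals in self.per_class.items()
            },
        }


def evaluate(matrix: ProbabilityMatrix, y_true, ks=(1, 3)) -> EvaluationReport:
    """Evaluate a (fused or single-model) probability matrix.

    Computes overall accuracy of the argmax predictions, per-class and
    aggregated precision/recall/F1, and top-k accuracy for each requested k
    (ks beyond the class count are dropped).
    """
    from .fusion import predict

    yt = _as_labels(y_true)
    y_pred = predict(matrix).labels
    counts = confusion_counts(yt, y_pred, n_classes=matrix.n_classes)
    precision, recall, f1 = class_metrics(counts)
    support = counts.support
    per_class = {
        name: {
            "precision": float(precision[i]),
            "recall": float(recall[i]),
            "f1": float(f1[i]),
            "support": int(support[i]),
        }
        for i, name in enumerate(matrix.class_names)
    }
    aggregated = {}
    for scheme in AGGREGATION_SCHEMES:
        p, r, f = aggregate(counts, scheme)
        aggregated[scheme] = {"precision": p, "recall": r, "f1": f}
    top_k = {
        int(k): top_k_accuracy(matrix, yt, int(k))
        for k in ks
        if 1 <= int(k) <= matrix.n_classes
    }
    return EvaluationReport(
        accuracy=overall_accuracy(yt, y_pred),
        per_class=per_class,
        aggregated=aggregated,
        top_k=top_k,
        class_names=matrix.class_names,
    )
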