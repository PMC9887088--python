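"""Metrics, bootstrap confidence intervals and confidence calibration.

Four metrics summarise classifier performance: accuracy, macro-averaged
F1, the multiclass Matthews correlation coefficient (MCC) and balanced
accuracy (macro recall).  95% confidence intervals come from resampling the
test set with replacement (1000 replicates by default) and multiplying the
bootstrap standard deviation by 1.96.  Calibration maps a prediction-
probability threshold to the error rate among retained predictions and the
fraction retained (coverage), so a threshold can be chosen for a target
error rate.  CATH-hierarchy-aware agreement gives partial credit at the
Class/Architecture/Topology levels for misclassified domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    balanced_accuracy_score,
    f1_score,
    matthews_corrcoef,
)

from .classifier import PredictionResult
from .records import NO_HIT_LABEL, OTHER_LABEL, is_superfamily_label

__all__ = [
    "MetricReport",
    "BootstrapCI",
    "CalibrationCurve",
    "HierarchyAgreement",
    "CalibrationError",
    "compute_metrics",
    "bootstrap_ci",
    "calibration_curve",
    "threshold_for_error",
    "hierarchy_agreement",
]

METRIC_NAMES = ("accuracy", "f1", "mcc", "balanced_accuracy")


class CalibrationError(RuntimeError):
    """No probability threshold achieves the requested error rate."""


@dataclass
class MetricReport:
    accuracy: float
    f1: float
    mcc: float
    balanced_accuracy: float
    n: int
    f1_average: str = "macro"
    per_class_f1: Optional[Dict[str, float]] = None

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "f1": self.f1,
            "mcc": self.mcc,
            "balanced_accuracy": self.balanced_accuracy,
            "n": self.n,
            "f1_average": self.f1_average,
        }


def compute_metrics(
    y_true: Sequence,
    y_pred: Sequence,
    f1_average: str = "macro",
    per_class: bool = False,
) -> MetricReport:
    """Accuracy, F1, MCC and balanced accuracy for label vectors.

    F1 and balanced accuracy average over the labels present in ``y_true``
    (macro by default; ``f1_average="weighted"`` switches convention and is
    recorded in the report).  Predictions outside the true-label set — e.g.
    the reserved ``no_hit`` outcome — count as plain errors.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or len(y_true) == 0:
        raise ValueError("y_true and y_pred must be equal-length 1-D vectors")
    true_labels = np.unique(y_true)
    import warnings as _warnings

    with _warnings.catch_warnings():
        # predictions outside the true-label set (e.g. "no_hit") are
        # legitimate errors, not a data problem worth warning about
        _warnings.filterwarnings(
            "ignore", message="y_pred contains classes not in y_true"
        )
        report = MetricReport(
            accuracy=float(accuracy_score(y_true, y_pred)),
            f1=float(
                f1_score(
                    y_true, y_pred, labels=true_labels, average=f1_average,
                    zero_division=0,
                )
            ),
            mcc=float(matthews_corrcoef(y_true, y_pred)),
            balanced_accuracy=float(balanced_accuracy_score(y_true, y_pred)),
            n=len(y_true),
            f1_average=f1_average,
        )
    if per_class:
        scores = f1_score(
            y_true, y_pred, labels=true_labels, average=None, zero_division=0
        )
        report.per_class_f1 = {str(l): float(s) for l, s in zip(true_labels, scores)}
    return report


@dataclass
class BootstrapCI:
    metric: str
    point: float
    half_width: float
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        if self.half_width < 0:
            raise ValueError("half_width must be >= 0")


def bootstrap_ci(
    y_true: Sequence,
    y_pred: Sequence,
    n_boot: int = 1000,
    seed: int = 0,
    f1_average: str = "macro",
) -> List[BootstrapCI]:
    """95% CIs by test-set bootstrap: half-width = 1.96 x SD over ``n_boot``
    resamples of the (true, predicted) pairs.  Predictions are fixed; only
    the evaluation sample is resampled."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    n = len(y_true)
    if n < 2:
        raise ValueError("need at least 2 samples to bootstrap")
    rng = np.random.default_rng(seed)
    point = compute_metrics(y_true, y_pred, f1_average=f1_average)
    samples = {m: np.empty(n_boot) for m in METRIC_NAMES}
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        rep = compute_metrics(y_true[idx], y_pred[idx], f1_average=f1_average)
        for m in METRIC_NAMES:
            samples[m][b] = getattr(rep, m)
    return [
        BootstrapCI(
            metric=m,
            point=getattr(point, m),
            half_width=float(1.96 * samples[m].std(ddof=1)),
            n_boot=n_boot,
            seed=seed,
        )
        for m in METRIC_NAMES
    ]


@dataclass
class CalibrationCurve:
    """Error rate and coverage as functions of a confidence threshold.

    ``error_rate[i]`` is the fraction of wrong predictions among those with
    ``max_proba >= thresholds[i]``; ``coverage[i]`` the fraction retained.
    Thresholds with zero coverage report error 0 with ``zero_coverage`` set
    so downstream threshold selection can skip them.
    """

    thresholds: np.ndarray
    error_rate: np.ndarray
    coverage: np.ndarray
    zero_coverage: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=np.float64)
        self.error_rate = np.asarray(self.error_rate, dtype=np.float64)
        self.coverage = np.asarray(self.coverage, dtype=np.float64)
        self.zero_coverage = np.asarray(self.zero_coverage, dtype=bool)
        if not (
            len(self.thresholds) == len(self.error_rate)
            == len(self.coverage) == len(self.zero_coverage)
        ):
            raise ValueError("curve arrays must have equal length")
        if np.any(np.diff(self.thresholds) < 0):
            raise ValueError("thresholds must be ascending")


def calibration_curve(
    y_true: Sequence,
    predictions: PredictionResult,
    thresholds: Sequence[float] = None,
) -> CalibrationCurve:
    """Sweep confidence thresholds over a prediction set."""
    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 1.0001, 0.05), 10)
    thresholds = np.sort(np.asarray(thresholds, dtype=np.float64))
    if np.any(thresholds < 0) or np.any(thresholds > 1):
        raise ValueError("thresholds must lie in [0, 1]")
    y_true = np.asarray(y_true)
    y_pred = np.asarray(predictions.predicted_label)
    conf = predictions.max_proba
    n = len(y_true)
    if n != len(y_pred):
        raise ValueError("label vector does not match predictions")
    wrong = y_true != y_pred
    error, coverage, empty = [], [], []
    for t in thresholds:
        covered = conf >= t
        m = int(covered.sum())
        coverage.append(m / n)
        if m == 0:
            error.append(0.0)
            empty.append(True)
        else:
            error.append(float(wrong[covered].mean()))
            empty.append(False)
    return CalibrationCurve(thresholds, error, coverage, empty)


def threshold_for_error(
    curve: CalibrationCurve, max_error: float = 0.005
) -> Tuple[float, float]:
    """Smallest threshold with error_rate <= ``max_error`` and nonzero
    coverage.  Returns (threshold, coverage); raises
    :class:`CalibrationError` if no threshold qualifies."""
    for t, err, cov, empty in zip(
        curve.thresholds, curve.error_rate, curve.coverage, curve.zero_coverage
    ):
        if not empty and err <= max_error:
            return float(t), float(cov)
    raise CalibrationError(
        f"uncalibratable: no threshold reaches error rate <= {max_error} "
        "with nonzero coverage"
    )


@dataclass
class HierarchyAgreement:
    """Partial CATH-hierarchy credit over misclassified domains."""

    n_misclassified: int
    correct_class: int
    correct_architecture: int
    correct_topology: int

    def __post_init__(self) -> None:
        for v in (self.correct_class, self.correct_architecture, self.correct_topology):
            if v > self.n_misclassified:
                raise ValueError("level count exceeds misclassification count")


def _split_node(label: str) -> Optional[List[str]]:
    if label in (OTHER_LABEL, NO_HIT_LABEL):
        return None
    if not is_superfamily_label(label):
        raise ValueError(f"malformed CATH node string: {label!r}")
    return label.split(".")


def hierarchy_agreement(y_true: Sequence[str], y_pred: Sequence[str]) -> HierarchyAgreement:
    """Count misclassified pairs that still agree at higher CATH levels.

    Only pairs where both labels are dotted nodes earn prefix credit;
    ``other``/``no_hit`` predictions are misclassified with no credit.
    """
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    n_mis = c1 = c2 = c3 = 0
    for t, p in zip(y_true, y_pred):
        if t == p:
            continue
        n_mis += 1
        tp, pp = _split_node(t), _split_node(p)
        if tp is None or pp is None:
            continue
        if tp[0] == pp[0]:
            c1 += 1
            if tp[1] == pp[1]:
                c2 += 1
                if tp[2] == pp[2]:
                    c3 += 1
    return HierarchyAgreement(n_mis, c1, c2, c3)
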