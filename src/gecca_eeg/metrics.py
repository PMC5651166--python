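"""Evaluation metrics for artifact removal.

All signal-level metrics compare three aligned signals: the ``raw``
(contaminated) channel, the ``filtered`` output of the pipeline, and the
``reference`` channel taken as the closest available stand-in for clean
EEG.  On synthetic data the reference may be the true clean signal.

* ``dsnr`` — the SNR *gain* in dB: the ratio of the raw error power to the
  filtered error power, both measured against the reference.
* ``lambda_metric`` — the fraction (in percent) of the attainable
  correlation with the reference that filtering recovered.
* ``correlation_improvement`` — plain difference of Pearson correlations.
* confusion counts and ROC parameters (sensitivity, specificity, PPV, NPV,
  accuracy) from per-sample artifact masks.

Per-sample artifact "truth" on real recordings is inherently a surrogate:
``artifact_masks`` labels a sample as artifact when it departs from the
reference by more than ``theta`` reference standard deviations.  On
synthetic data the generator's true event intervals should be preferred.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "ConfusionCounts",
    "RocParameters",
    "EvaluationReport",
    "mse",
    "rmse",
    "pearson",
    "dsnr",
    "correlation_improvement",
    "lambda_metric",
    "artifact_masks",
    "confusion_counts",
    "roc_parameters",
    "evaluate",
]

DSNR_CAP_DB = 120.0


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class RocParameters:
    """ROC operating-point parameters; a field is ``None`` when its
    denominator is zero (never coerced to 0)."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None


@dataclass
class EvaluationReport:
    """Full evaluation of one cleaned channel against a reference."""

    mse: float
    rmse: float
    dsnr_db: float
    lambda_pct: float
    corr_improvement: float
    confusion: ConfusionCounts
    roc: RocParameters
    config_echo: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "mse": self.mse,
            "rmse": self.rmse,
            "dsnr_db": self.dsnr_db,
            "lambda_pct": self.lambda_pct,
            "corr_improvement": self.corr_improvement,
            "confusion": {
                "tp": self.confusion.tp,
                "tn": self.confusion.tn,
                "fp": self.confusion.fp,
                "fn": self.confusion.fn,
            },
            "roc": {
                "sen": self.roc.sensitivity,
                "spe": self.roc.specificity,
                "ppv": self.roc.ppv,
                "npv": self.roc.npv,
                "accuracy_pct": None
                if self.roc.accuracy is None
                else 100.0 * self.roc.accuracy,
            },
            "config_echo": self.config_echo,
        }


def _check_lengths(*signals: np.ndarray) -> list[np.ndarray]:
    arrs = [np.asarray(s, dtype=float).ravel() for s in signals]
    if len({a.size for a in arrs}) != 1:
        raise ValueError(f"length mismatch: {[a.size for a in arrs]}")
    return arrs


def mse(x: np.ndarray, y: np.ndarray) -> float:
    """Mean squared error ``(1/n) * sum((x - y)**2)``."""
    a, b = _check_lengths(x, y)
    return float(np.mean((a - b) ** 2))


def rmse(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.sqrt(mse(x, y)))


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; 0 (with a warning) for zero-variance input."""
    a, b = _check_lengths(x, y)
    sa, sb = np.std(a), np.std(b)
    if sa == 0 or sb == 0:
        warnings.warn(
            "zero-variance signal in Pearson correlation; returning 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def dsnr(raw: np.ndarray, filtered: np.ndarray, reference: np.ndarray) -> float:
    """SNR gain of filtering, in dB, capped at +/-120 dB.

    ``10 * log10( sum((raw - ref)^2) / sum((filtered - ref)^2) )`` — positive
    when filtering moved the signal toward the reference.
    """
    r, f, ref = _check_lengths(raw, filtered, reference)
    num = float(np.sum((r - ref) ** 2))
    den = float(np.sum((f - ref) ** 2))
    if num == 0 and den == 0:
        warnings.warn(
            "raw and filtered both equal the reference; DSNR defined as 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    if den == 0:
        return DSNR_CAP_DB
    if num == 0:
        return -DSNR_CAP_DB
    return float(np.clip(10.0 * np.log10(num / den), -DSNR_CAP_DB, DSNR_CAP_DB))


def correlation_improvement(
    raw: np.ndarray, filtered: np.ndarray, reference: np.ndarray
) -> float:
    """``r(filtered, reference) - r(raw, reference)``."""
    r, f, ref = _check_lengths(raw, filtered, reference)
    return pearson(f, ref) - pearson(r, ref)


def lambda_metric(
    raw: np.ndarray, filtered: np.ndarray, reference: np.ndarray
) -> float:
    """Percent of the attainable correlation recovered by filtering.

    ``100 * (r(filtered, ref) - r(raw, ref)) / (1 - r(raw, ref))``; when the
    raw signal is already perfectly correlated with the reference there is
    nothing left to recover and the value is defined as 100.
    """
    r, f, ref = _check_lengths(raw, filtered, reference)
    r_raw = pearson(r, ref)
    if r_raw >= 1.0:
        return 100.0
    return float(100.0 * (pearson(f, ref) - r_raw) / (1.0 - r_raw))


def artifact_masks(
    raw: np.ndarray,
    filtered: np.ndarray,
    reference: np.ndarray,
    theta: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Surrogate per-sample artifact labels and detections.

    A sample is *truly* artifactual when the raw channel departs from the
    reference by more than ``theta`` reference standard deviations; it is
    *detected* as artifactual when filtering changed it by more than the
    same margin.
    """
    r, f, ref = _check_lengths(raw, filtered, reference)
    margin = theta * float(np.std(ref))
    truth = np.abs(r - ref) > margin
    detected = np.abs(r - f) > margin
    return truth, detected


def confusion_counts(truth_mask: np.ndarray, detected_mask: np.ndarray) -> ConfusionCounts:
    """Per-sample tabulation of detections against truth."""
    t = np.asarray(truth_mask, dtype=bool).ravel()
    d = np.asarray(detected_mask, dtype=bool).ravel()
    if t.size != d.size:
        raise ValueError(f"mask length mismatch: {t.size} vs {d.size}")
    return ConfusionCounts(
        tp=int(np.sum(t & d)),
        tn=int(np.sum(~t & ~d)),
        fp=int(np.sum(~t & d)),
        fn=int(np.sum(t & ~d)),
    )


def roc_parameters(counts: ConfusionCounts) -> RocParameters:
    """Sensitivity, specificity, PPV, NPV and accuracy from counts.

    Sen = TP/(TP+FN); Spe = TN/(TN+FP); PPV = TP/(TP+FP);
    NPV = TN/(TN+FN); accuracy = (TP+TN)/total.  A ratio with zero
    denominator is reported as ``None``.
    """

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return RocParameters(
        sensitivity=ratio(counts.tp, counts.tp + counts.fn),
        specificity=ratio(counts.tn, counts.tn + counts.fp),
        ppv=ratio(counts.tp, counts.tp + counts.fp),
        npv=ratio(counts.tn, counts.tn + counts.fn),
        accuracy=ratio(counts.tp + counts.tn, counts.total),
    )


def evaluate(
    raw: np.ndarray,
    filtered: np.ndarray,
    reference: np.ndarray,
    theta: float = 1.0,
    config_echo: dict[str, Any] | None = None,
) -> EvaluationReport:
    """Assemble the full report for one cleaned channel."""
    truth, detected = artifact_masks(raw, filtered, reference, theta)
    counts = confusion_counts(truth, detected)
    echo = dict(config_echo or {})
    echo.setdefault("theta", theta)
    echo.setdefault("dsnr_definition", "10*log10(sum((raw-ref)^2)/sum((filt-ref)^2))")
    echo.setdefault("lambda_definition", "100*(r_filt - r_raw)/(1 - r_raw)")
    return EvaluationReport(
        mse=mse(filtered, reference),
        rmse=rmse(filtered, reference),
        dsnr_db=dsnr(raw, filtered, reference),
        lambda_pct=lambda_metric(raw, filtered, reference),
        corr_improvement=correlation_improvement(raw, filtered, reference),
        confusion=counts,
        roc=roc_parameters(counts),
        config_echo=echo,
    )
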