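"""Millimetre error metrics and accuracy statistics.

All errors are Euclidean distances computed in original-resolution pixel
space (predictions are denormalized by the original width/height first)
and converted to millimetres with the fixed export scale of
0.1 mm/pixel.  On top of the per-landmark error tables this module
provides success rates at clinical thresholds (boundary inclusive),
cumulative-error-distribution areas (AUC-CED by trapezoidal integration
over 2-4 mm), one-sample significance tests against zero error,
compound two-landmark uncertainty, and the effective-scale consistency
check (coefficient of variation of per-subject mm/pixel ratios).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .schemas import AnnotatedImage, PointAnnotation, get_schema

BASE_SCALE_MM_PER_PX = 0.1
CLINICAL_THRESHOLD_MM = 2.0
DEFAULT_CED_THRESHOLDS = (2.0, 2.5, 3.0, 4.0)
CV_PASS_THRESHOLD_PCT = 10.0


@dataclass(frozen=True)
class ScaleCalibration:
    """Pixel-to-millimetre conversion at original export resolution."""

    base_scale_mm_per_px: float = BASE_SCALE_MM_PER_PX
    per_subject_effective_scale: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.base_scale_mm_per_px > 0:
            raise ValueError("scale must be positive")


def px_error_to_mm(p_true: Sequence[float] | PointAnnotation,
                   p_pred: Sequence[float] | PointAnnotation,
                   scale: float = BASE_SCALE_MM_PER_PX) -> float:
    """Euclidean error between two points in mm: ||true - pred|| * scale."""
    if isinstance(p_true, PointAnnotation):
        p_true = (p_true.x, p_true.y)
    if isinstance(p_pred, PointAnnotation):
        p_pred = (p_pred.x, p_pred.y)
    if not scale > 0:
        raise ValueError("scale must be positive")
    dx = float(p_true[0]) - float(p_pred[0])
    dy = float(p_true[1]) - float(p_pred[1])
    return float(np.hypot(dx, dy)) * scale


def effective_scale(original_width: float, normalized_width: int = 128,
                    base: float = BASE_SCALE_MM_PER_PX) -> float:
    """mm/pixel at the 128-normalized resolution: width/128 * base."""
    if not (original_width > 0 and normalized_width > 0):
        raise ValueError("widths must be positive")
    return original_width / normalized_width * base


@dataclass(frozen=True)
class ScaleConsistency:
    mean: float
    sd: float
    cv_percent: float
    passes: bool  # CV below the 10% acceptability threshold


def scale_consistency(scales: Sequence[float]) -> ScaleConsistency:
    """Mean, SD and coefficient of variation (%) of per-subject scales."""
    scales = np.asarray(scales, dtype=float)
    if scales.size < 2:
        raise ValueError("need at least two scale values")
    mean = float(scales.mean())
    if mean == 0:
        raise ValueError("zero mean scale")
    sd = float(scales.std(ddof=1))
    cv = 100.0 * sd / mean
    return ScaleConsistency(mean=mean, sd=sd, cv_percent=cv,
                            passes=cv < CV_PASS_THRESHOLD_PCT)


def per_landmark_errors(truths: Sequence[AnnotatedImage],
                        preds: Sequence[np.ndarray | Sequence[PointAnnotation]],
                        cal: ScaleCalibration | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(subject, landmark) error table plus per-landmark summary.

    ``preds[i]`` holds predicted original-resolution coordinates aligned
    with ``truths[i]`` (either an (L, 2) array or a point list in schema
    order).  Returns ``(table, summary)``: the table has one row per
    (subject, view, landmark) with error_px and error_mm; the summary
    has per-landmark n / mean error with overall mean and SD in
    ``summary.attrs``.
    """
    cal = cal or ScaleCalibration()
    if len(truths) != len(preds):
        raise ValueError("truths and preds must align")
    rows = []
    for truth, pred in zip(truths, preds):
        schema = get_schema(truth.view)
        t = truth.landmark_array()
        if isinstance(pred, np.ndarray):
            p = np.asarray(pred, dtype=float)
        else:
            p = np.array([[q.x, q.y] if isinstance(q, PointAnnotation)
                          else list(q) for q in pred], dtype=float)
        if p.shape != t.shape:
            raise ValueError(
                f"{truth.subject_id}/{truth.view}: prediction shape {p.shape} "
                f"does not match truth {t.shape}")
        err_px = np.linalg.norm(t - p, axis=1)
        for name, e in zip(schema.names, err_px):
            rows.append((truth.subject_id, truth.view, name, float(e),
                         float(e) * cal.base_scale_mm_per_px))
    table = pd.DataFrame(rows, columns=["subject_id", "view", "landmark",
                                        "error_px", "error_mm"])
    if table.empty:
        raise ValueError("no error rows produced")
    order = {n: i for view in table["view"].unique()
             for i, n in enumerate(get_schema(view).names)}
    summary = (table.groupby("landmark", sort=False)["error_mm"]
               .agg(n="count", mean_error_mm="mean")
               .reset_index()
               .sort_values("landmark", key=lambda s: s.map(order),
                            kind="stable")
               .reset_index(drop=True))
    summary.attrs["overall_mean_mm"] = float(table["error_mm"].mean())
    summary.attrs["overall_sd_mm"] = float(table["error_mm"].std(ddof=1))
    return table, summary


def success_rate(errors_mm: Sequence[float], threshold: float) -> float:
    """Fraction of errors <= threshold (boundary inclusive)."""
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    errors = np.asarray(errors_mm, dtype=float)
    if errors.size == 0:
        raise ValueError("empty error list")
    return float(np.mean(errors <= threshold))


@dataclass(frozen=True)
class CEDResult:
    """Cumulative-error-distribution summary at fixed thresholds."""

    thresholds: tuple[float, ...]
    success_rates: tuple[float, ...]
    auc_ced: float
    clinical_threshold: float = CLINICAL_THRESHOLD_MM


def auc_ced(success_rates: Sequence[float],
            thresholds: Sequence[float] = DEFAULT_CED_THRESHOLDS) -> float:
    """Trapezoidal area under the CED over the threshold axis.

    Integrates only over [first, last] stated thresholds (no
    extrapolation towards zero); with the default 2-4 mm grid a perfect
    model scores 2.0.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    rates = np.asarray(success_rates, dtype=float)
    if thresholds.size < 2:
        raise ValueError("need at least two thresholds")
    if thresholds.size != rates.size:
        raise ValueError("thresholds and success_rates must align")
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    if np.any((rates < 0) | (rates > 1)):
        raise ValueError("success rates must lie in [0, 1]")
    return float(np.trapezoid(rates, thresholds))


def compute_ced(errors_mm: Sequence[float],
                thresholds: Sequence[float] = DEFAULT_CED_THRESHOLDS
                ) -> CEDResult:
    rates = tuple(success_rate(errors_mm, t) for t in thresholds)
    return CEDResult(thresholds=tuple(float(t) for t in thresholds),
                     success_rates=rates,
                     auc_ced=auc_ced(rates, thresholds))


@dataclass(frozen=True)
class OneSampleTestResult:
    t_statistic: float
    p_value: float
    mean: float
    sd: float
    n: int
    degenerate: bool = False


def one_sample_t_vs_zero(errors: Sequence[float]) -> OneSampleTestResult:
    """Two-sided one-sample t-test of a landmark's errors against zero.

    Error magnitudes are nonnegative, so any accurate-but-imperfect
    model yields a significant result once mean >> SD/sqrt(n); the
    ``degenerate`` flag marks zero-variance samples, where p is 0 if the
    mean is nonzero and 1 otherwise.
    """
    errors = np.asarray(errors, dtype=float)
    if errors.size < 2:
        raise ValueError("need at least two values")
    mean = float(errors.mean())
    sd = float(errors.std(ddof=1))
    if sd <= 1e-12 * max(1.0, abs(mean)):  # identical values up to rounding
        return OneSampleTestResult(
            t_statistic=np.inf if mean != 0 else 0.0,
            p_value=0.0 if mean != 0 else 1.0,
            mean=mean, sd=sd, n=errors.size, degenerate=True)
    t, p = stats.ttest_1samp(errors, popmean=0.0)
    return OneSampleTestResult(t_statistic=float(t), p_value=float(p),
                               mean=mean, sd=sd, n=errors.size)


def significance_vs_zero(table: pd.DataFrame) -> pd.DataFrame:
    """Per-landmark one-sample t-tests against zero error.

    Takes the long-format error table from :func:`per_landmark_errors`
    and returns one row per landmark with n, mean, t and p.
    """
    rows = []
    for name, grp in table.groupby("landmark", sort=False):
        errs = grp["error_mm"].to_numpy()
        if errs.size < 2:  # single observation: test undefined
            rows.append((name, errs.size, float(errs.mean()),
                         np.nan, np.nan, True))
            continue
        res = one_sample_t_vs_zero(errs)
        rows.append((name, res.n, res.mean, res.t_statistic, res.p_value,
                     res.degenerate))
    return pd.DataFrame(rows, columns=["landmark", "n", "mean_error_mm",
                                       "t_statistic", "p_value", "degenerate"])


def compound_uncertainty(e1: float, e2: float) -> float:
    """Combined uncertainty of a two-landmark measurement: sqrt(e1^2+e2^2)."""
    if e1 < 0 or e2 < 0:
        raise ValueError("errors must be nonnegative")
    return float(np.hypot(e1, e2))
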