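"""Clinical-equivalence statistics: TOST, Bland-Altman, and ICC.

TOST (two one-sided tests) declares the automated method equivalent to
the manual reference when the mean difference is statistically inside a
prespecified +/-2 mm margin; following the evaluation convention used
here, the "differences" are per-landmark Euclidean error magnitudes, so
the lower one-sided test is trivially passed (errors are nonnegative)
and equivalence hinges on the upper test.  Bland-Altman agreement
reports the mean difference (bias) and 95% limits of agreement
bias +/- 1.96 * SD.  Intra-observer repeatability across two annotation
rounds is quantified with a two-way random-effects, absolute-agreement,
single-measurement intraclass correlation, ICC(2,1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .schemas import PointAnnotation, get_schema


@dataclass(frozen=True)
class EquivalenceConfig:
    margin_mm: float = 2.0        # symmetric +/- equivalence margin
    loa_multiplier: float = 1.96  # 95% limits of agreement
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.margin_mm > 0:
            raise ValueError("margin_mm must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class TOSTResult:
    p_lower: float
    p_upper: float
    p_tost: float  # max of the two one-sided p-values
    equivalent: bool
    mean: float
    sd: float
    n: int
    margin_mm: float
    degenerate: bool = False


def tost_equivalence(differences_mm, cfg: EquivalenceConfig | None = None
                     ) -> TOSTResult:
    """Two one-sided t-tests of the mean against -margin and +margin.

    Equivalence is declared iff max(p_lower, p_upper) < alpha.  With
    zero sample variance the t statistics are undefined; the degenerate
    contract declares equivalence iff |mean| < margin (p_tost 0), else
    non-equivalence (p_tost 1), and flags the result.
    """
    cfg = cfg or EquivalenceConfig()
    d = np.asarray(differences_mm, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two differences")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    n = d.size
    if sd <= 1e-12 * max(1.0, abs(mean)):  # identical values up to rounding
        inside = abs(mean) < cfg.margin_mm
        p = 0.0 if inside else 1.0
        return TOSTResult(p_lower=p, p_upper=p, p_tost=p, equivalent=inside,
                          mean=mean, sd=sd, n=n, margin_mm=cfg.margin_mm,
                          degenerate=True)
    se = sd / np.sqrt(n)
    df = n - 1
    t_lower = (mean + cfg.margin_mm) / se   # H1: mean > -margin
    t_upper = (mean - cfg.margin_mm) / se   # H1: mean < +margin
    p_lower = float(stats.t.sf(t_lower, df))
    p_upper = float(stats.t.cdf(t_upper, df))
    p_tost = max(p_lower, p_upper)
    return TOSTResult(p_lower=p_lower, p_upper=p_upper, p_tost=p_tost,
                      equivalent=p_tost < cfg.alpha, mean=mean, sd=sd, n=n,
                      margin_mm=cfg.margin_mm)


@dataclass(frozen=True)
class BlandAltmanResult:
    bias_mm: float
    sd_mm: float
    loa_lower: float
    loa_upper: float
    n: int


def bland_altman(differences_mm, cfg: EquivalenceConfig | None = None
                 ) -> BlandAltmanResult:
    """Bias (mean difference) and limits of agreement bias +/- 1.96*SD.

    SD is the sample standard deviation (n-1 denominator); 1.96 is used
    verbatim rather than a t quantile.
    """
    cfg = cfg or EquivalenceConfig()
    d = np.asarray(differences_mm, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two differences")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    half = cfg.loa_multiplier * sd
    return BlandAltmanResult(bias_mm=bias, sd_mm=sd,
                             loa_lower=bias - half, loa_upper=bias + half,
                             n=d.size)


def bland_altman_from_stats(mean: float, sd: float,
                            multiplier: float = 1.96) -> tuple[float, float]:
    """Limits of agreement from a printed mean/SD pair."""
    return mean - multiplier * sd, mean + multiplier * sd


@dataclass(frozen=True)
class ICCResult:
    icc: float
    form: str
    n_subjects: int
    n_raters: int


def icc_2_1(data: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``data`` is an (n_subjects, k_raters) matrix.  Computed from the
    two-way ANOVA mean squares:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    Perfect agreement gives 1; exchangeable noise with no
    between-subject variance gives ~0.  If all entries are identical the
    decomposition is 0/0 and 1.0 is returned (perfect agreement).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need an (n>=2 subjects, k>=2 raters) matrix")
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return 1.0 if np.allclose(data, data[0, 0]) or mse == 0 else float("nan")
    return float((msr - mse) / denom)


def icc_intra_observer(round1, round2) -> ICCResult:
    """ICC(2,1) between two paired measurement rounds on the same subjects."""
    r1 = np.asarray(round1, dtype=float).ravel()
    r2 = np.asarray(round2, dtype=float).ravel()
    if r1.shape != r2.shape:
        raise ValueError("rounds must have equal length")
    if r1.size < 2:
        raise ValueError("need at least two subjects")
    icc = icc_2_1(np.column_stack([r1, r2]))
    return ICCResult(icc=icc, form="ICC(2,1)", n_subjects=r1.size, n_raters=2)


def icc_by_landmark(round1_points: list[list[PointAnnotation]],
                    round2_points: list[list[PointAnnotation]],
                    view: str, scale_mm_per_px: float = 0.1) -> pd.DataFrame:
    """Per-landmark, per-axis ICC(2,1) across two annotation rounds.

    Each argument is a list (over images/subjects) of schema-ordered
    point lists.  Coordinates are converted to mm before the ICC so the
    statistic is scale-honest.  Returns a tidy frame (landmark, axis,
    icc) whose mean is the headline repeatability value.
    """
    schema = get_schema(view)
    a1 = np.array([[[p.x, p.y] for p in pts] for pts in round1_points],
                  dtype=float) * scale_mm_per_px
    a2 = np.array([[[p.x, p.y] for p in pts] for pts in round2_points],
                  dtype=float) * scale_mm_per_px
    if a1.shape != a2.shape:
        raise ValueError("annotation rounds must align")
    rows = []
    for li, name in enumerate(schema.names):
        for ai, axis in enumerate(("x", "y")):
            rows.append((name, axis,
                         icc_2_1(np.column_stack([a1[:, li, ai],
                                                  a2[:, li, ai]]))))
    return pd.DataFrame(rows, columns=["landmark", "axis", "icc"])
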