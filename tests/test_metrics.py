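"""Millimetre error metrics: conversions, tables, SR/CED/AUC, tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from softmark.metrics import (
    ScaleCalibration,
    auc_ced,
    compound_uncertainty,
    compute_ced,
    effective_scale,
    one_sample_t_vs_zero,
    per_landmark_errors,
    px_error_to_mm,
    scale_consistency,
    significance_vs_zero,
    success_rate,
)


def test_px_error_to_mm_basics():
    assert px_error_to_mm((10, 20), (10, 20), 0.1) == 0.0
    assert px_error_to_mm((100, 100), (103, 104), 0.1) == pytest.approx(0.5)
    # homogeneity: scaling both points by k scales the error by k
    e1 = px_error_to_mm((10, 20), (13, 24), 0.1)
    e2 = px_error_to_mm((20, 40), (26, 48), 0.1)
    assert e2 == pytest.approx(2 * e1)


def test_effective_scale():
    assert effective_scale(1034) == pytest.approx(0.8078125)
    assert effective_scale(128) == pytest.approx(0.1)
    assert effective_scale(2068) == pytest.approx(2 * effective_scale(1034))


def test_scale_consistency_cv():
    sc = scale_consistency([0.8] * 10)
    assert sc.cv_percent == 0.0 and sc.passes
    # independent two-pass oracle on simulated subject widths
    rng = np.random.default_rng(3)
    widths = rng.normal(1034, 56, size=20)
    scales = [effective_scale(w) for w in widths]
    sc = scale_consistency(scales)
    mean = sum(scales) / len(scales)
    var = sum((s - mean) ** 2 for s in scales) / (len(scales) - 1)
    assert sc.mean == pytest.approx(mean)
    assert sc.cv_percent == pytest.approx(100 * var ** 0.5 / mean)
    with pytest.raises(ValueError):
        scale_consistency([0.8])


def test_per_landmark_errors_zero_and_single_offset(small_cohort):
    frontal = [im for im in small_cohort if im.view == "frontal"][:3]
    exact = [im.landmark_array() for im in frontal]
    table, summary = per_landmark_errors(frontal, exact)
    assert np.all(table["error_mm"] == 0)
    assert len(table) == 3 * 22

    # one landmark off by a 3-4-5 triangle on one subject
    off = [a.copy() for a in exact]
    off[0][5] += [3.0, 4.0]
    table, summary = per_landmark_errors(frontal, off)
    name = frontal[0].schema.names[5]
    by_lm = summary.set_index("landmark")["mean_error_mm"]
    assert by_lm[name] == pytest.approx(0.5 / 3)  # mean over 3 subjects
    assert (by_lm.drop(name) == 0).all()
    # overall mean equals a flat recomputation
    assert summary.attrs["overall_mean_mm"] == pytest.approx(
        table["error_mm"].mean())


def test_per_landmark_errors_scale_linearity(small_cohort):
    frontal = [im for im in small_cohort if im.view == "frontal"][:2]
    preds = [im.landmark_array() + 2.0 for im in frontal]
    t1, _ = per_landmark_errors(frontal, preds, ScaleCalibration(0.1))
    t2, _ = per_landmark_errors(frontal, preds, ScaleCalibration(0.2))
    np.testing.assert_allclose(t2["error_mm"], 2 * t1["error_mm"])


def test_success_rate_counting_and_inclusive_boundary():
    assert success_rate([0.5, 1.5, 2.5], 2.0) == pytest.approx(2 / 3)
    assert success_rate([0.0, 0.0], 5.0) == 1.0
    assert success_rate([2.0, 3.0], 2.0) == 0.5  # boundary counts as success
    with pytest.raises(ValueError):
        success_rate([], 2.0)


def test_sr_monotone_and_auc_bounds(rng):
    errors = rng.gamma(2.0, 0.5, size=500)
    ced = compute_ced(errors)
    rates = np.array(ced.success_rates)
    assert np.all(np.diff(rates) >= 0)
    assert 0 <= ced.auc_ced <= ced.thresholds[-1] - ced.thresholds[0]


def test_auc_ced_known_values():
    # constant full success over [2, 4] -> area 2
    assert auc_ced([1.0, 1.0, 1.0, 1.0]) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        auc_ced([1.0], thresholds=[2.0])
    with pytest.raises(ValueError):
        auc_ced([0.5, 0.4], thresholds=[2.0, 2.0])


def test_auc_ced_matches_dense_riemann_oracle(rng):
    """Trapezoid over the 4 stated thresholds equals dense numerical
    integration of the piecewise-linear CED to 1e-9."""
    for _ in range(20):
        rates = np.sort(rng.uniform(0, 1, size=4))
        thresholds = (2.0, 2.5, 3.0, 4.0)
        area = auc_ced(rates, thresholds)
        grid = np.linspace(2.0, 4.0, 200_001)
        dense = np.interp(grid, thresholds, rates)
        riemann = float(np.trapezoid(dense, grid))
        assert area == pytest.approx(riemann, abs=1e-9)


def test_one_sample_t_closed_form():
    # n=20, mean 0.5, sd 0.3 -> t = 0.5 / (0.3/sqrt(20)) ~ 7.45
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, 20)
    x = (x - x.mean()) / x.std(ddof=1) * 0.3 + 0.5
    res = one_sample_t_vs_zero(x)
    t_expected = 0.5 / (0.3 / np.sqrt(20))
    assert res.t_statistic == pytest.approx(t_expected, rel=1e-9)
    p_expected = 2 * stats.t.sf(t_expected, df=19)
    assert res.p_value == pytest.approx(p_expected, rel=1e-9)
    assert res.p_value < 0.001
    assert not res.degenerate


def test_one_sample_t_degenerate_contract():
    res = one_sample_t_vs_zero([0.7, 0.7, 0.7])
    assert res.degenerate and res.p_value == 0.0
    res0 = one_sample_t_vs_zero([0.0, 0.0])
    assert res0.degenerate and res0.p_value == 1.0


def test_significance_table_per_landmark(small_cohort):
    frontal = [im for im in small_cohort if im.view == "frontal"]
    rng = np.random.default_rng(5)
    preds = [im.landmark_array() + rng.normal(0, 4, (22, 2))
             for im in frontal]
    table, _ = per_landmark_errors(frontal, preds)
    sig = significance_vs_zero(table)
    assert len(sig) == 22
    # nonnegative errors with mean >> SD/sqrt(n) are always significant
    assert (sig["p_value"] < 0.05).all()


@settings(derandomize=True, max_examples=50)
@given(
    errors=st.lists(st.floats(0.0, 10.0, allow_nan=False), min_size=1,
                    max_size=60),
    thresholds=st.lists(st.floats(0.1, 10.0, allow_nan=False), min_size=2,
                        max_size=8, unique=True),
)
def test_ced_properties_hold_for_arbitrary_errors(errors, thresholds):
    """CED invariants: success rates are non-decreasing in threshold and
    the AUC is bounded by the threshold-range width."""
    thresholds = sorted(thresholds)
    rates = [success_rate(errors, t) for t in thresholds]
    assert all(b >= a for a, b in zip(rates, rates[1:]))
    area = auc_ced(rates, thresholds)
    assert 0.0 <= area <= (thresholds[-1] - thresholds[0]) + 1e-12


def test_compound_uncertainty():
    assert compound_uncertainty(0.54, 0.54) == pytest.approx(0.76, abs=0.005)
    assert compound_uncertainty(0.0, 1.3) == pytest.approx(1.3)
    assert compound_uncertainty(3.0, 4.0) == pytest.approx(5.0)
    with pytest.raises(ValueError):
        compound_uncertainty(-1.0, 1.0)
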