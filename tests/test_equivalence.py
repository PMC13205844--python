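"""TOST equivalence, Bland-Altman agreement and ICC repeatability.

Independent oracles: statsmodels' TOST implementation, the confidence-
interval-inclusion characterization of equivalence, and pingouin's ICC.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from softmark.equivalence import (
    EquivalenceConfig,
    bland_altman,
    bland_altman_from_stats,
    icc_2_1,
    icc_by_landmark,
    icc_intra_observer,
    tost_equivalence,
)


class TestTOST:
    def test_closed_form_t_tail(self):
        # n=20, mean 0.5, sd 0.3, margin 2: t_upper = (0.5-2)/(0.3/sqrt(20))
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 20)
        x = (x - x.mean()) / x.std(ddof=1) * 0.3 + 0.5
        res = tost_equivalence(x, EquivalenceConfig(margin_mm=2.0))
        t_upper = (0.5 - 2.0) / (0.3 / np.sqrt(20))
        assert res.p_upper == pytest.approx(stats.t.cdf(t_upper, 19), rel=1e-9)
        assert res.p_tost < 1e-10
        assert res.equivalent

    def test_mean_at_margin_gives_half(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 30)
        x = (x - x.mean()) / x.std(ddof=1) * 0.4 + 2.0  # mean exactly at +margin
        res = tost_equivalence(x, EquivalenceConfig(margin_mm=2.0))
        assert res.p_upper == pytest.approx(0.5, abs=1e-9)
        assert not res.equivalent

    def test_degenerate_zero_variance(self):
        res = tost_equivalence([0.0, 0.0, 0.0])
        assert res.degenerate and res.equivalent and res.p_tost == 0.0
        res = tost_equivalence([3.0, 3.0, 3.0])
        assert res.degenerate and not res.equivalent and res.p_tost == 1.0

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.weightstats import DescrStatsW

        rng = np.random.default_rng(3)
        for _ in range(25):
            x = rng.normal(rng.uniform(-1, 3), rng.uniform(0.2, 2.0),
                           size=rng.integers(5, 60))
            res = tost_equivalence(x, EquivalenceConfig(margin_mm=2.0))
            p_sm, (t_lo, p_lo, _), (t_up, p_up, _) = DescrStatsW(x).ttost_mean(
                low=-2.0, upp=2.0)
            assert res.p_tost == pytest.approx(p_sm, rel=1e-9, abs=1e-12)
            assert res.p_lower == pytest.approx(p_lo, rel=1e-9, abs=1e-12)
            assert res.p_upper == pytest.approx(p_up, rel=1e-9, abs=1e-12)

    def test_equivalence_iff_ci_inside_margin(self):
        """TOST at alpha declares equivalence iff the (1-2 alpha) CI for
        the mean lies inside (-margin, +margin) -- 200 random datasets."""
        rng = np.random.default_rng(4)
        cfg = EquivalenceConfig(margin_mm=2.0, alpha=0.05)
        agree = 0
        for _ in range(200):
            x = rng.normal(rng.uniform(-3, 3), rng.uniform(0.1, 3.0),
                           size=rng.integers(4, 50))
            res = tost_equivalence(x, cfg)
            mean, se = x.mean(), x.std(ddof=1) / np.sqrt(len(x))
            tq = stats.t.ppf(1 - cfg.alpha, len(x) - 1)
            ci = (mean - tq * se, mean + tq * se)
            ci_inside = ci[0] > -cfg.margin_mm and ci[1] < cfg.margin_mm
            assert res.equivalent == ci_inside
            agree += 1
        assert agree == 200

    def test_margin_monotonicity(self):
        rng = np.random.default_rng(5)
        x = rng.normal(1.0, 1.0, 25)
        p_prev = 1.1
        for margin in (0.5, 1.0, 2.0, 4.0):
            p = tost_equivalence(x, EquivalenceConfig(margin_mm=margin)).p_tost
            assert p <= p_prev + 1e-12
            p_prev = p


class TestBlandAltman:
    def test_printed_reference_limits(self):
        """Limits from printed mean/SD pairs reproduce to 3 decimals."""
        lo, hi = bland_altman_from_stats(0.5385, 0.6914)
        assert lo == pytest.approx(-0.817, abs=5e-4)
        assert hi == pytest.approx(1.894, abs=5e-4)
        lo, hi = bland_altman_from_stats(0.5136, 0.2908)
        assert lo == pytest.approx(-0.056, abs=5e-4)
        assert hi == pytest.approx(1.084, abs=5e-4)

    def test_structure_invariants(self):
        rng = np.random.default_rng(6)
        d = rng.normal(0.5, 0.7, 100)
        res = bland_altman(d)
        assert res.bias_mm == pytest.approx(d.mean())
        assert res.loa_upper - res.loa_lower == pytest.approx(
            2 * 1.96 * res.sd_mm)
        assert (res.loa_lower + res.loa_upper) / 2 == pytest.approx(res.bias_mm)

    def test_zero_sd(self):
        res = bland_altman([1.5, 1.5, 1.5])
        assert res.loa_lower == res.loa_upper == res.bias_mm == 1.5


class TestICC:
    def test_perfect_agreement(self):
        x = np.arange(10.0)
        res = icc_intra_observer(x, x)
        assert res.icc == pytest.approx(1.0)
        assert res.form == "ICC(2,1)"

    def test_pure_noise_near_zero(self):
        """No between-subject variance and independent noise -> ICC ~ 0."""
        rng = np.random.default_rng(7)
        r1 = rng.normal(0, 1, 10_000)
        r2 = rng.normal(0, 1, 10_000)
        assert abs(icc_intra_observer(r1, r2).icc) < 0.02

    def test_shift_invariance(self):
        rng = np.random.default_rng(8)
        r1 = rng.normal(5, 2, 50)
        r2 = r1 + rng.normal(0, 0.5, 50)
        a = icc_intra_observer(r1, r2).icc
        b = icc_intra_observer(r1 + 100, r2 + 100).icc
        assert a == pytest.approx(b, rel=1e-9)
        assert a <= 1.0

    def test_matches_pingouin_oracle(self):
        import pingouin as pg

        rng = np.random.default_rng(9)
        for _ in range(5):
            n = int(rng.integers(8, 30))
            subj = rng.normal(0, 2, n)
            data = np.column_stack([subj + rng.normal(0.2, 0.5, n),
                                    subj + rng.normal(0.0, 0.5, n)])
            ours = icc_2_1(data)
            df = pd.DataFrame({
                "subject": np.repeat(np.arange(n), 2),
                "rater": np.tile([0, 1], n),
                "score": data.ravel(),
            })
            ref = pg.intraclass_corr(df, targets="subject", raters="rater",
                                     ratings="score")
            # two-way random, absolute agreement, single rater
            icc2 = float(ref.loc[ref["Type"].isin(["ICC2", "ICC(A,1)"]),
                                 "ICC"].iloc[0])
            assert ours == pytest.approx(icc2, rel=1e-6)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            icc_intra_observer([1.0], [1.0])
        with pytest.raises(ValueError):
            icc_intra_observer([1.0, 2.0], [1.0, 2.0, 3.0])


def test_icc_by_landmark_calibrated_jitter_in_band():
    """Two simulated annotation rounds at the calibrated default jitter
    give a mean per-landmark/axis ICC inside the 0.85-0.95 band."""
    from softmark.synthetic import (
        AnnotatorModel,
        DEFAULT_JITTER_SD_MM,
        landmark_template,
        sample_subject,
        simulate_annotator,
    )

    rng = np.random.default_rng(77)
    iccs = []
    for view, n in (("frontal", 10), ("profile", 10)):
        subjects = [sample_subject(i, 42) for i in range(n)]
        truths = [landmark_template(p, view) for p in subjects]
        rounds = []
        for _ in range(2):
            rounds.append([
                simulate_annotator(
                    t, AnnotatorModel(DEFAULT_JITTER_SD_MM,
                                      rng_seed=int(rng.integers(2 ** 31))),
                    0.1)
                for t in truths])
        df = icc_by_landmark(rounds[0], rounds[1], view, 0.1)
        iccs.append(df["icc"])
    mean_icc = float(pd.concat(iccs).mean())
    assert 0.85 <= mean_icc <= 0.95
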