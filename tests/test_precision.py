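import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import p4valid as p4
from p4valid.precision import AnalysisError, _cv_pct

from conftest import make_levels, noise_free_model, one_level_table, table_from_cells


class TestWithinRunCV:
    def test_zero_variance(self):
        t = one_level_table({1: (5, 5, 5, 5, 5)})
        assert p4.within_run_cv(t, "L1") == 0.0

    def test_hand_arithmetic(self):
        # sd(4,5,6) = 1, mean = 5 -> CV 20%
        t = one_level_table({1: (4, 5, 6)})
        assert p4.within_run_cv(t, "L1") == pytest.approx(20.0)

    def test_mean_over_days_and_day_filter(self):
        t = one_level_table({1: (4, 5, 6), 2: (8, 10, 12)})
        assert p4.within_run_cv(t, "L1") == pytest.approx(20.0)  # both days CV 20
        assert p4.within_run_cv(t, "L1", day=2) == pytest.approx(20.0)

    def test_single_replicate_days_unusable(self):
        t = one_level_table({1: (5.0,), 2: (6.0,)})
        with pytest.raises(AnalysisError):
            p4.within_run_cv(t, "L1")


class TestBetweenRunCV:
    def test_zero_variance(self):
        t = one_level_table({d: (10.0,) for d in range(1, 6)})
        assert p4.between_run_cv(t, "L1") == 0.0

    def test_hand_arithmetic(self):
        # day means 9, 10, 11 -> sd 1, mean 10 -> CV 10%
        t = one_level_table({1: (9.0,), 2: (10.0,), 3: (11.0,)})
        assert p4.between_run_cv(t, "L1") == pytest.approx(10.0)

    def test_needs_two_days(self):
        t = one_level_table({1: (9.0, 10.0)})
        with pytest.raises(AnalysisError):
            p4.between_run_cv(t, "L1")

    def test_day_effect_monte_carlo(self):
        """sd_between_day = 0.05 with no replicate noise is recovered as a
        ~5% between-run CV on average."""
        model = noise_free_model()
        model = p4.ErrorModel(**{**model.__dict__, "sd_between_day": 0.05})
        levels = make_levels([0, 5.0])
        ests = [
            p4.between_run_cv(
                p4.simulate_spike_panel(levels, 5, 5, model, seed=2000 + k), "L1"
            )
            for k in range(300)
        ]
        assert abs(np.mean(ests) - 5.0) < 0.5


@settings(max_examples=40, derandomize=True)
@given(
    st.lists(st.floats(0.5, 40), min_size=4, max_size=10),
    st.floats(0.01, 50),
)
def test_cv_scale_invariance(values, k):
    """Multiplying every measurement by k > 0 leaves CV% unchanged."""
    half = len(values) // 2
    by_day = {1: values[:half] or values, 2: values[half:] or values}
    t1 = one_level_table(by_day)
    t2 = one_level_table({d: [k * v for v in vs] for d, vs in by_day.items()})
    try:
        w1 = p4.within_run_cv(t1, "L1")
    except AnalysisError:
        return
    assert p4.within_run_cv(t2, "L1") == pytest.approx(w1, rel=1e-9)
    if len(by_day) >= 2:
        assert p4.between_run_cv(t2, "L1") == pytest.approx(
            p4.between_run_cv(t1, "L1"), rel=1e-9
        )


class TestTrendline:
    def test_linlog_exact_recovery(self):
        pts = {c: 8.9 - 1.7 * np.log10(c) for c in (0.5, 1, 2, 5, 10, 30)}
        fit = p4.fit_cv_trendline(pts, form="linlog")
        assert fit.coefficients == pytest.approx((8.9, -1.7), abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_profile_zero_slope(self):
        fit = p4.fit_cv_trendline({1: 5.0, 5: 5.0, 20: 5.0}, form="linlog")
        assert fit.coefficients[1] == pytest.approx(0.0, abs=1e-9)

    def test_quadratic_exact_recovery(self):
        pts = {c: 5.2 - 0.2 * c + 0.01 * c**2 for c in (1, 2, 5, 10, 20, 40)}
        fit = p4.fit_cv_trendline(pts, form="quadratic")
        assert fit.coefficients == pytest.approx((5.2, -0.2, 0.01), abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(AnalysisError):
            p4.fit_cv_trendline({2.0: 5.0}, form="linlog")
        with pytest.raises(AnalysisError):
            p4.fit_cv_trendline({1.0: 5.0, 2.0: 4.0}, form="quadratic")

    def test_published_cv_column_slopes_downward(self):
        """A falling CV-versus-concentration profile fits a negative slope."""
        from reference_panel import PLASMA_PANEL

        pts = {v[0]: v[1] for v in PLASMA_PANEL.values()}
        fit = p4.fit_cv_trendline(pts, form="linlog")
        assert fit.coefficients[1] < 0


class TestRecovery:
    def test_hand_arithmetic(self):
        # mean 4.93, control 0.31, spiked 5 -> recovery 92.4%, SRB -7.6%
        t = one_level_table({1: (4.93, 4.93), 2: (4.93, 4.93)}, spiked=5.0)
        r = p4.recovery_percent(t, "L1", control_mean=0.31)
        assert r.recovery_pct == pytest.approx(92.4)
        assert r.srb_pct == pytest.approx(-7.6)

    def test_perfect_recovery(self):
        t = one_level_table({1: (5.31,)}, spiked=5.0)
        r = p4.recovery_percent(t, "L1", control_mean=0.31)
        assert r.recovery_pct == pytest.approx(100.0)
        assert r.srb_pct == pytest.approx(0.0)

    def test_control_is_not_a_recovery_level(self):
        t = table_from_cells([("P0", 0.0, 1, 1, 0.3)])
        with pytest.raises(AnalysisError):
            p4.recovery_percent(t, "P0", control_mean=0.3)

    def test_srb_identity_on_simulated_panel(self, plasma_panel):
        rec = p4.recovery_table(plasma_panel)
        for r in rec.levels:
            assert r.srb_pct == pytest.approx(r.recovery_pct - 100.0, abs=1e-12)

    def test_noise_free_panel_recovers_injected_factor(self):
        t = p4.simulate_spike_panel(
            make_levels([0, 2.0, 10.0]), 3, 3,
            noise_free_model(baseline=0.0, srb_intercept=-10.0), seed=1,
        )
        rec = p4.recovery_table(t, control_mean=0.0)
        for r in rec.levels:
            assert r.recovery_pct == pytest.approx(90.0)
        prof = p4.precision_profile(t, trend_form=None)
        assert prof.overall_within_cv_pct == pytest.approx(0.0, abs=1e-9)


class TestPrecisionProfile:
    def test_overall_is_unweighted_mean(self, plasma_panel):
        prof = p4.precision_profile(plasma_panel)
        spiked = [r for r in prof.levels if r.spiked > 0]
        assert prof.overall_within_cv_pct == pytest.approx(
            np.mean([r.within_cv_pct for r in spiked])
        )
        assert prof.overall_between_cv_pct == pytest.approx(
            np.mean([r.between_cv_pct for r in spiked])
        )

    def test_cvs_nonnegative(self, plasma_panel):
        prof = p4.precision_profile(plasma_panel)
        assert all(r.within_cv_pct >= 0 for r in prof.levels)
        assert all(r.between_cv_pct >= 0 for r in prof.levels)


class TestDetectionLimits:
    def test_lob_zero_blank(self):
        t = one_level_table({1: (0.9, 1.1), 2: (1.0, 1.0)})
        lim = p4.detection_limits(t, blank=[0.0, 0.0, 0.0])
        assert lim.lob == 0.0

    def test_lod_hand_arithmetic(self):
        # control day means 0.24, 0.30, 0.36 -> mean 0.30, sd 0.06
        cells = [("P0", 0.0, d, 1, v) for d, v in enumerate((0.24, 0.30, 0.36), 1)]
        cells += [("L1", 1.0, d, 1, 1.0) for d in (1, 2, 3)]
        t = table_from_cells(cells)
        lim = p4.detection_limits(t)
        assert lim.lod == pytest.approx(0.30 + 1.65 * 0.06)
        assert lim.lod >= 0.30  # never below the control mean

    def test_loq_back_solved(self):
        # daily means averaging 1.075 with sd 0.0925 -> LOQ 1.26, CV 8.6%
        d = 0.0925 * np.sqrt(2) / 2
        cells = [("L1", 1.0, 1, 1, 1.075 - d), ("L1", 1.0, 2, 1, 1.075 + d)]
        cells += [("P0", 0.0, day, 1, 0.2) for day in (1, 2)]
        t = table_from_cells(cells)
        lim = p4.detection_limits(t)
        entry = lim.loq_by_level["L1"]
        assert entry.loq == pytest.approx(1.26, abs=5e-3)
        assert entry.between_cv_pct == pytest.approx(8.6, abs=0.05)

    def test_short_series_invalidates_only_that_limit(self):
        cells = [("P0", 0.0, 1, 1, 0.3)]  # one control day only
        cells += [("L1", 1.0, d, 1, 1.0 + 0.1 * d) for d in (1, 2, 3)]
        t = table_from_cells(cells)
        lim = p4.detection_limits(t)
        assert lim.lod is None
        assert any("LOD" in w for w in lim.warnings)
        assert "L1" in lim.loq_by_level
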