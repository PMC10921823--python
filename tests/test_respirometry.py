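import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import detphot as dp
from detphot.respirometry import Measurement, SlopeEstimate, _ols

from conftest import make_series


class TestFitO2Slope:
    def test_exact_line(self):
        s = make_series(1.5)
        est = dp.fit_o2_slope(s)
        assert est.mean == pytest.approx(1.5, rel=1e-9)
        assert est.sd < 1e-2

    def test_constant_trace_zero_slope(self):
        s = make_series(0.0)
        assert dp.fit_o2_slope(s).mean == pytest.approx(0.0, abs=1e-12)

    def test_posterior_mean_within_3sd_of_truth(self):
        s = make_series(1.859, noise_sd=0.2, seed=1)
        est = dp.fit_o2_slope(s)
        _, ols_se, _ = _ols(s.times, s.o2)
        assert abs(est.mean - 1.859) < 3 * est.sd
        assert est.sd == pytest.approx(ols_se, rel=0.1)

    def test_matches_ols_within_1pct_on_100_series(self):
        """Bayesian point estimates agree with closed-form OLS to <1%."""
        rng = np.random.default_rng(42)
        for i in range(100):
            slope = rng.uniform(-3, 3)
            s = make_series(slope, noise_sd=rng.uniform(0.05, 0.5),
                            seed=1000 + i)
            est = dp.fit_o2_slope(s)
            ols_slope, _, _ = _ols(s.times, s.o2)
            assert abs(est.mean - ols_slope) <= 0.01 * max(abs(ols_slope), 1e-6)

    def test_too_few_readings_rejected(self):
        with pytest.raises(ValueError):
            dp.IncubationSeries("x", "light", np.array([0.0, 10.0]),
                                np.array([200.0, 201.0]))


class TestTruncation:
    def test_noop_at_target_length(self):
        s = make_series(1.5, n=30)
        res = dp.truncate_series(s, 30)
        assert res.truncation == "none"
        assert len(res.series) == 30

    def test_noiseless_tie_breaks_to_start(self):
        s = make_series(1.5, n=35)
        res = dp.truncate_series(s, 30)
        assert res.truncation == "start"
        assert res.slope == pytest.approx(1.5, rel=1e-9)
        assert len(res.series) == 30

    def test_step_artefact_trimmed_from_start(self):
        """A step in the first 5 readings inflates the end-trim residual SE;
        the start trim removes it (verified against brute-force OLS)."""
        times = np.arange(35) * 10.0
        o2 = 200 + 0.25 * np.arange(35)
        o2[:5] += 8.0
        s = dp.IncubationSeries("x", "light", times, o2)
        res = dp.truncate_series(s, 30)
        # brute-force oracle: residual SE of both candidates
        _, _, se_start = _ols(times[:30], o2[5:])
        _, _, se_end = _ols(times[:30], o2[:30])
        assert se_start < se_end
        assert res.truncation == "start"
        assert res.slope == pytest.approx(1.5, rel=1e-9)

    def test_end_artefact_trimmed_from_end(self):
        times = np.arange(35) * 10.0
        o2 = 200 + 0.25 * np.arange(35)
        o2[-5:] += np.array([8.0, -6.0, 7.0, -5.0, 6.0])
        s = dp.IncubationSeries("x", "light", times, o2)
        assert dp.truncate_series(s, 30).truncation == "end"

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            dp.truncate_series(make_series(1.0, n=20), 30)

    def test_never_lengthens_and_preserves_clean_slope(self):
        for n in (30, 31, 40):
            s = make_series(-0.8, n=n)
            res = dp.truncate_series(s, 30)
            assert len(res.series) == 30
            assert res.slope == pytest.approx(-0.8, rel=1e-9)


class TestArithmeticOps:
    def test_blank_correction(self):
        sam = SlopeEstimate(1.5, 0.3, 30)
        blk = SlopeEstimate(0.2, 0.4, 30)
        out = dp.blank_correct(sam, blk)
        assert out.mean == pytest.approx(1.3)
        assert out.sd == pytest.approx(0.5)
        zero = dp.blank_correct(sam, SlopeEstimate(0.0, 0.0, 30))
        assert (zero.mean, zero.sd) == (1.5, 0.3)
        self_c = dp.blank_correct(sam, sam)
        assert self_c.mean == 0.0

    def test_slope_to_rate_value(self):
        """slope 1.859, V=0.1726 L, m=0.35 g → 55.0 µmol g⁻¹ h⁻¹."""
        est = SlopeEstimate(1.859, 0.1, 30)
        rate = dp.slope_to_rate(est, 0.1726, 0.35)
        assert rate.mean == pytest.approx(55.0, abs=0.05)
        assert dp.slope_to_rate(SlopeEstimate(0, 0, 30), 0.1726, 0.35).mean == 0

    def test_doubling_mass_halves_rate(self):
        est = SlopeEstimate(1.0, 0.2, 30)
        r1 = dp.slope_to_rate(est, 0.17, 0.3)
        r2 = dp.slope_to_rate(est, 0.17, 0.6)
        assert r2.mean == pytest.approx(r1.mean / 2)
        assert r2.sd == pytest.approx(r1.sd / 2)

    def test_slope_to_rate_validation(self):
        with pytest.raises(ValueError):
            dp.slope_to_rate(SlopeEstimate(1, 0, 30), 0.0, 0.3)
        with pytest.raises(ValueError):
            dp.slope_to_rate(SlopeEstimate(1, 0, 30), 0.17, -1)

    def test_gross_from_net_and_respiration(self):
        pg = dp.derive_gross(Measurement(55, 6.1), Measurement(29, 3.0))
        assert pg.mean == pytest.approx(84.0)
        assert pg.sd == pytest.approx(math.hypot(6.1, 3.0))
        assert dp.derive_gross(Measurement(55, 1), Measurement(0, 0)).mean == 55
        # measurement error can push gross photosynthesis below zero
        assert dp.derive_gross(Measurement(-5, 1), Measurement(3, 1)).mean == -2

    def test_daily_rate(self):
        daily = dp.derive_daily(Measurement(55, 0), Measurement(29, 0))
        assert daily.mean == pytest.approx(12 * 55 - 12 * 29)  # 312
        assert dp.derive_daily(Measurement(0, 0), Measurement(0, 0)).mean == 0
        with pytest.raises(ValueError):
            dp.derive_daily(Measurement(1, 0), Measurement(1, 0), 13, 12)
        with pytest.raises(ValueError):
            dp.derive_daily(Measurement(1, 0), Measurement(1, 0), 25, -1)

    def test_daily_slope_consistency_with_published_pairs(self):
        """24·β_Pn − 12·β_Pg applied to the slope pair (−1.1, −0.76)
        reproduces the printed daily slope −17 within its SD."""
        b_pn, b_pg = -1.1, -0.76
        daily = dp.derive_daily(Measurement(b_pn, 0),
                                Measurement(b_pg - b_pn, 0))
        assert daily.mean == pytest.approx(24 * b_pn - 12 * b_pg)
        assert abs(daily.mean - (-17.0)) < 11.0

    @given(scale=st.floats(0.1, 10), slope=st.floats(-3, 3))
    @settings(max_examples=30, deadline=None)
    def test_linearity_under_positive_scaling(self, scale, slope):
        """slope_to_rate and blank_correct commute with positive scaling."""
        est = SlopeEstimate(slope, 0.2, 30)
        scaled = SlopeEstimate(slope * scale, 0.2 * scale, 30)
        r1 = dp.slope_to_rate(est, 0.17, 0.3)
        r2 = dp.slope_to_rate(scaled, 0.17, 0.3)
        assert r2.mean == pytest.approx(r1.mean * scale, rel=1e-9, abs=1e-9)
        b1 = dp.blank_correct(scaled, SlopeEstimate(0.1 * scale, 0, 30))
        b2 = dp.blank_correct(est, SlopeEstimate(0.1, 0, 30))
        assert b1.mean == pytest.approx(b2.mean * scale, rel=1e-9, abs=1e-9)


class TestProcessExperiment:
    def test_conservation_pg_equals_pn_plus_r(self, rate_records):
        meas = rate_records.dropna(subset=["pn_mean"])
        np.testing.assert_allclose(meas["pg_mean"],
                                   meas["pn_mean"] + meas["r_mean"], rtol=1e-9)

    def test_initial_rates_in_published_regime(self, rate_records):
        init = rate_records[rate_records["age"] == 0]
        assert init["pn_mean"].mean() == pytest.approx(55, abs=8)
        assert init["pg_mean"].mean() == pytest.approx(84, abs=10)

    def test_disintegrated_rows_have_no_rates(self, rate_records):
        dis = rate_records[rate_records["disintegrated"]]
        if len(dis):
            assert dis["pn_mean"].isna().all()

    def test_blank_phase_mass_invariant(self):
        with pytest.raises(ValueError):
            dp.IncubationSeries("x", "blank", np.arange(3) * 10.0,
                                np.array([200.0, 200, 200]), dry_mass_g=0.3)
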