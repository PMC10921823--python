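import numpy as np
import pandas as pd
import pytest
from scipy import stats

import detphot as dp
from detphot.rate_model import RateDeclineResults, prob_negative

from conftest import FAST


SLOPES = {"dark": -1.1, "15C": -0.43, "20C": -0.87, "25C": -1.2}


def _linear_records(sigma, tau, s_p, seed, tanks=True,
                    ages=(6, 13, 27, 37, 82, 119)):
    """Records drawn directly from the linear truth (no incubation layer)."""
    rng = np.random.default_rng(seed)
    rows = []
    for tr, beta in SLOPES.items():
        for t in range(4):
            b_tank = rng.normal(0, tau)
            for age in ages:
                y = 55.0 + (beta + b_tank) * age + rng.normal(0, sigma)
                y_obs = y + rng.normal(0, s_p)
                rows.append({
                    "sample_id": f"{tr}.{t}.{age}", "age": float(age),
                    "treatment": tr,
                    "tank": f"{tr}.{t + 1}" if tanks else None,
                    "disintegrated": False, "pn_mean": y_obs, "pn_sd": s_p,
                })
    return pd.DataFrame(rows)


def injected_results(beta_draws_by_treatment, tau=None, seed=0):
    treatments = sorted(beta_draws_by_treatment)
    beta = np.column_stack([beta_draws_by_treatment[t] for t in treatments])
    n = beta.shape[0]
    alpha = np.full((n, len(treatments)), 55.0)
    return RateDeclineResults.from_draws(alpha, beta, treatments,
                                         tau=tau, seed=seed)


class TestProbNegative:
    def test_degenerate_draws(self):
        assert prob_negative(np.full(100, -1.0)) == 1.0
        assert prob_negative(np.full(100, 0.5)) == 0.0

    def test_symmetric_draws_half(self):
        draws = np.random.default_rng(0).normal(0, 1, 200_000)
        assert prob_negative(draws) == pytest.approx(0.5, abs=0.01)

    def test_normal_cdf_oracle(self):
        """10⁶ Normal(−1.1, 0.57) draws → Φ(1.1/0.57) ≈ 0.973."""
        draws = np.random.default_rng(1).normal(-1.1, 0.57, 1_000_000)
        assert prob_negative(draws) == pytest.approx(
            stats.norm.cdf(1.1 / 0.57), abs=0.002
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            prob_negative([])


class TestContrasts:
    def test_normal_cdf_oracle_on_injected_draws(self):
        """δβ ~ Normal(−1, 1) → P(δβ<0) = Φ(1) ≈ 0.841."""
        rng = np.random.default_rng(2)
        n = 400_000
        res = injected_results({
            "a": rng.normal(-1.0, np.sqrt(0.5), n),
            "b": rng.normal(0.0, np.sqrt(0.5), n),
        })
        c = res.contrast_slopes("a", "b", new_tank=False)
        assert c.p_negative == pytest.approx(stats.norm.cdf(1.0), abs=0.003)
        assert c.p_negative + c.p_positive == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_contrast(self):
        res = injected_results({"a": np.full(500, -1.0),
                                "b": np.full(500, -0.5)})
        assert res.contrast_slopes("a", "b", new_tank=False).p_negative == 1.0

    def test_self_contrast_is_half_with_tank_variability(self):
        rng = np.random.default_rng(3)
        n = 200_000
        res = injected_results(
            {"a": rng.normal(-1, 0.1, n), "b": rng.normal(-1, 0.1, n)},
            tau=np.full(n, 0.3),
        )
        c = res.contrast_slopes("a", "a")
        assert c.p_negative == pytest.approx(0.5, abs=0.01)

    def test_unknown_treatment_rejected(self):
        res = injected_results({"a": np.zeros(10), "b": np.zeros(10)})
        with pytest.raises(KeyError):
            res.contrast_slopes("a", "zz")


class TestPredictNewTank:
    def test_tau_zero_matches_fixed_effect_intervals(self):
        rng = np.random.default_rng(4)
        n = 50_000
        beta = rng.normal(-1.0, 0.2, n)
        alpha = rng.normal(55.0, 2.0, n)
        res = RateDeclineResults.from_draws(
            np.column_stack([alpha, alpha]), np.column_stack([beta, beta]),
            ["a", "b"], tau=np.zeros(n),
        )
        pred = res.predict_new_tank("a", [0.0, 50.0])
        fixed = alpha + 50.0 * beta
        assert pred["q90"].iloc[1] == pytest.approx(np.quantile(fixed, 0.9),
                                                    rel=0.01)
        # age 0 is centred on the intercept regardless of τ
        res2 = RateDeclineResults.from_draws(
            np.column_stack([alpha, alpha]), np.column_stack([beta, beta]),
            ["a", "b"], tau=np.full(n, 5.0),
        )
        p0 = res2.predict_new_tank("a", [0.0])
        assert p0["mean"].iloc[0] == pytest.approx(alpha.mean(), rel=1e-6)

    def test_empty_grid_rejected(self):
        res = injected_results({"a": np.zeros(10), "b": np.zeros(10)})
        with pytest.raises(ValueError):
            res.predict_new_tank("a", [])


class TestFitting:
    def test_parameter_recovery_low_noise(self):
        """τ=0, tiny σ and s_P: posterior β means land on the truth."""
        truth = dp.TruthParams(seed=21, tank_slope_sd=0.0, residual_sd=0.5,
                               r_residual_sd=0.2, o2_noise_sd=0.02,
                               hazard_baseline=-np.inf)
        reg, ser = dp.simulate_experiment(truth=truth)
        rec = dp.process_experiment(reg, ser)
        fit = dp.RateDeclineModel(rec, response="net").fit(
            dp.SamplerConfig(seed=5, **FAST)
        )
        for tr, b_true in [("dark", -1.1), ("15C", -0.43), ("20C", -0.87),
                           ("25C", -1.2)]:
            draws = fit.slope_draws(tr, new_tank=False)
            assert abs(draws.mean() - b_true) < 2 * max(draws.std(), 0.01)

    def test_no_information_age_zero_returns_prior(self):
        """With age identically 0 the slope is unidentified; its posterior
        must reproduce the prior scale rather than collapse."""
        rng = np.random.default_rng(6)
        n = 24
        rec = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "age": 0.0,
            "treatment": ["a", "b"] * (n // 2),
            "tank": [f"t{i % 4}" for i in range(n)],
            "disintegrated": False,
            "pn_mean": rng.normal(55, 3, n),
            "pn_sd": 1.0,
        })
        model = dp.RateDeclineModel(rec, response="net", covariates=())
        with pytest.warns(RuntimeWarning):
            fit = model.fit(dp.SamplerConfig(chains=2, iterations=600, seed=7))
        prior_sd = model.prior_scales["beta"]
        post_sd = fit.slope_draws("a", new_tank=False).std()
        assert 0.4 * prior_sd < post_sd < 1.8 * prior_sd

    def test_shrinkage_toward_treatment_mean(self):
        """Partial pooling: posterior tank slopes deviate less from their
        treatment mean than per-tank no-pooling OLS slopes. Residual noise
        is set large relative to the tank SD so that unpooled per-tank
        slopes are genuinely noisy."""
        records = _linear_records(sigma=25.0, tau=0.25, s_p=2.0, seed=51)
        model = dp.RateDeclineModel(records, response="net", covariates=())
        fit = model.fit(dp.SamplerConfig(seed=12, **FAST))
        pooled = fit.tank_slopes()
        meas = records
        rows = []
        for tank, grp in meas.groupby("tank"):
            if grp["age"].nunique() < 2:
                continue
            b = np.polyfit(grp["age"], grp["pn_mean"], 1)[0]
            rows.append({"tank": tank, "treatment": grp["treatment"].iloc[0],
                         "ols": b})
        ols = pd.DataFrame(rows)
        merged = pooled.merge(ols, on=["tank", "treatment"])
        dev_pooled = (
            merged["slope_mean"]
            - merged.groupby("treatment")["slope_mean"].transform("mean")
        ).abs().mean()
        dev_ols = (
            merged["ols"] - merged.groupby("treatment")["ols"].transform("mean")
        ).abs().mean()
        assert dev_pooled <= dev_ols

    def test_measurement_error_widens_not_biases(self):
        """Inflating s_P widens the slope posterior but the posterior mean
        stays near the truth (attenuation is corrected). Records carry no
        tank structure so the comparison is not confounded by how the tank
        SD re-absorbs variance."""
        rec = _linear_records(sigma=3.0, tau=0.0, s_p=0.5, seed=52,
                              tanks=False)
        rec_wide = rec.copy()
        rec_wide["pn_sd"] = 8.0
        cfg = dp.SamplerConfig(seed=8, **FAST)
        fit_narrow = dp.RateDeclineModel(rec, "net", covariates=()).fit(cfg)
        fit_wide = dp.RateDeclineModel(rec_wide, "net", covariates=()).fit(cfg)
        d_n = fit_narrow.slope_draws("dark", new_tank=False)
        d_w = fit_wide.slope_draws("dark", new_tank=False)
        assert d_w.std() > 1.5 * d_n.std()
        assert abs(d_w.mean() - (-1.1)) < 3 * d_w.std()

    def test_diagnostics_exposed(self, rate_fit):
        _, fit = rate_fit
        diag = fit.diagnostics
        assert {"parameter", "rhat", "ess"} <= set(diag.columns)
        assert np.isfinite(diag["rhat"]).all()

    def test_requires_two_treatments(self):
        rec = pd.DataFrame({
            "sample_id": ["a", "b", "c"], "age": [0, 5, 10.0],
            "treatment": "only", "tank": "t1", "disintegrated": False,
            "pn_mean": [55, 50, 45.0], "pn_sd": 1.0,
        })
        with pytest.raises(ValueError):
            dp.RateDeclineModel(rec)

    def test_plot_smoke(self, rate_fit):
        _, fit = rate_fit
        ax = fit.plot_predictions("dark", ages=np.linspace(0, 119, 10))
        assert ax.get_xlabel()
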