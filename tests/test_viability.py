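import numpy as np
import pandas as pd
import pytest

import detphot as dp
from detphot.viability import ViabilityResults, binarize, inv_logit, logit

from conftest import FAST


def record_row(sample_id="s1", age=6.0, pn=5.0, r=2.0, disintegrated=False,
               treatment="dark", tank="dark.1"):
    pg = pn + r
    daily = 12 * pn - 12 * r
    return {
        "sample_id": sample_id, "age": age, "treatment": treatment,
        "tank": tank, "disintegrated": disintegrated,
        "pn_mean": np.nan if disintegrated else pn,
        "pg_mean": np.nan if disintegrated else pg,
        "daily_mean": np.nan if disintegrated else daily,
    }


class TestLinks:
    def test_inv_logit_midpoint(self):
        assert inv_logit(0.0) == 0.5

    def test_published_start_probabilities(self):
        """Printed starting log odds 3.1 and 4.8 give 96% and 99%."""
        assert round(100 * inv_logit(3.1)) == 96
        assert round(100 * inv_logit(4.8)) == 99

    def test_round_trip_identity(self):
        x = np.linspace(-15, 15, 101)
        np.testing.assert_allclose(logit(inv_logit(x)), x, rtol=1e-7,
                                   atol=1e-7)

    def test_logit_domain(self):
        for bad in (0.0, 1.0, -0.1, 1.1):
            with pytest.raises(ValueError):
                logit(bad)


class TestBinarize:
    def test_all_positive(self):
        out = binarize(pd.DataFrame([record_row(pn=5, r=2)]))
        assert out.set_index("outcome")["value"].to_dict() == {
            "autotrophy": 1, "photosynthesis": 1, "daily_autotrophy": 1
        }

    def test_sign_cases_including_negative_gross(self):
        out = binarize(pd.DataFrame([record_row(pn=-5, r=3)]))
        assert (out["value"] == 0).all()

    def test_disintegrated_scores_zero_everywhere(self):
        out = binarize(pd.DataFrame([record_row(disintegrated=True)]))
        assert (out["value"] == 0).all()

    def test_totals_three_rows_per_sample(self):
        recs = pd.DataFrame([record_row(sample_id=f"s{i}", pn=i - 2.0)
                             for i in range(6)])
        out = binarize(recs)
        assert len(out) == 3 * len(recs)

    def test_missing_rates_without_flag_rejected(self):
        row = record_row()
        row["pn_mean"] = np.nan
        with pytest.raises(ValueError):
            binarize(pd.DataFrame([row]))


class TestInflection:
    def test_arithmetic(self):
        """α = 3, k = −0.1 → μ = 30 days."""
        res = ViabilityResults.from_draws(
            alpha=np.full(10, 3.0), k=np.full((10, 1), -0.1), treatments=["a"]
        )
        mu, excluded = res.inflection("a", new_tank=False)
        np.testing.assert_allclose(mu, 30.0)
        assert excluded == 0

    def test_joint_scaling_invariance(self):
        rng = np.random.default_rng(0)
        alpha = rng.normal(3, 0.5, 100)
        k = rng.normal(-0.1, 0.02, (100, 1))
        a = ViabilityResults.from_draws(alpha, k, ["a"])
        b = ViabilityResults.from_draws(2 * alpha, 2 * k, ["a"])
        np.testing.assert_allclose(a.inflection("a", new_tank=False)[0],
                                   b.inflection("a", new_tank=False)[0])

    def test_probability_half_at_inflection(self):
        rng = np.random.default_rng(1)
        res = ViabilityResults.from_draws(
            rng.normal(3, 0.5, 200), rng.normal(-0.1, 0.02, (200, 1)), ["a"]
        )
        mu, _ = res.inflection("a", new_tank=False)
        k = res.k_draws("a", new_tank=False)
        np.testing.assert_allclose(inv_logit(res.alpha + k * mu), 0.5,
                                   atol=1e-12)

    def test_zero_k_draws_excluded_and_counted(self):
        k = np.array([[-0.1], [0.0], [-0.2]])
        res = ViabilityResults.from_draws(np.full(3, 3.0), k, ["a"])
        mu, excluded = res.inflection("a", new_tank=False)
        assert excluded == 1
        assert len(mu) == 2

    def test_injected_inflection_difference(self):
        """Two treatments whose μ differ by 57 days → δμ summary = 57."""
        n = 1000
        res = ViabilityResults.from_draws(
            np.full(n, 3.1),
            np.column_stack([np.full(n, -3.1 / 30.0), np.full(n, -3.1 / 87.0)]),
            ["dark", "15C"],
        )
        c = res.contrast_inflection("15C", "dark", new_tank=False)
        assert c.mean == pytest.approx(57.0, abs=1e-9)


class TestOddsRatioIdentity:
    def test_k_difference_is_log_odds_ratio(self):
        """exp(δk) equals the ratio of odds slopes on injected draws."""
        n = 500
        res = ViabilityResults.from_draws(
            np.full(n, 3.0),
            np.column_stack([np.full(n, -0.12), np.full(n, -0.04)]),
            ["dark", "15C"],
        )
        c = res.contrast_k("dark", "15C", new_tank=False)
        assert np.exp(c.mean) == pytest.approx(np.exp(-0.12) / np.exp(-0.04))


class TestFitting:
    def test_parameter_recovery_from_logistic_truth(self):
        """Outcomes drawn at (α, k) truth are recovered within 2 SD."""
        out = dp.simulate_viability_outcomes(seed=31)
        fit = dp.ViabilityModel(out).fit(dp.SamplerConfig(seed=9, **FAST))
        assert abs(fit.alpha.mean() - 3.1) < 2 * fit.alpha.std()
        truth = {"dark": -0.12, "15C": -0.04, "20C": -0.13, "25C": -0.2}
        for tr, k_true in truth.items():
            draws = fit.k_draws(tr)
            assert abs(draws.mean() - k_true) < 2 * draws.std()
        # predicted starting probability in the published regime
        assert fit.start_probability().mean() == pytest.approx(0.96, abs=0.04)

    def test_complete_separation_still_samples(self):
        out = dp.simulate_viability_outcomes(seed=32)
        out["value"] = 1
        fit = dp.ViabilityModel(out).fit(
            dp.SamplerConfig(chains=2, iterations=600, seed=10)
        )
        assert np.isfinite(fit.alpha).all()
        assert fit.alpha.mean() > 1.0  # pushed up, bounded by the prior

    def test_missingness_zeros_steepen_decay(self):
        """Including disintegrated zeros makes k̂ more negative than
        complete-case fitting on the same data (the bias the binomial
        model exists to remove). Disintegration concentrates at late ages,
        as in the experiment being emulated."""
        truth = dp.TruthParams(seed=41, hazard_baseline=-9.0,
                               hazard_per_day=0.08)
        reg, ser = dp.simulate_experiment(truth=truth)
        records = dp.process_experiment(reg, ser)
        assert records["disintegrated"].sum() >= 4
        cfg = dp.SamplerConfig(chains=2, iterations=800, seed=11)
        full = binarize(records)
        cc = binarize(records[~records["disintegrated"]])
        k_full = dp.ViabilityModel(full, "autotrophy").fit(cfg)
        k_cc = dp.ViabilityModel(cc, "autotrophy").fit(cfg)
        mean_full = np.mean([k_full.k_draws(t, new_tank=False).mean()
                             for t in k_full.treatments])
        mean_cc = np.mean([k_cc.k_draws(t, new_tank=False).mean()
                           for t in k_cc.treatments])
        assert mean_full < mean_cc

    def test_monotone_decay_prediction(self, viability_fit):
        _, fit = viability_fit
        pred = fit.predict(np.linspace(0, 119, 25), "dark", new_tank=False)
        assert (np.diff(pred["mean"]) < 0).all()
        assert ((pred["mean"] > 0) & (pred["mean"] < 1)).all()

    def test_plot_smoke(self, viability_fit):
        _, fit = viability_fit
        ax = fit.plot("dark", ages=np.linspace(0, 119, 8))
        assert ax.get_ylabel().startswith("P(")
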