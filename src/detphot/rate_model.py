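"""Stage 2: hierarchical errors-in-variables regression of rate decline.

Observed rates carry a known stage-1 measurement SD s_P (the posterior SD of
the O₂ slope propagated through unit conversion). The model treats the
observation as a noisy measurement of a latent true rate that declines
linearly with detrital age at a treatment-specific slope with tank-level
partial pooling:

    y_i ~ Normal(true_i, s_i)
    true_i = α_Tr + (β_Tr + β_Ta[tank])·age_i + Σ γ_c·x_ic + ε_i
    β_Ta ~ Normal(0, τ),  ε_i ~ Normal(0, σ)

The measurement layer is marginalised analytically:
y_i ~ Normal(mean_i, sqrt(σ² + s_i²)). Covariates (initial incubation O₂ by
default) are standardised before fitting. Disintegrated samples are excluded
(complete-case); their information is carried by the viability model
instead. Treatment slopes reported for a new tank add τ·z, matching how the
published intervals fold tank variability into predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import bayes
from .bayes import PosteriorDraws, SamplerConfig
from .viability import Contrast, _interval_frame

RESPONSES = {
    "net": ("pn_mean", "pn_sd"),
    "gross": ("pg_mean", "pg_sd"),
    "daily": ("daily_mean", "daily_sd"),
}


def prob_negative(draws) -> float:
    """Fraction of posterior draws strictly below zero."""
    draws = np.asarray(draws, float)
    if draws.size == 0:
        raise ValueError("empty draws")
    return float(np.mean(draws < 0))


@dataclass(frozen=True)
class RatePriors:
    """Data-scaled weakly-informative priors.

    Scales multiply the empirical response SD (and divide by the age SD for
    slope-like parameters), so the priors stay weak in the units of the
    response — the analogue of standardising before assigning Normal(0, 1)
    priors, without leaving the paper's units.
    """

    alpha_scale: float = 2.5
    beta_scale: float = 2.5
    tau_scale: float = 1.0
    sigma_scale: float = 2.0
    gamma_scale: float = 2.5


class RateDeclineModel:
    """Multilevel regression of photosynthesis rates on age × treatment.

    Parameters
    ----------
    records
        RateRecord table from stage 1 (one row per sample; columns
        ``age, treatment, tank, disintegrated`` plus the response mean/sd).
    response
        'net', 'gross' or 'daily'.
    covariates
        Columns standardised and entered with linear coefficients γ.
    age_error_sd
        Optional Gaussian measurement SD on detrital age; marginalised
        exactly through the linear mean (off by default — no error estimate
        is available for the explanatory variable).
    """

    def __init__(
        self,
        records: pd.DataFrame,
        response: str = "net",
        covariates: tuple[str, ...] = ("o2_initial",),
        priors: RatePriors | None = None,
        age_error_sd: float = 0.0,
    ):
        if response not in RESPONSES:
            raise ValueError(f"response must be one of {sorted(RESPONSES)}")
        mean_col, sd_col = RESPONSES[response]
        data = records.copy()
        data = data[~data["disintegrated"].astype(bool)]
        data = data[pd.notna(data[mean_col])]
        if len(data) == 0:
            raise ValueError("no complete-case records to fit")
        self.response = response
        self.priors = priors or RatePriors()
        self.age_error_sd = float(age_error_sd)

        self.treatments = sorted(
            {t for t in data["treatment"] if t is not None and pd.notna(t)}
        )
        if len(self.treatments) < 2:
            raise ValueError("need at least 2 treatments")
        self.tanks = sorted({t for t in data["tank"] if t is not None and pd.notna(t)})

        tr_idx = {t: i for i, t in enumerate(self.treatments)}
        ta_idx = {t: i for i, t in enumerate(self.tanks)}
        self._tr = np.array(
            [tr_idx.get(t, len(self.treatments))
             if t is not None and pd.notna(t) else len(self.treatments)
             for t in data["treatment"]]
        )
        self._ta = np.array(
            [ta_idx.get(t, len(self.tanks))
             if t is not None and pd.notna(t) else len(self.tanks)
             for t in data["tank"]]
        )
        self._age = data["age"].to_numpy(float)
        self._age_bar = float(np.mean(self._age))
        self._y = data[mean_col].to_numpy(float)
        self._s = np.nan_to_num(data[sd_col].to_numpy(float), nan=0.0)

        self.covariates = tuple(c for c in covariates if c in data.columns)
        X = []
        for c in self.covariates:
            col = data[c].to_numpy(float)
            col = np.where(np.isnan(col), np.nanmean(col), col)
            sd = col.std(ddof=0)
            X.append((col - col.mean()) / (sd if sd > 0 else 1.0))
        self._X = np.column_stack(X) if X else np.zeros((len(data), 0))
        self.data = data

        # tank membership indicator (K, n) for the marginal likelihood
        K = len(self.tanks)
        self._M = np.zeros((K, len(data)))
        for j, t in enumerate(self._ta):
            if t < K:
                self._M[t, j] = 1.0

        # prior scales in response units
        y_sd = float(np.std(self._y, ddof=0)) or 1.0
        age_sd = float(np.std(self._age, ddof=0)) or 1.0
        self._y_mean = float(np.mean(self._y))
        p = self.priors
        self.prior_scales = {
            "alpha": p.alpha_scale * y_sd,
            "beta": p.beta_scale * y_sd / age_sd,
            "tau": p.tau_scale * y_sd / age_sd,
            "sigma": p.sigma_scale * y_sd,
            "gamma": p.gamma_scale * y_sd,
        }
        T, C = len(self.treatments), self._X.shape[1]
        self._ndim = T + T + 1 + C + 1

    # layout: [a_T (level at mean age), beta_T, log_tau, gamma_C, log_sigma]
    # The fixed effects are sampled as the treatment level at the mean age,
    # a_Tr = alpha_Tr + beta_Tr·age_bar, which decorrelates intercept and
    # slope; alpha is recovered as a − beta·age_bar everywhere downstream.
    # Tank deviations are marginalised analytically: within a tank the
    # deviation contributes a rank-1 term τ²·age·ageᵀ to the covariance,
    # handled with the Sherman–Morrison identity. Their conditional
    # posteriors are recovered in closed form after sampling.
    def _split(self, theta: np.ndarray):
        T, C = len(self.treatments), self._X.shape[1]
        i = 0
        a_level = theta[:, i : i + T]; i += T
        beta = theta[:, i : i + T]; i += T
        alpha = a_level - beta * self._age_bar
        log_tau = theta[:, i]; i += 1
        gamma = theta[:, i : i + C]; i += C
        log_sigma = theta[:, i]
        return alpha, beta, log_tau, gamma, log_sigma

    def _unpack(self, flat: np.ndarray) -> dict[str, np.ndarray]:
        alpha, beta, log_tau, gamma, log_sigma = self._split(flat)
        out = {
            "alpha": alpha,
            "beta": beta,
            "tau": np.exp(log_tau),
            "sigma": np.exp(log_sigma),
        }
        if gamma.shape[1]:
            out["gamma"] = gamma
        return out

    def _residual_and_var(self, alpha, beta, tau, sigma, gamma):
        W = len(alpha)
        alpha_full = np.concatenate(
            [alpha, alpha.mean(axis=1, keepdims=True)], axis=1
        )  # initials use the average intercept
        beta_full = np.concatenate([beta, np.zeros((W, 1))], axis=1)
        mean = alpha_full[:, self._tr] + beta_full[:, self._tr] * self._age[None, :]
        if gamma.shape[1]:
            mean = mean + gamma @ self._X.T
        var = sigma[:, None] ** 2 + self._s[None, :] ** 2
        if self.age_error_sd > 0:
            var = var + (
                (beta_full[:, self._tr] ** 2 + tau[:, None] ** 2)
                * self.age_error_sd**2
            )
        return self._y[None, :] - mean, var

    def _log_prob(self, theta: np.ndarray) -> np.ndarray:
        alpha, beta, log_tau, gamma, log_sigma = self._split(theta)
        tau = np.exp(np.clip(log_tau, -30.0, 20.0))
        sigma = np.exp(np.clip(log_sigma, -30.0, 20.0))
        resid, var = self._residual_and_var(alpha, beta, tau, sigma, gamma)

        # diagonal part
        loglik = -0.5 * np.sum(resid**2 / var + np.log(2 * np.pi * var), axis=1)
        # rank-1 tank corrections: cov_tank = D + τ²·a aᵀ
        a = self._age[None, :]
        A = (a**2 / var) @ self._M.T  # (W, K): aᵀD⁻¹a per tank
        B = (a * resid / var) @ self._M.T  # (W, K): aᵀD⁻¹r per tank
        t2 = tau[:, None] ** 2
        denom = 1.0 + t2 * A
        loglik = loglik + 0.5 * np.sum(t2 * B**2 / denom - np.log(denom), axis=1)

        s = self.prior_scales
        lp = -0.5 * np.sum(((alpha - self._y_mean) / s["alpha"]) ** 2, axis=1)
        lp = lp - 0.5 * np.sum((beta / s["beta"]) ** 2, axis=1)
        lp = lp - 0.5 * (tau / s["tau"]) ** 2 + log_tau
        if gamma.shape[1]:
            lp = lp - 0.5 * np.sum((gamma / s["gamma"]) ** 2, axis=1)
        lp = lp - 0.5 * (sigma / s["sigma"]) ** 2 + log_sigma
        return loglik + lp

    def conditional_tank_slopes(self, results: "RateDeclineResults") -> pd.DataFrame:
        """Posterior-mean slope per tank, E[β_Tr + τ·z_tank | data].

        Uses the closed-form conditional of the marginalised tank deviation:
        z | θ, y ~ Normal(τ·aᵀD⁻¹r / (1 + τ²aᵀD⁻¹a), ·).
        """
        raw = results._raw
        alpha, beta = raw["alpha"], raw["beta"]
        tau, sigma = raw["tau"], raw["sigma"]
        gamma = raw.get("gamma", np.zeros((len(tau), 0)))
        resid, var = self._residual_and_var(alpha, beta, tau, sigma, gamma)
        a = self._age[None, :]
        A = (a**2 / var) @ self._M.T
        B = (a * resid / var) @ self._M.T
        z_mean = tau[:, None] * B / (1.0 + tau[:, None] ** 2 * A)
        rows = []
        tr_of_tank = {
            t: self.treatments[self._tr[j]]
            for j, t in enumerate(self._ta)
            if t < len(self.tanks)
        }
        for k, tank in enumerate(self.tanks):
            tr_i = tr_of_tank[k]
            slope = beta[:, self.treatments.index(tr_i)] + tau * z_mean[:, k]
            rows.append({"tank": tank, "treatment": tr_i,
                         "slope_mean": float(slope.mean()),
                         "slope_sd": float(slope.std(ddof=1))})
        return pd.DataFrame(rows)

    def fit(self, config: SamplerConfig | None = None) -> "RateDeclineResults":
        config = config or SamplerConfig()
        T = len(self.treatments)
        x0 = np.zeros(self._ndim)
        x0[:T] = self._y_mean
        x0[2 * T] = np.log(self.prior_scales["tau"] / 4)
        x0[-1] = np.log(max(np.std(self._y, ddof=0) / 2, 1e-3))
        draws = bayes.sample(self._log_prob, self._ndim, self._unpack, config, x0=x0)
        if not draws.converged:
            warnings.warn(
                f"rate model did not converge (max R-hat = {draws.max_rhat:.3f})",
                RuntimeWarning,
                stacklevel=2,
            )
        return RateDeclineResults(
            self.treatments, self.tanks, draws, response=self.response,
            seed=config.seed, prior_scales=self.prior_scales, model=self,
        )


class RateDeclineResults:
    """Posterior draws, contrasts and new-tank predictions for one response."""

    def __init__(
        self,
        treatments: list[str],
        tanks: list[str],
        draws: PosteriorDraws | None,
        response: str = "net",
        seed: int = 0,
        prior_scales: dict[str, float] | None = None,
        raw: dict[str, np.ndarray] | None = None,
        model: "RateDeclineModel | None" = None,
    ):
        self.treatments = list(treatments)
        self.tanks = list(tanks)
        self.posterior = draws
        self.response = response
        self.seed = seed
        self.prior_scales = prior_scales or {}
        self.model = model
        if raw is not None:
            self._raw = {k: np.asarray(v, float) for k, v in raw.items()}
        else:
            self._raw = {
                "alpha": draws.flat("alpha"),
                "beta": draws.flat("beta"),
                "tau": draws.flat("tau"),
                "sigma": draws.flat("sigma"),
            }
            if "gamma" in draws.draws:
                self._raw["gamma"] = draws.flat("gamma")

    @classmethod
    def from_draws(cls, alpha, beta, treatments, tau=None, sigma=None, **kwargs):
        """Build a results object from externally supplied draws (no fit)."""
        beta = np.atleast_2d(np.asarray(beta, float))
        n = beta.shape[0]
        raw = {
            "alpha": np.atleast_2d(np.asarray(alpha, float)),
            "beta": beta,
            "tau": np.zeros(n) if tau is None else np.asarray(tau, float),
            "sigma": np.ones(n) if sigma is None else np.asarray(sigma, float),
        }
        return cls(treatments, [], None, raw=raw, **kwargs)

    @property
    def converged(self) -> bool:
        return True if self.posterior is None else self.posterior.converged

    @property
    def diagnostics(self) -> pd.DataFrame | None:
        return None if self.posterior is None else self.posterior.diagnostics

    @property
    def tau(self) -> np.ndarray:
        return self._raw["tau"]

    @property
    def sigma(self) -> np.ndarray:
        return self._raw["sigma"]

    def _tr_index(self, treatment: str) -> int:
        try:
            return self.treatments.index(treatment)
        except ValueError:
            raise KeyError(f"unknown treatment {treatment!r}") from None

    def slope_draws(self, treatment: str, new_tank: bool = True,
                    rng: np.random.Generator | None = None) -> np.ndarray:
        """β_Tr draws; with ``new_tank`` adds τ·z for an unseen tank."""
        beta = self._raw["beta"][:, self._tr_index(treatment)]
        if not new_tank:
            return beta
        rng = rng or np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(5, self._tr_index(treatment)))
        )
        return beta + self.tau * rng.normal(size=len(beta))

    def intercept_draws(self, treatment: str) -> np.ndarray:
        return self._raw["alpha"][:, self._tr_index(treatment)]

    def tank_slopes(self) -> pd.DataFrame:
        """Posterior-mean (partially pooled) slope for every observed tank."""
        if self.model is None:
            raise ValueError("tank slopes need the fitted model context")
        return self.model.conditional_tank_slopes(self)

    def contrast_slopes(self, a: str, b: str, new_tank: bool = True) -> Contrast:
        """δβ = β_a − β_b with tank variability propagated per draw."""
        rng = np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(6,)))
        da = self.slope_draws(a, new_tank=new_tank, rng=rng)
        db = self.slope_draws(b, new_tank=new_tank, rng=rng)
        return Contrast(a, b, da - db)

    def predict_new_tank(self, treatment: str, ages) -> pd.DataFrame:
        """Predictive mean and 50/80/90% intervals for a new tank.

        Per draw: α_Tr + (β_Tr + b_new)·age with b_new ~ Normal(0, τ)
        resampled independently for every draw. With τ → 0 this collapses
        to the fixed-effect prediction.
        """
        ages = np.asarray(ages, float)
        if ages.size == 0:
            raise ValueError("empty age grid")
        i = self._tr_index(treatment)
        rng = np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(9, i))
        )
        b_new = self.tau * rng.normal(size=len(self.tau))
        slope = self._raw["beta"][:, i] + b_new
        draws = self._raw["alpha"][:, i][:, None] + slope[:, None] * ages[None, :]
        return _interval_frame(ages, draws)

    def summary(self) -> pd.DataFrame:
        rows = []
        for i, tr in enumerate(self.treatments):
            a = self._raw["alpha"][:, i]
            b = self._raw["beta"][:, i]
            bn = self.slope_draws(tr, new_tank=True)
            rows.append({"parameter": f"alpha[{tr}]", "mean": float(a.mean()),
                         "sd": float(a.std(ddof=1))})
            rows.append({"parameter": f"beta[{tr}]", "mean": float(b.mean()),
                         "sd": float(b.std(ddof=1)),
                         "p_negative": prob_negative(bn)})
        for name in ("tau", "sigma"):
            arr = self._raw[name]
            rows.append({"parameter": name, "mean": float(arr.mean()),
                         "sd": float(arr.std(ddof=1))})
        if "gamma" in self._raw:
            g = self._raw["gamma"]
            for i in range(g.shape[1]):
                rows.append({"parameter": f"gamma[{i}]",
                             "mean": float(g[:, i].mean()),
                             "sd": float(g[:, i].std(ddof=1))})
        frame = pd.DataFrame(rows)
        if self.posterior is not None:
            diag = self.posterior.diagnostics.copy()
            diag["parameter"] = _relabel_rate(diag["parameter"], self.treatments)
            frame = frame.merge(diag, on="parameter", how="left")
        return frame

    def plot_predictions(self, treatment: str, ages=None, ax=None):
        """Plot new-tank predictive bands over detrital age."""
        import matplotlib.pyplot as plt

        if ages is None:
            ages = np.linspace(0.0, 120.0, 61)
        pred = self.predict_new_tank(treatment, ages)
        if ax is None:
            _, ax = plt.subplots()
        for lo, hi, alpha_ in (("q5", "q95", 0.2), ("q10", "q90", 0.3),
                               ("q25", "q75", 0.4)):
            ax.fill_between(pred["age"], pred[lo], pred[hi], alpha=alpha_,
                            color="tab:green", lw=0)
        ax.plot(pred["age"], pred["mean"], color="tab:green")
        ax.set_xlabel("detrital age (days)")
        ax.set_ylabel(f"{self.response} photosynthesis rate")
        ax.set_title(treatment)
        return ax


def _relabel_rate(params: pd.Series, treatments: list[str]) -> pd.Series:
    mapping = {}
    for i, tr in enumerate(treatments):
        mapping[f"alpha[{i}]"] = f"alpha[{tr}]"
        mapping[f"beta[{i}]"] = f"beta[{tr}]"
    return params.map(lambda p: mapping.get(p, p))
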