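"""Stage 4: thermal performance and light-threshold meta-analysis curves.

Three curve families constrain the tolerance envelope of the kelp before
the decomposition experiment:

* a Gaussian temperature–performance curve across studies, life stages and
  measures, with a study-level thermal optimum
  T_opt,s ~ Normal(T_opt, τ) so that "predicting the outcome of a new
  study" widens the T_opt posterior;
* a peaked Arrhenius (Sharpe–Schoolfield-type, high-temperature
  inactivation) temperature–rate curve

      r(T) = r_ref · exp(E_a/k_B · (1/T_ref − 1/T)) /
             (1 + E_a/(E_d − E_a) · exp(E_d/k_B · (1/T_opt − 1/T)))

  with E_d > E_a enforced, whose peak sits exactly at T_opt;
* gamma models for compensation (E_c) and saturation (E_k) irradiance,
  whose survival function gives the probability that a candidate irradiance
  is subcompensating.

Temperatures are °C at every interface; Arrhenius converts to Kelvin
internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import bayes
from .bayes import PosteriorDraws, SamplerConfig

BOLTZMANN_EV = 8.617333262e-5  # eV / K
T_REF_C = 20.0


def celsius_to_kelvin(t_c):
    return np.asarray(t_c, float) + 273.15


def gaussian_tpc_curve(temp_c, p_max, t_opt, sigma_t):
    """Gaussian thermal performance: P_max·exp(−(T−T_opt)²/(2σ_T²))."""
    temp_c = np.asarray(temp_c, float)
    return p_max * np.exp(-((temp_c - t_opt) ** 2) / (2.0 * sigma_t**2))


def peaked_arrhenius_curve(temp_c, rate_at_ref, e_a, e_d, t_opt_c,
                           t_ref_c: float = T_REF_C):
    """Rise–fall Arrhenius curve with high-temperature deactivation.

    ``rate_at_ref`` is the numerator rate at ``t_ref_c``; activation and
    deactivation energies are in eV with E_d > E_a required. The curve
    attains its maximum exactly at ``t_opt_c``.
    """
    if e_d <= e_a:
        raise ValueError("deactivation energy must exceed activation energy")
    T = celsius_to_kelvin(temp_c)
    t_ref = 273.15 + t_ref_c
    t_opt = 273.15 + t_opt_c
    rise = rate_at_ref * np.exp(e_a / BOLTZMANN_EV * (1.0 / t_ref - 1.0 / T))
    fall = 1.0 + e_a / (e_d - e_a) * np.exp(
        e_d / BOLTZMANN_EV * (1.0 / t_opt - 1.0 / T)
    )
    return rise / fall


@dataclass(frozen=True)
class TpcConfig:
    """Weak prior scales for the TPC fits (in data units)."""

    topt_sd_c: float = 15.0
    study_tau_scale_c: float = 3.0
    sigma_t_scale_c: float = 15.0
    e_a_log_mean: float = np.log(0.6)
    e_a_log_sd: float = 1.0
    de_log_mean: float = np.log(2.0)
    de_log_sd: float = 1.5


class GaussianTPC:
    """Gaussian temperature–performance model with study-level T_opt."""

    def __init__(self, data: pd.DataFrame, config: TpcConfig | None = None):
        required = {"temperature_c", "performance", "study_id"}
        if not required <= set(data.columns):
            raise ValueError(f"data must have columns {sorted(required)}")
        if len(data) < 5:
            raise ValueError("need at least 5 observations")
        if data["temperature_c"].nunique() < 3:
            raise ValueError("need observations spanning at least 3 temperatures")
        self.data = data.reset_index(drop=True)
        self.config = config or TpcConfig()
        self.studies = sorted(data["study_id"].unique())
        if len(self.studies) < 2:
            raise ValueError("need at least 2 studies for the new-study level")
        sidx = {s: i for i, s in enumerate(self.studies)}
        self._s = data["study_id"].map(sidx).to_numpy()
        self._T = data["temperature_c"].to_numpy(float)
        self._y = data["performance"].to_numpy(float)
        self._t_center = float(self._T.mean())
        self._y_scale = float(np.std(self._y, ddof=0)) or 1.0
        # layout: [log_pmax, topt, z_s(S), log_sigma_t, log_tau, log_sigma]
        self._ndim = 2 + len(self.studies) + 3

    def _unpack(self, flat):
        S = len(self.studies)
        return {
            "p_max": np.exp(flat[:, 0]),
            "t_opt": flat[:, 1],
            "z_study": flat[:, 2 : 2 + S],
            "sigma_t": np.exp(flat[:, 2 + S]),
            "tau_study": np.exp(flat[:, 3 + S]),
            "sigma": np.exp(flat[:, 4 + S]),
        }

    def _log_prob(self, theta):
        S = len(self.studies)
        log_pmax = np.clip(theta[:, 0], -20, 20)
        topt = theta[:, 1]
        z = theta[:, 2 : 2 + S]
        log_sigma_t = np.clip(theta[:, 2 + S], -10, 10)
        log_tau = np.clip(theta[:, 3 + S], -20, 10)
        log_sigma = np.clip(theta[:, 4 + S], -20, 10)
        pmax = np.exp(log_pmax)
        sigma_t = np.exp(log_sigma_t)
        tau = np.exp(log_tau)
        sigma = np.exp(log_sigma)

        topt_s = topt[:, None] + tau[:, None] * z  # (W, S)
        mu = pmax[:, None] * np.exp(
            -((self._T[None, :] - topt_s[:, self._s]) ** 2)
            / (2.0 * sigma_t[:, None] ** 2)
        )
        resid2 = (self._y[None, :] - mu) ** 2
        loglik = -0.5 * np.sum(
            resid2 / sigma[:, None] ** 2 + np.log(2 * np.pi) + 2 * log_sigma[:, None],
            axis=1,
        )
        c = self.config
        lp = -0.5 * ((topt - self._t_center) / c.topt_sd_c) ** 2
        lp = lp - 0.5 * (pmax / (2.5 * self._y_scale)) ** 2 + log_pmax
        lp = lp - 0.5 * np.sum(z**2, axis=1)
        lp = lp - 0.5 * (sigma_t / c.sigma_t_scale_c) ** 2 + log_sigma_t
        lp = lp - 0.5 * (tau / c.study_tau_scale_c) ** 2 + log_tau
        lp = lp - 0.5 * (sigma / (2.5 * self._y_scale)) ** 2 + log_sigma
        return loglik + lp

    def fit(self, config: SamplerConfig | None = None) -> "TpcResults":
        config = config or SamplerConfig()
        S = len(self.studies)
        x0 = np.zeros(self._ndim)
        x0[0] = np.log(max(self._y.max(), 0.1))
        x0[1] = self._T[np.argmax(self._y)]
        x0[2 + S] = np.log(np.ptp(self._T) / 3 or 5.0)
        x0[3 + S] = np.log(1.0)
        x0[4 + S] = np.log(self._y_scale / 2)
        draws = bayes.sample(self._log_prob, self._ndim, self._unpack, config, x0=x0)
        return TpcResults(
            "gaussian", draws, seed=config.seed,
            t_hull=(float(self._T.min()), float(self._T.max())),
        )


class PeakedArrhenius:
    """Peaked Arrhenius temperature–rate model with study-level T_opt."""

    def __init__(self, data: pd.DataFrame, config: TpcConfig | None = None,
                 t_ref_c: float = T_REF_C):
        required = {"temperature_c", "rate"}
        if not required <= set(data.columns):
            raise ValueError(f"data must have columns {sorted(required)}")
        if np.any(data["rate"].to_numpy(float) <= 0):
            raise ValueError("rates must be positive")
        self.data = data.reset_index(drop=True)
        self.config = config or TpcConfig()
        self.t_ref_c = t_ref_c
        if "study_id" in data.columns:
            self.studies = sorted(data["study_id"].unique())
        else:
            self.studies = ["study1"]
        sidx = {s: i for i, s in enumerate(self.studies)}
        self._s = (
            data["study_id"].map(sidx).to_numpy()
            if "study_id" in data.columns
            else np.zeros(len(data), dtype=int)
        )
        self._hier = len(self.studies) >= 2
        self._T = data["temperature_c"].to_numpy(float)
        self._y = data["rate"].to_numpy(float)
        self._t_center = float(self._T.mean())
        self._y_scale = float(np.std(self._y, ddof=0)) or 1.0
        # layout: [log_rref, log_ea, log_de, topt, z_s(S), log_tau, log_sigma]
        self._ndim = 4 + len(self.studies) + 2

    def _unpack(self, flat):
        S = len(self.studies)
        return {
            "rate_at_ref": np.exp(flat[:, 0]),
            "e_a": np.exp(flat[:, 1]),
            "e_d": np.exp(flat[:, 1]) + np.exp(flat[:, 2]),
            "t_opt": flat[:, 3],
            "z_study": flat[:, 4 : 4 + S],
            "tau_study": np.exp(flat[:, 4 + S]),
            "sigma": np.exp(flat[:, 5 + S]),
        }

    def _curve(self, topt_s, log_rref, e_a, e_d):
        T = celsius_to_kelvin(self._T)[None, :]
        t_ref = 273.15 + self.t_ref_c
        t_opt = 273.15 + topt_s[:, self._s]
        log_rise = log_rref[:, None] + e_a[:, None] / BOLTZMANN_EV * (
            1.0 / t_ref - 1.0 / T
        )
        expo = np.clip(
            e_d[:, None] / BOLTZMANN_EV * (1.0 / t_opt - 1.0 / T), -500, 500
        )
        fall = 1.0 + (e_a / (e_d - e_a))[:, None] * np.exp(expo)
        return np.exp(np.clip(log_rise, -500, 500)) / fall

    def _log_prob(self, theta):
        S = len(self.studies)
        log_rref = np.clip(theta[:, 0], -20, 20)
        log_ea = np.clip(theta[:, 1], -6, 4)
        log_de = np.clip(theta[:, 2], -6, 5)
        topt = theta[:, 3]
        z = theta[:, 4 : 4 + S]
        log_tau = np.clip(theta[:, 4 + S], -20, 6)
        log_sigma = np.clip(theta[:, 5 + S], -20, 15)
        e_a = np.exp(log_ea)
        e_d = e_a + np.exp(log_de)
        tau = np.exp(log_tau)
        sigma = np.exp(log_sigma)

        topt_s = topt[:, None] + (tau[:, None] * z if self._hier else 0.0 * z)
        mu = self._curve(topt_s, log_rref, e_a, e_d)
        resid2 = (self._y[None, :] - mu) ** 2
        loglik = -0.5 * np.sum(
            resid2 / sigma[:, None] ** 2 + np.log(2 * np.pi) + 2 * log_sigma[:, None],
            axis=1,
        )
        c = self.config
        lp = -0.5 * ((topt - self._t_center) / c.topt_sd_c) ** 2
        lp = lp - 0.5 * ((log_ea - c.e_a_log_mean) / c.e_a_log_sd) ** 2
        lp = lp - 0.5 * ((log_de - c.de_log_mean) / c.de_log_sd) ** 2
        lp = lp - 0.5 * ((log_rref - np.log(self._y.mean())) / 1.5) ** 2
        lp = lp - 0.5 * np.sum(z**2, axis=1)
        lp = lp - 0.5 * (tau / c.study_tau_scale_c) ** 2 + log_tau
        lp = lp - 0.5 * (sigma / (2.5 * self._y_scale)) ** 2 + log_sigma
        return loglik + lp

    def fit(self, config: SamplerConfig | None = None) -> "TpcResults":
        config = config or SamplerConfig()
        S = len(self.studies)
        x0 = np.zeros(self._ndim)
        x0[0] = np.log(self._y.mean())
        x0[1] = self.config.e_a_log_mean
        x0[2] = self.config.de_log_mean
        x0[3] = self._T[np.argmax(self._y)]
        x0[4 + S] = np.log(0.5)
        x0[5 + S] = np.log(self._y_scale / 2)
        draws = bayes.sample(self._log_prob, self._ndim, self._unpack, config, x0=x0)
        res = TpcResults(
            "peaked_arrhenius", draws, seed=config.seed,
            t_hull=(float(self._T.min()), float(self._T.max())),
            t_ref_c=self.t_ref_c,
        )
        if not res.peak_identified:
            warnings.warn(
                "T_opt posterior concentrates at the edge of the data hull; "
                "the peak is not identified by these (monotone) data",
                RuntimeWarning, stacklevel=2,
            )
        return res


class TpcResults:
    """T_opt posterior and new-study prediction for a fitted curve family."""

    def __init__(self, family: str, draws: PosteriorDraws, seed: int = 0,
                 t_hull: tuple[float, float] = (-np.inf, np.inf),
                 t_ref_c: float = T_REF_C):
        self.family = family
        self.posterior = draws
        self.seed = seed
        self.t_hull = t_hull
        self.t_ref_c = t_ref_c

    @property
    def converged(self) -> bool:
        return self.posterior.converged

    @property
    def diagnostics(self) -> pd.DataFrame:
        return self.posterior.diagnostics

    def t_opt_draws(self, new_study: bool = False) -> np.ndarray:
        topt = self.posterior.flat("t_opt")
        if not new_study:
            return topt
        tau = self.posterior.flat("tau_study")
        rng = np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(13,))
        )
        return topt + tau * rng.normal(size=len(topt))

    @property
    def peak_identified(self) -> bool:
        """False when the posterior T_opt mass escapes the data hull."""
        topt = self.t_opt_draws()
        lo, hi = self.t_hull
        margin = 0.15 * (hi - lo)
        inside = np.mean((topt > lo - margin) & (topt < hi + margin))
        return bool(inside >= 0.5)

    def curve(self, temp_c, draw_summary: str = "mean") -> np.ndarray:
        """Posterior-mean curve evaluated on a temperature grid."""
        temp_c = np.asarray(temp_c, float)
        post = self.posterior
        if self.family == "gaussian":
            return gaussian_tpc_curve(
                temp_c,
                float(post.flat("p_max").mean()),
                float(post.flat("t_opt").mean()),
                float(post.flat("sigma_t").mean()),
            )
        return peaked_arrhenius_curve(
            temp_c,
            float(post.flat("rate_at_ref").mean()),
            float(post.flat("e_a").mean()),
            float(post.flat("e_d").mean()),
            float(post.flat("t_opt").mean()),
            t_ref_c=self.t_ref_c,
        )

    def summary(self) -> pd.DataFrame:
        named = {k: v for k, v in self.posterior.draws.items() if k != "z_study"}
        frame = bayes.summarize(named)
        topt_new = self.t_opt_draws(new_study=True)
        frame.loc[len(frame)] = {
            "parameter": "t_opt_new_study",
            "mean": float(topt_new.mean()),
            "sd": float(topt_new.std(ddof=1)),
            **{f"q{int(p * 100)}": float(np.quantile(topt_new, p))
               for p in (0.05, 0.25, 0.5, 0.75, 0.95)},
        }
        return frame

    def plot(self, temp_grid=None, ax=None):
        import matplotlib.pyplot as plt

        lo, hi = self.t_hull
        if temp_grid is None:
            temp_grid = np.linspace(lo - 2, hi + 2, 100)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(temp_grid, self.curve(temp_grid), color="tab:red")
        ax.axvline(float(self.t_opt_draws().mean()), ls="--", color="grey")
        ax.set_xlabel("temperature (°C)")
        ax.set_ylabel("performance" if self.family == "gaussian" else "rate")
        return ax


class GammaThreshold:
    """Gamma model for compensation/saturation irradiance observations.

    Parameterised by (shape, mean) so that scaling the observations by c
    scales the fitted mean by c. An optional lognormal study effect on the
    mean provides a new-study predictive level.
    """

    def __init__(self, observations, threshold: str = "E_c",
                 study_id=None, hierarchical: bool = False):
        obs = np.asarray(
            observations["irradiance"]
            if isinstance(observations, pd.DataFrame)
            else observations,
            float,
        )
        if np.any(obs <= 0) or np.any(~np.isfinite(obs)):
            raise ValueError("irradiance observations must be positive and finite")
        self.obs = obs
        self.threshold = threshold
        if study_id is None and isinstance(observations, pd.DataFrame) \
                and "study_id" in observations:
            study_id = observations["study_id"]
        self.hierarchical = bool(hierarchical and study_id is not None)
        if self.hierarchical:
            self.studies = sorted(pd.unique(np.asarray(study_id)))
            sidx = {s: i for i, s in enumerate(self.studies)}
            self._s = np.array([sidx[s] for s in np.asarray(study_id)])
        else:
            self.studies = []
            self._s = np.zeros(len(obs), dtype=int)
        # layout: [log_shape, log_mean, (z_s..., log_tau)]
        self._ndim = 2 + (len(self.studies) + 1 if self.hierarchical else 0)
        self._log_mean_center = float(np.log(obs.mean()))

    def _unpack(self, flat):
        out = {"shape": np.exp(flat[:, 0]), "mean": np.exp(flat[:, 1])}
        if self.hierarchical:
            S = len(self.studies)
            out["z_study"] = flat[:, 2 : 2 + S]
            out["tau_study"] = np.exp(flat[:, 2 + S])
        return out

    def _log_prob(self, theta):
        log_shape = np.clip(theta[:, 0], -8, 8)
        log_mean = np.clip(theta[:, 1], -15, 15)
        shape = np.exp(log_shape)
        mean = np.exp(log_mean)
        if self.hierarchical:
            S = len(self.studies)
            z = theta[:, 2 : 2 + S]
            log_tau = np.clip(theta[:, 2 + S], -20, 3)
            tau = np.exp(log_tau)
            mean_j = mean[:, None] * np.exp(tau[:, None] * z)  # (W, S)
            mean_obs = mean_j[:, self._s]
        else:
            mean_obs = mean[:, None] * np.ones((1, len(self.obs)))
        rate = shape[:, None] / mean_obs
        x = self.obs[None, :]
        loglik = np.sum(
            shape[:, None] * np.log(rate)
            + (shape[:, None] - 1.0) * np.log(x)
            - rate * x
            - _gammaln(shape)[:, None],
            axis=1,
        )
        # priors act on the unclipped parameters so the tails always decay
        lp = -0.5 * ((theta[:, 0] - np.log(2.0)) / 1.5) ** 2
        lp = lp - 0.5 * ((theta[:, 1] - self._log_mean_center) / 1.5) ** 2
        if self.hierarchical:
            lp = lp - 0.5 * np.sum(z**2, axis=1)
            lp = lp - 0.5 * (tau / 0.5) ** 2 + log_tau
        return loglik + lp

    def fit(self, config: SamplerConfig | None = None) -> "GammaThresholdResults":
        config = config or SamplerConfig()
        x0 = np.zeros(self._ndim)
        x0[0] = np.log(4.0)
        x0[1] = self._log_mean_center
        if self.hierarchical:
            x0[-1] = np.log(0.2)
        draws = bayes.sample(self._log_prob, self._ndim, self._unpack, config, x0=x0)
        return GammaThresholdResults(self.threshold, draws, seed=config.seed,
                                     hierarchical=self.hierarchical)


def _gammaln(x):
    from scipy.special import gammaln

    return gammaln(x)


class GammaThresholdResults:
    """Posterior for a gamma-distributed irradiance threshold."""

    def __init__(self, threshold: str, draws: PosteriorDraws, seed: int = 0,
                 hierarchical: bool = False):
        self.threshold = threshold
        self.posterior = draws
        self.seed = seed
        self.hierarchical = hierarchical

    @property
    def converged(self) -> bool:
        return self.posterior.converged

    @property
    def diagnostics(self) -> pd.DataFrame:
        return self.posterior.diagnostics

    @property
    def shape_draws(self) -> np.ndarray:
        return self.posterior.flat("shape")

    def mean_draws(self, new_study: bool = False) -> np.ndarray:
        mean = self.posterior.flat("mean")
        if not new_study or not self.hierarchical:
            return mean
        tau = self.posterior.flat("tau_study")
        rng = np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(14,))
        )
        return mean * np.exp(tau * rng.normal(size=len(mean)))

    def prob_below(self, irradiance: float, new_study: bool = False) -> float:
        """P(threshold > irradiance): the queried light is subcompensating.

        Posterior-predictive, averaged over (shape, mean) draws of the
        gamma survival function.
        """
        if irradiance <= 0:
            raise ValueError("irradiance must be positive")
        shape = self.shape_draws
        mean = self.mean_draws(new_study=new_study)
        sf = stats.gamma.sf(irradiance, a=shape, scale=mean / shape)
        return float(np.mean(sf))

    def predictive_pdf(self, x, new_study: bool = False) -> np.ndarray:
        """Posterior-predictive density of a new threshold observation."""
        x = np.asarray(x, float)
        shape = self.shape_draws[:, None]
        mean = self.mean_draws(new_study=new_study)[:, None]
        return np.mean(stats.gamma.pdf(x[None, :], a=shape, scale=mean / shape),
                       axis=0)

    def summary(self) -> pd.DataFrame:
        named = {k: v for k, v in self.posterior.draws.items() if k != "z_study"}
        return bayes.summarize(named)


def prob_below(fit: GammaThresholdResults, irradiance: float, **kwargs) -> float:
    """Functional alias for :meth:`GammaThresholdResults.prob_below`."""
    return fit.prob_below(irradiance, **kwargs)
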