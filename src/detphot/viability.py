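"""Stage 3: probabilistic viability of detrital photosynthesis.

Measured rates are binarized into three Bernoulli outcomes — autotrophy
(P_n > 0), photosynthesis (P_g > 0) and daily autotrophy (daily net > 0) —
with disintegrated samples contributing 0 to all three, so that the
information in non-randomly missing (decomposed) samples enters inference.
Each outcome is modelled with a binomial multilevel model on the logit
scale:

    value ~ Bernoulli(inv_logit(α + (k_Tr + k_Ta[tank])·age)),
    k_Ta ~ Normal(0, τ_k)

with a common intercept α (all bags share the same starting material) and
detrital age in raw days, so k is literally log odds per day. The derived
inflection day μ = −α/k is the age at which viability probability crosses
0.5; differences of k between treatments are log odds ratios per day.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from . import bayes
from .bayes import PosteriorDraws, SamplerConfig

OUTCOMES = ("autotrophy", "photosynthesis", "daily_autotrophy")

_NO_TANK = "<none>"


def inv_logit(x):
    """inverse-logit(x) = 1 / (1 + exp(−x))."""
    return expit(x)


def logit(p):
    """log odds of a probability in the open interval (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("logit requires probabilities strictly inside (0, 1)")
    out = np.log(p / (1 - p))
    return float(out) if out.ndim == 0 else out


def binarize(records: pd.DataFrame) -> pd.DataFrame:
    """Binarize RateRecords into the three viability outcomes.

    Returns a long DataFrame (sample_id, age, treatment, tank, outcome,
    value) with one row per sample per outcome. Disintegrated samples score
    0 on all outcomes, including error-induced negative gross rates.
    """
    rows = []
    for rec in records.itertuples(index=False):
        disintegrated = bool(rec.disintegrated)
        has_rates = not (
            pd.isna(getattr(rec, "pn_mean", np.nan))
            or pd.isna(getattr(rec, "pg_mean", np.nan))
            or pd.isna(getattr(rec, "daily_mean", np.nan))
        )
        if not disintegrated and not has_rates:
            raise ValueError(
                f"sample {rec.sample_id} has neither rates nor a disintegration flag"
            )
        if disintegrated:
            values = {o: 0 for o in OUTCOMES}
        else:
            values = {
                "autotrophy": int(rec.pn_mean > 0),
                "photosynthesis": int(rec.pg_mean > 0),
                "daily_autotrophy": int(rec.daily_mean > 0),
            }
        for outcome, value in values.items():
            rows.append(
                {
                    "sample_id": rec.sample_id,
                    "age": float(rec.age),
                    "treatment": rec.treatment,
                    "tank": rec.tank,
                    "outcome": outcome,
                    "value": value,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ViabilityPriors:
    """Weakly-informative priors on the logit scale."""

    alpha_sd: float = 1.5
    k_sd: float = 1.5  # log odds per day
    tau_scale: float = 0.1  # half-Normal scale for the tank-deviation SD


class ViabilityModel:
    """Binomial logit decay model for one viability outcome.

    Parameters
    ----------
    data
        Long outcome table as produced by :func:`binarize`, already filtered
        to (or filterable by) one outcome.
    outcome
        Which outcome to model if ``data`` contains several.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str | None = None,
        priors: ViabilityPriors | None = None,
    ):
        if outcome is not None:
            data = data[data["outcome"] == outcome]
        elif "outcome" in data and data["outcome"].nunique() > 1:
            raise ValueError("data holds several outcomes; pass outcome=...")
        if len(data) == 0:
            raise ValueError("no outcome rows to fit")
        self.outcome = outcome or (
            data["outcome"].iloc[0] if "outcome" in data else "outcome"
        )
        self.priors = priors or ViabilityPriors()

        data = data.copy()
        data["treatment"] = data["treatment"].where(pd.notna(data["treatment"]), None)
        data["tank"] = data["tank"].where(pd.notna(data["tank"]), None)
        self.data = data
        self.treatments = sorted({t for t in data["treatment"] if t is not None})
        if len(self.treatments) < 2 and (data["age"] > 0).any():
            raise ValueError("need at least 2 treatments")
        self.tanks = sorted({t for t in data["tank"] if t is not None})

        tr_idx = {t: i for i, t in enumerate(self.treatments)}
        ta_idx = {t: i for i, t in enumerate(self.tanks)}
        self._tr = np.array(
            [tr_idx.get(t, len(self.treatments)) for t in data["treatment"]]
        )
        self._ta = np.array([ta_idx.get(t, len(self.tanks)) for t in data["tank"]])
        self._age = data["age"].to_numpy(float)
        self._y = data["value"].to_numpy(float)
        K = len(self.tanks)
        self._M = np.zeros((K, len(data)))  # tank membership
        for j, t in enumerate(self._ta):
            if t < K:
                self._M[t, j] = 1.0
        self._no_tank = (self._ta == K).astype(float)
        # Gauss–Hermite rule for marginalising the tank deviation
        gh_x, gh_w = np.polynomial.hermite_e.hermegauss(15)
        self._gh_z = gh_x  # probabilists' nodes: ∫φ(z)f(z)dz = Σ w_j f(z_j)/√(2π)
        self._gh_logw = np.log(gh_w) - 0.5 * np.log(2 * np.pi)
        self._ndim = 1 + len(self.treatments) + 1

    # layout: [alpha, k_Tr..., log_tau]; tank deviations are integrated out
    # per tank with a 15-node Gauss–Hermite rule (the logistic integrand in
    # z is smooth, so the rule is accurate far beyond sampling error).
    def _unpack(self, flat: np.ndarray) -> dict[str, np.ndarray]:
        T = len(self.treatments)
        return {
            "alpha": flat[:, 0],
            "k": flat[:, 1 : 1 + T],
            "tau_k": np.exp(flat[:, 1 + T]),
        }

    def _log_prob(self, theta: np.ndarray) -> np.ndarray:
        T = len(self.treatments)
        alpha = theta[:, 0]
        k = theta[:, 1 : 1 + T]
        log_tau = theta[:, 1 + T]
        tau = np.exp(np.clip(log_tau, -30.0, 5.0))

        k_full = np.concatenate([k, np.zeros((len(theta), 1))], axis=1)
        k_obs = k_full[:, self._tr]  # (W, n)
        base = alpha[:, None] + k_obs * self._age[None, :]
        # per-node linear predictor: eta = base + τ·z_j·age (tank members only)
        shift = tau[:, None] * self._age[None, :] * (1.0 - self._no_tank)[None, :]
        eta = base[:, None, :] + shift[:, None, :] * self._gh_z[None, :, None]
        ll = self._y[None, None, :] * eta - np.logaddexp(0.0, eta)  # (W, J, n)
        # tank-wise sums then log-sum-exp over nodes
        S = ll @ self._M.T  # (W, J, K)
        from scipy.special import logsumexp

        tank_ll = logsumexp(S + self._gh_logw[None, :, None], axis=1)  # (W, K)
        loglik = np.sum(tank_ll, axis=1)
        # observations outside the tank hierarchy enter directly
        loglik = loglik + np.sum(ll[:, 0, :] * self._no_tank[None, :], axis=1)

        pri = self.priors
        lp = -0.5 * (alpha / pri.alpha_sd) ** 2
        lp = lp - 0.5 * np.sum((k / pri.k_sd) ** 2, axis=1)
        lp = lp - 0.5 * (tau / pri.tau_scale) ** 2 + log_tau  # half-normal + Jacobian
        return loglik + lp

    def fit(self, config: SamplerConfig | None = None) -> "ViabilityResults":
        config = config or SamplerConfig()
        x0 = np.zeros(self._ndim)
        x0[-1] = np.log(self.priors.tau_scale / 2)
        draws = bayes.sample(self._log_prob, self._ndim, self._unpack, config, x0=x0)
        return ViabilityResults(self.treatments, self.tanks, draws,
                                outcome=self.outcome, seed=config.seed)

    @classmethod
    def from_rate_records(
        cls, records: pd.DataFrame, outcome: str = "autotrophy", **kwargs
    ) -> "ViabilityModel":
        return cls(binarize(records), outcome=outcome, **kwargs)


class ViabilityResults:
    """Posterior for one outcome: α, k per treatment, tank SD, derived μ."""

    def __init__(
        self,
        treatments: list[str],
        tanks: list[str],
        draws: PosteriorDraws | None,
        outcome: str = "outcome",
        seed: int = 0,
        raw: dict[str, np.ndarray] | None = None,
    ):
        self.treatments = list(treatments)
        self.tanks = list(tanks)
        self.posterior = draws
        self.outcome = outcome
        self.seed = seed
        if raw is not None:
            self._raw = {k: np.asarray(v, float) for k, v in raw.items()}
        else:
            self._raw = {
                "alpha": draws.flat("alpha"),
                "k": draws.flat("k"),
                "tau_k": draws.flat("tau_k"),
            }

    @classmethod
    def from_draws(
        cls,
        alpha: np.ndarray,
        k: np.ndarray,
        treatments: list[str],
        tau_k: np.ndarray | None = None,
        **kwargs,
    ) -> "ViabilityResults":
        """Build a results object from externally supplied draws (no fit)."""
        k = np.asarray(k, float)
        if tau_k is None:
            tau_k = np.zeros(len(k))
        raw = {"alpha": np.asarray(alpha, float), "k": k,
               "tau_k": np.asarray(tau_k, float)}
        return cls(treatments, [], None, raw=raw, **kwargs)

    # -- draws access -------------------------------------------------------
    @property
    def alpha(self) -> np.ndarray:
        return self._raw["alpha"]

    @property
    def tau_k(self) -> np.ndarray:
        return self._raw["tau_k"]

    def _tr_index(self, treatment: str) -> int:
        try:
            return self.treatments.index(treatment)
        except ValueError:
            raise KeyError(f"unknown treatment {treatment!r}") from None

    def k_draws(self, treatment: str, new_tank: bool = True,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Logistic-rate draws, optionally adding new-tank variability τ_k·z."""
        k = self._raw["k"][:, self._tr_index(treatment)]
        if not new_tank:
            return k
        rng = rng or np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(7, self._tr_index(treatment)))
        )
        return k + self.tau_k * rng.normal(size=len(k))

    def start_probability(self) -> np.ndarray:
        """P(viable) at age 0 per draw: inv_logit(α)."""
        return inv_logit(self.alpha)

    def inflection(self, treatment: str, new_tank: bool = True,
                   eps: float = 1e-12) -> tuple[np.ndarray, int]:
        """Inflection-day draws μ = −α/k; returns (draws, n_excluded).

        Draws with |k| ≤ eps are excluded and counted. μ is positive for a
        declining curve (α > 0, k < 0) and invariant under joint scaling of
        (α, k).
        """
        k = self.k_draws(treatment, new_tank=new_tank)
        keep = np.abs(k) > eps
        mu = -self.alpha[keep] / k[keep]
        return mu, int((~keep).sum())

    def contrast_k(self, a: str, b: str, new_tank: bool = True) -> "Contrast":
        """δk = k_a − k_b (the log odds ratio per day)."""
        rng = np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(8,)))
        ka = self.k_draws(a, new_tank=new_tank, rng=rng)
        kb = self.k_draws(b, new_tank=new_tank, rng=rng)
        return Contrast(a, b, ka - kb)

    def contrast_inflection(self, a: str, b: str, new_tank: bool = True) -> "Contrast":
        mu_a, _ = self.inflection(a, new_tank=new_tank)
        mu_b, _ = self.inflection(b, new_tank=new_tank)
        n = min(len(mu_a), len(mu_b))
        return Contrast(a, b, mu_a[:n] - mu_b[:n])

    def predict(self, ages, treatment: str, new_tank: bool = True) -> pd.DataFrame:
        """Viability probability P(t) per age: mean and 50/80/90% intervals."""
        ages = np.asarray(ages, float)
        if ages.size == 0:
            raise ValueError("empty age grid")
        k = self.k_draws(treatment, new_tank=new_tank)
        eta = self.alpha[:, None] + k[:, None] * ages[None, :]
        p = inv_logit(eta)
        return _interval_frame(ages, p)

    def summary(self) -> pd.DataFrame:
        rows = [{"parameter": "alpha", "mean": float(self.alpha.mean()),
                 "sd": float(self.alpha.std(ddof=1))}]
        for i, tr in enumerate(self.treatments):
            k = self._raw["k"][:, i]
            rows.append({"parameter": f"k[{tr}]", "mean": float(k.mean()),
                         "sd": float(k.std(ddof=1))})
        rows.append({"parameter": "tau_k", "mean": float(self.tau_k.mean()),
                     "sd": float(self.tau_k.std(ddof=1))})
        frame = pd.DataFrame(rows)
        if self.posterior is not None:
            diag = self.posterior.diagnostics
            frame = frame.merge(
                diag.assign(parameter=_relabel(diag["parameter"], self.treatments)),
                on="parameter", how="left",
            )
        return frame

    def plot(self, treatment: str, ages=None, ax=None):
        """Plot the posterior viability curve with 50/80/90% bands."""
        import matplotlib.pyplot as plt

        if ages is None:
            ages = np.linspace(0.0, 120.0, 61)
        pred = self.predict(ages, treatment)
        if ax is None:
            _, ax = plt.subplots()
        for lo, hi, alpha_ in (("q5", "q95", 0.2), ("q10", "q90", 0.3),
                               ("q25", "q75", 0.4)):
            ax.fill_between(pred["age"], pred[lo], pred[hi], alpha=alpha_,
                            color="tab:blue", lw=0)
        ax.plot(pred["age"], pred["mean"], color="tab:blue")
        ax.set_xlabel("detrital age (days)")
        ax.set_ylabel(f"P({self.outcome})")
        ax.set_title(treatment)
        return ax


@dataclass(frozen=True)
class Contrast:
    """Pairwise posterior contrast with direction probabilities."""

    a: str
    b: str
    draws: np.ndarray = field(repr=False)

    @property
    def p_negative(self) -> float:
        return float(np.mean(self.draws < 0))

    @property
    def p_positive(self) -> float:
        return float(np.mean(self.draws > 0))

    @property
    def mean(self) -> float:
        return float(np.mean(self.draws))

    @property
    def sd(self) -> float:
        return float(np.std(self.draws, ddof=1))


def inflection(fit: ViabilityResults, treatment: str, **kwargs):
    """Functional alias for :meth:`ViabilityResults.inflection`."""
    return fit.inflection(treatment, **kwargs)


def _interval_frame(ages: np.ndarray, draws_by_age: np.ndarray) -> pd.DataFrame:
    qs = {"q5": 0.05, "q10": 0.10, "q25": 0.25, "q75": 0.75, "q90": 0.90,
          "q95": 0.95}
    out = {"age": ages, "mean": draws_by_age.mean(axis=0)}
    for name, q in qs.items():
        out[name] = np.quantile(draws_by_age, q, axis=0)
    return pd.DataFrame(out)


def _relabel(params: pd.Series, treatments: list[str]) -> pd.Series:
    mapping = {f"k[{i}]": f"k[{tr}]" for i, tr in enumerate(treatments)}
    return params.map(lambda p: mapping.get(p, p))
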