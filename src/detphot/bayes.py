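"""Shared posterior-sampling machinery.

All hierarchical models in this package sample an unconstrained parameter
vector with an affine-invariant ensemble sampler (emcee). A "chain" in the
configuration is one independent walker ensemble started from its own
jittered mode; rank-normalised split-R-hat and effective sample size are
computed across chains with arviz. Scale parameters are sampled on the log
scale with the Jacobian folded into the log posterior; hierarchical
deviations use the non-centred parameterisation throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
import emcee
import arviz as az
from scipy import optimize

RHAT_LIMIT = 1.01


@dataclass(frozen=True)
class SamplerConfig:
    """Ensemble-sampler settings.

    ``iterations`` counts steps per walker including warm-up; half are
    discarded by default, mirroring the study's sampler budget (eight
    chains of 10⁴ iterations, half warm-up). ``walkers`` defaults to
    max(2·ndim + 2, 32), rounded up to an even number.
    """

    chains: int = 8
    iterations: int = 10_000
    warmup_frac: float = 0.5
    walkers: int | None = None
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for diagnostics")
        if not 0 < self.warmup_frac < 1:
            raise ValueError("warmup_frac must lie in (0, 1)")
        if self.iterations < 20:
            raise ValueError("iterations too small to be meaningful")

    def n_walkers(self, ndim: int) -> int:
        w = self.walkers if self.walkers is not None else max(2 * ndim + 2, 32)
        return w + (w % 2)


class PosteriorDraws:
    """Named posterior draws with sampler diagnostics.

    ``draws[name]`` has shape (chains, draws_per_chain) for scalars or
    (chains, draws_per_chain, k) for vector parameters.
    """

    def __init__(self, draws: dict[str, np.ndarray], diagnostics: pd.DataFrame,
                 config: SamplerConfig):
        self.draws = draws
        self.diagnostics = diagnostics
        self.config = config

    def flat(self, name: str) -> np.ndarray:
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    @property
    def n_draws(self) -> int:
        first = next(iter(self.draws.values()))
        return first.shape[0] * first.shape[1]

    @property
    def max_rhat(self) -> float:
        return float(self.diagnostics["rhat"].max())

    @property
    def min_ess(self) -> float:
        return float(self.diagnostics["ess"].min())

    @property
    def converged(self) -> bool:
        d = self.diagnostics
        return bool(np.isfinite(d["rhat"]).all() and d["rhat"].max() <= RHAT_LIMIT)


def _find_mode(
    log_prob: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    maxiter: int = 2000,
) -> np.ndarray:
    """Posterior mode used to centre walker initialisation."""

    def neg(theta: np.ndarray) -> float:
        val = float(log_prob(theta[None, :])[0])
        return -val if np.isfinite(val) else 1e12

    res = optimize.minimize(neg, x0, method="Nelder-Mead",
                            options={"maxiter": maxiter, "xatol": 1e-6,
                                     "fatol": 1e-8})
    best = res.x
    res2 = optimize.minimize(neg, best, method="Powell",
                             options={"maxiter": maxiter})
    if res2.fun < res.fun:
        best = res2.x
    return np.asarray(best, float)


def _laplace_scatter(log_prob, mode: np.ndarray, init_scale: float) -> np.ndarray:
    """Per-coordinate walker-initialisation SD from a diagonal Laplace
    approximation at the mode, capped by a coarse data-scale default.

    Mildly over-dispersed (2× the Laplace SD) so independent ensembles
    start from genuinely distinct states, but never so wide that walkers
    land unrecoverably far off a narrow posterior ridge.
    """
    ndim = len(mode)
    delta = 1e-3 * (1.0 + np.abs(mode))
    pts = np.vstack([mode, mode + np.diag(delta), mode - np.diag(delta)])
    vals = log_prob(pts)
    f0, fp, fm = vals[0], vals[1 : 1 + ndim], vals[1 + ndim :]
    d2 = (fp - 2 * f0 + fm) / delta**2
    coarse = init_scale * (1.0 + np.abs(mode))
    with np.errstate(divide="ignore", invalid="ignore"):
        lap = 2.0 / np.sqrt(np.maximum(-d2, 1e-300))
    lap = np.where(np.isfinite(lap), lap, coarse)
    return np.minimum(lap, coarse)


def sample(
    log_prob: Callable[[np.ndarray], np.ndarray],
    ndim: int,
    unpack: Callable[[np.ndarray], dict[str, np.ndarray]],
    config: SamplerConfig | None = None,
    x0: np.ndarray | None = None,
    init_scale: float = 0.1,
) -> PosteriorDraws:
    """Run independent walker ensembles and collect named draws.

    Parameters
    ----------
    log_prob
        Vectorised log posterior: takes (n_walkers, ndim), returns
        (n_walkers,). Must be finite except where it returns −inf.
    unpack
        Maps a flat draw matrix (N, ndim) to named arrays.
    x0
        Starting point for the mode search (defaults to zeros).
    """
    config = config or SamplerConfig()
    n_walkers = config.n_walkers(ndim)
    warmup = int(config.iterations * config.warmup_frac)
    keep = config.iterations - warmup
    if keep < 1:
        raise ValueError("no post-warm-up iterations left")

    user_log_prob = log_prob

    def log_prob(theta):  # noqa: F811 - deliberate shadowing
        # a vanishing quadratic pull keeps walkers off flat clipped
        # plateaus (degenerate likelihoods); negligible at data scale
        return user_log_prob(theta) - 1e-8 * np.sum(theta**2, axis=-1)

    if x0 is None:
        x0 = np.zeros(ndim)
    x0 = np.asarray(x0, float)
    mode = _find_mode(log_prob, x0)
    # flat (clipped) tails can let the optimiser wander; walk back to x0
    mode = np.where(np.isfinite(mode), mode, x0)
    bound = 1e3 * (1.0 + np.abs(x0))
    mode = np.clip(mode, x0 - bound, x0 + bound)
    scatter = _laplace_scatter(log_prob, mode, init_scale)

    per_chain: list[np.ndarray] = []
    for c in range(config.chains):
        ss = np.random.SeedSequence(config.seed, spawn_key=(c,))
        rng = np.random.default_rng(ss)
        p0 = mode[None, :] + scatter[None, :] * rng.normal(
            size=(n_walkers, ndim)
        )
        # nudge any invalid starting walkers back toward the mode
        lp = log_prob(p0)
        bad = ~np.isfinite(lp)
        tries = 0
        while bad.any() and tries < 50:
            p0[bad] = mode[None, :] + 0.01 * rng.normal(size=(bad.sum(), ndim))
            lp = log_prob(p0)
            bad = ~np.isfinite(lp)
            tries += 1
        moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
        sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob,
                                        vectorize=True, moves=moves)
        seed_int = int(ss.generate_state(1)[0]) % (2**31)
        sampler.random_state = np.random.RandomState(seed_int).get_state()
        sampler.run_mcmc(p0, config.iterations, skip_initial_state_check=True)
        chain = sampler.get_chain(discard=warmup, thin=config.thin)
        # (steps, walkers, ndim) -> every walker becomes a diagnostic chain
        per_chain.append(chain.transpose(1, 0, 2))

    stacked = np.concatenate(per_chain, axis=0)  # (ensembles·walkers, draws, ndim)
    named: dict[str, np.ndarray] = {}
    flat_all = stacked.reshape(-1, ndim)
    example = unpack(flat_all)
    for name, arr in example.items():
        named[name] = arr.reshape(stacked.shape[0], stacked.shape[1], *arr.shape[1:])

    diagnostics = _diagnostics(named)
    return PosteriorDraws(named, diagnostics, config)


def _diagnostics(named: dict[str, np.ndarray]) -> pd.DataFrame:
    idata = az.from_dict(posterior=named)
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rows = []
    for var in named:
        r = np.atleast_1d(np.asarray(rhat[var]))
        e = np.atleast_1d(np.asarray(ess[var]))
        for i, (rv, ev) in enumerate(zip(r.ravel(), e.ravel())):
            label = var if r.size == 1 else f"{var}[{i}]"
            rows.append({"parameter": label, "rhat": float(rv), "ess": float(ev)})
    return pd.DataFrame(rows)


def summarize(named: dict[str, np.ndarray],
              probs: tuple[float, ...] = (0.05, 0.25, 0.5, 0.75, 0.95)) -> pd.DataFrame:
    """Posterior mean/sd/quantile table for named draw arrays."""
    rows = []
    for name, arr in named.items():
        flat = arr.reshape(-1, *arr.shape[2:])
        flat2 = flat[:, None] if flat.ndim == 1 else flat
        for i in range(flat2.shape[1]):
            col = flat2[:, i]
            label = name if flat2.shape[1] == 1 and flat.ndim == 1 else f"{name}[{i}]"
            row = {"parameter": label, "mean": float(np.mean(col)),
                   "sd": float(np.std(col, ddof=1))}
            for p in probs:
                row[f"q{int(round(100 * p))}"] = float(np.quantile(col, p))
            rows.append(row)
    return pd.DataFrame(rows)
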