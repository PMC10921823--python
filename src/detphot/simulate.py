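"""Synthetic kelp-detritus experiments with known ground truth.

The generator reproduces the structure of the real study: a 4-treatment ×
4-tank × 7-bag litterbag design sampled over 119 days, latent net
photosynthesis and respiration declining linearly with detrital age at
treatment-specific rates with tank-level slope variation, a logistic
disintegration (missingness) hazard rising with age (faster in warm and
dark treatments), and raw closed-chamber O₂ series — 30 readings at 10-s
spacing with additive Gaussian reading noise plus a paired seawater blank.

Default truth parameters sit in the published regime for Ecklonia radiata
detritus (initial P_n ≈ 55, P_g ≈ 84 µmol O₂ g⁻¹ DM h⁻¹; net slopes
−1.1/−0.43/−0.87/−1.2 µmol g⁻¹ h⁻¹ day⁻¹ in darkness, 15, 20, 25 °C).

Randomness uses one global seed expanded into counter-based per-bag
substreams (``SeedSequence(seed, spawn_key=...)``), so enlarging the design
leaves existing draws untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .design import ExperimentDesign, generate_design
from .respirometry import (
    IncubationSeries,
    chamber_volume,
    dry_from_blotted,
)
from .viability import inv_logit


def _default_pn_slopes() -> dict[str, float]:
    return {"dark": -1.1, "15C": -0.43, "20C": -0.87, "25C": -1.2}


def _default_r_slopes() -> dict[str, float]:
    # chosen so that P_g = P_n + R declines at −0.76/−0.34/−1.2/−1.1
    return {"dark": 0.34, "15C": 0.09, "20C": -0.33, "25C": 0.1}


def _default_hazard_offsets() -> dict[str, float]:
    return {"dark": 1.0, "15C": 0.0, "20C": 0.8, "25C": 1.6}


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth parameters of the generative model.

    Rates are µmol O₂ g⁻¹ DM h⁻¹; slopes are per day of detrital age.
    The disintegration hazard is logistic:
    P(disintegrated at age t) = inv_logit(baseline + per_day·t + offset_Tr).
    A baseline of −inf disables disintegration entirely.
    """

    pn_intercept: dict[str, float] | float = 55.0
    pn_slope: dict[str, float] = field(default_factory=_default_pn_slopes)
    r_intercept: dict[str, float] | float = 29.0
    r_slope: dict[str, float] = field(default_factory=_default_r_slopes)
    tank_slope_sd: float = 0.3  # τ, µmol g⁻¹ h⁻¹ day⁻¹
    residual_sd: float = 5.0  # σ for P_n, µmol g⁻¹ h⁻¹
    r_residual_sd: float = 2.5  # residual SD for R
    hazard_baseline: float = -5.0
    hazard_per_day: float = 0.035
    hazard_offsets: dict[str, float] = field(default_factory=_default_hazard_offsets)
    o2_noise_sd: float = 0.2  # optode reading noise, µmol L⁻¹
    blotted_mass_mean: float = 2.4  # g, incubated (trimmed) laterals
    blotted_mass_sd: float = 0.84
    o2_start_mean: float = 250.0  # µmol L⁻¹, oxygenated seawater
    o2_start_sd: float = 8.0
    incubation_temp_c: tuple[float, float] = (18.0, 0.38)  # (mean, sd)
    incubation_pressure_hpa: tuple[float, float] = (1022.0, 4.3)
    incubation_salinity: tuple[float, float] = (35.0, 0.68)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tank_slope_sd", "residual_sd", "r_residual_sd", "o2_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.hazard_per_day < 0 and np.isfinite(self.hazard_baseline):
            raise ValueError("hazard_per_day must be non-negative")

    def _per_treatment(self, value, treatment: str) -> float:
        if isinstance(value, dict):
            return float(value[treatment])
        return float(value)

    def hazard(self, treatment: str | None, age: float) -> float:
        if not np.isfinite(self.hazard_baseline) and self.hazard_baseline < 0:
            return 0.0
        offset = 0.0 if treatment is None else self.hazard_offsets.get(treatment, 0.0)
        return float(inv_logit(self.hazard_baseline + self.hazard_per_day * age + offset))

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("incubation_temp_c", "incubation_pressure_hpa",
                    "incubation_salinity"):
            d[key] = list(d[key])
        if not np.isfinite(d["hazard_baseline"]):
            d["hazard_baseline"] = "-inf"
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TruthParams":
        d = dict(d)
        for key in ("incubation_temp_c", "incubation_pressure_hpa",
                    "incubation_salinity"):
            if key in d:
                d[key] = tuple(d[key])
        if d.get("hazard_baseline") == "-inf":
            d["hazard_baseline"] = -np.inf
        return cls(**d)


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def simulate_trajectories(
    design: ExperimentDesign | None = None,
    truth: TruthParams | None = None,
) -> pd.DataFrame:
    """Draw latent rate trajectories and disintegration for every bag.

    Returns the bag registry augmented with ``latent_pn``, ``latent_r``,
    ``latent_pg`` (evaluated at the bag's sampling age), the tank slope
    deviations used, and the ``disintegrated`` indicator. Spare bags (no
    sampling day) carry no rates; disintegrated bags carry no rates.
    """
    design = design or ExperimentDesign()
    truth = truth or TruthParams()
    registry = generate_design(design)

    tr_index = {tr: i for i, tr in enumerate(design.treatments)}
    tank_dev: dict[str, tuple[float, float]] = {}
    for tr in design.treatments:
        for t in range(design.tanks_per_treatment):
            rng = _stream(truth.seed, 0, tr_index[tr], t)
            dev = rng.normal(0.0, truth.tank_slope_sd, size=2)
            tank_dev[f"{tr}.{t + 1}"] = (float(dev[0]), float(dev[1]))

    alpha_bar = np.mean(
        [truth._per_treatment(truth.pn_intercept, tr) for tr in design.treatments]
    )
    r_alpha_bar = np.mean(
        [truth._per_treatment(truth.r_intercept, tr) for tr in design.treatments]
    )

    out = registry.copy()
    cols = {
        "disintegrated": np.zeros(len(out), dtype=bool),
        "tank_dev_pn": np.full(len(out), np.nan),
        "tank_dev_r": np.full(len(out), np.nan),
        "latent_pn": np.full(len(out), np.nan),
        "latent_r": np.full(len(out), np.nan),
    }
    for i, reg in enumerate(registry.itertuples(index=False)):
        if reg.is_initial:
            rng = _stream(truth.seed, 2, i)
            pn = alpha_bar + rng.normal(0.0, truth.residual_sd)
            r = r_alpha_bar + rng.normal(0.0, truth.r_residual_sd)
            cols["latent_pn"][i] = pn
            cols["latent_r"][i] = r
            continue
        if pd.isna(reg.sampling_day):
            continue
        tr = reg.treatment
        tank_i = int(reg.tank.rsplit(".", 1)[1]) - 1
        bag_i = int(reg.sample_id.rsplit("bag", 1)[1]) - 1
        rng = _stream(truth.seed, 1, tr_index[tr], tank_i, bag_i)
        age = float(reg.sampling_day)
        p_dis = truth.hazard(tr, age)
        disintegrated = bool(rng.uniform() < p_dis)
        cols["disintegrated"][i] = disintegrated
        if disintegrated:
            continue
        dev_pn, dev_r = tank_dev[reg.tank]
        cols["tank_dev_pn"][i] = dev_pn
        cols["tank_dev_r"][i] = dev_r
        alpha = truth._per_treatment(truth.pn_intercept, tr)
        beta = truth._per_treatment(truth.pn_slope, tr)
        cols["latent_pn"][i] = (
            alpha + (beta + dev_pn) * age + rng.normal(0.0, truth.residual_sd)
        )
        r_alpha = truth._per_treatment(truth.r_intercept, tr)
        r_beta = truth._per_treatment(truth.r_slope, tr)
        cols["latent_r"][i] = (
            r_alpha + (r_beta + dev_r) * age + rng.normal(0.0, truth.r_residual_sd)
        )
    for name, arr in cols.items():
        out[name] = arr
    out["latent_pg"] = out["latent_pn"] + out["latent_r"]
    return out


def simulate_incubation(
    rate: float,
    dry_mass_g: float,
    chamber_volume_l: float,
    noise_sd: float = 0.2,
    n_readings: int = 30,
    dt_s: float = 10.0,
    o2_start: float = 250.0,
    rng: np.random.Generator | None = None,
    sample_id: str = "sim",
    phase: str = "light",
    **series_kwargs,
) -> IncubationSeries:
    """Simulate one closed-chamber O₂ series for a mass-specific rate.

    The expected slope in µmol L⁻¹ min⁻¹ is
    rate × dry_mass / (60 × chamber_volume); readings get additive
    Gaussian noise. Rate 0 with noise 0 yields a constant trace.
    """
    if chamber_volume_l <= 0:
        raise ValueError("chamber volume must be positive")
    if dry_mass_g <= 0:
        raise ValueError("dry mass must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = rng or np.random.default_rng()
    times = np.arange(n_readings) * dt_s
    slope_per_min = rate * dry_mass_g / (60.0 * chamber_volume_l)
    o2 = o2_start + slope_per_min * times / 60.0
    if noise_sd > 0:
        o2 = o2 + rng.normal(0.0, noise_sd, size=n_readings)
    o2 = np.clip(o2, 0.0, None)
    masses = {}
    if phase != "blank":
        masses = {"blotted_mass_g": series_kwargs.pop("blotted_mass_g", None),
                  "dry_mass_g": dry_mass_g}
    return IncubationSeries(
        sample_id=sample_id,
        phase=phase,
        times=times,
        o2=o2,
        chamber_volume_l=chamber_volume_l,
        **masses,
        **series_kwargs,
    )


def simulate_experiment(
    design: ExperimentDesign | None = None,
    truth: TruthParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a full synthetic experiment.

    Returns ``(registry, series)``: the augmented bag registry (latent
    truths, masses, incubation covariates, disintegration) and a long-format
    O₂ series table with light, dark and blank runs for every measured
    sample. Byte-identical for identical design, truth and seed.
    """
    design = design or ExperimentDesign()
    truth = truth or TruthParams()
    registry = simulate_trajectories(design, truth)

    n = len(registry)
    blotted = np.full(n, np.nan)
    dry = np.full(n, np.nan)
    vol = np.full(n, np.nan)
    temp = np.full(n, np.nan)
    pres = np.full(n, np.nan)
    sal = np.full(n, np.nan)
    series_frames: list[pd.DataFrame] = []

    for i, reg in enumerate(registry.itertuples(index=False)):
        measured = not reg.disintegrated and pd.notna(reg.sampling_day)
        if not measured:
            continue
        rng = _stream(truth.seed, 3, i)
        b = float(np.clip(rng.normal(truth.blotted_mass_mean, truth.blotted_mass_sd),
                          0.3, None))
        d = dry_from_blotted(b)
        v = chamber_volume(b)
        blotted[i], dry[i], vol[i] = b, d, v
        temp[i] = rng.normal(*truth.incubation_temp_c)
        pres[i] = rng.normal(*truth.incubation_pressure_hpa)
        sal[i] = rng.normal(*truth.incubation_salinity)
        o2_start = rng.normal(truth.o2_start_mean, truth.o2_start_sd)
        env = dict(
            temperature_c=float(temp[i]),
            pressure_hpa=float(pres[i]),
            salinity_permille=float(sal[i]),
        )
        runs = [
            simulate_incubation(
                reg.latent_pn, d, v, truth.o2_noise_sd,
                o2_start=o2_start, rng=rng, sample_id=reg.sample_id,
                phase="light", blotted_mass_g=b, **env,
            ),
            simulate_incubation(
                -reg.latent_r, d, v, truth.o2_noise_sd,
                o2_start=o2_start, rng=rng, sample_id=reg.sample_id,
                phase="dark", blotted_mass_g=b, **env,
            ),
            simulate_incubation(
                0.0, 1.0, chamber_volume(None), truth.o2_noise_sd,
                o2_start=o2_start, rng=rng, sample_id=reg.sample_id,
                phase="blank", **env,
            ),
        ]
        def _f(x):
            return np.nan if x is None else float(x)

        for run in runs:
            frame = pd.DataFrame(
                {
                    "sample_id": run.sample_id,
                    "phase": run.phase,
                    "time_s": run.times,
                    "o2_umol_per_l": run.o2,
                    "temperature_c": _f(run.temperature_c),
                    "pressure_hpa": _f(run.pressure_hpa),
                    "salinity_permille": _f(run.salinity_permille),
                    "chamber_volume_l": _f(run.chamber_volume_l),
                    "blotted_mass_g": _f(run.blotted_mass_g),
                    "dry_mass_g": _f(run.dry_mass_g),
                }
            )
            series_frames.append(frame)

    registry = registry.copy()
    registry["blotted_mass_g"] = blotted
    registry["dry_mass_g"] = dry
    registry["chamber_volume_l"] = vol
    registry["temperature_c"] = temp
    registry["pressure_hpa"] = pres
    registry["salinity_permille"] = sal
    series = (
        pd.concat(series_frames, ignore_index=True)
        if series_frames
        else pd.DataFrame(
            columns=[
                "sample_id", "phase", "time_s", "o2_umol_per_l", "temperature_c",
                "pressure_hpa", "salinity_permille", "chamber_volume_l",
                "blotted_mass_g", "dry_mass_g",
            ]
        )
    )
    return registry, series


def save_generator_config(path, design: ExperimentDesign | None = None,
                          truth: TruthParams | None = None) -> None:
    """Write the generator configuration as YAML (keys mirror the
    ExperimentDesign and TruthParams fields)."""
    import yaml

    design = design or ExperimentDesign()
    truth = truth or TruthParams()
    payload = {
        "design": {
            "treatments": list(design.treatments),
            "tanks_per_treatment": design.tanks_per_treatment,
            "bags_per_tank": design.bags_per_tank,
            "sampling_days": list(design.sampling_days),
            "n_initial": design.n_initial,
        },
        "truth": truth.to_dict(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_generator_config(path) -> tuple[ExperimentDesign, TruthParams]:
    """Read a generator configuration written by
    :func:`save_generator_config`."""
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    d = payload.get("design", {})
    if "treatments" in d:
        d["treatments"] = tuple(d["treatments"])
    if "sampling_days" in d:
        d["sampling_days"] = tuple(d["sampling_days"])
    design = ExperimentDesign(**d)
    truth = TruthParams.from_dict(payload.get("truth", {}))
    return design, truth


def simulate_viability_outcomes(
    design: ExperimentDesign | None = None,
    alpha: float = 3.1,
    k: dict[str, float] | None = None,
    tau_k: float = 0.02,
    outcome: str = "autotrophy",
    seed: int = 0,
) -> pd.DataFrame:
    """Draw binary viability outcomes directly from the logistic truth.

    value ~ Bernoulli(inv_logit(alpha + (k_Tr + τ_k·z_tank)·age)); day-0
    laterals use inv_logit(alpha) alone. Defaults sit at the published
    regime (starting log odds 3.1; k ≈ −0.12 in darkness).
    """
    design = design or ExperimentDesign()
    if k is None:
        k = {"dark": -0.12, "15C": -0.04, "20C": -0.13, "25C": -0.2}
    registry = generate_design(design)
    tr_index = {tr: i for i, tr in enumerate(design.treatments)}
    tank_dev: dict[str, float] = {}
    for tr in design.treatments:
        for t in range(design.tanks_per_treatment):
            rng = _stream(seed, 20, tr_index[tr], t)
            tank_dev[f"{tr}.{t + 1}"] = float(rng.normal(0.0, tau_k))
    rows = []
    for i, reg in enumerate(registry.itertuples(index=False)):
        if not reg.is_initial and pd.isna(reg.sampling_day):
            continue
        age = 0.0 if reg.is_initial else float(reg.sampling_day)
        rate = 0.0 if reg.is_initial else k[reg.treatment] + tank_dev[reg.tank]
        p = inv_logit(alpha + rate * age)
        rng = _stream(seed, 21, i)
        rows.append(
            {
                "sample_id": reg.sample_id,
                "age": age,
                "treatment": reg.treatment,
                "tank": reg.tank,
                "outcome": outcome,
                "value": int(rng.uniform() < p),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Meta-analysis table generators (thermal/light tolerance inputs)


def simulate_performance_table(
    t_opt: float = 18.0,
    sigma_t: float = 6.0,
    p_max: float = 3.0,
    study_sd: float = 2.0,
    n_studies: int = 12,
    obs_per_study: int = 8,
    noise_sd: float = 0.5,
    t_range: tuple[float, float] = (5.0, 32.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic temperature–performance observations (z-scores, multi-study).

    Each study has its own thermal optimum drawn from
    Normal(t_opt, study_sd); performance follows a Gaussian curve in
    temperature with additive noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(10,)))
    rows = []
    for s in range(n_studies):
        topt_s = rng.normal(t_opt, study_sd)
        temps = rng.uniform(*t_range, size=obs_per_study)
        perf = p_max * np.exp(-((temps - topt_s) ** 2) / (2 * sigma_t**2))
        perf = perf + rng.normal(0.0, noise_sd, size=obs_per_study)
        for T, z in zip(temps, perf):
            rows.append(
                {"study_id": f"study{s + 1}", "temperature_c": float(T),
                 "performance": float(z), "measure": "performance"}
            )
    return pd.DataFrame(rows)


def simulate_rate_table(
    t_opt: float = 24.0,
    e_a: float = 0.6,
    e_d: float = 3.0,
    rate_at_ref: float = 50.0,
    n_studies: int = 2,
    obs_per_study: int = 12,
    study_sd: float = 0.8,
    noise_cv: float = 0.08,
    t_range: tuple[float, float] = (8.0, 32.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic temperature–rate pairs following a peaked Arrhenius curve."""
    from .thermal import peaked_arrhenius_curve

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(11,)))
    rows = []
    for s in range(n_studies):
        topt_s = rng.normal(t_opt, study_sd)
        temps = np.linspace(*t_range, obs_per_study) + rng.uniform(
            -0.5, 0.5, obs_per_study
        )
        mu = peaked_arrhenius_curve(temps, rate_at_ref, e_a, e_d, topt_s)
        rate = mu * (1.0 + rng.normal(0.0, noise_cv, size=obs_per_study))
        for T, r in zip(temps, rate):
            rows.append(
                {"study_id": f"study{s + 1}", "temperature_c": float(T),
                 "rate": float(max(r, 1e-6))}
            )
    return pd.DataFrame(rows)


def simulate_threshold_table(
    mean: float = 13.0,
    shape: float = 4.0,
    n_obs: int = 60,
    threshold: str = "E_c",
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic compensation/saturation irradiance observations.

    Gamma-distributed with the given shape and mean (the default mean of 13
    µmol photons m⁻² s⁻¹ with shape 4 puts ≈77% of the mass above
    8 µmol photons m⁻² s⁻¹).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(12,)))
    scale = mean / shape
    obs = rng.gamma(shape, scale, size=n_obs)
    return pd.DataFrame(
        {"irradiance": obs, "threshold": threshold,
         "study_id": [f"study{i % 6 + 1}" for i in range(n_obs)]}
    )
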