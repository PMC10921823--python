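"""Reproducible end-to-end runs: config, validation, orchestration, report.

A run executes the enabled stages in order — simulate → rates (slope
estimation + unit conversion) → fit_rates → fit_viability → fit_meta —
inside an output directory, writing CSV artefacts plus ``manifest.json``
(config, config hash, seed, package versions, per-stage wall time and
sampler diagnostics). Re-running the same config and seed reproduces every
summary byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bayes import SamplerConfig
from .design import ExperimentDesign
from .simulate import (
    TruthParams,
    simulate_experiment,
    simulate_performance_table,
    simulate_rate_table,
    simulate_threshold_table,
)
from .respirometry import process_experiment, DRY_TO_BLOTTED
from .rate_model import RateDeclineModel
from .viability import ViabilityModel, binarize
from .thermal import GaussianTPC, PeakedArrhenius, GammaThreshold

ALL_STAGES = ("simulate", "rates", "fit_rates", "fit_viability", "fit_meta")

SERIES_COLUMNS = ("sample_id", "phase", "time_s", "o2_umol_per_l")
REGISTRY_COLUMNS = ("sample_id", "treatment", "tank", "sampling_day", "is_initial")


@dataclass
class RunConfig:
    """Flat, documented configuration for one pipeline run."""

    output_dir: str = "detphot_run"
    stages: tuple[str, ...] = ALL_STAGES
    # inputs (ignored when the simulate stage is enabled)
    registry_path: str | None = None
    series_path: str | None = None
    performance_table: str | None = None
    rate_table: str | None = None
    threshold_table: str | None = None
    # sampler (defaults mirror the study: 8 chains × 10⁴ iterations)
    chains: int = 8
    iterations: int = 10_000
    warmup_frac: float = 0.5
    seed: int = 0
    # respirometry constants
    target_n: int = 30
    displacement: str = "density"
    dry_ratio: float = DRY_TO_BLOTTED
    light_hours: float = 12.0
    # model selections
    rate_response: str = "net"
    viability_outcome: str = "autotrophy"

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("chains must be >= 2")
        if self.warmup_frac > 0.5 + 1e-9:
            raise ValueError("iterations must be at least twice the warm-up")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def sampler(self) -> SamplerConfig:
        return SamplerConfig(chains=self.chains, iterations=self.iterations,
                             warmup_frac=self.warmup_frac, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def validate_inputs(registry_path: str | Path | None = None,
                    series_path: str | Path | None = None) -> pd.DataFrame:
    """Schema-check input CSVs; returns a row-level validation report.

    The report has columns ``file, level, row, message`` with levels
    ``error`` (fatal) and ``warning``. An unreadable file is fatal.
    """
    rows: list[dict] = []

    def add(file, level, message, row=None):
        rows.append({"file": str(file), "level": level, "row": row,
                     "message": message})

    if registry_path is not None:
        try:
            reg = pd.read_csv(registry_path)
        except Exception as exc:  # noqa: BLE001 - reported, not raised
            add(registry_path, "error", f"unreadable file: {exc}")
            reg = None
        if reg is not None:
            for col in REGISTRY_COLUMNS:
                if col not in reg.columns:
                    add(registry_path, "error", f"missing column {col!r}")
            if "dry_mass_g" in reg.columns:
                bad = reg.index[reg["dry_mass_g"] <= 0].tolist()
                for i in bad:
                    add(registry_path, "error",
                        "non-positive value in column 'dry_mass_g'", row=i)

    if series_path is not None:
        try:
            ser = pd.read_csv(series_path)
        except Exception as exc:  # noqa: BLE001
            add(series_path, "error", f"unreadable file: {exc}")
            ser = None
        if ser is not None:
            missing = [c for c in SERIES_COLUMNS if c not in ser.columns]
            for col in missing:
                add(series_path, "error", f"missing column {col!r}")
            if not missing:
                for (sid, phase), grp in ser.groupby(["sample_id", "phase"]):
                    t = grp["time_s"].to_numpy(float)
                    dup = np.where(np.diff(np.sort(t)) == 0)[0]
                    if dup.size:
                        add(series_path, "error",
                            f"duplicated timestamp in series {sid}/{phase}",
                            row=int(grp.index[dup[0] + 1]))
                    elif np.any(np.diff(t) <= 0):
                        add(series_path, "warning",
                            f"series {sid}/{phase} not time-sorted",
                            row=int(grp.index[0]))
                if (ser["o2_umol_per_l"] < 0).any():
                    i = int(ser.index[ser["o2_umol_per_l"] < 0][0])
                    add(series_path, "error",
                        "negative value in column 'o2_umol_per_l'", row=i)
                for col in ("dry_mass_g", "blotted_mass_g", "chamber_volume_l"):
                    if col in ser.columns:
                        bad = ser[col].notna() & (ser[col] <= 0)
                        if bad.any():
                            add(series_path, "error",
                                f"non-positive value in column {col!r}",
                                row=int(ser.index[bad][0]))
    return pd.DataFrame(rows, columns=["file", "level", "row", "message"])


def run_pipeline(config: RunConfig,
                 design: ExperimentDesign | None = None,
                 truth: TruthParams | None = None) -> dict:
    """Execute enabled stages in order; returns (and writes) the manifest.

    A stage failure raises with the failing stage named; artefacts written
    before the failure are retained in the output directory.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "versions": {"detphot": _version(), "numpy": np.__version__,
                     "pandas": pd.__version__},
        "stages": {},
    }
    state: dict = {}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        try:
            info = _STAGE_FUNCS[stage](config, out, state, design, truth)
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            _write_manifest(out, manifest)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        info["status"] = "ok"
        info["wall_s"] = round(time.perf_counter() - t0, 3)
        manifest["stages"][stage] = info
    _write_manifest(out, manifest)
    return manifest


def _version() -> str:
    from importlib.metadata import version

    try:
        return version("detphot")
    except Exception:  # noqa: BLE001 - uninstalled source tree
        return "unknown"


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))


def _stage_simulate(config, out, state, design, truth):
    design = design or ExperimentDesign()
    truth = truth or TruthParams(seed=config.seed)
    registry, series = simulate_experiment(design, truth)
    registry.to_csv(out / "registry.csv", index=False)
    series.to_csv(out / "series.csv", index=False)
    state["registry"], state["series"] = registry, series
    return {"n_bags": int(len(registry)), "n_series_rows": int(len(series))}


def _load_inputs(config, state):
    if "registry" not in state:
        if config.registry_path is None or config.series_path is None:
            raise ValueError("no inputs: enable the simulate stage or set "
                             "registry_path and series_path")
        report = validate_inputs(config.registry_path, config.series_path)
        errors = report[report["level"] == "error"]
        if len(errors):
            raise ValueError(f"input validation failed: "
                             f"{errors['message'].iloc[0]}")
        state["registry"] = pd.read_csv(config.registry_path)
        state["series"] = pd.read_csv(config.series_path)
    return state["registry"], state["series"]


def _stage_rates(config, out, state, design, truth):
    registry, series = _load_inputs(config, state)
    records = process_experiment(
        registry, series, target_n=config.target_n,
        light_hours=config.light_hours, displacement=config.displacement,
        dry_ratio=config.dry_ratio,
    )
    records.to_csv(out / "rate_records.csv", index=False)
    state["records"] = records
    return {"n_records": int(len(records)),
            "n_disintegrated": int(records["disintegrated"].sum())}


def _require_records(config, state):
    if "records" not in state:
        path = Path(config.output_dir) / "rate_records.csv"
        if not path.exists():
            raise ValueError("rates stage has not run and no rate_records.csv "
                             "found")
        state["records"] = pd.read_csv(path)
    return state["records"]


def _stage_fit_rates(config, out, state, design, truth):
    records = _require_records(config, state)
    model = RateDeclineModel(records, response=config.rate_response)
    res = model.fit(config.sampler())
    res.summary().to_csv(out / "rate_fit_summary.csv", index=False)
    _draws_to_csv(res.posterior.draws, out / "rate_fit_draws.csv")
    contrasts = []
    for i, a in enumerate(res.treatments):
        for b in res.treatments[i + 1:]:
            c = res.contrast_slopes(a, b)
            contrasts.append({"a": a, "b": b, "mean": c.mean, "sd": c.sd,
                              "p_negative": c.p_negative,
                              "p_positive": c.p_positive})
    pd.DataFrame(contrasts).to_csv(out / "rate_contrasts.csv", index=False)
    state["rate_fit"] = res
    return {"response": config.rate_response,
            "max_rhat": res.posterior.max_rhat,
            "min_ess": res.posterior.min_ess,
            "converged": res.converged}


def _stage_fit_viability(config, out, state, design, truth):
    records = _require_records(config, state)
    outcomes = binarize(records)
    outcomes.to_csv(out / "viability_outcomes.csv", index=False)
    model = ViabilityModel(outcomes, outcome=config.viability_outcome)
    res = model.fit(config.sampler())
    res.summary().to_csv(out / "viability_fit_summary.csv", index=False)
    _draws_to_csv(res.posterior.draws, out / "viability_fit_draws.csv")
    mus = []
    for tr in res.treatments:
        mu, n_excluded = res.inflection(tr)
        mus.append({"treatment": tr, "mu_mean": float(np.mean(mu)),
                    "mu_sd": float(np.std(mu, ddof=1)),
                    "n_excluded": n_excluded})
    pd.DataFrame(mus).to_csv(out / "viability_inflection.csv", index=False)
    state["viability_fit"] = res
    return {"outcome": config.viability_outcome,
            "max_rhat": res.posterior.max_rhat,
            "min_ess": res.posterior.min_ess,
            "converged": res.posterior.converged}


def _stage_fit_meta(config, out, state, design, truth):
    perf = (pd.read_csv(config.performance_table)
            if config.performance_table
            else simulate_performance_table(seed=config.seed))
    rate = (pd.read_csv(config.rate_table)
            if config.rate_table
            else simulate_rate_table(seed=config.seed))
    thr = (pd.read_csv(config.threshold_table)
           if config.threshold_table
           else simulate_threshold_table(seed=config.seed))
    sampler = config.sampler()
    info = {}
    g = GaussianTPC(perf).fit(sampler)
    g.summary().to_csv(out / "tpc_gaussian_summary.csv", index=False)
    info["gaussian_topt"] = float(g.t_opt_draws().mean())
    a = PeakedArrhenius(rate).fit(sampler)
    a.summary().to_csv(out / "tpc_arrhenius_summary.csv", index=False)
    info["arrhenius_topt"] = float(a.t_opt_draws().mean())
    t = GammaThreshold(thr).fit(sampler)
    t.summary().to_csv(out / "light_threshold_summary.csv", index=False)
    info["threshold_mean"] = float(t.mean_draws().mean())
    info["max_rhat"] = max(g.posterior.max_rhat, a.posterior.max_rhat,
                           t.posterior.max_rhat)
    state["meta_fits"] = {"gaussian": g, "arrhenius": a, "threshold": t}
    return info


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "rates": _stage_rates,
    "fit_rates": _stage_fit_rates,
    "fit_viability": _stage_fit_viability,
    "fit_meta": _stage_fit_meta,
}


def _draws_to_csv(draws: dict[str, np.ndarray], path: Path) -> None:
    cols = {}
    for name, arr in draws.items():
        flat = arr.reshape(-1, *arr.shape[2:])
        if flat.ndim == 1:
            cols[name] = flat
        else:
            for i in range(flat.shape[1]):
                cols[f"{name}[{i}]"] = flat[:, i]
    pd.DataFrame(cols).to_csv(path, index=False)


def report(run_dir: str | Path) -> str:
    """Plain-text summary of a completed run directory."""
    out = Path(run_dir)
    lines = [f"detphot run report: {out}"]
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        lines.append(f"config hash {manifest['config_hash']}, "
                     f"seed {manifest['seed']}")
        for stage, info in manifest["stages"].items():
            status = info.get("status", "?")
            extra = ", ".join(f"{k}={v}" for k, v in info.items()
                              if k not in ("status",))
            lines.append(f"  [{status}] {stage}: {extra}")
    for name, title in [
        ("rate_fit_summary.csv", "Rate-decline posterior"),
        ("rate_contrasts.csv", "Slope contrasts (P(δβ<0))"),
        ("viability_inflection.csv", "Viability inflection days (μ)"),
        ("tpc_gaussian_summary.csv", "Gaussian TPC"),
        ("tpc_arrhenius_summary.csv", "Peaked Arrhenius TPC"),
        ("light_threshold_summary.csv", "Light threshold (gamma)"),
    ]:
        path = out / name
        if path.exists():
            lines.append(f"\n== {title} ==")
            lines.append(pd.read_csv(path).round(4).to_string(index=False))
    return "\n".join(lines)
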