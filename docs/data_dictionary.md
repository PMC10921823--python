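# Data dictionary

All artefacts are plain CSV. Units are fixed by column name.

## Sample registry (`registry.csv`)

One row per bag or day-0 lateral.

| column | type | description |
|---|---|---|
| `sample_id` | str | unique sample key; bags are `<treatment>.<tank>.bag<k>`, initials `initial.<k>` |
| `treatment` | str/empty | treatment label (`dark`, `15C`, `20C`, `25C` by default); empty for day-0 laterals |
| `tank` | str/empty | tank key `<treatment>.<index>`; empty for day-0 laterals |
| `sampling_day` | int/empty | detrital age (days) at destructive sampling; empty for spare bags |
| `is_initial` | bool | day-0 lateral measured before tank allocation |
| `disintegrated` | bool | sample decomposed past measurability (no rates) |
| `blotted_mass_g` | float | blotted (fresh) mass of the incubated lateral, g |
| `dry_mass_g` | float | dry mass, g |
| `chamber_volume_l` | float | water volume of the incubation jar, L |
| `temperature_c`, `pressure_hpa`, `salinity_permille` | float | incubation conditions |
| `latent_pn`, `latent_r`, `latent_pg` | float | synthetic only: latent true rates, µmol O₂ g⁻¹ DM h⁻¹ |
| `tank_dev_pn`, `tank_dev_r` | float | synthetic only: tank slope deviations |

## O₂ series (`series.csv`, long format)

One row per optode reading; three phases per measured sample.

| column | type | description |
|---|---|---|
| `sample_id` | str | joins to the registry; blanks share the sample's id |
| `phase` | str | `light`, `dark` or `blank` |
| `time_s` | float | seconds from the start of the run, strictly increasing |
| `o2_umol_per_l` | float | dissolved O₂, µmol L⁻¹ (meter-compensated) |
| `temperature_c`, `pressure_hpa`, `salinity_permille` | float | incubation conditions |
| `chamber_volume_l` | float | water volume, L |
| `blotted_mass_g`, `dry_mass_g` | float | sample masses; empty for blanks |

## Rate records (`rate_records.csv`)

One row per measured or disintegrated sample (stage-1 output).

| column | description |
|---|---|
| `sample_id`, `age`, `treatment`, `tank`, `disintegrated` | keys/flags as above (`age` in days) |
| `pn_mean`, `pn_sd` | net photosynthesis ± SD, µmol O₂ g⁻¹ DM h⁻¹ |
| `r_mean`, `r_sd` | respiration (positive = consumption) ± SD |
| `pg_mean`, `pg_sd` | gross photosynthesis ± SD |
| `daily_mean`, `daily_sd` | daily net rate ± SD, µmol O₂ g⁻¹ DM day⁻¹ |
| `o2_initial` | first O₂ reading of the light run (confounder), µmol L⁻¹ |
| `temperature_c`, `pressure_hpa`, `salinity_permille`, `dry_mass_g` | covariates |

## Meta-analysis tables

- Performance (`fit-tpc --family gaussian`): `study_id`, `temperature_c`,
  `performance` (z-score), optional `measure`.
- Temperature–rate (`fit-tpc --family arrhenius`): `temperature_c`, `rate`
  (positive), optional `study_id`.
- Irradiance thresholds (`fit-light`): `irradiance`
  (µmol photons m⁻² s⁻¹, positive), optional `threshold`, `study_id`.

## Fit outputs

- `*_fit_summary.csv`: one row per parameter — posterior `mean`, `sd`,
  slope direction probabilities where applicable, and sampler diagnostics
  (`rhat`, `ess`).
- `*_fit_draws.csv`: flattened posterior draws, one column per scalar
  parameter (vector parameters indexed `name[i]`).
- `rate_contrasts.csv`: pairwise treatment slope contrasts with
  `p_negative`/`p_positive` (direction probabilities of δβ).
- `viability_inflection.csv`: per-treatment inflection day μ (mean, SD,
  number of k ≈ 0 draws excluded).
- `manifest.json`: config (+hash), seed, package versions, per-stage status,
  wall time and diagnostics.
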