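# detphot

Bayesian analysis of **detrital kelp photosynthesis**: how fast the
photosynthetic machinery of excised kelp laterals (the detrital phase of
*Ecklonia radiata*) decays with detrital age under different temperature and
light regimes, estimated from closed-chamber O₂ incubations.

The package is written for experimental marine ecologists and
biogeochemists running litterbag-style decomposition experiments: it takes
raw O₂ optode time series plus a sample registry and produces posterior
estimates of photosynthetic decline, viability lifetimes and thermal/light
tolerance envelopes — and it ships a synthetic-data generator that emulates
the full experiment with known ground truth, so every stage of the pipeline
is testable without any field data.

## The models

**Stage 1 — respirometry.** Each incubation gives ~30 dissolved-O₂ readings
at 10-s spacing. A conjugate Bayesian linear regression of O₂ (µmol L⁻¹) on
centred time (min) yields a slope posterior; series longer than the target
length are truncated from the start or end (choosing the side with lower
residual error), blank-corrected against a paired seawater run, and
converted to mass-specific rates:

    rate [µmol O₂ g⁻¹ DM h⁻¹] = slope × V × 60 / m_dry

Net photosynthesis *P*ₙ comes from the light run, respiration *R* from the
negated dark slope, *P*_g = *P*ₙ + *R*, and the daily net rate is
12·*P*ₙ − 12·*R* for a 12 h/12 h photoperiod.

**Stage 2 — rate decline.** A hierarchical errors-in-variables regression:

    y_i ~ Normal(α_Tr + (β_Tr + β_Ta[tank])·age_i + Σ γ·x_i, √(σ² + s_i²)),
    β_Ta ~ Normal(0, τ)

where *s*ᵢ is the known stage-1 slope SD. Treatment slopes β_Tr are
reported for a *new* tank (adding τ·z), pairwise slope contrasts carry
direction probabilities P(δβ < 0), and `predict_new_tank` gives calibrated
50/80/90% predictive bands.

**Stage 3 — viability.** Rates are binarized (autotrophy: *P*ₙ > 0;
photosynthesis: *P*_g > 0; daily autotrophy: daily > 0; disintegrated
samples count 0 everywhere, so non-random missingness informs the fit) and
modelled as Bernoulli with a logit link, `α + (k_Tr + k_Ta)·age`. The
derived inflection day μ = −α/k is when viability probability crosses 0.5.

**Stage 4 — tolerance curves.** A Gaussian temperature–performance curve
and a peaked Arrhenius (high-temperature-inactivation) temperature–rate
curve, both with study-level thermal optima (so "new study" predictions are
wider than given-data ones), and gamma models of the compensation (E_c) and
saturation (E_k) irradiance whose survival function answers "what is the
probability that a given irradiance is subcompensating?".

All posteriors are sampled with an ensemble MCMC (emcee) behind a common
interface with rank-normalised R-hat and ESS diagnostics; tank-level
deviations are marginalised analytically (Gaussian case) or by
Gauss–Hermite quadrature (Bernoulli case) for fast, well-mixed sampling.

## Worked example

```python
import detphot as dp

# a complete synthetic experiment in the published regime
truth = dp.TruthParams(seed=1)                    # slopes −1.1/−0.43/−0.87/−1.2
registry, series = dp.simulate_experiment(truth=truth)
records = dp.process_experiment(registry, series)  # stage 1

fit = dp.RateDeclineModel(records, response="net").fit(
    dp.SamplerConfig(chains=2, iterations=12_000, thin=4, seed=3)
)
print(fit.summary()[["parameter", "mean", "sd", "p_negative"]]
      .head(8).round(3).to_string())
c = fit.contrast_slopes("15C", "dark")
print(f"P(slower decline in light at 15C than darkness) = {c.p_positive:.2f}")
```

prints (abbreviated):

```
     parameter    mean     sd  p_negative
0   alpha[15C]  56.056  1.742         NaN
1    beta[15C]  -0.389  0.134       0.923
2   alpha[20C]  54.740  1.713         NaN
3    beta[20C]  -0.618  0.127       0.983
4   alpha[25C]  55.990  1.687         NaN
5    beta[25C]  -1.152  0.130       1.000
6  alpha[dark]  57.254  1.736         NaN
7   beta[dark]  -1.187  0.134       1.000
P(slower decline in light at 15C than darkness) = 0.97
```

i.e. the model recovers the generating slopes (−0.43, −0.87, −1.2, −1.1
µmol O₂ g⁻¹ DM h⁻¹ day⁻¹) from raw synthetic O₂ traces, with near-certain
evidence that net photosynthesis declines in every treatment
(`p_negative`), and that the subcompensating-light treatment at 15 °C
declines more slowly than darkness.

The same workflow is available from the shell:

```bash
detphot simulate --out run --seed 1
detphot rates --registry run/registry.csv --series run/series.csv --out records.csv
detphot fit-rates --records records.csv --response net
detphot fit-viability --records records.csv --outcome autotrophy
detphot run --out full_run          # all stages + manifest + report
detphot report full_run
```

Input/output CSV schemas are documented in `docs/data_dictionary.md`.

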