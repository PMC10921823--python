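# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limitations of detphot.

## Stage 1: O₂ slope estimation and rate conversion

Each closed-chamber incubation is modelled as a straight line of dissolved
O₂ (µmol L⁻¹) on centred incubation time in minutes. The fit is a conjugate
normal-inverse-gamma Bayesian regression with weak priors (coefficients ~
Normal(0, σ²·10⁸); σ² ~ InvGamma(10⁻³, 10⁻³)), giving the slope's marginal
posterior (a scaled Student-t) in closed form. The posterior mean agrees
with OLS to far better than 1% on any well-conditioned series, and the
closed form matters: a pipeline run fits hundreds of series, and a
deterministic exact posterior removes both Monte-Carlo noise and sampler
cost where neither buys anything. Fewer than 3 readings or zero time
variance are rejected.

**Truncation.** Series longer than the target length (default 30) are
trimmed from the start or the end. Both candidates are scored on residual
standard error and on |slope − untruncated slope|. The lower residual SE
wins; slope similarity breaks near-ties; exact ties drop the start. The
residual-SE criterion is primary by design: a transient artefact (probe
equilibration, stirring disturbance) inflates the residuals of whichever
trim retains it, whereas the untruncated slope is itself contaminated, so
similarity to it would systematically retain the artefact. This ordering is
a deliberate design choice where the source procedures were ambiguous.

**Constants.** Chamber volume defaults to the 175-mL jar minus sample
displacement at 1.0 g mL⁻¹ of blotted mass (a 2.4-g lateral leaves
0.1726 L); displacement can be switched off. Dry mass, when not recorded,
is 0.1458 × blotted mass (the ratio of the mean dry and blotted masses of
incubated laterals, 0.35 g / 2.4 g); configurable. Respiration is stored as
the negated dark slope, so R > 0 means O₂ consumption, and
P_g = P_n + R may be negative under measurement error (deliberately not
clipped — the viability stage binarizes negatives to 0). The daily net rate
is light_h·P_n − dark_h·R with a 12 h/12 h default, equivalent to
24·P_n − 12·P_g. Optode temperature/pressure/salinity compensation is
assumed already applied by the meter; the covariates are recorded but not
re-applied.

**Blank correction** subtracts the paired seawater-blank slope per
measurement round and adds variances. Pairing is per sample (each sample's
series table carries a blank run under the same id).

## Stage 2: hierarchical errors-in-variables rate model

For the observed rate y_i with known stage-1 SD s_i:

    y_i ~ Normal(m_i, sqrt(σ² + s_i²))
    m_i = α_Tr(i) + (β_Tr(i) + β_Ta(i))·age_i + Σ_c γ_c x_ic
    β_Ta ~ Normal(0, τ)

The measurement layer is exact marginalisation of the latent true rate.
Covariates are centred and scaled by their SD; only initial incubation O₂
is included by default (the only covariate with a consistent effect in this
kind of data); temperature, pressure, salinity and dry mass can be added.
Disintegrated samples are excluded — their information is deliberately
routed to the viability model. Day-0 laterals precede treatment allocation;
they enter through the average of the treatment intercepts (all treatments
share the same starting material). An optional Gaussian age-error term
(off by default, since no error estimate exists for detrital age) is
marginalised exactly through the linear mean, inflating the variance by
(slope·s_age)².

**Priors** are data-scaled and weakly informative: α ~ Normal(ȳ, 2.5·sd(y)),
β ~ Normal(0, 2.5·sd(y)/sd(age)), τ ~ half-Normal(sd(y)/sd(age)),
σ ~ half-Normal(2·sd(y)), γ ~ Normal(0, 2.5·sd(y)). This is the analogue of
standardising all variables and assigning unit-scale priors, but keeps the
parameters in their scientific units (µmol O₂ g⁻¹ DM h⁻¹ and per-day).

**Reported quantities.** Treatment slopes are summarised as *new-tank*
draws β_Tr + τ·z (z ~ N(0,1) per draw) — the tank-generalising quantity a
replicate experiment would see — and likewise the pairwise contrasts
δβ = (β_a + τz₁) − (β_b + τz₂) with direction probabilities P(δβ<0).
`predict_new_tank` returns the mean and central 50/80/90% intervals of
α + (β + τz)·age. Posterior-mean per-tank slopes (partial pooling in
action) are available from the closed-form conditional of the marginalised
tank deviation.

## Stage 3: binomial viability model

Three outcomes per sample — autotrophy (P_n > 0), photosynthesis (P_g > 0,
with error-induced negatives scored 0) and daily autotrophy (daily net
> 0) — all scored 0 for disintegrated samples, so that non-randomly missing
(fully decomposed) samples inform the decay instead of biasing it toward
zero. One outcome is fitted at a time:

    value ~ Bernoulli(inv_logit(α + (k_Tr + k_Ta)·age)),  k_Ta ~ N(0, τ_k)

α is pooled across treatments (one starting state); age is in raw days so k
is literally log odds per day, and differences of k are log odds ratios per
day. Priors: α, k ~ Normal(0, 1.5); τ_k ~ half-Normal(0.1) (a tank's decay
rate plausibly deviates by a few hundredths of a log-odds unit per day;
the scale is configurable). Complete separation is handled by these proper
priors — the fit stays finite and the posterior reflects the prior's reach.

The inflection day is μ = −α/k per draw, the age at which P(t) = 0.5
(positive for a declining curve, invariant under joint rescaling of α and
k); draws with k = 0 are excluded and counted. Contrasts of μ and of k use
new-tank draws analogously to stage 2.

## Stage 4: tolerance meta-analysis curves

**Gaussian TPC.** performance ~ Normal(P_max·exp(−(T−T_opt,s)²/(2σ_T²)), σ)
with study-level optima T_opt,s ~ Normal(T_opt, τ_study). Putting the
hierarchy on T_opt (not on an additive performance offset) is what makes a
"new study" prediction meaningful for the optimum itself: the given-data
posterior of T_opt is narrow, while a new study's predicted optimum adds
τ_study and is appropriately wide. Requires ≥ 5 observations over ≥ 3
temperatures and ≥ 2 studies.

**Peaked Arrhenius.** A Sharpe–Schoolfield-type rise-and-fall curve with
high-temperature inactivation:

    r(T) = r_ref·exp(E_a/k_B·(1/T_ref − 1/T)) /
           (1 + E_a/(E_d−E_a)·exp(E_d/k_B·(1/T_opt − 1/T)))

with E_d > E_a enforced by construction (E_d = E_a + ΔE, ΔE > 0), T in
kelvin internally, T_ref = 20 °C, and T_opt a native parameter (the curve's
maximum is exactly at T_opt; E_d → ∞ recovers the monotone Arrhenius law).
Energies carry lognormal priors centred at 0.6 eV (E_a) and 2 eV (ΔE).
The exact inactivation variant used by the sources this kind of
meta-analysis draws on is not uniquely determined; this parameterisation is
the package's documented choice, and any alternative can be fitted behind
the same interface. Monotone data leave the peak unidentified: the fit
flags posteriors whose T_opt mass escapes the data hull.

**Gamma thresholds.** Compensation/saturation irradiances are positive, so
E_c and E_k observations get a gamma likelihood parameterised by (shape,
mean) — which makes the fitted mean scale-equivariant — with an optional
lognormal study effect on the mean. `prob_below(E)` is the posterior
expectation of the gamma survival function at E: the probability that a
candidate irradiance is below the threshold (subcompensating). At the
defaults of the synthetic generator (shape 4, mean 13 µmol photons
m⁻² s⁻¹), an 8 µmol photons m⁻² s⁻¹ light treatment has ≈ 77% probability
of being subcompensating.

## Posterior sampling

All models are sampled with emcee's affine-invariant ensemble sampler using
differential-evolution moves (80% DE, 20% snooker) — a gradient-free,
pure-Python backend with no model-compilation step, well suited to the
low-dimensional marginalised posteriors below. Design choices that keep
this sampler honest on hierarchical posteriors:

- **Dimension reduction by marginalisation.** Tank deviations are
  integrated out analytically in the Gaussian rate model (Sherman–Morrison
  rank-1 update per tank; their conditional posteriors are recovered in
  closed form afterwards) and by 15-node Gauss–Hermite quadrature in the
  Bernoulli viability model. This removes 16 latent dimensions from each
  model and with them the funnel geometry that ensemble samplers handle
  poorly.
- **Unconstrained parameterisation.** Scale parameters are sampled on the
  log scale with the Jacobian in the posterior; half-Normal priors act on
  the natural scale. Treatment intercepts are sampled as the level at the
  mean age (α + β·age̅), decorrelating intercepts and slopes.
- **Chains and diagnostics.** A "chain" is an independent walker ensemble
  started from its own jittered mode (mode via Nelder-Mead/Powell; jitter
  = 2× a diagonal-Laplace SD, capped by a coarse data scale — wide enough
  to be over-dispersed, never so wide that walkers strand on flat clipped
  tails). Every walker is treated as a diagnostic chain; rank-normalised
  split-R-hat and ESS come from arviz, and fits warn when R-hat > 1.01.
  The default budget mirrors the study (8 chains × 10⁴ iterations, half
  warm-up); reduced budgets used in tests are stated where they appear.
- A vanishing quadratic pull (10⁻⁸·‖θ‖²) keeps walkers off perfectly flat
  plateaus that arise for degenerate inputs (e.g. zero-variance data).

## Synthetic-data generator

The generator emulates the study conditions end to end: the 4-treatment
(darkness at 15 °C; subcompensating light at 15, 20, 25 °C) × 4-tank ×
7-bag design sampled at days 6, 13, 27, 37, 82 and 119 (the seventh bag is
a spare) plus five day-0 laterals measured before tank allocation (outside
the tank hierarchy); latent P_n and R declining linearly in age with
treatment slopes defaulting to the published posterior means (net:
−1.1/−0.43/−0.87/−1.2; gross: −0.76/−0.34/−1.2/−1.1, via the respiration
slopes) around an initial P_n of 55 and R of 29 µmol O₂ g⁻¹ DM h⁻¹;
tank-level slope SD τ = 0.3 and residual SDs of 5 (P_n) and 2.5 (R) —
chosen so that realised rate spread matches the published measurement
regime; and raw O₂ series of 30 readings at 10-s spacing with 0.2 µmol L⁻¹
reading noise plus paired zero-slope blanks, using blotted masses
~ Normal(2.4, 0.84) g and incubation covariates at their reported means.

Disintegration is a logistic hazard in age with additive treatment offsets
(larger for warm and dark treatments): baseline −5, +0.035 per day, offsets
+1.0 (dark), 0 (15 °C), +0.8 (20 °C), +1.6 (25 °C). No disintegration-time
law is documented for the real experiment; these coefficients produce the
qualitative pattern the generator needs (missingness rising with age,
fastest in the 25 °C treatment) and are freely overridable. A baseline of
−inf disables the process.

One global seed expands into counter-based per-bag substreams
(`SeedSequence(seed, spawn_key=…)` keyed by treatment/tank/bag indices), so
outputs are byte-reproducible and enlarging the design does not perturb
existing draws.

**What it does not emulate** — and hence what passing tests do not show
about real data: microbial community dynamics, mass loss and stoichiometry;
optode drift or nonlinearity within an incubation; correlation between
disintegration and the latent rate (hazard depends on age and treatment
only); non-Gaussian rate residuals; and any spatial sediment structure.
Parameter recovery on this generator demonstrates the estimators are
self-consistent at the study's design size and noise level, not that the
model is correct for any particular field dataset.

## Verification strategy

- Stage-1 estimates are checked against closed-form OLS (within 1% on 100
  random series) and all conversions against hand arithmetic.
- Stage-2/3/4 fits are checked by parameter recovery at the full design
  size with truth set to the published posterior means, within 2 posterior
  SDs of the new-tank summaries (the quantity the study prints).
- New-tank 90% predictive intervals are checked by a simulation-based
  calibration experiment: 200 replicates of simulate → refit → test whether
  an unseen tank's latent trajectory falls in the band (nominal 90%,
  accepted 85–95%). Calibration replicates draw records directly from the
  linear truth with s_P fixed at the typical propagated value (1.1 µmol
  O₂ g⁻¹ DM h⁻¹), so a replicate costs one model fit rather than a full
  synthetic experiment.
- Problem sizes in the test suite: unit tests run reduced sampler budgets
  (2 ensembles × ~1500 iterations); the acceptance checks run 2 ensembles ×
  8000–16000 iterations, which reach R-hat ≤ 1.01 on every model here.

## Known limitations

- Ensemble MCMC needs many more iterations than HMC per effective draw;
  the defaults are sized accordingly and the diagnostics are the guard.
- The viability model assumes a common α across treatments; a
  per-treatment intercept exists behind a flag but is not the default.
- Explanatory-variable (age) measurement error is supported only as a
  variance inflation; a full latent-age treatment is not implemented.
- The gamma threshold model treats observations as exchangeable unless a
  study column is supplied and the hierarchy enabled.
- Blank pairing is per sample; per-day blank designs must be reshaped to
  that convention before input.
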