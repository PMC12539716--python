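# Methods

## Model structure

`depsim` simulates each person of 23 birth cohorts (1990–2012, default
1,000 persons per cohort) separately through ages 10–17 within the study
window 2000–2022. A person carries:

* sex (male birth share 0.512, configurable);
* a persistent baseline depression risk `I ~ Normal(mu, sigma)` on the
  log-odds scale (`sigma = 1.0`, expert-set; `mu` is the single calibrated
  parameter, default −1.80);
* six static factors fixed over ages 10–17 (parental psychiatric history;
  physical, emotional and sexual abuse; neglect; bullying), drawn once from
  sex-specific prevalences;
* persistent platform propensities and a shared co-use latent factor;
* annually redrawn time-varying factors (physical inactivity,
  obesity/overweight, chronic physical conditions, substance use) from
  sex × age-group (10–14 / 15–17) × year prevalence tables. An optional
  `persistence` probability carries last year's state forward (default 0:
  the assignment is specified by age/year/sex distributions and nothing is
  known about serial correlation, so independence is the parsimonious
  default and the knob makes the assumption explicit).

Annual mortality uses a flat adolescent death probability (2·10⁻⁴/year)
standing in for a full life table; the `LifeTable` type accepts arbitrary
sex × age schedules from CSV.

## Risk equation and event mechanisms

The annual linear predictor is `eta = Σ ln(OR_i)·A_i + ln(OR_band) + I`,
and risk is read as odds: `p = logistic(eta)`. The literal exponential
reading (`p = min(e^eta, 1)`) is available as `risk_mode="exp"` for
sensitivity; the logistic reading is the default because the coefficients
are odds ratios and the calibration classification threshold is stated as
a probability.

Two event mechanisms coexist in the source material and both are
implemented as explicit config:

* **Bernoulli** (simulation default): each person-year draws an event with
  probability `p`;
* **threshold** (calibration default): a person-year counts as depressed
  iff `p > 0.5`, i.e. `eta > 0`.

These two mechanisms are *not* equivalent and produce very different
prevalence levels at the same `mu` (with `mu = −1.80`, `sigma = 1`:
roughly 18–20% under Bernoulli vs 7–12% under the threshold rule once
factor contributions are included). The synthetic France-like scenario
reports prevalence under the threshold rule, which is the combination that
places the default baseline mean inside the observed 4–10% band; the
contradiction between the two mechanisms is inherited from the source
material and deliberately left visible rather than resolved.

"Cumulative onset" is the count of persons with a first event inside the
window; no episode-duration, remission or recurrence dynamics are modelled
within adolescence.

## Social-media exposure

Adoption of each platform (Facebook 2004, Twitter 2006, WhatsApp 2009,
Instagram 2010, Snapchat 2011, TikTok 2016) follows the Bass curve
`F(t) = (1 − e^{−(p+q)t}) / (1 + (q/p) e^{−(p+q)t})` with default
`p = 0.03, q = 0.38` (classic Bass averages; the source gives the
framework but not coefficients), scaled by sex-specific saturation
fractions (age 10–14 × 0.8). A person uses a platform in a year iff their
persistent propensity quantile ≤ saturation × F, which guarantees monotone
adoption and no churn. Co-use correlation (default 0.10) enters through a
one-factor Gaussian copula, making the correlation parameter directly
measurable on latent scores.

Daily minutes among users are gamma draws per platform with CV 0.20
(shape 25); platform means ramp linearly from 30% of their 2022 value at
launch. Per-platform gamma (rather than one draw on the summed mean) is
the default reading; `gamma_total_mode` switches to the total-time
interpretation. Duration bands `[0,30) [30,60) [60,120) [120,360)
[360,inf)` carry the exposure coefficients; 60 minutes falls in the
60–120 band (half-open, lower-inclusive).

## Physical-activity latent minutes

The inactivity indicator (<60 min activity/day) is classified from a
latent activity-minutes draw that is piecewise uniform and consistent with
the tabulated prevalence: inactive mass uniform on [0, 60), active mass on
[60, 180). This makes two minute-level rules mechanistic: the 2020
pandemic shock multiplies latent minutes by (1 − 0.42) before
classification, and the activity-substitution intervention adds +30 latent
minutes to recipients. A side effect worth knowing: the pandemic
multiplier can reclassify table-active people as inactive even when the
tabulated 2020 prevalence is low — the table is treated as pre-shock.

## Calibration

Only the population mean baseline risk `mu` is fitted. The loss is the
mean squared error between simulated and observed annual prevalence
proportions (this functional form makes the stated 0.001 stopping
threshold dimensionally sensible). The objective is evaluated under common
random numbers — one pre-drawn panel of every random number the simulation
needs — so it is deterministic in `mu`; without CRN the stochastic
objective defeats the Nelder–Mead simplex. Optimisation: one-dimensional
Nelder–Mead, initial simplex {start, start + 0.5}, 30 restarts with starts
uniform on [−4, 0], per-restart cap 300 iterations, early stop once the
loss falls below 10⁻³; the best evaluation across restarts is returned.
Pooled targets are the default; sex-stratified targets are accepted.

Parameter recovery on the synthetic scenario (truth `mu = −1.80`,
threshold mode, 1,000/cohort, independently seeded target and calibration
panels): single-run error ≲ 0.03, 20-replicate bias ≲ 0.01 — computed by
`tests/test_acceptance.py` and `scripts/acceptance.py`, not quoted from
anywhere.

## Scenarios

All scenarios share one panel (common random numbers) over window
2000–2022: `no_sm` (minutes → 0), `cap60` (min(m, 60)), `swap_pa`
(m − 30 for m ≥ 60, +30 latent activity minutes), `high_risk` (the top
8.5% by non-SM linear predictor — static factors as drawn, time-varying
factors at expected prevalence — stop use entirely; a cap-60 variant and
the alternative 10% fraction are config). Stop-vs-cap and 8.5%-vs-10% are
genuine ambiguities in the source; the defaults follow the wording the
headline results attach to. Scenario enforcement is perfect (no adherence
model). Note that with the shipped 60–120-minute coefficient being
*negative* (entered verbatim), capping at 60 can outperform full removal
and the targeted scenario can be approximately null — the dominance
property `no_sm ≤ cap60 ≤ current` is guaranteed (and tested) only for
non-negative band coefficients.

## Outcomes

Adolescent-onset cases scale to lifetime cases by 0.72/0.59 ≈ 1.22;
per-lifetime-case multipliers (suicide deaths 1.11·10⁻³, HALE 0.190
years, direct €3,556, productivity €1,917) are the ratios implied by the
published burden table's first column, documented as derived and
overridable; attempts = 25 × deaths. Adult recurrence uses the
risk-multiplier arithmetic (2.78 × 8.3% ≈ 23%) as published, with the
odds-correct alternative behind `adult_mode="odds"`. Suicide deaths are a
post-hoc per-case outcome, not a competing risk inside the simulation.
Extrapolation multiplies all fields by births-per-year (790,000) /
persons-per-cohort. No discounting, no cost-effectiveness ratios.

## Uncertainty

The ensemble (default 500 iterations; reduced runs are labelled) resamples
all non-calibrated parameters independently — normal with
SD = CI-width/3.92 where a 95% CI is published (a truncated-uniform-on-CI
option exists), uniform ±20% otherwise, probabilities clipped to [0, 1] —
and reruns the pipeline on a fresh derived seed; `mu` is never resampled.
Credible intervals are percentile intervals with linear interpolation.
Named, independently keyed random streams (cohort, factors, usage, onset,
mortality, params, …) ensure a change in one component never perturbs
another's draws.

## Synthetic ground truth

`synthetic_truth_config()` is the shipped default config plus two changes:
threshold-mode prevalence reporting and a small positive 2020 confinement
coefficient (+0.05) in place of the published −1.4816, whose sign would
collapse 2020 prevalence to ~0.5% — incompatible with the documented 2020
rise it is meant to encode. Placeholder values for the unprinted majority
of parameters (factor coefficients 0.15–0.30; high-duration SM bands 0.60
and 0.90; prevalence tables from French-plausible levels with mild linear
trends) were chosen once so the simulated series starts near 8% and rises
to ~12% within the 4–15% plausibility envelope. They are test scaffolding
with known ground truth, not estimates of any real population, and passing
tests demonstrate the machinery (recovery, dominance, robustness), not
real-world effect sizes. The generator does not emulate content-type or
engagement-quality dimensions of SM use, seasonal patterns, or any
serial correlation in time-varying risk factors.

## Numerical choices and problem sizes

Defaults were chosen for single-CPU practicality: 1,000 persons/cohort for
calibration-grade runs, 200/cohort for scenario sweeps and reduced
ensembles (always labelled). Panel memory at full scale is ~60 MB. Band
binning is `searchsorted` on half-open edges; ties in high-risk selection
break by ascending id; percentile and gamma conventions are stated above.
All fixtures regenerate from (config, seed); the repository ships no data
files.
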