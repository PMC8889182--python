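# Methods

This note documents the models behind `photoniche`, the defaults and why,
what the synthetic-data generators do and do not emulate, and the
numerical choices a maintainer would want written down.

## Optical model

Irradiance at depth follows the single-exponential attenuation law
`E_z = E_0 e^(−K_d z)` with depth positive downward in metres and the
surface at z = 0. K_d is estimated by ordinary least squares of
ln(irradiance) on depth — not nonlinear least squares — because the model
is exactly linear on the log scale, multiplicative sensor error becomes
additive and homoscedastic there, and a log-linear fit is standard optical
oceanography practice. `OpticalModel.r_squared` is the R² of that
log-linear regression. The fit requires at least three readings at three
distinct depths and strictly positive irradiance.

`equivalent_depth_increase` rests on the same law: two depth changes are
optically equivalent when they produce the same attenuation factor, i.e.
when K_d·Δz is conserved. The translation is exact under the model and
carries no uncertainty of its own.

Limitations: attenuation is treated as spectrally flat and vertically
homogeneous. Real water columns have wavelength-dependent K_d and often
vertical structure; K_d here is an effective PAR-weighted constant over
the profiled depth range.

## Logger summaries

Raw logger readings (default 30-min cadence) are aggregated to
calendar-day means before any statistic; days with no readings are
dropped and logged. The temperature contrast is a two-sample t-test on
daily means, pooled-variance by default (`equal_var=False` gives Welch).
Light variability is the coefficient of variation of *daily mean*
relative light per site, reported as the shallow/deep ratio; computing the
CV on raw readings would be dominated by the diel cycle, which is common
to both sites and uninformative about day-to-day (weather/turbidity)
variability. Daily means are serially independent in the generator but
likely autocorrelated in real data, so real-data p-values from this t-test
should be read as approximate.

## Excitation pressure and the Fv/Fm depth calibration

`Q_m = 1 − (ΔF/F_m′)/(F_v/F_m)` is computed without clamping: slightly
negative values arise when the noon yield exceeds the dusk yield through
measurement noise under light limitation, and erasing them would bias
group means upward (observed treatment means near zero imply such values
exist). Records missing either yield are skipped with a logged count; no
imputation.

Survey colonies measured only at noon get F_v/F_m from a per-species OLS
calibration of measured dusk yields on depth. Predictions are truncated
into (0, 1] (floor 1e−6) with a warning rather than an error, since the
calibration line itself is unconstrained; predictions outside the
calibration depth range warn about extrapolation but are evaluated. When
a survey colony does carry a dusk measurement, the measured value is used
and the record's `source` field says so (`measured` vs `fvfm_predicted`);
a flag forces all-predicted as a sensitivity analysis. Treatment
contrasts default to Welch's t-test because group variances in transplant
data are typically unequal.

## Depth limits

Per-species Q_m ~ depth lines are fitted by OLS; the depth limit is the
x-intercept z* = −b/m, defined only for declining lines (m < 0). Reported
values are rounded to 0.1 m; full precision is retained in JSON.

Uncertainty on z* uses a case-resampling bootstrap (percentile method,
default 2000 replicates, seed mandatory): resample colonies with
replacement, refit, recompute −b/m. Replicates whose resampled slope is
non-negative have no finite limit and are discarded with a count — a
warning fires above 10% discarded, at which point the interval should not
be trusted. The bootstrap was chosen over the delta method because z* is
a ratio of correlated estimates and its sampling distribution is visibly
skewed at survey sample sizes. A model built from bare published
coefficients (no records) yields a point estimate with no interval.

The ANCOVA compares the full model `qm ~ depth + species + depth:species`
to the no-interaction model by the extra-sum-of-squares F-test,
F = ΔRSS / (RSS_full/(N−4)) on (1, N−4) df. When the full model fits
exactly (RSS ≈ 0, e.g. collinear toy data) F is reported as infinite
rather than a float-noise-dominated ratio. Records are pooled regardless
of Q_m source; repeated measurements of a colony are treated as
independent (no mixed-effects structure), consistent with how such
surveys are normally analysed and a noted simplification.

## Survivorship and selection

The one-tailed Fisher exact test conditions on the table margins: the
number of deaths in the first-listed group is hypergeometric, and the
p-value is the exact upper tail P(deaths ≥ observed), computed from the
hypergeometric survival function (the test suite cross-checks every
result against an independent log-factorial enumeration of all
margin-fixed tables). The first-listed group is always the hypothesised
disadvantaged one, and the CLI requires explicit `A:B` ordering so the
tail is never silently flipped. Discarded colonies (detached fragments)
are removed before tallying — they are censored, not dead.

The standardized selection differential is s = (w₁ − w₂)/mean(w₁, w₂) on
survival proportions; it is antisymmetric in its arguments and bounded by
|s| ≤ 2 with equality only when one group's survival is zero. Mortality
is displayed as whole percentages; raw proportions live in the JSON.

## Synthetic data: what it emulates and what it does not

Defaults (all overridable in `SimulationConfig`, YAML-loadable):

| quantity | default | basis |
|---|---|---|
| K_d | 0.40 m⁻¹ | field estimate at the study site |
| profile | 21 depths, 0–10 m, log-noise σ 0.05 | typical diving-PAM profile |
| logger days | 176 (2014-09-26 start), 48 readings/day | deployment span/cadence |
| daily temperature | N(28.85, 0.96) shallow / N(28.46, 0.88) deep °C | reported site summaries |
| daily light CV | 0.50 shallow / 0.10 deep (ratio 5) | reported variability ratio |
| Q_m lines | 0.735 − 0.133·z / 0.422 − 0.054·z | reported per-species regressions |
| Q_m residual σ | 0.09 / 0.08 | reproduces the reported R² ≈ 0.71 / 0.50 over each depth range |
| F_v/F_m line | 0.48 + 0.02·z, σ 0.01 (both species) | reproduces reported treatment-level F_v/F_m means and calibration R² ≈ 0.8; per-species calibration tables are not published, so this is the package's own choice |
| survey n | 38 / 67, calibration subsample 10 / 21 | survey design |
| depth ranges | 2.5–6 m / 3–8 m | species vertical distributions |
| transplant arms | n = 27/29/44/28, death prob 0.00/0.27/0.02/0.04 | post-census group sizes and mortality rates; exact death counts are not published, so probabilities are set from the reported percentages |

Noise models are the simplest forms consistent with the summary
statistics being emulated: log-normal multiplicative error on irradiance,
truncated-Normal yields, Bernoulli survival, log-normal day-to-day light
levels. ΔF/F_m′ is *derived* from a simulated true Q_m via
ΔF/F_m′ = F_v/F_m·(1 − Q_m), so downstream estimation exercises the Q_m
formula as an inverse problem rather than tautologically recovering its
own inputs.

Deliberately not emulated: within-colony repeated-measures correlation,
serial correlation in logger series, spectral light structure, seasonal
temperature trend, and any microbial/symbiont community data. Passing
tests therefore demonstrate that the estimators recover known parameters
under the stated independence and noise assumptions — not that those
assumptions hold in the field.

All generators are pure functions of (config, seed) via numpy's
`default_rng`; `write_campaign` spawns per-table child seeds from one
root `SeedSequence` so each table is reproducible independently of the
others, and the pipeline does the same per stage.

## Problem sizes

Stochastic checks use the survey sizes above; replicate-based checks use
200–1000 seeded replicates (e.g. the daily-temperature t statistic
averages 1000 replicates of 176 + 176 days; bootstrap-coverage checks run
500 experiments of 1000–2000 bootstrap replicates each), chosen as the
point where Monte-Carlo error is comfortably below the tolerance being
asserted.

## Known limitations

- The depth limit is an extrapolation of a linear fit beyond the deepest
  sampled colony; it is a bioenergetic bound under the linear-decline
  assumption, not an observed distribution edge.
- Exact-test p-values are conservative for small tables, as is inherent
  to conditioning on margins.
- The equal-variance default for the *temperature* t-test (chosen to
  match the conventional reporting of a single pooled t) differs from the
  Welch default used for fluorometry contrasts; both are available
  everywhere via `equal_var`.
- YAML simulation configs may nest species/treatment blocks; there is no
  schema migration, unknown keys raise immediately.
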