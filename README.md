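# photoniche

Photic-niche analysis for depth-segregated reef corals.

Sibling coral species often partition reef habitat by depth, and light is
the axis that matters: the symbiotic algae of a shallow specialist and a
deep specialist experience radically different irradiance regimes a few
metres apart. `photoniche` implements the quantitative toolkit used to ask
whether such species are photophysiologically specialised to their depth
ranges, built for ecophysiologists analysing reciprocal-transplant
experiments and PAM-fluorometry depth surveys (the *Orbicella annularis* /
*O. franksi* system in the Caribbean is the motivating case).

## What it computes

**Water-column optics.** Downwelling irradiance decays as
`E_z = E_0 e^(−K_d z)`. `fit_kd` estimates the diffuse attenuation
coefficient K_d (m⁻¹) by OLS on log irradiance from a light–depth profile;
`percent_surface_irradiance` and `depth_for_irradiance` convert between
depth and % surface light; `equivalent_depth_increase` translates a depth
response across waters of different clarity by conserving the optical
thickness K_d·Δz. `summarize_loggers` contrasts shallow vs deep
temperature/light logger series on daily aggregates.

**Excitation pressure.** From PAM fluorometry, the maximum excitation
pressure over PSII is

```
Q_m = 1 − (ΔF/F_m′) / (F_v/F_m)
```

with ΔF/F_m′ the effective quantum yield at noon and F_v/F_m the maximum
quantum yield at dusk. Q_m ≈ 1 signals chronic light stress, Q_m ≈ 0
light-limited photosynthesis. For survey colonies measured only at noon,
F_v/F_m is predicted from a per-species linear depth calibration
(`calibrate_fvfm_depth` / `estimate_survey_qm`).

**Depth limits.** Q_m declines roughly linearly with depth. `fit_qm_depth`
fits the per-species line `Q_m = b + m·z`; its x-intercept `z* = −b/m` —
where excitation pressure reaches the theoretical minimum of 0 — is the
bioenergetic depth limit of the species' photic niche (`depth_limit`, with
a case-resampling bootstrap 95% CI). `ancova_interaction` tests the
species-by-depth interaction (extra sum-of-squares F), and `slope_ratio`
quantifies how much faster one species' Q_m declines.

**Transplant fitness.** `survivorship_report` tallies six-month
alive/dead outcomes per treatment (S-S, S-D, D-S, D-D), runs one-tailed
Fisher exact tests (exact hypergeometric tail, conditional on margins) on
the pairwise contrasts, and computes the standardized selection
differential `s = (w₁ − w₂) / mean(w₁, w₂)` on survival proportions per
habitat.

**Synthetic campaigns.** `photoniche.simulate` generates all four input
tables (light profile, loggers, PAM records, transplant outcomes) under a
seeded `SimulationConfig` whose defaults are the study conditions of the
motivating field experiment, so the entire pipeline runs and is tested
without any external data.

## Worked example

Generate a synthetic campaign and run the full pipeline:

```
photoniche simulate --out-dir data/ --seed 42
photoniche run --profile data/light_profile.csv --loggers data/loggers.csv \
    --pam data/pam.csv --outcomes data/outcomes.csv --seed 42
```

which prints:

```
photoniche analysis report
===========================
K_d = 0.40 m^-1 (R^2 = 0.999)
  3.5 m: 24.6% surface irradiance
  9.5 m: 2.2% surface irradiance
Daily temperature: shallow 28.83 ± 1.02 °C vs deep 28.47 ± 0.96 °C (t-value = 3.47, p = 0.000582)
Light variability ratio (shallow/deep CV): 5.2
O. annularis: Q_m = 0.749 -0.135 * depth (R^2 = 0.74, n = 38); depth limit = 5.6 m (95% CI 5.3-5.8 m)
O. franksi: Q_m = 0.470 -0.060 * depth (R^2 = 0.52, n = 67); depth limit = 7.9 m (95% CI 7.4-8.5 m)
Species x depth interaction: F_1,101 = 23.85, p = 3.91e-06; slope ratio = 2.25
...
```

Reading the output: the water column attenuates light at K_d = 0.40 m⁻¹,
so the shallow (3.5 m) and deep (9.5 m) sites receive ~25% and ~2% of
surface irradiance. The shallow specialist's excitation pressure falls
more than twice as fast with depth as the deep specialist's (slope ratio
2.25, interaction p < 10⁻⁵), and the fitted lines hit Q_m = 0 — the
theoretical niche floor — near 5.6 m and 7.9 m respectively: the shallow
specialist runs out of usable light several metres before its sibling.
The same library calls are available in Python (`photoniche.run_pipeline`,
or the individual stage functions); the equivalent JSON report is written
with `--out-dir`.

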