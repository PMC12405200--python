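# Methods

This note documents the statistical model behind `nabstat`, the choices
made where the methodology was genuinely open, and what the synthetic
studies do and do not demonstrate.

## Dose–response model and ND50

Serum dose is the volume fraction *x* ∈ (0, 1]; a 1/16 dilution is
x = 0.0625. All interval arithmetic and thresholds live on the log2
scale, matching the two-fold structure of dilution series.

Transduction efficiency is modeled as a four-parameter logistic with the
top asymptote fixed at 1 (the data are normalized to the antibody-free
control):

TE(x) = b + (1 − b) / (1 + (x/K)^h),  K > 0, h > 0, 0 ≤ b < 0.5.

The reported ND50 is the *absolute* 0.5 crossing,
ND50 = K·(0.5/(0.5 − b))^{1/h}, not the curve's half-height midpoint;
the two coincide only at b = 0. A floor b ≥ 0.5 (or a crossing beyond
undiluted serum) is an explicit error, not a number.

## Noise model of the synthetic generator

Luminescence variability scales with signal, so observations are
TE·exp(ε), ε ~ N(0, σ_ln) with σ_ln = √ln(1 + CV²) — the exact
log-normal relation, not the small-CV approximation. The noise is
median-preserving (no −σ²/2 shift): the generating curve is the central
tendency on the log scale, where the fit happens. Per-curve seeds derive
from the master seed via `SeedSequence(master, spawn_key=(index,))`, so
ensembles are reproducible element-wise.

What the generator does **not** emulate: plate-position effects, carry-
over between wells, pipetting error correlated along the dilution
ladder, day effects, or heteroscedasticity beyond the multiplicative
model. Passing simulation studies therefore validates the estimators
under idealized i.i.d. multiplicative noise, not against every failure
mode of real plates.

## The three estimators

**Threshold.** Scanning from the most dilute tested point, the first
dilution whose replicate-mean TE is below 0.5. If no mean is below 0.5
the ND50 is beyond the tested range (error); if all are, the estimate is
right-censored at the most dilute dilution and flagged.

**Linear bootstrap.** The adjacent dilution pair whose means bracket 0.5
(nearest the dilute end if noise creates several crossings; all
crossings are reported). Every combination of one replicate from each
side is interpolated linearly to y = 0.5 on the log2(x) axis — dilutions
are geometric, so log2 is the natural interpolation axis; a linear-axis
mode exists behind a flag but showed far heavier estimate tails in
pilot simulations. Point = mean of the interpolants (log2 scale);
interval = their 2.5th/97.5th percentiles. Equal-valued replicate pairs
(zero slope) are skipped and counted.

**Hill-MCMC.** Bayesian fit with priors: ND50 ~ Normal(μ = arithmetic
mean of the tested fractions, σ = 0.15) truncated to (0, 1]; slope
h ~ Normal(1, 0.05) truncated to h > 0; floor b ~ Half-Normal(0.5)
truncated to b < 0.5 (larger floors admit no ND50). The sampler is
parameterized by the ND50 itself — the quantity carrying the prior —
with the midpoint K derived per draw.

*Observation model.* For each dilution the modeled datum is the mean of
the natural-log replicates, with a known noise SD: the empirical SD of
those log replicates when ≥ 2 are available, floored at σ = 0.05
(typical assay variability); single replicates use σ = 0.05 outright.
The floor matters: an SD estimated from two or three replicates
routinely lands far below the variability it estimates, and an
unfloored near-zero SD lets one dilution veto the entire fit. In
calibration runs at CV = 10% (50 triplicate curves), the unfloored
per-replicate likelihood covered the generating ND50 with its 95%
credible interval only ~60% of the time; the floored mean-observation
model reaches ~94%, which is why it is the default. The fixed σ is in
natural-log units (σ = 0.05 ≙ CV ≈ 5%).

*Sampling.* Affine-invariant ensemble MCMC (differential-evolution and
snooker moves), 16 walkers partitioned into 4 chains of 4 walkers for
the rank-normalized split R-hat diagnostic, 800 burn-in steps, then
thinned-by-2 sampling until 2000 retained draws per chain. Walkers
within one ensemble interact, so this R-hat is a convergence screen
rather than a between-independent-chains statistic; estimates with
max R-hat ≥ 1.01 are flagged, not discarded. The `target_accept`
setting exists for interface parity with gradient-based samplers and is
ignored. All runs are deterministic given the seed.

*Summaries.* Point = posterior mean of log2(ND50); interval = posterior
2.5th/97.5th log2 percentiles. Posterior draws are retained on the
estimate for downstream use (e.g. direct posterior comparisons).

### Known bias of the free floor

With data that never approach the curve's floor (truth b = 0, tested
TEs ≥ 0.2), the one-sided half-normal prior on b lets posterior mass at
b > 0 trade against smaller ND50, shifting the posterior-mean ND50 about
−0.06 log2 at CV = 10%. Pilot runs confirmed the shift is a property of
the model class, not the parameterization (it persists under (K, h, b)
vs (ND50, h, b) sampling and under per-replicate vs mean likelihoods,
and vanishes only if b is fixed at 0). The shift is well inside the
practical-equivalence threshold of 0.3 log2, but it is systematic:
paired against the (long-run unbiased) linear bootstrap over a common
curve ensemble it is statistically detectable.

## Composite uncertainty across runs (CI-of-CIs)

Repeated runs give a set of 95% intervals; averaging their bounds
understates run-to-run variation. The composite interval is [2.5th
percentile of the lower bounds, 97.5th percentile of the upper bounds]
(linear-interpolation percentiles): never narrower than bound-averaging,
reducing to the common interval when all runs agree, permutation-
invariant. The aggregation rule is one defensible formalization of a
"confidence interval of credible intervals"; alternatives (pooled
draws, percentiles of centers) would be narrower.

The replicate-precision study partitions independently simulated
single-replicate curves without replacement into virtual runs of 1, 2
or 3 technical replicates (30 runs per condition by default), fits each
run, and aggregates. Between-run scatter of the point estimates falls
with replicate count as expected (≈ 0.17 / 0.13 / 0.09 log2 at
CV = 10% in the extrapolation regime). Composite widths, however, mix
that scatter with each run's own interval width, and the single-
replicate fits — whose σ is fixed at 0.05 while the simulated noise is
≈ 0.10 — are individually overconfident, i.e. too narrow. The net
effect is that composite width is not strictly monotone in replicate
count in this regime (the 2-replicate composite can exceed the
1-replicate one), even though the precision of the *estimates*
monotonically improves. Making the single-replicate σ track the
simulated noise restores much, but not all, of the monotonicity; the
default keeps the fixed σ = 0.05.

## Equivalence testing

Groups of log2 ND50 observations are modeled as Normal(μ_g, σ_g) with
priors μ_g ~ Normal(group sample mean, 0.5) (an empirical-Bayes
centering) and σ_g ~ Half-Normal(0.5); the same ensemble sampler (2000
draws/chain, 400 burn-in, thinning 3) yields the posterior of
Δ = μ₁ − μ₂ and P(|Δ| > θ) for each threshold θ.

θ = 0 is degenerate for continuous posteriors — P(|Δ| > 0) ≈ 1 always —
so the result also carries the probability of direction
max(P(Δ>0), P(Δ<0)) as the usable "any difference" measure. The
practical test uses θ = 0.3 log2: the 90th percentile of routine
credible-interval widths (`practical_threshold_from_widths` recomputes
such cutoffs for other platforms). Verdicts require exceedance
probability > 0.95. An explicit alternative mode compares two posterior
draw vectors directly by differencing (seeded pairing when lengths
differ); the mode is never inferred from the input shape.

## Plate pipeline

TE(well) = (RLU − mean background) / (mean antibody-free − mean
background), with the virus-free wells defining the floor and the
serum-free wells defining 100% transduction. The formula is invariant
under any positive gain rescaling of the instrument, and the
antibody-free wells average to TE = 1 exactly by construction. An
antibody-free mean at or below the background mean is a hard "no
signal" error. Negative TEs are clipped to 10⁻⁶ (kept strictly positive
for the log-scale likelihood) and the affected wells listed in the
curve metadata.

Layouts are TOML files (versioned schema: `data_path`,
`measurement_date`, `[plate_params]`, `[samples.<id>]` with parallel
`dilutions`/`wells` arrays, `[controls]` with `antibody_free` and
`background` wells); aggregator files list member layouts, resolved
relative to the aggregator. Wells are validated A1–H12 with exclusive
roles. The schema is this package's own design.

## Assay planner

All volumes follow the (n + 1) × 10 µL unit-volume rule (one spare
replicate volume absorbs pipetting loss): serum = (n+1)·10 µL; AAV mix
= steps·(n+1)·10 µL for the series plus (n+1)·10 µL for controls; AAV
stock per well = MOI·cells/titer·1000 µL. The two-fold ladder runs rows
A–G (serial 1/2^k, final 1/2^(k+1) after the equal-volume AAV-mix
addition); row H is the antibody-free control. Arithmetic is exact
(`fractions.Fraction`); `worksheet_display` rounds half-up to two
decimals only for presentation (0.625 → 0.63).

## Problem sizes and numerical choices

Defaults chosen for the simulation studies: 50 curves for the
parameter-recovery ensemble, 30 runs × {1,2,3} replicates (× 5 seeds
for median statements) for the precision study, 100 repeats for
equivalence calibration — large enough for the stochastic tolerances
asserted in the tests while keeping a full suite run in the
ten-minute range on one CPU. Unit tests use reduced sampler settings
(500 draws / 300 burn-in), which is a documented interface parameter,
not a different model.

Degenerate inputs handled explicitly: identical replicates (SD 0) fall
back to the fixed σ; zero-slope replicate pairs are skipped in the
bootstrap; constant-offset width comparisons short-circuit the t
statistic to ±∞ and identical lists to t = 0, p = 1; Wilcoxon uses
zero-splitting for ties.

## Limitations

- Single-lab, single-plate model: no hierarchical day/operator effects.
- The Hill floor prior induces the small downward ND50 shift described
  above whenever the tested range never approaches the floor.
- The fixed single-replicate σ encodes *typical* assay variability;
  analyses of data noisier than CV ≈ 5% with single replicates will be
  overconfident unless the caller raises `fixed_obs_sigma`.
- Equivalence verdicts inherit the empirical-Bayes prior centering;
  with n = 1 observations per group the posterior leans heavily on the
  Half-Normal(0.5) SD prior.
- 96-well geometry only; no vendor-binary plate formats.
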