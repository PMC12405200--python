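# nabstat

Statistical toolkit for AAV neutralizing-antibody (NAb)
transduction-inhibition assays: ND50 estimation with quantified
uncertainty, plus the data handling and bench planning around it.

## The problem

Gene-therapy vectors based on adeno-associated virus (AAV) are blocked
by pre-existing neutralizing antibodies in serum. The standard cell-based
readout is a transduction-inhibition assay: cells receive reporter-AAV
pre-incubated with a serial dilution of the serum, and the luminescence
in each well is normalized to virus-only control wells, giving a
transduction efficiency (TE) per dilution. The **ND50** is the serum
dilution at which TE crosses 0.5 — half the antibody-free control.

The conventional readout ("the first dilution whose mean response drops
below 50%") returns a bare grid point with no uncertainty, which makes
titers from different runs, days or labs hard to compare. `nabstat`
implements a pipeline in which every ND50 comes with a 95% interval and
differences are judged against assay-level variability.

## The model

TE as a function of serum volume fraction *x* is a Hill curve with the
top fixed at 1 by normalization:

```
TE(x) = b + (1 − b) / (1 + (x / K)^h),     ND50 = K · (0.5 / (0.5 − b))^(1/h)
```

Three estimators share one output type:

| method | idea | uncertainty |
|---|---|---|
| `estimate_threshold` | first tested dilution with mean TE < 0.5 | none |
| `estimate_linear_bootstrap` | linear interpolation of the 50% crossing on the log2 axis, once per replicate combination | percentiles of the interpolants |
| `estimate_hill_mcmc` | Bayesian Hill fit (affine-invariant ensemble MCMC, truncated-normal priors on ND50 and slope, half-normal on the floor, log-normal observation model) | posterior 2.5–97.5 percentiles |

Only the Hill fit works when the tested dilutions never bracket the 50%
point — it extrapolates with honest, widened intervals.

On top of the estimators:

* `ci_of_cis` — composite "CI of CIs" across repeated runs (2.5th
  percentile of lower bounds to 97.5th of upper bounds, log2 units);
* `replicate_precision_study` — simulation study of how technical
  replicates buy precision;
* `bayesian_threshold_test` — P(|Δ| > θ) for the log2 difference of two
  groups of ND50s, with θ = 0.3 log2 as the practical-equivalence
  cutoff (`practical_threshold_from_widths` derives such cutoffs from
  interval-width panels);
* `plate` module — 96-well plate-reader exports (CSV/XLSX grid or long
  format), versioned TOML layout/aggregator files, TE normalization;
* `planner` module — serum/AAV-mix volumes and the two-fold dilution
  worksheet, in exact rational arithmetic;
* `simulate` module — synthetic curves with median-preserving
  multiplicative log-normal noise at a stated CV.

## Worked example

```python
from nabstat import (HillParams, NoiseModel, TWOFOLD_SERIES,
                     simulate_curve, estimate_hill_mcmc, estimate_linear_bootstrap)
from nabstat.estimators import McmcSettings

truth = HillParams(midpoint=1/16)          # true ND50 = 1/16
curve = simulate_curve(truth, TWOFOLD_SERIES, n_replicates=3,
                       noise=NoiseModel(cv=0.10), seed=1)
boot = estimate_linear_bootstrap(curve)
mcmc = estimate_hill_mcmc(curve, settings=McmcSettings(seed=1))
```

Running `python examples/simulate_and_estimate.py` (which does exactly
this, plus the threshold method) prints:

```
true ND50: 1/16  (log2 = -4.00)

threshold        : Dilution(1/8)        (grid point, no interval)
linear-bootstrap : Dilution(0.0634301)  95% CI [0.0532, 0.0707] width 0.41 log2
Hill-MCMC        : Dilution(0.0618887)  95% CrI [0.0544, 0.0697] width 0.36 log2  (R-hat 1.004)
```

Both statistical estimates sit on the true 1/16 = 0.0625 with intervals
of a third to half a log2 unit; the threshold method can only answer
with the neighbouring grid dilution 1/8. The other scripts in
`examples/` walk through extrapolation and replicate precision,
equivalence testing, the plate pipeline and assay planning.

A thin CLI wraps the same functions:

```bash
nabstat --output-dir out simulate --nd50 0.0625 --cv 0.10 --curves 50 --seed 7
nabstat --output-dir out estimate --method hillmcmc --input out/curves.csv
nabstat --output-dir out plan --replicates 3 --steps 7
```

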