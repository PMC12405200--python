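"""ND50 estimation when the dilution series misses the 50% point.

A serum with true ND50 = 1/32 is measured only at 1/4, 1/8 and 1/16 —
every tested dilution suppresses transduction below 50%, so neither the
threshold scan nor bootstrap interpolation can return an estimate.  The
Hill-MCMC fit extrapolates with quantified uncertainty, and repeating
the virtual assay shows how technical replicates buy precision via the
composite CI-of-CIs.
"""

import numpy as np

from nabstat import HillParams
from nabstat.estimators import McmcSettings
from nabstat.meta import replicate_precision_study

# kept small for a quick demo; the full study uses 30 runs per condition
study = replicate_precision_study(
    truth=HillParams(1 / 32),
    dilutions=[1 / 4, 1 / 8, 1 / 16],
    cv=0.10,
    replicate_counts=(1, 3),
    n_runs=8,
    seed=5,
    settings=McmcSettings(draws=1000, tune=500),
)

print("true ND50: 1/32 (log2 = -5.00); tested range stops at 1/16\n")
for r, (comp, ests) in study.items():
    pts = [e.point.log2_value for e in ests]
    print(f"{r} replicate(s)/run: mean estimate {np.mean(pts):+.2f} log2, "
          f"between-run SD {np.std(pts):.2f}, "
          f"composite 95% CI-of-CIs [{comp.low:.2f}, {comp.high:.2f}] "
          f"(width {comp.width_log2:.2f} log2)")

print(
    "\nEven single-replicate runs yield finite estimates near the true "
    "-5.0 log2, and the\nbetween-run scatter shrinks as replicates are "
    "added. The composite interval folds\nthat scatter together with each "
    "run's own credible-interval width, so at this small\ndemo scale (8 "
    "runs, reduced sampler settings) its width is noisy; the full study\n"
    "uses 30 runs per condition."
)
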