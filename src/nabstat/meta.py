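"""Two-stage uncertainty aggregation across repeated runs (CI-of-CIs).

Each repeat of an assay (or simulation) yields its own 95% credible
interval for the ND50.  Simply averaging those intervals understates the
run-to-run spread, so the composite interval takes the 2.5th percentile
of the per-run lower bounds and the 97.5th percentile of the per-run
upper bounds: a conservative envelope that folds both measurement noise
and model-fitting uncertainty into a single interval.  All interval
arithmetic is in log2 dilution units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .estimators import HillPriors, McmcSettings, ND50Estimate, estimate_hill_mcmc
from .model import Dilution, HillParams, NeutralizationCurve
from .simulate import NoiseModel, simulate_curve, curve_seed

__all__ = [
    "CompositeInterval",
    "ci_of_cis",
    "replicate_precision_study",
    "compare_interval_widths",
    "WidthComparison",
]


@dataclass(frozen=True)
class CompositeInterval:
    """Composite CI-of-CIs bounds in log2 dilution units."""

    low: float
    high: float
    n_runs: int

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"low {self.low} > high {self.high}")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")

    @property
    def width_log2(self) -> float:
        return self.high - self.low

    def contains(self, value_log2: float) -> bool:
        return self.low <= value_log2 <= self.high


def ci_of_cis(intervals: Sequence[tuple[float, float]]) -> CompositeInterval:
    """Aggregate per-run (low, high) log2 intervals into one composite.

    Composite low = 2.5th percentile of the lows; composite high =
    97.5th percentile of the highs (linear-interpolation percentiles).
    Never narrower than averaging the bounds, and reduces to the common
    interval when all runs agree.
    """
    if len(intervals) == 0:
        raise ValueError("need >= 1 interval")
    lows = np.array([lo for lo, _ in intervals], dtype=float)
    highs = np.array([hi for _, hi in intervals], dtype=float)
    if np.any(lows > highs):
        raise ValueError("every interval needs low <= high")
    return CompositeInterval(
        low=float(np.percentile(lows, 2.5)),
        high=float(np.percentile(highs, 97.5)),
        n_runs=len(intervals),
    )


def replicate_precision_study(
    truth: HillParams,
    dilutions: Sequence[Dilution | float],
    cv: float,
    replicate_counts: Sequence[int] = (1, 2, 3),
    n_runs: int = 30,
    seed: int = 0,
    priors: HillPriors | None = None,
    settings: McmcSettings | None = None,
) -> dict[int, tuple[CompositeInterval, list[ND50Estimate]]]:
    """How technical-replicate count buys ND50 precision.

    For each replicate count r, a pool of ``n_runs * r`` independent
    single-replicate noisy curves is partitioned without replacement
    into ``n_runs`` virtual assay runs of r replicates each; every run
    is fitted by Hill-MCMC and the per-run 95% credible intervals are
    aggregated into one composite CI-of-CIs.  With noisy data the
    composite narrows as r grows.  Deterministic given the seed.
    """
    noise = NoiseModel(cv)
    base_settings = settings or McmcSettings()
    out: dict[int, tuple[CompositeInterval, list[ND50Estimate]]] = {}
    for r in replicate_counts:
        if r < 1:
            raise ValueError("replicate counts must be >= 1")
        estimates: list[ND50Estimate] = []
        for run in range(n_runs):
            # r single-replicate curves merged into one r-replicate run;
            # stream index encodes (replicate condition, run, member)
            member_te = []
            dils = None
            for m in range(r):
                rng = np.random.default_rng(curve_seed(seed, 100_000 * r + 100 * run + m))
                c = simulate_curve(truth, dilutions, 1, noise, seed=rng)
                member_te.append([row[0] for row in c.te])
                dils = c.dilutions
            te = [list(vals) for vals in zip(*member_te)]
            run_curve = NeutralizationCurve(
                dils, te, sample_id=f"r{r}_run{run:02d}",
                metadata={"replicates": r, "cv": cv},
            )
            run_settings = McmcSettings(
                draws=base_settings.draws,
                tune=base_settings.tune,
                target_accept=base_settings.target_accept,
                rhat_threshold=base_settings.rhat_threshold,
                chains=base_settings.chains,
                seed=(seed * 1_000_003 + 7919 * r + run) & 0x7FFFFFFF,
            )
            try:
                estimates.append(estimate_hill_mcmc(run_curve, priors, run_settings))
            except Exception as exc:  # annotate with the failing run
                raise type(exc)(f"run {run} (replicates={r}): {exc}") from exc
        comp = ci_of_cis(
            [(e.ci_low.log2_value, e.ci_high.log2_value) for e in estimates]
        )
        out[r] = (comp, estimates)
    return out


@dataclass(frozen=True)
class WidthComparison:
    """Paired comparison of two sets of interval widths."""

    mean_difference: float
    t_statistic: float
    t_pvalue: float
    wilcoxon_statistic: float
    wilcoxon_pvalue: float
    n: int


def compare_interval_widths(
    widths_a: Sequence[float], widths_b: Sequence[float]
) -> WidthComparison:
    """Paired t-test and Wilcoxon signed-rank on matched interval widths.

    Degenerate inputs are handled explicitly: identical lists give a
    zero statistic with p = 1, and constant nonzero offsets use the
    zero-split tie handling of the signed-rank test.
    """
    a = np.asarray(list(widths_a), dtype=float)
    b = np.asarray(list(widths_b), dtype=float)
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 2:
        raise ValueError("need >= 2 paired widths")
    d = a - b
    if np.allclose(d, 0.0):
        t_stat, t_p = 0.0, 1.0
    elif np.std(d, ddof=1) <= 1e-12 * max(1.0, abs(d.mean())):
        # constant nonzero offset: the t statistic diverges
        t_stat, t_p = np.inf * np.sign(d.mean()), 0.0
    else:
        t_stat, t_p = stats.ttest_rel(a, b)
    w_res = stats.wilcoxon(a, b, zero_method="zsplit")
    return WidthComparison(
        mean_difference=float(d.mean()),
        t_statistic=float(t_stat),
        t_pvalue=float(t_p),
        wilcoxon_statistic=float(w_res.statistic),
        wilcoxon_pvalue=float(w_res.pvalue),
        n=int(a.size),
    )
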