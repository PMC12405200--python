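"""The three ND50 estimators: threshold, linear-bootstrap, Hill-MCMC.

* ``estimate_threshold`` — the field's conventional rule: the first
  tested dilution (scanning from most dilute) whose mean response drops
  below 50% of the antibody-free control.  Simple, but yields a point on
  the tested grid with no uncertainty.
* ``estimate_linear_bootstrap`` — interpolates the 50% crossing between
  the two adjacent dilutions that bracket it, once per combination of
  technical replicates, and summarizes the resulting ND50 distribution.
* ``estimate_hill_mcmc`` — fits the full Hill curve by Bayesian MCMC
  with a log-normal observation model, returning a posterior over ND50.
  Unlike the other two it does not require the tested dilutions to
  bracket the 50% point, so it can extrapolate with honest uncertainty.

All three return an :class:`ND50Estimate` so downstream code (meta
analysis, equivalence testing, CLI) is method-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ._mcmc import WALKERS_PER_CHAIN, run_ensemble
from .errors import (
    BelowRangeError,
    BracketNotFoundError,
    ConvergenceError,
    CurveError,
)
from .model import Dilution, NeutralizationCurve

__all__ = [
    "ND50Estimate",
    "HillPriors",
    "McmcSettings",
    "estimate_threshold",
    "estimate_linear_bootstrap",
    "estimate_hill_mcmc",
    "check_convergence",
]


@dataclass
class ND50Estimate:
    """Universal estimator output: point, 95% interval, draws, diagnostics.

    ``draws`` hold the bootstrap / posterior ND50 values as serum
    fractions; interval endpoints are the 2.5th and 97.5th percentiles
    computed on the log2 scale.  The threshold method carries no
    interval (``ci_low``/``ci_high`` are ``None``).
    """

    method: str
    point: Dilution
    ci_low: Dilution | None = None
    ci_high: Dilution | None = None
    draws: np.ndarray | None = None
    diagnostics: dict[str, Any] = field(default_factory=dict)

    @property
    def width_log2(self) -> float:
        """95% interval width in log2 dilution units."""
        if self.ci_low is None or self.ci_high is None:
            raise ValueError(f"{self.method} estimate carries no interval")
        return self.ci_high.log2_value - self.ci_low.log2_value


@dataclass(frozen=True)
class HillPriors:
    """Priors of the Bayesian Hill fit.

    Truncated normals on the slope (mu=1, sigma=0.05, support h>0) and
    on the ND50-generating midpoint (mu = arithmetic mean of the tested
    dilution fractions unless given, sigma=0.15, support (0, 1]); a
    half-normal (sigma=0.5) on the lower asymptote.  ``fixed_obs_sigma``
    is the natural-log-scale observation SD used for dilutions with a
    single replicate (typical assay variability).
    """

    slope_mu: float = 1.0
    slope_sigma: float = 0.05
    nd50_mu: float | None = None  # None -> mean of the curve's tested fractions
    nd50_sigma: float = 0.15
    bottom_sigma: float = 0.5
    fixed_obs_sigma: float = 0.05

    def __post_init__(self) -> None:
        for name in ("slope_sigma", "nd50_sigma", "bottom_sigma", "fixed_obs_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class McmcSettings:
    """Sampler configuration shared by estimator runs.

    ``target_accept`` is kept for interface parity with gradient-based
    samplers; the ensemble sampler used here has no such tuning knob.
    """

    draws: int = 2000
    tune: int = 800
    target_accept: float = 0.95
    rhat_threshold: float = 1.01
    chains: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.draws, self.tune, self.chains) < 1:
            raise ValueError("draws, tune and chains must all be >= 1")
        if not (0.0 < self.target_accept < 1.0):
            raise ValueError("target_accept must be in (0, 1)")


# ---------------------------------------------------------------------------
# threshold method


def estimate_threshold(curve: NeutralizationCurve) -> ND50Estimate:
    """First tested dilution (most dilute first) whose mean TE is < 0.5.

    Raises :class:`BelowRangeError` when no tested dilution suppresses
    the mean response below 50% — the ND50 lies beyond the weakest
    tested inhibition.  When even the most dilute serum already
    suppresses below 50% the estimate is right-censored at that
    dilution and flagged.
    """
    means = curve.replicate_means()
    flags = ["no_uncertainty"]
    # stored order is most concentrated first; scan from the dilute end
    for i in range(len(curve) - 1, -1, -1):
        if means[i] < 0.5:
            if i == len(curve) - 1:
                flags.append("right-censored")
            return ND50Estimate(
                method="threshold",
                point=curve.dilutions[i],
                diagnostics={"flags": flags, "mean_te": float(means[i])},
            )
    raise BelowRangeError(
        f"sample {curve.sample_id!r}: mean TE >= 0.5 at every tested dilution"
    )


# ---------------------------------------------------------------------------
# linear-bootstrap method


def _crossings(means_dilute_first: np.ndarray) -> list[int]:
    """Indices i (dilute-first order) where the mean crosses 0.5 between i and i+1."""
    above = means_dilute_first >= 0.5
    return [i for i in range(len(above) - 1) if above[i] and not above[i + 1]]


def estimate_linear_bootstrap(
    curve: NeutralizationCurve, axis: str = "log2"
) -> ND50Estimate:
    """Replicate-combination linear interpolation of the 50% crossing.

    Finds the adjacent dilution pair whose replicate means bracket 0.5
    (mean >= 0.5 on the dilute side, < 0.5 on the concentrated side; when
    noise creates several crossings the one nearest the dilute end is
    used and all are listed in the diagnostics).  Every combination of
    one replicate from each side yields one interpolated ND50; the mean
    of these is the point estimate and their 2.5th/97.5th percentiles the
    interval.  Dilutions are geometric, so interpolation defaults to the
    log2(fraction) axis; ``axis="linear"`` interpolates on raw fractions.

    Replicate pairs with equal values (zero interpolation slope) are
    skipped and counted.
    """
    if axis not in ("log2", "linear"):
        raise ValueError(f"axis must be 'log2' or 'linear', got {axis!r}")
    n = len(curve)
    means = curve.replicate_means()[::-1]  # dilute-first
    crossings = _crossings(means)
    if not crossings:
        raise BracketNotFoundError(
            f"sample {curve.sample_id!r}: no adjacent dilution pair brackets 50% "
            "transduction; consider the Hill-MCMC estimator"
        )
    i = crossings[0]
    # translate dilute-first indices back to stored (concentrated-first) order
    idx_above = n - 1 - i        # dilute side, mean >= 0.5
    idx_below = n - 1 - (i + 1)  # concentrated side, mean < 0.5
    d_above, d_below = curve.dilutions[idx_above], curve.dilutions[idx_below]
    if axis == "log2":
        x1, x2 = d_above.log2_value, d_below.log2_value
    else:
        x1, x2 = d_above.fraction, d_below.fraction

    sols = []
    skipped = 0
    for a in curve.te[idx_above]:
        for b in curve.te[idx_below]:
            if a == b:
                skipped += 1
                continue
            sols.append(x1 + (0.5 - a) * (x2 - x1) / (b - a))
    if not sols:
        raise BracketNotFoundError(
            f"sample {curve.sample_id!r}: every replicate pair has zero slope"
        )
    sols = np.asarray(sols)
    if axis == "log2":
        point_l2, lo_l2, hi_l2 = sols.mean(), *np.percentile(sols, [2.5, 97.5])
        fr = 2.0 ** np.array([point_l2, lo_l2, hi_l2])
        draws = 2.0**sols
    else:
        point, lo, hi = sols.mean(), *np.percentile(sols, [2.5, 97.5])
        fr = np.array([point, lo, hi])
        draws = sols
    # interpolants can extrapolate past the tested range for noisy
    # replicate pairs; clamp the summary endpoints to valid fractions
    fr = np.clip(fr, 1e-9, 1.0)
    return ND50Estimate(
        method="linear_bootstrap",
        point=Dilution(float(fr[0])),
        ci_low=Dilution(float(fr[1])),
        ci_high=Dilution(float(fr[2])),
        draws=draws,
        diagnostics={
            "bracket": (d_above.fraction, d_below.fraction),
            "all_crossings": [
                (curve.dilutions[n - 1 - c].fraction, curve.dilutions[n - 2 - c].fraction)
                for c in crossings
            ],
            "n_combinations": int(sols.size),
            "zero_slope_pairs_skipped": skipped,
            "axis": axis,
        },
    )


# ---------------------------------------------------------------------------
# Hill-MCMC method


def _prepare_observations(
    curve: NeutralizationCurve, priors: HillPriors
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Reduce the curve to per-dilution (x, mean log TE, sigma) triples.

    The modeled observation at each dilution is the mean of the
    natural-log replicates; its noise SD is the empirical SD of those
    log replicates when >= 2 are available, never taken below the fixed
    typical-assay-variability value (an SD estimated from two or three
    replicates that lands under typical assay variability is an
    underestimate, and a near-zero SD would make that dilution veto the
    whole fit).  Single replicates use the fixed value outright.
    """
    xs, logys, sigmas = [], [], []
    n_fixed = 0
    for d, row in zip(curve.dilutions, curve.te):
        if np.any(row <= 0):
            raise CurveError(
                f"sample {curve.sample_id!r}: non-positive TE at dilution "
                f"{d!r}; the log-scale likelihood requires TE > 0"
            )
        logs = np.log(row)
        if row.size >= 2:
            sd = float(np.std(logs, ddof=1))
            if sd <= priors.fixed_obs_sigma:
                sd = priors.fixed_obs_sigma
                n_fixed += 1
        else:
            sd = priors.fixed_obs_sigma
            n_fixed += 1
        xs.append(d.fraction)
        logys.append(float(logs.mean()))
        sigmas.append(sd)
    return np.asarray(xs), np.asarray(logys), np.asarray(sigmas), n_fixed


def _hill_log_posterior(
    x: np.ndarray, logy: np.ndarray, sigma: np.ndarray, priors: HillPriors, nd50_mu: float
):
    """Vectorized log posterior over walker positions (nd50, h, b).

    The curve is parameterized by the ND50 (the absolute-0.5 crossing,
    which carries the stated truncated-normal prior) rather than the
    Hill midpoint; the midpoint is derived per position as
    ``K = nd50 * ((0.5 - b) / 0.5)^(1/h)``.  Support: nd50 in (0, 1],
    h > 0, b in [0, 0.5) — a lower asymptote at or above 0.5 admits no
    50% crossing, so the half-normal prior on b is truncated there.
    """
    inv_var = 1.0 / sigma**2

    def log_prob(theta: np.ndarray) -> np.ndarray:
        nd, h, b = theta[:, 0], theta[:, 1], theta[:, 2]
        lp = np.full(theta.shape[0], -np.inf)
        ok = (nd > 0) & (nd <= 1.0) & (h > 0) & (b >= 0) & (b < 0.5)
        if not np.any(ok):
            return lp
        ndo, ho, bo = nd[ok], h[ok], b[ok]
        k = ndo * ((0.5 - bo) / 0.5) ** (1.0 / ho)
        prior = (
            -0.5 * ((ndo - nd50_mu) / priors.nd50_sigma) ** 2
            - 0.5 * ((ho - priors.slope_mu) / priors.slope_sigma) ** 2
            - 0.5 * (bo / priors.bottom_sigma) ** 2
        )
        pred = bo[:, None] + (1.0 - bo[:, None]) / (
            1.0 + (x[None, :] / k[:, None]) ** ho[:, None]
        )
        resid = logy[None, :] - np.log(pred)
        lik = -0.5 * np.sum(resid**2 * inv_var[None, :], axis=1)
        lp[ok] = prior + lik
        return lp

    return log_prob


def estimate_hill_mcmc(
    curve: NeutralizationCurve,
    priors: HillPriors | None = None,
    settings: McmcSettings | None = None,
) -> ND50Estimate:
    """Bayesian Hill fit; posterior over the ND50 with a 95% credible interval.

    Natural-log-transformed observations are modeled with a normal
    likelihood centered on the log of the Hill prediction, with
    per-dilution SDs from replicates (or the fixed fallback for single
    replicates).  ND50 is computed per posterior draw from the Hill
    parameters; the point estimate is the log2-scale posterior mean and
    the interval the 2.5th–97.5th log2 percentiles.  The estimate is
    flagged non-converged when the maximum split R-hat reaches the
    configured threshold.
    """
    priors = priors or HillPriors()
    settings = settings or McmcSettings()
    if len(curve) < 2:
        raise CurveError("Hill fit needs >= 2 dilutions")
    x, logy, sigma, n_fixed = _prepare_observations(curve, priors)
    nd50_mu = priors.nd50_mu if priors.nd50_mu is not None else float(curve.fractions.mean())
    log_prob = _hill_log_posterior(x, logy, sigma, priors, nd50_mu)

    nwalkers = settings.chains * WALKERS_PER_CHAIN
    rng = np.random.default_rng(np.random.SeedSequence(settings.seed & 0x7FFFFFFF, spawn_key=(17,)))
    init = np.column_stack(
        [
            np.clip(rng.normal(nd50_mu, 0.1 * priors.nd50_sigma, nwalkers), 1e-4, 1.0),
            np.abs(rng.normal(priors.slope_mu, 0.02, nwalkers)) + 1e-3,
            np.abs(rng.normal(0.0, 0.02, nwalkers)),
        ]
    )
    result = run_ensemble(
        log_prob, init, draws=settings.draws, tune=settings.tune,
        chains=settings.chains, seed=settings.seed,
    )

    flat = result.flat
    nd50, h, b = flat[:, 0], flat[:, 1], flat[:, 2]
    midpoint = nd50 * ((0.5 - b) / 0.5) ** (1.0 / h)
    l2 = np.log2(nd50)
    point_l2 = float(l2.mean())
    lo_l2, hi_l2 = np.percentile(l2, [2.5, 97.5])
    max_rhat = result.max_rhat
    converged = max_rhat < settings.rhat_threshold
    diag: dict[str, Any] = {
        "r_hat": max_rhat,
        "r_hat_per_param": result.rhat.tolist(),
        "n_draws": int(nd50.size),
        "acceptance_fraction": result.acceptance_fraction,
        "n_fixed_sigma_dilutions": n_fixed,
        "converged": converged,
        "flags": [] if converged else ["non-converged"],
        "posterior_mean_params": {
            "midpoint": float(midpoint.mean()),
            "slope": float(h.mean()),
            "bottom": float(b.mean()),
        },
    }
    return ND50Estimate(
        method="hill_mcmc",
        point=Dilution(min(2.0**point_l2, 1.0)),
        ci_low=Dilution(min(2.0**lo_l2, 1.0)),
        ci_high=Dilution(min(2.0**hi_l2, 1.0)),
        draws=nd50,
        diagnostics=diag,
    )


def check_convergence(estimate: ND50Estimate, settings: McmcSettings | None = None) -> bool:
    """``True`` iff the estimate's maximum R-hat is below the threshold."""
    settings = settings or McmcSettings()
    if "r_hat" not in estimate.diagnostics:
        raise ConvergenceError(
            f"{estimate.method} estimate carries no r_hat diagnostic"
        )
    return float(estimate.diagnostics["r_hat"]) < settings.rhat_threshold
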