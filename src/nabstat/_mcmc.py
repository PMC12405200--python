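"""Shared affine-invariant ensemble MCMC machinery.

Both Bayesian procedures in this package (the Hill dose-response fit and
the two-group equivalence test) are low-dimensional (3-4 parameters), so
they are sampled with emcee's affine-invariant ensemble sampler.  One
ensemble of ``chains * walkers_per_chain`` walkers is run; for the
rank-normalized split R-hat diagnostic the walkers are partitioned into
``chains`` groups that are treated as chains.  Walkers within one
ensemble interact, so this R-hat is a pragmatic screen rather than a
between-independent-chains statistic; it is conservative in the
direction that matters (stuck or multimodal ensembles inflate it).

The acceptance-rate target of gradient-based samplers has no analogue
here; the corresponding setting is accepted for interface compatibility
and ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import emcee
import numpy as np

__all__ = ["EnsembleResult", "run_ensemble", "split_rhat"]

WALKERS_PER_CHAIN = 4
#: keep every THIN-th post-burn-in step; differential-evolution moves mix
#: well on these low-dimensional targets but successive steps are
#: correlated, and mild thinning keeps the split R-hat diagnostic sharp
THIN = 2


def _default_moves():
    return [
        (emcee.moves.DEMove(), 0.8),
        (emcee.moves.DESnookerMove(), 0.2),
    ]


@dataclass
class EnsembleResult:
    """Posterior draws arranged as (chain, draw, parameter) plus diagnostics."""

    draws: np.ndarray           # shape (chains, draws_per_chain, ndim)
    rhat: np.ndarray            # per-parameter split R-hat
    acceptance_fraction: float

    @property
    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    @property
    def max_rhat(self) -> float:
        return float(np.max(self.rhat))


def split_rhat(chain_draws: np.ndarray) -> np.ndarray:
    """Rank-normalized split R-hat per parameter.

    ``chain_draws`` has shape (chain, draw, ndim).  Delegates to arviz.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        import arviz as az

        return np.array(
            [float(az.rhat(np.ascontiguousarray(chain_draws[:, :, j])))
             for j in range(chain_draws.shape[-1])]
        )


def run_ensemble(
    log_prob: Callable[[np.ndarray], np.ndarray],
    init: np.ndarray,
    *,
    draws: int,
    tune: int,
    chains: int,
    seed: int,
    thin: int = THIN,
) -> EnsembleResult:
    """Sample a vectorized log-posterior with an affine-invariant ensemble.

    Parameters
    ----------
    log_prob
        Maps a (nwalkers, ndim) array to (nwalkers,) log densities
        (``-inf`` outside the support).
    init
        (nwalkers, ndim) starting positions inside the support, with
        ``nwalkers = chains * WALKERS_PER_CHAIN``.
    draws
        Retained draws per chain after burn-in.
    tune
        Burn-in (discarded) ensemble steps.
    seed
        Seeds emcee's internal RandomState; runs are reproducible.
    """
    nwalkers, ndim = init.shape
    if nwalkers != chains * WALKERS_PER_CHAIN:
        raise ValueError(f"init must have {chains * WALKERS_PER_CHAIN} walkers, got {nwalkers}")
    lp0 = log_prob(init)
    if not np.all(np.isfinite(lp0)):
        raise ValueError("all initial walker positions must have finite posterior density")

    sampler = emcee.EnsembleSampler(
        nwalkers, ndim, log_prob, vectorize=True, moves=_default_moves()
    )
    sampler._random = np.random.RandomState(seed & 0x7FFFFFFF)
    steps_post = -(-draws // WALKERS_PER_CHAIN)  # ceil
    sampler.run_mcmc(
        init, tune + steps_post * thin, progress=False, skip_initial_state_check=True
    )

    # (step, walker, ndim) -> per chain: flatten its walkers into the draw axis
    chain_tail = sampler.get_chain(discard=tune, thin=thin)
    per_chain = []
    for c in range(chains):
        block = chain_tail[:, c * WALKERS_PER_CHAIN:(c + 1) * WALKERS_PER_CHAIN, :]
        per_chain.append(block.reshape(-1, ndim)[:draws])
    arranged = np.stack(per_chain)  # (chains, draws, ndim)
    rhat = split_rhat(arranged)
    return EnsembleResult(
        draws=arranged,
        rhat=rhat,
        acceptance_fraction=float(np.mean(sampler.acceptance_fraction)),
    )
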