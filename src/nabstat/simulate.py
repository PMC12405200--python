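"""Synthetic neutralization curves with multiplicative log-normal noise.

Luminescence-assay variability scales with signal intensity, so noise is
modeled as multiplicative and log-normal: each observation is the Hill
prediction times ``exp(eps)`` with ``eps ~ Normal(0, sigma_ln)``.  The
noise is median-preserving (no ``-sigma^2/2`` mean correction): the
noiseless curve is the central tendency on the log scale, which is where
the Hill-MCMC likelihood operates.

The coefficient of variation maps to the log-space standard deviation
through the exact log-normal relation ``sigma_ln = sqrt(ln(1 + cv^2))``
rather than the small-CV approximation ``sigma ~ cv``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import Dilution, HillParams, NeutralizationCurve, hill_predict

__all__ = [
    "NoiseModel",
    "SimulationDesign",
    "simulate_curve",
    "simulate_ensemble",
    "TWOFOLD_SERIES",
]


def twofold_series(n_steps: int = 7, start: float = 0.25) -> list[Dilution]:
    """The assay's standard dilution ladder: ``start, start/2, ...``.

    Defaults reproduce the 7-step series 1/4 ... 1/256 delivered to cells.
    """
    return [Dilution(start / 2**k) for k in range(n_steps)]


#: The protocol's standard 7-step two-fold series, 1/4 down to 1/256.
TWOFOLD_SERIES: list[Dilution] = twofold_series()


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative log-normal noise at a stated coefficient of variation."""

    cv: float
    sigma_ln: float = field(init=False)

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError(f"cv must be >= 0, got {self.cv}")
        object.__setattr__(self, "sigma_ln", math.sqrt(math.log1p(self.cv**2)))


@dataclass(frozen=True)
class SimulationDesign:
    """Full specification of a simulation study.

    ``n_curves`` independent curves, each with ``n_replicates`` technical
    replicates at every dilution, generated from the true Hill parameters
    under the given noise model.
    """

    truth: HillParams
    dilutions: Sequence[Dilution]
    noise: NoiseModel
    n_replicates: int = 3
    n_curves: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_curves < 1:
            raise ValueError("n_curves must be >= 1")


def curve_seed(master_seed: int, curve_index: int) -> np.random.SeedSequence:
    """Deterministic per-curve seed, stable across runs and platforms.

    Implemented as ``SeedSequence(master, spawn_key=(index,))`` so that
    curve ``i`` of ensemble ``s`` always sees the same stream regardless
    of how many curves are drawn before it.
    """
    return np.random.SeedSequence(master_seed, spawn_key=(curve_index,))


def simulate_curve(
    truth: HillParams,
    dilutions: Sequence[Dilution | float],
    n_replicates: int,
    noise: NoiseModel,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    sample_id: str = "sim",
) -> NeutralizationCurve:
    """Draw one noisy neutralization curve from the Hill model.

    Each observation is ``hill_predict(truth, d) * exp(eps)`` with i.i.d.
    ``eps ~ Normal(0, noise.sigma_ln)``; deterministic given the seed.
    """
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(seed)
    dils = [d if isinstance(d, Dilution) else Dilution(float(d)) for d in dilutions]
    dils = sorted(dils, key=lambda d: -d.fraction)
    te = []
    for d in dils:
        mu = hill_predict(truth, d)
        eps = rng.normal(0.0, noise.sigma_ln, size=n_replicates)
        te.append(mu * np.exp(eps))
    meta = {"truth_midpoint": truth.midpoint, "truth_slope": truth.slope,
            "truth_bottom": truth.bottom, "cv": noise.cv}
    return NeutralizationCurve(dils, te, sample_id=sample_id, metadata=meta)


def simulate_ensemble(design: SimulationDesign) -> list[NeutralizationCurve]:
    """Independent curves with per-curve seeds derived from the master seed."""
    curves = []
    for i in range(design.n_curves):
        rng = np.random.default_rng(curve_seed(design.seed, i))
        curves.append(
            simulate_curve(
                design.truth,
                design.dilutions,
                design.n_replicates,
                design.noise,
                seed=rng,
                sample_id=f"sim{i:03d}",
            )
        )
    return curves
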