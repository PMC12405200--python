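"""Core domain types and the Hill dose-response model.

The assay measures transduction efficiency (TE) — reporter signal
normalized so that the antibody-free control averages 1 — as a function
of serum concentration, expressed as a volume fraction in (0, 1]
(1/16 dilution = fraction 0.0625).  Neutralizing serum suppresses
transduction, so TE decreases as the fraction grows.

The dose-response model is a four-parameter logistic (Hill) curve with
the top asymptote fixed at 1 by the normalization convention:

    TE(x) = b + (1 - b) / (1 + (x / K)^h)

with midpoint ``K > 0``, Hill coefficient ``h > 0`` and lower asymptote
``0 <= b < 1``.  The ND50 is defined as the serum fraction at which TE
crosses the absolute level 0.5 (half the antibody-free control), which
coincides with ``K`` only when ``b = 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

from .errors import AsymptoteAboveHalfError, CurveError

__all__ = [
    "Dilution",
    "NeutralizationCurve",
    "HillParams",
    "hill_predict",
    "nd50_from_params",
]


@dataclass(frozen=True)
class Dilution:
    """A serum dilution expressed as a volume fraction in (0, 1].

    Attributes
    ----------
    fraction
        Serum volume fraction; 1/16 dilution -> 0.0625.
    log2_value
        ``log2(fraction)``, derived; all interval arithmetic in this
        package happens on this scale.
    """

    fraction: float
    log2_value: float = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError(f"dilution fraction must be in (0, 1], got {self.fraction}")
        object.__setattr__(self, "log2_value", math.log2(self.fraction))

    @classmethod
    def from_log2(cls, log2_value: float) -> "Dilution":
        return cls(fraction=2.0**log2_value)

    def __repr__(self) -> str:  # 1/16 reads better than 0.0625
        inv = 1.0 / self.fraction
        if abs(inv - round(inv)) < 1e-9:
            return f"Dilution(1/{round(inv)})"
        return f"Dilution({self.fraction:g})"


def _as_dilution(d: "Dilution | float") -> Dilution:
    return d if isinstance(d, Dilution) else Dilution(float(d))


@dataclass(frozen=True)
class HillParams:
    """Hill-curve parameters (top asymptote fixed at 1).

    midpoint ``K``: fraction at which the curve is halfway between its own
    asymptotes; slope ``h``: Hill coefficient; bottom ``b``: lower asymptote.
    """

    midpoint: float
    slope: float = 1.0
    bottom: float = 0.0

    def __post_init__(self) -> None:
        if self.midpoint <= 0:
            raise ValueError(f"midpoint must be > 0, got {self.midpoint}")
        if self.slope <= 0:
            raise ValueError(f"slope must be > 0, got {self.slope}")
        if not (0.0 <= self.bottom < 1.0):
            raise ValueError(f"bottom must be in [0, 1), got {self.bottom}")


class NeutralizationCurve:
    """Observed neutralization curve: ordered dilutions with replicate TEs.

    Dilutions are stored with *strictly decreasing* serum fraction (most
    concentrated first, following the plate's top-to-bottom dilution
    order reversed); each dilution carries one or more technical-replicate
    transduction efficiencies.  Replicate counts may differ between
    dilutions, so the replicate table is a list of 1-D arrays rather than
    a rectangular matrix.
    """

    def __init__(
        self,
        dilutions: Sequence[Dilution | float],
        te: Sequence[Sequence[float]],
        sample_id: str = "",
        metadata: Mapping[str, Any] | None = None,
    ) -> None:
        dils = [_as_dilution(d) for d in dilutions]
        if len(dils) < 2:
            raise CurveError("a neutralization curve needs >= 2 dilutions")
        fracs = [d.fraction for d in dils]
        if any(b >= a for a, b in zip(fracs, fracs[1:])):
            raise CurveError("dilution fractions must be strictly decreasing (most concentrated first)")
        if len(te) != len(dils):
            raise CurveError(f"te has {len(te)} rows for {len(dils)} dilutions")
        rows = []
        for i, row in enumerate(te):
            arr = np.atleast_1d(np.asarray(row, dtype=float))
            if arr.size < 1:
                raise CurveError(f"dilution index {i} has no replicates")
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise CurveError(f"te values must be finite and >= 0 (dilution index {i})")
            rows.append(arr)
        self.dilutions: list[Dilution] = dils
        self.te: list[np.ndarray] = rows
        self.sample_id = sample_id
        self.metadata: dict[str, Any] = dict(metadata or {})

    def __len__(self) -> int:
        return len(self.dilutions)

    @property
    def fractions(self) -> np.ndarray:
        return np.array([d.fraction for d in self.dilutions])

    @property
    def log2_fractions(self) -> np.ndarray:
        return np.array([d.log2_value for d in self.dilutions])

    def replicate_means(self) -> np.ndarray:
        """Per-dilution mean TE, in stored (most concentrated first) order."""
        return np.array([row.mean() for row in self.te])

    def n_replicates(self) -> list[int]:
        return [row.size for row in self.te]

    def __repr__(self) -> str:
        reps = self.n_replicates()
        return (
            f"NeutralizationCurve(sample_id={self.sample_id!r}, "
            f"n_dilutions={len(self)}, replicates={min(reps)}-{max(reps)})"
        )


def hill_predict(params: HillParams, dilution: Dilution | float | np.ndarray) -> float | np.ndarray:
    """Transduction efficiency predicted by the Hill model at a dilution.

    Decreasing in the serum fraction: TE -> 1 as the fraction -> 0 and
    TE -> ``bottom`` as the fraction grows.
    """
    if isinstance(dilution, Dilution):
        x = dilution.fraction
    else:
        x = np.asarray(dilution, dtype=float) if np.ndim(dilution) else float(dilution)
    b, k, h = params.bottom, params.midpoint, params.slope
    return b + (1.0 - b) / (1.0 + (x / k) ** h)


def nd50_from_params(params: HillParams) -> Dilution:
    """Serum fraction at which the Hill curve crosses TE = 0.5.

    Solving ``b + (1-b)/(1+(x/K)^h) = 1/2`` gives the closed form

        ND50 = K * (0.5 / (0.5 - b)) ** (1/h)

    which reduces to ``K`` when ``b = 0``.  A curve whose lower asymptote
    is at or above 0.5 never reaches half the antibody-free control.
    """
    b = params.bottom
    if b >= 0.5:
        raise AsymptoteAboveHalfError(
            f"bottom asymptote {b} >= 0.5: the curve never crosses 50% transduction"
        )
    if b == 0.0:
        return Dilution(params.midpoint)
    frac = params.midpoint * (0.5 / (0.5 - b)) ** (1.0 / params.slope)
    if frac > 1.0:
        raise AsymptoteAboveHalfError(
            f"the 50% crossing ({frac:.3g}) lies beyond undiluted serum "
            "(fraction 1); no attainable ND50 for these parameters"
        )
    return Dilution(frac)
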