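"""Assay-design arithmetic: dilution schedule and reagent volumes.

The protocol runs a 7-step two-fold serum dilution series down a plate
column (rows A-G; row H is the antibody-free control), then adds an
equal volume of AAV mix, which halves every serum concentration once
more: well A1 ends at a final 1/4 dilution, B1 at 1/8, ..., G1 at 1/256.

Each dilution series consumes 10 uL of serum per replicate plus one
spare ("n + 1") to absorb pipetting loss, so the working unit volume is
``(n + 1) * 10`` uL.  All planner outputs are exact rationals
(:class:`fractions.Fraction`); rounding happens only in display views.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import pandas as pd

__all__ = [
    "serum_volume",
    "aav_volume_per_well",
    "AavDose",
    "aav_mix_total",
    "MixRequirement",
    "dilution_schedule",
    "DilutionStep",
    "PlatePlan",
    "plan_plate",
    "dilution_table",
    "layout_skeleton",
]

MAX_STEPS = 7  # rows A-G; row H is reserved for the antibody-free control


def serum_volume(n_replicates: int) -> int:
    """Serum needed for one dilution series, in uL: ``(n + 1) * 10``."""
    if not isinstance(n_replicates, int) or n_replicates < 1:
        raise ValueError(f"n_replicates must be an integer >= 1, got {n_replicates}")
    return (n_replicates + 1) * 10


@dataclass(frozen=True)
class AavDose:
    """Per-well viral dose: pipetting volume and genome count."""

    volume_ul: float
    vg_per_well: float


def aav_volume_per_well(moi: float, total_cells: float, titer_vg_per_ml: float) -> AavDose:
    """Volume of AAV stock per well: ``MOI * cells / titer * 1000`` uL."""
    if min(moi, total_cells, titer_vg_per_ml) <= 0:
        raise ValueError("moi, total_cells and titer must all be > 0")
    vg = moi * total_cells
    return AavDose(volume_ul=vg / titer_vg_per_ml * 1000.0, vg_per_well=vg)


@dataclass(frozen=True)
class MixRequirement:
    """AAV-mix volumes in uL for the dilution series and the control wells."""

    total_ul: int
    control_ul: int


def aav_mix_total(n_dilution_steps: int, n_replicates: int) -> MixRequirement:
    """AAV mix for the series (``steps * (n+1) * 10``) plus controls (``(n+1) * 10``)."""
    if not isinstance(n_dilution_steps, int) or n_dilution_steps < 1:
        raise ValueError(f"n_dilution_steps must be an integer >= 1, got {n_dilution_steps}")
    unit = serum_volume(n_replicates)  # same (n+1)*10 unit volume
    return MixRequirement(total_ul=n_dilution_steps * unit, control_ul=unit)


@dataclass(frozen=True)
class DilutionStep:
    """One row of the schedule: serial dilution, then final after AAV mix."""

    step: int                 # 1-based; row A = 1
    row: str
    serial_dilution: Fraction
    final_dilution: Fraction


def dilution_schedule(n_steps: int = MAX_STEPS) -> list[DilutionStep]:
    """Two-fold schedule for rows A.. : step k gives serial 1/2^k, final 1/2^(k+1)."""
    if not isinstance(n_steps, int) or not (1 <= n_steps <= MAX_STEPS):
        raise ValueError(
            f"n_steps must be an integer in [1, {MAX_STEPS}] (row H is the control row), "
            f"got {n_steps}"
        )
    return [
        DilutionStep(
            step=k,
            row="ABCDEFG"[k - 1],
            serial_dilution=Fraction(1, 2**k),
            final_dilution=Fraction(1, 2 ** (k + 1)),
        )
        for k in range(1, n_steps + 1)
    ]


@dataclass(frozen=True)
class PlatePlan:
    """Complete reagent plan for one serum sample."""

    n_replicates: int
    n_dilution_steps: int
    serum_volume_ul: int
    aav_volume_per_well_ul: float
    vg_per_well: float
    aav_mix_total_ul: int
    control_mix_ul: int
    schedule: tuple[DilutionStep, ...]


def plan_plate(
    n_replicates: int = 3,
    n_steps: int = MAX_STEPS,
    moi: float = 100.0,
    total_cells: float = 1e5,
    titer_vg_per_ml: float = 1e10,
) -> PlatePlan:
    """Assemble the full plan from the individual volume formulas."""
    dose = aav_volume_per_well(moi, total_cells, titer_vg_per_ml)
    mix = aav_mix_total(n_steps, n_replicates)
    return PlatePlan(
        n_replicates=n_replicates,
        n_dilution_steps=n_steps,
        serum_volume_ul=serum_volume(n_replicates),
        aav_volume_per_well_ul=dose.volume_ul,
        vg_per_well=dose.vg_per_well,
        aav_mix_total_ul=mix.total_ul,
        control_mix_ul=mix.control_ul,
        schedule=tuple(dilution_schedule(n_steps)),
    )


def dilution_table(n_replicates: int = 3, n_steps: int = MAX_STEPS) -> pd.DataFrame:
    """Exact per-well volume/dilution grid of the serial-dilution procedure.

    Columns mirror the bench worksheet: composition during the dilution
    process (before 1 unit volume is transferred onward), composition
    after the transfer, the serial serum dilution, and the transduction
    mix (serum retained + AAV mix) with the final dilution.  The last
    row is the antibody-free control.  All entries are exact
    :class:`~fractions.Fraction` values in uL; apply
    ``df.map(float)``/rounding only for display.
    """
    v = Fraction(serum_volume(n_replicates))  # unit volume, 40 uL at n=3
    rows = []
    for st in dilution_schedule(n_steps):
        serum_during = 2 * v * st.serial_dilution
        rows.append(
            {
                "well": f"{st.row}1",
                "during_fbs_diluent": v,
                "during_fbs_prev": (v - serum_during) if st.step > 1 else Fraction(0),
                "during_serum": serum_during,
                "during_total": 2 * v,
                "final_fbs_diluent": v / 2,
                "final_fbs_prev": ((v - serum_during) / 2) if st.step > 1 else Fraction(0),
                "final_serum": serum_during / 2,
                "final_total": v,
                "serial_dilution": st.serial_dilution,
                "mix_serum": serum_during / 2,
                "mix_aav": v,
                "final_dilution": st.final_dilution,
            }
        )
    # antibody-free control row (FBS only + AAV mix)
    rows.append(
        {
            "well": "H1",
            "during_fbs_diluent": v,
            "during_fbs_prev": Fraction(0),
            "during_serum": Fraction(0),
            "during_total": v,
            "final_fbs_diluent": v / 2,
            "final_fbs_prev": Fraction(0),
            "final_serum": Fraction(0),
            "final_total": v / 2,
            "serial_dilution": Fraction(0),
            "mix_serum": Fraction(0),
            "mix_aav": v,
            "final_dilution": Fraction(0),
        }
    )
    return pd.DataFrame(rows).set_index("well")


def worksheet_display(df: pd.DataFrame) -> pd.DataFrame:
    """Bench-sheet view of :func:`dilution_table`: floats rounded to two
    decimals with the half-up convention (0.625 uL prints as 0.63)."""
    from decimal import ROUND_HALF_UP, Decimal

    def _round(v):
        if isinstance(v, Fraction):
            d = Decimal(v.numerator) / Decimal(v.denominator)
            return float(d.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
        return v

    return df.map(_round)


def layout_skeleton(
    sample_ids: Sequence[str],
    n_replicates: int = 3,
    n_steps: int = MAX_STEPS,
    data_path: str = "plate.csv",
    measurement_date: str = "",
    plate_params: dict | None = None,
):
    """Plate layout matching the planned schedule, consumable by plate I/O.

    Each sample occupies ``n_replicates`` adjacent columns; dilutions
    run down rows A.., and row H carries the antibody-free (first
    sample's columns) and background (next columns) controls in
    triplicate.
    """
    from .plate import PlateLayoutSpec

    if not sample_ids:
        raise ValueError("need >= 1 sample id")
    if len(sample_ids) * n_replicates > 12:
        raise ValueError("samples x replicates exceeds 12 plate columns")
    sched = dilution_schedule(n_steps)
    sample_wells: dict[str, tuple[str, float, int]] = {}
    for s, sid in enumerate(sample_ids):
        cols = range(s * n_replicates + 1, (s + 1) * n_replicates + 1)
        for st in sched:
            for rep, col in enumerate(cols):
                sample_wells[f"{st.row}{col}"] = (str(sid), float(st.final_dilution), rep)
    ab_free = [f"H{j}" for j in range(1, 4)]
    background = [f"H{j}" for j in range(4, 7)]
    return PlateLayoutSpec(
        data_path=data_path,
        measurement_date=measurement_date,
        plate_params=dict(plate_params or {"moi": 100, "cell_number": 100000}),
        sample_wells=sample_wells,
        antibody_free_wells=ab_free,
        background_wells=background,
    )
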