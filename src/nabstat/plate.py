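"""Plate-reader exports, TOML layout metadata, and TE normalization.

A 96-well assay run produces (a) a raw luminescence export from the
plate reader — either an 8x12 labeled grid or a long ``well,rlu`` table,
CSV or XLSX — and (b) a TOML layout file recording where each serum
sample, dilution and control sits on the plate.  Aggregator TOML files
group several layouts for batch analysis.

Raw relative light units (RLU) are converted to transduction efficiency
by the standard assay convention

    TE(well) = (RLU(well) - mean_bg) / (mean_abfree - mean_bg)

where the background mean comes from the virus-free wells and the
antibody-free mean from the serum-free (virus-only) wells, so the
antibody-free wells average to TE = 1 by construction.  Negative
background-subtracted values are clipped (to a small positive floor so
the log-scale likelihood stays defined) and counted.

The TOML schema is versioned (``schema_version``) and deliberately
minimal::

    schema_version = 1
    data_path = "plate.csv"
    measurement_date = "2025-06-01"

    [plate_params]
    cell_number = 100000
    moi = 100
    serotype = "AAV9"

    [samples.serum01]
    dilutions = [0.25, 0.125, 0.0625]
    wells = [["A1", "A2", "A3"], ["B1", "B2", "B3"], ["C1", "C2", "C3"]]

    [controls]
    antibody_free = ["H1", "H2", "H3"]
    background = ["H4", "H5", "H6"]
"""

from __future__ import annotations

import csv
import re
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np

from .errors import NoSignalError, PlateError
from .model import Dilution, NeutralizationCurve

__all__ = [
    "RawPlate",
    "PlateLayoutSpec",
    "read_plate_export",
    "read_layout_toml",
    "read_aggregator_toml",
    "write_layout_toml",
    "write_plate_csv",
    "normalize",
    "te_map",
    "write_curves_csv",
    "read_curves_csv",
]

ROWS = "ABCDEFGH"
N_COLS = 12
_WELL_RE = re.compile(r"^([A-H])([1-9]|1[0-2])$")
#: floor applied to clipped TEs so downstream log-transforms stay defined
TE_FLOOR = 1e-6


def _check_well(well: str) -> str:
    w = well.strip().upper()
    if not _WELL_RE.match(w):
        raise PlateError(f"malformed well id {well!r} (expected A1..H12)")
    return w


@dataclass
class RawPlate:
    """Raw plate-reader readings: well id -> RLU."""

    readings: dict[str, float]
    source_path: str = ""
    read_date: str = ""

    def __post_init__(self) -> None:
        checked: dict[str, float] = {}
        for well, rlu in self.readings.items():
            w = _check_well(well)
            if w in checked:
                raise PlateError(f"duplicate well {w!r}")
            rlu = float(rlu)
            if not np.isfinite(rlu) or rlu < 0:
                raise PlateError(f"well {w!r}: RLU must be finite and >= 0, got {rlu}")
            checked[w] = rlu
        self.readings = checked

    def __getitem__(self, well: str) -> float:
        return self.readings[_check_well(well)]


@dataclass
class PlateLayoutSpec:
    """Layout metadata of one serum sample file (possibly several samples).

    ``sample_wells`` maps each sample well to
    (sample_id, dilution fraction, replicate index).
    """

    data_path: str
    measurement_date: str
    plate_params: dict[str, Any]
    sample_wells: dict[str, tuple[str, float, int]]
    antibody_free_wells: list[str]
    background_wells: list[str]
    schema_version: int = 1
    source_path: str = ""

    def __post_init__(self) -> None:
        if not self.antibody_free_wells or not self.background_wells:
            raise PlateError("control lists must be non-empty")
        roles: dict[str, str] = {}
        for w, (sid, frac, _rep) in self.sample_wells.items():
            w = _check_well(w)
            if not (0.0 < frac <= 1.0):
                raise PlateError(f"well {w}: dilution fraction {frac} outside (0, 1]")
            roles[w] = f"sample:{sid}"
        for role, wells in (
            ("antibody_free", self.antibody_free_wells),
            ("background", self.background_wells),
        ):
            for w in wells:
                w = _check_well(w)
                if w in roles:
                    raise PlateError(
                        f"well {w} assigned two roles ({roles[w]} and {role})"
                    )
                roles[w] = role

    def sample_ids(self) -> list[str]:
        seen: list[str] = []
        for sid, _f, _r in self.sample_wells.values():
            if sid not in seen:
                seen.append(sid)
        return seen


# ---------------------------------------------------------------------------
# raw exports


def _grid_from_rows(rows: list[list[Any]], path: str) -> dict[str, float]:
    # drop a header row of column numbers if present
    body = [r for r in rows if r and str(r[0]).strip().upper() in set(ROWS)]
    if len(body) != 8:
        raise PlateError(
            f"{path}: grid dialect expects 8 rows labeled A-H, found {len(body)}"
        )
    readings: dict[str, float] = {}
    for r in body:
        label = str(r[0]).strip().upper()
        vals = [v for v in r[1:] if str(v).strip() != ""]
        if len(vals) != N_COLS:
            raise PlateError(
                f"{path}: row {label} has {len(vals)} values, expected {N_COLS}"
            )
        for j, v in enumerate(vals, start=1):
            try:
                readings[f"{label}{j}"] = float(v)
            except (TypeError, ValueError):
                raise PlateError(f"{path}: non-numeric RLU {v!r} in well {label}{j}")
    return readings


def read_plate_export(path: str | Path, dialect: str = "grid") -> RawPlate:
    """Read a plate-reader export (CSV or XLSX) into a :class:`RawPlate`.

    ``grid``: 8 rows labeled A-H by 12 columns (a numeric header row is
    tolerated).  ``long``: two columns ``well,rlu`` (header optional).
    """
    path = Path(path)
    if dialect not in ("grid", "long"):
        raise ValueError(f"dialect must be 'grid' or 'long', got {dialect!r}")
    if path.suffix.lower() in (".xlsx", ".xls"):
        import pandas as pd

        frame = pd.read_excel(path, header=None)
        rows = frame.fillna("").values.tolist()
    else:
        with open(path, newline="") as fh:
            rows = [r for r in csv.reader(fh) if any(c.strip() for c in r)]

    if dialect == "grid":
        readings = _grid_from_rows(rows, str(path))
    else:
        readings = {}
        for r in rows:
            if len(r) < 2:
                raise PlateError(f"{path}: long dialect needs well,rlu columns")
            w = str(r[0]).strip()
            if w.lower() in ("well", ""):  # header row
                continue
            w = _check_well(w)
            if w in readings:
                raise PlateError(f"{path}: duplicate well {w}")
            try:
                readings[w] = float(r[1])
            except (TypeError, ValueError):
                raise PlateError(f"{path}: non-numeric RLU {r[1]!r} for well {w}")
    return RawPlate(readings=readings, source_path=str(path))


def write_plate_csv(plate: RawPlate | Mapping[str, float], path: str | Path,
                    dialect: str = "grid") -> None:
    """Write readings back out as CSV (grid dialect needs all 96 wells)."""
    readings = plate.readings if isinstance(plate, RawPlate) else dict(plate)
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        if dialect == "grid":
            writer.writerow([""] + [str(j) for j in range(1, N_COLS + 1)])
            for row in ROWS:
                out = [row]
                for j in range(1, N_COLS + 1):
                    well = f"{row}{j}"
                    if well not in readings:
                        raise PlateError(f"grid output needs well {well}")
                    out.append(repr(readings[well]))
                writer.writerow(out)
        elif dialect == "long":
            writer.writerow(["well", "rlu"])
            for well in sorted(readings, key=lambda w: (w[0], int(w[1:]))):
                writer.writerow([well, repr(readings[well])])
        else:
            raise ValueError(f"dialect must be 'grid' or 'long', got {dialect!r}")


# ---------------------------------------------------------------------------
# layout TOML


def _require(section: Mapping[str, Any], key: str, path: str) -> Any:
    if key not in section:
        raise PlateError(f"{path}: missing required section/key {key!r}")
    return section[key]


def read_layout_toml(path: str | Path) -> PlateLayoutSpec:
    """Parse a per-sample layout TOML file into a :class:`PlateLayoutSpec`."""
    path = Path(path)
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    data_path = str(_require(doc, "data_path", str(path)))
    date = str(_require(doc, "measurement_date", str(path)))
    plate_params = dict(_require(doc, "plate_params", str(path)))
    samples = _require(doc, "samples", str(path))
    controls = _require(doc, "controls", str(path))
    if not isinstance(samples, Mapping) or not samples:
        raise PlateError(f"{path}: [samples] must define >= 1 sample")

    sample_wells: dict[str, tuple[str, float, int]] = {}
    for sid, spec in samples.items():
        dils = _require(spec, "dilutions", f"{path}:[samples.{sid}]")
        wells = _require(spec, "wells", f"{path}:[samples.{sid}]")
        if len(dils) != len(wells):
            raise PlateError(
                f"{path}: sample {sid!r} has {len(dils)} dilutions but "
                f"{len(wells)} well rows"
            )
        for frac, row in zip(dils, wells):
            for rep, w in enumerate(row):
                w = _check_well(str(w))
                if w in sample_wells:
                    raise PlateError(f"{path}: well {w} listed twice")
                sample_wells[w] = (str(sid), float(frac), rep)

    ab_free = [_check_well(str(w)) for w in _require(controls, "antibody_free", f"{path}:[controls]")]
    background = [_check_well(str(w)) for w in _require(controls, "background", f"{path}:[controls]")]
    # resolve the data path relative to the layout file
    dp = Path(data_path)
    if not dp.is_absolute():
        dp = path.parent / dp
    return PlateLayoutSpec(
        data_path=str(dp),
        measurement_date=date,
        plate_params=plate_params,
        sample_wells=sample_wells,
        antibody_free_wells=ab_free,
        background_wells=background,
        schema_version=int(doc.get("schema_version", 1)),
        source_path=str(path),
    )


def _toml_value(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v).__name__} to TOML")


def write_layout_toml(spec: PlateLayoutSpec, path: str | Path) -> None:
    """Serialize a layout spec back to the versioned TOML schema."""
    # regroup sample_wells into per-sample dilution rows
    per_sample: dict[str, dict[float, list[tuple[int, str]]]] = {}
    for w, (sid, frac, rep) in spec.sample_wells.items():
        per_sample.setdefault(sid, {}).setdefault(frac, []).append((rep, w))
    lines = [
        f"schema_version = {spec.schema_version}",
        f"data_path = {_toml_value(spec.data_path)}",
        f"measurement_date = {_toml_value(spec.measurement_date)}",
        "",
        "[plate_params]",
    ]
    for k, v in spec.plate_params.items():
        lines.append(f"{k} = {_toml_value(v)}")
    for sid, by_frac in per_sample.items():
        fracs = sorted(by_frac, reverse=True)
        wells = [[w for _r, w in sorted(by_frac[f])] for f in fracs]
        lines += ["", f"[samples.{sid}]",
                  f"dilutions = {_toml_value(fracs)}",
                  f"wells = {_toml_value(wells)}"]
    lines += ["", "[controls]",
              f"antibody_free = {_toml_value(spec.antibody_free_wells)}",
              f"background = {_toml_value(spec.background_wells)}", ""]
    Path(path).write_text("\n".join(lines))


def read_aggregator_toml(path: str | Path) -> list[PlateLayoutSpec]:
    """Parse an aggregator TOML listing member layout files.

    Schema: ``layouts = ["a.toml", "b.toml"]``; relative member paths
    resolve against the aggregator's own directory.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    members = _require(doc, "layouts", str(path))
    if not members:
        raise PlateError(f"{path}: aggregator lists no layouts")
    specs = []
    for member in members:
        member_path = Path(member)
        if not member_path.is_absolute():
            member_path = path.parent / member_path
        try:
            specs.append(read_layout_toml(member_path))
        except Exception as exc:
            raise PlateError(f"{path}: failed to parse member {member_path}: {exc}") from exc
    return specs


# ---------------------------------------------------------------------------
# normalization


def _control_means(raw: RawPlate, layout: PlateLayoutSpec) -> tuple[float, float]:
    for w in list(layout.sample_wells) + layout.antibody_free_wells + layout.background_wells:
        if w not in raw.readings:
            raise PlateError(f"layout well {w} missing from the plate export")
    mean_bg = float(np.mean([raw[w] for w in layout.background_wells]))
    mean_free = float(np.mean([raw[w] for w in layout.antibody_free_wells]))
    if mean_free <= mean_bg:
        raise NoSignalError(
            f"antibody-free mean {mean_free} <= background mean {mean_bg}: no signal"
        )
    return mean_bg, mean_free


def te_map(raw: RawPlate, layout: PlateLayoutSpec) -> dict[str, float]:
    """Unclipped TE for every sample and control well on the layout."""
    mean_bg, mean_free = _control_means(raw, layout)
    span = mean_free - mean_bg
    wells = list(layout.sample_wells) + layout.antibody_free_wells + layout.background_wells
    return {w: (raw[w] - mean_bg) / span for w in wells}


def normalize(raw: RawPlate, layout: PlateLayoutSpec) -> dict[str, NeutralizationCurve]:
    """Per-sample neutralization curves from a raw plate and its layout.

    Negative TEs (readings below the background mean) are clipped to a
    small positive floor and counted per sample in the curve metadata.
    """
    mean_bg, mean_free = _control_means(raw, layout)
    span = mean_free - mean_bg
    curves: dict[str, NeutralizationCurve] = {}
    for sid in layout.sample_ids():
        by_frac: dict[float, list[tuple[int, float]]] = {}
        clipped = []
        for w, (s, frac, rep) in layout.sample_wells.items():
            if s != sid:
                continue
            te = (raw[w] - mean_bg) / span
            if te < 0:
                clipped.append(w)
                te = TE_FLOOR
            by_frac.setdefault(frac, []).append((rep, te))
        fracs = sorted(by_frac, reverse=True)
        te_rows = [[v for _r, v in sorted(by_frac[f])] for f in fracs]
        meta = dict(layout.plate_params)
        meta.update(
            measurement_date=layout.measurement_date,
            clipped_wells=clipped,
            mean_background=mean_bg,
            mean_antibody_free=mean_free,
        )
        curves[sid] = NeutralizationCurve(
            [Dilution(f) for f in fracs], te_rows, sample_id=sid, metadata=meta
        )
    return curves


# ---------------------------------------------------------------------------
# long-format curve CSV (sample_id, dilution_fraction, replicate, te)


def write_curves_csv(curves: Iterable[NeutralizationCurve], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "dilution_fraction", "replicate", "te"])
        for c in curves:
            for d, row in zip(c.dilutions, c.te):
                for rep, v in enumerate(row):
                    writer.writerow([c.sample_id, repr(d.fraction), rep, repr(float(v))])


def read_curves_csv(path: str | Path) -> list[NeutralizationCurve]:
    by_sample: dict[str, dict[float, list[tuple[int, float]]]] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        needed = {"sample_id", "dilution_fraction", "replicate", "te"}
        if reader.fieldnames is None or not needed.issubset(reader.fieldnames):
            raise PlateError(f"{path}: curve CSV needs columns {sorted(needed)}")
        for rec in reader:
            sid = rec["sample_id"]
            if sid not in by_sample:
                by_sample[sid] = {}
                order.append(sid)
            by_sample[sid].setdefault(float(rec["dilution_fraction"]), []).append(
                (int(rec["replicate"]), float(rec["te"]))
            )
    curves = []
    for sid in order:
        fracs = sorted(by_sample[sid], reverse=True)
        te = [[v for _r, v in sorted(by_sample[sid][f])] for f in fracs]
        curves.append(NeutralizationCurve(fracs, te, sample_id=sid))
    return curves
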