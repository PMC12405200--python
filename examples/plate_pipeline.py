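"""From plate-reader export to neutralization curves.

Builds a synthetic 96-well luminescence export (one serum in triplicate
columns, antibody-free and background controls in row H), documents it
with a TOML layout file, then runs the normalization pipeline:
TE = (RLU - background mean) / (antibody-free mean - background mean).
"""

import tempfile
from pathlib import Path

from nabstat import (
    HillParams,
    RawPlate,
    hill_predict,
    normalize,
    read_layout_toml,
    read_plate_export,
)
from nabstat.plate import write_layout_toml, write_plate_csv
from nabstat.planner import layout_skeleton

workdir = Path(tempfile.mkdtemp())

# --- fabricate a plate for a serum with true ND50 = 1/16 ------------------
truth = HillParams(1 / 16)
layout = layout_skeleton(["serum01"], n_replicates=3, n_steps=7,
                         data_path="plate.csv", measurement_date="2025-06-01",
                         plate_params={"moi": 100, "cell_number": 100_000,
                                       "serotype": "AAV9"})
background, window = 150.0, 95_000.0  # RLU floor and assay window
readings = {f"{row}{col}": background for row in "ABCDEFGH" for col in range(1, 13)}
for well, (_sid, fraction, _rep) in layout.sample_wells.items():
    readings[well] = background + window * hill_predict(truth, fraction)
for well in layout.antibody_free_wells:
    readings[well] = background + window
write_plate_csv(RawPlate(readings), workdir / "plate.csv")
write_layout_toml(layout, workdir / "layout.toml")
print(f"wrote {workdir / 'plate.csv'} and layout.toml")

# --- the analysis side: parse, normalize, inspect -------------------------
spec = read_layout_toml(workdir / "layout.toml")
raw = read_plate_export(spec.data_path, dialect="grid")
curves = normalize(raw, spec)

curve = curves["serum01"]
print(f"\n{curve!r}")
print("dilution   mean TE")
for d, row in zip(curve.dilutions, curve.te):
    print(f"{d!r:>14}  {row.mean():.3f}")
print(
    "\nTE = 1 means transduction equal to the antibody-free control; the "
    "mean response\ncrosses 0.5 at the serum's ND50 (here between 1/8 and "
    "1/32, consistent with the\ngenerating 1/16)."
)
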