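import numpy as np
import pytest

from nabstat import (
    NeutralizationCurve,
    PlateLayoutSpec,
    RawPlate,
    hill_predict,
    normalize,
    read_aggregator_toml,
    read_layout_toml,
    read_plate_export,
)
from nabstat.errors import NoSignalError, PlateError
from nabstat.model import HillParams
from nabstat.plate import (
    read_curves_csv,
    te_map,
    write_curves_csv,
    write_layout_toml,
    write_plate_csv,
)
from nabstat.planner import layout_skeleton


def full_plate(value=100.0, **overrides):
    readings = {f"{r}{c}": value for r in "ABCDEFGH" for c in range(1, 13)}
    readings.update(overrides)
    return RawPlate(readings=readings)


@pytest.fixture()
def demo_layout(tmp_path):
    """One sample in triplicate columns 1-3, dilutions 1/4 ... 1/256."""
    return layout_skeleton(
        ["serum01"], n_replicates=3, n_steps=7,
        data_path=str(tmp_path / "plate.csv"), measurement_date="2025-06-01",
    )


class TestRawPlate:
    def test_valid_well_lookup(self):
        p = RawPlate({"a1": 5.0, "H12": 7.0})
        assert p["A1"] == 5.0 and p["H12"] == 7.0

    @pytest.mark.parametrize("well", ["Z9", "A0", "A13", "I1", "AA1"])
    def test_malformed_well_ids(self, well):
        with pytest.raises(PlateError):
            RawPlate({well: 1.0})

    def test_negative_rlu_rejected(self):
        with pytest.raises(PlateError):
            RawPlate({"A1": -5.0})


class TestPlateExports:
    def test_grid_round_trip(self, tmp_path):
        plate = full_plate(100.0, A1=5100.0, H10=123.5)
        path = tmp_path / "grid.csv"
        write_plate_csv(plate, path, dialect="grid")
        back = read_plate_export(path, dialect="grid")
        assert back.readings == plate.readings
        assert len(back.readings) == 96

    def test_long_dialect(self, tmp_path):
        path = tmp_path / "long.csv"
        path.write_text("well,rlu\nA1,5100\nH10,100\n")
        plate = read_plate_export(path, dialect="long")
        assert plate.readings == {"A1": 5100.0, "H10": 100.0}

    def test_long_without_header(self, tmp_path):
        path = tmp_path / "long.csv"
        path.write_text("A1,5100\nH10,100\n")
        assert len(read_plate_export(path, dialect="long").readings) == 2

    def test_long_duplicate_well_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("well,rlu\nA1,1\nA1,2\n")
        with pytest.raises(PlateError):
            read_plate_export(path, dialect="long")

    def test_grid_bad_row_label(self, tmp_path):
        path = tmp_path / "bad.csv"
        rows = [",1,2,3,4,5,6,7,8,9,10,11,12"]
        for r in "ABCDEFG":
            rows.append(r + "," + ",".join(["1"] * 12))
        rows.append("Z," + ",".join(["1"] * 12))
        path.write_text("\n".join(rows))
        with pytest.raises(PlateError):
            read_plate_export(path, dialect="grid")

    def test_grid_non_numeric_value(self, tmp_path):
        path = tmp_path / "nan.csv"
        rows = [",1,2,3,4,5,6,7,8,9,10,11,12"]
        for r in "ABCDEFGH":
            vals = ["1"] * 12
            if r == "C":
                vals[4] = "oops"
            rows.append(r + "," + ",".join(vals))
        path.write_text("\n".join(rows))
        with pytest.raises(PlateError, match="C5"):
            read_plate_export(path, dialect="grid")

    def test_xlsx_grid(self, tmp_path):
        import openpyxl

        wb = openpyxl.Workbook()
        ws = wb.active
        ws.append([""] + list(range(1, 13)))
        for r in "ABCDEFGH":
            ws.append([r] + [100] * 12)
        path = tmp_path / "plate.xlsx"
        wb.save(path)
        plate = read_plate_export(path, dialect="grid")
        assert len(plate.readings) == 96
        assert plate["D7"] == 100.0


class TestLayoutToml:
    def test_write_read_round_trip(self, tmp_path, demo_layout):
        path = tmp_path / "layout.toml"
        write_layout_toml(demo_layout, path)
        back = read_layout_toml(path)
        assert back.sample_wells == demo_layout.sample_wells
        assert back.antibody_free_wells == demo_layout.antibody_free_wells
        assert back.background_wells == demo_layout.background_wells
        assert back.plate_params == demo_layout.plate_params
        assert back.schema_version == demo_layout.schema_version

    def test_missing_controls_section_named(self, tmp_path):
        path = tmp_path / "nc.toml"
        path.write_text(
            'data_path = "p.csv"\nmeasurement_date = "d"\n[plate_params]\n'
            "[samples.s1]\ndilutions = [0.25, 0.125]\n"
            'wells = [["A1"], ["B1"]]\n'
        )
        with pytest.raises(PlateError, match="controls"):
            read_layout_toml(path)

    def test_role_conflict_rejected(self, tmp_path):
        path = tmp_path / "conflict.toml"
        path.write_text(
            'data_path = "p.csv"\nmeasurement_date = "d"\n[plate_params]\n'
            "[samples.s1]\ndilutions = [0.25, 0.125]\n"
            'wells = [["A1"], ["B1"]]\n'
            '[controls]\nantibody_free = ["H1"]\nbackground = ["A1"]\n'
        )
        with pytest.raises(PlateError, match="A1"):
            read_layout_toml(path)

    def test_aggregator_lists_members_in_order(self, tmp_path, demo_layout):
        for name in ("one.toml", "two.toml"):
            write_layout_toml(demo_layout, tmp_path / name)
        agg = tmp_path / "agg.toml"
        agg.write_text('layouts = ["one.toml", "two.toml"]\n')
        specs = read_aggregator_toml(agg)
        assert len(specs) == 2
        assert specs[0].source_path.endswith("one.toml")

    def test_aggregator_empty_rejected(self, tmp_path):
        agg = tmp_path / "agg.toml"
        agg.write_text("layouts = []\n")
        with pytest.raises(PlateError):
            read_aggregator_toml(agg)

    def test_aggregator_broken_member_names_path(self, tmp_path):
        agg = tmp_path / "agg.toml"
        agg.write_text('layouts = ["missing.toml"]\n')
        with pytest.raises(PlateError, match="missing.toml"):
            read_aggregator_toml(agg)


class TestNormalize:
    def _single_sample_layout(self):
        return PlateLayoutSpec(
            data_path="p.csv", measurement_date="d", plate_params={},
            sample_wells={"A1": ("s", 0.25, 0), "B1": ("s", 0.125, 0)},
            antibody_free_wells=["H1", "H2"], background_wells=["H4", "H5"],
        )

    def test_midpoint_arithmetic(self):
        layout = self._single_sample_layout()
        plate = full_plate(100.0, A1=5100.0, B1=10100.0, H1=10100.0, H2=10100.0,
                           H4=100.0, H5=100.0)
        curves = normalize(plate, layout)
        c = curves["s"]
        assert c.te[0][0] == pytest.approx(0.5)   # A1, fraction 0.25
        assert c.te[1][0] == pytest.approx(1.0)   # B1 equals the ab-free mean

    def test_no_signal_error(self):
        layout = self._single_sample_layout()
        plate = full_plate(100.0, H1=90.0, H2=90.0, H4=100.0, H5=100.0)
        with pytest.raises(NoSignalError):
            normalize(plate, layout)

    def test_missing_well_error(self):
        layout = self._single_sample_layout()
        plate = RawPlate({"A1": 1.0, "H1": 2.0, "H2": 2.0, "H4": 0.0, "H5": 0.0})
        with pytest.raises(PlateError, match="B1"):
            normalize(plate, layout)

    def test_negative_te_clipped_and_reported(self):
        layout = self._single_sample_layout()
        plate = full_plate(100.0, A1=50.0, B1=5100.0, H1=10100.0, H2=10100.0,
                           H4=100.0, H5=100.0)
        c = normalize(plate, layout)["s"]
        assert c.metadata["clipped_wells"] == ["A1"]
        assert c.te[0][0] > 0  # floored, still log-transformable

    @pytest.mark.parametrize("gain", [0.25, 3.7])
    def test_invariant_under_positive_rescaling(self, gain):
        layout = self._single_sample_layout()
        base = full_plate(100.0, A1=5100.0, B1=2600.0, H1=10100.0, H2=10100.0,
                          H4=100.0, H5=100.0)
        scaled = RawPlate({w: gain * v for w, v in base.readings.items()})
        te_a = te_map(base, layout)
        te_b = te_map(scaled, layout)
        for w in te_a:
            assert te_a[w] == pytest.approx(te_b[w], rel=1e-12)

    def test_antibody_free_wells_average_to_one_exactly(self):
        layout = self._single_sample_layout()
        plate = full_plate(100.0, A1=5100.0, B1=2600.0, H1=9000.0, H2=11200.0,
                           H4=100.0, H5=100.0)
        tes = te_map(plate, layout)
        assert np.mean([tes["H1"], tes["H2"]]) == pytest.approx(1.0, abs=1e-15)

    def test_round_trip_from_known_curve(self, tmp_path):
        """Synthetic plate written from a known curve re-parses to the same
        TE values to machine precision."""
        truth = HillParams(1 / 16, 1.3, 0.05)
        layout = layout_skeleton(
            ["s1"], n_replicates=3, n_steps=7,
            data_path=str(tmp_path / "plate.csv"), measurement_date="d",
        )
        bg, span = 120.0, 9000.0
        readings = {f"{r}{c}": bg for r in "ABCDEFGH" for c in range(1, 13)}
        for well, (_sid, frac, _rep) in layout.sample_wells.items():
            readings[well] = bg + span * hill_predict(truth, frac)
        for well in layout.antibody_free_wells:
            readings[well] = bg + span
        for well in layout.background_wells:
            readings[well] = bg
        write_plate_csv(RawPlate(readings), tmp_path / "plate.csv")
        write_layout_toml(layout, tmp_path / "layout.toml")

        raw = read_plate_export(tmp_path / "plate.csv")
        spec = read_layout_toml(tmp_path / "layout.toml")
        curve = normalize(raw, spec)["s1"]
        for d, row in zip(curve.dilutions, curve.te):
            assert row == pytest.approx(hill_predict(truth, d), rel=1e-12)


class TestCurveCsv:
    def test_round_trip(self, tmp_path):
        c = NeutralizationCurve(
            [1 / 4, 1 / 8, 1 / 16], [[0.1, 0.2], [0.4, 0.5], [0.8, 0.9]], "s1"
        )
        path = tmp_path / "curves.csv"
        write_curves_csv([c], path)
        (back,) = read_curves_csv(path)
        assert back.sample_id == "s1"
        assert np.array_equal(back.fractions, c.fractions)
        for ra, rb in zip(back.te, c.te):
            assert np.array_equal(ra, rb)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(PlateError):
            read_curves_csv(path)
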