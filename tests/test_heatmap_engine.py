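"""Classification rules, matrix assembly and renders."""

import json

import pytest

from meatrba import (
    AssessmentConfig,
    ContributionResult,
    HazardResult,
    NOT_REPORTED,
    build_heatmap,
    classify_hazard_cell,
    classify_nutrient_cell,
    render,
)
from meatrba.heatmap_engine import (
    PALETTE,
    cell_color,
    load_matrix,
    matrix_from_dict,
    matrix_to_dict,
)

CFG = AssessmentConfig()


def _contribution(pct, amount=1.0, component="Protein", product="x"):
    return ContributionResult(product=product, component=component, sex="both",
                              amount_per_serving=amount, drv=100.0,
                              contribution_pct=pct, exceeds_drv=pct > 100)


def _moe_result(moe, product="x", component="PAH4"):
    return HazardResult(product=product, component=component, mode="moe",
                        observed=1.0, intake=0.1, benchmark=0.34,
                        moe=moe, exceeds=moe < CFG.moe_threshold)


class TestNutrientCells:
    def test_row_maximum_is_darkest(self):
        row = [5.07, 25.88, 26.99, 9.84, 24.15]  # the sodium contributions
        cell = classify_nutrient_cell(_contribution(26.99, component="Sodium"),
                                      "yellow_scale", row, CFG)
        assert cell.channel == "yellow" and cell.intensity == 1.0

    def test_gradient_proportional_within_row(self):
        row = [5.07, 25.88, 26.99, 9.84, 24.15]
        cell = classify_nutrient_cell(_contribution(5.07, component="Sodium"),
                                      "yellow_scale", row, CFG)
        assert cell.intensity == pytest.approx(5.07 / 26.99)

    def test_zero_threshold_zero_is_flat_green(self):
        cell = classify_nutrient_cell(
            ContributionResult(product="Fiambre", component="Total trans fatty acids",
                               sex="both", amount_per_serving=0.0),
            "zero_threshold_red", [0.18, 0.03, 0.0, 0.0, 0.02], CFG)
        assert (cell.channel, cell.intensity) == ("green", 0.0)

    def test_zero_threshold_nonzero_is_red(self):
        cell = classify_nutrient_cell(
            ContributionResult(product="Grilled Pork", component="Total trans fatty acids",
                               sex="both", amount_per_serving=0.18),
            "zero_threshold_red", [0.18, 0.03, 0.0, 0.0, 0.02], CFG)
        assert cell.channel == "red" and cell.intensity == 1.0

    def test_exceedance_forces_flat_red(self):
        cell = classify_nutrient_cell(_contribution(150.0), "green_scale",
                                      [150.0, 10.0], CFG)
        assert cell.channel == "red" and cell.intensity == 1.0 and cell.exceedance_flag

    def test_empty_row_context_rejected(self):
        with pytest.raises(Exception, match="row context"):
            classify_nutrient_cell(_contribution(10.0), "green_scale", [], CFG)


class TestHazardCells:
    @pytest.mark.parametrize("moe, channel", [
        (129990.71, "green"),
        (4011.68, "red"), (2980.57, "red"), (1613.29, "red"),
        (400.88, "red"), (0.62, "red"), (258.46, "red"), (428.13, "red"),
        (10000.0, "green"),  # the threshold itself is low-concern
        (9999.99, "red"),
    ])
    def test_moe_threshold_rule(self, moe, channel):
        assert classify_hazard_cell(_moe_result(moe), CFG).channel == channel

    def test_moe_far_below_threshold_saturates(self):
        cell = classify_hazard_cell(_moe_result(0.62), CFG)
        assert cell.intensity == 1.0  # > 4 decades under the threshold

    def test_nr_is_flat_green_labelled(self):
        r = HazardResult(product="x", component="Aflatoxins", mode="moe",
                         observed=NOT_REPORTED, benchmark=0.0004, nr=True)
        cell = classify_hazard_cell(r, CFG)
        assert (cell.channel, cell.intensity, cell.label, cell.nr) == ("green", 0.0, "NR", True)

    def test_reg_red_scaled_by_worst_exceeder(self):
        mk = lambda prod, obs: HazardResult(
            product=prod, component="L. monocytogenes", mode="reg_concentration",
            observed=obs, benchmark=100.0, ratio=obs / 100.0, exceeds=obs > 100.0)
        row = [mk("a", 800.0), mk("b", 3802.0), mk("c", 22.5)]
        worst = classify_hazard_cell(row[1], CFG, row_context=row)
        lesser = classify_hazard_cell(row[0], CFG, row_context=row)
        assert worst.intensity == 1.0
        assert lesser.intensity == pytest.approx((8.0 - 1.0) / (38.02 - 1.0))

    def test_reg_sole_exceeder_fully_dark(self):
        r = HazardResult(product="Salame", component="Histamine", mode="reg_concentration",
                         observed=235.69, benchmark=150.0, ratio=235.69 / 150.0,
                         exceeds=True)
        assert classify_hazard_cell(r, CFG, row_context=[r]).intensity == 1.0

    def test_reg_below_limit_darker_when_lower(self):
        mk = lambda obs: HazardResult(
            product="x", component="Histamine", mode="reg_concentration",
            observed=obs, benchmark=150.0, ratio=obs / 150.0, exceeds=False)
        low, high = classify_hazard_cell(mk(0.27), CFG), classify_hazard_cell(mk(140.0), CFG)
        assert low.channel == high.channel == "green"
        assert low.intensity > high.intensity


class TestBuildHeatmap:
    def test_shape_and_column_order(self, fixture_matrix):
        assert fixture_matrix.columns == ["Grilled Pork", "Chouriço", "Presunto",
                                          "Fiambre", "Salame"]
        hazard_rows = [r for r in fixture_matrix.rows if r.kind == "hazard"]
        assert [r.component for r in hazard_rows] == [
            "L. monocytogenes", "Histamine", "Nitrite",
            "Ochratoxin A", "PAH4", "Benzo(a)pyrene"]
        assert len(fixture_matrix.rows) == 23

    def test_hazard_red_cells_exactly(self, fixture_matrix):
        reds = set()
        for label, row in zip(fixture_matrix.rows, fixture_matrix.cells):
            if label.kind != "hazard":
                continue
            for col, cell in zip(fixture_matrix.columns, row):
                if cell.channel == "red":
                    reds.add((col, label.component))
        assert reds == {
            ("Fiambre", "L. monocytogenes"), ("Salame", "L. monocytogenes"),
            ("Salame", "Histamine"),
            ("Salame", "Ochratoxin A"), ("Presunto", "Ochratoxin A"),
            ("Grilled Pork", "PAH4"), ("Chouriço", "PAH4"), ("Salame", "PAH4"),
            ("Grilled Pork", "Benzo(a)pyrene"), ("Salame", "Benzo(a)pyrene"),
        }

    def test_channel_totality_and_intensity_range(self, fixture_matrix):
        for row in fixture_matrix.cells:
            for cell in row:
                assert cell.channel in ("green", "yellow", "red")
                assert 0.0 <= cell.intensity <= 1.0

    def test_empty_inputs_give_empty_matrix(self, fixture_ds):
        m = build_heatmap([], [], [], fixture_ds.components, fixture_ds.config)
        assert m.rows == [] and m.cells == []


class TestRender:
    def test_json_round_trip(self, fixture_matrix, tmp_path):
        path = str(tmp_path / "h.json")
        render(fixture_matrix, "json", path)
        assert load_matrix(path) == fixture_matrix
        assert matrix_from_dict(matrix_to_dict(fixture_matrix)) == fixture_matrix

    def test_csv_round_trip(self, fixture_matrix, tmp_path):
        path = str(tmp_path / "h.csv")
        render(fixture_matrix, "csv", path)
        assert load_matrix(path) == fixture_matrix

    @pytest.mark.parametrize("fmt", ["csv", "json", "html", "svg"])
    def test_renders_are_deterministic(self, fixture_matrix, tmp_path, fmt):
        a, b = (str(tmp_path / f"{i}.{fmt}") for i in "ab")
        render(fixture_matrix, fmt, a)
        render(fixture_matrix, fmt, b)
        assert open(a, "rb").read() == open(b, "rb").read()

    def test_palette_endpoints(self):
        for channel, (lo, hi) in PALETTE.items():
            assert cell_color(channel, 0.0) == lo
            assert cell_color(channel, 1.0) == hi

    def test_svg_nr_cell_is_flat_green(self, fixture_matrix, tmp_path):
        path = str(tmp_path / "h.svg")
        render(fixture_matrix, "svg", path)
        content = open(path).read()
        assert ">NR</text>" in content
        assert PALETTE["green"][0] in content  # the zero-intensity green fill
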