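"""Exposure, Margin of Exposure, regulatory comparison and NR propagation."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from meatrba import (
    NA,
    NOT_REPORTED,
    ReferenceValue,
    assess_risks,
    compare_to_limit,
    exposure_per_kg_bw,
    margin_of_exposure,
)
from meatrba.errors import ConfigurationError

HISTAMINE_LIMIT = ReferenceValue(component="Histamine", kind="reg_limit_concentration",
                                 value=150.0, unit="mg_per_kg")
LISTERIA_LIMIT = ReferenceValue(component="L. monocytogenes",
                                kind="reg_limit_concentration",
                                value=100.0, unit="CFU_per_g")


class TestExposure:
    @pytest.mark.parametrize("conc, serving, bw, expected", [
        (0.0, 21.0, 70.0, 0.0),
        (100.0, 21.0, 70.0, 0.03),
        (25.0, 21.0, 70.0, 0.0075),
    ])
    def test_values(self, conc, serving, bw, expected):
        assert exposure_per_kg_bw(conc, serving, bw) == pytest.approx(expected)

    def test_rejects_nonpositive_denominators(self):
        with pytest.raises(ValueError):
            exposure_per_kg_bw(1.0, 0.0, 70.0)
        with pytest.raises(ValueError):
            exposure_per_kg_bw(1.0, 21.0, -1.0)


class TestMarginOfExposure:
    def test_identity_at_equal_dose(self):
        assert margin_of_exposure(0.5, 0.5) == 1.0

    def test_pah_scale(self):
        assert margin_of_exposure(0.34, 8.5e-5) == pytest.approx(4000.0)

    def test_nr_and_zero_exposure_give_na(self):
        assert margin_of_exposure(0.34, NOT_REPORTED) is NA
        assert margin_of_exposure(0.34, 0.0) is NA

    def test_nonpositive_reference_point_rejected(self):
        with pytest.raises(ConfigurationError):
            margin_of_exposure(0.0, 1.0)

    @given(rp=st.floats(1e-6, 1e3), e=st.floats(1e-9, 1e3))
    def test_product_identity(self, rp, e):
        assert math.isclose(margin_of_exposure(rp, e) * e, rp, rel_tol=1e-12)

    @given(rp=st.floats(1e-6, 1e3), e1=st.floats(1e-9, 1e3),
           factor=st.floats(1.001, 1e3))
    def test_strictly_antitone_in_exposure(self, rp, e1, factor):
        assert margin_of_exposure(rp, e1) > margin_of_exposure(rp, e1 * factor)


class TestCompareToLimit:
    def test_salame_histamine_exceeds(self):
        exceeds, ratio = compare_to_limit(235.69, HISTAMINE_LIMIT)
        assert exceeds and ratio == pytest.approx(235.69 / 150.0)

    def test_presunto_listeria_below(self):
        exceeds, ratio = compare_to_limit(22.50, LISTERIA_LIMIT)
        assert not exceeds and ratio == pytest.approx(0.225)

    def test_zero_observation(self):
        assert compare_to_limit(0.0, HISTAMINE_LIMIT) == (False, 0.0)

    def test_basis_mismatch_is_type_error(self):
        with pytest.raises(TypeError):
            compare_to_limit(5.0, HISTAMINE_LIMIT, observed_basis="per_kg_bw_day")

    def test_non_limit_benchmark_rejected(self):
        ref = ReferenceValue(component="PAH4", kind="moe_reference_point",
                             value=0.34, unit="mg_per_kg_bw_day")
        with pytest.raises(TypeError):
            compare_to_limit(1.0, ref)

    @given(obs=st.floats(0, 1e6), limit=st.floats(1e-3, 1e6),
           k=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, obs, limit, k):
        ref = ReferenceValue(component="Histamine", kind="reg_limit_concentration",
                             value=limit, unit="mg_per_kg")
        ref_k = ReferenceValue(component="Histamine", kind="reg_limit_concentration",
                               value=limit * k, unit="mg_per_kg")
        e1, r1 = compare_to_limit(obs, ref)
        e2, r2 = compare_to_limit(obs * k, ref_k)
        assert e1 == e2
        assert math.isclose(r1, r2, rel_tol=1e-9, abs_tol=1e-12)

    @given(limit=st.floats(1e-3, 1e3), lo=st.floats(0, 1e3), hi=st.floats(0, 1e3))
    def test_exceeds_monotone_in_observed(self, limit, lo, hi):
        ref = ReferenceValue(component="Histamine", kind="reg_limit_concentration",
                             value=limit, unit="mg_per_kg")
        lo, hi = min(lo, hi), max(lo, hi)
        assert compare_to_limit(lo, ref)[0] <= compare_to_limit(hi, ref)[0]


class TestAssessRisks:
    def test_cardinality(self, fixture_risks):
        assert len(fixture_risks) == 35  # 5 products x 7 hazards

    def test_modes(self, fixture_risks):
        modes = {r.component: r.mode for r in fixture_risks}
        assert modes["L. monocytogenes"] == "reg_concentration"
        assert modes["Histamine"] == "reg_concentration"
        assert modes["Nitrite"] == "reg_intake"
        assert all(modes[c] == "moe"
                   for c in ("Aflatoxins", "Ochratoxin A", "PAH4", "Benzo(a)pyrene"))

    def test_salame_ochratoxin_low_margin(self, fixture_risks):
        r = next(r for r in fixture_risks
                 if (r.product, r.component) == ("Salame", "Ochratoxin A"))
        assert r.mode == "moe" and r.moe < 10000

    def test_nr_propagation(self, fixture_risks):
        nr_rows = [r for r in fixture_risks if r.nr]
        assert len(nr_rows) == 15  # Not-Reported cells in the occurrence table
        for r in nr_rows:
            assert r.observed is NOT_REPORTED
            assert r.moe is NA and r.exceeds is NA and r.intake is None

    def test_regulatory_exceeders_exactly(self, fixture_risks):
        exceeders = {(r.product, r.component) for r in fixture_risks
                     if r.mode != "moe" and r.exceeds is True}
        assert exceeders == {("Fiambre", "L. monocytogenes"),
                             ("Salame", "L. monocytogenes"),
                             ("Salame", "Histamine")}

    def test_nitrite_compared_on_intake_basis(self, fixture_risks):
        fiambre = next(r for r in fixture_risks
                       if (r.product, r.component) == ("Fiambre", "Nitrite"))
        # 100 mg/kg in the product, but the 21 g serving keeps the daily
        # intake (0.03 mg/kg bw) below the 0.07 ADI
        assert fiambre.exceeds is False
        assert fiambre.intake == pytest.approx(0.03)

    def test_extreme_scenarios_reverse_moe(self, fixture_ds):
        # a ranged ochratoxin occurrence: bigger exposure, smaller margin
        from meatrba.synthetic_data import SynthSpec, generate
        ds = generate(SynthSpec(n_products=4, seed=3, range_prob=1.0,
                                hazard_occurrence_prob=1.0))
        by_scenario = {s: {(r.product, r.component): r
                           for r in assess_risks(*ds, scenario=s)}
                       for s in ("min", "point", "max")}
        checked = 0
        for key, point in by_scenario["point"].items():
            if point.mode != "moe" or point.nr:
                continue
            lo, hi = by_scenario["min"][key], by_scenario["max"][key]
            assert hi.moe <= point.moe <= lo.moe
            checked += 1
        assert checked > 0
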