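"""Seeded generator of structurally faithful random datasets.

The generator emulates the statistical shape of the study's composition
and occurrence tables so every pipeline stage can be exercised without the
packaged fixture: per-product nutrient vectors spanning the observed
spread, sparse hazard occurrence (roughly half the hazard cells in the
study are Not Reported), log-uniform hazard concentrations (observed
levels span almost seven orders of magnitude across hazards), optional
min/max ranges for extreme-scenario runs, and survey-scale serving sizes.

It makes no attempt to model covariance between nutrients or the effect of
processing technology on hazards; generated products are draws, not
simulated foods.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from ._states import NOT_REPORTED
from .models import AssessmentConfig, Dataset, FoodProduct, Measurement
from .reference_data import (
    FIXTURE_PRODUCT_ORDER,
    HAZARDS,
    NUTRIENTS,
    component_registry,
    reference_values,
)

#: per-serving (low, high) bounds per nutrient, spanning the fixture spread
DEFAULT_NUTRIENT_RANGES: dict[str, tuple[float, float]] = {
    "Protein": (3.0, 9.0),
    "Lipid": (0.9, 22.0),
    "Total saturated fatty acids": (0.0, 8.0),
    "Linoleic acid": (0.1, 2.7),
    "Total trans fatty acids": (0.0, 0.2),
    "Sodium": (100.0, 560.0),
    "Potassium": (29.0, 150.0),
    "Calcium": (2.0, 18.0),
    "Phosphorus": (42.0, 57.0),
    "Magnesium": (3.0, 33.0),
    "Iron": (0.4, 0.7),
    "Zinc": (0.6, 1.5),
}

#: (low, high) concentration bounds per hazard, in the component's
#: concentration unit (CFU/g for the pathogen, mg/kg product otherwise);
#: chosen to straddle each benchmark so both exceeding and compliant
#: draws occur
DEFAULT_HAZARD_RANGES: dict[str, tuple[float, float]] = {
    "L. monocytogenes": (1.0, 4000.0),
    "Histamine": (0.2, 300.0),
    "Nitrite": (1.0, 150.0),
    "Aflatoxins": (1e-4, 1e-2),
    "Ochratoxin A": (1e-3, 150.0),
    "PAH4": (0.01, 10.0),
    "Benzo(a)pyrene": (0.001, 1.0),
}


class SynthSpec(BaseModel):
    """Parameters of one synthetic dataset draw."""

    model_config = ConfigDict(frozen=True)

    n_products: int = 5
    seed: int = 0
    nutrient_ranges: dict[str, tuple[float, float]] = DEFAULT_NUTRIENT_RANGES
    hazard_log_range: dict[str, tuple[float, float]] = DEFAULT_HAZARD_RANGES
    hazard_occurrence_prob: float = 0.5
    range_prob: float = 0.3
    serving_range: tuple[float, float] = (20.0, 60.0)

    @model_validator(mode="after")
    def _sane(self):
        for p in (self.hazard_occurrence_prob, self.range_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        for name, (lo, hi) in {**self.nutrient_ranges, **self.hazard_log_range,
                               "serving": self.serving_range}.items():
            if lo > hi or lo < 0:
                raise ValueError(f"range for {name} must be ordered and nonnegative")
        if self.n_products < 0:
            raise ValueError("n_products must be >= 0")
        return self


def generate(spec: SynthSpec) -> Dataset:
    """Draw a schema-valid dataset; identical for identical specs.

    Nutrients are uniform within their per-serving ranges; each hazard is
    reported with probability ``hazard_occurrence_prob`` and, when
    reported, its concentration is log-uniform within its bounds. With
    probability ``range_prob`` a reported measurement carries min/max
    bounds bracketing the point value. Benchmarks and DRVs are copied from
    the packaged registry. Product names never collide with the study's.
    """
    rng = np.random.default_rng(spec.seed)
    products: list[FoodProduct] = []
    for i in range(spec.n_products):
        name = f"synthetic_product_{i + 1:02d}"
        assert name not in FIXTURE_PRODUCT_ORDER
        serving = float(rng.uniform(*spec.serving_range))
        measurements: dict[str, Measurement] = {}
        for comp in NUTRIENTS:
            lo, hi = spec.nutrient_ranges[comp.name]
            value = float(rng.uniform(lo, hi))
            kwargs = {}
            if rng.random() < spec.range_prob:
                kwargs = {"value_min": value * float(rng.uniform(0.5, 1.0)),
                          "value_max": value * float(rng.uniform(1.0, 1.8))}
            measurements[comp.name] = Measurement(
                component=comp.name, basis="per_serving", value=value, **kwargs)
        for comp in HAZARDS:
            basis = "cfu_per_g" if comp.unit == "CFU_per_g" else "per_kg_product"
            if rng.random() >= spec.hazard_occurrence_prob:
                measurements[comp.name] = Measurement(
                    component=comp.name, basis=basis, value=NOT_REPORTED)
                continue
            lo, hi = spec.hazard_log_range[comp.name]
            value = float(10 ** rng.uniform(math.log10(lo), math.log10(hi)))
            kwargs = {}
            if rng.random() < spec.range_prob:
                kwargs = {"value_min": value * float(rng.uniform(0.5, 1.0)),
                          "value_max": value * float(rng.uniform(1.0, 1.8))}
            measurements[comp.name] = Measurement(
                component=comp.name, basis=basis, value=value, **kwargs)
        products.append(FoodProduct(
            name=name, scenario="fermented", serving_size=serving,
            measurements=measurements))
    return Dataset(products, component_registry(), reference_values(), AssessmentConfig())
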