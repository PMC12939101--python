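"""Domain types for the risk-benefit assessment of meat products.

The data model mirrors how the assessment treats food data:

* a :class:`FoodProduct` belongs to a consumption scenario (unprocessed
  reference, fermented, dry-cured, heat-treated) and carries one
  :class:`Measurement` per component;
* a :class:`ComponentDefinition` says whether a component is a nutrient
  (benefit) or a hazard (risk), which benchmark applies, and how its
  heatmap cells are colored;
* a :class:`ReferenceValue` is the benchmark itself — a Dietary Reference
  Value (possibly sex-specific or expressed as a fraction of daily energy),
  a regulatory limit, or a toxicological reference point (BMDL10) for
  margin-of-exposure calculations.

Measurements keep their basis explicit (per 100 g, per serving, per kg of
product, CFU/g, or mg per kg body weight per day); conversion between bases
only happens inside operations that document it.
"""

from __future__ import annotations

from typing import Literal, NamedTuple, Optional, Union

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from ._states import NOT_REPORTED, Sentinel, is_number

Scenario = Literal["reference", "fermented", "dry_cured", "heat_treated"]
Basis = Literal["per_100g", "per_serving", "per_kg_product", "cfu_per_g", "per_kg_bw_day"]
Unit = Literal["g", "mg", "mg_per_kg", "CFU_per_g", "mg_per_kg_bw_day"]
BenchmarkKind = Literal[
    "drv_absolute",
    "drv_energy_percent",
    "drv_as_low_as_possible",
    "reg_limit_concentration",
    "reg_limit_intake",
    "moe_reference_point",
]
ColorRule = Literal["green_scale", "yellow_scale", "zero_threshold_red", "reg_hazard", "moe_hazard"]
Sex = Literal["male", "female", "both"]

#: color rules admissible for each benchmark kind
_RULES_FOR_KIND: dict[str, set[str]] = {
    "drv_absolute": {"green_scale", "yellow_scale", "zero_threshold_red"},
    "drv_energy_percent": {"green_scale", "yellow_scale", "zero_threshold_red"},
    "drv_as_low_as_possible": {"green_scale", "yellow_scale", "zero_threshold_red"},
    "reg_limit_concentration": {"reg_hazard"},
    "reg_limit_intake": {"reg_hazard"},
    "moe_reference_point": {"moe_hazard"},
}


class Measurement(BaseModel):
    """An observed amount of one component in one product.

    ``value`` is either a nonnegative number in the unit implied by
    ``basis`` or the distinguished ``NOT_REPORTED`` state (never 0 in
    disguise). ``value_min``/``value_max`` bracket the reported range for
    extreme-scenario evaluation.
    """

    model_config = ConfigDict(arbitrary_types_allowed=True, frozen=True)

    component: str
    basis: Basis
    value: Union[float, Sentinel]
    value_min: Optional[float] = None
    value_max: Optional[float] = None

    @field_validator("value")
    @classmethod
    def _value_ok(cls, v):
        if isinstance(v, Sentinel):
            if v is not NOT_REPORTED:
                raise ValueError(f"only NOT_REPORTED is a valid measurement state, got {v!r}")
            return v
        if v < 0:
            raise ValueError(f"measurement value must be nonnegative, got {v}")
        return float(v)

    @model_validator(mode="after")
    def _bounds_ok(self):
        if self.value is NOT_REPORTED:
            if self.value_min is not None or self.value_max is not None:
                raise ValueError("NOT_REPORTED measurements cannot carry min/max bounds")
            return self
        lo = self.value_min if self.value_min is not None else self.value
        hi = self.value_max if self.value_max is not None else self.value
        if not (lo <= self.value <= hi):
            raise ValueError(
                f"{self.component}: bounds must satisfy min <= value <= max "
                f"({lo} <= {self.value} <= {hi})"
            )
        if lo < 0:
            raise ValueError("value_min must be nonnegative")
        return self

    @property
    def is_reported(self) -> bool:
        return self.value is not NOT_REPORTED

    def at_scenario(self, scenario: Literal["point", "min", "max"]) -> Union[float, Sentinel]:
        """Value under the point / minimum / maximum reported-level scenario."""
        if self.value is NOT_REPORTED:
            return NOT_REPORTED
        if scenario == "min" and self.value_min is not None:
            return self.value_min
        if scenario == "max" and self.value_max is not None:
            return self.value_max
        return self.value


class FoodProduct(BaseModel):
    """A scenario food with its serving size and component measurements."""

    model_config = ConfigDict(arbitrary_types_allowed=True)

    name: str
    scenario: Scenario
    serving_size: Optional[float] = None  # g per serving
    measurements: dict[str, Measurement] = {}

    @field_validator("serving_size")
    @classmethod
    def _serving_ok(cls, v):
        if v is not None and v <= 0:
            raise ValueError(f"serving_size must be > 0, got {v}")
        return v

    @model_validator(mode="after")
    def _keys_match(self):
        for key, m in self.measurements.items():
            if key != m.component:
                raise ValueError(f"measurement keyed {key!r} names component {m.component!r}")
        return self


class ComponentDefinition(BaseModel):
    """A nutrient or hazard: its unit, benchmark type, and display rule."""

    model_config = ConfigDict(frozen=True)

    name: str
    category: Literal["nutrient", "hazard"]
    unit: Unit
    benchmark_kind: BenchmarkKind
    color_rule: ColorRule

    @model_validator(mode="after")
    def _consistent(self):
        is_drv = self.benchmark_kind.startswith("drv_")
        if (self.category == "nutrient") != is_drv:
            raise ValueError(
                f"{self.name}: category {self.category!r} inconsistent with "
                f"benchmark_kind {self.benchmark_kind!r}"
            )
        if self.color_rule not in _RULES_FOR_KIND[self.benchmark_kind]:
            raise ValueError(
                f"{self.name}: color_rule {self.color_rule!r} not admissible for "
                f"benchmark_kind {self.benchmark_kind!r}"
            )
        return self


class ReferenceValue(BaseModel):
    """A sex-resolved DRV or a hazard benchmark (limit, ADI/TDI, BMDL10)."""

    model_config = ConfigDict(frozen=True)

    component: str
    sex: Sex = "both"
    kind: BenchmarkKind
    value: Optional[float] = None
    unit: Optional[Unit] = None
    energy_fraction: Optional[float] = None  # of daily energy intake
    upper_limit: Optional[float] = None  # tolerable upper intake, same unit

    @model_validator(mode="after")
    def _kind_ok(self):
        if self.kind == "drv_as_low_as_possible":
            if self.value is not None:
                raise ValueError(f"{self.component}: 'as low as possible' carries no number")
        elif self.kind == "drv_energy_percent":
            if self.energy_fraction is None or not (0 < self.energy_fraction <= 1):
                raise ValueError(f"{self.component}: energy_fraction must be in (0, 1]")
        else:
            if self.value is None or self.value < 0:
                raise ValueError(f"{self.component}: benchmark needs a nonnegative value")
        return self


class AssessmentConfig(BaseModel):
    """Assessment-wide constants.

    Defaults: 70 kg adult body weight, 2500/2000 kcal daily energy
    (male/female) consistent with the energy-relative DRV derivations,
    9 kcal per g of lipid, one serving per day, a margin-of-exposure
    decision threshold of 10,000, and a DRV exceedance flag at 100%.
    """

    model_config = ConfigDict(frozen=True)

    body_weight: float = 70.0  # kg
    energy_intake_male: float = 2500.0  # kcal/day
    energy_intake_female: float = 2000.0  # kcal/day
    lipid_energy_kcal_per_g: float = 9.0
    servings_per_day: float = 1.0
    moe_threshold: float = 10000.0
    drv_exceedance_flag: float = 100.0  # percent of DRV

    @model_validator(mode="after")
    def _positive(self):
        for name, v in self.model_dump().items():
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        return self


class Dataset(NamedTuple):
    """Everything one assessment run consumes."""

    products: list[FoodProduct]
    components: list[ComponentDefinition]
    references: list[ReferenceValue]
    config: AssessmentConfig


__all__ = [
    "AssessmentConfig",
    "Basis",
    "BenchmarkKind",
    "ColorRule",
    "ComponentDefinition",
    "Dataset",
    "FoodProduct",
    "Measurement",
    "ReferenceValue",
    "Scenario",
    "Sex",
    "Unit",
    "is_number",
]
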