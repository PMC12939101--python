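"""Hazard characterization: regulatory-limit comparison and Margin of Exposure.

Two evaluation modes exist, mirroring the benchmark available for each
hazard:

* **Reg** — the observed level is compared with a regulatory maximum,
  either on the concentration basis (*L. monocytogenes* vs 100 CFU/g,
  histamine vs 150 mg/kg) or on the intake basis (nitrite vs its ADI of
  0.07 mg/kg bw/day). Each component declares its own comparison basis.
* **MoE** — for genotoxic/carcinogenic contaminants with a BMDL10
  reference point (aflatoxins, ochratoxin A, PAH4, benzo(a)pyrene) the
  Margin of Exposure is the ratio

      MoE = BMDL10 / exposure

  with exposure in mg per kg body weight per day, assuming one serving per
  day and a 70 kg adult. MoE values below 10,000 signal potential concern.

NOT_REPORTED occurrences propagate: no arithmetic is ever performed on
them and every downstream quantity is the NA state.
"""

from __future__ import annotations

import warnings
from typing import Literal, Optional, Union

from pydantic import BaseModel, ConfigDict, model_validator

from ._states import NA, NOT_REPORTED, Sentinel, is_number
from ._util import round_half_up
from .errors import ConfigurationError, UnresolvableExposureError
from .models import (
    AssessmentConfig,
    ComponentDefinition,
    Dataset,
    FoodProduct,
    ReferenceValue,
)

PointScenario = Literal["point", "min", "max"]


class HazardResult(BaseModel):
    """One product x hazard evaluation."""

    model_config = ConfigDict(arbitrary_types_allowed=True, frozen=True)

    product: str
    component: str
    mode: Literal["reg_concentration", "reg_intake", "moe"]
    observed: Union[float, Sentinel]  # in the measurement's own basis
    observed_basis: Optional[str] = None
    intake: Optional[float] = None  # mg/kg bw/day
    benchmark: float
    benchmark_unit: Optional[str] = None
    ratio: Union[float, Sentinel] = NA  # observed/limit, reg modes only
    moe: Union[float, Sentinel] = NA
    exceeds: Union[bool, Sentinel] = NA
    nr: bool = False

    @model_validator(mode="after")
    def _coherent(self):
        if self.nr:
            if self.moe is not NA or self.exceeds is not NA:
                raise ValueError("NOT_REPORTED rows carry no MoE or exceedance")
        else:
            # moe mode: margin present unless NOT_REPORTED or zero exposure
            if self.mode == "moe" and not is_number(self.moe) and self.moe is not NA:
                raise ValueError("MoE must be a number or NA")
            if self.mode != "moe" and self.moe is not NA:
                raise ValueError("regulatory modes carry no MoE")
        if is_number(self.moe) and self.moe <= 0:
            raise ValueError("MoE must be positive when present")
        return self


def exposure_per_kg_bw(
    concentration: float, serving_size: float, body_weight: float,
    servings_per_day: float = 1.0,
) -> float:
    """Daily exposure in mg/kg bw from a concentration in mg per kg product."""
    if concentration < 0:
        raise ValueError("concentration must be nonnegative")
    if serving_size <= 0 or body_weight <= 0:
        raise ValueError("serving size and body weight must be positive")
    return concentration * (serving_size / 1000.0) * servings_per_day / body_weight


def margin_of_exposure(
    reference_point: float, exposure: Union[float, Sentinel]
) -> Union[float, Sentinel]:
    """BMDL10 / exposure; NA when exposure is zero or NOT_REPORTED."""
    if not is_number(reference_point) or reference_point <= 0:
        raise ConfigurationError(f"reference point must be positive, got {reference_point!r}")
    if exposure is NOT_REPORTED or exposure is NA:
        return NA
    if exposure < 0:
        raise ValueError("exposure must be nonnegative")
    if exposure == 0:
        return NA
    return reference_point / exposure


def compare_to_limit(
    observed: float, benchmark: ReferenceValue, *, observed_basis: Optional[str] = None
) -> tuple[bool, float]:
    """(exceeds, observed/limit) against a regulatory maximum.

    Concentrations compare only with concentration limits and intakes only
    with intake limits; mixing the two bases is a type error so that any
    conversion (via :func:`exposure_per_kg_bw`) stays explicit.
    """
    if benchmark.kind not in ("reg_limit_concentration", "reg_limit_intake"):
        raise TypeError(f"{benchmark.component}: {benchmark.kind} is not a regulatory limit")
    if observed_basis is not None:
        conc_bases = {"per_kg_product", "cfu_per_g"}
        needs_conc = benchmark.kind == "reg_limit_concentration"
        if needs_conc != (observed_basis in conc_bases):
            raise TypeError(
                f"{benchmark.component}: observed basis {observed_basis!r} does not match "
                f"{benchmark.kind}; convert explicitly first")
    if observed < 0:
        raise ValueError("observed must be nonnegative")
    limit = benchmark.value
    return observed > limit, (0.0 if observed == 0 else observed / limit)


def assess_risks(
    products: list[FoodProduct],
    components: list[ComponentDefinition],
    references: list[ReferenceValue],
    config: AssessmentConfig,
    scenario: PointScenario = "point",
) -> list[HazardResult]:
    """One :class:`HazardResult` per (product, hazard), product-major.

    For MoE hazards the exposure is taken from a per-kg-bw/day measurement
    when present; otherwise it is computed from the concentration and the
    product's serving size. In the extreme scenarios the minimum reported
    level gives the largest MoE and vice versa.
    """
    refs_by_comp = {r.component: r for r in references
                    if not r.kind.startswith("drv_")}
    results: list[HazardResult] = []
    for product in products:
        for comp in components:
            if comp.category != "hazard":
                continue
            bench = refs_by_comp.get(comp.name)
            if bench is None:
                warnings.warn(f"hazard {comp.name!r} has no benchmark", stacklevel=2)
                continue
            m = product.measurements.get(comp.name)
            value = NOT_REPORTED if m is None else m.at_scenario(scenario)
            mode = {"reg_limit_concentration": "reg_concentration",
                    "reg_limit_intake": "reg_intake",
                    "moe_reference_point": "moe"}[bench.kind]
            common = dict(product=product.name, component=comp.name, mode=mode,
                          observed=value, observed_basis=None if m is None else m.basis,
                          benchmark=bench.value, benchmark_unit=bench.unit)
            if value is NOT_REPORTED:
                results.append(HazardResult(**common, nr=True))
                continue
            if mode == "moe":
                if m.basis == "per_kg_bw_day":
                    exposure = value
                elif m.basis == "per_kg_product":
                    if product.serving_size is None:
                        raise UnresolvableExposureError(
                            f"({product.name}, {comp.name}): concentration without serving size")
                    exposure = exposure_per_kg_bw(
                        value, product.serving_size, config.body_weight,
                        config.servings_per_day)
                else:
                    raise TypeError(f"{comp.name}: basis {m.basis!r} unusable for MoE")
                moe = margin_of_exposure(bench.value, exposure)
                results.append(HazardResult(
                    **common, intake=exposure, moe=moe,
                    exceeds=NA if moe is NA else moe < config.moe_threshold))
                continue
            # regulatory comparison, on the component's declared basis
            if mode == "reg_intake" and m.basis == "per_kg_product":
                if product.serving_size is None:
                    raise UnresolvableExposureError(
                        f"({product.name}, {comp.name}): concentration without serving size")
                observed = exposure_per_kg_bw(value, product.serving_size,
                                              config.body_weight, config.servings_per_day)
                basis = "per_kg_bw_day"
            else:
                observed, basis = value, m.basis
            exceeds, ratio = compare_to_limit(observed, bench, observed_basis=basis)
            results.append(HazardResult(
                **common,
                intake=observed if basis == "per_kg_bw_day" else None,
                ratio=ratio, exceeds=exceeds))
    return results


def risks_table(results: list[HazardResult]) -> "pd.DataFrame":
    """Tidy frame: product,component,observed,unit,benchmark,intake,moe,exceeds,nr."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append({
            "product": r.product, "component": r.component, "mode": r.mode,
            "observed": "NR" if r.nr else r.observed,
            "benchmark": r.benchmark, "benchmark_unit": r.benchmark_unit,
            "intake": "" if r.intake is None else r.intake,
            "moe": "NA" if isinstance(r.moe, Sentinel) else round_half_up(r.moe, 2),
            "exceeds": "NA" if isinstance(r.exceeds, Sentinel) else r.exceeds,
            "nr": r.nr,
        })
    return pd.DataFrame(rows, columns=["product", "component", "mode", "observed",
                                       "benchmark", "benchmark_unit", "intake",
                                       "moe", "exceeds", "nr"])


def assess_risks_dataset(ds: Dataset, scenario: PointScenario = "point") -> list[HazardResult]:
    return assess_risks(ds.products, ds.components, ds.references, ds.config, scenario)
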