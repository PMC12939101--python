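"""Nutrient benefit characterization against Dietary Reference Values.

For each product and nutrient the per-serving amount is compared with the
applicable DRV and expressed as a percentage contribution to the daily
requirement:

    contribution (%) = 100 * amount_in_one_serving / DRV

DRVs come in three flavours: absolute amounts (possibly sex-specific, e.g.
magnesium 350/300 mg for males/females), energy-relative values stated as a
fraction of daily calorie intake (lipid 20%, linoleic acid 4%, converted to
grams at 9 kcal per g of lipid), and the "as low as possible" class (trans
and saturated fatty acids) for which no percentage is defined and only the
absolute amount is reported.
"""

from __future__ import annotations

import warnings
from typing import Literal, Optional, Union

from pydantic import BaseModel, ConfigDict

from ._states import AS_LOW_AS_POSSIBLE, NA, NOT_REPORTED, Sentinel
from ._util import round_half_up
from .errors import ConfigurationError
from .models import (
    AssessmentConfig,
    ComponentDefinition,
    Dataset,
    FoodProduct,
    Measurement,
    ReferenceValue,
)

PointScenario = Literal["point", "min", "max"]


class ContributionResult(BaseModel):
    """One product x nutrient (x sex) contribution to the DRV."""

    model_config = ConfigDict(arbitrary_types_allowed=True, frozen=True)

    product: str
    component: str
    sex: Literal["male", "female", "both"]
    amount_per_serving: float
    drv: Optional[float] = None  # absent for as-low-as-possible / missing DRV
    contribution_pct: Union[float, Sentinel, None] = None
    exceeds_drv: bool = False


def per_serving_amount(content_per_100g: float, serving_size: float) -> float:
    """Amount in one serving from a per-100 g composition value."""
    if content_per_100g < 0:
        raise ValueError("content must be nonnegative")
    if serving_size <= 0:
        raise ValueError("serving size must be positive")
    return content_per_100g / 100.0 * serving_size


def resolve_drv(
    ref: ReferenceValue,
    config: AssessmentConfig,
    sex: Literal["male", "female"],
) -> Union[float, Sentinel]:
    """Resolve a reference value to a number (g or mg) for the given sex.

    Energy-relative DRVs become grams:
    ``energy_fraction * daily_energy(sex) / kcal_per_g``. The
    as-low-as-possible class resolves to the ``AS_LOW_AS_POSSIBLE`` state.
    """
    if ref.sex not in ("both", sex):
        raise ValueError(f"reference for {ref.component} is {ref.sex}-specific, asked for {sex}")
    if ref.kind == "drv_as_low_as_possible":
        return AS_LOW_AS_POSSIBLE
    if ref.kind == "drv_energy_percent":
        energy = config.energy_intake_male if sex == "male" else config.energy_intake_female
        if energy is None or energy <= 0:
            raise ConfigurationError(f"no daily energy intake configured for sex {sex!r}")
        return ref.energy_fraction * energy / config.lipid_energy_kcal_per_g
    if not ref.kind.startswith("drv_"):
        raise TypeError(f"{ref.component}: {ref.kind} is not a DRV")
    return float(ref.value)


def contribution_pct(
    amount_per_serving: float, drv: Union[float, Sentinel]
) -> Union[float, Sentinel]:
    """Percentage of the DRV covered by one serving (NA when no DRV exists)."""
    if drv is AS_LOW_AS_POSSIBLE:
        return NA
    if not isinstance(drv, (int, float)):
        raise TypeError(f"drv must be a number or AS_LOW_AS_POSSIBLE, got {drv!r}")
    if drv <= 0:
        raise ValueError("drv must be positive")
    if amount_per_serving < 0:
        raise ValueError("amount must be nonnegative")
    return 100.0 * amount_per_serving / drv


def _amount_for(
    m: Measurement, product: FoodProduct, scenario: PointScenario
) -> float:
    value = m.at_scenario(scenario)
    if value is NOT_REPORTED:
        raise ValueError(f"nutrient {m.component} of {product.name} is NOT_REPORTED")
    if m.basis == "per_serving":
        return value
    if m.basis == "per_100g":
        if product.serving_size is None:
            raise ConfigurationError(
                f"{product.name}: per-100g nutrient {m.component} needs a serving size")
        return per_serving_amount(value, product.serving_size)
    raise TypeError(f"{m.component}: basis {m.basis!r} is not a nutrient basis")


def assess_benefits(
    products: list[FoodProduct],
    components: list[ComponentDefinition],
    references: list[ReferenceValue],
    config: AssessmentConfig,
    scenario: PointScenario = "point",
) -> list[ContributionResult]:
    """One :class:`ContributionResult` per (product, nutrient, sex).

    Sex-specific rows appear only where the resolved DRV differs between
    males and females; otherwise a single ``both`` row is emitted. Results
    are ordered product-major, then component in registry order. Nutrients
    without any reference value are emitted with an absent DRV and a
    warning, never dropped.
    """
    refs_by_comp: dict[str, list[ReferenceValue]] = {}
    for r in references:
        refs_by_comp.setdefault(r.component, []).append(r)

    results: list[ContributionResult] = []
    for product in products:
        for comp in components:
            if comp.category != "nutrient":
                continue
            m = product.measurements.get(comp.name)
            if m is None:
                continue
            amount = _amount_for(m, product, scenario)
            refs = refs_by_comp.get(comp.name)
            if not refs:
                warnings.warn(f"no reference value for nutrient {comp.name!r}", stacklevel=2)
                results.append(ContributionResult(
                    product=product.name, component=comp.name, sex="both",
                    amount_per_serving=amount))
                continue
            per_sex = {}
            for sex in ("male", "female"):
                ref = next((r for r in refs if r.sex == sex),
                           next((r for r in refs if r.sex == "both"), None))
                if ref is None:
                    raise ConfigurationError(f"no reference for {comp.name} / {sex}")
                per_sex[sex] = resolve_drv(ref, config, sex)
            sexes: tuple = (("both",) if per_sex["male"] == per_sex["female"]
                            or per_sex["male"] is AS_LOW_AS_POSSIBLE
                            else ("male", "female"))
            for sex in sexes:
                drv = per_sex["male" if sex in ("male", "both") else "female"]
                pct = contribution_pct(amount, drv)
                results.append(ContributionResult(
                    product=product.name, component=comp.name, sex=sex,
                    amount_per_serving=amount,
                    drv=None if drv is AS_LOW_AS_POSSIBLE else drv,
                    contribution_pct=pct,
                    exceeds_drv=isinstance(pct, float) and pct > config.drv_exceedance_flag))
    return results


def benefits_table(results: list[ContributionResult]) -> "pd.DataFrame":
    """Tidy frame: product,component,sex,amount,drv,contribution_pct,exceeds_drv.

    Percentages are display-rounded to 2 d.p. (half up); NA prints as "NA".
    """
    import pandas as pd

    rows = []
    for r in results:
        pct = r.contribution_pct
        rows.append({
            "product": r.product, "component": r.component, "sex": r.sex,
            "amount": r.amount_per_serving,
            "drv": "" if r.drv is None else round_half_up(r.drv, 2),
            "contribution_pct": "NA" if isinstance(pct, Sentinel) else
                                ("" if pct is None else round_half_up(pct, 2)),
            "exceeds_drv": r.exceeds_drv,
        })
    return pd.DataFrame(rows, columns=["product", "component", "sex", "amount",
                                       "drv", "contribution_pct", "exceeds_drv"])


def assess_benefits_dataset(
    ds: Dataset, scenario: PointScenario = "point"
) -> list[ContributionResult]:
    return assess_benefits(ds.products, ds.components, ds.references, ds.config, scenario)
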