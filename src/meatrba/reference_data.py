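"""Component registry, benchmark values, the packaged study fixture, and
dataset I/O.

The fixture describes five pork products — grilled pork (the unprocessed
reference), Chouriço and Salame (fermented), Presunto (dry-cured) and
Fiambre (heat-treated) — with twelve nutrients assessed against EFSA
Dietary Reference Values and seven microbiological/toxicological hazards
assessed against regulatory limits or margin-of-exposure reference points
(BMDL10).

Nutrient amounts are stored per serving. Hazard occurrence is stored on the
basis the comparison uses: CFU/g for *L. monocytogenes*, mg per kg of
product for histamine, and mg per kg body weight per day for nitrite and
the margin-of-exposure hazards (the published intakes are kept verbatim;
where an intake and a concentration disagree the intake wins). Serving
sizes are national-survey averages that were never published directly; the
values here are back-derived from printed concentration/intake pairs and
are approximations (see docs/methods.md).
"""

from __future__ import annotations

import json
import os
from typing import Optional, Union

import pandas as pd
import yaml

from ._states import NOT_REPORTED, Sentinel
from .errors import DatasetValidationError, IOFailure, SchemaError
from .models import (
    AssessmentConfig,
    ComponentDefinition,
    Dataset,
    FoodProduct,
    Measurement,
    ReferenceValue,
)

# --------------------------------------------------------------------------
# component registry

NUTRIENTS: tuple[ComponentDefinition, ...] = (
    ComponentDefinition(name="Protein", category="nutrient", unit="g",
                        benchmark_kind="drv_absolute", color_rule="green_scale"),
    ComponentDefinition(name="Lipid", category="nutrient", unit="g",
                        benchmark_kind="drv_energy_percent", color_rule="green_scale"),
    ComponentDefinition(name="Total saturated fatty acids", category="nutrient", unit="g",
                        benchmark_kind="drv_as_low_as_possible", color_rule="zero_threshold_red"),
    ComponentDefinition(name="Linoleic acid", category="nutrient", unit="g",
                        benchmark_kind="drv_energy_percent", color_rule="green_scale"),
    ComponentDefinition(name="Total trans fatty acids", category="nutrient", unit="g",
                        benchmark_kind="drv_as_low_as_possible", color_rule="zero_threshold_red"),
    ComponentDefinition(name="Sodium", category="nutrient", unit="mg",
                        benchmark_kind="drv_absolute", color_rule="yellow_scale"),
    ComponentDefinition(name="Potassium", category="nutrient", unit="mg",
                        benchmark_kind="drv_absolute", color_rule="green_scale"),
    ComponentDefinition(name="Calcium", category="nutrient", unit="mg",
                        benchmark_kind="drv_absolute", color_rule="green_scale"),
    ComponentDefinition(name="Phosphorus", category="nutrient", unit="mg",
                        benchmark_kind="drv_absolute", color_rule="green_scale"),
    ComponentDefinition(name="Magnesium", category="nutrient", unit="mg",
                        benchmark_kind="drv_absolute", color_rule="green_scale"),
    ComponentDefinition(name="Iron", category="nutrient", unit="mg",
                        benchmark_kind="drv_absolute", color_rule="green_scale"),
    ComponentDefinition(name="Zinc", category="nutrient", unit="mg",
                        benchmark_kind="drv_absolute", color_rule="green_scale"),
)

HAZARDS: tuple[ComponentDefinition, ...] = (
    ComponentDefinition(name="L. monocytogenes", category="hazard", unit="CFU_per_g",
                        benchmark_kind="reg_limit_concentration", color_rule="reg_hazard"),
    ComponentDefinition(name="Histamine", category="hazard", unit="mg_per_kg",
                        benchmark_kind="reg_limit_concentration", color_rule="reg_hazard"),
    ComponentDefinition(name="Nitrite", category="hazard", unit="mg_per_kg_bw_day",
                        benchmark_kind="reg_limit_intake", color_rule="reg_hazard"),
    ComponentDefinition(name="Aflatoxins", category="hazard", unit="mg_per_kg_bw_day",
                        benchmark_kind="moe_reference_point", color_rule="moe_hazard"),
    ComponentDefinition(name="Ochratoxin A", category="hazard", unit="mg_per_kg_bw_day",
                        benchmark_kind="moe_reference_point", color_rule="moe_hazard"),
    ComponentDefinition(name="PAH4", category="hazard", unit="mg_per_kg_bw_day",
                        benchmark_kind="moe_reference_point", color_rule="moe_hazard"),
    ComponentDefinition(name="Benzo(a)pyrene", category="hazard", unit="mg_per_kg_bw_day",
                        benchmark_kind="moe_reference_point", color_rule="moe_hazard"),
)


def component_registry() -> list[ComponentDefinition]:
    """All components in display order: nutrients first, then hazards."""
    return list(NUTRIENTS) + list(HAZARDS)


def get_component(name: str) -> ComponentDefinition:
    for c in component_registry():
        if c.name == name:
            return c
    raise KeyError(name)


# --------------------------------------------------------------------------
# benchmark values

def reference_values() -> list[ReferenceValue]:
    """DRVs (EFSA, adults), regulatory limits and BMDL10 reference points."""
    return [
        ReferenceValue(component="Protein", sex="both", kind="drv_absolute", value=46.2, unit="g"),
        ReferenceValue(component="Lipid", sex="both", kind="drv_energy_percent",
                       energy_fraction=0.20, unit="g"),
        ReferenceValue(component="Total saturated fatty acids", sex="both",
                       kind="drv_as_low_as_possible"),
        ReferenceValue(component="Linoleic acid", sex="both", kind="drv_energy_percent",
                       energy_fraction=0.04, unit="g"),
        ReferenceValue(component="Total trans fatty acids", sex="both",
                       kind="drv_as_low_as_possible"),
        ReferenceValue(component="Sodium", sex="both", kind="drv_absolute", value=2000.0, unit="mg"),
        ReferenceValue(component="Potassium", sex="both", kind="drv_absolute", value=3500.0, unit="mg"),
        # calcium: adequate intake for adults >= 25 y
        ReferenceValue(component="Calcium", sex="both", kind="drv_absolute", value=750.0, unit="mg"),
        ReferenceValue(component="Phosphorus", sex="both", kind="drv_absolute", value=550.0, unit="mg"),
        ReferenceValue(component="Magnesium", sex="male", kind="drv_absolute", value=350.0, unit="mg"),
        ReferenceValue(component="Magnesium", sex="female", kind="drv_absolute", value=300.0, unit="mg"),
        # iron: the female value is the premenopausal requirement
        ReferenceValue(component="Iron", sex="male", kind="drv_absolute", value=6.0, unit="mg"),
        ReferenceValue(component="Iron", sex="female", kind="drv_absolute", value=7.0, unit="mg"),
        ReferenceValue(component="Zinc", sex="male", kind="drv_absolute", value=10.13, unit="mg"),
        ReferenceValue(component="Zinc", sex="female", kind="drv_absolute", value=8.23, unit="mg"),
        # hazards
        ReferenceValue(component="L. monocytogenes", kind="reg_limit_concentration",
                       value=100.0, unit="CFU_per_g"),
        ReferenceValue(component="Histamine", kind="reg_limit_concentration",
                       value=150.0, unit="mg_per_kg"),
        # nitrite ADI, compared on the intake basis
        ReferenceValue(component="Nitrite", kind="reg_limit_intake",
                       value=0.07, unit="mg_per_kg_bw_day"),
        ReferenceValue(component="Aflatoxins", kind="moe_reference_point",
                       value=0.0004, unit="mg_per_kg_bw_day"),
        ReferenceValue(component="Ochratoxin A", kind="moe_reference_point",
                       value=0.01, unit="mg_per_kg_bw_day"),
        ReferenceValue(component="PAH4", kind="moe_reference_point",
                       value=0.34, unit="mg_per_kg_bw_day"),
        ReferenceValue(component="Benzo(a)pyrene", kind="moe_reference_point",
                       value=0.07, unit="mg_per_kg_bw_day"),
    ]


# --------------------------------------------------------------------------
# fixture tables

_NR = "NR"

#: per-serving nutrient amounts, registry order (g for the first five,
#: mg for the minerals)
_NUTRIENT_TABLE: dict[str, tuple[float, ...]] = {
    "Grilled Pork": (8.53, 21.35, 7.67, 2.59, 0.18, 101.40, 144.82, 17.68, 43.16, 32.76, 0.44, 0.94),
    "Chouriço":     (4.19, 9.25, 3.19, 0.91, 0.03, 517.00, 60.90, 5.57, 50.40, 4.41, 0.55, 0.65),
    "Fiambre":      (3.21, 0.97, 0.32, 0.12, 0.00, 196.70, 69.30, 2.24, 56.70, 3.29, 0.70, 1.40),
    "Presunto":     (5.25, 2.69, 0.86, 0.25, 0.00, 539.70, 121.80, 4.83, 42.00, 8.61, 0.42, 0.82),
    "Salame":       (4.10, 7.90, 2.71, 0.78, 0.02, 483.00, 29.40, 5.25, 42.00, 4.62, 0.48, 0.90),
}

#: hazard occurrence: (basis, value-or-"NR") per hazard, registry order
#: L. monocytogenes in CFU/g, histamine in mg/kg product, the rest as
#: published daily intakes in mg/kg bw
_HAZARD_TABLE: dict[str, tuple[tuple[str, object], ...]] = {
    "Grilled Pork": (
        ("cfu_per_g", _NR), ("per_kg_product", 4.10), ("per_kg_bw_day", _NR),
        ("per_kg_bw_day", _NR), ("per_kg_bw_day", _NR),
        ("per_kg_bw_day", 0.00008), ("per_kg_bw_day", 0.00002),
    ),
    "Chouriço": (
        ("cfu_per_g", _NR), ("per_kg_product", 5.0), ("per_kg_bw_day", 0.00750),
        ("per_kg_bw_day", _NR), ("per_kg_bw_day", _NR),
        ("per_kg_bw_day", 0.00021), ("per_kg_bw_day", 0.000001),
    ),
    "Fiambre": (
        ("cfu_per_g", 800.0), ("per_kg_product", 0.27), ("per_kg_bw_day", 0.03),
        ("per_kg_bw_day", _NR), ("per_kg_bw_day", _NR),
        ("per_kg_bw_day", _NR), ("per_kg_bw_day", _NR),
    ),
    "Presunto": (
        ("cfu_per_g", 22.50), ("per_kg_product", 6.05), ("per_kg_bw_day", 0.03),
        ("per_kg_bw_day", _NR), ("per_kg_bw_day", 0.000024),
        ("per_kg_bw_day", _NR), ("per_kg_bw_day", _NR),
    ),
    "Salame": (
        ("cfu_per_g", 3802.0), ("per_kg_product", 235.69), ("per_kg_bw_day", 0.00093),
        ("per_kg_bw_day", _NR), ("per_kg_bw_day", 0.01556),
        ("per_kg_bw_day", 0.00132), ("per_kg_bw_day", 0.00016),
    ),
}

_SCENARIOS: dict[str, str] = {
    "Grilled Pork": "reference",
    "Chouriço": "fermented",
    "Fiambre": "heat_treated",
    "Presunto": "dry_cured",
    "Salame": "fermented",
}

#: serving sizes (g), back-derived from published intake/concentration
#: pairs; approximations, used only for the concentration -> exposure path
_SERVING_SIZES: dict[str, float] = {
    "Grilled Pork": 52.07,  # from the histamine row (0.00305 * 70 / 4.10 kg)
    "Chouriço": 21.0,       # from the nitrite row
    "Fiambre": 21.0,
    "Presunto": 21.0,
    "Salame": 21.0,         # from the histamine row; other rows disagree
}

FIXTURE_PRODUCT_ORDER = ("Grilled Pork", "Chouriço", "Fiambre", "Presunto", "Salame")
#: column order of the published heatmap
HEATMAP_PRODUCT_ORDER = ("Grilled Pork", "Chouriço", "Presunto", "Fiambre", "Salame")


def load_fixture() -> Dataset:
    """The packaged five-product study dataset.

    Returns the five products with every nutrient per-serving amount,
    every hazard occurrence (including NOT_REPORTED states), all DRVs,
    regulatory limits and BMDL10 reference points, and the default
    configuration.
    """
    products: list[FoodProduct] = []
    for name in FIXTURE_PRODUCT_ORDER:
        measurements: dict[str, Measurement] = {}
        for comp, amount in zip(NUTRIENTS, _NUTRIENT_TABLE[name]):
            measurements[comp.name] = Measurement(
                component=comp.name, basis="per_serving", value=amount)
        for comp, (basis, value) in zip(HAZARDS, _HAZARD_TABLE[name]):
            measurements[comp.name] = Measurement(
                component=comp.name, basis=basis,
                value=NOT_REPORTED if value == _NR else float(value))
        products.append(FoodProduct(
            name=name, scenario=_SCENARIOS[name],
            serving_size=_SERVING_SIZES[name], measurements=measurements))
    ds = Dataset(products, component_registry(), reference_values(), AssessmentConfig())
    _validate_dataset(ds)
    return ds


# --------------------------------------------------------------------------
# dataset I/O

_UNIT_ALIASES: dict[str, str] = {
    "g": "g", "mg": "mg",
    "mg/kg": "mg_per_kg", "mg_per_kg": "mg_per_kg",
    "cfu/g": "CFU_per_g", "cfu_per_g": "CFU_per_g",
    "mg/kg bw/day": "mg_per_kg_bw_day", "mg/kg bw": "mg_per_kg_bw_day",
    "mg_per_kg_bw_day": "mg_per_kg_bw_day",
}

#: expected measurement unit for each basis; nutrient bases defer to the
#: component's own unit
_BASIS_UNIT: dict[str, Optional[str]] = {
    "per_100g": None, "per_serving": None,
    "per_kg_product": "mg_per_kg", "cfu_per_g": "CFU_per_g",
    "per_kg_bw_day": "mg_per_kg_bw_day",
}

_NR_TOKENS = {"NR", "NA", "nr", "na"}


def normalize_unit(token: str, *, row: str = "") -> str:
    key = token.strip()
    norm = _UNIT_ALIASES.get(key) or _UNIT_ALIASES.get(key.lower())
    if norm is None:
        raise SchemaError(f"unknown unit {token!r}{f' at {row}' if row else ''}")
    return norm


def _parse_value(tok: str, *, row: str) -> Union[float, Sentinel]:
    tok = tok.strip()
    if tok in _NR_TOKENS:
        return NOT_REPORTED
    try:
        v = float(tok)
    except ValueError:
        raise SchemaError(f"unparseable value {tok!r} at {row}") from None
    if v < 0:
        raise DatasetValidationError(f"negative value {v} at {row}")
    return v


def _validate_dataset(ds: Dataset) -> None:
    known = {c.name for c in ds.components}
    for p in ds.products:
        for comp in p.measurements:
            if comp not in known:
                raise SchemaError(f"unknown component {comp!r} for product {p.name!r}")
    ref_comps = {r.component for r in ds.references}
    missing = {c.name for c in ds.components if c.category == "hazard"} - ref_comps
    if missing:
        raise SchemaError(f"hazards without a benchmark: {sorted(missing)}")


def _expected_unit(component: ComponentDefinition, basis: str) -> str:
    u = _BASIS_UNIT[basis]
    return component.unit if u is None else u


def read_dataset(path: str, format: Optional[str] = None) -> Dataset:
    """Read a dataset from a directory of CSVs or a single JSON document.

    The CSV layout is three files: ``products.csv``
    (product,scenario,serving_size), ``measurements.csv``
    (product,component,basis,value,unit[,value_min,value_max], with the
    literal token ``NR`` permitted in value) and ``references.csv``
    (component,sex,kind,value,unit[,energy_fraction,upper_limit]), plus an
    optional ``config.yaml``/``config.json``. The JSON format mirrors the
    same content in one document.
    """
    if format is None:
        format = "json" if str(path).endswith(".json") else "csv"
    if format == "json":
        return _read_json(path)
    if format == "csv":
        return _read_csv_dir(path)
    raise SchemaError(f"unknown dataset format {format!r}")


def _read_csv_dir(path: str) -> Dataset:
    for fname in ("products.csv", "measurements.csv", "references.csv"):
        if not os.path.exists(os.path.join(path, fname)):
            raise IOFailure(f"missing {fname} under {path}")
    prod_df = pd.read_csv(os.path.join(path, "products.csv"),
                          dtype=str, keep_default_na=False)
    meas_df = pd.read_csv(os.path.join(path, "measurements.csv"),
                          dtype=str, keep_default_na=False)
    ref_df = pd.read_csv(os.path.join(path, "references.csv"),
                         dtype=str, keep_default_na=False)

    components = component_registry()
    by_name = {c.name: c for c in components}

    records: dict[str, dict[str, Measurement]] = {}
    seen: set[tuple[str, str]] = set()
    for i, row in meas_df.iterrows():
        where = f"measurements.csv row {i + 2}"
        prod, comp = row["product"], row["component"]
        if comp not in by_name:
            raise SchemaError(f"unknown component {comp!r} at {where}")
        if (prod, comp) in seen:
            raise DatasetValidationError(f"duplicate (product, component) ({prod}, {comp}) at {where}")
        seen.add((prod, comp))
        basis = row["basis"].strip()
        if basis not in _BASIS_UNIT:
            raise SchemaError(f"unknown basis {basis!r} at {where}")
        unit = normalize_unit(row["unit"], row=where)
        if unit != _expected_unit(by_name[comp], basis):
            raise SchemaError(
                f"unit {unit!r} inconsistent with component {comp!r} on basis "
                f"{basis!r} at {where}")
        value = _parse_value(row["value"], row=where)
        kwargs = {}
        for bound in ("value_min", "value_max"):
            tok = str(row.get(bound, "") or "").strip()
            if tok:
                kwargs[bound] = float(tok)
        try:
            m = Measurement(component=comp, basis=basis, value=value, **kwargs)
        except ValueError as e:
            raise DatasetValidationError(f"{e} at {where}") from None
        records.setdefault(prod, {})[comp] = m

    products: list[FoodProduct] = []
    for i, row in prod_df.iterrows():
        serving = str(row.get("serving_size", "") or "").strip()
        products.append(FoodProduct(
            name=row["product"], scenario=row["scenario"].strip(),
            serving_size=float(serving) if serving else None,
            measurements=records.pop(row["product"], {})))
    if records:
        raise SchemaError(f"measurements for undeclared products: {sorted(records)}")

    references: list[ReferenceValue] = []
    for i, row in ref_df.iterrows():
        where = f"references.csv row {i + 2}"
        val = str(row.get("value", "") or "").strip()
        frac = str(row.get("energy_fraction", "") or "").strip()
        upper = str(row.get("upper_limit", "") or "").strip()
        unit = str(row.get("unit", "") or "").strip()
        try:
            references.append(ReferenceValue(
                component=row["component"], sex=(row.get("sex") or "both").strip() or "both",
                kind=row["kind"].strip(),
                value=float(val) if val else None,
                unit=normalize_unit(unit, row=where) if unit else None,
                energy_fraction=float(frac) if frac else None,
                upper_limit=float(upper) if upper else None))
        except ValueError as e:
            raise DatasetValidationError(f"{e} at {where}") from None

    config = AssessmentConfig()
    for cfg_name in ("config.yaml", "config.json"):
        cfg_path = os.path.join(path, cfg_name)
        if os.path.exists(cfg_path):
            config = load_config(cfg_path)
            break

    ds = Dataset(products, components, references, config)
    _validate_dataset(ds)
    return ds


def _measurement_to_dict(prod: str, m: Measurement) -> dict:
    return {
        "product": prod, "component": m.component, "basis": m.basis,
        "value": "NR" if m.value is NOT_REPORTED else m.value,
        "value_min": m.value_min, "value_max": m.value_max,
    }


def _read_json(path: str) -> Dataset:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except OSError as e:
        raise IOFailure(str(e)) from None
    components = component_registry()
    by_name = {c.name: c for c in components}
    products = []
    for p in doc["products"]:
        measurements = {}
        for m in p["measurements"]:
            if m["component"] not in by_name:
                raise SchemaError(f"unknown component {m['component']!r}")
            value = NOT_REPORTED if m["value"] == "NR" else m["value"]
            if isinstance(value, (int, float)) and value < 0:
                raise DatasetValidationError(f"negative value for {m['component']}")
            if m["component"] in measurements:
                raise DatasetValidationError(
                    f"duplicate (product, component) ({p['name']}, {m['component']})")
            measurements[m["component"]] = Measurement(
                component=m["component"], basis=m["basis"], value=value,
                value_min=m.get("value_min"), value_max=m.get("value_max"))
        products.append(FoodProduct(
            name=p["name"], scenario=p["scenario"],
            serving_size=p.get("serving_size"), measurements=measurements))
    references = [ReferenceValue(**r) for r in doc["references"]]
    config = AssessmentConfig(**doc.get("config", {}))
    ds = Dataset(products, components, references, config)
    _validate_dataset(ds)
    return ds


def write_dataset(ds: Dataset, path: str, format: str = "csv") -> None:
    """Inverse of :func:`read_dataset`; round-trips exactly."""
    if format == "json":
        doc = {
            "products": [
                {"name": p.name, "scenario": p.scenario, "serving_size": p.serving_size,
                 "measurements": [_measurement_to_dict(p.name, m)
                                  for m in p.measurements.values()]}
                for p in ds.products
            ],
            "references": [
                {k: v for k, v in r.model_dump().items() if v is not None}
                for r in ds.references
            ],
            "config": ds.config.model_dump(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, ensure_ascii=False, indent=1)
        return
    if format != "csv":
        raise SchemaError(f"unknown dataset format {format!r}")
    os.makedirs(path, exist_ok=True)
    pd.DataFrame([
        {"product": p.name, "scenario": p.scenario, "serving_size": p.serving_size}
        for p in ds.products
    ]).to_csv(os.path.join(path, "products.csv"), index=False)
    rows = []
    for p in ds.products:
        for m in p.measurements.values():
            d = _measurement_to_dict(p.name, m)
            d["unit"] = _expected_unit(get_component(m.component), m.basis)
            # repr keeps the shortest decimal that round-trips the float
            for k in ("value", "value_min", "value_max"):
                if isinstance(d[k], float):
                    d[k] = repr(d[k])
            rows.append(d)
    pd.DataFrame(rows, columns=["product", "component", "basis", "value", "unit",
                                "value_min", "value_max"]).to_csv(
        os.path.join(path, "measurements.csv"), index=False)
    pd.DataFrame([
        {"component": r.component, "sex": r.sex, "kind": r.kind,
         "value": repr(r.value) if r.value is not None else "",
         "unit": r.unit or "",
         "energy_fraction": repr(r.energy_fraction) if r.energy_fraction is not None else "",
         "upper_limit": repr(r.upper_limit) if r.upper_limit is not None else ""}
        for r in ds.references
    ]).to_csv(os.path.join(path, "references.csv"), index=False)
    with open(os.path.join(path, "config.yaml"), "w") as fh:
        yaml.safe_dump(ds.config.model_dump(), fh)


def load_config(path: str) -> AssessmentConfig:
    """Load an :class:`AssessmentConfig` from YAML or JSON."""
    try:
        with open(path) as fh:
            doc = yaml.safe_load(fh) if path.endswith((".yaml", ".yml")) else json.load(fh)
    except OSError as e:
        raise IOFailure(str(e)) from None
    from .errors import ConfigurationError
    try:
        return AssessmentConfig(**(doc or {}))
    except ValueError as e:
        raise ConfigurationError(str(e)) from None
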