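"""Harmonized heatmap classification and rendering.

Coloring rules, applied per component row across products:

* most nutrients: green scale, darker = higher contribution to the DRV
  (intensity = value / row maximum);
* sodium: the same gradient in yellow, because higher intakes are
  undesirable;
* trans/saturated fatty acids ("as low as possible"): zero is flat green,
  any non-zero amount is red with darkness by amount;
* any contribution above 100% of the DRV: flat red exceedance flag;
* regulated hazards: red above the limit (darker = greater exceedance
  relative to the row's worst offender), green below (darker = further
  under the limit);
* margin-of-exposure hazards: green when MoE >= 10,000, red below, with
  intensity log-scaled in decades of distance from the threshold (the red
  side is capped at 4 decades, matching the span of observed margins);
* NOT_REPORTED: flat green labelled "NR" — absence of evidence, kept
  visually distinct from quantified results.

Intensities always live in [0, 1]. Rendered outputs map (channel,
intensity) to colors by linear interpolation between fixed palette
endpoints (:data:`PALETTE`).
"""

from __future__ import annotations

import html as _html
import json
import math
import os
from typing import Literal, Optional, Union

import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator

from ._states import NA, Sentinel, is_number
from ._util import round_half_up
from .errors import IOFailure, MeatRbaError
from .benefit_assessment import ContributionResult
from .risk_assessment import HazardResult
from .models import AssessmentConfig, ComponentDefinition, FoodProduct

#: (intensity 0, intensity 1) hex endpoints per channel
PALETTE: dict[str, tuple[str, str]] = {
    "green": ("#e8f5e9", "#1b5e20"),
    "yellow": ("#fffde7", "#f9a825"),
    "red": ("#ffebee", "#b71c1c"),
}

#: decades of MoE shortfall mapped onto the full red range
MOE_RED_DECADES = 4.0


class HeatmapCell(BaseModel):
    """One classified cell: value, color channel, intensity and flags."""

    model_config = ConfigDict(arbitrary_types_allowed=True, frozen=True)

    value: Union[float, Sentinel] = NA
    channel: Literal["green", "yellow", "red"]
    intensity: float
    label: str
    nr: bool = False
    exceedance_flag: bool = False

    @field_validator("intensity")
    @classmethod
    def _unit_interval(cls, v):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"intensity must lie in [0, 1], got {v}")
        return v


class RowLabel(BaseModel):
    model_config = ConfigDict(frozen=True)

    component: str
    sex: Literal["male", "female", "both"] = "both"
    kind: Literal["nutrient", "hazard"]

    def display(self) -> str:
        suffix = {"male": " (M)", "female": " (F)"}.get(self.sex, "")
        return f"{self.component}{suffix}"


class HeatmapMatrix(BaseModel):
    rows: list[RowLabel]
    columns: list[str]
    cells: list[list[HeatmapCell]]  # rows x columns

    model_config = ConfigDict(arbitrary_types_allowed=True)


def _fmt(value: Union[float, Sentinel]) -> str:
    if isinstance(value, Sentinel):
        return value.name
    if 0 < abs(value) < 0.01:  # keep tiny intakes legible
        return f"{value:.2g}"
    r = round_half_up(value, 2)
    return f"{r:.2f}"


def classify_nutrient_cell(
    result: ContributionResult,
    rule: Literal["green_scale", "yellow_scale", "zero_threshold_red"],
    row_context: list[float],
    config: AssessmentConfig,
) -> HeatmapCell:
    """Classify one benefit cell against its component row.

    ``row_context`` carries the same quantity for every product in the row
    (contribution % for gradient rules, absolute amount for the
    zero-threshold rule); the gradient is normalized by the row maximum.
    """
    if not row_context:
        raise MeatRbaError(f"{result.component}: empty row context")
    pct = result.contribution_pct
    if rule in ("green_scale", "yellow_scale"):
        value = pct if is_number(pct) else result.amount_per_serving
        row_max = max(row_context)
        intensity = 0.0 if row_max == 0 else min(1.0, value / row_max)
        channel = "green" if rule == "green_scale" else "yellow"
        cell = HeatmapCell(value=value, channel=channel, intensity=intensity,
                           label=_fmt(value))
    elif rule == "zero_threshold_red":
        value = result.amount_per_serving
        if value == 0:
            cell = HeatmapCell(value=0.0, channel="green", intensity=0.0, label=_fmt(0.0))
        else:
            row_max = max(row_context)
            cell = HeatmapCell(value=value, channel="red",
                               intensity=min(1.0, value / row_max), label=_fmt(value))
    else:
        raise MeatRbaError(f"{rule!r} is not a nutrient color rule")
    if is_number(pct) and pct > config.drv_exceedance_flag:
        cell = HeatmapCell(value=cell.value, channel="red", intensity=1.0,
                           label=cell.label, exceedance_flag=True)
    return cell


def classify_hazard_cell(
    result: HazardResult,
    config: AssessmentConfig,
    row_context: Optional[list[HazardResult]] = None,
) -> HeatmapCell:
    """Classify one hazard cell.

    For regulated hazards the red gradient is scaled by the worst
    exceedance in the row (``row_context``); a sole exceeder is fully dark.
    """
    if result.nr:
        return HeatmapCell(value=NA, channel="green", intensity=0.0, label="NR", nr=True)
    if result.mode == "moe":
        moe = result.moe
        if not is_number(moe):  # zero exposure: margin undefined
            return HeatmapCell(value=NA, channel="green", intensity=0.0, label="NA")
        if moe >= config.moe_threshold:
            intensity = min(1.0, math.log10(moe / config.moe_threshold))
            return HeatmapCell(value=moe, channel="green", intensity=intensity,
                               label=_fmt(moe))
        intensity = min(1.0, math.log10(config.moe_threshold / moe) / MOE_RED_DECADES)
        return HeatmapCell(value=moe, channel="red", intensity=intensity, label=_fmt(moe))
    # regulatory modes
    ratio = result.ratio
    if result.exceeds:
        peers = [r.ratio for r in (row_context or [result])
                 if is_number(r.ratio) and r.exceeds is True] or [ratio]
        ratio_max = max(peers)
        intensity = 1.0 if ratio_max <= 1.0 or ratio >= ratio_max \
            else min(1.0, (ratio - 1.0) / (ratio_max - 1.0))
        return HeatmapCell(value=result.observed, channel="red", intensity=intensity,
                           label=_fmt(result.observed))
    return HeatmapCell(value=result.observed, channel="green",
                       intensity=max(0.0, 1.0 - ratio), label=_fmt(result.observed))


def _heatmap_columns(products: list[FoodProduct]) -> list[str]:
    from .reference_data import FIXTURE_PRODUCT_ORDER, HEATMAP_PRODUCT_ORDER

    names = [p.name for p in products]
    if set(names) == set(FIXTURE_PRODUCT_ORDER):
        return list(HEATMAP_PRODUCT_ORDER)
    return names


def build_heatmap(
    benefits: list[ContributionResult],
    risks: list[HazardResult],
    products: list[FoodProduct],
    components: list[ComponentDefinition],
    config: AssessmentConfig,
) -> HeatmapMatrix:
    """Assemble the full matrix: nutrient rows (sex-split where DRVs
    differ) followed by hazard rows, columns in scenario display order.

    Hazard rows in which every product is NOT_REPORTED are omitted, as in
    the published summary; NR cells inside partially reported rows remain.
    """
    columns = _heatmap_columns(products)
    risk_products = {r.product for r in risks}
    benefit_products = {r.product for r in benefits}
    if risks and benefits and not risk_products <= set(columns):
        raise MeatRbaError("risk results reference unknown products")
    orphans = risk_products - benefit_products
    if benefits and orphans:
        raise MeatRbaError(f"products with risks but no benefits: {sorted(orphans)}")

    by_comp = {c.name: c for c in components}
    rows: list[RowLabel] = []
    cells: list[list[HeatmapCell]] = []

    ben_idx: dict[tuple[str, str, str], ContributionResult] = {
        (r.component, r.sex, r.product): r for r in benefits}
    ben_sexes: dict[str, list[str]] = {}
    for r in benefits:
        sexes = ben_sexes.setdefault(r.component, [])
        if r.sex not in sexes:
            sexes.append(r.sex)
    for comp in components:
        if comp.category != "nutrient" or comp.name not in ben_sexes:
            continue
        for sex in sorted(ben_sexes[comp.name], key=("male", "female", "both").index):
            row_results = [ben_idx[(comp.name, sex, col)] for col in columns
                           if (comp.name, sex, col) in ben_idx]
            if comp.color_rule == "zero_threshold_red":
                context = [r.amount_per_serving for r in row_results]
            else:
                context = [r.contribution_pct if is_number(r.contribution_pct)
                           else r.amount_per_serving for r in row_results]
            row_cells = []
            for col in columns:
                r = ben_idx.get((comp.name, sex, col))
                if r is None:
                    raise MeatRbaError(f"missing benefit cell ({comp.name}, {sex}, {col})")
                row_cells.append(classify_nutrient_cell(r, comp.color_rule, context, config))
            rows.append(RowLabel(component=comp.name, sex=sex, kind="nutrient"))
            cells.append(row_cells)

    risk_idx: dict[tuple[str, str], HazardResult] = {
        (r.component, r.product): r for r in risks}
    for comp in components:
        if comp.category != "hazard":
            continue
        row_results = [risk_idx[(comp.name, col)] for col in columns
                       if (comp.name, col) in risk_idx]
        if not row_results or all(r.nr for r in row_results):
            continue  # nothing reported anywhere: row carries no signal
        row_cells = []
        for col in columns:
            r = risk_idx.get((comp.name, col))
            if r is None:
                raise MeatRbaError(f"missing hazard cell ({comp.name}, {col})")
            row_cells.append(classify_hazard_cell(r, config, row_context=row_results))
        rows.append(RowLabel(component=comp.name, sex="both", kind="hazard"))
        cells.append(row_cells)

    return HeatmapMatrix(rows=rows, columns=columns, cells=cells)


# --------------------------------------------------------------------------
# serialization

def _cell_dict(c: HeatmapCell) -> dict:
    return {"value": "NA" if isinstance(c.value, Sentinel) else c.value,
            "channel": c.channel, "intensity": c.intensity, "label": c.label,
            "nr": c.nr, "exceedance_flag": c.exceedance_flag}


def _cell_from_dict(d: dict) -> HeatmapCell:
    return HeatmapCell(value=NA if d["value"] == "NA" else d["value"],
                       channel=d["channel"], intensity=d["intensity"],
                       label=d["label"], nr=d["nr"],
                       exceedance_flag=d["exceedance_flag"])


def matrix_to_dict(matrix: HeatmapMatrix) -> dict:
    return {
        "columns": list(matrix.columns),
        "rows": [r.model_dump() for r in matrix.rows],
        "cells": [[_cell_dict(c) for c in row] for row in matrix.cells],
    }


def matrix_from_dict(doc: dict) -> HeatmapMatrix:
    return HeatmapMatrix(
        rows=[RowLabel(**r) for r in doc["rows"]],
        columns=doc["columns"],
        cells=[[_cell_from_dict(c) for c in row] for row in doc["cells"]])


def matrix_to_frame(matrix: HeatmapMatrix) -> pd.DataFrame:
    rows = []
    for label, row in zip(matrix.rows, matrix.cells):
        for col, c in zip(matrix.columns, row):
            d = _cell_dict(c)
            rows.append({"component": label.component, "sex": label.sex,
                         "kind": label.kind, "product": col, **d})
    return pd.DataFrame(rows, columns=["component", "sex", "kind", "product",
                                       "value", "channel", "intensity", "label",
                                       "nr", "exceedance_flag"])


def matrix_from_frame(df: pd.DataFrame) -> HeatmapMatrix:
    rows: list[RowLabel] = []
    columns: list[str] = []
    cell_map: dict[tuple, HeatmapCell] = {}
    for _, rec in df.iterrows():
        label = RowLabel(component=rec["component"], sex=rec["sex"], kind=rec["kind"])
        if label not in rows:
            rows.append(label)
        if rec["product"] not in columns:
            columns.append(rec["product"])
        cell_map[(label.component, label.sex, rec["product"])] = _cell_from_dict({
            "value": "NA" if rec["value"] == "NA" else float(rec["value"]),
            "channel": rec["channel"], "intensity": float(rec["intensity"]),
            "label": str(rec["label"]),
            "nr": rec["nr"] in (True, "True"),
            "exceedance_flag": rec["exceedance_flag"] in (True, "True")})
    cells = [[cell_map[(r.component, r.sex, col)] for col in columns] for r in rows]
    return HeatmapMatrix(rows=rows, columns=columns, cells=cells)


def cell_color(channel: str, intensity: float) -> str:
    """Hex color for a cell by linear interpolation between palette endpoints."""
    lo, hi = PALETTE[channel]
    mix = []
    for i in (1, 3, 5):
        a, b = int(lo[i:i + 2], 16), int(hi[i:i + 2], 16)
        mix.append(round(a + (b - a) * intensity))
    return "#{:02x}{:02x}{:02x}".format(*mix)


def _render_html(matrix: HeatmapMatrix) -> str:
    out = ["<!DOCTYPE html>", "<html><head><meta charset='utf-8'>",
           "<style>table{border-collapse:collapse}td,th{border:1px solid #999;"
           "padding:4px 8px;font:12px sans-serif;text-align:center}</style>",
           "</head><body><table>", "<tr><th></th>"]
    out += [f"<th>{_html.escape(c)}</th>" for c in matrix.columns]
    out.append("</tr>")
    for label, row in zip(matrix.rows, matrix.cells):
        out.append(f"<tr><th>{_html.escape(label.display())}</th>")
        for c in row:
            out.append(f"<td style='background:{cell_color(c.channel, c.intensity)}'>"
                       f"{_html.escape(c.label)}</td>")
        out.append("</tr>")
    out += ["</table></body></html>", ""]
    return "\n".join(out)


def _render_svg(matrix: HeatmapMatrix, cw: int = 110, ch: int = 22,
                label_w: int = 220) -> str:
    width = label_w + cw * len(matrix.columns)
    height = ch * (len(matrix.rows) + 1)
    parts = [f"<svg xmlns='http://www.w3.org/2000/svg' width='{width}' "
             f"height='{height}' font-family='sans-serif' font-size='11'>"]
    for j, col in enumerate(matrix.columns):
        parts.append(f"<text x='{label_w + j * cw + cw / 2}' y='{ch - 7}' "
                     f"text-anchor='middle'>{_html.escape(col)}</text>")
    for i, (label, row) in enumerate(zip(matrix.rows, matrix.cells)):
        y = ch * (i + 1)
        parts.append(f"<text x='4' y='{y + ch - 7}'>{_html.escape(label.display())}</text>")
        for j, c in enumerate(row):
            x = label_w + j * cw
            parts.append(f"<rect x='{x}' y='{y}' width='{cw}' height='{ch}' "
                         f"fill='{cell_color(c.channel, c.intensity)}' "
                         f"stroke='#999'/>")
            parts.append(f"<text x='{x + cw / 2}' y='{y + ch - 7}' "
                         f"text-anchor='middle'>{_html.escape(c.label)}</text>")
    parts.append("</svg>")
    parts.append("")
    return "\n".join(parts)


def render(matrix: HeatmapMatrix, format: Literal["csv", "json", "html", "svg"],
           path: str) -> str:
    """Write the matrix to disk; CSV/JSON round-trip the matrix exactly."""
    if format == "json":
        content = json.dumps(matrix_to_dict(matrix), ensure_ascii=False, indent=1) + "\n"
    elif format == "csv":
        content = matrix_to_frame(matrix).to_csv(index=False)
    elif format == "html":
        content = _render_html(matrix)
    elif format == "svg":
        content = _render_svg(matrix)
    else:
        raise MeatRbaError(f"unknown render format {format!r}")
    try:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(content)
    except OSError as e:
        raise IOFailure(f"cannot write {path}: {e}") from None
    return path


def load_matrix(path: str) -> HeatmapMatrix:
    """Read a matrix back from a CSV or JSON render."""
    if path.endswith(".json"):
        with open(path, encoding="utf-8") as fh:
            return matrix_from_dict(json.load(fh))
    return matrix_from_frame(pd.read_csv(path, dtype=str, keep_default_na=False))
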