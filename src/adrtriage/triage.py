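"""Triage: extend report tables with assessments and signals, filter, export.

Filtering mirrors brushing on a parallel-coordinates display: a query is a
pure conjunction of per-column range predicates (one brush per axis).  Two
published exploration workflows ship as a named catalogue:

* ``fig5_opposite_assessments`` — suspect drugs whose model assessment
  strongly contradicts the reporter side (risk_s < -8) while the provincial
  experts rated the report probable or certain;
* ``fig6_unreviewed_certain`` — suspect drugs never reviewed provincially
  (prov_assess = -1) that the model rates certain (auto_assess = 5).

``export_viz`` writes the parallel-coordinates snapshot: a JSON document
with the default axis ordering and the red-yellow-blue category colour map
(category 1 red through 5 blue), plus a self-contained static HTML/SVG
rendering of it.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from html import escape
from pathlib import Path

import numpy as np
import pandas as pd

from .model import PPOResults
from .schema import ReportTable
from .signal import DEFAULT_VARIANT, compute_signal

__all__ = [
    "FilterPredicate",
    "TriageQuery",
    "parse_predicate",
    "extend_reports",
    "filter_reports",
    "paper_workflow_queries",
    "export_viz",
    "VIZ_AXES",
    "CATEGORY_COLORS",
]

#: Default parallel-coordinates axis ordering.
VIZ_AXES = (
    "new_ade", "serious_ade", "gender",
    "r_assess", "ri_assess", "muni_assess", "prov_assess",
    "suspect", "auto_assess", "risk_s", "risk_t",
)

#: 5-class red-yellow-blue map: causality category 1 (red) .. 5 (blue).
CATEGORY_COLORS = {
    1: "#d7191c", 2: "#fdae61", 3: "#ffffbf", 4: "#abd9e9", 5: "#2c7bb6",
}

_OPS = {
    "eq": lambda col, v: col == v,
    "ne": lambda col, v: col != v,
    "lt": lambda col, v: col < v,
    "le": lambda col, v: col <= v,
    "gt": lambda col, v: col > v,
    "ge": lambda col, v: col >= v,
    "in_set": lambda col, v: col.isin(list(v)),
    "between": lambda col, v: (col >= v[0]) & (col <= v[1]),
}


@dataclass(frozen=True)
class FilterPredicate:
    """One brushing condition: ``column op value``."""

    column: str
    op: str
    value: object

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ValueError(f"unknown operator {self.op!r}; choose from {sorted(_OPS)}")
        if self.op == "between":
            lo, hi = self.value
            if lo > hi:
                raise ValueError(f"between requires lo <= hi, got ({lo}, {hi})")

    def mask(self, df: pd.DataFrame) -> pd.Series:
        if self.column not in df.columns:
            raise KeyError(f"unknown column {self.column!r}")
        return _OPS[self.op](df[self.column], self.value)


@dataclass(frozen=True)
class TriageQuery:
    """Conjunction of predicates; an empty query selects everything."""

    predicates: tuple[FilterPredicate, ...] = ()
    name: str | None = None

    def mask(self, df: pd.DataFrame) -> pd.Series:
        mask = pd.Series(True, index=df.index)
        for pred in self.predicates:
            mask &= pred.mask(df)
        return mask


_PRED_RE = re.compile(r"^\s*(\w+)\s*(<=|>=|!=|=|<|>)\s*(-?\d+(?:\.\d+)?)\s*$")
_SYM_OPS = {"=": "eq", "!=": "ne", "<": "lt", "<=": "le", ">": "gt", ">=": "ge"}


def parse_predicate(text: str) -> FilterPredicate:
    """Parse ``"column op value"`` strings such as ``"risk_s<-8"``."""
    m = _PRED_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse predicate {text!r} (expected e.g. 'risk_s<-8')")
    column, op, value = m.groups()
    num = float(value)
    return FilterPredicate(column, _SYM_OPS[op], int(num) if num.is_integer() else num)


def extend_reports(
    table: ReportTable,
    model: PPOResults | None = None,
    variant: str = DEFAULT_VARIANT,
    y0_source: str = "ri_assess",
    predictions=None,
) -> ReportTable:
    """Append ``auto_assess``, ``risk_s``, ``risk_t`` and ``signal_variant``.

    The model assessment Y comes from ``model.predict_category`` (or the
    explicit ``predictions`` vector); Y0 from the ``y0_source`` column.
    Rows with a missing Y0 get an undefined signal (NaN), which range
    predicates never match.  Original columns and row order are untouched;
    re-running overwrites the same columns with identical content.
    """
    if (model is None) == (predictions is None):
        raise ValueError("provide exactly one of model or predictions")
    if y0_source not in ("r_assess", "ri_assess", "muni_assess", "prov_assess"):
        raise ValueError(f"invalid y0_source {y0_source!r}")
    df = table.df.copy()
    if predictions is None:
        auto = np.asarray(model.predict_category(table.predictors()), dtype=int)
    else:
        auto = np.asarray(predictions, dtype=int)
        if len(auto) != len(df):
            raise ValueError("predictions length must match table")
    y0 = df[y0_source].to_numpy(dtype=int)
    serious = df["serious_ade"].to_numpy(dtype=int) == 1

    s = np.full(len(df), np.nan)
    t = np.full(len(df), np.nan)
    for i, (yi, y0i, si) in enumerate(zip(auto, y0, serious)):
        sig = compute_signal(int(yi), int(y0i), bool(si), variant, y0_source)
        if sig.defined:
            s[i], t[i] = sig.s, sig.t
    df["auto_assess"] = auto
    df["risk_s"] = s
    df["risk_t"] = t
    df["signal_variant"] = variant
    return ReportTable(df, source=table.source)


def filter_reports(table: ReportTable, query: TriageQuery) -> ReportTable:
    """Rows satisfying every predicate, in original order."""
    mask = query.mask(table.df)
    return ReportTable(table.df[mask].copy(), source=table.source)


def paper_workflow_queries() -> dict[str, TriageQuery]:
    """The two published brushing workflows as named queries."""
    fig5 = TriageQuery(
        (
            FilterPredicate("suspect", "eq", 1),
            FilterPredicate("risk_s", "lt", -8),
            FilterPredicate("prov_assess", "gt", 3),
            FilterPredicate("r_assess", "le", 3),
            FilterPredicate("ri_assess", "le", 3),
            FilterPredicate("muni_assess", "le", 3),
        ),
        name="fig5_opposite_assessments",
    )
    fig6 = TriageQuery(
        (
            FilterPredicate("suspect", "eq", 1),
            FilterPredicate("prov_assess", "eq", -1),
            FilterPredicate("auto_assess", "eq", 5),
        ),
        name="fig6_unreviewed_certain",
    )
    return {q.name: q for q in (fig5, fig6)}


# ---------------------------------------------------------------------------
# static export

_HTML_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>ADR report parallel coordinates</title></head>
<body>
<h3>ADR reports — parallel-coordinates snapshot ({n} rows)</h3>
<p>Polylines coloured by model causality category: 1 (red) … 5 (blue).</p>
{svg}
</body></html>
"""


def _render_svg(df: pd.DataFrame, axes: tuple[str, ...], width=1100, height=420) -> str:
    pad, top, bottom = 50, 30, 40
    step = (width - 2 * pad) / (len(axes) - 1)
    spans = {}
    for ax in axes:
        vals = pd.to_numeric(df[ax], errors="coerce")
        lo, hi = float(vals.min()), float(vals.max())
        if not np.isfinite(lo) or lo == hi:
            lo, hi = lo - 0.5 if np.isfinite(lo) else 0.0, (hi + 0.5 if np.isfinite(hi) else 1.0)
        spans[ax] = (lo, hi)
    parts = []
    for i, ax in enumerate(axes):
        x = pad + i * step
        parts.append(
            f'<line x1="{x:.0f}" y1="{top}" x2="{x:.0f}" y2="{height - bottom}" stroke="#999"/>'
            f'<text x="{x:.0f}" y="{height - bottom + 16}" font-size="9" text-anchor="middle">{escape(ax)}</text>'
        )
    for _, row in df.iterrows():
        pts = []
        for i, ax in enumerate(axes):
            lo, hi = spans[ax]
            v = row[ax]
            v = lo if pd.isna(v) else float(v)
            y = height - bottom - (v - lo) / (hi - lo) * (height - top - bottom)
            pts.append(f"{pad + i * step:.1f},{y:.1f}")
        color = CATEGORY_COLORS.get(int(row["auto_assess"]), "#888888")
        parts.append(
            f'<polyline points="{" ".join(pts)}" fill="none" stroke="{color}" '
            'stroke-opacity="0.45" stroke-width="1"/>'
        )
    return (
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}">'
        + "".join(parts)
        + "</svg>"
    )


def export_viz(table: ReportTable, path: str | Path) -> None:
    """Write the visualization JSON and a static HTML/SVG snapshot.

    ``path`` names the HTML file; the JSON document (axis ordering, rows,
    colour map) is written next to it with a ``.json`` suffix.  Requires an
    extended table (``auto_assess``/``risk_s``/``risk_t`` present).
    """
    missing = [c for c in VIZ_AXES if c not in table.df.columns]
    if missing:
        raise ValueError(f"table not extended; missing column(s): {missing}")
    path = Path(path)
    df = table.df
    doc = {
        "axes": list(VIZ_AXES),
        "category_colors": {str(k): v for k, v in CATEGORY_COLORS.items()},
        "n": len(df),
        "rows": [
            [None if pd.isna(v) else (float(v) if isinstance(v, float) else int(v))
             for v in row]
            for row in df[list(VIZ_AXES)].itertuples(index=False)
        ],
    }
    json_path = path.with_suffix(".json")
    json_path.write_text(json.dumps(doc, indent=2), encoding="utf-8")
    html = _HTML_TEMPLATE.format(n=len(df), svg=_render_svg(df, VIZ_AXES))
    path.write_text(html, encoding="utf-8")
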