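"""Report data model for spontaneous ADR report tables.

A report table is a :class:`pandas.DataFrame` wrapped in light provenance
metadata.  Columns follow a fixed snake_case schema:

* eleven Boolean assessment predictors — ``casualty_assessment_1..5``
  (plausible time relationship, known ADR type, response to withdrawal,
  rechallenge, explainable by other factors) and ``severity_assessment_1..6``
  (death, carcinogenic/teratogenic, disability, life-threatening,
  hospitalization, other significant event);
* Boolean metadata flags ``new_ade``, ``serious_ade``, ``gender``,
  ``suspect``;
* four ordinal causality assessments ``r_assess``, ``ri_assess``,
  ``muni_assess``, ``prov_assess`` on the WHO-UMC-style 1..5 scale
  (1 = unassessable .. 5 = certain), with −1 as the missing sentinel;
* an optional expert label column ``label`` (same coding) for training;
* any further columns are carried through verbatim as free text.

Files are UTF-8 CSV with a mandatory header.  Booleans are accepted as
``{0, 1, true, false, TRUE, FALSE}`` and written back as ``0``/``1``.
Blank ordinal cells map to −1 (missing) with a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "PREDICTOR_COLUMNS",
    "CAUSALITY_COLUMNS",
    "FLAG_COLUMNS",
    "ORDINAL_VALUES",
    "MISSING",
    "ReportTable",
    "SchemaViolation",
    "SchemaError",
    "ValidationError",
    "read_report_table",
    "write_report_table",
    "validate_schema",
    "load_column_schema",
]

PREDICTOR_COLUMNS: tuple[str, ...] = tuple(
    [f"casualty_assessment_{i}" for i in range(1, 6)]
    + [f"severity_assessment_{i}" for i in range(1, 7)]
)
SEVERITY_COLUMNS: tuple[str, ...] = tuple(f"severity_assessment_{i}" for i in range(1, 7))
FLAG_COLUMNS: tuple[str, ...] = ("new_ade", "serious_ade", "gender", "suspect")
CAUSALITY_COLUMNS: tuple[str, ...] = ("r_assess", "ri_assess", "muni_assess", "prov_assess")

#: Valid ordinal codes: 1..5 increasing certainty, −1 missing.
ORDINAL_VALUES = frozenset({-1, 1, 2, 3, 4, 5})
MISSING = -1

REQUIRED_COLUMNS: tuple[str, ...] = PREDICTOR_COLUMNS + FLAG_COLUMNS + CAUSALITY_COLUMNS

_BOOL_TOKENS = {"0": 0, "1": 1, "true": 1, "false": 0}


class SchemaError(ValueError):
    """A required column is missing or mistyped."""


class ValidationError(ValueError):
    """A cell value violates the declared domain; message names row and column."""


@dataclass(frozen=True)
class SchemaViolation:
    """One violated rule, located by row index and column."""

    row: int
    column: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"row {self.row}, {self.column}: [{self.rule}] {self.message}"


@dataclass
class ReportTable:
    """An ordered collection of ADR report records.

    Thin wrapper over a DataFrame; ``df`` holds one row per report with the
    schema columns typed as integers and extra columns preserved as text.
    """

    df: pd.DataFrame
    source: str | None = None
    extra_columns: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        self.extra_columns = tuple(
            c for c in self.df.columns if c not in REQUIRED_COLUMNS and c != "label"
        )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def has_labels(self) -> bool:
        return "label" in self.df.columns

    def predictors(self) -> np.ndarray:
        """The n × 11 Boolean predictor matrix in schema order."""
        return self.df[list(PREDICTOR_COLUMNS)].to_numpy(dtype=float)

    def labels(self) -> np.ndarray:
        if not self.has_labels:
            raise SchemaError("table carries no 'label' column")
        return self.df["label"].to_numpy(dtype=int)

    def copy(self) -> "ReportTable":
        return ReportTable(self.df.copy(), source=self.source)


def load_column_schema() -> dict:
    """The machine-readable column schema shipped with the package."""
    text = resources.files("adrtriage").joinpath("report_schema.json").read_text("utf-8")
    return json.loads(text)


def _parse_bool(raw: object, row: int, column: str) -> int:
    token = str(raw).strip().lower()
    if token in _BOOL_TOKENS:
        return _BOOL_TOKENS[token]
    raise ValidationError(
        f"row {row}, {column}: invalid Boolean value {raw!r} (expected 0/1/true/false)"
    )


def _parse_ordinal(raw: object, row: int, column: str) -> int:
    token = str(raw).strip()
    if token == "" or token.lower() == "nan":
        warnings.warn(
            f"row {row}, {column}: blank assessment treated as missing (-1)",
            stacklevel=3,
        )
        return MISSING
    try:
        value = int(float(token))
    except ValueError:
        raise ValidationError(f"row {row}, {column}: non-numeric ordinal value {raw!r}") from None
    if value not in ORDINAL_VALUES:
        raise ValidationError(
            f"row {row}, {column}: ordinal code {value} outside {{-1, 1..5}}"
        )
    return value


def read_report_table(path: str | Path, *, sep: str = ",") -> ReportTable:
    """Read and validate a report CSV.

    Every Boolean and ordinal cell is parsed against the declared domain;
    the first offending cell raises :class:`ValidationError` naming its row
    (0-based data row) and column.  An empty file (header only) yields an
    empty table.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")

    out = pd.DataFrame(index=raw.index)
    bool_cols = PREDICTOR_COLUMNS + FLAG_COLUMNS
    for col in raw.columns:
        if col in bool_cols:
            out[col] = [_parse_bool(v, i, col) for i, v in enumerate(raw[col])]
        elif col in CAUSALITY_COLUMNS or col == "label":
            out[col] = [_parse_ordinal(v, i, col) for i, v in enumerate(raw[col])]
        elif col == "auto_assess":
            out[col] = pd.to_numeric(raw[col]).astype(int)
        elif col in ("risk_s", "risk_t"):
            # extension columns: blank = undefined signal
            out[col] = pd.to_numeric(raw[col].replace("", None))
        else:
            out[col] = raw[col]
    if "label" in out.columns and len(out) and (out["label"] == MISSING).any():
        row = int(out.index[out["label"] == MISSING][0])
        raise ValidationError(f"row {row}, label: training label may not be missing (-1)")
    return ReportTable(out, source=str(path))


def write_report_table(table: ReportTable, path: str | Path, *, sep: str = ",") -> None:
    """Write a table as canonical CSV (Booleans as 0/1, UTF-8)."""
    table.df.to_csv(Path(path), sep=sep, index=False, encoding="utf-8")


def _iter_violations(table: ReportTable) -> Iterable[SchemaViolation]:
    df = table.df
    for col in PREDICTOR_COLUMNS + FLAG_COLUMNS:
        bad = ~df[col].isin((0, 1))
        for row in df.index[bad]:
            yield SchemaViolation(int(row), col, "boolean_domain", f"value {df.at[row, col]!r} not in {{0,1}}")
    for col in CAUSALITY_COLUMNS + (("label",) if table.has_labels else ()):
        bad = ~df[col].isin(sorted(ORDINAL_VALUES))
        for row in df.index[bad]:
            yield SchemaViolation(int(row), col, "ordinal_domain", f"value {df.at[row, col]!r} not in {{-1,1..5}}")
    # serious_ade should agree with the OR of the severity items; real-data
    # ingestion tolerates disagreement, so this is a warning-level rule.
    sev_or = (df[list(SEVERITY_COLUMNS)].isin((0, 1)) & (df[list(SEVERITY_COLUMNS)] == 1)).any(axis=1)
    mismatch = df["serious_ade"].isin((0, 1)) & (df["serious_ade"].astype(int) != sev_or.astype(int))
    for row in df.index[mismatch]:
        yield SchemaViolation(
            int(row), "serious_ade", "severity_consistency",
            "serious_ade flag disagrees with OR of severity_assessment_1..6",
        )


def validate_schema(table: ReportTable) -> list[SchemaViolation]:
    """Check all invariants; returns located violations and never raises."""
    return list(_iter_violations(table))
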