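"""Loading, typing and role validation for rectangular cohort tables.

A cohort table is a samples x variables rectangle with one unique-identifier
column and one target (grouping) column whose values define the
subpopulations being compared (e.g. case vs control).  Cells are held as
floats (strict ``.``-decimal parse), strings, or a single missing marker —
identical content regardless of whether the source file was CSV or XLSX.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    DuplicateIdentifierError,
    EmptyTableError,
    RaggedRowsError,
    RoleConflictError,
    TargetCardinalityError,
    UnknownColumnError,
    UnreadableFileError,
)

#: Missing-value tokens recognized in input files (case-insensitive).
MISSING_TOKENS = frozenset({"", "na", "nan", "n/a", "null"})

#: The in-memory missing marker.  A single sentinel keeps cell-level equality
#: checks trivial (``pd.isna`` everywhere).
MISSING = pd.NA

#: Maximum number of distinct values for a numeric column to still be treated
#: as categorical; doubles as the subpopulation cap on the target variable.
MAX_CATEGORIES = 15

_NUMBER_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def parse_cell(raw: object) -> object:
    """Normalize one raw cell to float, string, or the missing marker.

    Numbers must use ``.`` as the decimal separator; anything else (including
    locale variants like ``1,5``) stays text, so a forced-continuous override
    on such a column fails loudly downstream rather than silently coercing.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return MISSING
    if isinstance(raw, (int, float)) and not isinstance(raw, bool):
        return float(raw)
    text = str(raw).strip()
    if text.lower() in MISSING_TOKENS:
        return MISSING
    if _NUMBER_RE.match(text):
        return float(text)
    return text


@dataclass(frozen=True)
class VariableSpec:
    """Per-variable metadata driving imputation and test selection."""

    name: str
    kind: str  # "categorical" | "continuous"
    role: str  # "identifier" | "target" | "feature"
    n_missing: int
    n_distinct: int
    is_binary: bool


@dataclass
class CohortTable:
    """The loaded samples x variables rectangle with assigned roles.

    ``df`` holds object-dtype cells (float | str | missing marker).
    ``id_column`` / ``target_column`` are None until `validate_roles` runs.
    """

    df: pd.DataFrame
    id_column: str | None = None
    target_column: str | None = None

    @property
    def n_rows(self) -> int:
        return len(self.df)

    @property
    def n_columns(self) -> int:
        return self.df.shape[1]

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    def ids(self) -> list:
        if self.id_column is None:
            raise RoleConflictError("identifier role not assigned yet")
        return list(self.df[self.id_column])

    def group_sizes(self) -> dict:
        """Subpopulation sizes of the target variable, by target value."""
        if self.target_column is None:
            raise RoleConflictError("target role not assigned yet")
        counts = self.df[self.target_column].value_counts(dropna=True)
        return {k: int(v) for k, v in counts.items()}

    def subset_by_ids(self, keep: Iterable) -> "CohortTable":
        keep = set(keep)
        mask = self.df[self.id_column].isin(keep)
        return replace(self, df=self.df[mask].reset_index(drop=True))

    def write_csv(self, path: str | Path) -> None:
        """Serialize back to CSV; missing cells become empty strings."""
        out = self.df.map(_render_cell)
        out.to_csv(path, index=False)


def _render_cell(value: object) -> str:
    if value is MISSING or (isinstance(value, float) and np.isnan(value)):
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def load_table(path: str | Path, format: str | None = None) -> CohortTable:
    """Load a CSV or XLSX file into a `CohortTable`.

    The format is inferred from the extension when not given.  Raises
    `UnreadableFileError`, `RaggedRowsError` or `EmptyTableError` as distinct
    failure modes.
    """
    path = Path(path)
    if not path.exists():
        raise UnreadableFileError(f"file not found: {path}")
    if format is None:
        format = "xlsx" if path.suffix.lower() in {".xlsx", ".xls"} else "csv"
    if format == "csv":
        rows = _read_csv_rows(path)
    elif format == "xlsx":
        rows = _read_xlsx_rows(path)
    else:
        raise UnreadableFileError(f"unknown format: {format!r}")

    if not rows:
        raise EmptyTableError(f"{path}: no header row")
    header = [str(h).strip() for h in rows[0]]
    if len(set(header)) != len(header):
        raise UnreadableFileError(f"{path}: duplicate column names in header")
    body = rows[1:]
    if not body or not header:
        raise EmptyTableError(f"{path}: table has no data rows")
    width = len(header)
    for i, row in enumerate(body, start=2):
        if len(row) != width:
            raise RaggedRowsError(
                f"{path}: row {i} has {len(row)} cells, header has {width}"
            )
    cells = [[parse_cell(c) for c in row] for row in body]
    df = pd.DataFrame(cells, columns=header, dtype=object)
    return CohortTable(df=df)


def _read_csv_rows(path: Path) -> list[list]:
    try:
        with open(path, newline="", encoding="utf-8-sig") as fh:
            return [row for row in csv.reader(fh)]
    except (OSError, UnicodeDecodeError, csv.Error) as exc:
        raise UnreadableFileError(f"cannot read {path}: {exc}") from exc


def _read_xlsx_rows(path: Path) -> list[list]:
    import openpyxl

    try:
        wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    except Exception as exc:  # openpyxl raises a zoo of types
        raise UnreadableFileError(f"cannot read {path}: {exc}") from exc
    ws = wb.worksheets[0]
    rows = [list(row) for row in ws.iter_rows(values_only=True)]
    wb.close()
    # trim fully-empty trailing rows that Excel files often carry
    while rows and all(c is None for c in rows[-1]):
        rows.pop()
    return rows


def infer_variable_types(
    table: CohortTable,
    overrides: Mapping[str, str] | None = None,
    max_categories: int = MAX_CATEGORIES,
) -> list[VariableSpec]:
    """Classify every column as categorical or continuous.

    A column is continuous iff all its non-missing values are numeric and it
    has more than ``max_categories`` distinct values; user overrides win.
    Roles already assigned on the table are reflected in the specs.
    """
    overrides = dict(overrides or {})
    for name in overrides:
        if name not in table.df.columns:
            raise UnknownColumnError(f"override names unknown column {name!r}")
        if overrides[name] not in {"categorical", "continuous"}:
            raise UnknownColumnError(
                f"override for {name!r} must be 'categorical' or 'continuous'"
            )
    specs = []
    for name in table.df.columns:
        col = table.df[name]
        non_missing = col[~col.isna()]
        n_missing = int(col.isna().sum())
        distinct = pd.unique(non_missing)
        n_distinct = len(distinct)
        all_numeric = bool(len(non_missing)) and all(
            isinstance(v, float) for v in non_missing
        )
        if name in overrides:
            kind = overrides[name]
        elif all_numeric and n_distinct > max_categories:
            kind = "continuous"
        else:
            kind = "categorical"
        if name == table.id_column:
            role = "identifier"
        elif name == table.target_column:
            role = "target"
        else:
            role = "feature"
        specs.append(
            VariableSpec(
                name=name,
                kind=kind,
                role=role,
                n_missing=n_missing,
                n_distinct=n_distinct,
                is_binary=(n_distinct == 2),
            )
        )
    return specs


def validate_roles(table: CohortTable, target: str, identifier: str) -> CohortTable:
    """Assign identifier and target roles, enforcing their invariants.

    The identifier must be unique and never missing; the target must yield
    between 2 and 15 subpopulations.
    """
    for name in (target, identifier):
        if name not in table.df.columns:
            raise UnknownColumnError(f"column {name!r} not in table")
    if target == identifier:
        raise RoleConflictError("target and identifier must be different columns")

    ids = table.df[identifier]
    if ids.isna().any():
        missing_rows = [i + 1 for i in ids[ids.isna()].index]
        raise DuplicateIdentifierError(
            f"identifier {identifier!r} missing in data row(s) {missing_rows}"
        )
    dupes = ids[ids.duplicated()]
    if len(dupes):
        raise DuplicateIdentifierError(
            f"identifier {identifier!r} has duplicate value(s): "
            f"{sorted(set(map(str, dupes)))}"
        )

    tgt = table.df[target]
    n_groups = tgt.dropna().nunique()
    if n_groups < 2:
        raise TargetCardinalityError(
            f"target {target!r} has {n_groups} subpopulation(s); need at least 2"
        )
    if n_groups > MAX_CATEGORIES:
        raise TargetCardinalityError(
            f"target {target!r} has too many subpopulations "
            f"({n_groups} > {MAX_CATEGORIES})"
        )
    return replace(table, id_column=identifier, target_column=target)
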