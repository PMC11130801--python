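"""Typed missing-value imputation applied before testing and equalization.

Categorical variables are filled with the mode regardless of how much is
missing (ties broken by the lexicographically smallest category, so the fill
is deterministic).  Continuous variables are only filled when strictly less
than half the values are missing: a Shapiro–Wilk gate picks the mean when the
observed values look normal (p > 0.05) and the median otherwise, so the fill
value tracks the distribution's natural centre.  Every fill is logged in an
`ImputationRecord` for the report.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd
from scipy import stats

from .dataset_io import MISSING, CohortTable, VariableSpec
from .errors import AllMissingError

#: continuous variables with at least this fraction missing are left alone
MISSINGNESS_CUTOFF = 0.5

#: Shapiro–Wilk p above this means "treat as normal"
NORMALITY_ALPHA = 0.05


@dataclass(frozen=True)
class ImputationRecord:
    variable: str
    method: str  # "mode" | "mean" | "median" | "none"
    n_imputed: int
    fill_value: object
    missing_fraction: float
    flag: str | None = None  # warning, e.g. excess missingness


def impute_categorical(values: list, variable: str = "") -> tuple[list, ImputationRecord]:
    """Fill missing cells with the mode of the observed values."""
    observed = [v for v in values if not pd.isna(v)]
    if not observed:
        raise AllMissingError(f"variable {variable!r} has no observed values")
    n_missing = len(values) - len(observed)
    counts: dict = {}
    for v in observed:
        counts[v] = counts.get(v, 0) + 1
    top = max(counts.values())
    # tie-break: lexicographically smallest category (compared as strings)
    fill = min((c for c, n in counts.items() if n == top), key=str)
    filled = [fill if pd.isna(v) else v for v in values]
    rec = ImputationRecord(
        variable=variable,
        method="mode" if n_missing else "none",
        n_imputed=n_missing,
        fill_value=fill if n_missing else None,
        missing_fraction=n_missing / len(values),
    )
    return filled, rec


def impute_continuous(values: list, variable: str = "") -> tuple[list, ImputationRecord]:
    """Normality-gated mean/median fill for a numeric column.

    At or above 50% missing the column is returned untouched with a warning
    flag.  With fewer than 3 observed values the Shapiro–Wilk test is
    undefined, so the median is used and flagged.
    """
    observed = [float(v) for v in values if not pd.isna(v)]
    if not observed:
        raise AllMissingError(f"variable {variable!r} has no observed values")
    n_missing = len(values) - len(observed)
    frac = n_missing / len(values)
    if frac >= MISSINGNESS_CUTOFF:
        rec = ImputationRecord(
            variable=variable, method="none", n_imputed=0, fill_value=None,
            missing_fraction=frac, flag="excess_missingness",
        )
        return list(values), rec
    if n_missing == 0:
        rec = ImputationRecord(
            variable=variable, method="none", n_imputed=0, fill_value=None,
            missing_fraction=0.0,
        )
        return list(values), rec

    ser = pd.Series(observed, dtype=float)
    flag = None
    if len(observed) < 3 or ser.nunique() == 1:
        method, fill = "median", float(ser.median())
        flag = "normality_test_undefined"
    else:
        _, p = stats.shapiro(observed)
        if p > NORMALITY_ALPHA:
            method, fill = "mean", float(ser.mean())
        else:
            method, fill = "median", float(ser.median())
    filled = [fill if pd.isna(v) else float(v) for v in values]
    rec = ImputationRecord(
        variable=variable, method=method, n_imputed=n_missing,
        fill_value=fill, missing_fraction=frac, flag=flag,
    )
    return filled, rec


def missingness_summary(table: CohortTable) -> list[tuple[str, int, float]]:
    """(variable, n_missing, missing_fraction) for every non-identifier column."""
    out = []
    n = table.n_rows
    for name in table.columns:
        if name == table.id_column:
            continue
        n_missing = int(table.df[name].isna().sum())
        out.append((name, n_missing, n_missing / n if n else 0.0))
    return out


def impute_table(
    table: CohortTable, specs: list[VariableSpec]
) -> tuple[CohortTable, list[ImputationRecord]]:
    """Apply the typed rules to every feature column; identifier and target
    columns are never imputed."""
    df = table.df.copy()
    records = []
    by_name = {s.name: s for s in specs}
    for name in table.columns:
        if name in (table.id_column, table.target_column):
            continue
        spec = by_name[name]
        values = list(df[name])
        if not any(pd.isna(v) for v in values):
            records.append(ImputationRecord(
                variable=name, method="none", n_imputed=0,
                fill_value=None, missing_fraction=0.0,
            ))
            continue
        if spec.kind == "categorical":
            filled, rec = impute_categorical(values, variable=name)
        else:
            filled, rec = impute_continuous(values, variable=name)
        df[name] = pd.Series(filled, dtype=object)
        records.append(rec)
    return replace(table, df=df), records
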