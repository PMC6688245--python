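"""CSV serialization and validation of survey tables.

The on-disk interchange format is a flat CSV with one row per most-recent
birth and a documented header (see :data:`obdecomp.simulate.SURVEY_COLUMNS`).
An optional variable dictionary maps arbitrary column names onto the model
roles, so users holding DHS exports can adapt their headers without editing
files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import BINARY_VARS, CATEGORICAL_LEVELS, COUNT_VARS, SchemaError
from .simulate import SURVEY_COLUMNS

__all__ = ["read_survey_csv", "write_survey_csv", "validate_survey_table"]

MANDATORY_COLUMNS = tuple(SURVEY_COLUMNS)
OPTIONAL_COLUMNS = ("mills_ratio", "sampling_weight", "selected")


def _bad_rows(mask: pd.Series, limit: int = 5) -> list[int]:
    return [int(i) for i in np.flatnonzero(mask.to_numpy())[:limit]]


def validate_survey_table(df: pd.DataFrame, require_outcome: bool = True) -> pd.DataFrame:
    """Check a survey table against the variable dictionary; row numbers in
    error messages are 0-based data rows."""
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    if len(df) == 0:
        raise SchemaError("survey table is empty")
    df = df.copy()
    for var in ("reform_period", "survey_year"):
        df[var] = pd.to_numeric(df[var], errors="raise").astype(int)
    has_selection = "selected" in df.columns
    if require_outcome:
        if has_selection:
            observed = df["selected"].astype(float) == 1.0
            bad = observed & ~df["outcome"].isin([0, 1])
        else:
            bad = ~df["outcome"].isin([0, 1])
        if bad.any():
            raise SchemaError(
                f"outcome must be 0/1; invalid values at rows {_bad_rows(bad)}"
            )
    for var, levels in CATEGORICAL_LEVELS.items():
        if var not in df.columns:
            continue
        bad = ~df[var].isin(levels)
        if bad.any():
            raise SchemaError(
                f"column {var!r} has undeclared categories at rows {_bad_rows(bad)}"
            )
    for var in BINARY_VARS:
        if var in df.columns:
            bad = ~df[var].isin([0, 1])
            if bad.any():
                raise SchemaError(f"column {var!r} must be 0/1; rows {_bad_rows(bad)}")
    for var in COUNT_VARS:
        vals = pd.to_numeric(df[var], errors="raise")
        bad = (vals < 0) | (vals != vals.round())
        if bad.any():
            raise SchemaError(f"column {var!r} must be a non-negative count; rows {_bad_rows(bad)}")
        df[var] = vals.astype(int)
    if (df["parity"] < 1).any():
        raise SchemaError(
            f"parity must be >= 1 for birth rows; rows {_bad_rows(df['parity'] < 1)}"
        )
    if "mills_ratio" in df.columns:
        bad = df["mills_ratio"].notna() & (df["mills_ratio"] <= 0)
        if bad.any():
            raise SchemaError(f"mills_ratio must be strictly positive; rows {_bad_rows(bad)}")
    return df


def read_survey_csv(path, variable_dictionary: dict[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a survey CSV.

    *variable_dictionary* maps file column names to model roles, e.g.
    ``{"v025": "residence"}``; unmapped columns keep their names.
    """
    df = pd.read_csv(path)
    if variable_dictionary:
        df = df.rename(columns=dict(variable_dictionary))
    has_selection = "selected" in df.columns
    df = validate_survey_table(df, require_outcome=True)
    if not has_selection:
        df["outcome"] = df["outcome"].astype(int)
    return df


def write_survey_csv(table: pd.DataFrame, path) -> None:
    """Write a survey table with the documented column order."""
    cols = [c for c in list(MANDATORY_COLUMNS) + list(OPTIONAL_COLUMNS) if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, index=False)
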