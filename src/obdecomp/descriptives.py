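"""Descriptive tables by residence group.

Percentages for categorical and binary variables, means for parity and
antenatal visits, the institutional-delivery rate, and an urban − rural gap
column in percentage points (for the mean rows, in the variable's units).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import BINARY_VARS, CATEGORICAL_LEVELS, COUNT_VARS

__all__ = ["descriptives", "outcome_gap_pp"]


def _group_stats(sub: pd.DataFrame) -> dict[tuple[str, str], float]:
    rows: dict[tuple[str, str], float] = {}
    n = len(sub)
    rows[("sample", "n")] = float(n)
    if n == 0:
        return rows
    rows[("outcome", "institutional_delivery_pct")] = 100.0 * sub["outcome"].mean()
    for var, levels in CATEGORICAL_LEVELS.items():
        if var in ("residence",) or var not in sub.columns:
            continue
        counts = sub[var].value_counts(normalize=True)
        for lvl in levels:
            rows[(var, str(lvl))] = 100.0 * float(counts.get(lvl, 0.0))
    for var in sorted(BINARY_VARS):
        if var in sub.columns:
            rows[(var, "pct")] = 100.0 * sub[var].mean()
    for var in sorted(COUNT_VARS):
        if var in sub.columns:
            rows[(var, "mean")] = float(sub[var].mean())
    if "anc_visits" in sub.columns:
        rows[("anc_visits", "four_plus_pct")] = 100.0 * (sub["anc_visits"] >= 4).mean()
    return rows


def descriptives(table: pd.DataFrame, by_year: bool = False) -> pd.DataFrame:
    """Per-residence descriptive statistics with an urban − rural gap column.

    Returns a frame indexed by (variable, statistic) with columns ``rural``,
    ``urban``, ``gap``; with *by_year* the columns gain a survey-year level.
    A group absent from the table yields NaN in its column and in the gap.
    """
    if len(table) == 0:
        raise ValueError("descriptives requires a non-empty table")

    def _one_window(win: pd.DataFrame) -> pd.DataFrame:
        cols = {}
        for group in ("rural", "urban"):
            cols[group] = pd.Series(_group_stats(win.loc[win["residence"] == group]))
        out = pd.DataFrame(cols)
        out["gap"] = out["urban"] - out["rural"]
        out.loc[("sample", "n"), "gap"] = np.nan
        return out

    if not by_year:
        return _one_window(table)
    frames = {"pooled": _one_window(table)}
    for year in sorted(table["survey_year"].unique()):
        frames[str(year)] = _one_window(table.loc[table["survey_year"] == year])
    return pd.concat(frames, axis=1)


def outcome_gap_pp(table: pd.DataFrame) -> float:
    """Urban − rural institutional-delivery gap in percentage points."""
    d = descriptives(table)
    return float(d.loc[("outcome", "institutional_delivery_pct"), "gap"])
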