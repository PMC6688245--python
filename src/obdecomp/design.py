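"""Variable dictionary and design-matrix construction.

Decomposition results depend on how categorical covariates are encoded, so the
design matrix is built here with a fixed, documented level order (first listed
level is the reference) rather than delegated to a formula engine.  Every
column of the design carries a stable term name (``var[level]`` for a dummy,
the bare variable name for a numeric column, ``intercept`` for the constant),
and the same namespace is shared by fitted coefficient vectors, population
coefficient vectors and detailed-decomposition variable groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORICAL_LEVELS",
    "BINARY_VARS",
    "COUNT_VARS",
    "OUTCOME_TERMS",
    "SELECTION_TERMS",
    "DesignMeta",
    "SchemaError",
    "build_design",
    "design_terms",
    "default_variable_groups",
]


class SchemaError(ValueError):
    """A table or term list does not match the declared variable dictionary."""


#: Declared level order per categorical variable; the first level is the
#: reference category in every design matrix.
CATEGORICAL_LEVELS: dict[str, list] = {
    "age_band": ["15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49"],
    "education": ["none", "primary", "secondary", "tertiary"],
    "wealth_quintile": ["q1", "q2", "q3", "q4", "q5"],
    "ethnicity": ["akan", "ga", "ewe", "other"],
    "religion": ["christian", "muslim", "traditional", "no_religion", "other"],
    "marital_status": ["married", "formerly_married", "never_married"],
    "reform_period": [1, 2, 3],
    "survey_year": [2003, 2008, 2014],
    "residence": ["rural", "urban"],
}

#: 0/1 variables entering designs as single numeric columns.
BINARY_VARS = frozenset({"complications", "distance_barrier", "contraceptive_use"})

#: Non-negative count variables entering designs as numeric columns.
COUNT_VARS = frozenset({"parity", "anc_visits"})

#: Numeric columns that may be attached to a table after estimation stages.
_NUMERIC_EXTRA = frozenset({"mills_ratio", "sampling_weight"})

#: Default outcome-equation term list: the full covariate set of the
#: institutional-delivery model (age, education, wealth, parity, pregnancy
#: complications, distance barrier, reform period, antenatal care, ethnicity,
#: religion, survey year).  Antenatal care enters as the 4+-visits indicator
#: by default; pass ``anc_visits`` instead for the continuous count.
OUTCOME_TERMS: tuple[str, ...] = (
    "age_band",
    "education",
    "wealth_quintile",
    "parity",
    "complications",
    "distance_barrier",
    "reform_period",
    "anc4",
    "ethnicity",
    "religion",
    "survey_year",
)

#: Default selection-equation term list (first-stage probit for having had a
#: birth): mother's age, education, wealth, religion, ethnicity, marital
#: status, residence and contraceptive use.
SELECTION_TERMS: tuple[str, ...] = (
    "age_band",
    "education",
    "wealth_quintile",
    "religion",
    "ethnicity",
    "marital_status",
    "residence",
    "contraceptive_use",
)


@dataclass(frozen=True)
class DesignMeta:
    """Encoding metadata: reference category per categorical variable and the
    variable behind each design column."""

    reference: dict[str, object] = field(default_factory=dict)
    term_variable: dict[str, str] = field(default_factory=dict)


def _expand_variable(var: str) -> list[str]:
    if var in CATEGORICAL_LEVELS:
        levels = CATEGORICAL_LEVELS[var]
        return [f"{var}[{lvl}]" for lvl in levels[1:]]
    return [var]


def design_terms(variables: list[str] | tuple[str, ...]) -> list[str]:
    """Expand a variable list into the full design term namespace
    (``intercept`` first, then dummy/numeric columns in declared order)."""
    terms = ["intercept"]
    for var in variables:
        terms.extend(_expand_variable(var))
    return terms


def _numeric_column(df: pd.DataFrame, var: str) -> np.ndarray:
    if var == "anc4":
        if "anc_visits" not in df.columns:
            raise SchemaError("term 'anc4' requires an 'anc_visits' column")
        return (df["anc_visits"].to_numpy(dtype=float) >= 4).astype(float)
    if var not in df.columns:
        raise SchemaError(f"unknown term {var!r}: no such column")
    col = df[var].to_numpy(dtype=float)
    if var in BINARY_VARS and not np.isin(col, (0.0, 1.0)).all():
        raise SchemaError(f"binary variable {var!r} has values outside {{0,1}}")
    return col


def build_design(
    df: pd.DataFrame, variables: list[str] | tuple[str, ...]
) -> tuple[pd.DataFrame, DesignMeta]:
    """Build the design matrix for *variables* from a survey table.

    Categorical variables expand to first-reference dummies with the level
    order of :data:`CATEGORICAL_LEVELS`; binary, count and derived variables
    become single float columns.  Returns the design (with an ``intercept``
    column) and the encoding metadata.
    """
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(df))}
    reference: dict[str, object] = {}
    term_variable: dict[str, str] = {"intercept": "intercept"}
    for var in variables:
        if var in CATEGORICAL_LEVELS:
            levels = CATEGORICAL_LEVELS[var]
            if var not in df.columns:
                raise SchemaError(f"unknown term {var!r}: no such column")
            values = df[var]
            bad = ~values.isin(levels)
            if bad.any():
                rows = list(values.index[bad][:5])
                raise SchemaError(
                    f"column {var!r} has undeclared categories "
                    f"{sorted(values[bad].unique().tolist(), key=str)} (rows {rows})"
                )
            reference[var] = levels[0]
            for lvl in levels[1:]:
                name = f"{var}[{lvl}]"
                cols[name] = (values == lvl).to_numpy(dtype=float)
                term_variable[name] = var
        else:
            cols[var] = _numeric_column(df, var)
            term_variable[var] = var
    X = pd.DataFrame(cols, index=df.index)
    return X, DesignMeta(reference=reference, term_variable=term_variable)


def default_variable_groups(terms: list[str]) -> dict[str, list[str]]:
    """Partition non-intercept *terms* into the named variable groups used by
    the detailed decomposition (wealth, education, antenatal care, parity, age,
    ethnicity, religion, marital status, distance, complications, reforms,
    survey effect, Mills ratio)."""
    group_of = {
        "wealth_quintile": "wealth",
        "education": "education",
        "anc4": "antenatal",
        "anc_visits": "antenatal",
        "parity": "parity",
        "age_band": "age",
        "ethnicity": "ethnicity",
        "religion": "religion",
        "marital_status": "marital_status",
        "distance_barrier": "distance",
        "complications": "complications",
        "mills_ratio": "mills_ratio",
        "reform_period": "reforms",
        "survey_year": "survey_effect",
        "residence": "residence",
        "contraceptive_use": "contraception",
    }
    groups: dict[str, list[str]] = {}
    for term in terms:
        if term == "intercept":
            continue
        var = term.split("[", 1)[0]
        groups.setdefault(group_of.get(var, var), []).append(term)
    return groups
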