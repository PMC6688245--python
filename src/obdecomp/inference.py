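"""Bootstrap inference for decomposition components.

The decomposition is a smooth functional of two independent group fits, so a
nonparametric pairs bootstrap, stratified by residence (and survey year when
pooling surveys), gives standard errors and percentile intervals for every
component.  A component is flagged significant at the 5% level when its
percentile 95% interval excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decompose import scheme_weight, threefold, twofold
from .estimation import ConvergenceError, _complete_cases, fit_group_model
from .design import OUTCOME_TERMS, build_design

__all__ = ["ComponentInference", "bootstrap_components", "decompose_table"]


@dataclass(frozen=True)
class ComponentInference:
    """Bootstrap summary for one scheme's components."""

    scheme: str
    point: dict[str, float]
    se: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    significant_at_5pct: dict[str, bool]
    n_replicates: int
    n_failed: int
    seed: int

    def __post_init__(self):
        for k in self.point:
            if self.ci_low[k] > self.ci_high[k]:
                raise ValueError(f"interval for {k!r} has lower > upper")


def decompose_table(
    table: pd.DataFrame,
    scheme: str,
    link: str = "logit",
    variables: tuple[str, ...] | list[str] | None = None,
    exclude_terms: tuple[str, ...] = (),
    include_mills: bool = False,
    omega: float | None = None,
):
    """Fit both group models on *table* and return the scheme's decomposition.

    The overall entry point used by the bootstrap and the pipeline: fits the
    urban and rural equations, builds the group designs, and dispatches to the
    three-fold (oaxaca/blinder) or two-fold (reimers/cotton, or an explicit
    *omega* override) decomposition.
    """
    fits = {}
    designs = {}
    variables_eff = list(variables if variables is not None else OUTCOME_TERMS)
    if include_mills and "mills_ratio" not in variables_eff:
        variables_eff.append("mills_ratio")
    for group in ("urban", "rural"):
        fit = fit_group_model(
            table, group, link=link, variables=variables_eff, exclude_terms=exclude_terms
        )
        sub = table.loc[table["residence"] == group]
        needed = ["outcome"] + [
            "anc_visits" if v == "anc4" else v for v in variables_eff
        ]
        sub = _complete_cases(sub, needed, f"{group} design")
        X, _ = build_design(sub, variables_eff)
        X = X.drop(columns=[t for t in exclude_terms if t in X.columns])
        fits[group] = fit
        designs[group] = X
    if omega is not None:
        return twofold(fits["urban"], fits["rural"], designs["urban"], designs["rural"],
                       omega, scheme=scheme), fits, designs
    if scheme in ("oaxaca", "blinder"):
        ref = "urban" if scheme == "oaxaca" else "rural"
        result = threefold(fits["urban"], fits["rural"], designs["urban"], designs["rural"], ref)
    else:
        w = scheme_weight(scheme, n_u=fits["urban"].n_obs, n_r=fits["rural"].n_obs)
        result = twofold(fits["urban"], fits["rural"], designs["urban"], designs["rural"],
                         w, scheme=scheme)
    return result, fits, designs


def _strata(table: pd.DataFrame, stratify_by_year: bool) -> list[np.ndarray]:
    keys = ["residence"]
    if stratify_by_year and "survey_year" in table.columns and table["survey_year"].nunique() > 1:
        keys.append("survey_year")
    grouped = table.groupby(keys, sort=True, observed=True)
    return [np.asarray(idx) for _, idx in grouped.indices.items()]


def bootstrap_components(
    table: pd.DataFrame,
    scheme: str = "oaxaca",
    link: str = "logit",
    variables: tuple[str, ...] | list[str] | None = None,
    exclude_terms: tuple[str, ...] = (),
    include_mills: bool = False,
    omega: float | None = None,
    B: int = 1000,
    seed: int = 0,
    max_failure_rate: float = 0.05,
) -> ComponentInference:
    """Pairs bootstrap of all decomposition components.

    Rows are resampled with replacement within strata defined by residence
    (and survey year when several surveys are pooled); both group equations
    are refit and the full decomposition recomputed per replicate.  Failed
    replicate fits (separation in a resample) are dropped and counted, with
    an error if more than *max_failure_rate* of replicates fail.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    for group in ("urban", "rural"):
        if (table["residence"] == group).sum() == 0:
            raise ValueError(f"group {group!r} absent from table; cannot bootstrap")
    point_result, _, _ = decompose_table(
        table, scheme, link=link, variables=variables,
        exclude_terms=exclude_terms, include_mills=include_mills, omega=omega,
    )
    point = dict(point_result.components())
    point["total"] = point_result.total
    table = table.reset_index(drop=True)
    strata = _strata(table, stratify_by_year=True)
    rng = np.random.default_rng(seed)
    draws: dict[str, list[float]] = {k: [] for k in point}
    n_failed = 0
    for _ in range(B):
        idx = np.concatenate([s[rng.integers(0, len(s), size=len(s))] for s in strata])
        boot = table.iloc[idx]
        try:
            res, _, _ = decompose_table(
                boot, scheme, link=link, variables=variables,
                exclude_terms=exclude_terms, include_mills=include_mills, omega=omega,
            )
        except ConvergenceError:
            n_failed += 1
            continue
        comps = dict(res.components())
        comps["total"] = res.total
        for k, v in comps.items():
            draws[k].append(v)
    if n_failed > max_failure_rate * B:
        raise ConvergenceError(
            f"{n_failed}/{B} bootstrap replicates failed to fit (> {max_failure_rate:.0%})"
        )
    se, lo, hi, sig = {}, {}, {}, {}
    for k, vals in draws.items():
        arr = np.asarray(vals)
        se[k] = float(arr.std(ddof=1))
        lo[k] = float(np.percentile(arr, 2.5))
        hi[k] = float(np.percentile(arr, 97.5))
        sig[k] = bool(lo[k] > 0.0 or hi[k] < 0.0)
    return ComponentInference(
        scheme=scheme,
        point=point,
        se=se,
        ci_low=lo,
        ci_high=hi,
        significant_at_5pct=sig,
        n_replicates=B - n_failed,
        n_failed=n_failed,
        seed=seed,
    )
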