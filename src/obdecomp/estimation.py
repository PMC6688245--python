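"""Group-wise outcome regressions and the Heckman two-step selection correction.

The institutional-delivery equation is fit separately for urban and rural
women by maximum likelihood (logit or probit) or least squares (linear
probability model).  Selection into the analysis sample — only women with a
recent birth are observed — is handled with the classical two-step
correction: a probit for having had a birth on the full sample of women,
then the inverse Mills ratio :math:`\\lambda(z)=\\phi(z)/\\Phi(z)` evaluated
at the fitted selection index is appended to the outcome equation as an
extra regressor.
"""

from __future__ import annotations

import logging
import warnings
from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special, stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .design import OUTCOME_TERMS, SELECTION_TERMS, DesignMeta, SchemaError, build_design

__all__ = [
    "ConvergenceError",
    "ModelFit",
    "SelectionFit",
    "fit_group_model",
    "inverse_mills",
    "heckman_augment",
]

logger = logging.getLogger(__name__)

MAX_ABS_COEF = 1e4  # fitted |beta| beyond this signals quasi-separation


class ConvergenceError(RuntimeError):
    """A maximum-likelihood fit failed to converge or the outcome is
    degenerate (single class / perfect separation)."""


@dataclass(frozen=True)
class ModelFit:
    """One group's fitted outcome equation."""

    group: str
    link: str
    coefficients: dict[str, float]
    covariance: pd.DataFrame
    n_obs: int
    converged: bool
    design_meta: DesignMeta
    n_dropped_rows: int = 0
    dropped_terms: tuple[str, ...] = ()

    def __post_init__(self):
        terms = list(self.coefficients)
        if list(self.covariance.index) != terms or list(self.covariance.columns) != terms:
            raise ValueError("covariance terms do not match coefficient terms")
        V = self.covariance.to_numpy()
        if not np.allclose(V, V.T, atol=1e-8):
            raise ValueError("covariance matrix is not symmetric")

    @property
    def se(self) -> dict[str, float]:
        d = np.sqrt(np.clip(np.diag(self.covariance.to_numpy()), 0.0, None))
        return dict(zip(self.coefficients, d))

    def to_json_dict(self) -> dict:
        return {
            "group": self.group,
            "link": self.link,
            "n_obs": self.n_obs,
            "coefficients": dict(self.coefficients),
            "se": self.se,
            "reference_categories": {k: str(v) for k, v in self.design_meta.reference.items()},
            "dropped_terms": list(self.dropped_terms),
            "n_dropped_rows": self.n_dropped_rows,
        }


@dataclass(frozen=True)
class SelectionFit:
    """First-stage selection probit (having had a recent birth)."""

    gamma: dict[str, float]
    n_total: int
    n_selected: int
    design_meta: DesignMeta = field(default_factory=DesignMeta)

    def __post_init__(self):
        if self.n_selected > self.n_total:
            raise ValueError("n_selected cannot exceed n_total")


def _complete_cases(df: pd.DataFrame, columns: list[str], what: str) -> pd.DataFrame:
    present = [c for c in columns if c in df.columns]
    kept = df.dropna(subset=present)
    n_dropped = len(df) - len(kept)
    if n_dropped:
        logger.info("%s: dropped %d incomplete rows of %d", what, n_dropped, len(df))
    return kept


def fit_group_model(
    table: pd.DataFrame,
    group: str,
    link: str = "logit",
    variables: tuple[str, ...] | list[str] | None = None,
    exclude_terms: tuple[str, ...] = (),
    include_mills: bool = False,
) -> ModelFit:
    """Fit the outcome equation on the rows of one residence group.

    *variables* is the plain term list of the outcome equation (default: the
    full institutional-delivery covariate set); ``include_mills`` appends the
    ``mills_ratio`` column produced by :func:`heckman_augment`.
    *exclude_terms* removes individual design columns (used by the pipeline to
    drop terms constant within an analysis window, recorded on the fit).
    """
    if group not in ("urban", "rural"):
        raise ValueError(f"group must be 'urban' or 'rural', got {group!r}")
    if "residence" not in table.columns or "outcome" not in table.columns:
        raise SchemaError("table must contain 'residence' and 'outcome' columns")
    variables = list(variables if variables is not None else OUTCOME_TERMS)
    if include_mills and "mills_ratio" not in variables:
        variables.append("mills_ratio")
    sub = table.loc[table["residence"] == group]
    needed = ["outcome"] + [
        "anc_visits" if v == "anc4" else v for v in variables if v != "intercept"
    ]
    sub = _complete_cases(sub, needed, f"{group} outcome equation")
    n_dropped = int((table["residence"] == group).sum()) - len(sub)
    if len(sub) == 0:
        raise ConvergenceError(f"no usable rows for group {group!r}")
    y = sub["outcome"].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise SchemaError("outcome must be strictly binary (0/1)")
    if y.min() == y.max():
        raise ConvergenceError(
            f"group {group!r} outcome is single-class (all {int(y[0])}); model is degenerate"
        )
    X, meta = build_design(sub, variables)
    dropped = []
    for term in exclude_terms:
        if term in X.columns and term != "intercept":
            X = X.drop(columns=term)
            dropped.append(term)
    const = [c for c in X.columns if c != "intercept" and X[c].nunique() <= 1]
    if const:
        raise ConvergenceError(
            f"design columns constant within group {group!r}: {const}; "
            "exclude them explicitly (exclude_terms) before fitting"
        )
    try:
        if link in ("logit", "probit"):
            model = sm.Logit(y, X) if link == "logit" else sm.Probit(y, X)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(disp=0, maxiter=100)
                if not res.mle_retvals.get("converged", True):
                    # Newton can stall near flat regions; BFGS is slower but robust
                    res = model.fit(disp=0, method="bfgs", maxiter=500)
        elif link == "linear":
            res = sm.OLS(y, X).fit()
        else:
            raise ValueError(f"unknown link {link!r}")
    except PerfectSeparationError as exc:
        raise ConvergenceError(f"perfect separation in group {group!r}: {exc}") from exc
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError(f"singular design in group {group!r}: {exc}") from exc
    converged = bool(getattr(res, "mle_retvals", {"converged": True}).get("converged", True))
    params = np.asarray(res.params, dtype=float)
    if not converged or not np.all(np.isfinite(params)) or np.abs(params).max() > MAX_ABS_COEF:
        raise ConvergenceError(
            f"{link} fit for group {group!r} did not converge (possible quasi-separation)"
        )
    cov = pd.DataFrame(np.asarray(res.cov_params()), index=X.columns, columns=X.columns)
    cov = (cov + cov.T) / 2.0
    return ModelFit(
        group=group,
        link=link,
        coefficients=dict(zip(X.columns, params)),
        covariance=cov,
        n_obs=len(sub),
        converged=converged,
        design_meta=meta,
        n_dropped_rows=n_dropped,
        dropped_terms=tuple(dropped),
    )


def inverse_mills(z):
    """Inverse Mills ratio :math:`\\lambda(z) = \\phi(z)/\\Phi(z)`.

    Evaluated as ``exp(logpdf(z) - logcdf(z))`` so the far-left tail
    (``z <= -8``, where :math:`\\Phi(z)` underflows in naive form) stays
    finite and accurate; there :math:`\\lambda(z) \\approx -z`.
    """
    z_arr = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z_arr)):
        raise ValueError("inverse_mills requires finite input")
    out = np.exp(stats.norm.logpdf(z_arr) - special.log_ndtr(z_arr))
    return float(out) if np.isscalar(z) or z_arr.ndim == 0 else out


HeckmanResult = namedtuple("HeckmanResult", ["table", "selection_fit"])


def heckman_augment(
    full_table: pd.DataFrame,
    selection_variables: tuple[str, ...] | list[str] | None = None,
    selection_col: str = "selected",
) -> HeckmanResult:
    """Two-step selection correction.

    Stage 1 fits a probit for *selection_col* (1 = had a birth, hence observed
    in the outcome sample) on the full sample; stage 2 returns the selected
    rows with a ``mills_ratio`` column equal to the inverse Mills ratio of the
    fitted selection index.  Downstream outcome fits include ``mills_ratio``
    as a regressor.
    """
    variables = list(selection_variables if selection_variables is not None else SELECTION_TERMS)
    if selection_col not in full_table.columns:
        raise SchemaError(f"selection indicator column {selection_col!r} is missing")
    missing = [
        v for v in variables if v != "anc4" and v not in full_table.columns
    ]
    if missing:
        raise SchemaError(f"selection covariates missing from table: {missing}")
    work = _complete_cases(full_table, [selection_col] + variables, "selection equation")
    s = work[selection_col].to_numpy(dtype=float)
    if not np.isin(s, (0.0, 1.0)).all():
        raise SchemaError("selection indicator must be strictly binary (0/1)")
    if s.min() == s.max():
        raise ConvergenceError("selection indicator is single-class; probit is degenerate")
    W, meta = build_design(work, variables)
    const = [c for c in W.columns if c != "intercept" and W[c].nunique() <= 1]
    if const:
        logger.info("selection probit: dropping constant columns %s", const)
        W = W.drop(columns=const)
    try:
        res = sm.Probit(s, W).fit(disp=0, maxiter=100)
    except PerfectSeparationError as exc:
        raise ConvergenceError(f"perfect separation in selection probit: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise ConvergenceError("selection probit did not converge")
    gamma = np.asarray(res.params, dtype=float)
    index = W.to_numpy(dtype=float) @ gamma
    selected = work.loc[s == 1.0].copy()
    selected["mills_ratio"] = inverse_mills(index[s == 1.0])
    fit = SelectionFit(
        gamma=dict(zip(W.columns, gamma)),
        n_total=len(work),
        n_selected=int(s.sum()),
        design_meta=meta,
    )
    return HeckmanResult(table=selected, selection_fit=fit)
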