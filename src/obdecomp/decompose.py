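"""Overall and detailed decompositions of a two-group gap in a binary outcome.

The gap in mean outcome between an advantaged ("urban") and a disadvantaged
("rural") group is split using counterfactual predicted means.  With fitted
coefficient vectors :math:`\\beta_U, \\beta_R` and group design matrices
:math:`X_U, X_R`, write :math:`m(\\beta, X)` for the mean of the inverse link
applied to the linear index over the rows of :math:`X`.  The three-fold
decomposition with the urban coefficients as reference prices endowment
differences at urban returns:

.. math::

    \\underbrace{m(\\beta_U,X_U)-m(\\beta_U,X_R)}_{\\text{explained}}
    + \\underbrace{m(\\beta_U,X_U)-m(\\beta_R,X_U)}_{\\text{unexplained}}
    + \\text{interaction} = m(\\beta_U,X_U)-m(\\beta_R,X_R)

and the rural-reference version swaps the pricing.  The two-fold
decomposition replaces the reference with a blend
:math:`\\beta^* = \\omega\\beta_U + (1-\\omega)\\beta_R` and splits the
residual into urban *advantage* and rural *disadvantage*.  The four classical
weighting schemes fix :math:`\\omega`: Oaxaca 1, Blinder 0, Reimers 0.5,
Cotton the urban sample share.

The detailed decomposition allocates the explained component across
covariate groups with linearization weights
:math:`W_k = \\Delta\\bar x_k \\beta^*_k / \\sum_j \\Delta\\bar x_j \\beta^*_j`,
which is exact for the linear link and the standard (Yun-style) allocation
for logit/probit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .design import default_variable_groups

__all__ = [
    "SCHEMES",
    "ContractError",
    "DecompositionResult",
    "DetailedContributions",
    "counterfactual_mean",
    "link_inverse",
    "threefold",
    "twofold",
    "scheme_weight",
    "detailed_explained",
]

SCHEMES = ("oaxaca", "blinder", "reimers", "cotton")

_SUM_TOL = 1e-10
_PCT_TOL = 1e-6


class ContractError(ValueError):
    """Inputs violate a decomposition contract (mismatched links, term sets,
    or an out-of-range weight)."""


def link_inverse(index: np.ndarray, link: str) -> np.ndarray:
    """Inverse link: expit for logit, standard normal CDF for probit,
    identity for linear (the index is the probability itself)."""
    index = np.asarray(index, dtype=float)
    if link == "logit":
        return special.expit(index)
    if link == "probit":
        return special.ndtr(index)
    if link == "linear":
        return index
    raise ContractError(f"unknown link {link!r}")


def _coef_vector(coefficients, columns) -> np.ndarray:
    names = set(coefficients.keys() if hasattr(coefficients, "keys") else coefficients.index)
    cols = set(columns)
    if names != cols:
        raise ContractError(
            f"coefficient names do not match design columns "
            f"(missing {sorted(cols - names)}, extra {sorted(names - cols)})"
        )
    return np.array([float(coefficients[c]) for c in columns])


def counterfactual_mean(coefficients, X: pd.DataFrame, link: str) -> float:
    """Mean predicted outcome when the rows of *X* are priced with
    *coefficients*: ``mean(link_inverse(X @ beta))``."""
    beta = _coef_vector(coefficients, X.columns)
    return float(np.mean(link_inverse(X.to_numpy(dtype=float) @ beta, link)))


@dataclass(frozen=True)
class DecompositionResult:
    """Overall decomposition of the urban−rural gap, on the probability scale.

    Three-fold results carry ``explained/unexplained/interaction``; two-fold
    results carry ``explained/advantage/disadvantage``.  Components always sum
    to ``total`` and ``percent_of_total`` to 100 (enforced at construction).
    """

    scheme: str
    omega: float
    link: str
    total: float
    explained: float
    unexplained: float | None = None
    interaction: float | None = None
    advantage: float | None = None
    disadvantage: float | None = None
    reference: str | None = None
    mc_se: dict[str, float] | None = None
    percent_of_total: dict[str, float] = field(default_factory=dict)

    @property
    def kind(self) -> str:
        return "threefold" if self.unexplained is not None else "twofold"

    def components(self) -> dict[str, float]:
        if self.unexplained is not None:
            return {
                "explained": self.explained,
                "unexplained": self.unexplained,
                "interaction": self.interaction,
            }
        return {
            "explained": self.explained,
            "advantage": self.advantage,
            "disadvantage": self.disadvantage,
        }

    def __post_init__(self):
        if not 0.0 <= self.omega <= 1.0:
            raise ContractError(f"omega must lie in [0,1], got {self.omega!r}")
        comps = self.components()
        if any(v is None for v in comps.values()):
            raise ContractError("incomplete component set for decomposition result")
        gap = abs(sum(comps.values()) - self.total)
        if gap > _SUM_TOL:
            raise ContractError(
                f"components sum to total violated by {gap:.3e} (tolerance {_SUM_TOL})"
            )
        if not self.percent_of_total:
            object.__setattr__(self, "percent_of_total", self._percentages(comps))
        elif abs(sum(self.percent_of_total.values()) - 100.0) > _PCT_TOL:
            raise ContractError("percent_of_total does not sum to 100")

    def _percentages(self, comps: dict[str, float]) -> dict[str, float]:
        if self.total == 0.0:
            return dict.fromkeys(comps, 0.0)
        return {k: 100.0 * v / self.total for k, v in comps.items()}


def _means(X: pd.DataFrame) -> pd.Series:
    return X.mean(axis=0)


def _check_pair(fit_u, fit_r):
    if fit_u.link != fit_r.link:
        raise ContractError(f"mismatched links: {fit_u.link!r} vs {fit_r.link!r}")
    if set(fit_u.coefficients) != set(fit_r.coefficients):
        raise ContractError("urban and rural fits do not share a term namespace")


def threefold(fit_u, fit_r, X_u: pd.DataFrame, X_r: pd.DataFrame, reference: str = "urban") -> DecompositionResult:
    """Three-fold decomposition with the stated *reference* group's
    coefficients pricing endowment differences (``urban`` = Oaxaca,
    ``rural`` = Blinder)."""
    _check_pair(fit_u, fit_r)
    if reference not in ("urban", "rural"):
        raise ContractError(f"reference must be 'urban' or 'rural', got {reference!r}")
    link = fit_u.link
    b_u, b_r = fit_u.coefficients, fit_r.coefficients
    m_uu = counterfactual_mean(b_u, X_u, link)
    m_rr = counterfactual_mean(b_r, X_r, link)
    m_ur = counterfactual_mean(b_u, X_r, link)  # urban prices, rural endowments
    m_ru = counterfactual_mean(b_r, X_u, link)
    total = m_uu - m_rr
    if reference == "urban":
        explained = m_uu - m_ur
        unexplained = m_uu - m_ru
    else:
        explained = m_ru - m_rr
        unexplained = m_ur - m_rr
    interaction = total - explained - unexplained
    return DecompositionResult(
        scheme="oaxaca" if reference == "urban" else "blinder",
        omega=1.0 if reference == "urban" else 0.0,
        link=link,
        total=total,
        explained=explained,
        unexplained=unexplained,
        interaction=interaction,
        reference=reference,
    )


def twofold(fit_u, fit_r, X_u: pd.DataFrame, X_r: pd.DataFrame, omega: float, scheme: str = "reimers") -> DecompositionResult:
    """Two-fold decomposition with pooled coefficients
    ``beta* = omega*beta_u + (1-omega)*beta_r``."""
    _check_pair(fit_u, fit_r)
    if not 0.0 <= omega <= 1.0:
        raise ContractError(f"omega must lie in [0,1], got {omega!r}")
    link = fit_u.link
    b_u, b_r = fit_u.coefficients, fit_r.coefficients
    b_star = {k: omega * b_u[k] + (1.0 - omega) * b_r[k] for k in b_u}
    m_uu = counterfactual_mean(b_u, X_u, link)
    m_rr = counterfactual_mean(b_r, X_r, link)
    m_su = counterfactual_mean(b_star, X_u, link)
    m_sr = counterfactual_mean(b_star, X_r, link)
    total = m_uu - m_rr
    explained = m_su - m_sr
    advantage = m_uu - m_su
    disadvantage = m_sr - m_rr
    return DecompositionResult(
        scheme=scheme,
        omega=omega,
        link=link,
        total=total,
        explained=explained,
        advantage=advantage,
        disadvantage=disadvantage,
    )


def scheme_weight(scheme: str, n_u: int | None = None, n_r: int | None = None) -> float:
    """Weight omega on the urban coefficient vector for each classical
    scheme; Cotton requires the group sample sizes."""
    if scheme == "oaxaca":
        return 1.0
    if scheme == "blinder":
        return 0.0
    if scheme == "reimers":
        return 0.5
    if scheme == "cotton":
        if not n_u or not n_r or n_u < 1 or n_r < 1:
            raise ContractError("cotton weight requires group sizes n_u, n_r >= 1")
        return n_u / (n_u + n_r)
    raise ContractError(f"unknown scheme {scheme!r}; valid schemes: {', '.join(SCHEMES)}")


@dataclass(frozen=True)
class DetailedContributions:
    """Per-variable-group contributions to the explained component.

    ``contributions`` are on the probability scale; ``shares`` are fractions
    of the explained component; ``residual`` is the numerical-audit remainder
    (zero by construction of the linearization weights).
    """

    explained: float
    omega: float
    link: str
    contributions: dict[str, float]
    shares: dict[str, float]
    residual: float
    degenerate: bool = False

    def __post_init__(self):
        gap = abs(sum(self.contributions.values()) + self.residual - self.explained)
        if gap > _SUM_TOL:
            raise ContractError(f"detailed contributions fail the adding-up audit by {gap:.3e}")
        if not self.degenerate and self.shares:
            share_sum = sum(self.shares.values())
            if abs(share_sum - 1.0) > _PCT_TOL:
                raise ContractError(f"detailed shares sum to {share_sum!r}, not 1")


def detailed_explained(
    fit_u,
    fit_r,
    X_u: pd.DataFrame,
    X_r: pd.DataFrame,
    omega: float,
    variable_groups: dict[str, list[str]] | None = None,
) -> DetailedContributions:
    """Allocate the explained component across covariate groups.

    *variable_groups* must partition the non-intercept terms; when omitted the
    default grouping (wealth, education, antenatal, ...) is derived from the
    term names.  The Mills ratio, when present, forms its own group.
    """
    _check_pair(fit_u, fit_r)
    if not 0.0 <= omega <= 1.0:
        raise ContractError(f"omega must lie in [0,1], got {omega!r}")
    link = fit_u.link
    terms = [t for t in X_u.columns if t != "intercept"]
    if variable_groups is None:
        variable_groups = default_variable_groups(list(X_u.columns))
    covered = [t for group in variable_groups.values() for t in group]
    if sorted(covered) != sorted(terms):
        raise ContractError(
            "variable_groups must partition the non-intercept terms exactly"
        )
    b_u, b_r = fit_u.coefficients, fit_r.coefficients
    b_star = {k: omega * b_u[k] + (1.0 - omega) * b_r[k] for k in b_u}
    explained = counterfactual_mean(b_star, X_u, link) - counterfactual_mean(b_star, X_r, link)
    dx = _means(X_u) - _means(X_r)
    raw = {t: float(dx[t]) * b_star[t] for t in terms}
    denom = sum(raw.values())
    if denom == 0.0:
        warnings.warn(
            "no endowment differences on the index scale; detailed contributions set to zero",
            RuntimeWarning,
            stacklevel=2,
        )
        zeros = dict.fromkeys(variable_groups, 0.0)
        return DetailedContributions(
            explained=explained,
            omega=omega,
            link=link,
            contributions=zeros,
            shares=dict.fromkeys(variable_groups, 0.0),
            residual=explained,
            degenerate=True,
        )
    contributions = {
        g: sum(raw[t] for t in group) / denom * explained
        for g, group in variable_groups.items()
    }
    residual = explained - sum(contributions.values())
    shares = (
        {g: c / explained for g, c in contributions.items()}
        if explained != 0.0
        else dict.fromkeys(contributions, 0.0)
    )
    return DetailedContributions(
        explained=explained,
        omega=omega,
        link=link,
        contributions=contributions,
        shares=shares,
        residual=residual,
        degenerate=explained == 0.0,
    )
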