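"""Parametric description of a two-group survey population.

A :class:`PopulationSpec` fully determines the data-generating process for a
DHS-like table of most-recent births: the rural share of births, per-group
covariate distributions (categorical probability vectors, Bernoulli rates,
count distributions for parity and antenatal visits), link-scale coefficient
vectors for the institutional-delivery index of each group, and a probit
selection stage (having had a birth) whose latent error may be correlated
with the outcome error.  It is both the input to the simulator and the ground
truth for decomposition oracles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .design import (
    BINARY_VARS,
    CATEGORICAL_LEVELS,
    COUNT_VARS,
    OUTCOME_TERMS,
    SELECTION_TERMS,
    design_terms,
)

__all__ = ["CountDist", "GroupCovariates", "PopulationSpec", "SpecValidationError"]

LINKS = ("logit", "probit", "linear")

_PROB_TOL = 1e-12


class SpecValidationError(ValueError):
    """A population spec violates one of its invariants; the message names
    the offending field."""


@dataclass(frozen=True)
class CountDist:
    """Shifted count distribution ``offset + NB(mean, r)``.

    ``r`` is the negative-binomial dispersion (number of successes); ``r=None``
    gives the Poisson limit.  ``offset=1`` encodes parity (every sampled woman
    has at least one birth); antenatal visits use ``offset=0``.
    """

    mean: float
    offset: int = 0
    r: float | None = None

    def validate(self, name: str) -> None:
        if not np.isfinite(self.mean) or self.mean < 0:
            raise SpecValidationError(f"{name}: count mean must be >= 0")
        if self.offset < 0:
            raise SpecValidationError(f"{name}: count offset must be >= 0")
        if self.r is not None and self.r <= 0:
            raise SpecValidationError(f"{name}: dispersion r must be > 0")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.mean == 0:
            base = np.zeros(n, dtype=int)
        elif self.r is None:
            base = rng.poisson(self.mean, size=n)
        else:
            p = self.r / (self.r + self.mean)
            base = rng.negative_binomial(self.r, p, size=n)
        return base + self.offset


@dataclass(frozen=True)
class GroupCovariates:
    """Covariate distributions for one residence group, all independent."""

    categorical: dict[str, dict[object, float]]
    binary: dict[str, float]
    counts: dict[str, CountDist]

    def validate(self, group: str) -> None:
        for var, probs in self.categorical.items():
            if var not in CATEGORICAL_LEVELS:
                raise SpecValidationError(f"{group}.categorical: unknown variable {var!r}")
            levels = CATEGORICAL_LEVELS[var]
            unknown = set(probs) - set(levels)
            if unknown:
                raise SpecValidationError(
                    f"{group}.categorical[{var!r}]: undeclared levels {sorted(unknown, key=str)}"
                )
            total = float(sum(probs.values()))
            if abs(total - 1.0) > _PROB_TOL:
                raise SpecValidationError(
                    f"{group}.categorical[{var!r}]: probabilities sum to {total!r}, not 1"
                )
            if any(p < 0 for p in probs.values()):
                raise SpecValidationError(f"{group}.categorical[{var!r}]: negative probability")
        for var, p in self.binary.items():
            if var not in BINARY_VARS:
                raise SpecValidationError(f"{group}.binary: unknown variable {var!r}")
            if not 0.0 <= p <= 1.0:
                raise SpecValidationError(f"{group}.binary[{var!r}]: rate {p!r} outside [0,1]")
        for var, dist in self.counts.items():
            if var not in COUNT_VARS:
                raise SpecValidationError(f"{group}.counts: unknown variable {var!r}")
            dist.validate(f"{group}.counts[{var!r}]")


@dataclass(frozen=True)
class PopulationSpec:
    group_share_rural: float
    urban: GroupCovariates
    rural: GroupCovariates
    beta_urban: dict[str, float]
    beta_rural: dict[str, float]
    gamma_selection: dict[str, float]
    link: str = "logit"
    rho_selection: float = 0.0
    outcome_variables: tuple[str, ...] = OUTCOME_TERMS
    selection_variables: tuple[str, ...] = SELECTION_TERMS

    def __post_init__(self) -> None:
        object.__setattr__(self, "outcome_variables", tuple(self.outcome_variables))
        object.__setattr__(self, "selection_variables", tuple(self.selection_variables))

    def covariates(self, group: str) -> GroupCovariates:
        if group not in ("urban", "rural"):
            raise ValueError(f"group must be 'urban' or 'rural', got {group!r}")
        return self.urban if group == "urban" else self.rural

    def beta(self, group: str) -> dict[str, float]:
        if group not in ("urban", "rural"):
            raise ValueError(f"group must be 'urban' or 'rural', got {group!r}")
        return self.beta_urban if group == "urban" else self.beta_rural

    def validate(self) -> "PopulationSpec":
        if not 0.0 < self.group_share_rural < 1.0:
            raise SpecValidationError(
                f"group_share_rural must lie in (0,1), got {self.group_share_rural!r}"
            )
        if self.link not in LINKS:
            raise SpecValidationError(f"link must be one of {LINKS}, got {self.link!r}")
        if not -1.0 < self.rho_selection < 1.0:
            raise SpecValidationError("rho_selection must lie in (-1,1)")
        self.urban.validate("urban")
        self.rural.validate("rural")
        outcome_ns = set(design_terms(list(self.outcome_variables)))
        for name, beta in (("beta_urban", self.beta_urban), ("beta_rural", self.beta_rural)):
            missing = outcome_ns - set(beta)
            extra = set(beta) - outcome_ns
            if missing or extra:
                raise SpecValidationError(
                    f"{name}: term namespace mismatch with outcome design "
                    f"(missing {sorted(missing)}, extra {sorted(extra)})"
                )
        sel_ns = set(design_terms(list(self.selection_variables)))
        missing = sel_ns - set(self.gamma_selection)
        extra = set(self.gamma_selection) - sel_ns
        if missing or extra:
            raise SpecValidationError(
                f"gamma_selection: term namespace mismatch with selection design "
                f"(missing {sorted(missing)}, extra {sorted(extra)})"
            )
        return self

    def replace(self, **changes) -> "PopulationSpec":
        """Return a copy with *changes* applied (and revalidated)."""
        return dataclasses.replace(self, **changes).validate()

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        def _cov(gc: GroupCovariates) -> dict:
            return {
                "categorical": {v: dict(p) for v, p in gc.categorical.items()},
                "binary": dict(gc.binary),
                "counts": {
                    v: {"mean": d.mean, "offset": d.offset, "r": d.r}
                    for v, d in gc.counts.items()
                },
            }

        return {
            "group_share_rural": self.group_share_rural,
            "urban": _cov(self.urban),
            "rural": _cov(self.rural),
            "beta_urban": dict(self.beta_urban),
            "beta_rural": dict(self.beta_rural),
            "gamma_selection": dict(self.gamma_selection),
            "link": self.link,
            "rho_selection": self.rho_selection,
            "outcome_variables": list(self.outcome_variables),
            "selection_variables": list(self.selection_variables),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationSpec":
        def _cov(cd: dict) -> GroupCovariates:
            return GroupCovariates(
                categorical={v: dict(p) for v, p in cd.get("categorical", {}).items()},
                binary=dict(cd.get("binary", {})),
                counts={
                    v: CountDist(
                        mean=c["mean"], offset=c.get("offset", 0), r=c.get("r")
                    )
                    for v, c in cd.get("counts", {}).items()
                },
            )

        return cls(
            group_share_rural=d["group_share_rural"],
            urban=_cov(d["urban"]),
            rural=_cov(d["rural"]),
            beta_urban=dict(d["beta_urban"]),
            beta_rural=dict(d["beta_rural"]),
            gamma_selection=dict(d.get("gamma_selection", {})),
            link=d.get("link", "logit"),
            rho_selection=d.get("rho_selection", 0.0),
            outcome_variables=tuple(d.get("outcome_variables", OUTCOME_TERMS)),
            selection_variables=tuple(d.get("selection_variables", SELECTION_TERMS)),
        ).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PopulationSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
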