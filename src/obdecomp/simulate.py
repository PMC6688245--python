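"""Synthetic DHS-like survey generator and population-truth oracle.

Given a :class:`~obdecomp.popspec.PopulationSpec`, this module draws
most-recent-birth tables (``generate_survey``), full women samples with a
selection stage (``generate_population``), and computes population-truth
decomposition components by Monte Carlo (``population_components``).
``default_ghana_spec`` is a documented preset whose margins approximate the
pooled Ghana DHS 2003/2008/2014 birth sample: 58.9% of births rural,
institutional-delivery rates near 0.431 (rural) and 0.847 (urban), wealth
heavily skewed poor in the rural stratum.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special

from .decompose import DecompositionResult, link_inverse, scheme_weight
from .design import CATEGORICAL_LEVELS, build_design, design_terms
from .popspec import CountDist, GroupCovariates, PopulationSpec

__all__ = [
    "generate_survey",
    "generate_population",
    "birth_sample",
    "population_components",
    "default_ghana_spec",
    "compact_spec",
]

#: Column order of a serialized survey table.
SURVEY_COLUMNS = [
    "outcome",
    "residence",
    "age_band",
    "education",
    "wealth_quintile",
    "parity",
    "complications",
    "distance_barrier",
    "reform_period",
    "anc_visits",
    "ethnicity",
    "religion",
    "marital_status",
    "contraceptive_use",
    "survey_year",
]


def _draw_covariates(spec: PopulationSpec, group: str, n: int, rng: np.random.Generator) -> pd.DataFrame:
    gc = spec.covariates(group)
    data: dict[str, np.ndarray] = {}
    for var in sorted(gc.categorical):
        probs = gc.categorical[var]
        levels = [lvl for lvl in CATEGORICAL_LEVELS[var] if lvl in probs]
        p = np.array([probs[lvl] for lvl in levels], dtype=float)
        p = p / p.sum()
        idx = rng.choice(len(levels), size=n, p=p)
        data[var] = np.array(levels, dtype=object)[idx]
    for var in sorted(gc.binary):
        data[var] = (rng.random(n) < gc.binary[var]).astype(int)
    for var in sorted(gc.counts):
        data[var] = gc.counts[var].sample(rng, n)
    df = pd.DataFrame(data)
    for var in ("reform_period", "survey_year"):
        if var in df.columns:
            df[var] = df[var].astype(int)
    return df


def _outcome_index(spec: PopulationSpec, df: pd.DataFrame, group: str) -> np.ndarray:
    X, _ = build_design(df, spec.outcome_variables)
    beta = spec.beta(group)
    b = np.array([beta[c] for c in X.columns])
    return X.to_numpy(dtype=float) @ b


def _selection_index(spec: PopulationSpec, df: pd.DataFrame) -> np.ndarray:
    W, _ = build_design(df, spec.selection_variables)
    g = np.array([spec.gamma_selection[c] for c in W.columns])
    return W.to_numpy(dtype=float) @ g


def _bernoulli_prob(index: np.ndarray, link: str) -> np.ndarray:
    # the linear link is an index model for decomposition algebra; clamp
    # only when a probability is actually needed to draw outcomes
    return np.clip(link_inverse(index, link), 0.0, 1.0)


def _assemble(parts: dict[str, pd.DataFrame], residence: np.ndarray) -> pd.DataFrame:
    frames = [
        df.set_index(np.flatnonzero(residence == group)) for group, df in parts.items()
    ]
    out = pd.concat(frames).sort_index()
    out.insert(0, "residence", residence)
    return out


def generate_survey(spec: PopulationSpec, n: int, seed: int) -> pd.DataFrame:
    """Draw a most-recent-birth survey table of exactly *n* rows.

    Residence is Bernoulli(rural share), covariates are drawn per group from
    the spec's distributions, and the binary institutional-delivery outcome
    from ``linkinv(beta_groupᵀ x)``.  Identical ``(spec, n, seed)`` give a
    bit-identical table.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec.validate()
    rng = np.random.default_rng(seed)
    residence = np.where(rng.random(n) < spec.group_share_rural, "rural", "urban")
    parts: dict[str, pd.DataFrame] = {}
    outcomes: dict[str, np.ndarray] = {}
    for group in ("rural", "urban"):
        n_g = int((residence == group).sum())
        cov = _draw_covariates(spec, group, n_g, rng)
        if n_g:
            p = _bernoulli_prob(_outcome_index(spec, cov, group), spec.link)
            outcomes[group] = (rng.random(n_g) < p).astype(int)
        else:
            outcomes[group] = np.zeros(0, dtype=int)
        parts[group] = cov.assign(outcome=outcomes[group])
    table = _assemble(parts, residence)
    cols = [c for c in SURVEY_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    return table[cols + extra]


def generate_population(spec: PopulationSpec, n: int, seed: int) -> pd.DataFrame:
    """Draw a full sample of *n* women including the selection stage.

    Each woman gets a latent selection index ``gammaᵀ w + u`` with
    ``u ~ N(0,1)``; ``selected`` marks women with a recent birth.  The
    outcome error is coupled to the selection error through a Gaussian
    copula with correlation ``rho_selection``: the outcome for a selected
    woman is ``1{Φ(e) <= linkinv(betaᵀx)}`` with ``corr(e, u) = rho``.  For
    the probit link this is exactly the bivariate-probit selection model;
    for every link ``rho = 0`` reduces to independent draws.  Unselected
    women carry an NaN outcome.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec.validate()
    rng = np.random.default_rng(seed)
    rho = spec.rho_selection
    residence = np.where(rng.random(n) < spec.group_share_rural, "rural", "urban")
    parts: dict[str, pd.DataFrame] = {}
    for group in ("rural", "urban"):
        n_g = int((residence == group).sum())
        cov = _draw_covariates(spec, group, n_g, rng)
        u = rng.standard_normal(n_g)
        v = rng.standard_normal(n_g)
        e = rho * u + np.sqrt(1.0 - rho * rho) * v
        if n_g:
            sel = (_selection_index(spec, cov.assign(residence=group)) + u > 0).astype(int)
            p = _bernoulli_prob(_outcome_index(spec, cov, group), spec.link)
            outcome = np.where(sel == 1, (special.ndtr(e) <= p).astype(float), np.nan)
        else:
            sel = np.zeros(0, dtype=int)
            outcome = np.zeros(0)
        parts[group] = cov.assign(selected=sel, outcome=outcome)
    table = _assemble(parts, residence)
    cols = [c for c in SURVEY_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    return table[cols + extra]


def birth_sample(population: pd.DataFrame) -> pd.DataFrame:
    """Selected (gave-birth) rows of a full sample, with integer outcome."""
    births = population.loc[population["selected"] == 1].copy()
    births["outcome"] = births["outcome"].astype(int)
    return births


def _component_se(
    entries: dict[str, list[tuple[float, str]]],
    p: dict[str, np.ndarray],
) -> dict[str, float]:
    """Monte-Carlo standard errors, per component, at the Bernoulli-outcome
    level (covariate-draw variance plus outcome variance), which is the right
    yardstick for comparing finite-sample estimates against the truth."""
    ses = {}
    for comp, terms in entries.items():
        var = 0.0
        for g in ("u", "r"):
            combo = sum(
                sign * p[key] for sign, key in terms if key.endswith(g)
            )
            if isinstance(combo, np.ndarray) and combo.size:
                var += combo.var() / combo.size
        for sign, key in terms:
            arr = p[key]
            var += np.mean(np.clip(arr * (1.0 - arr), 0.0, None)) / arr.size
        ses[comp] = float(np.sqrt(var))
    return ses


def population_components(
    spec: PopulationSpec,
    scheme: str = "oaxaca",
    n_mc: int = 200_000,
    seed: int = 0,
) -> DecompositionResult:
    """Population-truth decomposition components by Monte Carlo.

    Draws ``n_mc`` covariate vectors per group from the spec (no selection
    stage, no outcome noise) and averages the true link-inverse probabilities
    under each (coefficient vector, covariate group) combination.  The
    returned result carries ``mc_se`` per component.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    X = {}
    for g, group in (("u", "urban"), ("r", "rural")):
        cov = _draw_covariates(spec, group, n_mc, rng)
        Xg, _ = build_design(cov, spec.outcome_variables)
        X[g] = Xg.to_numpy(dtype=float)
    terms = design_terms(list(spec.outcome_variables))
    b = {
        "u": np.array([spec.beta_urban[t] for t in terms]),
        "r": np.array([spec.beta_rural[t] for t in terms]),
    }
    if scheme == "cotton":
        omega = 1.0 - spec.group_share_rural  # population urban share
    else:
        omega = scheme_weight(scheme)
    b["s"] = omega * b["u"] + (1 - omega) * b["r"]
    p = {
        f"{coef}{xg}": link_inverse(X[xg] @ b[coef], spec.link)
        for coef in ("u", "r", "s")
        for xg in ("u", "r")
    }
    m = {k: float(v.mean()) for k, v in p.items()}
    total = m["uu"] - m["rr"]
    if scheme in ("oaxaca", "blinder"):
        if scheme == "oaxaca":
            explained = m["uu"] - m["ur"]
            unexplained = m["uu"] - m["ru"]
            entries = {
                "total": [(1, "uu"), (-1, "rr")],
                "explained": [(1, "uu"), (-1, "ur")],
                "unexplained": [(1, "uu"), (-1, "ru")],
                "interaction": [(-1, "uu"), (1, "ur"), (1, "ru"), (-1, "rr")],
            }
        else:
            explained = m["ru"] - m["rr"]
            unexplained = m["ur"] - m["rr"]
            entries = {
                "total": [(1, "uu"), (-1, "rr")],
                "explained": [(1, "ru"), (-1, "rr")],
                "unexplained": [(1, "ur"), (-1, "rr")],
                "interaction": [(1, "uu"), (-1, "ru"), (-1, "ur"), (1, "rr")],
            }
        interaction = total - explained - unexplained
        return DecompositionResult(
            scheme=scheme,
            omega=omega,
            link=spec.link,
            total=total,
            explained=explained,
            unexplained=unexplained,
            interaction=interaction,
            reference="urban" if scheme == "oaxaca" else "rural",
            mc_se=_component_se(entries, p),
        )
    explained = m["su"] - m["sr"]
    advantage = m["uu"] - m["su"]
    disadvantage = m["sr"] - m["rr"]
    entries = {
        "total": [(1, "uu"), (-1, "rr")],
        "explained": [(1, "su"), (-1, "sr")],
        "advantage": [(1, "uu"), (-1, "su")],
        "disadvantage": [(1, "sr"), (-1, "rr")],
    }
    return DecompositionResult(
        scheme=scheme,
        omega=omega,
        link=spec.link,
        total=total,
        explained=explained,
        advantage=advantage,
        disadvantage=total - explained - advantage,
        mc_se=_component_se(entries, p),
    )


# ---------------------------------------------------------------------------
# Ghana-like preset
# ---------------------------------------------------------------------------

def _norm(d: dict) -> dict:
    s = sum(d.values())
    return {k: v / s for k, v in d.items()}


# Pooled birth-sample margins by residence (percent scale in the source
# tables; normalized here).  Covariates are drawn independently within a
# group: the source reports marginal distributions only, so no joint
# dependence is imposed, and the preset is documented as approximate.
_RURAL_CATEGORICAL = {
    "age_band": _norm({"15-19": 3.81, "20-24": 19.11, "25-29": 26.49, "30-34": 20.91,
                       "35-39": 17.36, "40-44": 9.08, "45-49": 3.84}),
    "education": _norm({"none": 48.60, "primary": 22.67, "secondary": 28.05, "tertiary": 0.68}),
    "wealth_quintile": _norm({"q1": 46.80, "q2": 29.84, "q3": 16.23, "q4": 5.88, "q5": 1.25}),
    "ethnicity": _norm({"akan": 34.87, "ga": 4.52, "ewe": 11.79, "other": 48.81}),
    "religion": _norm({"christian": 66.35, "muslim": 18.16, "traditional": 8.06,
                       "no_religion": 7.33, "other": 0.10}),
    "marital_status": _norm({"married": 87.35, "formerly_married": 5.57, "never_married": 3.92}),
    "reform_period": _norm({1: 35.0, 2: 25.0, 3: 40.0}),
    "survey_year": _norm({2003: 2801.0, 2008: 1992.0, 2014: 3540.0}),
}
_URBAN_CATEGORICAL = {
    "age_band": _norm({"15-19": 3.27, "20-24": 16.28, "25-29": 26.87, "30-34": 25.67,
                       "35-39": 17.98, "40-44": 7.41, "45-49": 2.51}),
    "education": _norm({"none": 21.37, "primary": 19.69, "secondary": 52.68, "tertiary": 6.26}),
    "wealth_quintile": _norm({"q1": 5.67, "q2": 7.58, "q3": 20.96, "q4": 32.59, "q5": 33.21}),
    "ethnicity": _norm({"akan": 48.98, "ga": 6.96, "ewe": 11.91, "other": 32.15}),
    "religion": _norm({"christian": 71.86, "muslim": 24.66, "traditional": 0.99,
                       "no_religion": 2.42, "other": 0.07}),
    "marital_status": _norm({"married": 87.06, "formerly_married": 6.17, "never_married": 6.77}),
    "reform_period": _norm({1: 30.0, 2: 25.0, 3: 45.0}),
    "survey_year": _norm({2003: 1043.0, 2008: 1000.0, 2014: 2344.0}),
}

# Negative-binomial dispersions chosen so that P(anc_visits >= 4) matches the
# 4+-visit shares (0.742 rural, 0.910 urban) at the stated means.
_RURAL_COUNTS = {
    "parity": CountDist(mean=3.05, offset=1, r=3.0),
    "anc_visits": CountDist(mean=7.13, offset=0, r=2.75),
}
_URBAN_COUNTS = {
    "parity": CountDist(mean=2.13, offset=1, r=3.0),
    "anc_visits": CountDist(mean=8.89, offset=0, r=7.0),
}

# Outcome coefficients on the logit scale.  Slopes are plausible magnitudes
# for institutional delivery (steep wealth and education gradients, strong
# antenatal-care association, negative distance-barrier and parity effects);
# urban and rural slopes differ moderately so that both explained and
# unexplained components are nonzero.  Intercepts were calibrated once by
# simulation so group delivery rates land near 0.431 (rural) / 0.847 (urban).
_BETA_RURAL = {
    "intercept": -1.8314,
    "age_band[20-24]": 0.10, "age_band[25-29]": 0.15, "age_band[30-34]": 0.15,
    "age_band[35-39]": 0.10, "age_band[40-44]": 0.05, "age_band[45-49]": 0.0,
    "education[primary]": 0.30, "education[secondary]": 0.70, "education[tertiary]": 1.50,
    "wealth_quintile[q2]": 0.40, "wealth_quintile[q3]": 0.90,
    "wealth_quintile[q4]": 1.50, "wealth_quintile[q5]": 2.20,
    "parity": -0.08,
    "complications": 0.25,
    "distance_barrier": -0.50,
    "reform_period[2]": 0.30, "reform_period[3]": 0.60,
    "anc4": 0.90,
    "ethnicity[ga]": 0.10, "ethnicity[ewe]": 0.05, "ethnicity[other]": -0.20,
    "religion[muslim]": -0.10, "religion[traditional]": -0.40,
    "religion[no_religion]": -0.30, "religion[other]": -0.10,
    "survey_year[2008]": 0.20, "survey_year[2014]": 0.60,
}
_BETA_URBAN = {
    "intercept": -1.4293,
    "age_band[20-24]": 0.05, "age_band[25-29]": 0.10, "age_band[30-34]": 0.10,
    "age_band[35-39]": 0.05, "age_band[40-44]": 0.0, "age_band[45-49]": 0.0,
    "education[primary]": 0.35, "education[secondary]": 0.80, "education[tertiary]": 1.60,
    "wealth_quintile[q2]": 0.30, "wealth_quintile[q3]": 0.70,
    "wealth_quintile[q4]": 1.20, "wealth_quintile[q5]": 1.80,
    "parity": -0.05,
    "complications": 0.30,
    "distance_barrier": -0.35,
    "reform_period[2]": 0.25, "reform_period[3]": 0.50,
    "anc4": 1.10,
    "ethnicity[ga]": 0.10, "ethnicity[ewe]": 0.10, "ethnicity[other]": -0.10,
    "religion[muslim]": -0.05, "religion[traditional]": -0.30,
    "religion[no_religion]": -0.20, "religion[other]": -0.10,
    "survey_year[2008]": 0.15, "survey_year[2014]": 0.45,
}

# Selection probit: fertility rises steeply out of the 15-19 band, falls with
# education and wealth, is much lower for never-married women and slightly
# lower for urban residents; ever-use of contraception marks ever-fertile
# women, hence a positive sign.
_GAMMA_SELECTION = {
    "intercept": -0.30,
    "age_band[20-24]": 0.80, "age_band[25-29]": 1.20, "age_band[30-34]": 1.40,
    "age_band[35-39]": 1.50, "age_band[40-44]": 1.50, "age_band[45-49]": 1.40,
    "education[primary]": -0.10, "education[secondary]": -0.30, "education[tertiary]": -0.60,
    "wealth_quintile[q2]": -0.05, "wealth_quintile[q3]": -0.10,
    "wealth_quintile[q4]": -0.20, "wealth_quintile[q5]": -0.30,
    "religion[muslim]": 0.05, "religion[traditional]": 0.10,
    "religion[no_religion]": 0.05, "religion[other]": 0.0,
    "ethnicity[ga]": 0.0, "ethnicity[ewe]": 0.0, "ethnicity[other]": 0.10,
    "marital_status[formerly_married]": -0.30, "marital_status[never_married]": -1.20,
    "residence[urban]": -0.20,
    "contraceptive_use": 0.30,
}


def default_ghana_spec(rho_selection: float = 0.0, link: str = "logit") -> PopulationSpec:
    """Preset population approximating the pooled Ghana birth sample.

    Margins target the pooled descriptive table of the three surveys: 58.9%
    of births rural; delivery rates ≈ 0.431 rural / 0.847 urban; education
    and wealth strongly skewed toward the poor, less-educated end in the
    rural stratum.  Covariates are independent within group (marginal
    calibration only).  ``rho_selection`` defaults to 0 — the birth table is
    then free of selection effects; pass a nonzero value to study the
    Heckman correction.
    """
    rural_binary = {"complications": 0.6788, "distance_barrier": 0.4534, "contraceptive_use": 0.22}
    urban_binary = {"complications": 0.7927, "distance_barrier": 0.1755, "contraceptive_use": 0.32}
    spec = PopulationSpec(
        group_share_rural=0.589,
        urban=GroupCovariates(
            categorical=_URBAN_CATEGORICAL, binary=urban_binary, counts=_URBAN_COUNTS
        ),
        rural=GroupCovariates(
            categorical=_RURAL_CATEGORICAL, binary=rural_binary, counts=_RURAL_COUNTS
        ),
        beta_urban=dict(_BETA_URBAN),
        beta_rural=dict(_BETA_RURAL),
        gamma_selection=dict(_GAMMA_SELECTION),
        link=link,
        rho_selection=rho_selection,
    )
    return spec.validate()


def compact_spec(
    link: str = "logit", rho_selection: float = 0.0, small_effects: bool = False
) -> PopulationSpec:
    """Small three-covariate population for demonstrations and simulation
    studies.

    Education, a distance barrier and parity drive the outcome (six
    coefficients per group), so repeated refits are cheap.  The selection
    probit has a strong exclusion restriction (contraceptive use enters
    selection only), giving the Mills-ratio correction an identifiable
    signal when ``rho_selection`` is nonzero.  ``small_effects`` halves the
    outcome slopes — the regime where the mean-shift bias from selection
    dominates the scale distortion a two-step correction cannot remove.
    """

    def cov(edu, dist, contra, parity_mean):
        return GroupCovariates(
            categorical={"education": edu},
            binary={"distance_barrier": dist, "contraceptive_use": contra},
            counts={"parity": CountDist(mean=parity_mean, offset=1, r=3.0)},
        )

    rural = cov({"none": 0.50, "primary": 0.25, "secondary": 0.22, "tertiary": 0.03},
                0.45, 0.45, 3.0)
    urban = cov({"none": 0.20, "primary": 0.20, "secondary": 0.50, "tertiary": 0.10},
                0.18, 0.50, 2.1)
    if small_effects:
        beta_r = {"intercept": -0.5, "education[primary]": 0.2, "education[secondary]": 0.45,
                  "education[tertiary]": 0.7, "distance_barrier": -0.3, "parity": -0.05}
        beta_u = {"intercept": 0.2, "education[primary]": 0.15, "education[secondary]": 0.4,
                  "education[tertiary]": 0.65, "distance_barrier": -0.2, "parity": -0.03}
    else:
        beta_r = {"intercept": -0.8, "education[primary]": 0.4, "education[secondary]": 0.9,
                  "education[tertiary]": 1.4, "distance_barrier": -0.6, "parity": -0.10}
        beta_u = {"intercept": 0.3, "education[primary]": 0.3, "education[secondary]": 0.8,
                  "education[tertiary]": 1.3, "distance_barrier": -0.4, "parity": -0.05}
    gamma = {"intercept": -0.6, "education[primary]": -0.1, "education[secondary]": -0.2,
             "education[tertiary]": -0.3, "residence[urban]": -0.2, "contraceptive_use": 1.8}
    return PopulationSpec(
        group_share_rural=0.6,
        urban=urban,
        rural=rural,
        beta_urban=beta_u,
        beta_rural=beta_r,
        gamma_selection=gamma,
        link=link,
        rho_selection=rho_selection,
        outcome_variables=("education", "distance_barrier", "parity"),
        selection_variables=("education", "residence", "contraceptive_use"),
    ).validate()
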