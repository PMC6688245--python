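"""Group fits, the inverse Mills ratio, and the two-step selection correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats
from scipy.special import expit

from obdecomp import (
    ConvergenceError,
    SchemaError,
    birth_sample,
    compact_spec,
    fit_group_model,
    generate_population,
    generate_survey,
    heckman_augment,
    inverse_mills,
)
from obdecomp.design import build_design


def _hand_table():
    # 8 rows, one binary covariate; outcome chosen so OLS solution is nondegenerate
    return pd.DataFrame(
        {
            "residence": ["rural"] * 8,
            "outcome": [0, 1, 0, 1, 1, 1, 0, 1],
            "complications": [0, 0, 0, 0, 1, 1, 1, 1],
        }
    )


class TestFitGroupModel:
    def test_linear_link_matches_normal_equations(self):
        table = _hand_table()
        fit = fit_group_model(table, "rural", link="linear", variables=["complications"])
        X = np.column_stack([np.ones(8), table["complications"]])
        y = table["outcome"].to_numpy(float)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.coefficients["intercept"] == pytest.approx(beta[0], abs=1e-12)
        assert fit.coefficients["complications"] == pytest.approx(beta[1], abs=1e-12)

    def test_single_class_outcome_raises(self):
        table = _hand_table().assign(outcome=1)
        with pytest.raises(ConvergenceError, match="single-class"):
            fit_group_model(table, "rural", link="logit", variables=["complications"])

    def test_unknown_term_raises_schema_error(self):
        with pytest.raises(SchemaError, match="no such column"):
            fit_group_model(_hand_table(), "rural", link="linear", variables=["wealth_quintile"])

    def test_logit_score_identity(self, small_spec, small_table):
        """Mean fitted probability equals the observed outcome rate."""
        fit = fit_group_model(
            small_table, "rural", link="logit", variables=small_spec.outcome_variables
        )
        sub = small_table.loc[small_table["residence"] == "rural"]
        X, _ = build_design(sub, small_spec.outcome_variables)
        b = np.array([fit.coefficients[c] for c in X.columns])
        assert expit(X.to_numpy(float) @ b).mean() == pytest.approx(
            sub["outcome"].mean(), abs=1e-8
        )

    def test_parameter_recovery_on_known_dgp(self, ghana_spec):
        """Logit fits on a large simulated sample recover the generating
        coefficients within 3 reported standard errors."""
        table = generate_survey(ghana_spec, 50_000, seed=0)
        for group, truth in (("urban", ghana_spec.beta_urban), ("rural", ghana_spec.beta_rural)):
            fit = fit_group_model(table, group, link="logit")
            se = fit.se
            misses = [
                term
                for term, b in fit.coefficients.items()
                if abs(b - truth[term]) > 3 * se[term]
            ]
            assert not misses, f"{group}: outside 3 SE: {misses}"

    def test_covariance_is_symmetric_psd(self, small_spec, small_table):
        fit = fit_group_model(
            small_table, "urban", link="logit", variables=small_spec.outcome_variables
        )
        V = fit.covariance.to_numpy()
        assert np.allclose(V, V.T)
        assert np.linalg.eigvalsh(V).min() > -1e-12


class TestInverseMills:
    def test_at_zero(self):
        assert inverse_mills(0.0) == pytest.approx(0.7978845608, abs=1e-9)

    @pytest.mark.parametrize("z", [1.96, -1.0, 0.5, -6.0])
    def test_matches_truncated_normal_mean_quadrature(self, z):
        """λ(z) equals E[U | U > -z] for U ~ N(0,1), computed by quadrature."""
        num, _ = integrate.quad(lambda t: t * stats.norm.pdf(t), -z, np.inf)
        den = stats.norm.sf(-z)
        assert inverse_mills(z) == pytest.approx(num / den, rel=1e-6)

    def test_deep_tail_is_stable(self):
        val = inverse_mills(-40.0)
        assert np.isfinite(val)
        assert val == pytest.approx(40.0, rel=1e-2)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            inverse_mills(np.nan)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(min_value=-30, max_value=8))
    def test_positive_decreasing_dominates_negated_argument(self, z):
        lam = inverse_mills(z)
        assert lam > 0
        assert lam > -z
        assert inverse_mills(z + 1e-3) < lam


class TestHeckman:
    def test_constant_covariates_give_constant_mills(self):
        rng = np.random.default_rng(0)
        n = 400
        full = pd.DataFrame(
            {
                "residence": ["rural"] * n,
                "education": ["none"] * n,
                "contraceptive_use": 0,
                "selected": rng.integers(0, 2, size=n),
            }
        )
        res = heckman_augment(
            full, selection_variables=("education", "residence", "contraceptive_use")
        )
        mills = res.table["mills_ratio"]
        assert mills.nunique() == 1
        assert (mills > 0).all()

    def test_missing_selection_indicator_raises(self, small_table):
        with pytest.raises(SchemaError, match="selection indicator"):
            heckman_augment(small_table.drop(columns=[], errors="ignore"))

    def test_no_selection_limit_leaves_coefficients_unchanged(self):
        """With rho = 0 the corrected and uncorrected outcome fits agree
        within 3 standard errors."""
        spec = compact_spec(rho_selection=0.0)
        pop = generate_population(spec, 8000, seed=21)
        aug = heckman_augment(pop, selection_variables=spec.selection_variables)
        births = aug.table.copy()
        births["outcome"] = births["outcome"].astype(int)
        plain = fit_group_model(births, "rural", variables=spec.outcome_variables)
        mills = fit_group_model(
            births, "rural", variables=spec.outcome_variables, include_mills=True
        )
        for term, b in plain.coefficients.items():
            se = max(plain.se[term], 1e-12)
            assert abs(mills.coefficients[term] - b) < 3 * se, term

    def test_strong_selection_correction_reduces_bias(self):
        """Under strong selection (rho = 0.7) the Mills regressor reduces the
        mean absolute bias of the outcome coefficients across replicates."""
        spec = compact_spec(link="probit", rho_selection=0.7, small_effects=True)
        truth = spec.beta_rural
        names = list(truth)
        errs_plain, errs_mills = [], []
        for rep in range(40):
            pop = generate_population(spec, 4000, seed=40_000 + rep)
            aug = heckman_augment(pop, selection_variables=spec.selection_variables)
            births = aug.table.copy()
            births["outcome"] = births["outcome"].astype(int)
            f0 = fit_group_model(births, "rural", link="probit", variables=spec.outcome_variables)
            f1 = fit_group_model(
                births, "rural", link="probit",
                variables=spec.outcome_variables, include_mills=True,
            )
            errs_plain.append([f0.coefficients[k] - truth[k] for k in names])
            errs_mills.append([f1.coefficients[k] - truth[k] for k in names])
        bias_plain = np.abs(np.mean(errs_plain, axis=0)).mean()
        bias_mills = np.abs(np.mean(errs_mills, axis=0)).mean()
        assert bias_mills < bias_plain

    def test_selection_fit_counts(self):
        spec = compact_spec(rho_selection=0.3)
        pop = generate_population(spec, 3000, seed=77)
        res = heckman_augment(pop, selection_variables=spec.selection_variables)
        assert res.selection_fit.n_total == 3000
        assert res.selection_fit.n_selected == len(res.table)
        assert res.selection_fit.n_selected == len(birth_sample(pop))
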