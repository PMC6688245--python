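"""Decomposition algebra: counterfactual means, overall and detailed splits."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from obdecomp import (
    ContractError,
    DecompositionResult,
    counterfactual_mean,
    decompose_table,
    detailed_explained,
    scheme_weight,
    threefold,
    twofold,
)
from obdecomp.design import build_design

from conftest import make_fit


def _design(df, variables):
    X, _ = build_design(df, variables)
    return X


@pytest.fixture()
def hand_linear():
    """6-row linear-link instance with one binary covariate per group."""
    X_u = pd.DataFrame({"intercept": 1.0, "x": [1.0, 1.0, 0.0]})
    X_r = pd.DataFrame({"intercept": 1.0, "x": [1.0, 0.0, 0.0]})
    fit_u = make_fit({"intercept": 0.30, "x": 0.40}, link="linear", group="urban")
    fit_r = make_fit({"intercept": 0.20, "x": 0.25}, link="linear", group="rural")
    return fit_u, fit_r, X_u, X_r


class TestCounterfactualMean:
    def test_all_zero_logit_is_half(self):
        X = pd.DataFrame({"intercept": [1.0, 1.0], "x": [3.0, -2.0]})
        assert counterfactual_mean({"intercept": 0.0, "x": 0.0}, X, "logit") == 0.5

    def test_intercept_only_closed_form(self):
        X = pd.DataFrame({"intercept": np.ones(5), "x": np.arange(5.0)})
        c = 0.73
        val = counterfactual_mean({"intercept": c, "x": 0.0}, X, "logit")
        assert val == pytest.approx(1 / (1 + np.exp(-c)), abs=1e-15)

    def test_three_row_hand_average(self):
        X = pd.DataFrame({"intercept": [1.0, 1.0, 1.0], "x": [0.0, 1.0, 2.0]})
        beta = {"intercept": -0.5, "x": 0.8}
        expected = np.mean([expit(-0.5), expit(0.3), expit(1.1)])
        assert counterfactual_mean(beta, X, "logit") == pytest.approx(expected, abs=1e-15)

    def test_name_mismatch_raises(self):
        X = pd.DataFrame({"intercept": [1.0], "x": [1.0]})
        with pytest.raises(ContractError, match="design columns"):
            counterfactual_mean({"intercept": 0.0, "z": 1.0}, X, "logit")


class TestThreefold:
    def test_identical_fits_have_zero_unexplained(self, hand_linear):
        fit_u, _, X_u, X_r = hand_linear
        fit_r = make_fit(dict(fit_u.coefficients), link="linear", group="rural")
        res = threefold(fit_u, fit_r, X_u, X_r, reference="urban")
        assert res.unexplained == pytest.approx(0.0, abs=1e-15)
        assert res.interaction == pytest.approx(0.0, abs=1e-15)
        assert res.explained == pytest.approx(res.total, abs=1e-15)

    def test_linear_hand_oracle(self, hand_linear):
        """Components equal the closed-form ΔX̄β and X̄Δβ matrix products."""
        fit_u, fit_r, X_u, X_r = hand_linear
        xbar_u = np.array([1.0, 2 / 3])
        xbar_r = np.array([1.0, 1 / 3])
        b_u = np.array([0.30, 0.40])
        b_r = np.array([0.20, 0.25])
        res = threefold(fit_u, fit_r, X_u, X_r, reference="urban")
        assert res.total == pytest.approx(xbar_u @ b_u - xbar_r @ b_r, abs=1e-15)
        assert res.explained == pytest.approx((xbar_u - xbar_r) @ b_u, abs=1e-15)
        assert res.unexplained == pytest.approx(xbar_u @ (b_u - b_r), abs=1e-15)
        res_r = threefold(fit_u, fit_r, X_u, X_r, reference="rural")
        assert res_r.explained == pytest.approx((xbar_u - xbar_r) @ b_r, abs=1e-15)
        assert res_r.unexplained == pytest.approx(xbar_r @ (b_u - b_r), abs=1e-15)

    def test_reference_explained_difference_equals_interaction(self, hand_linear):
        fit_u, fit_r, X_u, X_r = hand_linear
        res_u = threefold(fit_u, fit_r, X_u, X_r, reference="urban")
        res_r = threefold(fit_u, fit_r, X_u, X_r, reference="rural")
        assert res_u.explained - res_r.explained == pytest.approx(res_r.interaction, abs=1e-14)
        assert res_u.interaction == pytest.approx(-res_r.interaction, abs=1e-14)

    def test_mismatched_links_rejected(self, hand_linear):
        fit_u, fit_r, X_u, X_r = hand_linear
        bad = make_fit(dict(fit_r.coefficients), link="logit", group="rural")
        with pytest.raises(ContractError, match="links"):
            threefold(fit_u, bad, X_u, X_r)


class TestTwofold:
    def test_omega_one_matches_urban_reference(self, hand_linear):
        fit_u, fit_r, X_u, X_r = hand_linear
        two = twofold(fit_u, fit_r, X_u, X_r, omega=1.0)
        three = threefold(fit_u, fit_r, X_u, X_r, reference="urban")
        assert two.advantage == pytest.approx(0.0, abs=1e-15)
        assert two.explained == pytest.approx(three.explained, abs=1e-15)

    def test_omega_half_linear_averages_references(self, hand_linear):
        fit_u, fit_r, X_u, X_r = hand_linear
        two = twofold(fit_u, fit_r, X_u, X_r, omega=0.5)
        e_u = threefold(fit_u, fit_r, X_u, X_r, "urban").explained
        e_r = threefold(fit_u, fit_r, X_u, X_r, "rural").explained
        assert two.explained == pytest.approx((e_u + e_r) / 2, abs=1e-15)

    @pytest.mark.parametrize("omega", [0.0, 0.25, 0.5, 0.9, 1.0])
    def test_equal_coefficients_kill_advantage_terms(self, hand_linear, omega):
        fit_u, _, X_u, X_r = hand_linear
        fit_r = make_fit(dict(fit_u.coefficients), link="linear", group="rural")
        res = twofold(fit_u, fit_r, X_u, X_r, omega=omega)
        assert res.advantage == pytest.approx(0.0, abs=1e-15)
        assert res.disadvantage == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("omega", [0.0, 0.3, 0.5, 1.0])
    def test_label_swap_antisymmetry(self, hand_linear, omega):
        """Swapping the group labels negates the total and exchanges
        advantage with disadvantage."""
        fit_u, fit_r, X_u, X_r = hand_linear
        fwd = twofold(fit_u, fit_r, X_u, X_r, omega=omega)
        rev = twofold(fit_r, fit_u, X_r, X_u, omega=1 - omega)
        assert rev.total == pytest.approx(-fwd.total, abs=1e-14)
        assert rev.explained == pytest.approx(-fwd.explained, abs=1e-14)
        assert rev.advantage == pytest.approx(-fwd.disadvantage, abs=1e-14)
        assert rev.disadvantage == pytest.approx(-fwd.advantage, abs=1e-14)

    def test_omega_out_of_range(self, hand_linear):
        fit_u, fit_r, X_u, X_r = hand_linear
        with pytest.raises(ContractError, match="omega"):
            twofold(fit_u, fit_r, X_u, X_r, omega=1.2)


class TestSchemeWeight:
    def test_classical_weights(self):
        assert scheme_weight("oaxaca") == 1.0
        assert scheme_weight("blinder") == 0.0
        assert scheme_weight("reimers") == 0.5

    def test_cotton_uses_sample_shares(self):
        w = scheme_weight("cotton", n_u=5672, n_r=8130)
        assert w == pytest.approx(5672 / 13802, abs=1e-12)
        assert 1 - w == pytest.approx(0.5891, abs=1e-4)

    def test_unknown_scheme_lists_valid(self):
        with pytest.raises(ContractError, match="oaxaca, blinder, reimers, cotton"):
            scheme_weight("kitagawa")


class TestDetailed:
    def test_single_source_gap_takes_whole_explained(self):
        X_u = pd.DataFrame({"intercept": [1.0, 1.0], "a": [1.0, 1.0], "b": [2.0, 0.0]})
        X_r = pd.DataFrame({"intercept": [1.0, 1.0], "a": [0.0, 0.0], "b": [2.0, 0.0]})
        fit_u = make_fit({"intercept": 0.1, "a": 0.3, "b": 0.2}, "linear", "urban")
        fit_r = make_fit({"intercept": 0.1, "a": 0.3, "b": 0.2}, "linear", "rural")
        det = detailed_explained(
            fit_u, fit_r, X_u, X_r, omega=0.5, variable_groups={"A": ["a"], "B": ["b"]}
        )
        assert det.contributions["A"] == pytest.approx(det.explained, abs=1e-15)
        assert det.contributions["B"] == pytest.approx(0.0, abs=1e-15)

    def test_linear_contributions_equal_brute_force(self):
        rng = np.random.default_rng(3)
        X_u = pd.DataFrame(
            {"intercept": 1.0, "a": rng.random(8), "b": rng.random(8), "c": rng.random(8)}
        )
        X_r = pd.DataFrame(
            {"intercept": 1.0, "a": rng.random(8), "b": rng.random(8), "c": rng.random(8)}
        )
        b_u = {"intercept": 0.1, "a": 0.5, "b": -0.4, "c": 0.2}
        b_r = {"intercept": 0.0, "a": 0.3, "b": -0.1, "c": 0.4}
        omega = 0.3
        det = detailed_explained(
            make_fit(b_u, "linear", "urban"),
            make_fit(b_r, "linear", "rural"),
            X_u, X_r, omega=omega,
            variable_groups={"ab": ["a", "b"], "c": ["c"]},
        )
        b_star = {k: omega * b_u[k] + (1 - omega) * b_r[k] for k in b_u}
        dx = X_u.mean() - X_r.mean()
        brute_ab = dx["a"] * b_star["a"] + dx["b"] * b_star["b"]
        brute_c = dx["c"] * b_star["c"]
        assert det.contributions["ab"] == pytest.approx(brute_ab, abs=1e-14)
        assert det.contributions["c"] == pytest.approx(brute_c, abs=1e-14)
        assert det.residual == pytest.approx(0.0, abs=1e-14)

    def test_shares_reproduce_printed_arithmetic(self):
        """A wealth contribution of 0.161 against an explained component of
        0.261 is a 61.7% share."""
        assert round(100 * 0.161 / 0.261, 1) == 61.7

    def test_no_endowment_difference_warns_and_zeroes(self):
        X = pd.DataFrame({"intercept": [1.0, 1.0], "a": [0.5, 0.5]})
        fit_u = make_fit({"intercept": 0.4, "a": 0.2}, "linear", "urban")
        fit_r = make_fit({"intercept": 0.1, "a": 0.2}, "linear", "rural")
        with pytest.warns(RuntimeWarning, match="no endowment differences"):
            det = detailed_explained(fit_u, fit_r, X, X.copy(), omega=0.5,
                                     variable_groups={"A": ["a"]})
        assert det.contributions["A"] == 0.0

    def test_groups_must_partition_terms(self):
        X = pd.DataFrame({"intercept": [1.0], "a": [1.0], "b": [2.0]})
        fit_u = make_fit({"intercept": 0.0, "a": 1.0, "b": 1.0}, "linear", "urban")
        fit_r = make_fit({"intercept": 0.0, "a": 0.5, "b": 0.5}, "linear", "rural")
        with pytest.raises(ContractError, match="partition"):
            detailed_explained(fit_u, fit_r, X, X, omega=0.5, variable_groups={"A": ["a"]})


class TestFittedDecompositions:
    def test_all_schemes_share_one_total(self, small_spec, small_table):
        totals = []
        for scheme in ("oaxaca", "blinder", "reimers", "cotton"):
            res, _, _ = decompose_table(
                small_table, scheme, variables=small_spec.outcome_variables
            )
            assert abs(sum(res.components().values()) - res.total) < 1e-10
            totals.append(res.total)
        assert max(totals) - min(totals) < 1e-10

    def test_logit_total_equals_raw_gap(self, small_spec, small_table):
        """With the logit link the decomposition total reproduces the raw
        difference in observed group means (score identity)."""
        res, _, _ = decompose_table(small_table, "oaxaca", variables=small_spec.outcome_variables)
        raw = (
            small_table.loc[small_table["residence"] == "urban", "outcome"].mean()
            - small_table.loc[small_table["residence"] == "rural", "outcome"].mean()
        )
        assert res.total == pytest.approx(raw, abs=1e-7)

    def test_printed_row_identity_auditor(self):
        """Construction doubles as an identity audit: component rows that sum
        to their total pass, anything else is rejected."""
        DecompositionResult(
            scheme="oaxaca", omega=1.0, link="logit",
            total=0.324, explained=0.234, unexplained=0.136, interaction=-0.046,
        )
        with pytest.raises(ContractError, match="sum to total"):
            DecompositionResult(
                scheme="oaxaca", omega=1.0, link="logit",
                total=0.324, explained=0.234, unexplained=0.136, interaction=0.046,
            )


class TestReferenceInvariance:
    def test_group_contribution_invariant_to_reference_category(self):
        """Re-encoding a categorical variable with a different reference level
        leaves the variable-group contribution unchanged."""
        rng = np.random.default_rng(11)
        n = 40
        lvl_u = rng.choice(3, size=n, p=[0.5, 0.3, 0.2])
        lvl_r = rng.choice(3, size=n, p=[0.2, 0.3, 0.5])
        z_u, z_r = rng.random(n), rng.random(n)

        def encode(levels, z, ref):
            others = [l for l in range(3) if l != ref]
            return pd.DataFrame(
                {
                    "intercept": 1.0,
                    f"edu[{others[0]}]": (levels == others[0]).astype(float),
                    f"edu[{others[1]}]": (levels == others[1]).astype(float),
                    "z": z,
                }
            )

        # coefficients in reference-0 encoding
        b0 = {0: 0.0, 1: 0.4, 2: 0.9}
        b0_r = {0: 0.0, 1: 0.2, 2: 0.6}

        def coefs(b, ref, intercept):
            others = [l for l in range(3) if l != ref]
            return {
                "intercept": intercept + b[ref],
                f"edu[{others[0]}]": b[others[0]] - b[ref],
                f"edu[{others[1]}]": b[others[1]] - b[ref],
                "z": 0.3,
            }

        results = {}
        for ref in (0, 2):
            X_u = encode(lvl_u, z_u, ref)
            X_r = encode(lvl_r, z_r, ref)
            edu_terms = [c for c in X_u.columns if c.startswith("edu[")]
            fit_u = make_fit(coefs(b0, ref, -0.1), "linear", "urban")
            fit_r = make_fit(coefs(b0_r, ref, 0.05), "linear", "rural")
            det = detailed_explained(
                fit_u, fit_r, X_u, X_r, omega=0.5,
                variable_groups={"education": edu_terms, "z": ["z"]},
            )
            results[ref] = det
        assert results[0].explained == pytest.approx(results[2].explained, abs=1e-12)
        assert results[0].contributions["education"] == pytest.approx(
            results[2].contributions["education"], abs=1e-12
        )
        assert results[0].contributions["z"] == pytest.approx(
            results[2].contributions["z"], abs=1e-12
        )
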