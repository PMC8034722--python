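"""Distributed IRLS: per-node algebra, pooled equivalence, failure modes."""

import numpy as np
import pandas as pd
import pytest

from fedres.disclosure import DisclosureBlocked, DisclosureConfig
from fedres.federation import ServerNode
from fedres.glm import (
    FederatedBlockedError,
    GLMError,
    GLMSpec,
    NonIdentifiableError,
    compute_contribution,
    design_matrix,
    glm_fit_federated,
    glm_pooled_oracle,
    glm_server_step,
)
from fedres.synthetic import StudyTruth, gen_tabular_study
from tests.conftest import build_session


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestSpec:
    def test_formula_parsing(self):
        spec = GLMSpec("y ~ x1 + x2")
        assert spec.parse_formula() == ("y", ("x1", "x2"), True)
        assert GLMSpec("y ~ 1").parse_formula() == ("y", (), True)
        assert GLMSpec("y ~ 0 + x1").parse_formula() == ("y", ("x1",), False)

    @pytest.mark.parametrize("formula", ["y", "~ x", "y ~ 0"])
    def test_malformed_formulas_rejected(self, formula):
        with pytest.raises(GLMError):
            GLMSpec(formula)

    def test_unknown_family_rejected(self):
        with pytest.raises(GLMError, match="family"):
            GLMSpec("y ~ x1", family="gamma")


class TestServerStep:
    def test_gaussian_intercept_only_share(self):
        # identity link: X'WX = n, X'Wz = sum(y) at any beta
        node = ServerNode("s", disclosure=DisclosureConfig(mode="off"))
        node.environment["D"] = pd.DataFrame({"y": [1.0, 2.0, 3.0]})
        contrib = glm_server_step(node, GLMSpec("y ~ 1"), beta=[0.0])
        assert contrib["information"].tolist() == [[3.0]]
        assert contrib["score_cross"].tolist() == [6.0]
        assert contrib["n_obs"] == 3
        # deviance is evaluated at the incoming beta (here 0): sum(y^2)
        assert contrib["deviance"] == pytest.approx(14.0)

    def test_validity_filter_blocks_small_node(self):
        node = ServerNode("s")  # full checks, 5 obs per parameter
        rng = np.random.default_rng(0)
        node.environment["D"] = pd.DataFrame(
            {"y": rng.normal(size=12), "x1": rng.normal(size=12), "x2": rng.normal(size=12)}
        )
        with pytest.raises(DisclosureBlocked, match="model-validity"):
            glm_server_step(node, GLMSpec("y ~ x1 + x2"), beta=[0.0, 0.0, 0.0])

    def test_binomial_share_matches_dense_oracle(self):
        rng = np.random.default_rng(42)
        n, p = 60, 3
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        y = rng.binomial(1, 0.5, n).astype(float)
        beta = np.array([0.3, -0.2, 0.5])
        contrib = compute_contribution(y, X, beta, "binomial")
        # independent dense computation of the weighted cross-products
        eta = X @ beta
        mu = _expit(eta)
        W = np.diag(mu * (1 - mu))
        z = eta + (y - mu) / (mu * (1 - mu))
        np.testing.assert_allclose(contrib["information"], X.T @ W @ X, rtol=1e-12)
        np.testing.assert_allclose(contrib["score_cross"], X.T @ W @ z, rtol=1e-12)


def _session_for(tables, **kwargs):
    return build_session([{"D": t} for t in tables], **kwargs)


class TestPooledEquivalence:
    @pytest.mark.parametrize("family", ["gaussian", "binomial", "poisson"])
    def test_federated_fit_equals_pooled_fit(self, family):
        truth = StudyTruth(seed=5, family=family, intercept=0.2)
        tables = gen_tabular_study((400, 300, 500), truth)
        spec = GLMSpec("y ~ x1 + x2 + bin1", family=family)
        fed = glm_fit_federated(_session_for(tables), spec)
        pooled = glm_pooled_oracle(tables, spec)
        assert fed.converged and pooled.converged
        np.testing.assert_allclose(fed.coefficients, pooled.coefficients, rtol=1e-6)
        np.testing.assert_allclose(fed.standard_errors, pooled.standard_errors, rtol=1e-6)
        assert fed.deviance == pytest.approx(pooled.deviance, rel=1e-6)
        assert fed.n_total == pooled.n_total == 1200

    @pytest.mark.parametrize("family", ["gaussian", "binomial", "poisson"])
    def test_agrees_with_statsmodels(self, family):
        import statsmodels.api as sm

        truth = StudyTruth(seed=6, family=family, intercept=0.2)
        tables = gen_tabular_study((500, 500), truth)
        spec = GLMSpec("y ~ x1 + x2 + bin1", family=family)
        fed = glm_fit_federated(_session_for(tables), spec)
        pooled = pd.concat(tables, ignore_index=True)
        X = sm.add_constant(pooled[["x1", "x2", "bin1"]])
        sm_family = {
            "gaussian": sm.families.Gaussian,
            "binomial": sm.families.Binomial,
            "poisson": sm.families.Poisson,
        }[family]()
        ref = sm.GLM(pooled["y"], X, family=sm_family).fit()
        np.testing.assert_allclose(fed.coefficients, ref.params.to_numpy(), rtol=1e-6)
        np.testing.assert_allclose(fed.standard_errors, ref.bse.to_numpy(), rtol=1e-5)

    def test_single_node_equals_local_fit(self):
        tables = gen_tabular_study((300,), StudyTruth(seed=7))
        spec = GLMSpec("y ~ x1 + x2 + bin1")
        fed = glm_fit_federated(_session_for(tables), spec)
        local = glm_pooled_oracle(tables, spec)
        np.testing.assert_allclose(fed.coefficients, local.coefficients, rtol=1e-10)

    def test_node_permutation_and_row_moves_leave_fit_unchanged(self):
        tables = gen_tabular_study((200, 300, 250), StudyTruth(seed=8))
        spec = GLMSpec("y ~ x1 + x2 + bin1", family="gaussian")
        base = glm_fit_federated(_session_for(tables), spec)
        permuted = glm_fit_federated(_session_for(tables[::-1]), spec)
        np.testing.assert_allclose(base.coefficients, permuted.coefficients, rtol=1e-9)
        # move 50 rows from node 0 to node 1
        moved = [tables[0].iloc[50:], pd.concat([tables[1], tables[0].iloc[:50]]), tables[2]]
        refit = glm_fit_federated(_session_for(moved), spec)
        np.testing.assert_allclose(base.coefficients, refit.coefficients, rtol=1e-9)
        np.testing.assert_allclose(base.standard_errors, refit.standard_errors, rtol=1e-9)


class TestFailureModes:
    def test_blocked_node_aborts_with_its_messages(self):
        tables = gen_tabular_study((200, 12), StudyTruth(seed=9))
        session = _session_for(tables)  # node 1 has 12 < 5*4 observations
        with pytest.raises(FederatedBlockedError, match="study1") as err:
            glm_fit_federated(session, GLMSpec("y ~ x1 + x2 + bin1"))
        assert any("model-validity" in m for m in err.value.messages)

    def test_perfect_separation_flags_non_convergence(self):
        x = np.concatenate([np.linspace(-3, -0.5, 30), np.linspace(0.5, 3, 30)])
        y = (x > 0).astype(float)
        table = pd.DataFrame({"y": y, "x": x})
        session = _session_for([table], disclosure=DisclosureConfig(mode="off"))
        fit = glm_fit_federated(session, GLMSpec("y ~ x", family="binomial"))
        assert not fit.converged

    def test_constant_column_is_non_identifiable(self):
        table = pd.DataFrame({"y": np.random.default_rng(0).normal(size=50), "c": 0.0})
        session = _session_for([table], disclosure=DisclosureConfig(mode="off"))
        with pytest.raises(NonIdentifiableError):
            glm_fit_federated(session, GLMSpec("y ~ c"))

    def test_categorical_level_mismatch_across_nodes(self):
        t0 = pd.DataFrame({"y": [1.0, 2, 3, 4] * 10, "g": ["a", "b"] * 20})
        t1 = pd.DataFrame({"y": [1.0, 2, 3, 4] * 10, "g": ["a", "c"] * 20})
        with pytest.raises(GLMError, match="mismatch"):
            glm_fit_federated(_session_for([t0, t1]), GLMSpec("y ~ g"))


class TestPooledOracle:
    def test_empty_concatenation_is_an_error(self):
        with pytest.raises(GLMError, match="empty"):
            glm_pooled_oracle([], GLMSpec("y ~ 1"))

    def test_intercept_only_recovers_the_mean(self):
        table = pd.DataFrame({"y": [1.0, 2.0, 3.0]})
        fit = glm_pooled_oracle([table], GLMSpec("y ~ 1"))
        assert fit.coefficients[0] == pytest.approx(2.0, abs=1e-12)

    def test_parameter_recovery_within_three_se(self):
        truth = StudyTruth(seed=10)
        tables = gen_tabular_study((2000, 2000, 2000), truth)
        fit = glm_pooled_oracle(tables, GLMSpec("y ~ x1 + x2 + bin1"))
        expected = truth.true_vector()
        for name, est, se in zip(fit.names, fit.coefficients, fit.standard_errors):
            assert abs(est - expected[name]) < 3 * se


class TestDesign:
    def test_complete_case_drops_missing_rows(self):
        df = pd.DataFrame({"y": [1.0, 2.0, np.nan, 4.0], "x": [1.0, np.nan, 3.0, 4.0]})
        y, X, names = design_matrix(df, GLMSpec("y ~ x"))
        assert len(y) == 2
        assert names == ("(Intercept)", "x")

    def test_treatment_coding_against_first_level(self):
        df = pd.DataFrame({"y": [1.0, 2, 3, 4], "g": ["b", "a", "c", "a"]})
        _, X, names = design_matrix(df, GLMSpec("y ~ g"))
        assert names == ("(Intercept)", "g[b]", "g[c]")

    def test_binomial_outcome_validation(self):
        df = pd.DataFrame({"y": [0.0, 1.0, 2.0], "x": [1.0, 2.0, 3.0]})
        with pytest.raises(GLMError, match="binomial"):
            design_matrix(df, GLMSpec("y ~ x", family="binomial"))
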