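import numpy as np
import pytest
from scipy.stats import multivariate_normal

from seamsel import (
    EndpointModel,
    TrialDesign,
    friede_selection_prob,
    joint_selection_prob,
    mvn_orthant,
    stallard_selection_prob,
)
from seamsel.scenarios import correlation_sign_example, selection_frequencies


class TestMvnOrthant:
    def test_univariate_symmetry(self):
        assert mvn_orthant([0.0], [[1.0]]) == pytest.approx(0.5)

    def test_bivariate_independence(self):
        assert mvn_orthant([0.0, 0.0], np.eye(2)) == pytest.approx(0.25, abs=1e-8)

    def test_bivariate_arcsine_closed_form(self):
        cov = [[1.0, 0.5], [0.5, 1.0]]
        expected = 0.25 + np.arcsin(0.5) / (2 * np.pi)
        assert mvn_orthant([0.0, 0.0], cov) == pytest.approx(expected, abs=1e-6)

    def test_invalid_covariance_rejected(self):
        with pytest.raises(ValueError):
            mvn_orthant([0.0, 0.0], [[1.0, 0.2], [0.3, 1.0]])
        with pytest.raises(ValueError):
            mvn_orthant([0.0, 0.0], [[1.0, 2.0], [2.0, 1.0]])

    def test_degenerate_rank_one(self):
        # X2 = X1 exactly: P(X1 <= 0, X1 <= 0) = P(X1 <= -mu)
        cov = np.ones((2, 2))
        assert mvn_orthant([0.5, 0.5], cov) == pytest.approx(
            float(multivariate_normal.cdf([-0.5], mean=[0], cov=[[1]])), abs=1e-8
        )

    def test_degenerate_rank_two_rectangle(self):
        # (X1, X2) full rank plus X3 = -X1: polytope -m3 <= X1 <= -m1, X2 <= -m2
        rho = 0.3
        base = np.array([[1.0, rho], [rho, 1.0]])
        cov = np.zeros((3, 3))
        cov[:2, :2] = base
        cov[2, 2] = 1.0
        cov[0, 2] = cov[2, 0] = -1.0
        cov[1, 2] = cov[2, 1] = -rho
        mean = np.array([-1.0, 0.2, -1.5])
        got = mvn_orthant(mean, cov)
        # oracle: with Z = X[:2] - mean[:2], the orthant event is the rectangle
        # -1.5 <= Z1 <= 1.0, Z2 <= -0.2 under the bivariate law with corr rho
        from scipy.integrate import dblquad

        det = 1 - rho**2

        def pdf(y, x):
            return np.exp(-(x**2 - 2 * rho * x * y + y**2) / (2 * det)) / (
                2 * np.pi * np.sqrt(det)
            )

        expected, _ = dblquad(pdf, -1.5, 1.0, -9.0, -0.2)
        assert got == pytest.approx(expected, abs=1e-6)


class TestMarginalProbabilities:
    def test_exchangeable_arms_friede(self):
        p = [friede_selection_prob(i, np.zeros(5), 1.0, 32) for i in range(1, 5)]
        np.testing.assert_allclose(p, 0.25, atol=1e-6)

    def test_exchangeable_arms_stallard(self, null_model):
        p = [stallard_selection_prob(i, null_model, 4, 32) for i in range(1, 4)]
        np.testing.assert_allclose(p, 1 / 3, atol=1e-6)

    def test_probabilities_sum_to_one(self, effects_model):
        pf = sum(
            friede_selection_prob(i, effects_model.mu_b, 1.0, 32) for i in range(1, 4)
        )
        ps = sum(stallard_selection_prob(i, effects_model, 4, 32) for i in range(1, 4))
        assert pf == pytest.approx(1.0, abs=1e-5)
        assert ps == pytest.approx(1.0, abs=1e-5)

    def test_stallard_sign_invariance(self, effects_model):
        from dataclasses import replace

        minus = replace(effects_model, rho_w=-effects_model.rho_w)
        for i in (1, 2, 3):
            assert stallard_selection_prob(i, effects_model, 4, 32) == pytest.approx(
                stallard_selection_prob(i, minus, 4, 32), abs=1e-12
            )

    def test_stallard_monotone_in_theta(self, effects_model):
        from dataclasses import replace

        bigger = replace(
            effects_model, mu_B=effects_model.mu_B + np.array([0.0, 0.2, 0.0, 0.0])
        )
        assert stallard_selection_prob(1, bigger, 4, 32) > stallard_selection_prob(
            1, effects_model, 4, 32
        )

    def test_matches_full_mvn_orthant_route(self, effects_model):
        """The equicorrelated 1-d reduction equals direct (k-1)-dim integration."""
        means = effects_model.delta * np.sqrt(32 / 2.0)
        diff_mean = np.array([means[j] - means[0] for j in (1, 2)])
        cov = np.full((2, 2), 0.5) + 0.5 * np.eye(2)
        direct = mvn_orthant(diff_mean, cov)
        assert friede_selection_prob(1, effects_model.mu_b, 1.0, 32) == pytest.approx(
            direct, abs=1e-6
        )

    def test_empirical_frequencies_match(self, effects_model):
        design = TrialDesign(k=3, N1=32, n1=4, n2=64)
        freqs = selection_frequencies(effects_model, design, 100_000, seed=5)
        se3 = 3 * np.sqrt(0.25 / 100_000)
        for i in (1, 2, 3):
            pf = friede_selection_prob(i, effects_model.mu_b, 1.0, 32)
            ps = stallard_selection_prob(i, effects_model, 4, 32)
            assert abs(freqs["friede"][i - 1] - pf) < se3
            assert abs(freqs["stallard"][i - 1] - ps) < se3


class TestJointProbabilities:
    def test_marginals_consistent(self):
        model, design = correlation_sign_example(-0.5)
        t = joint_selection_prob(1, model, design)
        assert t.p_friede == pytest.approx(
            friede_selection_prob(1, model.mu_b, 1.0, 32), abs=1e-5
        )
        assert t.p_stallard == pytest.approx(
            stallard_selection_prob(1, model, 4, 32), abs=1e-5
        )
        assert t.p_both <= min(t.p_friede, t.p_stallard) + 1e-12
        cells = [t.p_both, t.p_friede_only, t.p_stallard_only, t.p_neither]
        assert all(c >= 0 for c in cells)
        assert sum(cells) == pytest.approx(1.0, abs=1e-9)

    def test_sign_of_rho_matters_for_agreement(self):
        m_neg, d = correlation_sign_example(-0.9)
        m_pos, _ = correlation_sign_example(0.9)
        t_neg = joint_selection_prob(1, m_neg, d)
        t_pos = joint_selection_prob(1, m_pos, d)
        assert t_neg.p_friede == pytest.approx(t_pos.p_friede, abs=1e-6)
        assert t_neg.p_stallard == pytest.approx(t_pos.p_stallard, abs=1e-6)
        assert t_pos.p_both - t_neg.p_both > 0.1

    def test_perfect_positive_correlation_always_agrees(self):
        # rho_w = 1, equal SDs, proportional effects: the two statistics are
        # monotone transforms of each other
        model = EndpointModel(
            mu_b=np.array([0.0, 0.2, 0.1, 0.05]),
            mu_B=np.array([0.0, 0.2, 0.1, 0.05]),
            sigma0=1.0,
            sigma=1.0,
            rho_w=1.0,
        )
        design = TrialDesign(k=3, N1=32, n1=4, n2=64)
        t = joint_selection_prob(1, model, design)
        assert t.p_both == pytest.approx(t.p_friede, abs=2e-3)
        assert t.p_both == pytest.approx(t.p_stallard, abs=2e-3)

    def test_agreement_table_matches_simulation(self):
        model, design = correlation_sign_example(-0.9)
        t = joint_selection_prob(1, model, design)
        freqs = selection_frequencies(model, design, 100_000, seed=17)
        se3 = 3 * np.sqrt(0.25 / 100_000)
        table = freqs["agreement_T1"]
        assert abs(table["both"] - t.p_both) < se3
        assert abs(table["neither"] - t.p_neither) < se3
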