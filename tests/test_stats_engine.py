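import numpy as np
import pytest

from seamsel import (
    EndpointModel,
    SimSeed,
    Stage1Data,
    Stage1FinalData,
    Stage2Data,
    TrialDesign,
    early_z,
    estimate_model,
    final_z_stage1,
    final_z_stage2,
    score_information,
    score_statistics_estimated,
    score_statistics_known,
    simulate_stage1,
)
from seamsel.scenarios import _simulate_chunk


def make_stage1(early, final):
    return Stage1Data(early=np.asarray(early, float), final=np.asarray(final, float))


class TestZStatistics:
    def test_early_z_hand_example(self):
        s1 = make_stage1([[0, 0], [1, 1]], [[0], [0]])
        np.testing.assert_allclose(early_z(s1, sigma0=1.0), [1.0])

    def test_early_z_zero_for_equal_means(self):
        s1 = make_stage1([[1, 3], [4, 0]], [[0], [0]])
        np.testing.assert_allclose(early_z(s1, sigma0=2.0), [0.0])

    def test_final_z_stage1_hand_example(self):
        s1f = Stage1FinalData(final=np.array([[0.0, 0.0], [2.0, 2.0]]))
        np.testing.assert_allclose(final_z_stage1(s1f, sigma=2.0), [1.0])

    def test_final_z_stage2_hand_example(self):
        s2 = Stage2Data(selected=1, control=np.zeros(8), treatment=np.ones(8))
        assert final_z_stage2(s2, sigma=1.0) == pytest.approx(2.0)

    def test_location_invariance(self, small_trial):
        s1, _ = small_trial
        shifted = Stage1Data(early=s1.early + 17.3, final=s1.final + 17.3)
        np.testing.assert_allclose(early_z(shifted, 1.0), early_z(s1, 1.0), atol=1e-10)

    def test_distributional_contract(self, null_model, std_design):
        """Var 1 and pairwise correlation 1/2 across 10,000 null trials."""
        rng = np.random.default_rng(42)
        x, _ = _simulate_chunk(null_model, std_design, 10_000, rng)
        means = x.mean(axis=-1)
        zb = (means[:, 1:] - means[:, :1]) * np.sqrt(std_design.N1 / 2.0)
        se = 4.0 / np.sqrt(10_000)
        assert np.allclose(zb.var(axis=0), 1.0, atol=4 * np.sqrt(2) * se)
        corr = np.corrcoef(zb.T)
        assert abs(corr[0, 1] - 0.5) < 4 * se
        assert abs(corr[0, 2] - 0.5) < 4 * se


class TestScoreStatistics:
    def test_information_limits(self):
        # rho = 0: final-only information on n1 per group
        assert score_information(4, 32, 1.0, 0.0) == pytest.approx(4 / 2)
        # n1 = N1: information on N1 per group regardless of rho
        assert score_information(32, 32, 1.0, 0.8) == pytest.approx(32 / 2)

    def test_information_increasing_in_rho_and_N1(self):
        lo = score_information(4, 32, 1.0, 0.2)
        hi = score_information(4, 32, 1.0, 0.8)
        assert hi > lo
        assert score_information(4, 64, 1.0, 0.5) > score_information(4, 32, 1.0, 0.5)

    def test_information_sign_invariant(self):
        assert score_information(4, 32, 1.0, 0.7) == score_information(4, 32, 1.0, -0.7)

    def test_reduces_to_final_z_when_rho_zero(self, small_trial):
        s1, _ = small_trial
        model = EndpointModel(mu_b=np.zeros(4), mu_B=np.zeros(4), sigma0=1, sigma=1, rho_w=0.0)
        scores, info = score_statistics_known(s1, model)
        zf = final_z_stage1(Stage1FinalData(final=s1.final), 1.0)
        np.testing.assert_allclose(scores, zf, atol=1e-12)
        assert info == pytest.approx(s1.n1 / 2)

    def test_reduces_to_final_z_when_fully_observed(self, null_model):
        d = TrialDesign(k=3, N1=8, n1=8, n2=16)
        s1, s1f = simulate_stage1(null_model, d, SimSeed(13))
        for rho in (-0.9, 0.3, 1.0):
            model = EndpointModel(mu_b=np.zeros(4), mu_B=np.zeros(4),
                                  sigma0=1, sigma=1, rho_w=rho)
            scores, info = score_statistics_known(s1, model)
            np.testing.assert_allclose(scores, final_z_stage1(s1f, 1.0), atol=1e-12)
            assert info == pytest.approx(8 / 2)

    def test_known_score_law(self):
        """Mean theta*sqrt(I) and unit variance over 100,000 simulated trials."""
        model = EndpointModel(mu_b=np.array([0.0, 0.3]), mu_B=np.array([0.0, 0.4]),
                              sigma0=1.0, sigma=1.0, rho_w=0.5)
        design = TrialDesign(k=1, N1=32, n1=4, n2=8)
        rng = np.random.default_rng(99)
        x, y = _simulate_chunk(model, design, 100_000, rng)
        from seamsel.stats_engine import _scores_from_arrays

        scores, info = _scores_from_arrays(x, y[:, :, :4], 1.0, 1.0, 0.5)
        s1 = scores[:, 0]
        se = 1.0 / np.sqrt(100_000)
        assert abs(s1.mean() - 0.4 * np.sqrt(info)) < 4 * se
        assert abs(s1.var() - 1.0) < 4 * np.sqrt(2) * se

    def test_estimated_consistent_with_known_at_large_n(self):
        model = EndpointModel(mu_b=np.array([0.0, 0.0]), mu_B=np.array([0.0, 0.0]),
                              sigma0=1.0, sigma=1.0, rho_w=0.5)
        d = TrialDesign(k=1, N1=10_000, n1=10_000, n2=8)
        s1, _ = simulate_stage1(model, d, SimSeed(21))
        est, _ = score_statistics_estimated(s1)
        known, _ = score_statistics_known(s1, model)
        np.testing.assert_allclose(est, known, atol=0.05)

    def test_insufficient_df_rejected(self):
        s1 = make_stage1([[0, 1, 2], [1, 2, 0]], [[0, 1], [1, 0]])
        with pytest.raises(ValueError, match="n1 >= 3"):
            score_statistics_estimated(s1)

    def test_degenerate_perfect_pairs_finite(self):
        early = np.array([[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 1.0, 3.0]])
        s1 = Stage1Data(early=early, final=early[:, :3])
        scores, info = score_statistics_estimated(s1)
        assert np.isfinite(scores).all() and np.isfinite(info)


class TestEstimateModel:
    def test_perfect_linear_pairs_clip(self):
        early = np.array([[1.0, 2.0, 3.0], [0.0, 1.0, 2.0]])
        final = 2.0 * early
        est = estimate_model(Stage1Data(early=early, final=final))
        assert est.rho_w == pytest.approx(0.99)

    def test_zero_variance_rejected(self):
        s1 = make_stage1(np.ones((2, 4)), np.ones((2, 3)))
        with pytest.raises(ValueError, match="variance"):
            estimate_model(s1)

    def test_parameter_recovery_large_n(self):
        model = EndpointModel(mu_b=np.array([0.0, 1.0]), mu_B=np.array([0.5, 2.0]),
                              sigma0=1.0, sigma=1.0, rho_w=0.5)
        d = TrialDesign(k=1, N1=50_000, n1=50_000, n2=8)
        s1, _ = simulate_stage1(model, d, SimSeed(31))
        est = estimate_model(s1)
        assert est.sigma0 == pytest.approx(1.0, rel=0.02)
        assert est.sigma == pytest.approx(1.0, rel=0.02)
        assert est.rho_w == pytest.approx(0.5, rel=0.02)
        np.testing.assert_allclose(est.mu_b, model.mu_b, atol=0.02)
        np.testing.assert_allclose(est.mu_B, model.mu_B, atol=0.02)
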