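"""Balanced ANOVA, normal-theory SEs and the missing-cell estimator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from gvarcomp import (DesignSpec, DistributionSpec, VarianceComponents,
                      anova_core, synthetic_data)

matrices = arrays(
    np.float64, st.tuples(st.integers(2, 7), st.integers(2, 6)),
    elements=st.floats(-50, 50, allow_nan=False, width=32),
)


class TestMeanSquares:
    def test_hand_example(self, hand_matrix):
        ms = anova_core.mean_squares(hand_matrix)
        assert (ms.ms_p, ms.ms_i, ms.ms_pi) == (6.25, 2.25, 0.25)
        assert (ms.df_p, ms.df_i, ms.df_pi) == (1, 1, 1)

    def test_constant_matrix_all_zero(self):
        ms = anova_core.mean_squares(np.full((4, 3), 7.0))
        assert ms.ms_p == ms.ms_i == ms.ms_pi == 0.0

    @given(matrices)
    @settings(max_examples=60, deadline=None)
    def test_sum_of_squares_identity(self, x):
        """SS_p + SS_i + SS_pi equals the total centred sum of squares."""
        ms = anova_core.mean_squares(x)
        total = ((x - x.mean()) ** 2).sum()
        parts = (ms.ms_p * ms.df_p + ms.ms_i * ms.df_i + ms.ms_pi * ms.df_pi)
        assert parts == pytest.approx(total, rel=1e-10, abs=1e-8)

    def test_rejects_degenerate_shapes(self):
        with pytest.raises(ValueError):
            anova_core.mean_squares(np.ones((1, 5)))
        with pytest.raises(ValueError):
            anova_core.mean_squares(np.array([[1.0, np.inf], [0.0, 1.0]]))


class TestEstimateVc:
    def test_hand_example(self, hand_matrix):
        vc = anova_core.estimate_vc(anova_core.mean_squares(hand_matrix))
        assert vc == VarianceComponents(3.0, 1.0, 0.25)

    def test_equal_ms_gives_zero_component(self):
        ms = anova_core.MeanSquares(2.0, 5.0, 2.0, 3, 2, 6)
        vc = anova_core.estimate_vc(ms)
        assert vc.vc_p == 0.0

    def test_negative_estimates_retained_and_truncation_optional(self):
        ms = anova_core.MeanSquares(1.0, 1.0, 4.0, 3, 2, 6)
        vc = anova_core.estimate_vc(ms)
        assert vc.vc_p < 0 and vc.vc_i < 0
        vc_t = anova_core.estimate_vc(ms, truncate=True)
        assert vc_t.vc_p == 0.0 and vc_t.vc_pi == 4.0

    @given(matrices, st.floats(0.1, 10))
    @settings(max_examples=40, deadline=None)
    def test_scale_equivariance(self, x, c):
        """Scaling scores by c scales every component by c^2."""
        base = anova_core.estimate_vc_batch(x)
        scaled = anova_core.estimate_vc_batch(c * x)
        assert np.allclose(scaled, c ** 2 * base, rtol=1e-8, atol=1e-6)

    def test_batch_matches_scalar_path(self, rng):
        x = rng.normal(size=(5, 6, 4))
        batch = anova_core.estimate_vc_batch(x)
        for k in range(5):
            one = anova_core.estimate_vc(anova_core.mean_squares(x[k]))
            assert np.allclose(batch[k], one.as_array())


class TestTraditionalSe:
    def test_zero_ms_gives_zero_se(self):
        ms = anova_core.MeanSquares(0, 0, 0, 99, 19, 1881)
        assert np.all(anova_core.traditional_se(ms) == 0)

    def test_df_plus_two_formula_at_expected_mean_squares(self, study_design):
        # direct evaluation of the estimator at EMS (144, 1664, 64)
        ms = anova_core.MeanSquares(144.0, 1664.0, 64.0, 99, 19, 1881)
        se = anova_core.traditional_se(ms, study_design)
        expected_p = np.sqrt(2 * ((144 / 20) ** 2 / 101 + (64 / 20) ** 2 / 1883))
        assert se[0] == pytest.approx(expected_p, rel=1e-12)
        assert round(se[0], 4) == 1.0185

    def test_squared_se_unbiased_for_population_variance(self, study_design, normal_spec):
        """E[SE^2] from the df+2 estimator equals the df-denominator truth."""
        pop = anova_core.normal_theory_se(
            synthetic_data.population_vc(normal_spec), study_design)
        rng = np.random.default_rng(5150)
        n_reps = 10_000
        acc = np.zeros(3)
        for _ in range(n_reps):
            x = synthetic_data.generate(study_design, normal_spec, rng)
            acc += anova_core.traditional_se(
                anova_core.mean_squares(x), study_design) ** 2
        mean_sq = acc / n_reps
        # MC tolerance: dominant chi-square terms give ~2-4% SE on each mean
        assert np.allclose(mean_sq, pop ** 2, rtol=0.10)


class TestPopulationSe:
    def test_normal_closed_form_matches_reference_to_4dp(self, study_design, normal_spec):
        se = anova_core.population_se(normal_spec, study_design)
        assert np.round(se, 4).tolist() == [1.0287, 5.3988, 2.0869]

    def test_degenerate_variances_give_zero(self, study_design):
        vc = VarianceComponents(0.0, 0.0, 0.0)
        assert np.all(anova_core.normal_theory_se(vc, study_design) == 0)

    def test_oracle_route_close_to_closed_form_on_normal(self, study_design):
        """The MC oracle (used for non-normal families) agrees with the
        analytic normal answer within Monte-Carlo error."""
        spec = DistributionSpec.normal()
        analytic = anova_core.normal_theory_se(
            synthetic_data.population_vc(spec), study_design)
        rng = np.random.default_rng(11)
        est = np.stack([
            anova_core.estimate_vc_batch(synthetic_data.generate(study_design, spec, rng))
            for _ in range(800)
        ])
        assert np.allclose(est.std(0, ddof=1), analytic, rtol=0.15)


class TestTraditionalCi:
    def test_zero_se_degenerate_interval(self):
        ci = anova_core.traditional_ci(4.0, 0.0)
        assert np.all(ci == 4.0)

    def test_worked_interval(self):
        # 4 +/- z_0.9 * 1.0287 with the exact z = 1.281552
        ci = anova_core.traditional_ci(4.0, 1.0287, level=0.80)
        z = stats.norm.ppf(0.9)
        assert np.allclose(ci, [[4 - z * 1.0287, 4 + z * 1.0287]])
        assert np.round(ci, 3).tolist() == [[2.682, 5.318]]

    def test_level_validation(self):
        with pytest.raises(ValueError):
            anova_core.traditional_ci(1.0, 1.0, level=1.5)


class TestMissingCell:
    def test_reduces_to_balanced_anova(self, rng):
        x = rng.normal(size=(6, 4))
        vc = anova_core.estimate_vc(anova_core.mean_squares(x))
        vc_m = anova_core.estimate_vc_missing_cell(x)
        assert np.allclose(vc.as_array(), np.asarray(vc_m), rtol=1e-10)

    def test_matches_expected_quadratic_form_oracle(self, rng):
        """Brute-force oracle: build the covariance of the observed cells
        explicitly and solve E[quadratic form] = tr(Q V) for the
        coefficients of each Henderson form."""
        x = rng.normal(size=(3, 3))
        missing = (1, 2)
        n_p, n_i = x.shape
        obs = [(p, i) for p in range(n_p) for i in range(n_i) if (p, i) != missing]
        n = len(obs)

        # design matrices of the observed cells
        zp = np.zeros((n, n_p))
        zi = np.zeros((n, n_i))
        for k, (p, i) in enumerate(obs):
            zp[k, p] = 1.0
            zi[k, i] = 1.0
        covs = [zp @ zp.T, zi @ zi.T, np.eye(n)]

        r = zp.sum(axis=0)
        c = zi.sum(axis=0)
        q_p = zp @ np.diag(1.0 / r) @ zp.T
        q_i = zi @ np.diag(1.0 / c) @ zi.T
        q_mu = np.full((n, n), 1.0 / n)
        q_0 = np.eye(n)

        y = np.array([x[p, i] for p, i in obs])
        forms = [q_p - q_mu, q_i - q_mu, q_0 - q_mu]
        coef = np.array([[np.trace(q @ v) for v in covs] for q in forms])
        rhs = np.array([y @ q @ y for q in forms])
        oracle = np.linalg.solve(coef, rhs)

        vc = anova_core.estimate_vc_missing_cell(x, missing)
        assert np.allclose(np.asarray(vc), oracle, rtol=1e-9)

    def test_unbiased_under_normal_model(self):
        """Mean estimate over simulated 10 x 5 matrices with one deleted
        cell recovers the generating components."""
        design = DesignSpec(10, 5)
        spec = DistributionSpec.normal(sigma_p=1.5, sigma_i=1.0, sigma_pi=2.0)
        rng = np.random.default_rng(99)
        n_reps = 10_000
        acc = np.zeros(3)
        for _ in range(n_reps):
            x = synthetic_data.generate(design, spec, rng)
            acc += np.asarray(anova_core.estimate_vc_missing_cell(x, (0, 0)))
        mean = acc / n_reps
        truth = np.array([1.5 ** 2, 1.0, 4.0])
        # 3 MC standard errors, conservatively ~0.05-0.15 per component
        assert np.allclose(mean, truth, atol=np.array([0.10, 0.12, 0.15]))

    def test_rejects_out_of_range_missing(self, rng):
        with pytest.raises(ValueError):
            anova_core.estimate_vc_missing_cell(rng.normal(size=(3, 3)), (5, 0))
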