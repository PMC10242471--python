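"""Delay embedding, simplex projection, E selection, S-map and nonlinearity."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mccm import (
    CoupledMapParams,
    DegenerateSeriesError,
    EmbeddingConfig,
    InsufficientDataError,
    delay_embed,
    generate_coupled_logistic,
    nonlinearity_test,
    preprocess,
    select_embedding_dimension,
    simplex_forecast,
    smap_forecast,
)
from mccm.reference import (
    naive_global_linear_predictions,
    naive_simplex_predictions,
)


class TestPreprocess:
    def test_two_point_zscore_uses_population_sd(self):
        np.testing.assert_allclose(
            preprocess([1, 3], transform="none", standardize=True), [-1.0, 1.0]
        )

    def test_log1p_values(self):
        np.testing.assert_allclose(
            preprocess([0.0, math.e - 1], transform="log1p", standardize=False),
            [0.0, 1.0],
        )

    def test_constant_series_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            preprocess([0, 0, 0, 0], standardize=True)


class TestDelayEmbed:
    def test_direct_construction(self):
        m = delay_embed([1, 2, 3, 4, 5], EmbeddingConfig(E=2, tau=1))
        np.testing.assert_array_equal(
            m.points, [[2, 1], [3, 2], [4, 3], [5, 4]]
        )
        np.testing.assert_array_equal(m.times, [1, 2, 3, 4])

    def test_E1_identity(self):
        series = [3.0, 1.0, 4.0, 1.0, 5.0]
        m = delay_embed(series, EmbeddingConfig(E=1))
        np.testing.assert_array_equal(m.points[:, 0], series)
        assert m.n_points == 5

    def test_boundary_single_point(self):
        # length 5, E=3, tau=2 leaves one point (x4, x2, x0), but tp=1
        # forbids it (no future); tp is infeasible, so relax to length 6.
        m = delay_embed([0, 1, 2, 3, 4, 5], EmbeddingConfig(E=3, tau=2))
        assert m.n_points == 2
        np.testing.assert_array_equal(m.points[0], [4, 2, 0])

    def test_too_short_names_minimum(self):
        with pytest.raises(InsufficientDataError, match="minimum 6"):
            delay_embed([1, 2, 3], EmbeddingConfig(E=3, tau=2))

    @given(
        T=st.integers(min_value=2, max_value=60),
        E=st.integers(min_value=1, max_value=6),
        tau=st.integers(min_value=1, max_value=4),
    )
    def test_point_count_identity(self, T, E, tau):
        """|points| = T - (E-1)*tau whenever the embedding is feasible."""
        series = np.arange(T, dtype=float)
        try:
            m = delay_embed(series, EmbeddingConfig(E=E, tau=tau))
        except InsufficientDataError:
            assert T < (E - 1) * tau + 2
            return
        assert m.n_points == T - (E - 1) * tau
        # coordinates reproduce the lagged source values exactly
        for j in range(E):
            np.testing.assert_array_equal(m.points[:, j], series[m.times - j * tau])


class TestSimplex:
    def test_periodic_series_perfect_skill(self):
        series = np.array([1.0, 0.0] * 25)
        res = simplex_forecast(delay_embed(series, EmbeddingConfig(E=2)))
        assert res.skill == pytest.approx(1.0)
        np.testing.assert_allclose(res.predictions, res.observations)

    def test_logistic_map_near_perfect(self):
        x = [0.4]
        for _ in range(199):
            x.append(3.8 * x[-1] * (1 - x[-1]))
        res = simplex_forecast(delay_embed(np.array(x), EmbeddingConfig(E=2)))
        assert res.skill > 0.99

    def test_iid_noise_unforecastable(self):
        skills = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            res = simplex_forecast(
                delay_embed(rng.normal(size=500), EmbeddingConfig(E=3))
            )
            skills.append(res.skill)
        assert np.all(np.abs(skills) < 0.2)

    @pytest.mark.parametrize("E", [1, 2, 3, 5])
    def test_matches_bruteforce_oracle(self, E):
        rng = np.random.default_rng(E)
        series = rng.normal(size=80)
        res = simplex_forecast(delay_embed(series, EmbeddingConfig(E=E)))
        preds, obs = naive_simplex_predictions(series, E)
        np.testing.assert_allclose(res.predictions, preds, atol=1e-12)
        np.testing.assert_array_equal(res.observations, obs)

    def test_prediction_is_convex_combination(self, logistic_series):
        """Each forecast lies within the range of the neighbor futures."""
        res = simplex_forecast(delay_embed(logistic_series, EmbeddingConfig(E=2)))
        lo, hi = logistic_series.min(), logistic_series.max()
        assert np.all(res.predictions >= lo - 1e-12)
        assert np.all(res.predictions <= hi + 1e-12)

    def test_skill_affine_invariant(self, logistic_series):
        base = simplex_forecast(delay_embed(logistic_series, EmbeddingConfig(E=2)))
        scaled = simplex_forecast(
            delay_embed(5.0 * logistic_series - 3.0, EmbeddingConfig(E=2))
        )
        assert scaled.skill == pytest.approx(base.skill, abs=1e-12)


class TestSelectE:
    def test_logistic_map_low_dimensional(self, logistic_series):
        E_star, curve = select_embedding_dimension(logistic_series)
        assert E_star in (1, 2, 3)
        assert curve[E_star] > 0.99

    def test_sine_wave_two_dimensional(self):
        t = np.arange(200)
        series = np.sin(2 * np.pi * t / 20)
        _, curve = select_embedding_dimension(series)
        assert curve[2] >= 0.99

    def test_short_series_reports_feasible_only(self):
        series = np.sin(np.arange(12, dtype=float))
        _, curve = select_embedding_dimension(series, E_range=range(1, 11))
        assert set(curve) == {E for E in range(1, 11) if E <= 5}

    def test_no_feasible_E(self):
        with pytest.raises(InsufficientDataError, match="no feasible"):
            select_embedding_dimension([1.0, 2.0, 1.0], E_range=range(8, 11))


class TestSmap:
    def test_theta_zero_equals_global_least_squares(self, ar1_series):
        res = smap_forecast(ar1_series, E=2, theta=0.0, exclusion_radius=-1)
        preds, obs = naive_global_linear_predictions(ar1_series, E=2)
        np.testing.assert_allclose(res.predictions, preds, atol=1e-8)
        np.testing.assert_array_equal(res.observations, obs)

    def test_logistic_map_improves_with_theta(self):
        wins = 0
        for seed in range(20):
            x, _ = generate_coupled_logistic(CoupledMapParams(T=300, seed=seed))
            xp = preprocess(x, "none", True)
            s0 = smap_forecast(xp, E=2, theta=0.0).skill
            best = max(
                smap_forecast(xp, E=2, theta=t).skill
                for t in (0.5, 1.0, 2.0, 4.0, 8.0)
            )
            wins += best > s0
        assert wins == 20

    def test_negative_theta_rejected(self, ar1_series):
        with pytest.raises(ValueError, match="theta"):
            smap_forecast(ar1_series, E=1, theta=-1.0)

    def test_skill_affine_invariant(self, logistic_series):
        a = smap_forecast(logistic_series, E=2, theta=2.0).skill
        b = smap_forecast(10.0 * logistic_series + 7.0, E=2, theta=2.0).skill
        assert b == pytest.approx(a, abs=1e-9)


class TestNonlinearityTest:
    def test_logistic_flagged_nonlinear(self, logistic_series):
        prof = nonlinearity_test(preprocess(logistic_series, "none", True), E=2)
        assert prof.is_nonlinear
        assert prof.delta_rho > 0.01
        assert prof.delta_rho == pytest.approx(
            max(prof.skill_by_theta[1:]) - prof.skill_by_theta[0]
        )

    def test_ar1_not_flagged(self, ar1_series):
        prof = nonlinearity_test(preprocess(ar1_series, "none", True), E=2)
        assert not prof.is_nonlinear

    def test_grid_must_start_at_zero(self, ar1_series):
        with pytest.raises(ValueError, match="theta_grid"):
            nonlinearity_test(ar1_series, E=1, theta_grid=(0.5, 1.0))

    def test_constant_series_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            nonlinearity_test(np.zeros(100), E=2)
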