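"""Per-user directional scores and cohort-level aggregation."""

import numpy as np
import pytest

from mccm import (
    AnalysisConfig,
    CoupledMapParams,
    VariableRegistry,
    aggregate_pair,
    directional_score,
    generate_coupled_logistic,
    run_mccm,
    score_user,
)
from mccm.scoring import PairSummary, UserCausalScore
from mccm.synthetic import EngagementCohortParams, generate_engagement_cohort


class TestDirectionalScore:
    def test_skill_difference_arithmetic(self):
        score, margin = directional_score(0.7, 0.2, 0.4)
        assert score == pytest.approx(0.5)
        assert margin == pytest.approx(0.3)

    def test_equal_skills_zero_score(self):
        score, _ = directional_score(0.55, 0.55, 0.1)
        assert score == 0.0

    def test_dominant_skill_convention(self):
        assert directional_score(0.7, 0.2, 0.0, "dominant_skill")[0] == 0.7
        assert directional_score(0.2, 0.7, 0.0, "dominant_skill")[0] == -0.7
        assert directional_score(0.5, 0.5, 0.0, "dominant_skill")[0] == 0.0

    def test_margin_uses_absolute_correlation(self):
        _, margin = directional_score(0.3, 0.1, -0.6)
        assert margin == pytest.approx(-0.3)


class TestScoreUser:
    def test_identical_series_score_zero(self, fast_config):
        x, _ = generate_coupled_logistic(CoupledMapParams(T=200, seed=0))
        sc = score_user(x, x.copy(), user_id="u", seed=1, config=fast_config)
        assert sc.score == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry_under_stream_swap(self, fast_config):
        x, y = generate_coupled_logistic(
            CoupledMapParams(T=300, beta_xy=0.32, seed=4)
        )
        a = score_user(x, y, user_id="u", seed=7, config=fast_config)
        b = score_user(y, x, user_id="u", seed=7, config=fast_config)
        assert b.score == pytest.approx(-a.score, abs=1e-12)
        assert b.skill_margin == pytest.approx(a.skill_margin, abs=1e-12)
        assert b.valid == a.valid

    def test_true_direction_recovered(self, fast_config):
        """Planted social -> therapy coupling yields positive scores."""
        wins = 0
        n = 20
        for seed in range(n):
            x, y = generate_coupled_logistic(
                CoupledMapParams(T=400, beta_xy=0.32, seed=seed)
            )
            sc = score_user(x, y, user_id=seed, seed=seed, config=fast_config)
            wins += sc.score > 0
        assert wins >= 0.9 * n


class TestAggregatePair:
    def _score(self, user, value, valid=True):
        return UserCausalScore(
            user_id=user, pair=("s", "t"), score=value,
            skill_social_to_therapy=0.5, skill_therapy_to_social=0.1,
            baseline_corr=0.1, skill_margin=0.4, valid=valid,
            E_social_to_therapy=2, E_therapy_to_social=2,
        )

    def test_mean_and_sample_sd(self):
        summ = aggregate_pair([self._score("a", 0.2), self._score("b", 0.4)])
        assert summ.mean_score == pytest.approx(0.3)
        assert summ.sd_score == pytest.approx(0.1414, abs=1e-4)
        assert summ.direction_flag == "social_drives_therapy"

    def test_single_valid_user_sd_flagged(self):
        summ = aggregate_pair([self._score("a", 0.354)])
        assert summ.mean_score == pytest.approx(0.354)
        assert summ.sd_score is None
        assert summ.n_valid == 1

    def test_negative_mean_flags_therapy_direction(self):
        summ = aggregate_pair(
            [self._score("a", -0.1), self._score("b", -0.2), self._score("c", 0.06)]
        )
        assert summ.mean_score == pytest.approx(-0.08)
        assert summ.direction_flag == "therapy_drives_social"

    def test_invalid_users_never_counted(self):
        summ = aggregate_pair(
            [self._score("a", 0.2), self._score("b", 99.0, valid=False)]
        )
        assert summ.mean_score == pytest.approx(0.2)
        assert summ.n_valid == 1
        assert summ.n_total == 2

    def test_all_invalid_flagged_not_fabricated(self):
        summ = aggregate_pair([self._score("a", 0.5, valid=False)])
        assert summ.mean_score is None
        assert summ.direction_flag is None

    def test_order_invariance(self):
        scores = [self._score(u, v) for u, v in [("a", 0.1), ("b", -0.3), ("c", 0.2)]]
        fwd = aggregate_pair(scores)
        rev = aggregate_pair(scores[::-1])
        assert fwd.mean_score == pytest.approx(rev.mean_score)
        assert fwd.sd_score == pytest.approx(rev.sd_score)

    def test_mixed_pairs_rejected(self):
        bad = self._score("a", 0.1)
        bad.pair = ("s2", "t")
        with pytest.raises(ValueError, match="mix"):
            aggregate_pair([self._score("a", 0.1), bad])

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            aggregate_pair([])


@pytest.fixture(scope="module")
def tiny_cohort(small_registry):
    return generate_engagement_cohort(
        EngagementCohortParams(
            n_users=2,
            length_range=(100, 120),
            registry=small_registry,
            base_rate=20.0,
            zero_inflation=0.1,
            emission_gain=4.0,
            seed=9,
        )
    )


class TestRunMCCM:
    def test_one_summary_per_registry_pair(self, tiny_cohort, fast_config):
        res = run_mccm(tiny_cohort, fast_config, seed=0)
        assert len(res.summaries) == 4
        assert {s.pair for s in res.summaries} == set(
            tiny_cohort.registry.pairs()
        )

    def test_deterministic_and_order_independent(self, tiny_cohort, fast_config):
        a = run_mccm(tiny_cohort, fast_config, seed=3)
        b = run_mccm(tiny_cohort, fast_config, seed=3)
        for sa, sb in zip(a.summaries, b.summaries):
            assert sa == sb
        for pair in a.scores:
            for ua, ub in zip(a.scores[pair], b.scores[pair]):
                assert ua.score == ub.score

    def test_degenerate_user_skipped_others_unaffected(
        self, small_registry, fast_config
    ):
        from mccm import Cohort, UsageSeries

        good = generate_engagement_cohort(
            EngagementCohortParams(
                n_users=1,
                length_range=(100, 100),
                registry=small_registry,
                base_rate=20.0,
                zero_inflation=0.1,
                emission_gain=4.0,
                seed=1,
            )
        )
        series = dict(good.series)
        for v in small_registry.all_vars:
            series[("zz_flat", v)] = UsageSeries(
                "zz_flat", v, np.zeros(100, dtype=int)
            )
        cohort = Cohort(small_registry, series)
        res = run_mccm(cohort, fast_config, seed=0)
        skipped_users = {u for u, _, _ in res.skipped}
        assert skipped_users == {"zz_flat"}
        for s in res.summaries:
            assert s.n_total == 1  # only the live user enters the census

    def test_single_user_summary_equals_user_score(self, small_registry, fast_config):
        cohort = generate_engagement_cohort(
            EngagementCohortParams(
                n_users=1,
                length_range=(150, 150),
                registry=small_registry,
                base_rate=20.0,
                zero_inflation=0.1,
                emission_gain=4.0,
                seed=2,
            )
        )
        res = run_mccm(cohort, fast_config, seed=5)
        for s in res.summaries:
            (user_score,) = res.scores[s.pair]
            if user_score.valid:
                assert s.mean_score == pytest.approx(user_score.score)
            else:
                assert s.mean_score is None


def test_nonlinearity_gating_can_invalidate(fast_config):
    """With gating on, a valid verdict also requires nonlinear dynamics."""
    from mccm import AnalysisConfig

    x, y = generate_coupled_logistic(CoupledMapParams(T=300, beta_xy=0.32, seed=3))
    gated = AnalysisConfig(gate_on_nonlinearity=True)
    sc = score_user(x, y, user_id="u", seed=1, config=gated)
    assert sc.nonlinearity_social is not None
    if sc.valid:  # chaotic maps should be flagged nonlinear
        assert sc.nonlinearity_social.is_nonlinear
        assert sc.nonlinearity_therapy.is_nonlinear
    # gating without the diagnostic is a configuration error
    bad = AnalysisConfig(gate_on_nonlinearity=True, run_nonlinearity=False)
    with pytest.raises(ValueError, match="requires nonlinearity"):
        score_user(x, y, user_id="u", seed=1, config=bad)
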