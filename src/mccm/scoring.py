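"""Per-user directional scoring and cohort aggregation (the MCCM step).

CCM judges causal direction for a single user; multiple convergent cross
mapping (MCCM) repeats that per-user analysis across a cohort and summarizes
the signed directional effect for every (social, therapy) variable pair.

Sign convention: positive scores mean the social-networking stream drives
the therapy stream, negative scores the reverse. A user's result is *valid*
only when the best cross-map skill exceeds the absolute plain correlation
between the two raw series (otherwise CCM adds no power beyond simple
correlation) and at least one direction shows convergence.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .ccm import CCMResult, LibrarySchedule, cross_map
from .config import AnalysisConfig
from .edm import (
    DegenerateSeriesError,
    InsufficientDataError,
    NonlinearityProfile,
    nonlinearity_test,
    preprocess,
    select_embedding_dimension,
)
from .usage_io import Cohort

__all__ = [
    "UserCausalScore",
    "PairSummary",
    "MCCMResult",
    "directional_score",
    "score_user",
    "aggregate_pair",
    "run_mccm",
]


@dataclass
class UserCausalScore:
    """One user's signed directional result for one (social, therapy) pair."""

    user_id: object
    pair: tuple[str, str]  # (social_var, therapy_var)
    score: float
    skill_social_to_therapy: float
    skill_therapy_to_social: float
    baseline_corr: float
    skill_margin: float
    valid: bool
    E_social_to_therapy: int
    E_therapy_to_social: int
    ccm_social_to_therapy: CCMResult | None = None
    ccm_therapy_to_social: CCMResult | None = None
    nonlinearity_social: NonlinearityProfile | None = None
    nonlinearity_therapy: NonlinearityProfile | None = None


@dataclass
class PairSummary:
    """Cohort-level effect size for one (social, therapy) pair."""

    pair: tuple[str, str]
    mean_score: float | None
    sd_score: float | None
    n_valid: int
    n_total: int
    direction_flag: str | None


@dataclass
class MCCMResult:
    """Everything a full cohort run produces."""

    summaries: list[PairSummary]
    scores: dict  # (social_var, therapy_var) -> list[UserCausalScore]
    skipped: list  # (user_id, pair, reason)


def directional_score(
    skill_social_to_therapy: float,
    skill_therapy_to_social: float,
    baseline_corr: float,
    convention: str = "skill_difference",
) -> tuple[float, float]:
    """Combine the two directional cross-map skills into (score, margin).

    ``skill_difference`` (default): score = skill(social->therapy test)
    minus skill(therapy->social test), antisymmetric in the two streams.
    ``dominant_skill``: the stronger direction's skill, signed by direction.
    The margin is the best directional skill minus the absolute plain
    correlation of the raw series.
    """
    s_st, s_ts = float(skill_social_to_therapy), float(skill_therapy_to_social)
    if convention == "skill_difference":
        score = s_st - s_ts
    elif convention == "dominant_skill":
        if s_st > s_ts:
            score = s_st
        elif s_ts > s_st:
            score = -s_ts
        else:
            score = 0.0
    else:
        raise ValueError(f"unknown score convention {convention!r}")
    margin = max(s_st, s_ts) - abs(float(baseline_corr))
    return score, margin


def _baseline_correlation(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0.0 or b.std() == 0.0:
        raise DegenerateSeriesError("degenerate series: zero variance")
    return float(np.corrcoef(a, b)[0, 1])


def _schedule_for(n_points: int, E: int, cfg: AnalysisConfig) -> LibrarySchedule:
    if cfg.library_sizes is not None:
        return LibrarySchedule(
            sizes=cfg.library_sizes,
            n_samples=cfg.n_samples,
            sampling=cfg.sampling,
        )
    sched = LibrarySchedule.default(
        n_points, E, n_sizes=cfg.library_size_count, n_samples=cfg.n_samples
    )
    if cfg.sampling != sched.sampling:
        sched = LibrarySchedule(sched.sizes, sched.n_samples, cfg.sampling)
    return sched


def _score_from_embeddings(
    social_pre: np.ndarray,
    therapy_pre: np.ndarray,
    E_therapy: int,
    E_social: int,
    baseline_corr: float,
    cfg: AnalysisConfig,
    seed,
    user_id,
    pair: tuple[str, str],
    nl_social: NonlinearityProfile | None = None,
    nl_therapy: NonlinearityProfile | None = None,
) -> UserCausalScore:
    """Run both cross-map directions on preprocessed series and assemble."""
    social_var, therapy_var = pair
    n_t = len(therapy_pre) - (E_therapy - 1) * cfg.tau
    n_s = len(social_pre) - (E_social - 1) * cfg.tau
    # Testing social -> therapy: the therapy manifold cross-maps the social
    # series; E was selected on the therapy (effect) series.
    ccm_st = cross_map(
        therapy_pre,
        social_pre,
        E=E_therapy,
        tau=cfg.tau,
        schedule=_schedule_for(n_t, E_therapy, cfg),
        exclusion_radius=cfg.exclusion_radius,
        convergence_margin=cfg.convergence_margin,
        seed=seed,
        cause_name=social_var,
        effect_name=therapy_var,
        user_id=user_id,
    )
    ccm_ts = cross_map(
        social_pre,
        therapy_pre,
        E=E_social,
        tau=cfg.tau,
        schedule=_schedule_for(n_s, E_social, cfg),
        exclusion_radius=cfg.exclusion_radius,
        convergence_margin=cfg.convergence_margin,
        seed=seed,
        cause_name=therapy_var,
        effect_name=social_var,
        user_id=user_id,
    )
    score, margin = directional_score(
        ccm_st.skill_full, ccm_ts.skill_full, baseline_corr, cfg.score_convention
    )
    valid = margin > 0 and (ccm_st.convergent or ccm_ts.convergent)
    if cfg.gate_on_nonlinearity:
        if nl_social is None or nl_therapy is None:
            raise ValueError(
                "gate_on_nonlinearity requires nonlinearity diagnostics"
            )
        valid = valid and nl_social.is_nonlinear and nl_therapy.is_nonlinear
    return UserCausalScore(
        user_id=user_id,
        pair=pair,
        score=score,
        skill_social_to_therapy=ccm_st.skill_full,
        skill_therapy_to_social=ccm_ts.skill_full,
        baseline_corr=baseline_corr,
        skill_margin=margin,
        valid=bool(valid),
        E_social_to_therapy=E_therapy,
        E_therapy_to_social=E_social,
        ccm_social_to_therapy=ccm_st,
        ccm_therapy_to_social=ccm_ts,
        nonlinearity_social=nl_social,
        nonlinearity_therapy=nl_therapy,
    )


def score_user(
    social_series,
    therapy_series,
    user_id=None,
    config: AnalysisConfig | None = None,
    seed=None,
    pair: tuple[str, str] = ("social", "therapy"),
) -> UserCausalScore:
    """Score the causal direction between one user's two usage streams.

    Both series are preprocessed, the embedding dimension is selected on
    each effect (manifold) series, CCM runs in both directions with the same
    seed, and the signed score, skill margin and validity flag are derived.
    Swapping the two streams negates the score exactly.

    Raises ``DegenerateSeriesError`` if either series is constant; the
    caller should skip this user for this pair.
    """
    cfg = config or AnalysisConfig()
    baseline = _baseline_correlation(social_series, therapy_series)
    s_pre = preprocess(social_series, cfg.transform, cfg.standardize)
    t_pre = preprocess(therapy_series, cfg.transform, cfg.standardize)
    E_t, _ = select_embedding_dimension(
        t_pre, cfg.E_range, tau=cfg.tau, tp=cfg.tp,
        exclusion_radius=cfg.exclusion_radius,
    )
    E_s, _ = select_embedding_dimension(
        s_pre, cfg.E_range, tau=cfg.tau, tp=cfg.tp,
        exclusion_radius=cfg.exclusion_radius,
    )
    nl_s = nl_t = None
    if cfg.run_nonlinearity:
        nl_s = nonlinearity_test(
            s_pre, E=E_s, theta_grid=cfg.theta_grid,
            margin=cfg.nonlinearity_margin, tau=cfg.tau, tp=cfg.tp,
            exclusion_radius=cfg.exclusion_radius,
        )
        nl_t = nonlinearity_test(
            t_pre, E=E_t, theta_grid=cfg.theta_grid,
            margin=cfg.nonlinearity_margin, tau=cfg.tau, tp=cfg.tp,
            exclusion_radius=cfg.exclusion_radius,
        )
    return _score_from_embeddings(
        s_pre, t_pre, E_t, E_s, baseline, cfg, seed, user_id, pair, nl_s, nl_t
    )


def aggregate_pair(scores) -> PairSummary:
    """Summarize one pair's user scores over the *valid* users only.

    Mean and sample SD (n-1 denominator) of valid scores; an empty valid set
    yields flagged ``None`` values, never a fabricated number. The direction
    flag follows the sign of the mean.
    """
    scores = list(scores)
    if not scores:
        raise ValueError("cannot aggregate an empty score list")
    pairs = {s.pair for s in scores}
    if len(pairs) != 1:
        raise ValueError(f"scores mix multiple pairs: {sorted(pairs)}")
    (pair,) = pairs
    valid = np.array([s.score for s in scores if s.valid], dtype=float)
    n_valid = len(valid)
    mean = float(valid.mean()) if n_valid >= 1 else None
    sd = float(valid.std(ddof=1)) if n_valid >= 2 else None
    if mean is None or mean == 0.0:
        flag = None
    else:
        flag = "social_drives_therapy" if mean > 0 else "therapy_drives_social"
    return PairSummary(
        pair=pair,
        mean_score=mean,
        sd_score=sd,
        n_valid=n_valid,
        n_total=len(scores),
        direction_flag=flag,
    )


def _child_seed(master_seed, user_id, social_var: str, therapy_var: str):
    """Deterministic per-(user, pair) seed, stable under user ordering."""
    tag = zlib.crc32(f"{user_id}|{social_var}|{therapy_var}".encode())
    return np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, tag])


def run_mccm(
    cohort: Cohort, config: AnalysisConfig | None = None, seed: int = 0
) -> MCCMResult:
    """Run the full MCCM analysis over every (social, therapy) pair.

    Per user and pair: preprocess, select E on each cross-mapped (effect)
    series, record the S-map nonlinearity diagnostic, cross-map both
    directions, score; then aggregate valid users per pair. Degenerate or
    too-short series skip that user for the affected pair (logged in
    ``skipped``, excluded from ``n_total``) without aborting the run.
    Deterministic given ``seed`` regardless of user ordering.
    """
    cfg = config or AnalysisConfig()
    reg = cohort.registry
    pre_cache: dict = {}
    E_cache: dict = {}
    nl_cache: dict = {}

    def _pre(user, var):
        key = (user, var)
        if key not in pre_cache:
            try:
                pre_cache[key] = preprocess(
                    cohort.get(user, var).values, cfg.transform, cfg.standardize
                )
            except (DegenerateSeriesError, InsufficientDataError) as exc:
                pre_cache[key] = exc
        return pre_cache[key]

    def _E(user, var, series):
        key = (user, var)
        if key not in E_cache:
            try:
                E_cache[key] = select_embedding_dimension(
                    series, cfg.E_range, tau=cfg.tau, tp=cfg.tp,
                    exclusion_radius=cfg.exclusion_radius,
                )[0]
            except InsufficientDataError as exc:
                E_cache[key] = exc
        return E_cache[key]

    def _nl(user, var, series, E):
        if not cfg.run_nonlinearity:
            return None
        key = (user, var, E)
        if key not in nl_cache:
            try:
                nl_cache[key] = nonlinearity_test(
                    series, E=E, theta_grid=cfg.theta_grid,
                    margin=cfg.nonlinearity_margin, tau=cfg.tau, tp=cfg.tp,
                    exclusion_radius=cfg.exclusion_radius,
                )
            except (DegenerateSeriesError, InsufficientDataError):
                nl_cache[key] = None
        return nl_cache[key]

    scores: dict = {pair: [] for pair in reg.pairs()}
    skipped: list = []
    for pair in reg.pairs():
        social_var, therapy_var = pair
        for user in cohort.users:
            s_pre = _pre(user, social_var)
            t_pre = _pre(user, therapy_var)
            if isinstance(s_pre, Exception) or isinstance(t_pre, Exception):
                reason = str(s_pre if isinstance(s_pre, Exception) else t_pre)
                skipped.append((user, pair, reason))
                continue
            E_t = _E(user, therapy_var, t_pre)
            E_s = _E(user, social_var, s_pre)
            if isinstance(E_t, Exception) or isinstance(E_s, Exception):
                reason = str(E_t if isinstance(E_t, Exception) else E_s)
                skipped.append((user, pair, reason))
                continue
            try:
                baseline = _baseline_correlation(
                    cohort.get(user, social_var).values,
                    cohort.get(user, therapy_var).values,
                )
                score = _score_from_embeddings(
                    s_pre,
                    t_pre,
                    E_t,
                    E_s,
                    baseline,
                    cfg,
                    _child_seed(seed, user, social_var, therapy_var),
                    user,
                    pair,
                    _nl(user, social_var, s_pre, E_s),
                    _nl(user, therapy_var, t_pre, E_t),
                )
            except (DegenerateSeriesError, InsufficientDataError) as exc:
                skipped.append((user, pair, str(exc)))
                continue
            scores[pair].append(score)

    summaries = []
    for pair in reg.pairs():
        if scores[pair]:
            summaries.append(aggregate_pair(scores[pair]))
        else:
            summaries.append(
                PairSummary(
                    pair=pair,
                    mean_score=None,
                    sd_score=None,
                    n_valid=0,
                    n_total=0,
                    direction_flag=None,
                )
            )
    return MCCMResult(summaries=summaries, scores=scores, skipped=skipped)
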