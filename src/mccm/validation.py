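"""End-to-end validation experiments with known ground truth.

Each function runs one self-contained experiment — oracle agreement checks,
nonlinearity discrimination, causal-direction recovery on coupled maps,
null calibration on uncoupled systems, and cohort-level parameter recovery —
and returns its summary metrics. They are used by the acceptance test suite
and by ``scripts/acceptance.py``.

All randomness flows from the single ``seed`` argument. The cohort-recovery
experiment runs the engagement generator in a high-engagement, low-noise
regime (high base rate, strong emission gain, little unstructured zeroing):
cross mapping reconstructs states from the effect series' attractor, so the
planted direction is only recoverable when count discretization does not
drown the latent dynamics. The methods note discusses what this implies for
sparse real-world logs.
"""

from __future__ import annotations

import filecmp
from pathlib import Path

import numpy as np

from .ccm import cross_map
from .config import AnalysisConfig
from .edm import (
    EmbeddingConfig,
    delay_embed,
    nonlinearity_test,
    preprocess,
    select_embedding_dimension,
    simplex_forecast,
    smap_forecast,
)
from .reference import (
    naive_global_linear_predictions,
    naive_simplex_predictions,
)
from .scoring import run_mccm, score_user
from .synthetic import (
    CoupledMapParams,
    EngagementCohortParams,
    generate_coupled_logistic,
    generate_engagement_cohort,
)
from .usage_io import VariableRegistry

__all__ = [
    "simplex_oracle_gap",
    "smap_linear_gap",
    "nonlinearity_discrimination",
    "direction_recovery",
    "null_calibration",
    "cohort_recovery",
    "pipeline_determinism",
    "structural_fidelity",
]

#: Generator regime for the cohort-recovery experiment (see module docstring).
COHORT_RECOVERY_REGIME = dict(
    base_rate=100.0, zero_inflation=0.05, emission_gain=5.0
)
COHORT_COUPLING_STRENGTH = 0.2


def _spawn_ints(seed, n):
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2**31 - 1, size=n)


def simplex_oracle_gap(seed: int, n_series: int = 20) -> dict:
    """Max |optimized - brute force| simplex prediction over random series."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_series):
        T = int(rng.integers(40, 101))
        E = int(rng.integers(1, 6))
        series = rng.normal(size=T)
        res = simplex_forecast(delay_embed(series, EmbeddingConfig(E=E)))
        preds, _ = naive_simplex_predictions(series, E)
        worst = max(worst, float(np.max(np.abs(res.predictions - preds))))
    return {"max_abs_diff": worst, "n": n_series}


def smap_linear_gap(seed: int, T: int = 500, E: int = 2) -> dict:
    """Max |S-map(theta=0) - global OLS| forecast on a Gaussian AR(1)."""
    rng = np.random.default_rng(seed)
    x = np.empty(T)
    x[0] = rng.normal()
    for t in range(T - 1):
        x[t + 1] = 0.6 * x[t] + rng.normal()
    res = smap_forecast(x, E=E, theta=0.0, exclusion_radius=-1)
    preds, _ = naive_global_linear_predictions(x, E=E)
    return {"max_abs_diff": float(np.max(np.abs(res.predictions - preds))), "n": T}


def nonlinearity_discrimination(seed: int, n_rep: int = 20) -> dict:
    """Delta-rho nonlinearity flag rates on chaotic vs linear-Gaussian series."""
    seeds = _spawn_ints(seed, 2 * n_rep)
    logistic_flags = 0
    for s in seeds[:n_rep]:
        x, _ = generate_coupled_logistic(CoupledMapParams(T=200, seed=int(s)))
        xp = preprocess(x, "none", True)
        E, _ = select_embedding_dimension(xp)
        logistic_flags += nonlinearity_test(xp, E=E).is_nonlinear
    ar_flags = 0
    for s in seeds[n_rep:]:
        rng = np.random.default_rng(int(s))
        x = np.empty(500)
        x[0] = rng.normal()
        for t in range(499):
            x[t + 1] = 0.6 * x[t] + rng.normal()
        xp = preprocess(x, "none", True)
        E, _ = select_embedding_dimension(xp)
        ar_flags += nonlinearity_test(xp, E=E).is_nonlinear
    return {
        "logistic_flag_rate": logistic_flags / n_rep,
        "ar1_flag_rate": ar_flags / n_rep,
        "n": n_rep,
    }


def direction_recovery(seed: int, n_rep: int = 50) -> dict:
    """Recovery of the planted direction on unidirectionally coupled maps.

    X forces Y with strength 0.32; X plays the social role, so the correct
    per-user score is positive. Also checks that cross-map skill in the true
    direction grows from the smallest to the largest library.
    """
    cfg = AnalysisConfig(run_nonlinearity=False)
    seeds = _spawn_ints(seed, n_rep)
    positive = 0
    increasing = 0
    for s in seeds:
        x, y = generate_coupled_logistic(
            CoupledMapParams(T=400, beta_xy=0.32, beta_yx=0.0, seed=int(s))
        )
        sc = score_user(x, y, user_id=int(s), seed=int(s), config=cfg)
        positive += sc.score > 0
        ccm_true = sc.ccm_social_to_therapy  # cross-map x from M_y
        increasing += ccm_true.skill_by_L[-1] > ccm_true.skill_by_L[0]
    return {
        "correct_sign_rate": positive / n_rep,
        "skill_increase_rate": increasing / n_rep,
        "n": n_rep,
    }


def null_calibration(seed: int, n_rep: int = 50) -> dict:
    """Score and validity behaviour when the two series share no dynamics."""
    cfg = AnalysisConfig(run_nonlinearity=False)
    seeds = _spawn_ints(seed, n_rep)
    scores = []
    n_valid = 0
    for s in seeds:
        x, y = generate_coupled_logistic(
            CoupledMapParams(T=400, beta_xy=0.0, beta_yx=0.0, seed=int(s))
        )
        sc = score_user(x, y, user_id=int(s), seed=int(s), config=cfg)
        scores.append(sc.score)
        n_valid += sc.valid
    return {
        "mean_score": float(np.mean(scores)),
        "valid_rate": n_valid / n_rep,
        "n": n_rep,
    }


def _recovery_registry() -> tuple[VariableRegistry, dict]:
    registry = VariableRegistry(
        ("steps_started", "actions_done"), ("posts", "reactions")
    )
    coupling = {
        ("posts", "steps_started"): COHORT_COUPLING_STRENGTH,
        ("reactions", "actions_done"): COHORT_COUPLING_STRENGTH,
    }
    return registry, coupling


def cohort_recovery(seed: int, n_seeds: int = 10, n_users: int = 20) -> dict:
    """End-to-end parameter recovery on synthetic engagement cohorts.

    Two of the four (social, therapy) pairs carry planted social -> therapy
    coupling; valid users' scores are pooled across seeds per pair class.
    """
    registry, coupling = _recovery_registry()
    seeds = _spawn_ints(seed, n_seeds)
    coupled_scores, uncoupled_scores = [], []
    flag_ok = flag_n = 0
    for s in seeds:
        params = EngagementCohortParams(
            n_users=n_users,
            registry=registry,
            coupling=coupling,
            seed=int(s),
            **COHORT_RECOVERY_REGIME,
        )
        cohort = generate_engagement_cohort(params)
        result = run_mccm(cohort, AnalysisConfig(), seed=int(s))
        for summ in result.summaries:
            bucket = coupled_scores if summ.pair in coupling else uncoupled_scores
            bucket.extend(
                sc.score for sc in result.scores[summ.pair] if sc.valid
            )
            if summ.pair in coupling and summ.mean_score is not None:
                flag_n += 1
                flag_ok += summ.direction_flag == "social_drives_therapy"
    coupled_mean = float(np.mean(coupled_scores)) if coupled_scores else float("nan")
    uncoupled_mean = (
        float(np.mean(uncoupled_scores)) if uncoupled_scores else 0.0
    )
    return {
        "coupled_mean_score": coupled_mean,
        "uncoupled_mean_score": uncoupled_mean,
        "coupled_flag_correct_rate": flag_ok / flag_n if flag_n else float("nan"),
        "n_coupled_valid": len(coupled_scores),
        "n_uncoupled_valid": len(uncoupled_scores),
        "n": n_seeds,
    }


def _run_cli(usage: Path, out: Path, seed: int, registry: VariableRegistry) -> Path:
    from click.testing import CliRunner

    from .cli import main

    res = CliRunner().invoke(
        main,
        [
            "run", "--input", str(usage), "--out", str(out), "--seed", str(seed),
            "--therapy-vars", ",".join(registry.therapy_vars),
            "--social-vars", ",".join(registry.social_vars),
        ],
        catch_exceptions=False,
    )
    if res.exit_code != 0:
        raise RuntimeError(f"pipeline run failed: {res.output}")
    return out


def pipeline_determinism(seed: int, workdir) -> dict:
    """Byte-compare the output files of two identically seeded runs.

    The resolved-config file records the run's own output directory, so it is
    provenance rather than an analysis output; it is excluded from the byte
    comparison.
    """
    from .usage_io import write_usage_log

    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    registry, coupling = _recovery_registry()
    usage = workdir / "usage.csv"
    params = EngagementCohortParams(
        n_users=3,
        length_range=(80, 120),
        registry=registry,
        coupling=coupling,
        seed=seed,
        base_rate=20.0,
        zero_inflation=0.1,
        emission_gain=4.0,
    )
    write_usage_log(generate_engagement_cohort(params), usage)
    a = _run_cli(usage, workdir / "a", seed, registry)
    b = _run_cli(usage, workdir / "b", seed, registry)
    files = sorted(
        p.name for p in a.iterdir() if p.name != "resolved_config.yaml"
    )
    identical = sum(
        filecmp.cmp(a / name, b / name, shallow=False) for name in files
    )
    return {
        "identical_fraction": identical / len(files) if files else float("nan"),
        "n": len(files),
    }


def structural_fidelity(seed: int, n_users: int = 4) -> dict:
    """Shape and flag conventions of a default-registry cohort run."""
    from .usage_io import default_registry

    registry = default_registry()
    params = EngagementCohortParams(
        n_users=n_users,
        length_range=(282, 528),
        registry=registry,
        coupling={("posts", "steps_started"): COHORT_COUPLING_STRENGTH},
        seed=seed,
        **COHORT_RECOVERY_REGIME,
    )
    cohort = generate_engagement_cohort(params)
    result = run_mccm(cohort, AnalysisConfig(), seed=seed)
    n_pairs = len(result.summaries)
    flag_ok = flag_n = 0
    for summ in result.summaries:
        if summ.mean_score is None:
            continue
        flag_n += 1
        want = (
            "social_drives_therapy"
            if summ.mean_score > 0
            else "therapy_drives_social"
        )
        flag_ok += summ.direction_flag == want or summ.mean_score == 0
    return {
        "n_pair_summaries": n_pairs,
        "n_therapy_vars": len(registry.therapy_vars),
        "n_social_vars": len(registry.social_vars),
        "flag_consistency_rate": flag_ok / flag_n if flag_n else 1.0,
        "n": n_users,
    }
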