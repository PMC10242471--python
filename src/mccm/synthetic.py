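"""Synthetic data with known causal ground truth.

Two generators:

* canonical coupled logistic maps — the standard benchmark for
  cross-mapping methods, where the true causal direction is known by
  construction;
* an engagement-cohort generator shaped like digital-intervention usage
  logs (heterogeneous series lengths, zero-inflated daily counts on therapy
  and social-networking variables) with configurable directional coupling
  between the two streams.

The cohort generator gives every usage variable a latent daily engagement
state evolving on (coupled) logistic-map dynamics and emits zero-inflated
Poisson counts from it. Deterministic nonlinear latent dynamics are a
prerequisite, not a convenience: cross mapping recovers causal direction by
reconstructing states from the effect's attractor, so a cohort whose ground
truth should be recoverable must actually contain such an attractor.
Stochastic linear latents (e.g. AR(1)) leave the planted direction
unidentifiable to any state-space method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .usage_io import Cohort, UsageSeries, VariableRegistry, default_registry

__all__ = [
    "CoupledMapParams",
    "EngagementCohortParams",
    "generate_coupled_logistic",
    "generate_engagement_cohort",
]


@dataclass
class CoupledMapParams:
    """Parameters of the two-species coupled logistic benchmark.

    ``beta_xy`` is the strength with which X forces Y (it appears in Y's
    update); ``beta_yx`` the reverse. ``noise_sd`` adds Gaussian observation
    noise after the deterministic trajectory is generated.
    """

    r_x: float = 3.8
    r_y: float = 3.5
    beta_xy: float = 0.0
    beta_yx: float = 0.0
    T: int = 400
    burn_in: int = 300
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.beta_xy < 0 or self.beta_yx < 0:
            raise ValueError("coupling strengths must be non-negative")
        if self.T < 1 or self.burn_in < 0:
            raise ValueError("need T >= 1 and burn_in >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def generate_coupled_logistic(
    params: CoupledMapParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterate the coupled logistic maps and return (x, y) after burn-in.

    Dynamics::

        x[t+1] = x[t] * (r_x - r_x * x[t] - beta_yx * y[t])
        y[t+1] = y[t] * (r_y - r_y * y[t] - beta_xy * x[t])

    Initial conditions are drawn uniformly in (0.1, 0.9) from the seeded
    generator. Parameter combinations whose trajectory leaves the open unit
    interval are rejected with ``ValueError``.
    """
    rng = np.random.default_rng(params.seed)
    total = params.burn_in + params.T
    x = np.empty(total)
    y = np.empty(total)
    x[0] = rng.uniform(0.1, 0.9)
    y[0] = rng.uniform(0.1, 0.9)
    for t in range(total - 1):
        x[t + 1] = x[t] * (params.r_x - params.r_x * x[t] - params.beta_yx * y[t])
        y[t + 1] = y[t] * (params.r_y - params.r_y * y[t] - params.beta_xy * x[t])
        if not (0.0 < x[t + 1] < 1.0 and 0.0 < y[t + 1] < 1.0):
            raise ValueError(
                f"trajectory left (0, 1) at step {t + 1}; "
                "rejecting this parameter combination"
            )
    x = x[params.burn_in:]
    y = y[params.burn_in:]
    if params.noise_sd > 0:
        x = x + rng.normal(0.0, params.noise_sd, size=params.T)
        y = y + rng.normal(0.0, params.noise_sd, size=params.T)
    return x, y


@dataclass
class EngagementCohortParams:
    """Shape and dynamics of a synthetic usage-log cohort.

    Each registered variable carries a latent daily engagement state on the
    unit interval. Undriven variables follow independent chaotic logistic
    maps (growth ``r_undriven``); a positive
    ``coupling[(social_var, therapy_var)]`` makes the therapy variable's
    latent a logistic map (growth ``r_driven``) forced by the social
    variable's lagged state (social drives therapy), a negative value the
    reverse. Counts are zero-inflated Poisson with a state-dependent
    structural-zero probability (inactive days cluster when the latent
    engagement state is low)::

        lam[v, t] = base_rate * exp(emission_gain * (z[v, t] - 0.5) - decay * t)
        p0[v, t]  = 1 - (1 - zero_inflation) ** (2 * (1 - z[v, t]))
        count[v, t] = 0 with prob p0[v, t] else Poisson(lam[v, t])

    ``p0`` is approximately ``2 * zero_inflation * (1 - z)`` for small
    ``zero_inflation`` and reaches 1 for every state when
    ``zero_inflation = 1`` (an all-zero cohort).

    Cohort shape defaults (82 users, 282-528 days each) mirror the kind of
    long-term intervention cohort the pipeline targets. ``emission_gain``
    sets how sharply the count intensity tracks the latent state; together
    with ``base_rate`` it controls how much of the latent dynamics survives
    count discretization (see the methods note: at sparse realistic rates
    most users are, correctly, unrecoverable).
    """

    n_users: int = 82
    length_range: tuple[int, int] = (282, 528)
    registry: VariableRegistry = field(default_factory=default_registry)
    coupling: dict = field(default_factory=dict)  # (social, therapy) -> float
    base_rate: float = 2.0
    zero_inflation: float = 0.3
    decay: float = 0.001
    emission_gain: float = 3.0
    r_undriven: float = 3.8
    r_driven: float = 3.5
    burn_in: int = 300
    seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError("length_range must satisfy 1 <= lo <= hi")
        if self.n_users < 1:
            raise ValueError("n_users must be >= 1")
        if not (0.0 <= self.zero_inflation <= 1.0):
            raise ValueError("zero_inflation must be in [0, 1]")
        if self.base_rate <= 0:
            raise ValueError("base_rate must be positive")
        for key, c in self.coupling.items():
            s, t = key
            if s not in self.registry.social_vars:
                raise ValueError(f"invalid coupling key: {s!r} is not a social var")
            if t not in self.registry.therapy_vars:
                raise ValueError(f"invalid coupling key: {t!r} is not a therapy var")
            if abs(c) > 0.4:
                raise ValueError(
                    f"|coupling| {abs(c)} too strong; trajectories escape (max 0.4)"
                )


def _latent_states(
    params: EngagementCohortParams, T: int, rng: np.random.Generator
) -> np.ndarray:
    """Iterate all variables' latent maps jointly; returns (T, n_vars)."""
    reg = params.registry
    variables = list(reg.all_vars)
    idx = {v: i for i, v in enumerate(variables)}
    nv = len(variables)
    # K[i, j] = forcing of variable j's state on variable i's update.
    K = np.zeros((nv, nv))
    for (s, t), c in params.coupling.items():
        if c > 0:  # social drives therapy
            K[idx[t], idx[s]] = c
        elif c < 0:  # therapy drives social
            K[idx[s], idx[t]] = -c
    driven = K.any(axis=1)
    r = np.where(driven, params.r_driven, params.r_undriven)

    total = params.burn_in + T
    z = np.empty((total, nv))
    z[0] = rng.uniform(0.1, 0.9, size=nv)
    for t in range(total - 1):
        z[t + 1] = z[t] * (r - r * z[t] - K @ z[t])
        if not ((z[t + 1] > 0.0) & (z[t + 1] < 1.0)).all():
            raise ValueError(
                f"latent trajectory left (0, 1) at step {t + 1}; "
                "rejecting this parameter combination"
            )
    return z[params.burn_in:]


def generate_engagement_cohort(params: EngagementCohortParams) -> Cohort:
    """Simulate a cohort of zero-inflated daily usage counts.

    Per user: draw a series length uniformly within ``length_range``, evolve
    the latent engagement states from seeded initial conditions, and emit
    counts for every registered variable. Deterministic under ``seed``.
    """
    rng = np.random.default_rng(params.seed)
    reg = params.registry
    variables = list(reg.all_vars)
    lo, hi = params.length_range
    series: dict = {}
    width = len(str(params.n_users))
    for u in range(params.n_users):
        user = f"u{u + 1:0{width}d}"
        T = int(rng.integers(lo, hi + 1))
        z = _latent_states(params, T, rng)
        trend = params.decay * np.arange(T)[:, None]
        lam = params.base_rate * np.exp(
            params.emission_gain * (z - 0.5) - trend
        )
        counts = rng.poisson(lam)
        p0 = 1.0 - (1.0 - params.zero_inflation) ** (2.0 * (1.0 - z))
        counts[rng.random(size=lam.shape) < p0] = 0
        for j, v in enumerate(variables):
            series[(user, v)] = UsageSeries(user, v, counts[:, j])
    return Cohort(registry=reg, series=series)
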