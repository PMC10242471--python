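"""Empirical dynamic modeling (EDM) primitives.

Delay-coordinate embedding of a single observed series, simplex-projection
forecasting (nearest-neighbor prediction on the reconstructed attractor),
embedding-dimension selection, and S-map forecasting with the associated
nonlinearity test. These are the building blocks on which convergent cross
mapping (:mod:`mccm.ccm`) operates.

Notation follows common EDM usage: ``E`` is the embedding dimension, ``tau``
the lag between delay coordinates, ``tp`` the prediction horizon, ``theta``
the S-map local-weighting exponent and forecast skill ``rho`` the Pearson
correlation between predictions and observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "DegenerateSeriesError",
    "InsufficientDataError",
    "EmbeddingConfig",
    "EmbeddingModel",
    "ForecastResult",
    "NonlinearityProfile",
    "DEFAULT_THETA_GRID",
    "preprocess",
    "delay_embed",
    "simplex_forecast",
    "select_embedding_dimension",
    "smap_forecast",
    "nonlinearity_test",
    "forecast_skill",
]

#: Default S-map local-weighting exponents; 0 is the global linear map.
DEFAULT_THETA_GRID: tuple[float, ...] = (0.0, 0.1, 0.3, 0.5, 1.0, 2.0, 4.0, 8.0)


class DegenerateSeriesError(ValueError):
    """The series is constant (zero variance) after preprocessing.

    Callers are expected to skip the affected user / variable pair rather
    than impute: a flat usage series carries no dynamics to reconstruct.
    """


class InsufficientDataError(ValueError):
    """The series is too short (or the library too sparse) for the request."""


@dataclass(frozen=True)
class EmbeddingConfig:
    """Delay-embedding parameters.

    Parameters
    ----------
    E : int
        Embedding dimension (number of delay coordinates), >= 1.
    tau : int
        Delay between coordinates, in sampling steps (days), >= 1.
    tp : int
        Prediction horizon in sampling steps, >= 1.
    """

    E: int
    tau: int = 1
    tp: int = 1

    def __post_init__(self) -> None:
        if self.E < 1:
            raise ValueError(f"E must be >= 1, got {self.E}")
        if self.tau < 1:
            raise ValueError(f"tau must be >= 1, got {self.tau}")
        if self.tp < 1:
            raise ValueError(f"tp must be >= 1, got {self.tp}")


@dataclass
class EmbeddingModel:
    """A delay-coordinate reconstruction (shadow manifold) of one series.

    ``points[i]`` is the vector ``(x_t, x_{t-tau}, ..., x_{t-(E-1)tau})`` for
    ``t = times[i]``; points are ordered by time index and there are exactly
    ``T - (E-1)*tau`` of them.
    """

    source: np.ndarray
    config: EmbeddingConfig
    points: np.ndarray
    times: np.ndarray

    @property
    def n_points(self) -> int:
        return len(self.times)


@dataclass
class ForecastResult:
    """Point forecasts with their realized observations and skill."""

    predictions: np.ndarray
    observations: np.ndarray
    skill: float
    n_pred: int
    target_times: np.ndarray | None = None


@dataclass
class NonlinearityProfile:
    """S-map skill across the theta grid and the derived nonlinearity flags.

    ``delta_rho`` is max skill over theta > 0 minus skill at theta = 0 (the
    global linear map). ``is_nonlinear`` uses the conventional delta-rho
    criterion with a margin; ``is_nonlinear_literal`` is the weaker
    "maximum skill > 0" reading, reported alongside for audit.
    """

    theta_grid: tuple[float, ...]
    skill_by_theta: tuple[float, ...]
    delta_rho: float
    is_nonlinear: bool
    is_nonlinear_literal: bool
    margin: float = 0.01


def preprocess(
    values, transform: str = "log1p", standardize: bool = True
) -> np.ndarray:
    """Transform a raw daily count series for embedding.

    Applies ``log(1 + x)`` (default) or no transform, then optional
    centering/scaling to zero mean and unit (population) variance. Daily
    event counts are zero-inflated and right-skewed; without the transform
    rare large counts dominate the Euclidean neighborhoods on the manifold.

    Raises
    ------
    DegenerateSeriesError
        If ``standardize`` is requested on a constant series.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InsufficientDataError("series must be 1-D with length >= 2")
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite values")
    if transform == "log1p":
        x = np.log1p(x)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}; use 'none' or 'log1p'")
    if standardize:
        sd = float(x.std())
        if sd == 0.0:
            raise DegenerateSeriesError(
                "degenerate series: zero variance, cannot standardize"
            )
        x = (x - x.mean()) / sd
    return x


def delay_embed(series, config: EmbeddingConfig) -> EmbeddingModel:
    """Build the delay-coordinate reconstruction of ``series``.

    Requires ``T >= (E-1)*tau + 1 + tp`` so that at least one embedded point
    has a ``tp``-step future.
    """
    x = np.asarray(series, dtype=float)
    T = len(x)
    E, tau, tp = config.E, config.tau, config.tp
    min_T = (E - 1) * tau + 1 + tp
    if T < min_T:
        raise InsufficientDataError(
            f"insufficient length: T={T} < required minimum {min_T} "
            f"for E={E}, tau={tau}, tp={tp}"
        )
    times = np.arange((E - 1) * tau, T)
    points = np.column_stack([x[times - j * tau] for j in range(E)])
    return EmbeddingModel(source=x, config=config, points=points, times=times)


def forecast_skill(predictions: np.ndarray, observations: np.ndarray) -> float:
    """Pearson correlation between forecasts and realized values.

    Raises ``InsufficientDataError`` when fewer than 3 forecast points exist
    or the observations have zero variance (skill undefined). Constant
    predictions against varying observations score 0 (no linear association).
    """
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observations, dtype=float)
    if p.shape != o.shape or p.ndim != 1:
        raise ValueError("predictions and observations must be equal-length 1-D")
    if len(p) < 3:
        raise InsufficientDataError("skill undefined: fewer than 3 forecast points")
    oc = o - o.mean()
    so = float(np.sqrt(oc @ oc))
    if so == 0.0:
        raise InsufficientDataError("skill undefined: zero variance in observations")
    pc = p - p.mean()
    sp = float(np.sqrt(pc @ pc))
    if sp == 0.0:
        return 0.0
    return float(np.clip((pc @ oc) / (sp * so), -1.0, 1.0))


def simplex_neighbor_predict(
    dist: np.ndarray,
    target_times: np.ndarray,
    lib_times: np.ndarray,
    lib_response: np.ndarray,
    k: int,
    exclusion_radius: int = 0,
) -> np.ndarray:
    """Core simplex predictor on a precomputed distance matrix.

    For each row (target), selects the ``k`` nearest admissible library
    columns, weights them ``w_i = exp(-d_i / d_min)`` (indicator weights on
    the zero-distance set when ``d_min == 0``), and returns the weighted
    mean of ``lib_response``. Library points within ``exclusion_radius`` time
    steps of the target are inadmissible (radius < 0 disables exclusion;
    radius 0 removes only the exact self-match).

    Neighbor selection uses a linear-time partition; the ordering of the
    selected set is immaterial because the weights depend only on the
    distances. Exact distance ties at the selection boundary are resolved by
    the (deterministic) partition order; they arise only on series with
    repeated values, where the zero-distance indicator weighting already
    makes the prediction insensitive to the choice.
    """
    d = np.asarray(dist, dtype=float)
    if exclusion_radius >= 0:
        excl = (
            np.abs(target_times[:, None] - lib_times[None, :]) <= exclusion_radius
        )
        d = np.where(excl, np.inf, d)
    n_lib = d.shape[1]
    if n_lib < k:
        raise InsufficientDataError(
            f"fewer than {k} admissible neighbors for at least one target"
        )
    if n_lib == k:
        nn = np.broadcast_to(np.arange(k), d.shape).copy()
    else:
        nn = np.argpartition(d, k - 1, axis=1)[:, :k]
    dk = np.take_along_axis(d, nn, axis=1)
    if not np.isfinite(dk).all():
        raise InsufficientDataError(
            f"fewer than {k} admissible neighbors for at least one target"
        )
    dmin = dk.min(axis=1, keepdims=True)
    safe = np.where(dmin > 0, dmin, 1.0)
    w = np.exp(-dk / safe)
    zero_rows = dmin[:, 0] == 0.0
    if zero_rows.any():
        w[zero_rows] = (dk[zero_rows] == 0.0).astype(float)
    w /= w.sum(axis=1, keepdims=True)
    return (w * lib_response[nn]).sum(axis=1)


def simplex_forecast(
    model: EmbeddingModel,
    targets: np.ndarray | None = None,
    exclusion_radius: int = 0,
) -> ForecastResult:
    """Leave-one-out simplex-projection forecast over the embedded series.

    Each target's ``tp``-step future is predicted as the exponentially
    weighted average of the futures of its ``E + 1`` nearest neighbors on
    the shadow manifold. Skill is the Pearson correlation between predicted
    and observed futures.

    Parameters
    ----------
    targets : array of time indices, optional
        Time indices (on the source series) to forecast; defaults to every
        embedded point with an observable future.
    exclusion_radius : int
        Theiler-style temporal exclusion window; 0 excludes only the target
        itself, negative disables exclusion entirely.
    """
    x = model.source
    E, tp = model.config.E, model.config.tp
    T = len(x)
    has_future = model.times + tp <= T - 1
    lib_pos = np.where(has_future)[0]
    if targets is None:
        tgt_pos = lib_pos
    else:
        targets = np.asarray(targets)
        pos = targets - model.times[0]
        if (
            (pos < 0).any()
            or (pos >= model.n_points).any()
            or (targets + tp > T - 1).any()
        ):
            raise ValueError("targets must be embedded times with a tp-step future")
        tgt_pos = pos
    if len(tgt_pos) < 3:
        raise InsufficientDataError("skill undefined: fewer than 3 forecast points")
    dist = cdist(model.points[tgt_pos], model.points[lib_pos])
    preds = simplex_neighbor_predict(
        dist,
        model.times[tgt_pos],
        model.times[lib_pos],
        x[model.times[lib_pos] + tp],
        k=E + 1,
        exclusion_radius=exclusion_radius,
    )
    obs = x[model.times[tgt_pos] + tp]
    return ForecastResult(
        predictions=preds,
        observations=obs,
        skill=forecast_skill(preds, obs),
        n_pred=len(preds),
        target_times=model.times[tgt_pos],
    )


def select_embedding_dimension(
    series,
    E_range=None,
    tau: int = 1,
    tp: int = 1,
    exclusion_radius: int = 0,
) -> tuple[int, dict[int, float]]:
    """Choose E by maximizing leave-one-out simplex forecast skill.

    Returns the selected dimension and the full skill-vs-E curve so the
    choice can be audited. Infeasible dimensions (series too short) are
    absent from the curve rather than reported as zero skill. Ties break
    toward the smaller E.
    """
    if E_range is None:
        E_range = range(1, 11)
    skills: dict[int, float] = {}
    for E in E_range:
        try:
            model = delay_embed(series, EmbeddingConfig(E=E, tau=tau, tp=tp))
            res = simplex_forecast(model, exclusion_radius=exclusion_radius)
        except InsufficientDataError:
            continue
        skills[E] = res.skill
    if not skills:
        raise InsufficientDataError(
            "no feasible embedding dimension in range for this series length"
        )
    E_star = max(skills, key=lambda E: (skills[E], -E))
    return E_star, skills


def smap_forecast(
    series,
    E: int,
    theta: float,
    tau: int = 1,
    tp: int = 1,
    exclusion_radius: int = 0,
) -> ForecastResult:
    """Sequentially locally weighted (S-map) forecast of the embedded series.

    For each target point the admissible library receives weights
    ``w_i = exp(-theta * d_i / d_bar)`` with ``d_bar`` the target's mean
    admissible distance, and a weighted least-squares linear map (with
    intercept) from library vectors to their ``tp``-step futures produces
    the forecast. ``theta = 0`` gives uniform weights, i.e. a single global
    linear autoregressive map; larger theta makes the map increasingly
    state-dependent.

    All targets are solved in one batched normal-equations pass; singular
    systems fall back to per-target SVD least squares.
    """
    if theta < 0:
        raise ValueError(f"theta must be >= 0, got {theta}")
    model = delay_embed(series, EmbeddingConfig(E=E, tau=tau, tp=tp))
    x = model.source
    T = len(x)
    has_future = model.times + tp <= T - 1
    lib_pos = np.where(has_future)[0]
    tgt_pos = lib_pos
    if len(tgt_pos) < 3:
        raise InsufficientDataError("skill undefined: fewer than 3 forecast points")
    lib_times = model.times[lib_pos]
    tgt_times = model.times[tgt_pos]
    P_lib = model.points[lib_pos]
    P_tgt = model.points[tgt_pos]
    y = x[lib_times + tp]

    D = cdist(P_tgt, P_lib)
    if exclusion_radius >= 0:
        excl = np.abs(tgt_times[:, None] - lib_times[None, :]) <= exclusion_radius
    else:
        excl = np.zeros_like(D, dtype=bool)
    adm = ~excl
    n_adm = adm.sum(axis=1)
    if (n_adm < E + 2).any():
        bad = int(np.argmin(n_adm))
        raise InsufficientDataError(
            f"target at t={tgt_times[bad]} has too few admissible library points"
        )
    dbar = np.where(adm, D, 0.0).sum(axis=1) / n_adm
    if (dbar == 0.0).any():
        raise DegenerateSeriesError(
            "degenerate series: all admissible manifold distances are zero"
        )
    W = np.exp(-theta * D / dbar[:, None])
    W[excl] = 0.0

    X = np.column_stack([np.ones(len(P_lib)), P_lib])  # (n_lib, E+1)
    Xt = np.column_stack([np.ones(len(P_tgt)), P_tgt])
    A = np.einsum("tl,li,lj->tij", W, X, X, optimize=True)
    b = np.einsum("tl,li,l->ti", W, X, y, optimize=True)
    try:
        beta = np.linalg.solve(A, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        beta = np.empty_like(b)
        for t in range(len(tgt_pos)):
            sw = np.sqrt(W[t])
            if not sw.any():
                raise InsufficientDataError(
                    f"no solvable S-map at target index {t} (t={tgt_times[t]})"
                )
            coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
            beta[t] = coef
    preds = (Xt * beta).sum(axis=1)
    obs = x[tgt_times + tp]
    return ForecastResult(
        predictions=preds,
        observations=obs,
        skill=forecast_skill(preds, obs),
        n_pred=len(preds),
        target_times=tgt_times,
    )


def nonlinearity_test(
    series,
    E: int,
    theta_grid=None,
    margin: float = 0.01,
    tau: int = 1,
    tp: int = 1,
    exclusion_radius: int = 0,
) -> NonlinearityProfile:
    """Test for state-dependent (nonlinear) dynamics via the S-map theta scan.

    A series is flagged nonlinear when local weighting improves forecast
    skill over the global linear map by more than ``margin`` (delta-rho
    criterion) while the best skill is positive. The literal
    "max skill > 0" flag is also recorded: it is nearly always true for any
    autocorrelated series and cannot separate linear from nonlinear
    dynamics on its own, so it is kept only for comparison.
    """
    if theta_grid is None:
        theta_grid = DEFAULT_THETA_GRID
    grid = tuple(float(t) for t in theta_grid)
    if len(grid) < 2 or grid[0] != 0.0 or any(
        b <= a for a, b in zip(grid, grid[1:])
    ):
        raise ValueError("theta_grid must start at 0 and be strictly increasing")
    skills = tuple(
        smap_forecast(
            series, E=E, theta=t, tau=tau, tp=tp, exclusion_radius=exclusion_radius
        ).skill
        for t in grid
    )
    delta_rho = max(skills[1:]) - skills[0]
    max_skill = max(skills)
    return NonlinearityProfile(
        theta_grid=grid,
        skill_by_theta=skills,
        delta_rho=float(delta_rho),
        is_nonlinear=bool(delta_rho > margin and max_skill > 0),
        is_nonlinear_literal=bool(max_skill > 0),
        margin=margin,
    )
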