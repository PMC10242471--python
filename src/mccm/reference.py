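"""Naive, loop-based reference implementations used as cross-checks.

These re-derive simplex projection, the global linear (theta = 0) forecast
and cross mapping with plain Python loops and exhaustive distance scans.
They are deliberately slow and independent of the vectorized code paths in
:mod:`mccm.edm` and :mod:`mccm.ccm`; tests compare the two routes
numerically.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "naive_simplex_predictions",
    "naive_global_linear_predictions",
    "naive_cross_map_skill",
    "naive_pearson",
]


def _embed(x: np.ndarray, E: int, tau: int) -> tuple[list[list[float]], list[int]]:
    points, times = [], []
    for t in range((E - 1) * tau, len(x)):
        points.append([float(x[t - j * tau]) for j in range(E)])
        times.append(t)
    return points, times


def _euclid(a, b) -> float:
    return math.sqrt(sum((ai - bi) ** 2 for ai, bi in zip(a, b)))


def _simplex_point(
    target_vec, target_time, lib_vecs, lib_times, lib_resp, k, exclusion_radius
):
    cand = []
    for v, t, r in zip(lib_vecs, lib_times, lib_resp):
        if exclusion_radius >= 0 and abs(t - target_time) <= exclusion_radius:
            continue
        cand.append((_euclid(target_vec, v), t, r))
    cand.sort(key=lambda c: (c[0], c[1]))  # ties -> smaller time index
    if len(cand) < k:
        raise ValueError("not enough admissible neighbors")
    near = cand[:k]
    dmin = near[0][0]
    if dmin == 0.0:
        weights = [1.0 if d == 0.0 else 0.0 for d, _, _ in near]
    else:
        weights = [math.exp(-d / dmin) for d, _, _ in near]
    total = sum(weights)
    return sum(w * r for w, (_, _, r) in zip(weights, near)) / total


def naive_simplex_predictions(
    series, E: int, tau: int = 1, tp: int = 1, exclusion_radius: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out simplex forecasts by exhaustive pairwise scan.

    Returns (predictions, observations) over every embedded point with a
    ``tp``-step future, in time order.
    """
    x = np.asarray(series, dtype=float)
    points, times = _embed(x, E, tau)
    lib = [(p, t) for p, t in zip(points, times) if t + tp <= len(x) - 1]
    lib_vecs = [p for p, _ in lib]
    lib_times = [t for _, t in lib]
    lib_resp = [float(x[t + tp]) for t in lib_times]
    preds, obs = [], []
    for vec, t in lib:
        preds.append(
            _simplex_point(
                vec, t, lib_vecs, lib_times, lib_resp, E + 1, exclusion_radius
            )
        )
        obs.append(float(x[t + tp]))
    return np.asarray(preds), np.asarray(obs)


def naive_global_linear_predictions(
    series, E: int, tau: int = 1, tp: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary least-squares autoregressive forecasts on the embedded points.

    One global linear map (with intercept) fitted to all embedded points with
    a future; predictions are its fitted values. This is the closed-form
    limit that an S-map with theta = 0 and no temporal exclusion must match.
    """
    x = np.asarray(series, dtype=float)
    points, times = _embed(x, E, tau)
    rows = [(p, t) for p, t in zip(points, times) if t + tp <= len(x) - 1]
    X = np.array([[1.0] + p for p, _ in rows])
    y = np.array([x[t + tp] for _, t in rows])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return X @ coef, y


def naive_pearson(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    am, bm = a - a.mean(), b - b.mean()
    den = math.sqrt(float(am @ am)) * math.sqrt(float(bm @ bm))
    return float(am @ bm) / den


def naive_cross_map_skill(
    effect_series,
    cause_series,
    E: int,
    tau: int = 1,
    exclusion_radius: int = 0,
    library_positions=None,
) -> float:
    """Full-library (or given-subset) cross-map skill by exhaustive scan.

    Embeds the effect series, estimates the concurrent cause value at every
    manifold point from its E+1 nearest library neighbors, and returns the
    Pearson correlation with the true cause values.
    """
    eff = np.asarray(effect_series, dtype=float)
    cau = np.asarray(cause_series, dtype=float)
    points, times = _embed(eff, E, tau)
    if library_positions is None:
        library_positions = range(len(points))
    lib_vecs = [points[i] for i in library_positions]
    lib_times = [times[i] for i in library_positions]
    lib_resp = [float(cau[t]) for t in lib_times]
    preds, obs = [], []
    for vec, t in zip(points, times):
        preds.append(
            _simplex_point(
                vec, t, lib_vecs, lib_times, lib_resp, E + 1, exclusion_radius
            )
        )
        obs.append(float(cau[t]))
    return naive_pearson(preds, obs)
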