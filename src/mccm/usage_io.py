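"""Reading, validating and writing daily usage-log data.

The input is a long-format delimited file with one row per
(user, day, variable) observation of a digital-intervention platform:
how many times that user triggered that usage event on that day. Days a
user generated no record are explicit zero counts — the platform logs
events, so absence of a record means no activity, not missing data.
Day indexing is 0-based per user from the user's first observed day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "VariableRegistry",
    "UsageSeries",
    "Cohort",
    "default_registry",
    "read_usage_log",
    "write_usage_log",
    "write_pair_summary_table",
    "write_user_scatter",
    "truncate_trailing_zero_days",
]

#: Therapy-stream usage variables of the default registry.
DEFAULT_THERAPY_VARS = (
    "steps_started",
    "pathways_started",
    "actions_done",
    "suggested_content_visits",
    "message_visits",
    "therapy_visits",
)
#: Social-networking-stream usage variables of the default registry.
DEFAULT_SOCIAL_VARS = ("posts", "comments", "likes", "reactions")

_FLOAT_FMT = "%.6f"


@dataclass(frozen=True)
class VariableRegistry:
    """Declared usage variables, split into therapy and social streams."""

    therapy_vars: tuple[str, ...]
    social_vars: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "therapy_vars", tuple(self.therapy_vars))
        object.__setattr__(self, "social_vars", tuple(self.social_vars))
        if not self.therapy_vars or not self.social_vars:
            raise ValueError("registry needs at least one variable in each stream")
        names = self.therapy_vars + self.social_vars
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique across both streams")

    @property
    def all_vars(self) -> tuple[str, ...]:
        return self.therapy_vars + self.social_vars

    def pairs(self) -> list[tuple[str, str]]:
        """All (social_var, therapy_var) pairs, therapy-major order."""
        return [
            (s, t) for t in self.therapy_vars for s in self.social_vars
        ]


def default_registry() -> VariableRegistry:
    """The 6 therapy x 4 social variable registry of the platform."""
    return VariableRegistry(DEFAULT_THERAPY_VARS, DEFAULT_SOCIAL_VARS)


@dataclass
class UsageSeries:
    """One user's gap-free daily count series for one variable."""

    user_id: str
    variable: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("values must be a non-empty 1-D array")
        if not np.issubdtype(v.dtype, np.integer):
            if not np.all(np.equal(np.mod(v, 1), 0)):
                raise ValueError("counts must be integral")
            v = v.astype(np.int64)
        if (v < 0).any():
            raise ValueError("counts must be non-negative")
        self.values = v.astype(np.int64)

    @property
    def T(self) -> int:
        return len(self.values)


@dataclass
class Cohort:
    """All users' series for every registered variable."""

    registry: VariableRegistry
    series: dict = field(default_factory=dict)  # (user_id, variable) -> UsageSeries

    def __post_init__(self) -> None:
        users = self.users
        for u in users:
            lengths = set()
            for v in self.registry.all_vars:
                if (u, v) not in self.series:
                    raise ValueError(f"user {u!r} missing series for {v!r}")
                lengths.add(self.series[(u, v)].T)
            if len(lengths) != 1:
                raise ValueError(f"user {u!r} has unequal series lengths {lengths}")

    @property
    def users(self) -> list[str]:
        return sorted({u for (u, _) in self.series})

    @property
    def n_users(self) -> int:
        return len(self.users)

    def get(self, user_id: str, variable: str) -> UsageSeries:
        return self.series[(user_id, variable)]

    def user_length(self, user_id: str) -> int:
        return self.series[(user_id, self.registry.all_vars[0])].T


def _resolve_days(df: pd.DataFrame) -> pd.Series:
    """Map a 'day' or ISO 'date' column to per-user 0-based day offsets."""
    if "day" in df.columns:
        day = pd.to_numeric(df["day"], errors="coerce")
        bad = day.isna() | (np.mod(day, 1) != 0) | (day < 0)
        if bad.any():
            row = int(df.index[bad][0]) + 2
            raise ValueError(f"invalid day value at file row {row}")
        return day.astype(np.int64)
    if "date" in df.columns:
        dates = pd.to_datetime(df["date"], errors="coerce", format="ISO8601")
        if dates.isna().any():
            row = int(df.index[dates.isna()][0]) + 2
            raise ValueError(f"unparseable date at file row {row}")
        origin = dates.groupby(df["user"]).transform("min")
        return (dates - origin).dt.days.astype(np.int64)
    raise ValueError("input must have a 'day' or 'date' column")


def read_usage_log(
    path, registry: VariableRegistry | None = None, delimiter: str = ","
) -> Cohort:
    """Read a long-format usage log into a calendar-aligned :class:`Cohort`.

    Expects header columns ``user``, ``day`` (or ISO ``date``), ``variable``,
    ``count``. Missing (user, day, variable) combinations within each user's
    observed span become zero counts; ISO dates are converted to per-user day
    offsets from that user's first date.

    Raises ``ValueError`` on unknown variable names, negative or non-integer
    counts (with the offending file row number), or duplicate
    (user, day, variable) keys.
    """
    registry = registry or default_registry()
    df = pd.read_csv(path, sep=delimiter, dtype={"user": str, "variable": str})
    required = {"user", "variable", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"input is missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("input contains no rows")

    unknown = sorted(set(df["variable"]) - set(registry.all_vars))
    if unknown:
        raise ValueError(f"unknown variable name(s): {unknown}")

    count = pd.to_numeric(df["count"], errors="coerce")
    bad = count.isna() | (np.mod(count, 1) != 0) | (count < 0)
    if bad.any():
        row = int(df.index[bad][0]) + 2
        raise ValueError(
            f"negative or non-integer count at file row {row}: "
            f"{df.loc[df.index[bad][0], 'count']!r}"
        )
    df = df.assign(count=count.astype(np.int64), day=_resolve_days(df))

    dup = df.duplicated(subset=["user", "day", "variable"], keep=False)
    if dup.any():
        first = df.loc[dup, ["user", "day", "variable"]].iloc[0]
        raise ValueError(
            "duplicate (user, day, variable) row: "
            f"({first['user']!r}, {int(first['day'])}, {first['variable']!r})"
        )

    series: dict = {}
    for user, grp in df.groupby("user", sort=True):
        T = int(grp["day"].max()) + 1
        for var in registry.all_vars:
            values = np.zeros(T, dtype=np.int64)
            sub = grp[grp["variable"] == var]
            values[sub["day"].to_numpy()] = sub["count"].to_numpy()
            series[(user, var)] = UsageSeries(user, var, values)
    return Cohort(registry=registry, series=series)


def write_usage_log(cohort: Cohort, path, delimiter: str = ",") -> Path:
    """Write a cohort back to the long format (all days, zeros included)."""
    rows = []
    for user in cohort.users:
        for var in cohort.registry.all_vars:
            s = cohort.get(user, var)
            rows.append(
                pd.DataFrame(
                    {
                        "user": user,
                        "day": np.arange(s.T),
                        "variable": var,
                        "count": s.values,
                    }
                )
            )
    path = Path(path)
    pd.concat(rows, ignore_index=True).to_csv(path, sep=delimiter, index=False)
    return path


def truncate_trailing_zero_days(cohort: Cohort) -> Cohort:
    """Drop each user's trailing all-zero days (post-disengagement tail).

    A user's new length is one past the last day with any activity on any
    registered variable (minimum length 1). Optional preprocessing; the
    reader itself never truncates.
    """
    series: dict = {}
    for user in cohort.users:
        stack = np.stack(
            [cohort.get(user, v).values for v in cohort.registry.all_vars]
        )
        active = np.where(stack.sum(axis=0) > 0)[0]
        T_new = int(active[-1]) + 1 if len(active) else 1
        for v in cohort.registry.all_vars:
            series[(user, v)] = UsageSeries(
                user, v, cohort.get(user, v).values[:T_new]
            )
    return Cohort(registry=cohort.registry, series=series)


def _fmt_cell(mean, sd) -> str:
    if mean is None:
        return "NA"
    if sd is None:
        return f"{mean:.3f} (NA)"
    return f"{mean:.3f} ({sd:.3f})"


def write_pair_summary_table(
    summaries, path, registry: VariableRegistry | None = None, delimiter: str = ","
) -> tuple[Path, Path]:
    """Write the cohort summary matrix plus a machine-readable companion.

    The matrix has therapy variables as rows, social variables as columns and
    "mean (SD)" cells; the long-format companion (``<stem>_long.csv``) adds
    the direction flag and validity counts per pair. Positive means carry the
    ``social_drives_therapy`` flag, negative means ``therapy_drives_social``.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no pair summaries to write")
    seen = set()
    for s in summaries:
        if s.pair in seen:
            raise ValueError(f"duplicate pair summary for {s.pair}")
        seen.add(s.pair)

    if registry is not None:
        therapy_order = list(registry.therapy_vars)
        social_order = list(registry.social_vars)
    else:
        therapy_order = list(dict.fromkeys(s.pair[1] for s in summaries))
        social_order = list(dict.fromkeys(s.pair[0] for s in summaries))

    by_pair = {s.pair: s for s in summaries}
    matrix = pd.DataFrame(index=therapy_order, columns=social_order, dtype=object)
    for t in therapy_order:
        for s in social_order:
            summ = by_pair.get((s, t))
            matrix.loc[t, s] = (
                _fmt_cell(summ.mean_score, summ.sd_score) if summ else "NA"
            )
    path = Path(path)
    matrix.index.name = "therapy_var"
    matrix.to_csv(path, sep=delimiter)

    long_path = path.with_name(path.stem + "_long" + path.suffix)
    long_df = pd.DataFrame(
        {
            "therapy_var": [s.pair[1] for s in summaries],
            "social_var": [s.pair[0] for s in summaries],
            "mean_score": [s.mean_score for s in summaries],
            "sd_score": [s.sd_score for s in summaries],
            "n_valid": [s.n_valid for s in summaries],
            "n_total": [s.n_total for s in summaries],
            "direction_flag": [s.direction_flag for s in summaries],
        }
    )
    long_df.to_csv(
        long_path, sep=delimiter, index=False, float_format=_FLOAT_FMT, na_rep="NA"
    )
    return path, long_path


def write_user_scatter(scores, path, delimiter: str = ",") -> Path:
    """Write per-user points for one variable pair's causality scatter.

    One row per user: the signed directional score (x-position), the skill
    margin over the plain correlation (y-position) and the validity flag,
    plus the cohort mean of valid users' scores (the dashed reference line;
    NA when no user is valid).
    """
    scores = list(scores)
    if not scores:
        raise ValueError("no user scores to write")
    pairs = {s.pair for s in scores}
    if len(pairs) != 1:
        raise ValueError(f"scores mix multiple pairs: {sorted(pairs)}")
    valid = [s.score for s in scores if s.valid]
    mean_valid = float(np.mean(valid)) if valid else np.nan
    df = pd.DataFrame(
        {
            "user": [s.user_id for s in scores],
            "score": [s.score for s in scores],
            "skill_margin": [s.skill_margin for s in scores],
            "valid": [s.valid for s in scores],
            "mean_valid_score": mean_valid,
        }
    )
    path = Path(path)
    df.to_csv(path, sep=delimiter, index=False, float_format=_FLOAT_FMT, na_rep="NA")
    return path
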