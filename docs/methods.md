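# Methods

This note documents the models, estimators, numerical choices and known
limitations of the `mccm` package. It is the design record: every default
named here is the one the code ships with, and every empirical claim is one
the test suite or `scripts/acceptance.py` computes.

## Problem setting

A cohort of users interacts daily with a two-stream digital platform: a
*therapy* stream (modules started, actions completed, content visits, ...)
and a *social-networking* stream (posts, comments, likes, reactions). The
data are per-user, per-day event counts. The question is directional: does
social activity drive subsequent therapy activity, or the reverse? Daily
usage is treated as the observable of a nonlinear dynamical system per user,
and causal direction is assessed with convergent cross mapping (CCM),
repeated per user and aggregated across the cohort (multiple CCM, MCCM).

## Empirical dynamic modeling core

**Delay embedding.** A series `x_0..x_{T-1}` is embedded as vectors
`v_t = (x_t, x_{t-τ}, ..., x_{t-(E-1)τ})`. Defaults `τ = 1` day and
prediction horizon `tp = 1` day: the data are daily, so one day is the
natural lag unit. Both are configurable.

**Simplex projection.** Each target's `tp`-step future is the weighted
average of the futures of its `E+1` nearest neighbors on the shadow
manifold, with weights `exp(-d_i / d_min)`. When `d_min = 0` the weights
degenerate to indicators on the zero-distance neighbors (exact matches
dominate; this avoids 0/0). Forecast skill ρ is the Pearson correlation
between forecasts and realized values. Leave-one-out evaluation with a
Theiler exclusion radius of 0 (the target itself) by default; the radius is
configurable because daily counts are autocorrelated and users may want a
wider window. Neighbor search uses a linear-time partition; neighbor order
never enters the prediction, so exact distance ties at the selection
boundary (probability zero for continuous data) are resolved by the
deterministic partition order.

**Embedding dimension selection.** `E` is chosen from 1..10 as the argmax
of leave-one-out simplex skill, ties toward smaller `E`; the full skill-vs-E
curve is returned for audit. Dimensions infeasible for the series length are
reported as absent, not as zero skill.

**S-map and the nonlinearity test.** The S-map fits, per target, a weighted
linear map (with intercept) from library vectors to their futures, with
weights `exp(-θ d_i / d̄)`. At `θ = 0` this is a single global linear
autoregression — verified in the tests to match the ordinary least-squares
fit to 1e-8. The solver is a batched weighted normal-equations pass
(`np.linalg.solve` over all targets at once); any singular system falls back
to per-target SVD least squares, which handles rank deficiency. A series is
flagged *nonlinear* when the best skill over θ > 0 exceeds the θ = 0 skill
by more than `nonlinearity_margin` (default 0.01) and the best skill is
positive (the Δρ criterion). A weaker "best skill > 0" flag is also
recorded; it is true for nearly any autocorrelated series and cannot
separate linear from nonlinear dynamics, so it is reported only for
comparison. Nonlinearity results are diagnostics: they do not gate user
inclusion by default (a config flag can enable gating).

**Count preprocessing.** Default `log1p` then z-scoring per series. Daily
counts are zero-inflated and right-skewed; without the transform, rare
large counts dominate Euclidean neighborhoods. Constant series raise a
degenerate-series signal and the affected user/pair is skipped and logged,
never imputed.

## Convergent cross mapping

To test "cause → effect", the *effect* series is embedded and the simplex
neighbors of each manifold point estimate the *concurrent* cause values
(classic CCM; no cross-map lag scan). Skill is evaluated over a library-size
schedule: 8 sizes geometrically spaced from `max(E+2, 10)` to the full
embedding, 20 random without-replacement draws per size (one deterministic
draw at the full size). `E` is selected on the effect (manifold) series,
separately per direction.

**Convergence criterion.** A direction converges when all of:

1. Kendall rank correlation between library size and mean skill > 0;
2. skill gain from the smallest to the largest library >
   `convergence_margin × (1 − skill(L₁))`;
3. full-library skill > 0.

The gain is normalized by the headroom `1 − skill(L₁)` so the criterion
behaves consistently both near zero skill (requirement ≈ the plain margin)
and near the ceiling, where an already near-perfect small-library cross-map
has no room left to grow yet is plainly convergent (e.g. a series
cross-mapping itself).

`convergence_margin` defaults to **0.2**, calibrated by simulation against
independent chaotic series (T = 400): cross-map skill between independent
systems fluctuates with a standard deviation near 0.13 at the full library —
far wider than i.i.d. noise intuition suggests, because cross-map estimates
are smooth fields on the effect attractor with few effective degrees of
freedom. A margin of 0.05 lets ~40% of independent pairs through; 0.2 keeps
the false-verdict rate under 10% while leaving the coupled-map benchmark
(gains ≈ 0.6) untouched. The null-calibration and direction-recovery tests
pin both sides of this trade-off.

## Per-user scoring and cohort aggregation

For a (social, therapy) pair, both directions are cross-mapped with the same
seed and

```
score        = ρ(social→therapy test) − ρ(therapy→social test)
skill_margin = max(ρ_st, ρ_ts) − |r(social, therapy)|
```

where `r` is the plain Pearson correlation of the two raw count series.
Positive scores mean social drives therapy. The score is antisymmetric under
swapping the streams (verified exactly in the tests). An alternative
"dominant skill" convention (the stronger direction's skill, signed) is
available behind `score_convention`. A user's verdict is **valid** only when
`skill_margin > 0` — otherwise cross mapping offers no power beyond simple
correlation — and at least one direction converges.

Cohort aggregation takes the mean and sample SD (n−1) of *valid* users'
scores per pair; an empty valid set is flagged (`NA`), never fabricated.
The summary matrix has therapy variables as rows, social variables as
columns, "mean (SD)" cells, and a long-format companion carrying the
direction flag (`social_drives_therapy` for positive means,
`therapy_drives_social` for negative) and validity counts. Per-user scatter
files carry the signed score (x), the skill margin (y), the validity flag
and the valid-mean reference line.

Per-(user, pair) seeds are derived from the master seed with a CRC of the
user and variable names, so results are reproducible and independent of
user ordering; two identically seeded runs write byte-identical analysis
outputs.

## Synthetic data

**Coupled logistic maps.** The benchmark
`x' = x(r_x − r_x x − β_yx y)`, `y' = y(r_y − r_y y − β_xy x)` with
defaults `r_x = 3.8`, `r_y = 3.5`, burn-in 300 steps, seeded initial
conditions in (0.1, 0.9); parameter combinations whose trajectory leaves
(0, 1) are rejected. `β_xy = 0.32, β_yx = 0` is the canonical
unidirectional setting used in the recovery tests.

**Engagement cohorts.** Every registered variable carries a latent daily
engagement state on (coupled) logistic-map dynamics; a positive pair
coupling feeds the social variable's lagged state into the therapy
variable's map (social drives therapy), negative the reverse. Counts are
zero-inflated Poisson with intensity
`λ = base_rate · exp(emission_gain (z − ½) − decay·t)` and a
state-dependent structural-zero probability
`p₀ = 1 − (1 − zero_inflation)^{2(1−z)}` — inactive days cluster when
latent engagement is low, and `zero_inflation = 1` yields an all-zero
cohort. Cohort shape defaults (82 users, series lengths uniform on 282–528
days) mirror the long-term intervention cohorts the pipeline targets;
dynamic-rate defaults are `base_rate = 2` events/day, `zero_inflation =
0.3`, `decay = 0.001`/day (slow disengagement over ~1.5 years),
`emission_gain = 3`.

The latent dynamics are deliberately deterministic and nonlinear rather
than stochastic-autoregressive. Cross mapping identifies direction by
reconstructing states from the effect's attractor; a generator with linear
stochastic latents (we tried AR(1) log-intensities first) plants a ground
truth that no state-space method can recover — both cross-map directions
collapse toward what a lagged regression would see, and the planted
direction is unidentifiable. A validation generator must contain the
structure whose recovery it is meant to test.

## What the recovery experiments do and do not show

The end-to-end cohort-recovery experiment runs the generator in a
**high-engagement, low-noise regime** (`base_rate = 100`, `emission_gain =
5`, `zero_inflation = 0.05`, coupling 0.2). This is a deliberate choice:
cross-map direction recovery is acutely sensitive to observation noise on
the effect series. On the coupled-map benchmark, Gaussian observation noise
of just 2% of the signal range already flips the skill asymmetry (the
reverse direction inherits the coupling-induced synchrony component, which
is more noise-robust than fine-grained attractor reconstruction), and
Poisson counting noise at realistic daily rates (~1–2 events/day) is far
larger than that. At such rates the pipeline behaves correctly in a
different sense: nearly all users fail the validity filter, i.e. cross
mapping honestly reports that it cannot beat plain correlation. Passing the
recovery test therefore demonstrates that the estimator chain is correct
when its assumptions hold — not that direction is recoverable from sparse
real-world usage logs. For real cohorts, the per-user validity flag and the
share of invalid users are as informative as the scores themselves.

## Numerical and degenerate-input choices

- Forecast skill needs ≥ 3 forecast points and non-constant observations;
  constant predictions score 0 (no linear association).
- Skill is invariant under affine rescaling of the input series (simplex
  and S-map with intercept); property-tested.
- The embedding count identity `|points| = T − (E−1)τ` and the convex-hull
  property of simplex predictions are property-tested.
- Trailing all-zero periods (post-disengagement) are kept by ingestion; an
  explicit `truncate_trailing_zero_days` helper is provided for users who
  want to drop them.
- Per-user failures (degenerate or too-short series) never abort a cohort
  run; they are recorded in a skip census with reasons.

## Known limitations

- No surrogate-data significance testing and no cross-map lag scanning;
  both are future work, not silently approximated.
- No confidence intervals on cohort mean scores.
- The convergence margin trades power for null calibration; cohorts with
  weak coupling and short series will see many invalid users.
- Direction recovery from low-rate count data is fundamentally limited by
  observation noise (see above); the pipeline reports this through the
  validity filter rather than attempting to correct for it.
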