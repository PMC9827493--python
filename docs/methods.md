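# Methods

## Model and assumptions

The package works on post-estimation output of a choice model: one
preference weight per attribute level on a common rescaled utility scale.
Three assumptions underpin every computation:

1. **Additive separability.** Expected utility is the sum of the benefit
   attributes' weights and one term per adverse-event risk. Risks are
   preferentially independent: the value of changing one risk's probability
   does not depend on the level of another. No interaction terms are
   supported.
2. **Piecewise-linear risk utility.** A probabilistic attribute with
   effect-coded levels identifies utility only at the presented
   probabilities; the curve interpolates linearly between those knots. The
   composite `l_j(p)·k_j(AE_j)` is stored as a single curve because the
   effect-coded estimates only identify the product, never the factors.
3. **Percent scale.** All probabilities are percentage points in [0, 100],
   matching how risk levels are presented to respondents. Callers using
   proportions must convert.

## Inversion (MAR)

`invert_disutility` solves `u(p) = u(p0) − Δ` segment by segment in closed
form, scanning upward from the baseline and returning the **first
crossing**. There is no iteration and no tolerance beyond float arithmetic;
on strictly monotone segments the round-trip `invert(u(p)) = p` holds to
1e-9 (property-tested on 10⁴ random queries).

Curves need not be globally monotone (the packaged bleeding curve rises to
+0.49 at 2% before falling — a common artifact of effect-coded estimation
at probabilities respondents discount). First-crossing semantics are well
defined there, but the componentwise-dominance property of joint acceptance
is only guaranteed for monotone curves and is only asserted for them. An
optional `RiskUtilityCurve.monotonized()` preprocessing step (isotonic
regression, decreasing) is provided but off by default: the as-estimated
weights are the data.

Known discrepancy: for the packaged heart-failure study, first-crossing
inversion of the as-is bleeding curve gives an incremental threshold of
2.5 points for the NYHA II→I benefit, whereas the originating study reports
1.9. The study's handling of the non-monotone 2% level is not documented
(skipping that knot, or re-anchoring the segment, would each give different
values); this cell is therefore not treated as a reference value anywhere
in the tests.

## Extrapolation and censoring

Beyond the last knot, the default policy extends the final segment's slope
(`extend_last_segment`); `clamp` and `forbid` are available. Below the
first knot only `clamp` is defined — studies anchor their grid at the
lowest presented level (1% in the heart-failure study) and never evaluate
beneath it. Inverted thresholds crossing `censor_max` (default 20% in the
CLI, matching the originating study's bound) are reported *at* the bound
with a censored flag, never dropped: this keeps batch tables and percentile
intervals well defined and reproduces ">20%"-style reporting.

Baselines default to each curve's first knot. Incremental MARs are reported
relative to the baseline; a non-positive benefit yields an incremental MAR
of zero with an explicit `no_risk_acceptable` flag rather than a negative
threshold, which the framework does not define.

## Joint thresholds (SMART)

`joint_acceptability` evaluates the margin
`Δ − Σ_j [u_j(baseline_j) − u_j(p_j)]`; a combination is acceptable iff the
margin is ≥ 0 (indifference counts as acceptable, consistent with
"maximum acceptable" semantics). `smart_boundary` fixes the non-focal risks
on a grid, subtracts their disutility from Δ, and reuses the single-risk
inversion at the residual. Design points:

- residual exactly 0 → the boundary touches the focal baseline (continuity);
- residual < 0 → the point is flagged `unreachable`, never silently
  dropped;
- the default conditioning-grid step is 0.1 percentage points
  (configurable); no canonical resolution exists, this is simply fine
  enough that linear interpolation between boundary points is visually and
  numerically irrelevant at the reported 1-decimal precision;
- for three or more risks the surface is a dense table plus an evaluator;
  3-D rendering is presentational and not built in.

Correctness of the boundary is checked two independent ways: against an
exhaustive-enumeration oracle (`brute_force_acceptance_region`, forward
evaluation of the margin on a fine grid, exponential in the number of risks
and capped at 3) on 100 seeded random models spanning curvatures −0.8…0.9,
and against closed forms in the linear case, where the boundary satisfies
`Σ_j (p_j − baseline_j)/MAR_j = 1` and its slope is `−MAR₁/MAR₂` exactly.

## Uncertainty

Intervals are Krinsky–Robb-style: draw coefficient vectors from
N(weights, vcov), recompute the statistic per draw, report empirical
percentiles. Censored draws enter at the censoring bound. The point
estimate is the statistic at the mean weights, because that is also how the
point thresholds are computed; per-draw values are exposed for users who
prefer means of draws. The sampler uses an eigendecomposition so singular
covariances (including the zero matrix, which collapses the interval to the
point) are valid.

Nominal coverage is verified by a nested Monte-Carlo experiment: a true
linear one-risk model with sampling noise on the benefit weights (making
the MAR a linear statistic, so the percentile interval is asymptotically
exact), 500 replications of "estimate, then simulate 2000 draws", checking
that the 95% interval covers the true MAR 93–97% of the time. This
verifies the interval machinery, not any particular study's covariance —
the heart-failure fixture ships without one because the originating study
does not publish it, so its confidence intervals are not reproduced.

## Synthetic data

`random_model` generates monotone-decreasing risk curves on a fixed grid:
utility falls from 0 at the first knot to minus a random overall importance
(default range 4–10, bracketing the packaged examples' importances of
3.61–7.5) at the last. A curvature parameter in [−1, 1] maps to the segment
shape `t^exp(1.2·curvature)`: 0 gives exactly constant slopes, positive
gives increasing marginal disutility, negative decreasing — the three
qualitative regimes that determine whether the joint boundary is linear,
concave, or convex. A two-level benefit attribute (gain 30–90% of the
smallest risk importance, so thresholds are interior) and a diagonal
covariance (sd = 5% of each weight + 0.02) complete the model. What it does
*not* emulate: correlated coefficients, preference heterogeneity across
respondents, non-monotone estimates (except via an explicit stress flag),
and choice-level sampling error — so passing property tests demonstrate
correctness of the threshold arithmetic, not robustness to estimation
pathologies in real data.

## Problem sizes

The test suite uses grids of 0.25–0.5 percentage points for the oracle
comparisons (61 points per risk axis, up to 61³ joint points), 10⁴
round-trip inversion queries, and the 500×2000 coverage experiment; the
full suite runs in about a minute on one CPU. These sizes were chosen so
every check is exhaustive at the resolution where the closed forms are
exact; finer grids change nothing but runtime.

## Limitations

- Preference weights are taken as given; no estimation from choice data.
- Only piecewise-linear `l(·)`; parametric families would need dense grids.
- No interaction utilities between risks, no latent-class heterogeneity,
  and no minimum-acceptable-benefit inversion (the mirror problem).
- Below-first-knot behaviour is undefined except under `clamp`.
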