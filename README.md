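# smartmar

Benefit-risk threshold analysis from discrete-choice-experiment (DCE)
preference weights: conventional single-risk **maximum acceptable risk
(MAR)** values and **simultaneous maximum acceptable risk thresholds
(SMART)** over two or more concurrent adverse-event risks, with
baseline-risk offsets, extrapolation, censoring, and simulation-based
uncertainty intervals.

## Who this is for

Preference researchers and benefit-risk analysts who already have estimated
attribute-level preference weights (e.g. from a mixed-logit fit of DCE
choice data) and need to translate them into risk-tolerance measures for
clinical or regulatory decision making. Estimating the weights themselves is
out of scope — the input is the post-estimation weight table.

## The model

Expected utility of a treatment profile is additively separable in its
non-risk features and its adverse-event risks:

    E[U] = g(H) + Σ_j l_j(p_j) · k_j(AE_j)

where `g(H)` collects the benefit attributes' level weights, `p_j` is the
probability of adverse event *j*, and the weighted probability function
`l_j(·)` (composed with the event's disutility `k_j`) is operationalized as
a **piecewise-linear curve through the effect-coded level weights** —
exactly what a categorical risk attribute in a DCE identifies.

For a benefit with utility gain Δ = g(H¹) − g(H⁰) and a single risk with
baseline probability p⁰, the MAR is the probability increase whose
disutility exactly offsets the gain, found by closed-form inversion of the
piecewise-linear curve:

    u(p*) = u(p⁰) − Δ,      MAR = p* − p⁰

For linear curves with slope −β this collapses to MAR = Δ/β. When several
risks change at once, spending the whole Δ on each risk separately
double-counts the benefit; the joint condition is

    Δ = Σ_j [ u_j(p_j⁰) − u_j(p_j¹) ]

and the SMART boundary is the set of risk combinations satisfying it: fix
all but one (focal) risk on a grid, subtract their disutility from Δ, and
invert the focal curve at the residual. With every other risk at its
baseline this reduces to the conventional MAR, so the boundary's axis
intercepts equal the single-risk MARs. Thresholds beyond the largest
defensible extrapolation (default 20%) are censored at that bound.

## Worked example

The packaged heart-failure device study has physical functioning (NYHA
class equivalents) as the benefit and 30-day death / severe bleeding as
risks on the probability grid {1, 2, 4, 7, 10}%:

```sh
smartmar fixtures --out fx
smartmar mar --weights fx/heart_failure.csv \
  --benefit "physical functioning:NYHA IV:NYHA III" \
  --benefit "physical functioning:NYHA III:NYHA II" \
  --risks "30-day death,severe bleeding"
```

prints

```
from_level to_level            risk  benefit_value  baseline  absolute  incremental  censored
   NYHA IV NYHA III    30-day death           7.75       1.0      10.7          9.7     False
   NYHA IV NYHA III severe bleeding           7.75       1.0      20.0         19.0      True
  NYHA III  NYHA II    30-day death           1.53       1.0       3.0          2.0     False
  NYHA III  NYHA II severe bleeding           1.53       1.0       4.7          3.7     False
```

Reading: respondents would accept up to a 9.7-percentage-point increase in
30-day mortality risk (over the 1% baseline) in exchange for improving from
NYHA IV to NYHA III; the bleeding threshold for the same benefit lies beyond
the 20% censoring bound (`censored=True`). These are *single-risk* numbers —
accepting both at once would double-count the benefit. The joint surface:

```sh
smartmar smart --weights fx/heart_failure.csv \
  --benefit "physical functioning:NYHA IV:NYHA III" \
  --focal "30-day death" --grid-step 0.5 --out surface.csv --plot surface.png
```

exports one row per bleeding level with the maximum acceptable death risk at
that level, and renders the crest lines. The same library calls are
available in Python (`compute_mar`, `mar_table`, `joint_acceptability`,
`smart_boundary`, `interval_for`); see the module docstrings.

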