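"""Simultaneous maximum acceptable risk thresholds (SMART).

A treatment usually carries several adverse-event risks that must be accepted
as a bundle.  Conventional MARs invert one risk at a time, implicitly
spending the full benefit on each risk separately; accepting every single-risk
MAR at once would double- (or triple-) count the benefit.  With additively
separable risk preferences the joint condition is

    delta  =  sum_j [ u_j(baseline_j) - u_j(p_j) ]

i.e. the benefit's utility gain is allocated across the simultaneous risk
increases.  The SMART boundary fixes all but one (focal) risk on a grid,
subtracts their disutility from the benefit, and inverts the focal curve at
the residual — exactly the single-risk MAR computation with a reduced
benefit.  Holding every conditioning risk at its baseline therefore recovers
the conventional MAR.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mar import compute_mar
from .model import (
    BenefitDelta,
    ContractError,
    PreferenceModel,
    ValidationError,
    utility_at,
)

__all__ = [
    "RiskCombination",
    "AcceptanceDecision",
    "ThresholdSurface",
    "joint_acceptability",
    "smart_boundary",
    "linear_slope",
    "brute_force_acceptance_region",
]


@dataclass(frozen=True)
class RiskCombination:
    """Absolute probabilities (percent) for a subset of a model's risks."""

    entries: tuple[tuple[str, float], ...]

    @classmethod
    def of(cls, mapping: Mapping[str, float]) -> "RiskCombination":
        return cls(tuple(mapping.items()))

    def as_dict(self) -> dict[str, float]:
        return dict(self.entries)


@dataclass(frozen=True)
class AcceptanceDecision:
    """Joint accept/reject verdict for one risk combination.

    ``utility_margin`` is the benefit's utility gain minus the total expected
    disutility of the risk increases; the combination is acceptable when the
    margin is non-negative (indifference counts as acceptable, consistent
    with "maximum acceptable" semantics).
    """

    combination: RiskCombination
    benefit: BenefitDelta
    utility_margin: float

    @property
    def acceptable(self) -> bool:
        return self.utility_margin >= 0


def _baseline_for(model: PreferenceModel, baselines, name: str) -> float:
    if baselines and name in baselines:
        return float(baselines[name])
    return model.risk(name).domain_min


def joint_acceptability(
    model: PreferenceModel,
    benefit: BenefitDelta,
    combo: RiskCombination | Mapping[str, float],
    baselines: Mapping[str, float] | None = None,
) -> AcceptanceDecision:
    """Evaluate the joint acceptance condition at one risk combination.

    Risks absent from ``combo`` are held at their baselines and contribute no
    disutility.
    """
    if not isinstance(combo, RiskCombination):
        combo = RiskCombination.of(combo)
    total_disutility = 0.0
    for name, p in combo.entries:
        curve = model.risk(name)
        b = _baseline_for(model, baselines, name)
        total_disutility += utility_at(curve, b) - utility_at(curve, p)
    return AcceptanceDecision(combo, benefit, benefit.value - total_disutility)


@dataclass(frozen=True)
class ThresholdSurface:
    """The SMART boundary for one benefit level and one focal risk.

    ``boundary`` maps each conditioning-grid tuple (ordered as
    ``conditioning_risks``) to the focal risk's threshold probability with
    flags: ``censored`` when the inversion hit the censoring bound and
    ``unreachable`` when the conditioning risks alone already exhaust the
    benefit (no focal increase — not even zero — is acceptable there).
    """

    benefit: BenefitDelta
    focal_risk: str
    conditioning_risks: tuple[str, ...]
    boundary: dict[tuple[float, ...], tuple[float, bool, bool]]
    baselines: dict[str, float]

    def focal_at(self, point: Sequence[float]) -> tuple[float, bool, bool]:
        return self.boundary[tuple(float(x) for x in point)]

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: one row per conditioning tuple."""
        rows = []
        for point, (p, cens, unreach) in self.boundary.items():
            row = {"benefit": self.benefit.value, "focal_risk": self.focal_risk}
            for name, val in zip(self.conditioning_risks, point):
                row[name] = val
            row.update(boundary_p=p, censored=cens, unreachable=unreach)
            rows.append(row)
        return pd.DataFrame(rows)


def smart_boundary(
    model: PreferenceModel,
    benefit: BenefitDelta,
    focal_risk: str,
    conditioning_grid: Mapping[str, Sequence[float]],
    baselines: Mapping[str, float] | None = None,
) -> ThresholdSurface:
    """Trace the SMART boundary over a grid of conditioning-risk levels.

    For each tuple of conditioning probabilities, the residual benefit is the
    gain left after paying those risks' disutility; the focal curve is then
    inverted at the residual exactly as in a single-risk MAR.  A negative
    residual flags the point unreachable; a zero residual puts the boundary
    at the focal baseline (continuity).
    """
    if focal_risk in conditioning_grid:
        raise ValidationError("focal risk must not appear in the conditioning grid")
    names = tuple(conditioning_grid.keys())
    grids = [np.asarray(conditioning_grid[n], dtype=float) for n in names]
    if any(g.size == 0 for g in grids) or not names:
        raise ValidationError("conditioning grid must be non-empty")

    focal_curve = model.risk(focal_risk)
    base = {n: _baseline_for(model, baselines, n) for n in names}
    base[focal_risk] = _baseline_for(model, baselines, focal_risk)

    # Per-axis disutility relative to baseline, computed once per grid value.
    axis_dis = []
    for n, g in zip(names, grids):
        curve = model.risk(n)
        u0 = utility_at(curve, base[n])
        axis_dis.append(u0 - utility_at(curve, g))

    boundary: dict[tuple[float, ...], tuple[float, bool, bool]] = {}
    for combo in itertools.product(*(range(g.size) for g in grids)):
        point = tuple(float(grids[a][i]) for a, i in enumerate(combo))
        spent = float(sum(axis_dis[a][i] for a, i in enumerate(combo)))
        residual = benefit.value - spent
        if residual < 0:
            boundary[point] = (np.nan, False, True)
            continue
        res = compute_mar(focal_curve, BenefitDelta(residual), base[focal_risk])
        boundary[point] = (res.absolute_p, res.censored, False)
    return ThresholdSurface(benefit, focal_risk, names, boundary, base)


def linear_slope(mar_focal: float, mar_other: float) -> float:
    """Exchange-rate slope of a linear two-risk boundary: -MAR1/MAR2.

    Only meaningful for curves with constant marginal disutility, where the
    boundary is a straight line between the two single-risk MAR intercepts.
    Both MARs must be positive and uncensored.
    """
    if mar_focal <= 0 or mar_other <= 0:
        raise ContractError("linear_slope requires positive uncensored MARs")
    return -mar_focal / mar_other


def brute_force_acceptance_region(
    model: PreferenceModel,
    benefit: BenefitDelta,
    fine_grid_step: float,
    baselines: Mapping[str, float] | None = None,
    max_points: int = 10_000_000,
) -> tuple[tuple[str, ...], np.ndarray, np.ndarray]:
    """Exhaustive-enumeration oracle for the joint acceptance condition.

    Grids every risk from its baseline to its last knot at ``fine_grid_step``
    and evaluates the joint margin at every point.  Exponential in the number
    of risks; limited to 3 risks and ``max_points`` grid points.

    Returns ``(risk_names, grids, acceptable)`` where ``grids`` is the list of
    per-risk probability axes and ``acceptable`` a boolean array of shape
    ``(len(grids[0]), len(grids[1]), ...)``.
    """
    names = model.risk_names
    if len(names) > 3:
        raise ValidationError("brute-force oracle supports at most 3 risks")
    if fine_grid_step <= 0:
        raise ValidationError("grid step must be positive")

    axes = []
    axis_dis = []
    total = 1
    for n in names:
        curve = model.risk(n)
        b = _baseline_for(model, baselines, n)
        g = np.arange(b, curve.domain_max + 1e-9, fine_grid_step)
        total *= g.size
        if total > max_points:
            raise ValidationError(f"grid exceeds {max_points} points")
        axes.append(g)
        axis_dis.append(utility_at(curve, b) - utility_at(curve, g))

    # Joint margin via broadcast sum of per-axis disutilities (the additive
    # separability that also underlies joint_acceptability).
    spent = np.zeros([g.size for g in axes])
    for a, d in enumerate(axis_dis):
        shape = [1] * len(axes)
        shape[a] = d.size
        spent = spent + d.reshape(shape)
    margin = benefit.value - spent
    return tuple(names), axes, margin >= -1e-12
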