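"""Domain types for preference-weight tables and piecewise-linear risk-utility
curves.

A discrete-choice experiment (DCE) yields one preference weight per attribute
level on a common (rescaled) utility scale.  For a probabilistic adverse-event
attribute the effect-coded level weights form the knots of a piecewise-linear
weighted-probability function: utility as a function of the stated probability
of the event.  All threshold computations downstream (single-risk MAR, joint
SMART surfaces) reduce to interpolation and inversion of these curves, which
is what this module provides.

Probabilities are handled throughout in percentage points on [0, 100],
matching how DCE risk attributes are presented to respondents; callers working
in proportions must convert first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "DomainError",
    "ContractError",
    "UnreachableError",
    "Extrapolation",
    "BenefitAttribute",
    "RiskUtilityCurve",
    "PreferenceModel",
    "BenefitDelta",
    "build_risk_curve",
    "utility_at",
    "invert_disutility",
    "benefit_delta",
]


class ValidationError(ValueError):
    """Malformed inputs: too few points, duplicate levels, non-finite weights."""


class DomainError(ValueError):
    """A probability outside the curve's domain under the active policy."""


class ContractError(ValueError):
    """A call that violates an operation's precondition (e.g. inverting to a
    utility above the value at baseline: no risk increase is needed)."""


class UnreachableError(ValueError):
    """The curve never attains the requested utility under the active
    extrapolation policy."""


class Extrapolation:
    """Policy tags for evaluating a curve beyond its last grid point."""

    EXTEND_LAST_SEGMENT = "extend_last_segment"
    CLAMP = "clamp"
    FORBID = "forbid"

    ALL = (EXTEND_LAST_SEGMENT, CLAMP, FORBID)


@dataclass(frozen=True)
class BenefitAttribute:
    """A non-risk attribute with one preference weight per level.

    Levels are ordered as presented in the study; weights live on the study's
    rescaled utility scale and are directly comparable across attributes.
    """

    name: str
    levels: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValidationError(
                f"benefit attribute {self.name!r} needs at least 2 levels"
            )
        labels = [lab for lab, _ in self.levels]
        if len(set(labels)) != len(labels):
            raise ValidationError(
                f"benefit attribute {self.name!r} has duplicate level labels"
            )
        for lab, w in self.levels:
            if not math.isfinite(w):
                raise ValidationError(
                    f"non-finite weight for {self.name!r} level {lab!r}"
                )

    def weight(self, label: str) -> float:
        for lab, w in self.levels:
            if lab == label:
                return w
        raise KeyError(f"unknown level {label!r} for attribute {self.name!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.levels)


@dataclass(frozen=True)
class RiskUtilityCurve:
    """Piecewise-linear utility of an adverse-event probability.

    ``points`` are (probability in percent, utility) knots, strictly
    increasing in probability.  The curve stores the composite of the weighted
    probability function and the event's disutility as a single function,
    because effect-coded DCE output only identifies the product.

    The curve is defined from its first knot upward (studies often anchor at a
    non-zero "baseline" probability level, e.g. 1%).  ``extrapolation``
    controls behaviour beyond the last knot; ``censor_max`` truncates inverted
    thresholds at the largest defensible extrapolation bound.
    """

    name: str
    probs: np.ndarray
    utils: np.ndarray
    extrapolation: str = Extrapolation.EXTEND_LAST_SEGMENT
    censor_max: float | None = None
    _validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "probs", np.asarray(self.probs, dtype=float))
        object.__setattr__(self, "utils", np.asarray(self.utils, dtype=float))
        if not self._validate:
            return
        p, u = self.probs, self.utils
        if p.ndim != 1 or p.shape != u.shape:
            raise ValidationError("probabilities and utilities must be 1-d and equal length")
        if p.size < 2:
            raise ValidationError(f"curve {self.name!r} needs at least 2 points")
        if np.any(~np.isfinite(p)) or np.any(~np.isfinite(u)):
            raise ValidationError(f"curve {self.name!r} has non-finite entries")
        if np.any(p < 0) or np.any(p > 100):
            raise ValidationError(f"curve {self.name!r} probabilities must lie in [0, 100]")
        if np.any(np.diff(p) <= 0):
            raise ValidationError(
                f"curve {self.name!r} probabilities must be strictly increasing"
            )
        if self.extrapolation not in Extrapolation.ALL:
            raise ValidationError(f"unknown extrapolation policy {self.extrapolation!r}")
        if (
            self.extrapolation == Extrapolation.EXTEND_LAST_SEGMENT
            and p[-1] == p[-2]
        ):  # unreachable given strict monotonicity, kept as an explicit contract
            raise ValidationError("last two knots must have distinct probabilities")
        if self.censor_max is not None and not math.isfinite(self.censor_max):
            raise ValidationError("censor_max must be finite or None")

    @property
    def points(self) -> tuple[tuple[float, float], ...]:
        return tuple(zip(self.probs.tolist(), self.utils.tolist()))

    @property
    def domain_min(self) -> float:
        return float(self.probs[0])

    @property
    def domain_max(self) -> float:
        return float(self.probs[-1])

    def is_monotone_decreasing(self) -> bool:
        return bool(np.all(np.diff(self.utils) < 0))

    def monotonized(self) -> "RiskUtilityCurve":
        """Return a copy with utilities made non-increasing by isotonic
        regression (pool-adjacent-violators), for stress-testing curves with
        a locally positive level weight.  Off by default everywhere."""
        from sklearn.isotonic import IsotonicRegression

        iso = IsotonicRegression(increasing=False)
        u = iso.fit_transform(self.probs, self.utils)
        return replace(self, utils=np.asarray(u, dtype=float))

    # Convenience wrappers around the module-level operations.
    def __call__(self, p):
        return utility_at(self, p)

    def invert(self, target_utility: float, baseline_p: float):
        return invert_disutility(self, target_utility, baseline_p)


@dataclass(frozen=True)
class BenefitDelta:
    """A utility gain g(H1) - g(H0) between two treatment profiles.

    May be zero or negative; a non-positive gain means no additional risk is
    acceptable.
    """

    value: float
    description: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValidationError("benefit delta must be finite")


@dataclass(frozen=True)
class PreferenceModel:
    """A full study: benefit attributes, one utility curve per risk, and an
    optional coefficient covariance over the concatenated weight vector.

    Expected utility is additively separable: each adverse event contributes
    its curve value independently of the other risks (preferential
    independence), so joint thresholds are sums of per-risk disutilities.
    """

    benefits: tuple[BenefitAttribute, ...]
    risks: tuple[RiskUtilityCurve, ...]
    vcov: np.ndarray | None = None
    provenance: str = ""
    _validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "benefits", tuple(self.benefits))
        object.__setattr__(self, "risks", tuple(self.risks))
        if self.vcov is not None:
            object.__setattr__(self, "vcov", np.asarray(self.vcov, dtype=float))
        if not self._validate:
            return
        names = [c.name for c in self.risks] + [b.name for b in self.benefits]
        if len(set(names)) != len(names):
            raise ValidationError("attribute and risk names must be unique")
        if self.vcov is not None:
            k = self.n_weights
            if self.vcov.shape != (k, k):
                raise ValidationError(
                    f"vcov must be {k}x{k} to match the weight vector"
                )
            if not np.allclose(self.vcov, self.vcov.T, atol=1e-10):
                raise ValidationError("vcov must be symmetric")
            eigmin = float(np.linalg.eigvalsh(self.vcov).min())
            if eigmin < -1e-8:
                raise ValidationError("vcov must be positive semi-definite")

    # -- weight-vector view -------------------------------------------------
    @property
    def weight_index(self) -> tuple[str, ...]:
        """Ordered ``attribute:level`` keys of the concatenated weight vector
        (benefit levels first, then each risk curve's knots)."""
        keys: list[str] = []
        for b in self.benefits:
            keys.extend(f"{b.name}:{lab}" for lab in b.labels)
        for c in self.risks:
            keys.extend(f"{c.name}:{p:g}" for p in c.probs)
        return tuple(keys)

    @property
    def n_weights(self) -> int:
        return sum(len(b.levels) for b in self.benefits) + sum(
            c.probs.size for c in self.risks
        )

    @property
    def weights(self) -> np.ndarray:
        parts = [np.array([w for _, w in b.levels]) for b in self.benefits]
        parts += [c.utils for c in self.risks]
        return np.concatenate(parts) if parts else np.empty(0)

    def with_weights(self, vector: Sequence[float]) -> "PreferenceModel":
        """Rebuild the model with a new weight vector (same structure).

        Used in simulation loops, so it skips re-validation of structure that
        cannot change.
        """
        vec = np.asarray(vector, dtype=float)
        if vec.shape != (self.n_weights,):
            raise ValidationError(
                f"weight vector must have length {self.n_weights}"
            )
        i = 0
        benefits = []
        for b in self.benefits:
            k = len(b.levels)
            levels = tuple(
                (lab, float(vec[i + j])) for j, (lab, _) in enumerate(b.levels)
            )
            benefits.append(replace(b, levels=levels))
            i += k
        risks = []
        for c in self.risks:
            k = c.probs.size
            risks.append(replace(c, utils=vec[i : i + k], _validate=False))
            i += k
        return PreferenceModel(
            tuple(benefits), tuple(risks), vcov=self.vcov,
            provenance=self.provenance, _validate=False,
        )

    # -- lookups ------------------------------------------------------------
    def risk(self, name: str) -> RiskUtilityCurve:
        for c in self.risks:
            if c.name == name:
                return c
        raise KeyError(f"unknown risk {name!r}")

    def benefit(self, name: str) -> BenefitAttribute:
        for b in self.benefits:
            if b.name == name:
                return b
        raise KeyError(f"unknown benefit attribute {name!r}")

    @property
    def risk_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.risks)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def build_risk_curve(
    name: str,
    points: Iterable[tuple[float, float]],
    extrapolation: str = Extrapolation.EXTEND_LAST_SEGMENT,
    censor_max: float | None = None,
) -> RiskUtilityCurve:
    """Validate and sort (probability, utility) knots into a curve.

    Points are sorted ascending by probability; duplicate probabilities are
    rejected (they would make the function multivalued).
    """
    pts = sorted((float(p), float(u)) for p, u in points)
    if len(pts) < 2:
        raise ValidationError(f"curve {name!r} needs at least 2 points")
    probs = np.array([p for p, _ in pts])
    utils = np.array([u for _, u in pts])
    if np.any(np.diff(probs) == 0):
        raise ValidationError(f"curve {name!r} has duplicate probabilities")
    return RiskUtilityCurve(name, probs, utils, extrapolation, censor_max)


def utility_at(curve: RiskUtilityCurve, p):
    """Evaluate the curve at probability ``p`` (percent); scalar or array.

    Exact at knots, linear between adjacent knots.  Beyond the last knot the
    extrapolation policy applies: ``extend_last_segment`` continues the final
    segment's slope, ``clamp`` holds the last utility, ``forbid`` raises.
    Below the first knot only ``clamp`` is defined (the study never presented
    lower probabilities); other policies raise.
    """
    p_arr = np.asarray(p, dtype=float)
    scalar = p_arr.ndim == 0
    p_arr = np.atleast_1d(p_arr)
    if np.any(p_arr < 0):
        raise DomainError("probabilities must be non-negative")

    lo, hi = curve.probs[0], curve.probs[-1]
    below = p_arr < lo
    above = p_arr > hi
    if np.any(below) and curve.extrapolation != Extrapolation.CLAMP:
        raise DomainError(
            f"probability below curve {curve.name!r} domain start {lo:g}%"
        )
    if np.any(above) and curve.extrapolation == Extrapolation.FORBID:
        raise DomainError(
            f"probability above curve {curve.name!r} domain end {hi:g}%"
        )

    out = np.interp(p_arr, curve.probs, curve.utils)
    if np.any(above) and curve.extrapolation == Extrapolation.EXTEND_LAST_SEGMENT:
        slope = (curve.utils[-1] - curve.utils[-2]) / (curve.probs[-1] - curve.probs[-2])
        out = np.where(above, curve.utils[-1] + slope * (p_arr - hi), out)
    # np.interp already clamps on both sides, which is the CLAMP behaviour.
    return float(out[0]) if scalar else out


def invert_disutility(
    curve: RiskUtilityCurve, target_utility: float, baseline_p: float
) -> tuple[float, bool]:
    """First probability ``p >= baseline_p`` with utility equal to the target.

    Scans segments upward from the baseline and solves the crossing in closed
    form on the segment where it occurs (no iteration).  Returns
    ``(absolute_p, censored)``; if the crossing exceeds the curve's
    ``censor_max`` the bound is returned with ``censored=True``.

    ``target_utility`` must not exceed the utility at baseline (otherwise no
    risk increase is needed and the call is a contract violation).
    """
    u0 = utility_at(curve, baseline_p)
    tol = 1e-12
    if target_utility > u0 + 1e-9:
        raise ContractError(
            "target utility above the curve value at baseline: "
            "no risk increase needed"
        )
    cmax = curve.censor_max

    def _finish(p: float) -> tuple[float, bool]:
        if cmax is not None and p > cmax:
            return float(cmax), True
        return float(p), False

    if target_utility >= u0 - tol:
        return _finish(baseline_p)

    probs, utils = curve.probs, curve.utils
    # Walk knot segments starting at the baseline.
    start = float(baseline_p)
    u_start = u0
    idx = int(np.searchsorted(probs, start, side="right"))
    for k in range(idx, probs.size):
        p_b, u_b = float(probs[k]), float(utils[k])
        if (u_start - target_utility) * (u_b - target_utility) <= 0 and u_b != u_start:
            # crossing inside [start, p_b]
            frac = (target_utility - u_start) / (u_b - u_start)
            return _finish(start + frac * (p_b - start))
        if abs(u_b - target_utility) <= tol:
            return _finish(p_b)
        start, u_start = p_b, u_b

    # Beyond the last knot.
    if curve.extrapolation == Extrapolation.EXTEND_LAST_SEGMENT:
        slope = (utils[-1] - utils[-2]) / (probs[-1] - probs[-2])
        if slope < 0:
            p = probs[-1] + (target_utility - utils[-1]) / slope
            if p >= start - tol:
                return _finish(max(p, start))
    raise UnreachableError(
        f"curve {curve.name!r} never reaches utility {target_utility:g} "
        f"above {start:g}% under policy {curve.extrapolation!r}"
    )


def benefit_delta(
    model: PreferenceModel,
    transitions: Sequence[tuple[str, str, str]],
    description: str | None = None,
) -> BenefitDelta:
    """Utility gain of moving each named attribute from one level to another.

    The value is the sum over transitions of (weight at ``to_level`` minus
    weight at ``from_level``); a single transition is the usual g(H1) - g(H0),
    and a composite benefit across several attributes is their sum.
    """
    total = 0.0
    parts = []
    for attr, frm, to in transitions:
        a = model.benefit(attr)
        total += a.weight(to) - a.weight(frm)
        parts.append(f"{attr}: {frm}->{to}")
    return BenefitDelta(total, description or "; ".join(parts))
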