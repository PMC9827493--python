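"""Packaged example studies and seeded random preference-model generators.

Two example data sets ship with the package in the weight-table CSV schema
(so the same reader path users exercise is also the tested path):

* ``hypothetical_curves`` — a stylized two-adverse-event set on the grid
  {0, 3, 6, 10, 15}% in three flavours (constant / increasing / decreasing
  marginal disutility of risk), each with overall importance 7.5, used to
  illustrate how curvature shapes the joint threshold.
* ``heart_failure_model`` — rescaled mixed-logit preference weights from a
  published heart-failure device study: physical functioning (NYHA class
  equivalents) and hospitalizations as benefits, 30-day death and severe
  bleeding as risks on the grid {1, 2, 4, 7, 10}%, with last-segment
  extrapolation and thresholds censored at 20%.

``random_model`` generates seeded monotone-decreasing curves with
controllable curvature for property tests.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .io import read_weight_table
from .model import (
    BenefitAttribute,
    Extrapolation,
    PreferenceModel,
    RiskUtilityCurve,
    ValidationError,
)

__all__ = ["CURVE_SHAPES", "hypothetical_curves", "heart_failure_model", "random_model"]

CURVE_SHAPES = ("constant", "increasing", "decreasing")


def _data_path(name: str):
    return resources.files("smartmar.data").joinpath(name)


def hypothetical_curves(shape: str) -> tuple[RiskUtilityCurve, RiskUtilityCurve]:
    """The AE1/AE2 curve pair for one marginal-disutility shape."""
    if shape not in CURVE_SHAPES:
        raise ValidationError(f"unknown curve shape {shape!r}; one of {CURVE_SHAPES}")
    with resources.as_file(_data_path(f"hypothetical_{shape}.csv")) as p:
        model = read_weight_table(p)
    return model.risk("AE1"), model.risk("AE2")


def hypothetical_model(shape: str) -> PreferenceModel:
    """The two curves wrapped in a model (no benefit attributes; benefit
    deltas are supplied directly on the normalized 0-10 scale)."""
    a, b = hypothetical_curves(shape)
    return PreferenceModel((), (a, b), provenance=f"hypothetical/{shape}")


def heart_failure_model(censor_max: float | None = 20.0) -> PreferenceModel:
    """The heart-failure device study weights, censored at 20% by default."""
    with resources.as_file(_data_path("heart_failure.csv")) as p:
        return read_weight_table(
            p, extrapolation=Extrapolation.EXTEND_LAST_SEGMENT, censor_max=censor_max
        )


def random_model(
    seed: int,
    n_risks: int = 2,
    grid: tuple[float, ...] = (0.0, 3.0, 6.0, 10.0, 15.0),
    curvature: float = 0.0,
    importance_range: tuple[float, float] = (4.0, 10.0),
    censor_max: float | None = None,
    non_monotone: bool = False,
) -> PreferenceModel:
    """Seeded random preference model with monotone-decreasing risk curves.

    Each curve falls from 0 at the first knot to minus a random overall
    importance at the last.  ``curvature`` shapes the marginal disutility:
    0 gives exactly constant segment slopes, positive gives increasing
    magnitude (convex-down), negative decreasing.  A two-level benefit
    attribute and a diagonal coefficient covariance are included so
    uncertainty propagation is exercisable.  ``non_monotone`` injects a
    small positive bump at the second knot (bleeding-style stress case).
    """
    g = np.asarray(grid, dtype=float)
    if g.size < 2 or np.any(np.diff(g) <= 0):
        raise ValidationError("grid must be strictly increasing with >= 2 points")
    if n_risks < 1:
        raise ValidationError("n_risks must be >= 1")
    rng = np.random.default_rng(seed)

    t = (g - g[0]) / (g[-1] - g[0])
    exponent = float(np.exp(1.2 * curvature))  # 1 at curvature 0
    shape_f = t**exponent

    risks = []
    importances = []
    for j in range(n_risks):
        imp = float(rng.uniform(*importance_range))
        importances.append(imp)
        utils = -imp * shape_f
        if non_monotone and utils.size >= 3:
            utils = utils.copy()
            utils[1] = abs(0.05 * imp)
        risks.append(
            RiskUtilityCurve(
                f"risk_{j}", g.copy(), utils,
                Extrapolation.EXTEND_LAST_SEGMENT, censor_max,
            )
        )

    gain = float(rng.uniform(0.3, 0.9) * min(importances))
    benefit = BenefitAttribute("outcome", (("worse", 0.0), ("better", gain)))

    model = PreferenceModel((benefit,), tuple(risks), provenance=f"random/seed={seed}")
    sd = 0.05 * np.abs(model.weights) + 0.02
    vcov = np.diag(sd**2)
    return PreferenceModel(
        model.benefits, model.risks, vcov=vcov, provenance=model.provenance
    )
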