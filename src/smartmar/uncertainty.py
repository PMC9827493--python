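"""Simulation-based uncertainty for derived threshold quantities.

Preference weights from a choice model come with a sampling distribution
(asymptotically multivariate normal with the estimated coefficient
covariance).  Thresholds are nonlinear functions of the weights, so intervals
are built by simulation in the Krinsky-Robb style: draw coefficient vectors
from N(mean weights, vcov), recompute the statistic per draw, and report
empirical percentiles.  Censored draws are retained at the censoring bound —
not discarded — so percentiles stay well defined and reproduce reporting like
"[0, >20]".

The point estimate is the statistic at the mean weights, which is how the
point thresholds themselves are computed; per-draw values are exposed so
users can summarize differently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .mar import MarResult
from .model import PreferenceModel, ValidationError

__all__ = ["CoefficientDraws", "IntervalResult", "draw_coefficients", "interval_for"]


class ConfigurationError(ValueError):
    """Missing prerequisites (e.g. a model without a coefficient covariance)."""


@dataclass(frozen=True)
class CoefficientDraws:
    """Simulated coefficient vectors, one row per draw, columns ordered as
    the model's ``weight_index``."""

    draws: np.ndarray
    seed: int
    weight_index: tuple[str, ...]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws, columns=list(self.weight_index))


@dataclass(frozen=True)
class IntervalResult:
    """Percentile interval around a point estimate.

    ``lower_censored`` / ``upper_censored`` mark interval ends that sit at
    the censoring bound (the true end lies beyond it).
    """

    point: float
    lower: float
    upper: float
    level: float
    lower_censored: bool = False
    upper_censored: bool = False
    point_censored: bool = False


def draw_coefficients(
    model: PreferenceModel, n_draws: int, seed: int
) -> CoefficientDraws:
    """Draw coefficient vectors from N(model.weights, model.vcov).

    Reproducible for a fixed seed.  Uses an eigendecomposition-based sampler
    so singular (including zero) covariances are valid.
    """
    if model.vcov is None:
        raise ConfigurationError("model has no coefficient covariance (vcov)")
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(
        model.weights, model.vcov, size=n_draws, method="eigh"
    )
    return CoefficientDraws(draws, seed, model.weight_index)


def _evaluate(statistic, model: PreferenceModel) -> tuple[float, bool]:
    out = statistic(model)
    if isinstance(out, MarResult):
        return out.incremental_mar, out.censored
    if isinstance(out, tuple):
        val, cens = out
        return float(val), bool(cens)
    return float(out), False


def interval_for(
    statistic: Callable[[PreferenceModel], "MarResult | float | tuple[float, bool]"],
    model: PreferenceModel,
    draws: CoefficientDraws,
    level: float = 0.95,
    return_draws: bool = False,
):
    """Percentile interval for a per-draw recomputed statistic.

    ``statistic`` receives the model rebuilt with each drawn weight vector
    and returns a ``MarResult``, a bare value, or a ``(value, censored)``
    pair.  The interval is the empirical ((1-level)/2, 1-(1-level)/2)
    percentile pair of the per-draw values (censored draws entered at the
    bound); the point estimate is the statistic at the mean weights.
    """
    if not 0 < level < 1:
        raise ValidationError("level must be in (0, 1)")
    tail = (1 - level) / 2
    if draws.n_draws < 1 / tail:
        raise ValidationError(
            f"{draws.n_draws} draws cannot resolve the {tail:.3%} percentile"
        )

    values = np.empty(draws.n_draws)
    censored = np.zeros(draws.n_draws, dtype=bool)
    for i in range(draws.n_draws):
        values[i], censored[i] = _evaluate(statistic, model.with_weights(draws.draws[i]))

    point, point_cens = _evaluate(statistic, model)
    lower, upper = np.quantile(values, [tail, 1 - tail])

    lower_cens = upper_cens = False
    if censored.any():
        bound = values[censored].min()  # censored draws all sit at the bound
        lower_cens = lower >= bound - 1e-12
        upper_cens = upper >= bound - 1e-12
    result = IntervalResult(
        point=point, lower=float(lower), upper=float(upper), level=level,
        lower_censored=lower_cens, upper_censored=upper_cens,
        point_censored=point_cens,
    )
    if return_draws:
        return result, pd.DataFrame(
            {"draw_id": np.arange(draws.n_draws), "value": values, "censored": censored}
        )
    return result
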