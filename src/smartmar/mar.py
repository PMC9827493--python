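"""Conventional single-risk maximum acceptable risk (MAR).

The MAR of an adverse event, for a given benefit, is the probability increase
whose expected disutility exactly offsets the benefit's utility gain, all
other attributes held fixed:

    u(p*) = u(p0) - delta

where u is the risk's piecewise-linear utility curve, p0 the baseline
probability and delta the benefit's utility gain.  For a linear curve with
slope -beta per percentage point and zero baseline this collapses to the
familiar ratio MAR = delta / beta.

MARs are reported as increments over the baseline, mirroring how studies with
a non-zero lowest risk level present them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .model import (
    BenefitDelta,
    ContractError,
    PreferenceModel,
    RiskUtilityCurve,
    ValidationError,
    benefit_delta,
    invert_disutility,
    utility_at,
)

__all__ = ["MarResult", "compute_mar", "mar_table", "mar_table_frame"]


@dataclass(frozen=True)
class MarResult:
    """A single-risk MAR.

    ``absolute_p`` is the threshold probability itself; ``incremental_mar``
    the increase over the baseline (what studies typically report).
    ``censored`` marks thresholds truncated at the curve's censoring bound;
    ``no_risk_acceptable`` marks non-positive benefits, for which the MAR is
    zero by definition.
    """

    risk_name: str
    benefit: BenefitDelta
    baseline_p: float
    absolute_p: float
    censored: bool = False
    no_risk_acceptable: bool = False

    @property
    def incremental_mar(self) -> float:
        return self.absolute_p - self.baseline_p


def compute_mar(
    curve: RiskUtilityCurve, benefit: BenefitDelta, baseline_p: float
) -> MarResult:
    """Invert the risk curve at the benefit's utility gain.

    Solves u(p) = u(baseline) - benefit.value for the smallest p at or above
    the baseline.  A non-positive benefit yields an incremental MAR of zero
    with ``no_risk_acceptable`` set: no extra risk offsets a non-gain.
    """
    if benefit.value <= 0:
        return MarResult(
            curve.name, benefit, baseline_p, absolute_p=baseline_p,
            no_risk_acceptable=benefit.value < 0,
        )
    u0 = utility_at(curve, baseline_p)
    target = u0 - benefit.value
    absolute_p, censored = invert_disutility(curve, target, baseline_p)
    return MarResult(curve.name, benefit, baseline_p, absolute_p, censored)


def mar_table(
    model: PreferenceModel,
    transitions: Sequence[tuple[str, str, str]],
    risks: Sequence[str],
    baselines: dict[str, float] | None = None,
) -> list[MarResult]:
    """One MAR per (benefit transition, risk) pair, in the given order.

    ``baselines`` maps risk name to its baseline probability; a risk not
    listed defaults to its curve's first knot (the study's lowest presented
    level).
    """
    if not transitions or not risks:
        raise ValidationError("transitions and risks must be non-empty")
    baselines = baselines or {}
    out: list[MarResult] = []
    for tr in transitions:
        delta = benefit_delta(model, [tr])
        for rname in risks:
            curve = model.risk(rname)
            b = baselines.get(rname, curve.domain_min)
            out.append(compute_mar(curve, delta, b))
    return out


def mar_table_frame(results: Sequence[MarResult]) -> pd.DataFrame:
    """Serialize MAR results to a tidy table (full precision; round at
    presentation time)."""
    rows = []
    for r in results:
        desc = r.benefit.description
        frm, to = "", ""
        if "->" in desc:
            head, _, tail = desc.partition("->")
            frm, to = head.split(":")[-1].strip(), tail.strip()
        rows.append(
            {
                "from_level": frm,
                "to_level": to,
                "risk": r.risk_name,
                "benefit_value": r.benefit.value,
                "baseline": r.baseline_p,
                "absolute": r.absolute_p,
                "incremental": r.incremental_mar,
                "censored": r.censored,
                "no_risk_acceptable": r.no_risk_acceptable,
            }
        )
    return pd.DataFrame(rows)
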