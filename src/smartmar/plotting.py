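"""Crest-line plots of SMART boundaries.

The standard visualization for two simultaneous risks: one line per benefit
level, both axes absolute risk percentages starting at the baseline level, so
each line's axis intercepts equal the corresponding single-risk MARs.
Plotting consumes the long-format surface export (`ThresholdSurface.to_frame`
or its CSV) and never recomputes values.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_crest_lines"]


def plot_crest_lines(
    surface: pd.DataFrame,
    conditioning_risk: str | None = None,
    ax: "plt.Axes | None" = None,
    labels: Sequence[str] | None = None,
):
    """Plot boundary lines from a long-format surface table.

    ``surface`` must contain columns ``benefit``, ``focal_risk``,
    ``boundary_p``, ``unreachable`` and one column per conditioning risk;
    with a single conditioning risk the x axis is inferred.
    """
    focal = surface["focal_risk"].iloc[0]
    if conditioning_risk is None:
        extra = [
            c
            for c in surface.columns
            if c not in ("benefit", "focal_risk", "boundary_p", "censored", "unreachable")
        ]
        if len(extra) != 1:
            raise ValueError(
                f"cannot infer the conditioning axis from columns {extra}; "
                "pass conditioning_risk"
            )
        conditioning_risk = extra[0]

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    benefits = sorted(surface["benefit"].unique())
    for i, b in enumerate(benefits):
        sub = surface[(surface["benefit"] == b) & (~surface["unreachable"])]
        sub = sub.sort_values(conditioning_risk)
        label = labels[i] if labels else f"benefit = {b:g}"
        ax.plot(sub[conditioning_risk], sub["boundary_p"], label=label)
    ax.set_xlabel(f"{conditioning_risk} (absolute %, held at grid value)")
    ax.set_ylabel(f"{focal} (maximum acceptable absolute %)")
    ax.legend(fontsize=8)
    ax.set_title("Simultaneous maximum acceptable risk threshold")
    return ax
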