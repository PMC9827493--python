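"""Readers and writers for the weight-table schema.

One row per attribute level:

    attribute,kind,level_label,level_value,weight,ci_lower,ci_upper

``kind`` is ``benefit`` or ``risk``.  For risk rows ``level_value`` is the
probability in percent (the curve knot); for benefit rows it is optional.
The confidence-bound columns are carried for documentation but the in-memory
model keeps only the weights (and, separately, a full covariance when one is
supplied).  A JSON mirror of the same rows is supported by file extension.

A companion covariance file is a square CSV whose header and first column are
``attribute:level`` keys matching the model's weight index.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    BenefitAttribute,
    Extrapolation,
    PreferenceModel,
    RiskUtilityCurve,
    ValidationError,
    build_risk_curve,
)

__all__ = [
    "SchemaError",
    "read_weight_table",
    "write_weight_table",
    "read_vcov",
    "write_vcov",
]

COLUMNS = ["attribute", "kind", "level_label", "level_value", "weight", "ci_lower", "ci_upper"]


class SchemaError(ValueError):
    """The file does not conform to the weight-table schema."""


def _rows_to_model(
    df: pd.DataFrame,
    extrapolation: str,
    censor_max: float | None,
    provenance: str,
) -> PreferenceModel:
    missing = [c for c in ("attribute", "kind", "level_label", "weight") if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    if df.empty:
        raise SchemaError("weight table has no rows")

    benefits: list[BenefitAttribute] = []
    risks: list[RiskUtilityCurve] = []
    for attr in df["attribute"].drop_duplicates():
        sub = df[df["attribute"] == attr]
        kinds = set(sub["kind"])
        if len(kinds) != 1:
            raise SchemaError(f"attribute {attr!r} mixes kinds {sorted(kinds)}")
        kind = kinds.pop()
        if kind == "benefit":
            levels = []
            for i, row in sub.iterrows():
                w = _num(row["weight"], i, "weight")
                levels.append((str(row["level_label"]), w))
            benefits.append(BenefitAttribute(str(attr), tuple(levels)))
        elif kind == "risk":
            pts = []
            for i, row in sub.iterrows():
                p = _num(row.get("level_value"), i, "level_value")
                w = _num(row["weight"], i, "weight")
                pts.append((p, w))
            risks.append(build_risk_curve(str(attr), pts, extrapolation, censor_max))
        else:
            raise SchemaError(f"unknown kind {kind!r} for attribute {attr!r}")
    return PreferenceModel(tuple(benefits), tuple(risks), provenance=provenance)


def _num(value, row, col) -> float:
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise SchemaError(f"row {row}: non-numeric {col}: {value!r}") from None
    if np.isnan(out):
        raise SchemaError(f"row {row}: missing {col}")
    return out


def read_weight_table(
    path: str | Path,
    extrapolation: str = Extrapolation.EXTEND_LAST_SEGMENT,
    censor_max: float | None = None,
) -> PreferenceModel:
    """Load a preference model from a weight-table CSV or JSON file."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        df = pd.DataFrame(payload.get("rows", []))
        provenance = payload.get("provenance", str(path))
    else:
        try:
            df = pd.read_csv(path, float_precision="round_trip")
        except pd.errors.EmptyDataError:
            raise SchemaError(f"{path}: empty file") from None
        provenance = str(path)
    return _rows_to_model(df, extrapolation, censor_max, provenance)


def model_to_rows(model: PreferenceModel) -> pd.DataFrame:
    rows = []
    for b in model.benefits:
        for lab, w in b.levels:
            rows.append(
                dict(attribute=b.name, kind="benefit", level_label=lab,
                     level_value="", weight=w, ci_lower="", ci_upper="")
            )
    for c in model.risks:
        for p, u in zip(c.probs, c.utils):
            rows.append(
                dict(attribute=c.name, kind="risk", level_label=f"{p:g}%",
                     level_value=float(p), weight=float(u), ci_lower="", ci_upper="")
            )
    return pd.DataFrame(rows, columns=COLUMNS)


def write_weight_table(model: PreferenceModel, path: str | Path) -> None:
    """Write a model back out in the weight-table schema (CSV or JSON by
    extension); canonical ordering makes repeated writes byte-stable."""
    path = Path(path)
    df = model_to_rows(model)
    if path.suffix.lower() == ".json":
        payload = {
            "provenance": model.provenance,
            "rows": df.to_dict(orient="records"),
        }
        path.write_text(json.dumps(payload, indent=1) + "\n")
    else:
        # %.17g guarantees float round-trip, which makes repeated writes
        # byte-stable
        df.to_csv(path, index=False, float_format="%.17g")


def read_vcov(path: str | Path, model: PreferenceModel) -> np.ndarray:
    """Read a companion covariance CSV and order it to the model's weight
    index."""
    df = pd.read_csv(path, index_col=0)
    keys = list(model.weight_index)
    missing = [k for k in keys if k not in df.index or k not in df.columns]
    if missing:
        raise SchemaError(f"covariance file missing keys: {missing[:5]}")
    return df.loc[keys, keys].to_numpy(dtype=float)


def write_vcov(model: PreferenceModel, path: str | Path) -> None:
    if model.vcov is None:
        raise ValidationError("model has no vcov to write")
    keys = list(model.weight_index)
    pd.DataFrame(model.vcov, index=keys, columns=keys).to_csv(path)
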