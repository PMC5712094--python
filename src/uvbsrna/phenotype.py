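"""Closed-form phenotype metrics: total chlorophyll and ddCt expression."""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

CHL_A645_COEF = 20.29
CHL_A663_COEF = 8.05


@dataclass(frozen=True)
class AbsorbancePair:
    a645: float
    a663: float
    sample: str = ""
    stage: str = ""

    def __post_init__(self):
        for name, v in (("a645", self.a645), ("a663", self.a663)):
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a finite non-negative absorbance")


def chlorophyll_total(pair: AbsorbancePair) -> float:
    """Total chlorophyll (mg/g FW) = 20.29 * A645 + 8.05 * A663."""
    return CHL_A645_COEF * pair.a645 + CHL_A663_COEF * pair.a663


def chlorophyll_table(df: pd.DataFrame) -> pd.DataFrame:
    """Add a chlorophyll_total column to a table with a645/a663 columns."""
    out = df.copy()
    out["chlorophyll_total"] = [
        chlorophyll_total(AbsorbancePair(row.a645, row.a663))
        for row in df.itertuples()
    ]
    return out


def relative_expression(ct: pd.DataFrame, calibrator: str) -> pd.DataFrame:
    """2^-ddCt relative expression per sample.

    ``ct`` columns: sample, ct_target, ct_reference; one row per technical
    replicate.  Replicates are averaged on the Ct scale before the power
    transform; amplification efficiency is fixed at 2.
    """
    required = {"sample", "ct_target", "ct_reference"}
    if not required <= set(ct.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    if ct[["ct_target", "ct_reference"]].isna().any().any():
        bad = ct[ct[["ct_target", "ct_reference"]].isna().any(axis=1)]["sample"]
        raise ValueError(f"missing Ct values for samples: {sorted(set(bad))}")
    vals = ct[["ct_target", "ct_reference"]]
    if ((vals <= 0) | (vals >= 45)).any().any():
        raise ValueError("Ct values must lie in (0, 45)")
    means = ct.groupby("sample")[["ct_target", "ct_reference"]].mean()
    if calibrator not in means.index:
        raise ValueError(f"calibrator sample {calibrator!r} not in table")
    dct = means["ct_target"] - means["ct_reference"]
    ddct = dct - dct.loc[calibrator]
    out = means.copy()
    out["delta_ct"] = dct
    out["delta_delta_ct"] = ddct
    out["fold"] = 2.0 ** (-ddct)
    return out.reset_index()
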