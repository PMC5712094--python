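"""Formulaic differential expression on pooled count libraries.

Normalized expression = count / clean total * 1e6 (reads per million);
fold change = log2(treatment RPM / control RPM); the unlogged ratio drives
regulation calls (> 2 up, < 1/2 down, strict inequalities).  Significance:
|FC| > 1 with p < 0.01 is highly significant, |FC| > 1 with 0.01 <= p <= 0.05
is significant, anything else is not.  Replicates are summed per condition
before normalization; the p-value comes from a two-sided exact binomial test
of the treatment count against the proportion expected from the library
totals (an explicit stand-in — the source procedure names no test).
Zero counts on one side are handled by adding one read to the zero side
before normalization, and the result is flagged as pseudocounted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from scipy import stats

REG_UP = "up"
REG_DOWN = "down"
REG_UNCHANGED = "unchanged"

SIG_HIGH = "highly_significant"
SIG_SIG = "significant"
SIG_NOT = "not_significant"


@dataclass
class DEThresholds:
    fc_cut: float = 1.0
    p_high: float = 0.01
    p_sig: float = 0.05
    ratio_up: float = 2.0
    ratio_down: float = 0.5


@dataclass(frozen=True)
class DEResult:
    mirna_id: str
    rpm_control: float
    rpm_treatment: float
    fold_change: float
    p_value: float
    ratio: float
    significance: str
    regulation: str
    pseudocounted: bool = False


def normalize(count: int, total_clean: int) -> float:
    """Reads-per-million: count / total * 1e6."""
    if total_clean <= 0:
        raise ValueError("total_clean must be positive")
    if not 0 <= count <= total_clean:
        raise ValueError(f"count {count} outside [0, {total_clean}]")
    return count / total_clean * 1e6


def fold_change(rpm_treatment: float, rpm_control: float) -> float:
    """log2(treatment / control); both inputs must be positive."""
    if rpm_treatment <= 0 or rpm_control <= 0:
        raise ValueError("fold_change requires positive normalized values; "
                         "apply the pseudocount policy upstream")
    return math.log2(rpm_treatment / rpm_control)


def de_test(count_t: int, total_t: int, count_c: int, total_c: int) -> float:
    """Two-sided exact binomial test of count_t | (count_t + count_c).

    Under equal expression the treatment share of the pooled count is
    total_t / (total_t + total_c).  Returns 1.0 when there is no evidence
    (zero pooled count).
    """
    if total_t <= 0 or total_c <= 0:
        raise ValueError("library totals must be positive")
    n = count_t + count_c
    if n == 0:
        return 1.0
    p0 = total_t / (total_t + total_c)
    return float(stats.binomtest(count_t, n, p0, alternative="two-sided").pvalue)


def classify(fc: float, p_value: float, ratio: float,
             thresholds: DEThresholds | None = None) -> tuple[str, str]:
    """Map (fold change, p, ratio) to (significance class, regulation)."""
    th = thresholds or DEThresholds()
    if abs(fc) > th.fc_cut and p_value < th.p_high:
        sig = SIG_HIGH
    elif abs(fc) > th.fc_cut and th.p_high <= p_value <= th.p_sig:
        sig = SIG_SIG
    else:
        sig = SIG_NOT
    if ratio > th.ratio_up:
        reg = REG_UP
    elif ratio < th.ratio_down:
        reg = REG_DOWN
    else:
        reg = REG_UNCHANGED
    return sig, reg


def run_de(
    counts: pd.DataFrame,
    totals: Mapping[str, int],
    design: Mapping[str, str],
    control: str = "CK",
    treatment: str = "T",
    thresholds: DEThresholds | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Pooled differential expression over a count matrix.

    ``counts``: rows miRNA ids, columns libraries.  ``design`` maps each
    library to its condition label.  Returns (result table sorted by |FC|
    descending, excluded ids with reasons).
    """
    th = thresholds or DEThresholds()
    ck_libs = sorted(l for l in counts.columns if design[l] == control)
    t_libs = sorted(l for l in counts.columns if design[l] == treatment)
    if not ck_libs or not t_libs:
        raise ValueError("both conditions need at least one library")
    total_c = sum(totals[l] for l in ck_libs)
    total_t = sum(totals[l] for l in t_libs)
    if total_c <= 0 or total_t <= 0:
        raise ValueError("condition with zero clean total")

    results: list[DEResult] = []
    excluded: list[str] = []
    for mid in counts.index:
        c = int(counts.loc[mid, ck_libs].sum())
        t = int(counts.loc[mid, t_libs].sum())
        if c == 0 and t == 0:
            excluded.append(f"{mid}: zero counts in both conditions")
            continue
        pseudo = c == 0 or t == 0
        c_adj = max(c, 1)
        t_adj = max(t, 1)
        rpm_c = normalize(c_adj, total_c)
        rpm_t = normalize(t_adj, total_t)
        fc = fold_change(rpm_t, rpm_c)
        ratio = rpm_t / rpm_c
        p = de_test(t, total_t, c, total_c)
        sig, reg = classify(fc, p, ratio, th)
        results.append(
            DEResult(str(mid), rpm_c, rpm_t, fc, p, ratio, sig, reg, pseudo)
        )

    results.sort(key=lambda r: (-abs(r.fold_change), r.mirna_id))
    per_lib = {
        f"rpm_{lib}": [
            normalize(int(counts.loc[r.mirna_id, lib]), totals[lib])
            for r in results
        ]
        for lib in ck_libs + t_libs
    }
    table = pd.DataFrame(
        {
            "mirna_id": [r.mirna_id for r in results],
            **per_lib,
            "rpm_control": [r.rpm_control for r in results],
            "rpm_treatment": [r.rpm_treatment for r in results],
            "fold_change": [r.fold_change for r in results],
            "p_value": [r.p_value for r in results],
            "ratio": [r.ratio for r in results],
            "significance": [r.significance for r in results],
            "regulation": [r.regulation for r in results],
            "pseudocounted": [r.pseudocounted for r in results],
        }
    )
    return table, excluded
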