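"""Plant miRNA target prediction on ungapped miRNA:site duplexes.

A candidate site is scored position by position against the miRNA (antiparallel,
positions numbered 1..L from the miRNA 5' end).  Watson-Crick pairs score 0,
G:U wobbles score 0.5, mismatches score 1.  Six acceptance rules are applied:

  a. no run of more than two adjacent mismatches anywhere in the duplex
  b. total score <= 4
  c. score over positions 1-12 <= 2.5
  d. no mismatch at positions 10 or 11
  e. no two adjacent mismatches within positions 2-12
  f. duplex MFE >= 75% of the MFE of the miRNA bound to its perfect complement

G:U wobbles contribute to the summed scores of rules b and c but do not count
as mismatches for the positional rules a, d and e.  MFEs use the stacked-pair
model shared with :mod:`uvbsrna.fold`; a zero perfect-complement MFE fails
rule f closed.  Gapped/bulged duplexes are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from ._seq import is_gu, is_wc, normalize, pair_weight, validate_alphabet

WC = "WC"
GU = "GU"
MISMATCH = "MM"

MFE_RATIO_MIN = 0.75


@dataclass(frozen=True)
class DuplexAlignment:
    """Ungapped miRNA:target duplex with per-position pairing states.

    ``states``/``scores`` are indexed 0-based but all rule arithmetic uses the
    1-based miRNA 5'->3' position convention.  miRNA position ``i`` (1-based)
    faces the site base at 0-based site index ``L - i`` (site given 5'->3' on
    the transcript, paired antiparallel).
    """

    mirna: str
    site: str
    states: tuple[str, ...]
    scores: tuple[float, ...]
    mfe_duplex: int
    mfe_perfect: int

    @property
    def total_score(self) -> float:
        return sum(self.scores)

    @property
    def mfe_ratio(self) -> float:
        if self.mfe_perfect == 0:
            return 0.0
        return self.mfe_duplex / self.mfe_perfect


@dataclass(frozen=True)
class RuleVerdict:
    a: bool
    b: bool
    c: bool
    d: bool
    e: bool
    f: bool
    mfe_ratio: float

    @property
    def overall(self) -> bool:
        return self.a and self.b and self.c and self.d and self.e and self.f

    def failing(self) -> tuple[str, ...]:
        return tuple(r for r in "abcdef" if not getattr(self, r))


@dataclass(frozen=True)
class TargetHit:
    mirna_id: str
    transcript_id: str
    position: int  # 0-based start of the site on the transcript
    duplex: DuplexAlignment
    verdict: RuleVerdict


def score_duplex(mirna: str, site: str) -> DuplexAlignment:
    """Score an ungapped duplex between ``mirna`` and a transcript ``site``.

    Both are 5'->3'; pairing is antiparallel.  Lengths must be equal and in
    18-26 nt (the rules are positionally defined on a fixed index).
    """
    mi = normalize(mirna)
    st = normalize(site)
    if len(mi) != len(st):
        raise ValueError(
            f"gapped duplexes are not supported: miRNA length {len(mi)} "
            f"!= site length {len(st)}"
        )
    if not 18 <= len(mi) <= 26:
        raise ValueError(f"duplex length {len(mi)} outside 18-26 nt")
    validate_alphabet(mi, context="miRNA")
    validate_alphabet(st, context="target site")

    L = len(mi)
    states = []
    scores = []
    partners = []
    for i in range(1, L + 1):
        a = mi[i - 1]
        b = st[L - i]
        partners.append(b)
        if is_wc(a, b):
            states.append(WC)
            scores.append(0.0)
        elif is_gu(a, b):
            states.append(GU)
            scores.append(0.5)
        else:
            states.append(MISMATCH)
            scores.append(1.0)

    # stacked-pair MFEs under the shared model: adjacent paired positions
    # stack with the weight of the lower-indexed pair
    mfe_duplex = 0
    for i in range(L - 1):
        if states[i] != MISMATCH and states[i + 1] != MISMATCH:
            mfe_duplex += pair_weight(mi[i], partners[i])
    mfe_perfect = sum(
        -2 if mi[i] in "GC" else -1 for i in range(L - 1)
    )
    return DuplexAlignment(mi, st, tuple(states), tuple(scores), mfe_duplex, mfe_perfect)


def apply_rules(duplex: DuplexAlignment) -> RuleVerdict:
    """Evaluate the six target rules on a scored duplex."""
    states = duplex.states
    scores = duplex.scores
    L = len(states)

    # a: longest run of adjacent mismatch positions <= 2
    run = longest = 0
    for s in states:
        run = run + 1 if s == MISMATCH else 0
        longest = max(longest, run)
    rule_a = longest <= 2

    rule_b = duplex.total_score <= 4.0
    rule_c = sum(scores[: min(12, L)]) <= 2.5

    rule_d = states[9] != MISMATCH and states[10] != MISMATCH

    rule_e = True
    for pos in range(2, min(12, L)):  # 1-based pairs (pos, pos+1) within 2..12
        if states[pos - 1] == MISMATCH and states[pos] == MISMATCH:
            rule_e = False
            break

    ratio = duplex.mfe_ratio
    rule_f = duplex.mfe_perfect < 0 and ratio >= MFE_RATIO_MIN

    return RuleVerdict(rule_a, rule_b, rule_c, rule_d, rule_e, rule_f, ratio)


def evaluate_site(mirna: str, site: str) -> RuleVerdict:
    """Convenience wrapper: score then judge a single site."""
    return apply_rules(score_duplex(mirna, site))


def scan_transcriptome(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    *,
    keep_rejected: bool = False,
) -> list[TargetHit]:
    """Slide each miRNA over every transcript and collect rule-passing sites.

    Returns hits sorted by (miRNA id, transcript id, position).  With
    ``keep_rejected`` every scored window is returned, passing or not.
    """
    import warnings as _warnings

    if not transcripts:
        _warnings.warn("empty transcript set: no target scan performed")
        return []
    hits: list[TargetHit] = []
    for mid in sorted(mirnas):
        mseq = normalize(mirnas[mid])
        L = len(mseq)
        for tid in sorted(transcripts):
            tseq = normalize(transcripts[tid])
            for pos in range(0, len(tseq) - L + 1):
                duplex = score_duplex(mseq, tseq[pos : pos + L])
                verdict = apply_rules(duplex)
                if verdict.overall or keep_rejected:
                    hits.append(TargetHit(mid, tid, pos, duplex, verdict))
    return hits


def hits_table(hits: Iterable[TargetHit]):
    """Target hits as a pandas DataFrame (the TSV surface of the module)."""
    import pandas as pd

    rows = []
    for h in hits:
        rows.append(
            {
                "mirna_id": h.mirna_id,
                "transcript_id": h.transcript_id,
                "position": h.position,
                "total_score": h.duplex.total_score,
                "mfe_ratio": round(h.verdict.mfe_ratio, 6),
                **{f"rule_{r}": getattr(h.verdict, r) for r in "abcdef"},
                "pass": h.verdict.overall,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna_id",
            "transcript_id",
            "position",
            "total_score",
            "mfe_ratio",
            *(f"rule_{r}" for r in "abcdef"),
            "pass",
        ],
    )
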