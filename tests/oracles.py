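"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive everything from first principles (explicit
enumeration, all-pairs scans, direct re-reading of the rule sentences) and
share no algorithmic path with the package code they check.
"""

from __future__ import annotations

from functools import lru_cache

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
_WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU_PAIRS = {("G", "T"), ("T", "G")}
MIN_LOOP = 3


# --- folding -----------------------------------------------------------------


def enumerate_structures(seq: str):
    """Yield every pseudoknot-free structure (as a tuple of pairs)."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int):
        if j - i < MIN_LOOP + 1:
            return ((),)
        out = list(rec(i + 1, j))  # i unpaired
        for k in range(i + MIN_LOOP + 1, j + 1):
            if (seq[i], seq[k]) in _PAIRS:
                for left in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        out.append(((i, k),) + left + right)
        return tuple(out)

    return rec(0, len(seq) - 1) if seq else ((),)


def structure_energy(seq: str, pairs) -> int:
    """Energy of a pair set: each stacked pair (i,j) over (i+1,j-1) adds
    -2 when (i,j) is G:C and -1 otherwise."""
    pairset = set(map(tuple, pairs))
    total = 0
    for i, j in pairset:
        if (i + 1, j - 1) in pairset:
            total += -2 if {seq[i], seq[j]} == {"G", "C"} else -1
    return total


def brute_mfe(seq: str) -> int:
    return min(structure_energy(seq, s) for s in enumerate_structures(seq))


# --- duplex rules ------------------------------------------------------------


def brute_rule_check(mirna: str, site: str) -> dict[str, bool]:
    """Direct transliteration of the six target rules.

    Position i (1-based from the miRNA 5' end) faces site base L-i (0-based);
    G:U counts 0.5 toward the summed scores (b, c) and is not a mismatch for
    the positional rules (a, d, e); rule f compares stacking MFEs and fails
    when the perfect-complement MFE is zero.
    """
    L = len(mirna)
    state = []
    for i in range(1, L + 1):
        pair = (mirna[i - 1], site[L - i])
        if pair in _WC_PAIRS:
            state.append("wc")
        elif pair in _GU_PAIRS:
            state.append("gu")
        else:
            state.append("mm")
    score = [0.0 if s == "wc" else (0.5 if s == "gu" else 1.0) for s in state]

    # a: no more than two adjacent mismatches anywhere
    runs = []
    run = 0
    for s in state:
        if s == "mm":
            run += 1
        else:
            runs.append(run)
            run = 0
    runs.append(run)
    rule_a = max(runs) <= 2

    rule_b = sum(score) <= 4.0
    rule_c = sum(score[:12]) <= 2.5
    rule_d = state[10 - 1] != "mm" and state[11 - 1] != "mm"
    rule_e = not any(
        state[p - 1] == "mm" and state[p] == "mm" for p in range(2, 12)
    )

    # rule f via stacking energies computed here from scratch
    def wt(a, b):
        return -2 if {a, b} == {"G", "C"} else -1

    duplex = 0
    for i in range(L - 1):
        if state[i] != "mm" and state[i + 1] != "mm":
            duplex += wt(mirna[i], site[L - 1 - i])
    perfect = 0
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    for i in range(L - 1):
        perfect += wt(mirna[i], comp[mirna[i]])
    rule_f = perfect < 0 and duplex / perfect >= 0.75
    return {
        "a": rule_a,
        "b": rule_b,
        "c": rule_c,
        "d": rule_d,
        "e": rule_e,
        "f": rule_f,
    }


# --- known matching ----------------------------------------------------------


def brute_match(tag: str, db: dict[str, str], max_mm: int = 2):
    """All-pairs Hamming scan; returns (id, mm) or None, ties to smallest id."""
    best = None
    for mid in sorted(db):
        seq = db[mid]
        if len(seq) != len(tag):
            continue
        mm = sum(a != b for a, b in zip(tag, seq))
        if mm <= max_mm and (best is None or mm < best[1]):
            best = (mid, mm)
    return best


# --- tag classification ------------------------------------------------------

CLASS_ORDER = [
    "miRNA",
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "scRNA",
    "repeat",
    "exon",
    "intron",
]
_TYPE_TO_CLASS = {
    "miRNA_primary_transcript": "miRNA",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "snRNA": "snRNA",
    "snoRNA": "snoRNA",
    "scRNA": "scRNA",
    "repeat_region": "repeat",
    "exon": "exon",
    "intron": "intron",
}


def brute_classify(tag: str, genome: dict[str, str], features) -> str:
    """Exhaustive per-position scan of both strands + interval overlap."""
    comp = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}
    rc = "".join(comp[b] for b in reversed(tag))
    found = []
    for chrom, seq in genome.items():
        for probe in (tag, rc):
            for pos in range(0, len(seq) - len(tag) + 1):
                if seq[pos : pos + len(tag)] == probe:
                    found.append((chrom, pos, pos + len(tag)))
    best = None
    for chrom, start, end in found:
        for f in features:
            if f.chrom == chrom and f.start < end and start < f.end:
                cls = _TYPE_TO_CLASS[f.ftype]
                rank = CLASS_ORDER.index(cls)
                if best is None or rank < best[0]:
                    best = (rank, cls)
    return best[1] if best else "unannotated"


# --- exact two-sided binomial ------------------------------------------------


def brute_binom_two_sided(x: int, n: int, p: float) -> float:
    """Min-likelihood two-sided exact binomial p-value by full enumeration."""
    from scipy.stats import binom

    pmf = binom.pmf(range(n + 1), n, p)
    px = pmf[x]
    return float(pmf[pmf <= px * (1 + 1e-12)].sum())
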