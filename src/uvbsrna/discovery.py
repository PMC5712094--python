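"""Known-miRNA matching and novel hairpin-candidate discovery.

Known matching: a tag matches a database entry iff the lengths are equal and
the Hamming distance is at most ``max_mm`` (default 2).  Each tag is assigned
to exactly one entry — the one with the fewest mismatches, ties broken by
lexicographically smallest id (the tie is recorded on the hit).  Known
matching takes precedence over novel discovery, so no tag is counted twice.

Novel discovery: unannotated genome-mapped tags are clustered (gap <= 30 nt on
the same chromosome/strand), each cluster yields one flank-extended window
around its most abundant tag, the window is folded with the shared
stacked-pair engine, and the fold is judged against Mireap-style criteria.
The criteria set is a stated stand-in, configurable, not a claim about any
external tool's thresholds.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from ._seq import hamming, normalize, revcomp
from .fold import FoldResult, fold
from .preprocess import GenomeIndex

_FAMILY_RE = re.compile(r"^(?:[A-Za-z]{2,5}[-_])?((?:miR|MIR|let)[-]?\d+)", re.IGNORECASE)


def family_name(mirna_id: str) -> str:
    """Collapse a mature miRNA id to its family (ppe-miR395d-5p -> miR395)."""
    m = _FAMILY_RE.match(mirna_id)
    if m:
        return m.group(1).replace("-", "")
    return mirna_id


@dataclass(frozen=True)
class KnownMiRNAHit:
    tag: str
    mirna_id: str
    family: str
    mismatches: int
    tied_ids: tuple[str, ...] = ()


class _HammingIndex:
    """mm-tolerant lookup: split each entry into max_mm+1 exact segments."""

    def __init__(self, db: Mapping[str, str], max_mm: int):
        self.max_mm = max_mm
        self.db = db
        self._segments: dict[tuple[int, int, str], list[str]] = {}
        n_seg = max_mm + 1
        for mid, seq in db.items():
            L = len(seq)
            bounds = [round(k * L / n_seg) for k in range(n_seg + 1)]
            for k in range(n_seg):
                key = (L, k, seq[bounds[k] : bounds[k + 1]])
                self._segments.setdefault(key, []).append(mid)

    def candidates(self, tag: str) -> set[str]:
        L = len(tag)
        n_seg = self.max_mm + 1
        bounds = [round(k * L / n_seg) for k in range(n_seg + 1)]
        out: set[str] = set()
        for k in range(n_seg):
            out.update(self._segments.get((L, k, tag[bounds[k] : bounds[k + 1]]), ()))
        return out


def match_known(
    tags: Mapping[str, Mapping[str, int]],
    mirna_db: Mapping[str, str],
    max_mm: int = 2,
) -> tuple[list[KnownMiRNAHit], pd.DataFrame]:
    """Match tags against a mature-miRNA database.

    Returns the per-tag hits and a count matrix (rows: matched miRNA ids,
    columns: libraries) with each tag's counts credited to exactly one entry.
    """
    db = {}
    for mid, seq in mirna_db.items():
        if mid in db:
            raise ValueError(f"duplicate database id {mid!r}")
        db[mid] = normalize(seq)
    for mid, seq in db.items():
        if not 18 <= len(seq) <= 26:
            raise ValueError(f"database entry {mid} length {len(seq)} outside 18-26 nt")
    index = _HammingIndex(db, max_mm)

    libs = sorted({lib for counts in tags.values() for lib in counts})
    hits: list[KnownMiRNAHit] = []
    counts: dict[str, Counter] = {}
    for tag in sorted(tags):
        best_mm = max_mm + 1
        best_ids: list[str] = []
        for mid in index.candidates(tag):
            seq = db[mid]
            mm = hamming(tag, seq)
            if mm > max_mm:
                continue
            if mm < best_mm:
                best_mm = mm
                best_ids = [mid]
            elif mm == best_mm:
                best_ids.append(mid)
        if not best_ids:
            continue
        best_ids.sort()
        chosen = best_ids[0]
        hits.append(
            KnownMiRNAHit(
                tag,
                chosen,
                family_name(chosen),
                best_mm,
                tuple(best_ids[1:]),
            )
        )
        acc = counts.setdefault(chosen, Counter())
        for lib, n in tags[tag].items():
            acc[lib] += n
    matrix = pd.DataFrame(
        {lib: [counts[mid][lib] for mid in sorted(counts)] for lib in libs},
        index=sorted(counts),
        dtype="int64",
    )
    matrix.index.name = "mirna_id"
    return hits, matrix


# ---------------------------------------------------------------------------
# novel candidates


@dataclass
class CandidateLocus:
    """Flank-extended genomic window around a cluster of supporting tags."""

    chrom: str
    start: int
    end: int
    strand: str
    mature_start: int  # genomic coords of the dominant tag
    mature_end: int
    support: int
    tags: tuple[str, ...]
    clipped: bool = False

    def window_sequence(self, genome: Mapping[str, str]) -> str:
        seq = genome[self.chrom][self.start : self.end]
        return revcomp(seq) if self.strand == "-" else seq

    def mature_in_window(self) -> tuple[int, int]:
        if self.strand == "+":
            return self.mature_start - self.start, self.mature_end - self.start
        return self.end - self.mature_end, self.end - self.mature_start


def extract_candidate_loci(
    tags: Mapping[str, Mapping[str, int]],
    genome: Mapping[str, str],
    flank: int = 150,
    merge_dist: int = 30,
    max_window: int = 400,
    min_support: int = 1,
    index: GenomeIndex | None = None,
) -> list[CandidateLocus]:
    """Cluster mapped tags and emit one folding window per cluster.

    Tags mapping within ``merge_dist`` on the same chromosome and strand are
    merged.  The window is the cluster span extended by ``flank`` on both
    sides; clusters whose extended span would exceed ``max_window`` are
    re-centred on the cluster's most abundant tag (folding cost is cubic in
    window length).  Windows are clipped at chromosome ends and flagged.
    """
    if flank < 50:
        raise ValueError("flank must be >= 50")
    gidx = index or GenomeIndex(genome)
    placements: dict[tuple[str, str], list[tuple[int, int, str, int]]] = {}
    for tag in sorted(tags):
        total = sum(tags[tag].values())
        for chrom, pos, strand in gidx.map(tag):
            placements.setdefault((chrom, strand), []).append(
                (pos, pos + len(tag), tag, total)
            )

    loci: list[CandidateLocus] = []
    for (chrom, strand), items in sorted(placements.items()):
        items.sort()
        cluster: list[tuple[int, int, str, int]] = []

        def _flush():
            if not cluster:
                return
            support = sum(c[3] for c in cluster)
            if support < min_support:
                return
            span_start = min(c[0] for c in cluster)
            span_end = max(c[1] for c in cluster)
            # dominant tag: highest count, then leftmost, then lexicographic
            dom = max(cluster, key=lambda c: (c[3], -c[0], c[2]))
            if span_end - span_start + 2 * flank > max_window:
                span_start, span_end = dom[0], dom[1]
            start = span_start - flank
            end = span_end + flank
            clipped = start < 0 or end > len(genome[chrom])
            start = max(0, start)
            end = min(len(genome[chrom]), end)
            loci.append(
                CandidateLocus(
                    chrom,
                    start,
                    end,
                    strand,
                    dom[0],
                    dom[1],
                    support,
                    tuple(sorted({c[2] for c in cluster})),
                    clipped,
                )
            )

        for item in items:
            if cluster and item[0] - max(c[1] for c in cluster) > merge_dist:
                _flush()
                cluster = []
            cluster.append(item)
        _flush()
    return loci


@dataclass
class HairpinCriteria:
    """Mireap-style acceptance thresholds for folded candidates.

    ``max_energy`` is an absolute score bound; ``max_energy_per_nt`` scales
    with precursor length, which is what actually separates designed stems
    (about -0.6/nt under this model) from shuffled or random sequence
    (about -0.35/nt).
    """

    min_precursor: int = 60
    max_precursor: int = 300
    max_energy: float = -18.0
    max_energy_per_nt: float = -0.5
    min_mature_paired: int = 16


@dataclass
class HairpinCandidate:
    """Folded candidate with per-criterion flags."""

    locus: CandidateLocus
    precursor: str
    fold: FoldResult
    mature: tuple[int, int]  # window coordinates
    star: tuple[int, int] | None
    support: int
    flags: dict[str, bool] = field(default_factory=dict)

    @property
    def accepted(self) -> bool:
        return all(self.flags.values())

    @property
    def arm(self) -> str:
        if self.star is None:
            return "?"
        return "5p" if self.mature[0] < self.star[0] else "3p"


def evaluate_hairpin(
    precursor: str,
    mature: tuple[int, int],
    criteria: HairpinCriteria | None = None,
    locus: CandidateLocus | None = None,
    support: int = 0,
    fold_result: FoldResult | None = None,
) -> HairpinCandidate:
    """Fold a candidate window and judge it against the hairpin criteria.

    ``mature`` is the (start, end) of the supporting mature tag in window
    coordinates.  Rejection with per-criterion flags is the normal path.
    """
    crit = criteria or HairpinCriteria()
    fr = fold_result or fold(precursor)
    m0, m1 = mature
    partners = {}
    for i, j in fr.pairs:
        partners[i] = j
        partners[j] = i
    mature_partners = [partners[p] for p in range(m0, m1) if p in partners]
    outside = [q for q in mature_partners if q < m0 or q >= m1]
    # pairs internal to the mature interval mean it spans the terminal loop
    internal = len(mature_partners) - len(outside)
    all_right = all(q >= m1 for q in outside)
    all_left = all(q < m0 for q in outside)

    flags = {
        "length": crit.min_precursor <= len(precursor) <= crit.max_precursor,
        "energy": (
            fr.energy <= crit.max_energy
            and fr.energy <= crit.max_energy_per_nt * len(precursor)
        ),
        "mature_paired": len(outside) >= crit.min_mature_paired,
        "one_arm": bool(outside) and (all_right or all_left),
        "no_loop_crossing": internal == 0 and (all_right or all_left),
    }
    star = None
    if outside:
        star = (min(outside), max(outside) + 1)
    return HairpinCandidate(locus, precursor, fr, (m0, m1), star, support, flags)


def refine_hairpin(
    window: str, mature: tuple[int, int], pad: int = 8
) -> tuple[str, tuple[int, int], tuple[int, int]]:
    """Trim a flank-extended window down to the stem-loop around the mature.

    The window is folded once; the pairing partners of the mature positions
    locate the star region, and the precursor span is the mature..star extent
    plus ``pad`` on each side.  Returns (precursor, mature in precursor
    coordinates, (lo, hi) span in window coordinates).  Windows whose mature
    is essentially unpaired are returned untrimmed — downstream evaluation
    rejects them anyway.
    """
    fr = fold(window)
    m0, m1 = mature
    partners = {}
    for i, j in fr.pairs:
        partners[i] = j
        partners[j] = i
    outside = sorted(
        q for q in (partners.get(p) for p in range(m0, m1))
        if q is not None and (q < m0 or q >= m1)
    )
    if len(outside) < 5:
        return window, mature, (0, len(window))
    lo = max(0, min(m0, outside[0]) - pad)
    hi = min(len(window), max(m1, outside[-1] + 1) + pad)
    return window[lo:hi], (m0 - lo, m1 - lo), (lo, hi)


def discover_novel(
    tags: Mapping[str, Mapping[str, int]],
    genome: Mapping[str, str],
    criteria: HairpinCriteria | None = None,
    flank: int = 150,
    merge_dist: int = 30,
    min_support: int = 1,
    index: GenomeIndex | None = None,
) -> list[HairpinCandidate]:
    """Full novel-candidate pass: cluster, window, trim, fold, evaluate."""
    loci = extract_candidate_loci(
        tags,
        genome,
        flank=flank,
        merge_dist=merge_dist,
        min_support=min_support,
        index=index,
    )
    out = []
    for locus in loci:
        window = locus.window_sequence(genome)
        mature = locus.mature_in_window()
        precursor, sub_mature, (lo, hi) = refine_hairpin(window, mature)
        if locus.strand == "+":
            g_start, g_end = locus.start + lo, locus.start + hi
        else:
            g_start, g_end = locus.end - hi, locus.end - lo
        refined = CandidateLocus(
            locus.chrom,
            g_start,
            g_end,
            locus.strand,
            locus.mature_start,
            locus.mature_end,
            locus.support,
            locus.tags,
            locus.clipped,
        )
        out.append(
            evaluate_hairpin(
                precursor, sub_mature, criteria, locus=refined, support=locus.support
            )
        )
    return _dedupe_candidates(out)


def _dedupe_candidates(cands: list[HairpinCandidate]) -> list[HairpinCandidate]:
    """Collapse candidates whose refined loci overlap (a near-perfect stem
    makes the mature tag map to both strands of its own precursor)."""
    ranked = sorted(
        cands,
        key=lambda c: (
            not c.accepted,
            -c.support,
            c.fold.energy,
            c.locus.chrom,
            c.locus.start,
            c.locus.strand,
        ),
    )
    kept: list[HairpinCandidate] = []
    for cand in ranked:
        loc = cand.locus
        clash = any(
            k.locus.chrom == loc.chrom
            and k.locus.start < loc.end
            and loc.start < k.locus.end
            for k in kept
        )
        if not clash:
            kept.append(cand)
    kept.sort(key=lambda c: (c.locus.chrom, c.locus.start, c.locus.strand))
    return kept


def novel_id(candidate: HairpinCandidate) -> str:
    locus = candidate.locus
    return f"{locus.chrom}_{locus.mature_start + 1}-{candidate.arm}"


def count_matrix(
    known_counts: pd.DataFrame,
    novel: Sequence[HairpinCandidate],
    tags: Mapping[str, Mapping[str, int]],
    totals: Mapping[str, int],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Combine known rows with accepted novel candidates into one matrix.

    Tags already credited to known miRNAs keep precedence; a novel candidate
    row sums the counts of its own supporting tags only.
    """
    libs = sorted(totals)
    rows: dict[str, Counter] = {}
    for cand in novel:
        if not cand.accepted:
            continue
        nid = novel_id(cand)
        acc = rows.setdefault(nid, Counter())
        for tag in cand.locus.tags:
            for lib, n in tags.get(tag, {}).items():
                acc[lib] += n
    novel_df = pd.DataFrame(
        {lib: [rows[nid][lib] for nid in sorted(rows)] for lib in libs},
        index=sorted(rows),
        dtype="int64",
    )
    novel_df.index.name = "mirna_id"
    known = known_counts.reindex(columns=libs, fill_value=0)
    combined = pd.concat([known, novel_df]) if len(novel_df) else known
    combined = combined.fillna(0).astype("int64")
    for lib in libs:
        if combined[lib].sum() > totals[lib]:
            raise ValueError(f"counts for {lib} exceed clean total")
    return combined, dict(totals)
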