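"""Raw-read cleaning, QC accounting, length distributions and tag annotation.

Removal reasons are assigned in a fixed precedence so that the QC categories
are disjoint and reconcile exactly to the raw total:

  malformed/N-containing -> low-quality -> adapter-only (insert null) ->
  no adapter found (removed-adapter) -> poly-A -> too short -> too long

The adapter is located as the first exact occurrence of the full adapter in
the read; failing that, a 3'-terminal prefix of the adapter of >= 8 nt with
at most one mismatch is accepted (truncated adapters at the end of the read).
Reads with no adapter evidence are discarded: a small-RNA insert is shorter
than the read, so a missing adapter implies a failed ligation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import revcomp
from .io import Feature

#: classification precedence, highest first; "unannotated" is the fallthrough
CLASS_PRECEDENCE = [
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
UNANNOTATED = "unannotated"

#: map GFF feature types onto report classes
FEATURE_CLASS = {
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

QC_CATEGORIES = [
    "n_containing",
    "low_quality",
    "insert_null",
    "removed_adapter",
    "poly_a",
    "too_short",
    "too_long",
]


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str
    quality: str

    def __post_init__(self):
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.read_id}: sequence/quality length mismatch "
                f"({len(self.sequence)} vs {len(self.quality)})"
            )


@dataclass
class QCThresholds:
    """Tunable cleaning thresholds (defaults follow common sRNA-seq practice)."""

    min_len: int = 18
    max_len: int = 30
    low_q_phred: int = 20
    max_low_q_frac: float = 0.10
    polya_frac: float = 0.80
    polya_run: int = 10
    adapter_min_overlap: int = 8
    adapter_overlap_mm: int = 1


@dataclass
class QCRow:
    """Per-library Table-1-style accounting; counts, not percentages."""

    library: str
    raw: int = 0
    clean: int = 0
    categories: Counter = field(default_factory=Counter)

    def reconciles(self) -> bool:
        return self.clean + sum(self.categories.values()) == self.raw

    def percentages(self) -> dict[str, float]:
        if self.raw == 0:
            return {}
        out = {"clean": 100.0 * self.clean / self.raw}
        for cat in QC_CATEGORIES:
            out[cat] = 100.0 * self.categories.get(cat, 0) / self.raw
        return out


class FastqParseError(ValueError):
    pass


def _find_adapter(seq: str, adapter: str, thresholds: QCThresholds) -> int:
    """Return insert length (adapter start) or -1 when no adapter evidence."""
    pos = seq.find(adapter)
    if pos >= 0:
        return pos
    # truncated adapter at the 3' end of the read
    max_over = min(len(adapter) - 1, len(seq))
    for over in range(max_over, thresholds.adapter_min_overlap - 1, -1):
        tail = seq[len(seq) - over :]
        prefix = adapter[:over]
        mm = sum(a != b for a, b in zip(tail, prefix))
        if mm <= thresholds.adapter_overlap_mm:
            return len(seq) - over
    return -1


def _is_polya(insert: str, thresholds: QCThresholds) -> bool:
    if not insert:
        return False
    if insert.count("A") / len(insert) >= thresholds.polya_frac:
        return True
    return "A" * thresholds.polya_run in insert


def clean_reads(
    reads: Iterable[tuple[str, str, str] | ReadRecord],
    adapter: str,
    thresholds: QCThresholds | None = None,
    library: str = "lib",
) -> tuple[Counter, QCRow]:
    """Clean one library; returns (tag sequence -> read count, QC row).

    ``reads`` yields (id, sequence, quality) tuples or ReadRecords.  Results
    are memoized per (sequence, quality) pair, which makes collapsed/simulated
    libraries cheap to process.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    th = thresholds or QCThresholds()
    qc = QCRow(library=library)
    tags: Counter = Counter()
    low_q_chars = frozenset(chr(33 + q) for q in range(th.low_q_phred))
    cache: dict[tuple[str, str], tuple[str, str | None]] = {}

    for idx, rec in enumerate(reads):
        if isinstance(rec, ReadRecord):
            rid, seq, qual = rec.read_id, rec.sequence, rec.quality
        else:
            rid, seq, qual = rec
        if len(seq) != len(qual) or not seq:
            raise FastqParseError(
                f"malformed FASTQ record #{idx} ({rid}): "
                f"sequence/quality length mismatch"
            )
        qc.raw += 1
        key = (seq, qual)
        hit = cache.get(key)
        if hit is None:
            hit = _clean_one(seq, qual, adapter, th, low_q_chars)
            cache[key] = hit
        category, tag = hit
        if tag is not None:
            qc.clean += 1
            tags[tag] += 1
        else:
            qc.categories[category] += 1
    return tags, qc


def _clean_one(seq, qual, adapter, th, low_q_chars):
    seq = seq.upper().replace("U", "T")
    if "N" in seq:
        return "n_containing", None
    n_low = sum(q in low_q_chars for q in qual)
    if n_low > th.max_low_q_frac * len(qual):
        return "low_quality", None
    pos = _find_adapter(seq, adapter, th)
    if pos == 0:
        return "insert_null", None
    if pos < 0:
        return "removed_adapter", None
    insert = seq[:pos]
    if _is_polya(insert, th):
        return "poly_a", None
    if len(insert) < th.min_len:
        return "too_short", None
    if len(insert) > th.max_len:
        return "too_long", None
    return "clean", insert


def qc_report(rows: Sequence[QCRow]) -> pd.DataFrame:
    """Table-1-style QC report (counts plus percentages of raw)."""
    records = []
    for row in rows:
        rec = {"library": row.library, "raw_reads": row.raw, "clean_reads": row.clean}
        pct = row.percentages()
        rec["clean_pct"] = round(pct.get("clean", 0.0), 4)
        for cat in QC_CATEGORIES:
            rec[cat] = row.categories.get(cat, 0)
            rec[f"{cat}_pct"] = round(pct.get(cat, 0.0), 4)
        records.append(rec)
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# collapsed tags


def merge_tag_counts(per_library: Mapping[str, Counter]) -> dict[str, dict[str, int]]:
    """Merge per-library tag counters into {sequence: {library: count}}."""
    merged: dict[str, dict[str, int]] = {}
    for lib in per_library:
        for seq, n in per_library[lib].items():
            merged.setdefault(seq, {})[lib] = n
    return merged


def tag_fasta_records(tags: Mapping[str, Mapping[str, int]]) -> dict[str, str]:
    """Collapsed-tag FASTA payload with >tag{serial}_x{count} headers."""
    out = {}
    for serial, seq in enumerate(sorted(tags, key=lambda s: (-sum(tags[s].values()), s))):
        total = sum(tags[seq].values())
        out[f"tag{serial}_x{total}"] = seq
    return out


def length_distribution(
    tags: Mapping[str, Mapping[str, int]],
    min_len: int = 18,
    max_len: int = 30,
) -> pd.DataFrame:
    """Per-length fractions of total reads and of unique tags, per library.

    Rows are lengths ``min_len..max_len``; columns ``{lib}_reads`` /
    ``{lib}_tags``; each column sums to 1.
    """
    if not tags:
        raise ValueError("length_distribution requires a non-empty tag set")
    libs = sorted({lib for counts in tags.values() for lib in counts})
    lengths = range(min_len, max_len + 1)
    read_counts = {lib: Counter() for lib in libs}
    tag_counts = {lib: Counter() for lib in libs}
    for seq, counts in tags.items():
        L = len(seq)
        for lib, n in counts.items():
            if n > 0:
                read_counts[lib][L] += n
                tag_counts[lib][L] += 1
    data = {}
    for lib in libs:
        rt = sum(read_counts[lib].values())
        tt = sum(tag_counts[lib].values())
        data[f"{lib}_reads"] = [read_counts[lib][L] / rt if rt else 0.0 for L in lengths]
        data[f"{lib}_tags"] = [tag_counts[lib][L] / tt if tt else 0.0 for L in lengths]
    return pd.DataFrame(data, index=pd.Index(lengths, name="length"))


# ---------------------------------------------------------------------------
# genome mapping and annotation classes


class GenomeIndex:
    """Exact-match mapping of short tags to a genome via a seed k-mer index."""

    def __init__(self, genome: Mapping[str, str], seed_len: int = 18):
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.seed_len = seed_len
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in sorted(self.genome.items()):
            for i in range(len(seq) - seed_len + 1):
                self._index.setdefault(seq[i : i + seed_len], []).append((chrom, i))

    def _exact(self, tag: str) -> list[tuple[str, int]]:
        out = []
        for chrom, pos in self._index.get(tag[: self.seed_len], ()):
            if self.genome[chrom][pos : pos + len(tag)] == tag:
                out.append((chrom, pos))
        return out

    def map(self, tag: str) -> list[tuple[str, int, str]]:
        """All exact full-length matches as (chrom, 0-based start, strand)."""
        if len(tag) < self.seed_len:
            raise ValueError(f"tag shorter than seed length {self.seed_len}")
        hits = [(c, p, "+") for c, p in self._exact(tag)]
        for c, p in self._exact(revcomp(tag)):
            hits.append((c, p, "-"))
        return sorted(hits)


class _ClassGrid:
    """Per-base best-class array per chromosome (precedence-resolved)."""

    def __init__(self, genome: Mapping[str, str], features: Iterable[Feature]):
        self.rank = {c: i for i, c in enumerate(CLASS_PRECEDENCE)}
        self.fallback = len(CLASS_PRECEDENCE)
        self.grid = {
            c: np.full(len(s), self.fallback, dtype=np.int8) for c, s in genome.items()
        }
        for f in features:
            cls = FEATURE_CLASS.get(f.ftype)
            if cls is None:
                raise ValueError(f"unknown annotation feature type {f.ftype!r}")
            if f.chrom not in self.grid:
                raise ValueError(f"annotation references unknown chromosome {f.chrom!r}")
            code = self.rank[cls]
            seg = self.grid[f.chrom][f.start : f.end]
            np.minimum(seg, code, out=seg)

    def best_class(self, chrom: str, start: int, end: int) -> str:
        code = int(self.grid[chrom][start:end].min()) if end > start else self.fallback
        if code >= self.fallback:
            return UNANNOTATED
        return CLASS_PRECEDENCE[code]


@dataclass
class ClassBreakdown:
    """Per-class read/tag counts per library plus the per-tag class map."""

    reads: pd.DataFrame  # class x library, count-weighted
    tags: pd.DataFrame  # class x library, unique tags
    tag_class: dict[str, str]
    tag_hits: dict[str, list[tuple[str, int, str]]]

    def table(self) -> pd.DataFrame:
        r = self.reads.add_suffix("_reads")
        t = self.tags.add_suffix("_tags")
        return pd.concat([r, t], axis=1)


def classify_tags(
    tags: Mapping[str, Mapping[str, int]],
    genome: Mapping[str, str],
    features: Iterable[Feature],
    index: GenomeIndex | None = None,
) -> ClassBreakdown:
    """Assign each tag one annotation class by genome mapping + precedence.

    A tag overlapping several features (or mapping to several loci) takes the
    highest-precedence class among all of them; unmapped tags, and mapped tags
    overlapping nothing, are ``unannotated``.
    """
    features = list(features)
    grid = _ClassGrid(genome, features)
    gidx = index or GenomeIndex(genome)
    libs = sorted({lib for counts in tags.values() for lib in counts})
    classes = CLASS_PRECEDENCE + [UNANNOTATED]
    read_acc = {lib: Counter() for lib in libs}
    uniq_acc = {lib: Counter() for lib in libs}
    tag_class: dict[str, str] = {}
    tag_hits: dict[str, list[tuple[str, int, str]]] = {}

    for seq in sorted(tags):
        hits = gidx.map(seq)
        tag_hits[seq] = hits
        best = UNANNOTATED
        best_rank = len(CLASS_PRECEDENCE) + 1
        for chrom, pos, _strand in hits:
            cls = grid.best_class(chrom, pos, pos + len(seq))
            rank = grid.rank.get(cls, len(CLASS_PRECEDENCE))
            if rank < best_rank:
                best_rank = rank
                best = cls
        tag_class[seq] = best
        for lib, n in tags[seq].items():
            if n > 0:
                read_acc[lib][best] += n
                uniq_acc[lib][best] += 1
    reads = pd.DataFrame(
        {lib: [read_acc[lib][c] for c in classes] for lib in libs},
        index=classes,
        dtype=np.int64,
    )
    uniq = pd.DataFrame(
        {lib: [uniq_acc[lib][c] for c in classes] for lib in libs},
        index=classes,
        dtype=np.int64,
    )
    return ClassBreakdown(reads, uniq, tag_class, tag_hits)
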