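"""Synthetic reference bundle and two-condition sRNA library simulator.

Everything downstream is testable offline against the ground truth produced
here: a toy genome with designed miRNA precursor hairpins and annotated
ncRNA/repeat/exon/intron loci, a mature-miRNA database (a configurable subset
withheld as "novel"), transcripts carrying planted target sites with known
rule violations, and gzip FASTQ libraries (CK1..CKn vs T1..Tn) with planted
between-condition expression ratios and Table-1-style contaminant classes.

Determinism: all sampling flows from one ``numpy`` seed sequence; the same
seed reproduces byte-identical FASTA/GFF/FASTQ output.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._seq import revcomp
from .io import Feature, write_fasta, write_fastq_gz, write_gff, write_tsv
from .targets import evaluate_site

#: standard Illumina small-RNA 3' adapter (the study never prints its own)
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

#: sequenced after the 3' adapter on short inserts (arbitrary fixed filler)
_POST_ADAPTER_PAD = "CGTATGCCGTCTTCTGCTTGAAAAAAAAAACGTATGCCGTCTTCTGCTTG"

#: insert-length weights over 18..30 nt: dominant 21 nt mode, secondary 24 nt
DEFAULT_LENGTH_WEIGHTS = {
    18: 0.030,
    19: 0.050,
    20: 0.080,
    21: 0.300,
    22: 0.080,
    23: 0.060,
    24: 0.150,
    25: 0.060,
    26: 0.050,
    27: 0.040,
    28: 0.040,
    29: 0.030,
    30: 0.030,
}

NCRNA_CLASSES = ["rRNA", "tRNA", "snRNA", "snoRNA", "scRNA", "repeat", "exon", "intron"]
_CLASS_FEATURE = {
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "snRNA": "snRNA",
    "snoRNA": "snoRNA",
    "scRNA": "scRNA",
    "repeat": "repeat_region",
    "exon": "exon",
    "intron": "intron",
}
_CLASS_LENGTH = {
    "rRNA": 160,
    "tRNA": 75,
    "snRNA": 105,
    "snoRNA": 90,
    "scRNA": 120,
    "repeat": 220,
    "exon": 260,
    "intron": 200,
}

_PRECURSOR_EXT = 8  # stem extension on each side of the mature/star duplex
_PRECURSOR_LOOP = "AAAAAAAAA"

#: a base that neither Watson-Crick- nor wobble-pairs with the key
MISMATCH_PARTNER = {"A": "C", "C": "A", "G": "A", "T": "C"}


class SizingError(ValueError):
    pass


class InfeasibleViolationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# planted target sites


@dataclass(frozen=True)
class PlantedSite:
    transcript_id: str
    mirna_id: str
    position: int  # 0-based start on the transcript
    violation: str | None
    site: str
    failing_rules: tuple[str, ...]


def _violation_plans(mirna: str, violation: str | None):
    """Candidate edit plans [(1-based miRNA position, 'mm'|'gu'), ...]."""
    L = len(mirna)
    gu_ok = [p for p in range(1, L + 1) if mirna[p - 1] in "GT"]
    if violation is None:
        yield []
        return
    if violation == "a":  # run of 3 mismatches outside 2..12
        for s in range(13, L - 1):
            yield [(s, "mm"), (s + 1, "mm"), (s + 2, "mm")]
    elif violation == "b":  # 5 isolated mismatches, mostly outside 1..12
        pools = [
            [13, 15, 17, 19, 21],
            [14, 16, 18, 20, 22],
            [1, 13, 15, 17, 19],
            [1, 14, 16, 18, 20],
        ]
        for pool in pools:
            if all(1 <= p <= L for p in pool):
                yield [(p, "mm") for p in pool]
    elif violation == "c":  # > 2.5 points within 1..12, nothing else broken
        gu12 = [p for p in gu_ok if p <= 12]
        if len(gu12) >= 6:
            yield [(p, "gu") for p in gu12[:6]]
        for mm_pair in ([2, 5], [3, 6], [2, 7], [4, 8]):
            gu2 = [p for p in gu12 if p not in mm_pair][:2]
            if len(gu2) == 2:
                yield [(p, "mm") for p in mm_pair] + [(p, "gu") for p in gu2]
        for trip in ([2, 5, 8], [3, 6, 9], [2, 4, 7], [1, 4, 7]):
            yield [(p, "mm") for p in trip]
    elif violation == "d":
        yield [(10, "mm")]
        yield [(11, "mm")]
    elif violation == "e":  # adjacent mismatches within 2..12, away from 10/11
        for s in (5, 6, 4, 3, 7, 2, 8):
            yield [(s, "mm"), (s + 1, "mm")]
    elif violation == "f":  # enough 3'-end damage to drop the MFE ratio
        for pool in ([13, 15, 17, 19], [14, 16, 18, 20], [13, 15, 17, 19, 21]):
            if all(p <= L for p in pool):
                yield [(p, "mm") for p in pool]
    else:
        raise ValueError(f"unknown rule id {violation!r}")


def _build_site(mirna: str, plan) -> str | None:
    L = len(mirna)
    site = list(revcomp(mirna))
    for pos, kind in plan:
        base = mirna[pos - 1]
        idx = L - pos
        if kind == "mm":
            site[idx] = MISMATCH_PARTNER[base]
        else:
            if base == "G":
                site[idx] = "T"
            elif base == "T":
                site[idx] = "G"
            else:
                return None
    return "".join(site)


def make_site(mirna: str, violation: str | None) -> tuple[str, tuple[str, ...]]:
    """Design a target site that fails exactly ``violation`` (or passes).

    Returns (site sequence, failing rules under the package's own checker).
    Prefers a site whose only failing rule is the requested one; where that is
    arithmetically impossible (e.g. five ungapped mismatches necessarily drag
    the MFE ratio down too) the requested rule is still guaranteed to be among
    the failures.
    """
    fallback = None
    for plan in _violation_plans(mirna, violation):
        site = _build_site(mirna, plan)
        if site is None:
            continue
        verdict = evaluate_site(mirna, site)
        failing = verdict.failing()
        if violation is None:
            if not failing:
                return site, failing
            continue
        if failing == (violation,):
            return site, failing
        if violation in failing and fallback is None:
            fallback = (site, failing)
    if fallback is not None:
        return fallback
    raise InfeasibleViolationError(
        f"cannot construct a site violating rule {violation!r} "
        f"for miRNA {mirna}"
    )


def plant_target_site(
    transcript: str,
    mirna: str,
    violation: str | None = None,
    position: int | None = None,
    mirna_id: str = "",
    transcript_id: str = "",
) -> tuple[str, PlantedSite]:
    """Embed a designed (possibly rule-violating) site into a transcript."""
    L = len(mirna)
    if not 20 <= L <= 24:
        raise ValueError(f"miRNA length {L} outside 20-24 nt")
    if position is None:
        position = (len(transcript) - L) // 2
    if not 0 <= position <= len(transcript) - L:
        raise ValueError("site position outside transcript")
    site, failing = make_site(mirna, violation)
    new = transcript[:position] + site + transcript[position + L :]
    return new, PlantedSite(transcript_id, mirna_id, position, violation, site, failing)


# ---------------------------------------------------------------------------
# reference bundle


@dataclass(frozen=True)
class PrecursorLocus:
    mirna_id: str
    chrom: str
    start: int
    end: int
    strand: str
    mature: tuple[int, int]  # genomic, 0-based half-open
    star: tuple[int, int]
    novel: bool


@dataclass
class ReferenceParams:
    n_chroms: int = 2
    n_mirnas: int = 24
    n_novel: int = 4
    n_per_ncrna_class: int = 2
    n_transcripts: int = 8
    transcript_length: int = 400
    n_clean_sites: int = 4
    violations: tuple[str, ...] = ("a", "b", "c", "d", "e", "f")
    chrom_length: int | None = None
    gap_min: int = 150
    gap_max: int = 400
    mirna_length_weights: Mapping[int, float] = field(
        default_factory=lambda: {20: 0.15, 21: 0.50, 22: 0.15, 24: 0.20}
    )


@dataclass
class SyntheticReference:
    genome: dict[str, str]
    precursors: list[PrecursorLocus]
    mirna_db: dict[str, str]  # all expressed mature miRNAs, novel included
    novel_ids: frozenset[str]
    features: list[Feature]  # the annotation that goes into the GFF
    intergenic: list[tuple[str, int, int]]
    transcripts: dict[str, str]
    planted_sites: list[PlantedSite]
    ncrna_loci: list[tuple[str, int, int, str]]  # (chrom, start, end, class)
    seed: int

    @property
    def known_db(self) -> dict[str, str]:
        return {k: v for k, v in self.mirna_db.items() if k not in self.novel_ids}

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "annotation": outdir / "annotation.gff3",
            "mirna": outdir / "mirna_mature.fa",
            "transcripts": outdir / "transcripts.fa",
            "precursors": outdir / "precursors.tsv",
        }
        write_fasta(paths["genome"], self.genome)
        write_gff(paths["annotation"], self.features)
        write_fasta(paths["mirna"], self.known_db)
        write_fasta(paths["transcripts"], self.transcripts)
        write_tsv(
            paths["precursors"],
            pd.DataFrame(
                [
                    {
                        "mirna_id": p.mirna_id,
                        "chrom": p.chrom,
                        "start": p.start,
                        "end": p.end,
                        "strand": p.strand,
                        "mature_start": p.mature[0],
                        "mature_end": p.mature[1],
                        "novel": p.novel,
                    }
                    for p in self.precursors
                ]
            ),
        )
        return paths


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def build_precursor(mature: str, ext5: str) -> tuple[str, tuple[int, int], tuple[int, int]]:
    """Designed stem-loop: (ext+mature) + loop + revcomp(ext+mature).

    Returns (precursor, mature interval, star interval) in precursor coords.
    """
    arm = ext5 + mature
    prec = arm + _PRECURSOR_LOOP + revcomp(arm)
    m0 = len(ext5)
    m1 = m0 + len(mature)
    s0 = len(arm) + len(_PRECURSOR_LOOP)
    s1 = s0 + len(mature)
    return prec, (m0, m1), (s0, s1)


def generate_reference(params: ReferenceParams | None = None, seed: int = 0) -> SyntheticReference:
    """Build the full reference bundle; deterministic for a fixed seed."""
    p = params or ReferenceParams()
    if p.n_novel > p.n_mirnas:
        raise ValueError("n_novel cannot exceed n_mirnas")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    # mature miRNAs: known ids share families in pairs (miR###a/b)
    lens = sorted(p.mirna_length_weights)
    lweights = np.array([p.mirna_length_weights[k] for k in lens], dtype=float)
    lweights /= lweights.sum()
    mirna_db: dict[str, str] = {}
    n_known = p.n_mirnas - p.n_novel
    seen: set[str] = set()
    for i in range(p.n_mirnas):
        if i < n_known:
            mid = f"ppe-miR{1000 + i // 2}{'ab'[i % 2]}"
        else:
            mid = f"nov{i - n_known:03d}"
        while True:
            L = int(rng.choice(lens, p=lweights))
            seq = _random_seq(rng, L)
            if seq not in seen:
                seen.add(seq)
                break
        mirna_db[mid] = seq
    novel_ids = frozenset(k for k in mirna_db if k.startswith("nov"))

    # build the feature queue: precursors + ncRNA loci, then lay out genomes
    items: list[tuple[str, str, str]] = []  # (kind, name, sequence)
    prec_layout: dict[str, tuple[str, tuple[int, int], tuple[int, int], str]] = {}
    for mid, seq in mirna_db.items():
        ext5 = _random_seq(rng, _PRECURSOR_EXT)
        prec, mat, star = build_precursor(seq, ext5)
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        prec_layout[mid] = (prec, mat, star, strand)
        items.append(("precursor", mid, prec))
    for cls in NCRNA_CLASSES:
        for k in range(p.n_per_ncrna_class):
            length = _CLASS_LENGTH[cls] + int(rng.integers(0, 60))
            items.append((cls, f"{cls}_{k}", _random_seq(rng, length)))
    order = rng.permutation(len(items))
    items = [items[i] for i in order]

    if p.chrom_length is not None:
        need = sum(len(s) for _, _, s in items) + (len(items) + 1) * p.gap_min
        capacity = p.n_chroms * p.chrom_length
        if need > capacity:
            raise SizingError(
                f"features need >= {need} bases but genome capacity is "
                f"{capacity}; increase chrom_length or reduce features"
            )

    genome: dict[str, str] = {}
    features: list[Feature] = []
    precursors: list[PrecursorLocus] = []
    intergenic: list[tuple[str, int, int]] = []
    ncrna_loci: list[tuple[str, int, int, str]] = []
    per_chrom: list[list[tuple[str, str, str]]] = [[] for _ in range(p.n_chroms)]
    for i, item in enumerate(items):
        per_chrom[i % p.n_chroms].append(item)

    margin = 35  # keep intergenic sampling windows clear of feature edges
    for ci in range(p.n_chroms):
        chrom = f"chr{ci + 1}"
        parts: list[str] = []
        pos = 0

        def _gap():
            nonlocal pos
            g = int(rng.integers(p.gap_min, p.gap_max + 1))
            parts.append(_random_seq(rng, g))
            if g > 2 * margin + 40:
                intergenic.append((chrom, pos + margin, pos + g - margin))
            pos += g

        _gap()
        for kind, name, seq in per_chrom[ci]:
            start = pos
            if kind == "precursor":
                prec, mat, star, strand = prec_layout[name]
                placed = prec if strand == "+" else revcomp(prec)
                parts.append(placed)
                pos += len(placed)
                end = pos
                if strand == "+":
                    mat_g = (start + mat[0], start + mat[1])
                    star_g = (start + star[0], start + star[1])
                else:
                    mat_g = (end - mat[1], end - mat[0])
                    star_g = (end - star[1], end - star[0])
                precursors.append(
                    PrecursorLocus(
                        name, chrom, start, end, strand, mat_g, star_g,
                        name in novel_ids,
                    )
                )
                if name not in novel_ids:
                    features.append(
                        Feature(chrom, start, end, strand, "miRNA_primary_transcript", name)
                    )
            else:
                parts.append(seq)
                pos += len(seq)
                end = pos
                features.append(Feature(chrom, start, end, "+", _CLASS_FEATURE[kind], name))
                ncrna_loci.append((chrom, start, end, kind))
            _gap()
        if p.chrom_length is not None and pos < p.chrom_length:
            pad = p.chrom_length - pos
            parts.append(_random_seq(rng, pad))
            if pad > 2 * margin + 40:
                intergenic.append((chrom, pos + margin, pos + pad - margin))
            pos += pad
        genome[chrom] = "".join(parts)

    # transcripts with planted sites
    transcripts: dict[str, str] = {}
    planted: list[PlantedSite] = []
    known_ids = sorted(k for k in mirna_db if k not in novel_ids)
    plan: list[str | None] = [None] * p.n_clean_sites + list(p.violations)
    for t, violation in enumerate(plan):
        tid = f"tx{t:03d}"
        mid = known_ids[t % len(known_ids)]
        base = _random_seq(rng, p.transcript_length)
        seq, site = plant_target_site(
            base, mirna_db[mid], violation, mirna_id=mid, transcript_id=tid
        )
        transcripts[tid] = seq
        planted.append(site)
    for t in range(len(plan), p.n_transcripts):
        transcripts[f"tx{t:03d}"] = _random_seq(rng, p.transcript_length)

    ref = SyntheticReference(
        genome,
        precursors,
        mirna_db,
        novel_ids,
        features,
        intergenic,
        transcripts,
        planted,
        ncrna_loci,
        seed,
    )
    _check_reference(ref)
    return ref


def _check_reference(ref: SyntheticReference) -> None:
    for prec in ref.precursors:
        seq = ref.genome[prec.chrom][prec.start : prec.end]
        if prec.strand == "-":
            seq = revcomp(seq)
        mature = ref.mirna_db[prec.mirna_id]
        if mature not in seq:
            raise AssertionError(f"mature {prec.mirna_id} not in its precursor")
        for chrom, s, e, cls in ref.ncrna_loci:
            if chrom == prec.chrom and s < prec.end and prec.start < e:
                raise AssertionError("precursor overlaps an ncRNA locus")
    for site in ref.planted_sites:
        if site.violation is None and site.failing_rules:
            raise AssertionError("clean planted site fails the rule checker")


# ---------------------------------------------------------------------------
# library simulation


@dataclass
class ContaminationFractions:
    insert_null: float = 0.015
    poly_a: float = 0.030
    too_short: float = 0.120
    too_long: float = 0.050
    low_quality: float = 0.010
    n_containing: float = 0.005
    no_adapter: float = 0.010

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    def total(self) -> float:
        return sum(self.as_dict().values())


@dataclass
class SimulationDesign:
    expression_profile: dict[str, float]
    n_replicates: int = 3
    depth: int = 50_000
    planted_ratios: dict[str, float] = field(default_factory=dict)
    contamination: ContaminationFractions = field(default_factory=ContaminationFractions)
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 50
    mirna_fraction: float = 0.55
    ncrna_fraction: float = 0.35
    intergenic_fraction: float = 0.10
    length_weights: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_WEIGHTS)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not self.adapter:
            raise ValueError("adapter must be non-empty")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate per condition")
        fr = self.contamination.as_dict()
        if any(not 0 <= v <= 1 for v in fr.values()):
            raise ValueError("contamination fractions must lie in [0, 1]")
        if self.contamination.total() >= 1:
            raise ValueError("contamination fractions must sum to < 1")
        missing = set(self.planted_ratios) - set(self.expression_profile)
        if missing:
            raise ValueError(f"planted ratios for unknown miRNAs: {sorted(missing)}")
        if any(r <= 0 for r in self.planted_ratios.values()):
            raise ValueError("planted ratios must be positive")


@dataclass
class GroundTruth:
    origin_counts: dict[str, Counter]  # library -> label -> reads
    mirna_counts: dict[str, Counter]  # library -> miRNA id -> reads
    read_labels: dict[str, str]
    true_ratio: dict[str, float]
    regulation: dict[str, str]
    libraries: dict[str, str]  # library -> condition
    depth: int
    warnings: list[str] = field(default_factory=list)

    def regulation_of(self, ratio: float) -> str:
        return "up" if ratio > 2 else ("down" if ratio < 0.5 else "unchanged")

    def table(self) -> pd.DataFrame:
        rows = []
        for lib in sorted(self.origin_counts):
            for label, n in sorted(self.origin_counts[lib].items()):
                rows.append({"library": lib, "origin": label, "reads": n})
        return pd.DataFrame(rows)


def _origin_probs(ref: SyntheticReference, design: SimulationDesign, condition: str):
    """Fixed-order origin labels with per-condition probabilities."""
    contam = design.contamination.as_dict()
    clean = 1.0 - design.contamination.total()
    fr = np.array(
        [design.mirna_fraction, design.ncrna_fraction, design.intergenic_fraction]
    )
    fr = fr / fr.sum()
    f_mir, f_nc, f_int = (clean * fr).tolist()

    mids = sorted(design.expression_profile)
    weights = np.array([design.expression_profile[m] for m in mids], dtype=float)
    weights = weights / weights.sum()
    p_mir = f_mir * weights
    if condition == "T":
        ratios = np.array([design.planted_ratios.get(m, 1.0) for m in mids])
        delta = float((p_mir * (ratios - 1.0)).sum())
        p_mir = p_mir * ratios
        f_int = f_int - delta
        if f_int < (0.002 if delta > 0 else -1e-12):
            raise ValueError(
                "planted ratios inflate the miRNA pool beyond what the "
                "intergenic fraction can absorb; lower ratios or abundances"
            )
        f_int = max(f_int, 0.0)

    labels = [("contaminant", c) for c in sorted(contam)]
    probs = [contam[c] for c in sorted(contam)]
    labels += [("miRNA", m) for m in mids]
    probs += list(p_mir)
    n_loci = len(ref.ncrna_loci)
    for idx in range(n_loci):
        labels.append(("ncRNA", idx))
        probs.append(f_nc / n_loci)
    labels.append(("intergenic", ""))
    probs.append(f_int)
    probs = np.array(probs)
    probs = probs / probs.sum()
    return labels, probs


def _sample_lengths(rng, weights: Mapping[int, float], n: int) -> np.ndarray:
    lens = np.array(sorted(weights))
    w = np.array([weights[int(k)] for k in lens], dtype=float)
    w /= w.sum()
    return rng.choice(lens, size=n, p=w)


class _ReadFactory:
    def __init__(self, ref, design, rng):
        self.ref = ref
        self.design = design
        self.rng = rng
        self.adapter = design.adapter
        self.rl = design.read_length
        self.clean_qual = "I" * self.rl
        n_bad = max(int(np.ceil(0.25 * self.rl)), 1)
        self.lowq_qual = "&" * n_bad + "I" * (self.rl - n_bad)
        gaps = ref.intergenic
        self._gap_w = np.array([e - s for _, s, e in gaps], dtype=float)
        self._gap_w /= self._gap_w.sum()

    def _assemble(self, insert: str, qual: str | None = None) -> tuple[str, str]:
        full = insert + self.adapter + _POST_ADAPTER_PAD
        return full[: self.rl], qual or self.clean_qual

    def _random_insert(self, length: int) -> str:
        from .preprocess import QCThresholds, _is_polya

        th = QCThresholds()
        for _ in range(50):
            ins = _random_seq(self.rng, length)
            if not _is_polya(ins, th):
                return ins
        return ins  # pragma: no cover - astronomically unlikely

    def _genomic_insert(self, length: int) -> str:
        gi = int(self.rng.choice(len(self.ref.intergenic), p=self._gap_w))
        chrom, s, e = self.ref.intergenic[gi]
        length = min(length, e - s)
        off = int(self.rng.integers(s, e - length + 1))
        return self.ref.genome[chrom][off : off + length]

    def _ncrna_insert(self, locus_idx: int, length: int) -> str:
        chrom, s, e, _cls = self.ref.ncrna_loci[locus_idx]
        length = min(length, e - s)
        off = int(self.rng.integers(s, e - length + 1))
        return self.ref.genome[chrom][off : off + length]

    def contaminant(self, category: str) -> tuple[str, str]:
        from .preprocess import QCThresholds, _find_adapter, _is_polya

        th = QCThresholds()
        rng = self.rng
        if category == "insert_null":
            return self._assemble("")
        if category == "poly_a":
            k = int(_sample_lengths(rng, self.design.length_weights, 1)[0])
            return self._assemble("A" * k)
        if category == "too_short":
            return self._assemble(self._random_insert(int(rng.integers(8, 18))))
        if category == "too_long":
            return self._assemble(self._random_insert(int(rng.integers(31, 41))))
        if category == "low_quality":
            k = int(_sample_lengths(rng, self.design.length_weights, 1)[0])
            seq, _ = self._assemble(self._random_insert(k))
            return seq, self.lowq_qual
        if category == "n_containing":
            k = int(_sample_lengths(rng, self.design.length_weights, 1)[0])
            ins = self._random_insert(k)
            ins = ins[: k // 2] + "N" + ins[k // 2 + 1 :]
            return self._assemble(ins)
        if category == "no_adapter":
            for _ in range(50):
                seq = _random_seq(rng, self.rl)
                if (
                    _find_adapter(seq, self.adapter, th) < 0
                    and not _is_polya(seq, th)
                ):
                    return seq, self.clean_qual
            raise AssertionError("could not draw an adapter-free read")
        raise ValueError(f"unknown contaminant category {category!r}")


def simulate_libraries(
    ref: SyntheticReference,
    design: SimulationDesign,
    outdir=None,
) -> tuple[dict[str, object], GroundTruth]:
    """Simulate CK/T libraries; returns (per-library output, ground truth).

    With ``outdir`` set, gzip FASTQ files and a ground-truth TSV are written
    and the per-library mapping holds paths; otherwise it holds in-memory
    lists of (id, sequence, quality) records.
    """
    design.validate()
    lib_names = [f"CK{i + 1}" for i in range(design.n_replicates)] + [
        f"T{i + 1}" for i in range(design.n_replicates)
    ]
    conditions = {lib: ("CK" if lib.startswith("CK") else "T") for lib in lib_names}

    true_ratio = {
        m: design.planted_ratios.get(m, 1.0) for m in design.expression_profile
    }
    truth = GroundTruth(
        origin_counts={},
        mirna_counts={},
        read_labels={},
        true_ratio=true_ratio,
        regulation={},
        libraries=conditions,
        depth=design.depth,
    )
    for mid, r in true_ratio.items():
        truth.regulation[mid] = truth.regulation_of(r)

    seed_seq = np.random.SeedSequence(design.seed)
    lib_seeds = seed_seq.spawn(len(lib_names))
    outputs: dict[str, object] = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)

    for lib, sseq in zip(lib_names, lib_seeds):
        rng = np.random.default_rng(sseq)
        labels, probs = _origin_probs(ref, design, conditions[lib])
        for (kind, key), pr in zip(labels, probs):
            if kind == "miRNA" and pr * design.depth < 1 and key in design.planted_ratios:
                msg = f"{lib}: planted miRNA {key} has expected count < 1"
                truth.warnings.append(msg)
        counts = rng.multinomial(design.depth, probs)
        factory = _ReadFactory(ref, design, rng)
        records: list[tuple[str, str, str]] = []
        origin_counter: Counter = Counter()
        mirna_counter: Counter = Counter()
        serial = 0
        for (kind, key), n in zip(labels, counts):
            if n == 0:
                continue
            if kind == "miRNA":
                label = f"miRNA:{key}"
                seq, qual = factory._assemble(ref.mirna_db[key])
                mirna_counter[key] += int(n)
                for _ in range(int(n)):
                    rid = f"{lib}:{serial}"
                    serial += 1
                    records.append((rid, seq, qual))
                    truth.read_labels[rid] = label
            elif kind == "ncRNA":
                cls = ref.ncrna_loci[key][3]
                label = f"ncRNA:{cls}"
                lens = _sample_lengths(rng, design.length_weights, int(n))
                for L in lens:
                    seq, qual = factory._assemble(factory._ncrna_insert(key, int(L)))
                    rid = f"{lib}:{serial}"
                    serial += 1
                    records.append((rid, seq, qual))
                    truth.read_labels[rid] = label
            elif kind == "intergenic":
                label = "intergenic"
                lens = _sample_lengths(rng, design.length_weights, int(n))
                for L in lens:
                    seq, qual = factory._assemble(factory._genomic_insert(int(L)))
                    rid = f"{lib}:{serial}"
                    serial += 1
                    records.append((rid, seq, qual))
                    truth.read_labels[rid] = label
            else:
                label = f"contaminant:{key}"
                for _ in range(int(n)):
                    seq, qual = factory.contaminant(key)
                    rid = f"{lib}:{serial}"
                    serial += 1
                    records.append((rid, seq, qual))
                    truth.read_labels[rid] = label
            origin_counter[label] += int(n)
        truth.origin_counts[lib] = origin_counter
        truth.mirna_counts[lib] = mirna_counter
        if outdir is not None:
            path = outdir / f"{lib}.fastq.gz"
            write_fastq_gz(path, records)
            outputs[lib] = path
        else:
            outputs[lib] = records

    if outdir is not None:
        write_tsv(outdir / "ground_truth.tsv", truth.table())
        ratios = pd.DataFrame(
            {
                "mirna_id": sorted(truth.true_ratio),
                "true_ratio": [truth.true_ratio[m] for m in sorted(truth.true_ratio)],
                "regulation": [truth.regulation[m] for m in sorted(truth.true_ratio)],
            }
        )
        write_tsv(outdir / "true_ratios.tsv", ratios)
    for w in truth.warnings:
        warnings.warn(w)
    return outputs, truth


def default_design(
    ref: SyntheticReference,
    n_replicates: int = 3,
    depth: int = 50_000,
    planted_up: int = 5,
    ratio: float = 4.0,
    seed: int = 0,
    **kwargs,
) -> SimulationDesign:
    """Convenience design: lognormal baseline abundances, a few low-abundance
    known miRNAs planted at ``ratio`` so the intergenic pool can absorb the
    treatment-side inflation."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]).spawn(1)[0])
    ids = sorted(ref.mirna_db)
    known = sorted(k for k in ids if k not in ref.novel_ids)
    planted_ids = known[:planted_up]
    weights = rng.lognormal(0.0, 1.0, size=len(ids))
    profile = dict(zip(ids, weights / weights.sum()))
    planted_weight = 0.008
    rest = 1.0 - planted_weight * len(planted_ids)
    other_total = sum(v for k, v in profile.items() if k not in planted_ids)
    for k in ids:
        if k in planted_ids:
            profile[k] = planted_weight
        else:
            profile[k] = profile[k] / other_total * rest
    return SimulationDesign(
        expression_profile=profile,
        n_replicates=n_replicates,
        depth=depth,
        planted_ratios={m: ratio for m in planted_ids},
        seed=seed,
        **kwargs,
    )
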