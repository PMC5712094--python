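"""File-format boundaries: FASTA, FASTQ (gzip), GFF3 and TSV tables.

FASTQ is written through gzip with ``mtime=0`` and an empty embedded filename
so that reruns with the same seed are byte-identical.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

from ._seq import normalize

GFF_COLUMNS = [
    "seqid",
    "source",
    "type",
    "start",
    "end",
    "score",
    "strand",
    "phase",
    "attributes",
]


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict[str, str]:
    """FASTA as an id -> T-normalized uppercase sequence mapping."""
    with _open_text(path) as fh:
        records = {}
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in records:
                raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
            records[rec.id] = normalize(str(rec.seq))
    return records


def write_fasta(path, sequences: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        SeqIO.write(
            (SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()),
            fh,
            "fasta",
        )


def iter_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (read id, sequence, quality string) tuples from (gzip) FASTQ."""
    with _open_text(path) as fh:
        yield from FastqGeneralIterator(fh)


def write_fastq_gz(path, records: Iterable[tuple[str, str, str]]) -> None:
    """Deterministic gzip FASTQ writer (fixed mtime, no embedded name)."""
    with open(path, "wb") as raw:
        with gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0) as gz:
            chunk: list[str] = []
            for rid, seq, qual in records:
                chunk.append(f"@{rid}\n{seq}\n+\n{qual}\n")
                if len(chunk) >= 10000:
                    gz.write("".join(chunk).encode())
                    chunk.clear()
            if chunk:
                gz.write("".join(chunk).encode())


@dataclass(frozen=True)
class Feature:
    """One annotated genomic interval (0-based half-open internally)."""

    chrom: str
    start: int
    end: int
    strand: str
    ftype: str
    name: str

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


def read_gff(path) -> list[Feature]:
    """Read the package's GFF3 dialect back into Feature records."""
    features = []
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GFF line in {path}: {line!r}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = parts
            name = ""
            for field in attrs.split(";"):
                if field.startswith("ID="):
                    name = field[3:]
            features.append(
                Feature(seqid, int(start) - 1, int(end), strand, ftype, name)
            )
    return features


def write_gff(path, features: Iterable[Feature], source: str = "uvbsrna") -> None:
    """Write features as GFF3 (1-based closed coordinates at the boundary)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                "\t".join(
                    [
                        f.chrom,
                        source,
                        f.ftype,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        f"ID={f.name}",
                    ]
                )
                + "\n"
            )


def write_tsv(path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g", lineterminator="\n")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
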