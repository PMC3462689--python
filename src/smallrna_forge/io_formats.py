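"""Readers and writers for every external format the pipeline touches.

All coordinates emitted anywhere in the package are 1-based, fully closed
intervals; strand is "+" or "-".  Sequences are carried verbatim by the
readers (T vs U preserved as written); conversion to the internal RNA
alphabet happens at the preprocessing / reference-loading boundary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, List, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord


class FormatError(ValueError):
    """A file does not conform to its declared format."""


@dataclass
class SeqRecord:
    """A named nucleotide sequence with optional Phred qualities."""

    id: str
    seq: str
    qual: Optional[List[int]] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        if not self.seq:
            raise ValueError(f"SeqRecord {self.id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"SeqRecord {self.id!r}: {len(self.seq)} bases but "
                f"{len(self.qual)} quality scores"
            )

    def mean_qual(self) -> float:
        if self.qual is None:
            raise ValueError(f"SeqRecord {self.id!r} has no qualities")
        return sum(self.qual) / len(self.qual)


@dataclass(frozen=True)
class UniqueTag:
    """A collapsed small-RNA sequence with its read count.

    The atom flowing through annotation and miRNA calling: ``seq`` is on the
    RNA alphabet (U internally) and ``count`` is the number of clean reads
    that collapsed onto it.
    """

    seq: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"UniqueTag count must be >= 1, got {self.count}")

    def __len__(self) -> int:
        return len(self.seq)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path) -> Iterator[SeqRecord]:
    """Yield records from a FASTA file in file order.

    The header token before the first whitespace becomes the id; multi-line
    sequences are merged.  A non-empty file whose first non-blank line does
    not start with '>' raises :class:`FormatError` naming the line.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if line.strip() == "":
            continue
        if not line.startswith(">"):
            raise FormatError(f"{path}:{lineno}: expected FASTA header '>'")
        break
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            yield SeqRecord(id=rec.id, seq=str(rec.seq).upper())


def write_fasta(records: Iterable[SeqRecord], path) -> None:
    bio = (
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    )
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")


def read_fastq(path) -> Iterator[SeqRecord]:
    """Yield 4-line FASTQ records with Phred+33 qualities decoded to ints."""
    path = Path(path)
    with open(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                yield SeqRecord(
                    id=rec.id,
                    seq=str(rec.seq).upper(),
                    qual=list(rec.letter_annotations["phred_quality"]),
                )
        except ValueError as exc:  # Biopython signals truncation/mismatch
            raise FormatError(f"{path}: {exc}") from exc


def write_fastq(records: Iterable[SeqRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            if r.qual is None:
                raise ValueError(f"record {r.id!r} has no qualities")
            qstr = "".join(chr(q + 33) for q in r.qual)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qstr}\n")


# ---------------------------------------------------------------------------
# Tag TSV
# ---------------------------------------------------------------------------

TAG_COLUMNS = ["seq", "count"]


def write_tags(tags: Sequence[UniqueTag], path) -> None:
    """Write tags as TSV (seq, count), descending count then lexicographic."""
    ordered = sorted(tags, key=lambda t: (-t.count, t.seq))
    df = pd.DataFrame(
        {"seq": [t.seq for t in ordered], "count": [t.count for t in ordered]}
    )
    df.to_csv(path, sep="\t", index=False)


def read_tags(path) -> List[UniqueTag]:
    df = pd.read_csv(path, sep="\t", dtype={"seq": str, "count": int})
    if list(df.columns) != TAG_COLUMNS:
        raise FormatError(f"{path}: expected columns {TAG_COLUMNS}, got {list(df.columns)}")
    out = []
    for seq, count in zip(df["seq"], df["count"]):
        if count < 1:
            raise FormatError(f"{path}: non-positive count {count} for {seq}")
        out.append(UniqueTag(seq=seq, count=int(count)))
    return out


# ---------------------------------------------------------------------------
# GFF3 (hairpin / target-site emission)
# ---------------------------------------------------------------------------

@dataclass
class Gff3Feature:
    seqid: str
    type: str          # "miRNA_primary_transcript" or "target_site"
    start: int         # 1-based closed
    end: int
    strand: str = "+"
    score: Optional[float] = None
    attributes: dict = field(default_factory=dict)


def write_gff3(features: Iterable[Gff3Feature], path, source: str = "smallrna_forge") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            score = "." if f.score is None else f"{f.score:g}"
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items()) or "."
            fh.write(
                f"{f.seqid}\t{source}\t{f.type}\t{f.start}\t{f.end}\t"
                f"{score}\t{f.strand}\t.\t{attrs}\n"
            )
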