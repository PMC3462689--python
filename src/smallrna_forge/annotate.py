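"""Hierarchical annotation of unique tags against reference sequence sets.

A tag is classified by the first category in a precedence order for which it
has a perfect, full-length match (either strand) in that category's
reference set.  Only exact substring matches count: the annotation stage has
no mismatch tolerance.  Category precedence defaults to
ncRNA > repeat > known miRNA > exon > intron, so structural RNA fragments
are removed before any miRNA reasoning, and the partition property holds:
every tag gets exactly one category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from ._util import percent, revcomp, to_rna
from .io_formats import SeqRecord, UniqueTag

#: default category precedence (configurable in classify_tag)
DEFAULT_PRECEDENCE = (
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "repeat",
    "known_miRNA",
    "exon_sense",
    "exon_antisense",
    "intron_sense",
    "intron_antisense",
)

UNANNOTATED = "unannotated"

#: reference-set kind -> annotation category (strand-split kinds map later)
_KIND_TO_CATEGORY = {
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "snRNA": "snRNA",
    "snoRNA": "snoRNA",
    "repeat": "repeat",
    "known_miRNA_mature": "known_miRNA",
    "known_miRNA_precursor": "known_miRNA",
    "exon": "exon",
    "intron": "intron",
    "genome": "genome",
}


@dataclass
class ReferenceSet:
    """A named FASTA-backed category used for exact-match annotation."""

    name: str
    records: List[SeqRecord]
    kind: str

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"reference set {self.name!r} is empty")
        if self.kind not in _KIND_TO_CATEGORY:
            raise ValueError(f"unknown reference kind {self.kind!r}")


@dataclass
class AnnotationRecord:
    tag: UniqueTag
    category: str
    hit_id: Optional[str] = None
    strand: Optional[str] = None


class SearchIndex:
    """Exact substring lookup of 18-30 nt tags against reference sets.

    For each reference set every substring in the queryable length range is
    hashed (forward strand); a query is looked up as written (strand +) and
    as its reverse complement (strand -).  Memory scales with total
    reference length times the number of distinct query lengths, which is
    fine for the transcriptome-scale references this package targets.
    """

    def __init__(
        self,
        refs: Sequence[ReferenceSet],
        min_len: int = 18,
        max_len: int = 30,
    ) -> None:
        self.min_len = min_len
        self.max_len = max_len
        self.refs = list(refs)
        # set name -> {substring -> ref id}
        self._maps: Dict[str, Dict[str, str]] = {}
        for ref in self.refs:
            m: Dict[str, str] = {}
            for rec in ref.records:
                seq = to_rna(rec.seq)
                n = len(seq)
                for k in range(min_len, min(max_len, n) + 1):
                    for i in range(n - k + 1):
                        m.setdefault(seq[i : i + k], rec.id)
            self._maps[ref.name] = m

    def hits(self, query: str) -> Dict[str, Tuple[str, str]]:
        """Map reference-set name -> (hit id, strand) for a query tag."""
        q = to_rna(query)
        rc = revcomp(q)
        out: Dict[str, Tuple[str, str]] = {}
        for ref in self.refs:
            m = self._maps[ref.name]
            if q in m:
                out[ref.name] = (m[q], "+")
            elif rc in m:
                out[ref.name] = (m[rc], "-")
        return out


def build_index(refs: Sequence[ReferenceSet], min_len: int = 18, max_len: int = 30) -> SearchIndex:
    return SearchIndex(refs, min_len=min_len, max_len=max_len)


def _category_for(ref: ReferenceSet, strand: str) -> str:
    base = _KIND_TO_CATEGORY[ref.kind]
    if base in ("exon", "intron"):
        return f"{base}_{'sense' if strand == '+' else 'antisense'}"
    return base


def classify_tag(
    tag: UniqueTag,
    index: SearchIndex,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> AnnotationRecord:
    """Assign the first precedence category with a perfect full-length hit."""
    hits = index.hits(tag.seq)
    # category -> (hit_id, strand), resolved per reference set
    by_cat: Dict[str, Tuple[str, str]] = {}
    for ref in index.refs:
        if ref.name in hits:
            hit_id, strand = hits[ref.name]
            by_cat.setdefault(_category_for(ref, strand), (hit_id, strand))
    for cat in precedence:
        if cat in by_cat:
            hit_id, strand = by_cat[cat]
            return AnnotationRecord(tag=tag, category=cat, hit_id=hit_id, strand=strand)
    return AnnotationRecord(tag=tag, category=UNANNOTATED)


def classify_all(
    tags: Iterable[UniqueTag],
    index: SearchIndex,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> List[AnnotationRecord]:
    return [classify_tag(t, index, precedence) for t in tags]


@dataclass
class AnnotationSummary:
    """Per-category unique/redundant counts and percentages (table shape)."""

    table: pd.DataFrame  # index: category; columns: unique, redundant, unique_pct, redundant_pct
    total_unique: int
    total_clean: int

    def redundant(self, category: str) -> int:
        if category not in self.table.index:
            raise KeyError(f"unknown category {category!r}")
        return int(self.table.loc[category, "redundant"])


def summarize(records: Sequence[AnnotationRecord], total_clean: int) -> AnnotationSummary:
    """Aggregate annotation records into the category accounting table.

    Percentages are of total unique tags / total clean reads, rounded
    half-up to 2 decimals.
    """
    rows: Dict[str, List[int]] = {}
    for rec in records:
        u, r = rows.setdefault(rec.category, [0, 0])
        rows[rec.category] = [u + 1, r + rec.tag.count]
    total_unique = len(records)
    if sum(v[1] for v in rows.values()) > total_clean:
        raise ValueError("sum of tag counts exceeds total_clean")
    categories = [c for c in (*DEFAULT_PRECEDENCE, UNANNOTATED) if c in rows]
    categories += [c for c in rows if c not in categories]
    data = {
        "unique": [rows[c][0] for c in categories],
        "redundant": [rows[c][1] for c in categories],
    }
    df = pd.DataFrame(data, index=pd.Index(categories, name="category"))
    df["unique_pct"] = [
        percent(u, total_unique) if total_unique else 0.0 for u in df["unique"]
    ]
    df["redundant_pct"] = [
        percent(r, total_clean) if total_clean else 0.0 for r in df["redundant"]
    ]
    return AnnotationSummary(table=df, total_unique=total_unique, total_clean=total_clean)


def summary_from_counts(
    unique: Dict[str, int],
    redundant: Dict[str, int],
    total_unique: int,
    total_clean: int,
) -> AnnotationSummary:
    """Build an accounting table from already-aggregated category counts.

    Useful when the per-tag records are external (e.g. a published table)
    and only the percentage/subtraction arithmetic is needed.
    """
    categories = list(unique)
    df = pd.DataFrame(
        {
            "unique": [unique[c] for c in categories],
            "redundant": [redundant.get(c, 0) for c in categories],
        },
        index=pd.Index(categories, name="category"),
    )
    df["unique_pct"] = [percent(u, total_unique) for u in df["unique"]]
    df["redundant_pct"] = [percent(r, total_clean) for r in df["redundant"]]
    return AnnotationSummary(table=df, total_unique=total_unique, total_clean=total_clean)


def subtract_classes(summary: AnnotationSummary, classes: Iterable[str]) -> int:
    """Clean-read total after removing the redundant counts of ``classes``."""
    remaining = summary.total_clean
    for c in classes:
        remaining -= summary.redundant(c)
    return remaining


def length_profile(tags: Iterable[UniqueTag]) -> pd.DataFrame:
    """Per-length unique/redundant counts and the unique/redundant ratio."""
    rows: Dict[int, List[int]] = {}
    for t in tags:
        u, r = rows.setdefault(len(t.seq), [0, 0])
        rows[len(t.seq)] = [u + 1, r + t.count]
    lengths = sorted(rows)
    df = pd.DataFrame(
        {
            "unique": [rows[n][0] for n in lengths],
            "redundant": [rows[n][1] for n in lengths],
        },
        index=pd.Index(lengths, name="length"),
    )
    if len(df):
        df["ratio"] = df["unique"] / df["redundant"]
    else:
        df["ratio"] = pd.Series(dtype=float)
    return df
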