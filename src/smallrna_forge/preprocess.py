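"""Read-cleanup cascade for raw small-RNA libraries.

The cascade mirrors the accounting a sequencing-facility sRNA pipeline
reports: quality filter, 3' adapter locate/trim, insert-null and 5'-adapter
contaminant removal, poly(A) removal, length selection, and collapsing of
identical inserts into :class:`~smallrna_forge.io_formats.UniqueTag` counts.
Every raw read is assigned exactly one terminal fate, so category counts
plus clean reads reconstruct the raw total.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, asdict
from typing import Iterable, List, Optional, Tuple

from ._util import percent, to_rna
from .io_formats import SeqRecord, UniqueTag

#: sentinel fates returned by the adapter finder
ADAPTER_NULL = "ADAPTER_NULL"
INSERT_NULL = "INSERT_NULL"


@dataclass
class PreprocessParams:
    """Tunable knobs of the cleanup cascade.

    Lengths are the standard plant sRNA window 18-30 nt; ``min_mean_qual``
    defines "low quality" (mean Phred below it, or any N).  Adapter matching
    is seed-and-extend with a mismatch-rate tolerance; a match must be
    suffix-anchored (the adapter runs off the 3' end of the read) or contain
    the full adapter internally.
    """

    adapter3: str = "UCGUAUGCCGUCUUCUGCUUG"
    adapter5: str = "GUUCAGAGUUCUACAGUCCGACGAUC"
    min_len: int = 18
    max_len: int = 30
    min_mean_qual: float = 20.0
    polyA_frac: float = 0.8
    adapter_min_overlap: int = 6
    adapter_max_mismatch_rate: float = 0.1

    def __post_init__(self) -> None:
        self.adapter3 = to_rna(self.adapter3)
        self.adapter5 = to_rna(self.adapter5)
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")
        if not (0 < self.polyA_frac <= 1):
            raise ValueError("polyA_frac must be in (0, 1]")


@dataclass
class LibraryStats:
    """Per-category read accounting (the library statistics table).

    Categories are mutually exclusive terminal fates; ``percent_of_raw``
    reports each as a share of ``total_raw`` rounded half-up to 2 decimals.
    """

    total_raw: int = 0
    high_quality: int = 0
    low_quality: int = 0
    adaptor3_null: int = 0
    insert_null: int = 0
    adaptor5_contaminant: int = 0
    small_insert: int = 0
    polyA: int = 0
    long_insert: int = 0
    total_clean: int = 0
    unique_18_30: int = 0
    singletons: int = 0
    unique_multi: int = 0

    DISCARD_FIELDS = (
        "low_quality",
        "adaptor3_null",
        "insert_null",
        "adaptor5_contaminant",
        "small_insert",
        "polyA",
        "long_insert",
    )

    def percent_of_raw(self) -> dict:
        if self.total_raw == 0:
            return {}
        keys = (
            "high_quality",
            "adaptor3_null",
            "insert_null",
            "adaptor5_contaminant",
            "small_insert",
            "polyA",
            "total_clean",
            "unique_18_30",
            "singletons",
            "unique_multi",
        )
        return {k: percent(getattr(self, k), self.total_raw) for k in keys}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["percent"] = self.percent_of_raw()
        return d


# ---------------------------------------------------------------------------
# individual filters
# ---------------------------------------------------------------------------

def quality_filter(
    reads: Iterable[SeqRecord], params: PreprocessParams
) -> Tuple[List[SeqRecord], int]:
    """Keep reads with mean Phred >= threshold and no N; order preserved."""
    kept: List[SeqRecord] = []
    n_discarded = 0
    for r in reads:
        if r.qual is None:
            raise ValueError(f"read {r.id!r} has no quality scores")
        if "N" in r.seq or r.mean_qual() < params.min_mean_qual:
            n_discarded += 1
        else:
            kept.append(r)
    return kept, n_discarded


def _match_mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def find_and_trim_adapter3(read: SeqRecord, params: PreprocessParams) -> object:
    """Locate the 3' adapter and return the upstream insert.

    Scans every offset; a candidate match is the full adapter (internal) or
    an adapter prefix reaching the read's 3' end (suffix-anchored), with
    overlap >= ``adapter_min_overlap`` and mismatch rate <=
    ``adapter_max_mismatch_rate``.  The best match minimises mismatch rate,
    then maximises overlap, then is leftmost.  Returns the insert
    :class:`SeqRecord`, or ``ADAPTER_NULL`` if no match, or ``INSERT_NULL``
    for a zero-length insert (adapter at position 0).
    """
    seq = to_rna(read.seq)
    adapter = params.adapter3
    best = None  # (mismatch_rate, -overlap, position)
    for i in range(0, len(seq) - params.adapter_min_overlap + 1):
        overlap = min(len(adapter), len(seq) - i)
        mm = _match_mismatches(seq[i : i + overlap], adapter[:overlap])
        rate = mm / overlap
        if rate <= params.adapter_max_mismatch_rate:
            key = (rate, -overlap, i)
            if best is None or key < best:
                best = key
    if best is None:
        return ADAPTER_NULL
    pos = best[2]
    if pos == 0:
        return INSERT_NULL
    qual = read.qual[:pos] if read.qual is not None else None
    return SeqRecord(id=read.id, seq=seq[:pos], qual=qual)


def is_adapter5_contaminant(insert: SeqRecord, params: PreprocessParams) -> bool:
    """True iff the insert starts with a suffix of the 5' adapter."""
    seq = to_rna(insert.seq)
    adapter = params.adapter5
    max_ov = min(len(adapter), len(seq))
    for overlap in range(max_ov, params.adapter_min_overlap - 1, -1):
        mm = _match_mismatches(seq[:overlap], adapter[-overlap:])
        if mm / overlap <= params.adapter_max_mismatch_rate:
            return True
    return False


def is_polyA(insert: SeqRecord, params: PreprocessParams) -> bool:
    """True iff the fraction of A in the insert is >= polyA_frac."""
    seq = insert.seq.upper()
    return seq.count("A") / len(seq) >= params.polyA_frac


# ---------------------------------------------------------------------------
# the cascade
# ---------------------------------------------------------------------------

def run_cascade(
    reads: Iterable[SeqRecord], params: Optional[PreprocessParams] = None
) -> Tuple[List[UniqueTag], LibraryStats]:
    """Run the full cleanup cascade and collapse clean inserts to tags.

    Fixed order: quality -> 3' adapter -> insert-null -> 5' contaminant ->
    poly(A) -> length window -> collapse.  Stats categories are mutually
    exclusive and, together with ``total_clean``, sum to ``total_raw``.
    """
    params = params or PreprocessParams()
    stats = LibraryStats()
    clean_counter: Counter = Counter()

    for read in reads:
        stats.total_raw += 1
        if read.qual is None:
            raise ValueError(f"read {read.id!r} has no quality scores")
        if "N" in read.seq or read.mean_qual() < params.min_mean_qual:
            stats.low_quality += 1
            continue
        stats.high_quality += 1
        insert = find_and_trim_adapter3(read, params)
        if insert is ADAPTER_NULL:
            stats.adaptor3_null += 1
            continue
        if insert is INSERT_NULL:
            stats.insert_null += 1
            continue
        if is_adapter5_contaminant(insert, params):
            stats.adaptor5_contaminant += 1
            continue
        if is_polyA(insert, params):
            stats.polyA += 1
            continue
        if len(insert.seq) < params.min_len:
            stats.small_insert += 1
            continue
        if len(insert.seq) > params.max_len:
            stats.long_insert += 1
            continue
        stats.total_clean += 1
        clean_counter[to_rna(insert.seq)] += 1

    tags = [
        UniqueTag(seq=s, count=c)
        for s, c in sorted(clean_counter.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    stats.unique_18_30 = len(tags)
    stats.singletons = sum(1 for t in tags if t.count == 1)
    stats.unique_multi = stats.unique_18_30 - stats.singletons
    return tags, stats


def singleton_fraction(tags: List[UniqueTag]) -> Tuple[float, int]:
    """(fraction of tags seen exactly once, integer-rounded percent)."""
    if not tags:
        raise ValueError("singleton_fraction of empty tag list is undefined")
    n_single = sum(1 for t in tags if t.count == 1)
    frac = n_single / len(tags)
    return frac, int(percent(n_single, len(tags), 0))
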