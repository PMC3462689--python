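"""Conserved miRNA identification by mismatch-bounded homology.

Candidate tags are compared against a database of known mature plant
miRNAs with an exact mismatch-bounded search (ungapped, with a small
end-shift tolerance for isomiR-style offsets).  Perfect matches are
accepted outright; homologous (non-identical) hits additionally require a
hairpin-passing precursor in the transcriptome.  Families follow miRBase
nomenclature: the numeric core of the name (miR156a -> MIR156), with an
optional user merge map for families treated jointly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._util import percent, to_rna
from .hairpin import HairpinParams, find_precursor
from .io_formats import SeqRecord, UniqueTag

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}


@dataclass
class HomologyParams:
    max_mismatch: int = 2        # "fewer than 3 mismatches"
    allow_shift: int = 2         # end-shift tolerance, nt
    require_precursor: bool = True

    def __post_init__(self) -> None:
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")


@dataclass
class ConservedMirna:
    name: str
    mature: UniqueTag
    family: str
    source_hit: str
    mismatches: int
    has_5prime_U: bool
    precursor_id: Optional[str] = None


class MatureDb:
    """Known mature miRNAs, pre-encoded for fast per-tag comparison."""

    def __init__(self, records: Sequence[SeqRecord]) -> None:
        self.ids = [r.id for r in records]
        self.seqs = [to_rna(r.seq) for r in records]
        self._by_len: Dict[int, Tuple[List[int], np.ndarray]] = {}
        for idx, s in enumerate(self.seqs):
            self._by_len.setdefault(len(s), ([], None))[0].append(idx)
        for length, (idxs, _) in list(self._by_len.items()):
            arr = np.array(
                [[_BASE_CODE[c] for c in self.seqs[i]] for i in idxs], dtype=np.int8
            )
            self._by_len[length] = (idxs, arr)

    def __len__(self) -> int:
        return len(self.ids)


def _shift_mismatches(tag: str, entry: str, shift: int) -> int:
    """Mismatches of an ungapped comparison at relative offset ``shift``.

    ``shift`` is the offset of the tag's first base relative to the entry's
    first base.  Unaligned tag bases count as mismatches, so a shifted or
    truncated comparison can never beat an equal-length identical one.
    """
    n = len(tag)
    lo = max(0, shift)
    hi = min(n + shift, len(entry))
    overlap = hi - lo
    if overlap <= 0:
        return n
    t = tag[lo - shift : hi - shift]
    e = entry[lo:hi]
    mm = sum(1 for a, b in zip(t, e) if a != b)
    return mm + (n - overlap)


def match_known(
    tag: UniqueTag, db: MatureDb, params: Optional[HomologyParams] = None
) -> Optional[Tuple[str, int]]:
    """Best known-miRNA hit: fewest mismatches over all entries and shifts.

    Ties are broken by database order, then by smaller |shift|.  Returns
    None when the minimum exceeds ``max_mismatch``.
    """
    params = params or HomologyParams()
    q = to_rna(tag.seq)
    qarr = np.array([_BASE_CODE[c] for c in q], dtype=np.int8)
    n = len(q)
    best_mm = params.max_mismatch + 1
    best_idx = -1
    shifts = sorted(range(-params.allow_shift, params.allow_shift + 1), key=abs)
    for length, (idxs, arr) in db._by_len.items():
        for shift in shifts:
            lo = max(0, shift)
            hi = min(n + shift, length)
            overlap = hi - lo
            if overlap <= 0:
                continue
            extra = n - overlap
            if extra >= best_mm:
                continue
            mm = (arr[:, lo:hi] != qarr[lo - shift : hi - shift]).sum(axis=1) + extra
            k = int(np.argmin(mm))
            m = int(mm[k])
            # scan for the earliest db index achieving the minimum
            winners = np.flatnonzero(mm == m)
            cand_idx = min(idxs[w] for w in winners)
            if m < best_mm or (m == best_mm and cand_idx < best_idx):
                best_mm = m
                best_idx = cand_idx
    if best_mm > params.max_mismatch:
        return None
    return db.ids[best_idx], best_mm


_FAMILY_RE = re.compile(r"^(?:[a-z]{1,5}-)?mir(n?)(\d+)", re.IGNORECASE)


def assign_family(source_id: str, merge_map: Optional[Dict[str, str]] = None) -> str:
    """miRBase-style id -> family ("ath-miR156a" -> "MIR156").

    Letters and numeric suffixes after the core are stripped; miR156 and
    miR157 stay distinct families unless merged via ``merge_map``.
    """
    m = _FAMILY_RE.match(source_id.strip())
    if not m:
        raise ValueError(f"cannot parse miRNA id {source_id!r}")
    fam = f"MIR{'n' if m.group(1) else ''}{m.group(2)}"
    if merge_map and fam in merge_map:
        return merge_map[fam]
    return fam


def identify_conserved(
    tags: Sequence[UniqueTag],
    db: MatureDb,
    params: Optional[HomologyParams] = None,
    transcripts: Sequence[SeqRecord] = (),
    hairpin_params: Optional[HairpinParams] = None,
    prefix: str = "cln",
    merge_map: Optional[Dict[str, str]] = None,
) -> List[ConservedMirna]:
    """Call conserved miRNAs among tags.

    Identical hits pass without precursor support; homologous hits must
    have a hairpin-passing precursor in ``transcripts`` when
    ``require_precursor`` is set.  Output names are ``<prefix>-<source>``
    suffixed per family member in order of discovery.
    """
    params = params or HomologyParams()
    out: List[ConservedMirna] = []
    seen_seqs = set()
    used_names: Dict[str, int] = {}
    for tag in tags:
        if not (18 <= len(tag.seq) <= 26) or tag.seq in seen_seqs:
            continue
        hit = match_known(tag, db, params)
        if hit is None:
            continue
        source_id, mm = hit
        precursor_id = None
        if mm > 0 and params.require_precursor:
            cand = find_precursor(tag, transcripts, hairpin_params)
            if cand is None:
                continue
            precursor_id = cand.transcript_id
        seen_seqs.add(tag.seq)
        stem = source_id.split("-", 1)[-1]
        name = f"{prefix}-{stem}"
        used_names[name] = used_names.get(name, 0) + 1
        if used_names[name] > 1:  # distinct sequence variants of one source
            name = f"{name}.{used_names[name]}"
        out.append(
            ConservedMirna(
                name=name,
                mature=tag,
                family=assign_family(source_id, merge_map),
                source_hit=source_id,
                mismatches=mm,
                has_5prime_U=to_rna(tag.seq).startswith("U"),
                precursor_id=precursor_id,
            )
        )
    return out


def five_prime_u_fraction(mirnas: Sequence[ConservedMirna]) -> Tuple[int, float, int]:
    """(count starting with U, fraction, percent rounded half-up)."""
    if not mirnas:
        raise ValueError("five_prime_u_fraction of empty list is undefined")
    count = sum(1 for m in mirnas if m.has_5prime_U)
    return count, count / len(mirnas), int(percent(count, len(mirnas), 0))


def family_census(mirnas: Sequence[ConservedMirna]) -> pd.DataFrame:
    """Family -> distinct member count; multi-member family count attached.

    The frame carries one row per family plus ``attrs['n_multi_member']``.
    """
    names: Dict[str, set] = {}
    for m in mirnas:
        names.setdefault(m.family, set()).add(m.name)
    fams = sorted(names)
    df = pd.DataFrame(
        {"members": [len(names[f]) for f in fams]},
        index=pd.Index(fams, name="family"),
    )
    df.attrs["n_multi_member"] = int((df["members"] > 1).sum())
    return df
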