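"""Mapping of 5'-RACE clone ends onto predicted miRNA target sites.

Slicer-type cleavage leaves the 3' fragment's 5' end at the phosphodiester
bond opposite miRNA positions 10-11; we label that boundary offset 10.  A
clone whose 5' end falls inside the binding site gets an offset in miRNA
coordinates; ends outside the site are reported in transcript-relative nt
upstream/downstream of the canonical boundary.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .targets import TargetHit

CANONICAL_OFFSET = 10


@dataclass
class RaceClone:
    clone_id: str
    transcript_id: str
    five_prime_pos: int  # 1-based transcript coordinate of the fragment 5' end


#: an in-site offset (int, miRNA coordinates) or ("downstream"/"upstream", nt)
Offset = Union[int, Tuple[str, int]]


def canonical_position(site: TargetHit) -> int:
    """Transcript coordinate of the 3'-fragment 5' end for canonical cleavage."""
    return site.site_span[1] - CANONICAL_OFFSET + 1


def map_clone(clone: RaceClone, site: TargetHit) -> Offset:
    """Express a clone 5' end relative to the miRNA binding site.

    Inside the site, offset k means the clone end sits opposite miRNA
    position k (offset 10 = canonical cleavage between positions 10/11).
    Outside, the offset is reported relative to the canonical boundary in
    transcript nt ("downstream" = toward the transcript 3' end).
    """
    if clone.transcript_id != site.transcript_id:
        raise ValueError(
            f"clone {clone.clone_id} maps to {clone.transcript_id}, "
            f"site is on {site.transcript_id}"
        )
    s, e = site.site_span
    pos = clone.five_prime_pos
    if s <= pos <= e:
        return e - pos + 1
    canon = canonical_position(site)
    delta = pos - canon
    return ("downstream", delta) if delta > 0 else ("upstream", -delta)


def offset_to_position(offset: int, site: TargetHit) -> int:
    """Inverse of map_clone for in-site offsets (transcript coordinate)."""
    return site.site_span[1] - offset + 1


@dataclass
class CleavageTally:
    site: TargetHit
    per_offset: Dict[Offset, int]
    canonical_count: int
    total: int
    classification: str  # "canonical" | "shifted(k)" | "dispersed"


def tally(clones: Sequence[RaceClone], site: TargetHit) -> CleavageTally:
    """Histogram clone ends over a site and classify the cleavage pattern.

    canonical: the modal offset is 10 with a strict plurality; shifted(k):
    modal offset k != 10 with a strict plurality; dispersed: no strict
    plurality (ties included).
    """
    if not clones:
        raise ValueError("tally of an empty clone set is undefined")
    counts: Counter = Counter(map_clone(c, site) for c in clones)
    total = sum(counts.values())
    ranked = counts.most_common()
    top_offset, top_n = ranked[0]
    strict = len(ranked) == 1 or ranked[1][1] < top_n
    if not strict:
        classification = "dispersed"
    elif top_offset == CANONICAL_OFFSET:
        classification = "canonical"
    else:
        classification = f"shifted({top_offset})"
    return CleavageTally(
        site=site,
        per_offset=dict(counts),
        canonical_count=counts.get(CANONICAL_OFFSET, 0),
        total=total,
        classification=classification,
    )


# ---------------------------------------------------------------------------
# TSV plumbing
# ---------------------------------------------------------------------------

CLONE_COLUMNS = ["clone_id", "transcript_id", "five_prime_pos"]


def read_clones(path) -> List[RaceClone]:
    df = pd.read_csv(path, sep="\t")
    missing = set(CLONE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        RaceClone(str(r.clone_id), str(r.transcript_id), int(r.five_prime_pos))
        for r in df.itertuples()
    ]


def write_tally(tallies: Sequence[CleavageTally], path) -> None:
    rows = []
    for t in tallies:
        for off, n in sorted(t.per_offset.items(), key=lambda kv: str(kv[0])):
            rows.append(
                {
                    "transcript_id": t.site.transcript_id,
                    "mirna_id": t.site.mirna_id,
                    "offset": off if isinstance(off, int) else f"{off[1]}_{off[0]}",
                    "clones": n,
                    "classification": t.classification,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
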