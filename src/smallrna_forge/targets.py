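"""Penalty-scored miRNA target prediction (miRU/psRNATarget-style).

A miRNA is aligned antiparallel against a candidate transcript window.
Each duplex column contributes a penalty: 0 for a Watson-Crick pair, 0.5
for a G:U wobble, 1 for a mismatch, 2 for a gap; penalties within the seed
(miRNA positions 2-7 from the 5' end) are doubled.  At most one gap is
allowed - either a bulged target base (site one nt longer) or an unpaired
miRNA base (site one nt shorter).  By default no gap may sit opposite
miRNA positions 10-11 (the cleavage site) and no more than 2 consecutive
mismatches are tolerated.  Sites scoring at or below the cutoff (default
4.0) are putative targets; all penalties live on a 0.5 lattice, which is
why reported scores print with one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._util import to_rna
from .io_formats import SeqRecord

_BASE = {"A": 0, "C": 1, "G": 2, "U": 3}
_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class ScoringScheme:
    mismatch_penalty: float = 1.0
    gu_penalty: float = 0.5
    gap_penalty: float = 2.0
    seed_start: int = 2              # 1-based from the miRNA 5' end
    seed_end: int = 7
    seed_multiplier: float = 2.0
    max_gaps: int = 1
    cutoff: float = 4.0
    forbid_gap_at_cleavage: bool = True   # no gap opposite positions 10-11
    max_consecutive_mismatch: int = 2     # 0 disables the rule


@dataclass
class TargetHit:
    mirna_id: str
    transcript_id: str
    site_span: Tuple[int, int]   # 1-based closed, on the transcript
    score: float
    alignment: List[str]         # duplex columns 5'->3' of the miRNA: WC/GU/MM/GAP
    site_seq: str = ""


def _pair_state(m: str, t: str) -> str:
    if (m, t) in _WC:
        return "WC"
    if (m, t) in _GU:
        return "GU"
    return "MM"


def _column_penalty(state: str, gov_pos: int, scheme: ScoringScheme) -> float:
    base = {
        "WC": 0.0,
        "GU": scheme.gu_penalty,
        "MM": scheme.mismatch_penalty,
        "GAP": scheme.gap_penalty,
    }[state]
    if scheme.seed_start <= gov_pos <= scheme.seed_end:
        base *= scheme.seed_multiplier
    return base


def _score_columns(
    cols: List[Tuple[int, str]], scheme: ScoringScheme
) -> Optional[float]:
    """Sum column penalties; None if the consecutive-mismatch rule trips."""
    run = 0
    for _, st in cols:
        run = run + 1 if st == "MM" else 0
        if scheme.max_consecutive_mismatch and run > scheme.max_consecutive_mismatch:
            return None
    return sum(_column_penalty(st, pos, scheme) for pos, st in cols)


def score_site(
    mirna: str, site: str, scheme: Optional[ScoringScheme] = None
) -> Tuple[float, List[str]]:
    """Minimum-penalty alignment of a miRNA against one site.

    ``site`` is the transcript subsequence in mRNA orientation (5'->3');
    the miRNA binds antiparallel, so miRNA position 1 faces the site's
    last base.  Returns (score, duplex column states ordered 5'->3' along
    the miRNA); infeasible windows score ``inf``.  Ties prefer fewer
    gaps, then the leftmost gap.
    """
    scheme = scheme or ScoringScheme()
    m = to_rna(mirna)
    s = to_rna(site)
    if "N" in m or "N" in s:
        raise ValueError("sequences with N cannot be scored")
    if abs(len(s) - len(m)) > scheme.max_gaps:
        raise ValueError("site/miRNA length difference exceeds max_gaps")
    t = s[::-1]  # t[i] faces miRNA position i+1
    n = len(m)

    best: Optional[Tuple[float, int, int, List[str]]] = None

    def consider(cols: List[Tuple[int, str]], ngaps: int, gappos: int) -> None:
        nonlocal best
        score = _score_columns(cols, scheme)
        if score is None:
            return
        key = (score, ngaps, gappos)
        if best is None or key < (best[0], best[1], best[2]):
            best = (score, ngaps, gappos, [st for _, st in cols])

    if len(t) == n:
        consider([(i + 1, _pair_state(m[i], t[i])) for i in range(n)], 0, 0)
    elif len(t) == n + 1:
        # one bulged target base: t[g] skipped, GAP column before miRNA g+1
        for g in range(0, n + 1):
            gov = min(g + 1, n)
            if scheme.forbid_gap_at_cleavage and gov in (10, 11):
                continue
            cols: List[Tuple[int, str]] = []
            for i in range(n):
                if i == g:
                    cols.append((gov, "GAP"))
                ti = t[i] if i < g else t[i + 1]
                cols.append((i + 1, _pair_state(m[i], ti)))
            if g == n:
                cols.append((gov, "GAP"))
            consider(cols, 1, gov)
    elif len(t) == n - 1:
        # one unpaired miRNA base g (1-based)
        for g in range(1, n + 1):
            if scheme.forbid_gap_at_cleavage and g in (10, 11):
                continue
            cols = []
            for i in range(n):
                if i == g - 1:
                    cols.append((i + 1, "GAP"))
                else:
                    ti = t[i] if i < g - 1 else t[i - 1]
                    cols.append((i + 1, _pair_state(m[i], ti)))
            consider(cols, 1, g)
    if best is None:
        return float("inf"), []
    return best[0], best[3]


# ---------------------------------------------------------------------------
# vectorised transcript scan
# ---------------------------------------------------------------------------

def _penalty_matrix(scheme: ScoringScheme) -> np.ndarray:
    P = np.full((4, 4), scheme.mismatch_penalty)
    for (a, b) in _WC:
        P[_BASE[a], _BASE[b]] = 0.0
    for (a, b) in _GU:
        P[_BASE[a], _BASE[b]] = scheme.gu_penalty
    return P


def _candidate_offsets(
    mcode: np.ndarray, scode: np.ndarray, scheme: ScoringScheme
) -> List[Tuple[int, int]]:
    """(start, width) windows whose best alignment can be <= cutoff.

    One vectorised pass per gap pattern, ignoring the consecutive-mismatch
    rule (which only removes hits); the exact scorer confirms each
    candidate.
    """
    n = len(mcode)
    L = len(scode)
    P = _penalty_matrix(scheme)
    mult = np.array(
        [
            scheme.seed_multiplier
            if scheme.seed_start <= i + 1 <= scheme.seed_end
            else 1.0
            for i in range(n)
        ]
    )
    out = set()

    def scan_pattern(
        width: int,
        mc: np.ndarray,
        site_idx: np.ndarray,
        weights: np.ndarray,
        extra: float,
    ) -> None:
        if L - width + 1 <= 0:
            return
        windows = np.lib.stride_tricks.sliding_window_view(scode, width)
        pen = (P[mc[None, :], windows[:, site_idx]] * weights[None, :]).sum(
            axis=1
        ) + extra
        for s in np.flatnonzero(pen <= scheme.cutoff):
            out.add((int(s), width))

    # ungapped: miRNA position i+1 faces the window's (n-1-i)-th base
    scan_pattern(n, mcode, np.arange(n - 1, -1, -1), mult, 0.0)
    if scheme.max_gaps >= 1:
        # bulged target base (width n+1): reversed-site index g skipped
        for g in range(0, n + 1):
            gov = min(g + 1, n)
            if scheme.forbid_gap_at_cleavage and gov in (10, 11):
                continue
            tidx = [i if i < g else i + 1 for i in range(n)]
            site_idx = np.array([n - k for k in tidx])
            extra = _column_penalty("GAP", gov, scheme)
            scan_pattern(n + 1, mcode, site_idx, mult, extra)
        # unpaired miRNA base g (width n-1)
        for g in range(1, n + 1):
            if scheme.forbid_gap_at_cleavage and g in (10, 11):
                continue
            keep = [i for i in range(n) if i != g - 1]
            tidx = [i if i < g - 1 else i - 1 for i in keep]
            site_idx = np.array([n - 2 - k for k in tidx])
            extra = _column_penalty("GAP", g, scheme)
            scan_pattern(n - 1, mcode[keep], site_idx, mult[keep], extra)
    return sorted(out)


def scan_transcript(
    mirna_id: str,
    mirna: str,
    transcript: SeqRecord,
    scheme: Optional[ScoringScheme] = None,
    min_separation: int = 5,
) -> List[TargetHit]:
    """All target sites of a miRNA on one transcript.

    Overlapping windows are reduced to local score minima separated by at
    least ``min_separation`` nt (ties keep the leftmost site).
    """
    scheme = scheme or ScoringScheme()
    m = to_rna(mirna)
    seq = to_rna(transcript.seq)
    n = len(m)
    if len(seq) < n - scheme.max_gaps or "N" in seq:
        return []
    mcode = np.array([_BASE[c] for c in m], dtype=np.int64)
    scode = np.array([_BASE[c] for c in seq], dtype=np.int64)
    raw: List[TargetHit] = []
    for start, width in _candidate_offsets(mcode, scode, scheme):
        site = seq[start : start + width]
        score, states = score_site(m, site, scheme)
        if score <= scheme.cutoff:
            raw.append(
                TargetHit(
                    mirna_id=mirna_id,
                    transcript_id=transcript.id,
                    site_span=(start + 1, start + width),
                    score=score,
                    alignment=states,
                    site_seq=site,
                )
            )
    raw.sort(key=lambda h: (h.site_span[0], h.site_span[1]))
    out: List[TargetHit] = []
    for hit in raw:
        if out and hit.site_span[0] - out[-1].site_span[0] < min_separation:
            if hit.score < out[-1].score:
                out[-1] = hit
        else:
            out.append(hit)
    return out


def predict_targets(
    mirnas: Sequence[Tuple[str, str, str]],   # (mirna_id, family, sequence)
    transcripts: Sequence[SeqRecord],
    scheme: Optional[ScoringScheme] = None,
) -> pd.DataFrame:
    """Family-level target table, deduplicated per (family, transcript).

    The union of member hits is taken per family and the best (lowest)
    score per transcript kept, matching how per-family target lists with
    parenthesised scores are reported.
    """
    scheme = scheme or ScoringScheme()
    best: Dict[Tuple[str, str], TargetHit] = {}
    for mirna_id, family, seq in mirnas:
        for tr in transcripts:
            for hit in scan_transcript(mirna_id, seq, tr, scheme):
                key = (family, tr.id)
                if key not in best or hit.score < best[key].score:
                    best[key] = hit
    rows = [
        {
            "family": fam,
            "transcript_id": tid,
            "mirna_id": h.mirna_id,
            "start": h.site_span[0],
            "end": h.site_span[1],
            "score": round(h.score, 1),
        }
        for (fam, tid), h in sorted(best.items())
    ]
    return pd.DataFrame(
        rows, columns=["family", "transcript_id", "mirna_id", "start", "end", "score"]
    )
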