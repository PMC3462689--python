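"""Pre-miRNA hairpin evaluation and novel miRNA calling.

A candidate precursor passes when it folds into a single dominant stem-loop
with MFE at or below a threshold (default -30 kcal/mol), a minimal folding
free energy index (MFEI) of at least 0.60, and - when a mature sequence is
supplied - the mature sits on one arm of the stem, does not span the
terminal loop, and pairs to a contiguous miRNA* region with the 2-nt 3'
overhang geometry that marks a Dicer product.

MFEI = AMFE / GC%, with AMFE = |MFE| / length * 100 and GC% on the 0-100
scale; values around 0.6-1.2 are characteristic of plant pre-miRNAs and
separate them from mRNA fragments and other structured RNAs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

from ._util import gc_percent, revcomp, to_rna
from .fold import FoldResult, fold
from .io_formats import SeqRecord, UniqueTag


def amfe(mfe: float, length: int) -> float:
    """Adjusted MFE: |MFE| per 100 nt."""
    if length <= 0:
        raise ValueError("length must be positive")
    return abs(mfe) / length * 100.0


def mfei(mfe: float, length: int, gc_pct: float) -> float:
    """Minimal folding free energy index: AMFE / GC% (GC on 0-100 scale)."""
    if mfe == 0:
        return 0.0
    if gc_pct == 0:
        raise ZeroDivisionError("MFEI undefined for GC% of 0")
    if not (0 < gc_pct < 100):
        raise ValueError("gc_pct must be in (0, 100)")
    return amfe(mfe, length) / gc_pct


@dataclass
class HairpinParams:
    """Filter thresholds; MFE-related values are fold-engine-relative."""

    mfe_max: float = -30.0           # kcal/mol; pass iff mfe <= mfe_max
    mfei_min: float = 0.60
    max_duplex_mismatch: int = 4     # unpaired mature bases tolerated
    min_duplex_run: int = 8          # shortest acceptable contiguous helix
    require_single_stem: bool = True
    min_mature_len: int = 18
    max_mature_len: int = 25
    window_up: int = 20              # excision window upstream of the mature
    window_down: int = 160
    max_precursor_len: int = 300
    engine: str = "builtin"


@dataclass
class DuplexGeometry:
    """Placement of the miRNA/miRNA* duplex on the precursor.

    Spans are 1-based closed intervals on the precursor.  The star span is
    read off the pairing partners of the mature with the 2-nt 3' offset on
    both strands, so the overhang fields record the Dicer signature the
    construction encodes.
    """

    mature_span: Tuple[int, int]
    star_span: Tuple[int, int]
    overhang3_mature: int
    overhang3_star: int
    n_mismatch_in_duplex: int
    mature_in_loop: bool = False


@dataclass
class HairpinReport:
    fold: FoldResult
    length: int
    gc_percent: float
    amfe: float
    mfei: float
    n_stems: int
    mature_arm: str                      # "5p" | "3p" | "none"
    duplex: Optional[DuplexGeometry]
    passes: bool
    failed_criteria: List[str] = field(default_factory=list)


def mature_spans_loop(result: FoldResult, mature_span: Tuple[int, int]) -> bool:
    """True if the mature folds back on itself (straddles the terminal loop)."""
    m5, m3 = mature_span
    return any(
        (p := result.partner(pos)) is not None and m5 <= p <= m3
        for pos in range(m5, m3 + 1)
    )


def find_duplex(
    result: FoldResult,
    mature_span: Tuple[int, int],
    max_duplex_mismatch: int = 4,
    min_duplex_run: int = 8,
) -> Optional[DuplexGeometry]:
    """Locate the miRNA* of a mature span from the fold's pairing table.

    The star is the contiguous region pairing the mature, shifted 2 nt
    toward its own 3' end (so each strand of the excised duplex carries a
    2-nt 3' overhang).  Returns None when the mature overlaps the terminal
    loop, has more than ``max_duplex_mismatch`` unpaired bases, its
    partners are not contiguous enough to form a duplex, or no contiguous
    helix of at least ``min_duplex_run`` base pairs exists (chance
    complementarity yields fragmented runs; a Dicer substrate does not).
    """
    m5, m3 = mature_span
    n = len(result.seq)
    if not (1 <= m5 <= m3 <= n):
        raise ValueError("mature_span outside the precursor")
    mature_len = m3 - m5 + 1
    if mature_spans_loop(result, mature_span):
        return None

    # A Dicer duplex is an antiparallel helix with substitution mismatches
    # only: every mature/star pair must lie on one pairing diagonal
    # (pos + partner = const).  Bases that are unpaired, captured by the
    # opposite flank, or paired off-diagonal (i.e. via bulges) all count as
    # duplex mismatches.  This deliberately rejects chance bulged helices.
    partners = [result.partner(pos) for pos in range(m5, m3 + 1)]
    diagonals = Counter(
        (m5 + k) + p
        for k, p in enumerate(partners)
        if p is not None and not (m5 <= p <= m3)
    )
    if not diagonals:
        return None
    diag, n_on_diag = diagonals.most_common(1)[0]
    unpaired = mature_len - n_on_diag
    if unpaired > max_duplex_mismatch:
        return None
    run = best_run = 0
    for k in range(mature_len):
        if partners[k] is not None and (m5 + k) + partners[k] == diag:
            run += 1
            best_run = max(best_run, run)
        else:
            run = 0
    if best_run < min(min_duplex_run, mature_len):
        return None

    # the star with its 2-nt 3' overhang, read off the diagonal
    star_lo = diag - (m3 - 2)
    star_hi = diag - m5 + 2
    if star_lo < 1 or star_hi > n or star_lo > star_hi:
        return None
    return DuplexGeometry(
        mature_span=(m5, m3),
        star_span=(star_lo, star_hi),
        overhang3_mature=2,
        overhang3_star=2,
        n_mismatch_in_duplex=unpaired,
    )


def _terminal_loops(result: FoldResult, region: Optional[Tuple[int, int]] = None) -> int:
    """Number of hairpin (terminal) loops, optionally restricted to a region."""
    lo, hi = region if region else (1, len(result.seq))
    count = 0
    pt = result.pair_table
    for i, j in enumerate(pt):
        if j > i:  # closing pair (i, j), 0-based
            if all(pt[k] < 0 for k in range(i + 1, j)):
                if lo <= i + 1 and j + 1 <= hi:
                    count += 1
    return count


def evaluate_precursor(
    seq: str,
    mature=None,
    params: Optional[HairpinParams] = None,
) -> HairpinReport:
    """Fold a candidate precursor and apply all hairpin criteria.

    ``mature`` may be a sequence (located by exact search) or a 1-based
    closed span.  Failures never raise; they are listed in
    ``failed_criteria`` and reflected in ``passes``.
    """
    params = params or HairpinParams()
    rna = to_rna(seq)
    result = fold(rna, engine=params.engine)
    length = len(rna)
    gc = gc_percent(rna)
    a = amfe(result.mfe, length)
    fi = mfei(result.mfe, length, gc) if 0 < gc < 100 else 0.0

    failed: List[str] = []
    if result.mfe > params.mfe_max:
        failed.append("MFE")
    if fi < params.mfei_min:
        failed.append("MFEI")

    duplex = None
    mature_arm = "none"
    mature_span: Optional[Tuple[int, int]] = None
    if mature is not None:
        if isinstance(mature, str):
            pos = rna.find(to_rna(mature))
            if pos < 0:
                raise ValueError("mature sequence not found in precursor")
            mature_span = (pos + 1, pos + len(mature))
        else:
            mature_span = (int(mature[0]), int(mature[1]))
        if mature_spans_loop(result, mature_span):
            failed.append("mature_in_loop")
        duplex = find_duplex(
            result, mature_span, params.max_duplex_mismatch, params.min_duplex_run
        )
        if duplex is None:
            if "mature_in_loop" not in failed:
                failed.append("duplex")
        else:
            partners = [
                result.partner(p)
                for p in range(mature_span[0], mature_span[1] + 1)
                if result.partner(p) is not None
            ]
            n_down = sum(1 for p in partners if p > mature_span[1])
            mature_arm = "5p" if n_down >= len(partners) - n_down else "3p"

    if mature_span is not None and duplex is not None:
        region = (
            min(mature_span[0], duplex.star_span[0]),
            max(mature_span[1], duplex.star_span[1]),
        )
        n_stems = _terminal_loops(result, region)
    else:
        n_stems = _terminal_loops(result)
    if params.require_single_stem and n_stems != 1:
        failed.append("n_stems")

    return HairpinReport(
        fold=result,
        length=length,
        gc_percent=gc,
        amfe=a,
        mfei=fi,
        n_stems=n_stems,
        mature_arm=mature_arm,
        duplex=duplex,
        passes=not failed,
        failed_criteria=failed,
    )


# ---------------------------------------------------------------------------
# novel miRNA detection
# ---------------------------------------------------------------------------

@dataclass
class NovelCandidate:
    mature: UniqueTag
    transcript_id: str
    strand: str
    precursor_span: Tuple[int, int]  # 1-based closed on the (oriented) transcript
    report: HairpinReport


def _excision_windows(
    seq: str, hit_start: int, mature_len: int, params: HairpinParams
) -> Iterable[Tuple[int, int]]:
    """Candidate precursor windows (0-based half-open) around a mature hit.

    The two wide windows put the mature near the 5' or 3' end of a long
    precursor; the two narrow ones cover compact hairpins whose stems a
    maximum-pairing fold would otherwise trade against long-range context
    pairs.
    """
    for up, down in ((params.window_up, params.window_down),
                     (params.window_down, params.window_up),
                     (30, 80), (80, 30)):
        lo = max(0, hit_start - up)
        hi = min(len(seq), hit_start + mature_len + down)
        if hi - lo <= params.max_precursor_len and hi - lo >= mature_len + 20:
            yield lo, hi


def candidate_precursors(
    tag: UniqueTag,
    transcripts: Sequence[SeqRecord],
    params: Optional[HairpinParams] = None,
):
    """Yield (transcript_id, strand, window_span, precursor_seq, mature_offset)
    for every perfect mapping of the tag, on either strand."""
    params = params or HairpinParams()
    q = to_rna(tag.seq)
    for rec in transcripts:
        for strand in "+-":
            seq = to_rna(rec.seq) if strand == "+" else revcomp(to_rna(rec.seq))
            start = seq.find(q)
            while start >= 0:
                for lo, hi in _excision_windows(seq, start, len(q), params):
                    yield (
                        rec.id,
                        strand,
                        (lo + 1, hi),
                        seq[lo:hi],
                        start - lo,
                    )
                start = seq.find(q, start + 1)


def find_precursor(
    tag: UniqueTag,
    transcripts: Sequence[SeqRecord],
    params: Optional[HairpinParams] = None,
) -> Optional[NovelCandidate]:
    """First hairpin-passing precursor for a tag, or None."""
    params = params or HairpinParams()
    for tid, strand, span, pre, offset in candidate_precursors(tag, transcripts, params):
        report = evaluate_precursor(
            pre, mature=(offset + 1, offset + len(tag.seq)), params=params
        )
        if report.passes:
            return NovelCandidate(
                mature=tag,
                transcript_id=tid,
                strand=strand,
                precursor_span=span,
                report=report,
            )
    return None


def detect_novel(
    tags: Iterable[UniqueTag],
    transcripts: Sequence[SeqRecord],
    known_precursors: Sequence[SeqRecord] = (),
    params: Optional[HairpinParams] = None,
) -> List[NovelCandidate]:
    """Call novel miRNAs among tags already depleted of ncRNA/repeat classes.

    A tag qualifies when a flanking window around one of its perfect
    transcript mappings passes all hairpin criteria with the tag as mature.
    Tags found inside a known precursor are conserved, not novel, and are
    excluded.
    """
    params = params or HairpinParams()
    known = [to_rna(r.seq) for r in known_precursors]
    out: List[NovelCandidate] = []
    for tag in tags:
        if not (params.min_mature_len <= len(tag.seq) <= params.max_mature_len):
            continue
        q = to_rna(tag.seq)
        if any(q in k or revcomp(q) in k for k in known):
            continue
        cand = find_precursor(tag, transcripts, params)
        if cand is not None:
            out.append(cand)
    return out
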