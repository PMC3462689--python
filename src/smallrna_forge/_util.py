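"""Shared helpers: alphabet handling, rounding, percentages."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

RNA_ALPHABET = set("ACGUN")
DNA_ALPHABET = set("ACGTN")

_COMPLEMENT_RNA = str.maketrans("ACGUN", "UGCAN")
_COMPLEMENT_DNA = str.maketrans("ACGTN", "TGCAN")


def to_rna(seq: str) -> str:
    """Convert a nucleotide string to the internal RNA alphabet (T -> U)."""
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    """Reverse complement; works on RNA (U) and DNA (T) strings alike."""
    s = seq.upper()
    if "U" in s or ("T" not in s):
        return s.translate(_COMPLEMENT_RNA)[::-1]
    return s.translate(_COMPLEMENT_DNA)[::-1]


def gc_percent(seq: str) -> float:
    """G+C content on the 0-100 scale."""
    if not seq:
        raise ValueError("gc_percent of empty sequence is undefined")
    gc = sum(1 for c in seq.upper() if c in "GC")
    return 100.0 * gc / len(seq)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero at the given precision (table printing rule).

    Python's builtin round() is banker's rounding, which disagrees with the
    half-up convention used when printing percentages; Decimal avoids the
    float-representation traps of adding 0.5 by hand.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, decimals: int = 2) -> float:
    """Percentage numerator/denominator * 100, rounded half-up."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator, decimals)
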