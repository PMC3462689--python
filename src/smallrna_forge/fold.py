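"""RNA secondary-structure engine for hairpin screening.

The default engine is self-contained: a Nussinov-style maximum-pairing
dynamic program (minimum hairpin loop of 3 unpaired bases, Watson-Crick and
G:U wobble pairs) with a deterministic traceback that prefers long outer
helices, followed by an energy assignment from an approximate
nearest-neighbour stacking table.  Only stacked pairs contribute energy, so
the reported MFE is always <= 0 and equals 0 for unpairable sequences.

This is not a thermodynamic partition-function folder: energies are
engine-relative, which is why every MFE threshold downstream is
configurable.  Any external engine that satisfies the ``fold`` signature can
be plugged in; an adapter around the ``RNAfold`` executable is provided and
used only when that binary is on PATH.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from ._util import to_rna

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
MIN_LOOP = 3  # unpaired bases enclosed by any pair

# pair type codes for the stacking table
_PAIR_CODE = {
    (0, 3): 0,  # AU
    (3, 0): 1,  # UA
    (1, 2): 2,  # CG
    (2, 1): 3,  # GC
    (2, 3): 4,  # GU
    (3, 2): 5,  # UG
}

# stack energies (kcal/mol): row = outer pair (i,j), col = inner pair (i+1,j-1).
# Approximate nearest-neighbour values; magnitudes chosen to reproduce the
# familiar ordering GC-rich stacks < AU stacks < GU stacks.
_STACK = np.array(
    [
        # AU     UA     CG     GC     GU     UG     (inner)
        [-0.9, -1.1, -2.2, -2.1, -0.6, -1.4],  # outer AU
        [-1.3, -0.9, -2.4, -2.1, -1.0, -1.3],  # outer UA
        [-2.1, -2.1, -3.3, -2.4, -1.4, -2.1],  # outer CG
        [-2.4, -2.2, -3.4, -3.3, -1.5, -2.5],  # outer GC
        [-1.3, -1.4, -2.5, -2.1, -0.5, +0.0],  # outer GU
        [-1.0, -0.6, -1.5, -1.4, +0.0, -0.5],  # outer UG
    ]
)

_CANPAIR = np.zeros((4, 4), dtype=np.bool_)
for (a, b) in _PAIR_CODE:
    _CANPAIR[a, b] = True


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_CODE[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-RNA base {exc.args[0]!r} in sequence") from exc


# ---------------------------------------------------------------------------
# DP core (numba-compiled when available; identical pure-Python fallback)
# ---------------------------------------------------------------------------

def _nussinov_dp_py(code, canpair, eps):
    """Fill W (free) and V (outer pair forced) score matrices.

    Score = number of pairs + eps per stacked pair.  With eps small enough
    that the total stacking bonus stays below 1, any optimal structure
    still carries the Nussinov-maximal pair count; among those, contiguous
    helices are preferred, which is what makes planted stems recoverable.
    """
    n = len(code)
    W = np.zeros((n, n), dtype=np.float64)
    V = np.full((n, n), -1.0, dtype=np.float64)
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            if canpair[code[i], code[j]]:
                inner_w = W[i + 1, j - 1]
                v = 1.0 + inner_w
                if V[i + 1, j - 1] >= 0.0 and 1.0 + V[i + 1, j - 1] + eps > v:
                    v = 1.0 + V[i + 1, j - 1] + eps
                V[i, j] = v
            best = W[i + 1, j]
            for k in range(i + MIN_LOOP + 1, j + 1):
                if V[i, k] >= 0.0:
                    right = W[k + 1, j] if k + 1 <= j else 0.0
                    cand = V[i, k] + right
                    if cand > best:
                        best = cand
            W[i, j] = best
    return W, V


try:  # pragma: no cover - exercised indirectly
    import numba

    _nussinov_dp = numba.njit(cache=True)(_nussinov_dp_py)
except Exception:  # pragma: no cover
    _nussinov_dp = _nussinov_dp_py

_TOL = 1e-9


def _traceback(W, V, code, canpair, eps) -> List[int]:
    """Deterministic traceback; prefers stacked continuation, then the
    rightmost pairing partner for the left edge."""
    n = len(code)
    partner = [-1] * n
    stack = [(0, n - 1, False)]  # (i, j, outer pair forced)
    while stack:
        i, j, forced = stack.pop()
        if i >= j or j - i <= MIN_LOOP:
            continue
        if forced:
            partner[i] = j
            partner[j] = i
            if (
                V[i + 1, j - 1] >= 0.0
                and abs(V[i, j] - (1.0 + V[i + 1, j - 1] + eps)) < _TOL
            ):
                stack.append((i + 1, j - 1, True))
            else:
                stack.append((i + 1, j - 1, False))
            continue
        if W[i, j] < _TOL:
            continue
        paired = False
        for k in range(j, i + MIN_LOOP, -1):
            if V[i, k] >= 0.0:
                right = W[k + 1, j] if k + 1 <= j else 0.0
                if abs(V[i, k] + right - W[i, j]) < _TOL:
                    stack.append((i, k, True))
                    if k + 1 <= j:
                        stack.append((k + 1, j, False))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j, False))
    return partner


def _stack_energy(code, partner) -> float:
    e = 0.0
    for i, j in enumerate(partner):
        if j > i:
            # stack with the enclosed pair, if directly adjacent
            if i + 1 < j - 1 and partner[i + 1] == j - 1:
                outer = _PAIR_CODE[(code[i], code[j])]
                inner = _PAIR_CODE[(code[i + 1], code[j - 1])]
                e += _STACK[outer, inner]
    return min(e, 0.0)


@dataclass
class FoldResult:
    """A folded sequence: dot-bracket structure, MFE and the pair table."""

    seq: str
    structure: str
    mfe: float
    pair_table: List[int]  # 0-based partner index, -1 if unpaired

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.seq):
            raise ValueError("structure/sequence length mismatch")

    @property
    def n_pairs(self) -> int:
        return sum(1 for i, j in enumerate(self.pair_table) if j > i)

    def partner(self, pos1: int) -> Optional[int]:
        """1-based partner of a 1-based position, or None if unpaired."""
        p = self.pair_table[pos1 - 1]
        return None if p < 0 else p + 1


def _dotbracket(partner: List[int]) -> str:
    out = []
    for i, j in enumerate(partner):
        out.append("." if j < 0 else ("(" if j > i else ")"))
    return "".join(out)


def fold(seq: str, engine: str = "builtin") -> FoldResult:
    """Fold an RNA sequence with the selected engine.

    Deterministic for a fixed sequence.  ``engine`` is "builtin" (default)
    or "rnafold" (requires the ViennaRNA ``RNAfold`` executable on PATH).
    """
    rna = to_rna(seq)
    if engine == "rnafold":
        return _fold_rnafold(rna)
    if engine != "builtin":
        raise ValueError(f"unknown fold engine {engine!r}")
    code = _encode(rna)
    n = len(code)
    if n <= MIN_LOOP + 1:
        return FoldResult(rna, "." * n, 0.0, [-1] * n)
    eps = 1.0 / (4.0 * n)
    W, V = _nussinov_dp(code, _CANPAIR, eps)
    partner = _traceback(np.asarray(W), np.asarray(V), code, _CANPAIR, eps)
    mfe = _stack_energy(code, partner)
    return FoldResult(rna, _dotbracket(partner), float(mfe), partner)


def _pairs_from_dotbracket(db: str) -> List[int]:
    partner = [-1] * len(db)
    stack: List[int] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            partner[i] = j
            partner[j] = i
    return partner


def _fold_rnafold(rna: str) -> FoldResult:  # pragma: no cover - needs binary
    exe = shutil.which("RNAfold")
    if exe is None:
        raise RuntimeError("RNAfold executable not found on PATH")
    out = subprocess.run(
        [exe, "--noPS"], input=rna + "\n", capture_output=True, text=True, check=True
    ).stdout.splitlines()
    struct_line = out[1]
    db = struct_line.split()[0]
    mfe = float(struct_line.rsplit("(", 1)[1].rstrip(")").strip())
    return FoldResult(rna, db, mfe, _pairs_from_dotbracket(db))
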