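"""Affine-gap pairwise protein alignment, implemented in-house.

Local (Smith–Waterman) and global (Needleman–Wunsch) optima are computed
with the Gotoh three-state recurrence.  A gap of length L costs
``gap_open + (L - 1) * gap_extend``.  The default scoring scheme is BLOSUM62
with gap open 10 and gap extend 0.5, with ambiguity residues (X, B, Z)
scoring 0 against everything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

__all__ = [
    "ScoringScheme",
    "GlobalHomology",
    "local_align",
    "global_align",
    "map_aligned_position",
]

_NEG = -1e30  # effectively -inf but safe under addition

_AMBIGUOUS = "BZX*"


def _blosum62_matrix() -> tuple[str, np.ndarray]:
    m = substitution_matrices.load("BLOSUM62")
    alphabet = str(m.alphabet)
    arr = np.array(m, dtype=np.float64)
    for ch in _AMBIGUOUS:
        if ch in alphabet:
            k = alphabet.index(ch)
            arr[k, :] = 0.0
            arr[:, k] = 0.0
    return alphabet, arr


@dataclass(frozen=True)
class ScoringScheme:
    """Residue-pair scores plus affine gap penalties (penalties are positive
    numbers subtracted from the score)."""

    alphabet: str
    matrix: np.ndarray
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (len(self.alphabet), len(self.alphabet)):
            raise ValueError("matrix shape does not match alphabet")
        if not np.allclose(m, m.T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def blosum62(cls, gap_open: float = 10.0, gap_extend: float = 0.5) -> "ScoringScheme":
        alphabet, arr = _blosum62_matrix()
        return cls(alphabet, arr, gap_open, gap_extend)

    def encode(self, seq: str) -> np.ndarray:
        x_idx = self.alphabet.index("X") if "X" in self.alphabet else 0
        lut = np.full(128, x_idx, dtype=np.int64)
        for i, ch in enumerate(self.alphabet):
            lut[ord(ch)] = i
        codes = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        return lut[codes]

    def pair_score(self, a: str, b: str) -> float:
        ia = self.encode(a)[0]
        ib = self.encode(b)[0]
        return float(self.matrix[ia, ib])


_DEFAULT: Optional[ScoringScheme] = None


def default_scheme() -> ScoringScheme:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = ScoringScheme.blosum62()
    return _DEFAULT


@njit(cache=True)
def _gotoh_fill(a, b, S, gap_open, gap_ext, local):  # pragma: no cover - numba
    n, m = len(a), len(b)
    H = np.full((n + 1, m + 1), _NEG)
    E = np.full((n + 1, m + 1), _NEG)  # gap in b (vertical, consumes a)
    F = np.full((n + 1, m + 1), _NEG)  # gap in a (horizontal, consumes b)
    H[0, 0] = 0.0
    for i in range(1, n + 1):
        E[i, 0] = -(gap_open + (i - 1) * gap_ext)
        H[i, 0] = 0.0 if local else E[i, 0]
    for j in range(1, m + 1):
        F[0, j] = -(gap_open + (j - 1) * gap_ext)
        H[0, j] = 0.0 if local else F[0, j]
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = max(H[i - 1, j] - gap_open, E[i - 1, j] - gap_ext)
            f = max(H[i, j - 1] - gap_open, F[i, j - 1] - gap_ext)
            d = H[i - 1, j - 1] + S[a[i - 1], b[j - 1]]
            h = max(d, e, f)
            if local and h < 0.0:
                h = 0.0
            E[i, j] = e
            F[i, j] = f
            H[i, j] = h
            if local and h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


def _traceback(a, b, ai, bi_codes, S, gap_open, gap_ext, H, E, F, i, j, local):
    """Recover one optimal alignment ending at (i, j) by retracing the
    recurrence (exact float comparisons against stored cell values)."""
    out_a: list[str] = []
    out_b: list[str] = []
    state = "H"
    while i > 0 or j > 0:
        if local and state == "H" and H[i, j] == 0.0:
            break
        if state == "H":
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + S[ai[i - 1], bi_codes[j - 1]]:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
            elif i > 0 and H[i, j] == E[i, j]:
                state = "E"
            elif j > 0 and H[i, j] == F[i, j]:
                state = "F"
            elif not local and i > 0 and j == 0:
                state = "E"
            elif not local and j > 0 and i == 0:
                state = "F"
            else:  # pragma: no cover - recurrence guarantees a predecessor
                raise AssertionError("traceback dead end")
        elif state == "E":
            out_a.append(a[i - 1])
            out_b.append("-")
            if E[i, j] == H[i - 1, j] - gap_open or i == 1:
                state = "H"
            i -= 1
        else:  # F
            out_a.append("-")
            out_b.append(b[j - 1])
            if F[i, j] == H[i, j - 1] - gap_open or j == 1:
                state = "H"
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), i, j


def local_align(
    a: str, b: str, scheme: ScoringScheme | None = None
) -> tuple[float, str, str]:
    """Optimal Smith–Waterman local alignment.

    Returns (score, aligned_a, aligned_b).  Empty input gives score 0 with an
    empty alignment (the local-alignment floor).
    """
    scheme = scheme or default_scheme()
    if not a or not b:
        return 0.0, "", ""
    ac = scheme.encode(a)
    bc = scheme.encode(b)
    H, E, F, best, bi, bj = _gotoh_fill(
        ac, bc, scheme.matrix, scheme.gap_open, scheme.gap_extend, True
    )
    if best <= 0.0:
        return 0.0, "", ""
    aln_a, aln_b, _, _ = _traceback(
        a, b, ac, bc, scheme.matrix, scheme.gap_open, scheme.gap_extend,
        H, E, F, bi, bj, local=True,
    )
    return float(best), aln_a, aln_b


def local_score(a: str, b: str, scheme: ScoringScheme | None = None) -> float:
    """Local alignment score only (skips traceback)."""
    scheme = scheme or default_scheme()
    if not a or not b:
        return 0.0
    _, _, _, best, _, _ = _gotoh_fill(
        scheme.encode(a), scheme.encode(b), scheme.matrix,
        scheme.gap_open, scheme.gap_extend, True,
    )
    return float(max(best, 0.0))


@dataclass(frozen=True)
class GlobalHomology:
    """A global alignment with percentages computed over the full alignment
    length so that gap columns count against homology."""

    score: float
    aligned_a: str
    aligned_b: str
    pct_identity: float
    pct_similarity: float

    def __post_init__(self):
        if not 0 <= self.pct_identity <= self.pct_similarity <= 100:
            raise ValueError("need 0 <= identity <= similarity <= 100")


def global_align(
    a: str, b: str, scheme: ScoringScheme | None = None
) -> GlobalHomology:
    """Optimal Needleman–Wunsch global alignment with affine gaps.

    Identity counts columns with equal unambiguous residues; similarity
    counts columns whose pair score is positive.  Both use the full
    alignment length (gap columns included) as denominator.
    """
    scheme = scheme or default_scheme()
    if not a or not b:
        raise ValueError("global alignment requires two non-empty sequences")
    ac = scheme.encode(a)
    bc = scheme.encode(b)
    H, E, F, _, _, _ = _gotoh_fill(
        ac, bc, scheme.matrix, scheme.gap_open, scheme.gap_extend, False
    )
    n, m = len(a), len(b)
    aln_a, aln_b, i0, j0 = _traceback(
        a, b, ac, bc, scheme.matrix, scheme.gap_open, scheme.gap_extend,
        H, E, F, n, m, local=False,
    )
    assert i0 == 0 and j0 == 0
    ident = 0
    simil = 0
    for ca, cb in zip(aln_a, aln_b):
        if ca == "-" or cb == "-":
            continue
        s = scheme.pair_score(ca, cb)
        if s > 0:
            simil += 1
            if ca.upper() == cb.upper():
                ident += 1
    length = len(aln_a)
    return GlobalHomology(
        score=float(H[n, m]),
        aligned_a=aln_a,
        aligned_b=aln_b,
        pct_identity=100.0 * ident / length,
        pct_similarity=100.0 * simil / length,
    )


def map_aligned_position(
    aligned_a: str, aligned_b: str, query_pos: int
) -> tuple[Optional[int], bool]:
    """Map a 1-based residue index of the ungapped first sequence onto the
    second through a gapped alignment.

    Returns (target_pos, exact).  When the query residue sits opposite a gap,
    the nearest aligned target index 5'-ward is returned with exact=False
    (None if there is none).
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings differ in length")
    if query_pos < 1:
        raise ValueError("query position must be >= 1")
    qi = 0
    ti = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca != "-":
            qi += 1
        if cb != "-":
            ti += 1
        if ca != "-" and qi == query_pos:
            if cb != "-":
                return ti, True
            return (ti if ti > 0 else None), False
    raise ValueError(
        f"query position {query_pos} beyond ungapped query length {qi}"
    )
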