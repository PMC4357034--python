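"""Affine-gap pairwise alignment engine (Smith-Waterman / Needleman-Wunsch).

Scoring follows the gapped-BLAST convention: a gap of length L costs
``gap_open + gap_extend * L``, substitution scores come from BLOSUM62
(loaded from biopython). The dynamic programs are Gotoh three-state
recurrences; the inner loops are numba-compiled. Traceback tie-breaks are
fixed (diagonal, then up, then left) so alignments are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

NEG_INF = -1.0e18

# Residues accepted in protein inputs. '*' and non-IUPAC letters are errors.
PROTEIN_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX"
_RES_INDEX = {c: i for i, c in enumerate(PROTEIN_ALPHABET)}


@lru_cache(maxsize=1)
def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 as a dense float array over PROTEIN_ALPHABET."""
    m = substitution_matrices.load("BLOSUM62")
    n = len(PROTEIN_ALPHABET)
    out = np.zeros((n, n), dtype=np.float64)
    for i, a in enumerate(PROTEIN_ALPHABET):
        for j, b in enumerate(PROTEIN_ALPHABET):
            out[i, j] = m[a, b]
    return out


def encode_protein(seq: str) -> np.ndarray:
    """Encode a protein string as BLOSUM62 row indices.

    Raises ValueError on empty input or characters outside the protein
    alphabet.
    """
    if not seq:
        raise ValueError("empty sequence")
    try:
        return np.array([_RES_INDEX[c] for c in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-protein character {exc.args[0]!r} in sequence") from None


@dataclass(frozen=True)
class LocalAlignment:
    """Optimal local alignment: score and half-open spans on each sequence."""

    score: float
    a_start: int
    a_end: int
    b_start: int
    b_end: int


@dataclass(frozen=True)
class GlobalAlignment:
    """Optimal global alignment as parallel gapped index arrays.

    ``a_idx[k]``/``b_idx[k]`` give the residue index aligned in column k,
    or -1 for a gap.
    """

    score: float
    a_idx: np.ndarray
    b_idx: np.ndarray

    def gapped(self, a: str, b: str) -> tuple[str, str]:
        ga = "".join(a[i] if i >= 0 else "-" for i in self.a_idx)
        gb = "".join(b[j] if j >= 0 else "-" for j in self.b_idx)
        return ga, gb


@njit(cache=False)
def _local_kernel(grid, gap_open, gap_ext):  # pragma: no cover - compiled
    m, n = grid.shape
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG_INF)  # gap in a (left moves)
    F = np.full((m + 1, n + 1), NEG_INF)  # gap in b (up moves)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] - gap_open - gap_ext, E[i, j - 1] - gap_ext)
            F[i, j] = max(H[i - 1, j] - gap_open - gap_ext, F[i - 1, j] - gap_ext)
            h = H[i - 1, j - 1] + grid[i - 1, j - 1]
            if F[i, j] > h:
                h = F[i, j]
            if E[i, j] > h:
                h = E[i, j]
            if h < 0.0:
                h = 0.0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback for start coordinates; priority diagonal > up > left
    i, j = bi, bj
    state = 0  # 0=H, 1=F(up), 2=E(left)
    while i > 0 and j > 0:
        if state == 0:
            h = H[i, j]
            if h == 0.0:
                break
            if h == H[i - 1, j - 1] + grid[i - 1, j - 1]:
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            if F[i, j] == H[i - 1, j] - gap_open - gap_ext:
                state = 0
            i -= 1
        else:
            if E[i, j] == H[i, j - 1] - gap_open - gap_ext:
                state = 0
            j -= 1
    return best, i, bi, j, bj


@njit(cache=False)
def _global_kernel(grid, gap_open, gap_ext):  # pragma: no cover - compiled
    m, n = grid.shape
    H = np.full((m + 1, n + 1), NEG_INF)
    E = np.full((m + 1, n + 1), NEG_INF)
    F = np.full((m + 1, n + 1), NEG_INF)
    H[0, 0] = 0.0
    for j in range(1, n + 1):
        E[0, j] = -gap_open - gap_ext * j
        H[0, j] = E[0, j]
    for i in range(1, m + 1):
        F[i, 0] = -gap_open - gap_ext * i
        H[i, 0] = F[i, 0]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = E[i, j - 1] - gap_ext
            t = H[i, j - 1] - gap_open - gap_ext
            if t > e:
                e = t
            E[i, j] = e
            f = F[i - 1, j] - gap_ext
            t = H[i - 1, j] - gap_open - gap_ext
            if t > f:
                f = t
            F[i, j] = f
            h = H[i - 1, j - 1] + grid[i - 1, j - 1]
            if f > h:
                h = f
            if e > h:
                h = e
            H[i, j] = h
    # traceback; priority diagonal > up > left
    a_idx = np.empty(m + n, dtype=np.int64)
    b_idx = np.empty(m + n, dtype=np.int64)
    k = 0
    i, j = m, n
    state = 0
    while i > 0 or j > 0:
        if state == 0:
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + grid[i - 1, j - 1]:
                i -= 1
                j -= 1
                a_idx[k] = i
                b_idx[k] = j
                k += 1
                continue
            if i > 0 and H[i, j] == F[i, j]:
                state = 1
                continue
            state = 2
            continue
        if state == 1:
            if F[i, j] == H[i - 1, j] - gap_open - gap_ext:
                state = 0
            i -= 1
            a_idx[k] = i
            b_idx[k] = -1
            k += 1
        else:
            if E[i, j] == H[i, j - 1] - gap_open - gap_ext:
                state = 0
            j -= 1
            a_idx[k] = -1
            b_idx[k] = j
            k += 1
    return H[m, n], a_idx[:k][::-1].copy(), b_idx[:k][::-1].copy()


def score_grid(a_idx: np.ndarray, b_idx: np.ndarray, matrix: np.ndarray | None = None) -> np.ndarray:
    if matrix is None:
        matrix = blosum62_matrix()
    return np.ascontiguousarray(matrix[np.ix_(a_idx, b_idx)])


def sw_align(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> LocalAlignment:
    """Optimal Smith-Waterman local alignment of two protein sequences."""
    grid = score_grid(encode_protein(a), encode_protein(b))
    score, a0, a1, b0, b1 = _local_kernel(grid, float(gap_open), float(gap_extend))
    return LocalAlignment(float(score), int(a0), int(a1), int(b0), int(b1))


def sw_score_only(a_idx: np.ndarray, b_idx: np.ndarray, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Local-alignment score for pre-encoded sequences (bulk scanning path)."""
    grid = score_grid(a_idx, b_idx)
    score, _, _, _, _ = _local_kernel(grid, float(gap_open), float(gap_extend))
    return float(score)


def nw_align(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> GlobalAlignment:
    """Optimal Needleman-Wunsch global alignment (end gaps penalized)."""
    grid = score_grid(encode_protein(a), encode_protein(b))
    score, a_idx, b_idx = _global_kernel(grid, float(gap_open), float(gap_extend))
    return GlobalAlignment(float(score), a_idx, b_idx)


def nw_align_grid(grid: np.ndarray, gap_open: float, gap_extend: float) -> GlobalAlignment:
    """Global alignment over an arbitrary precomputed column-score grid.

    Used for profile-profile merges in the progressive aligner.
    """
    score, a_idx, b_idx = _global_kernel(
        np.ascontiguousarray(grid, dtype=np.float64), float(gap_open), float(gap_extend)
    )
    return GlobalAlignment(float(score), a_idx, b_idx)
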