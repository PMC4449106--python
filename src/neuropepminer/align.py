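"""Affine-gap pairwise alignment (Smith-Waterman and Needleman-Wunsch).

Both aligners are exact Gotoh dynamic programs. A gap of length L costs
``gap_open + L * gap_extend`` (the BLAST convention, so the default 11/1
scores a length-1 gap at -12). Substitution scores come from the published
integer BLOSUM matrices, with one local convention: 'X' (unknown residue,
e.g. from an N-containing codon) scores 0 against everything, so ambiguous
translation neither rewards nor penalises a match.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

RESIDUES = "ARNDCQEGHILKMFPSTWYVBZX*"
_IDX = {aa: i for i, aa in enumerate(RESIDUES)}

NEG_INF = -1_000_000_000


@lru_cache(maxsize=None)
def load_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """Return a (24, 24) int substitution matrix indexed by `RESIDUES`.

    'X' rows/columns are forced to 0.
    """
    pub = substitution_matrices.load(name)
    m = np.zeros((len(RESIDUES), len(RESIDUES)), dtype=np.int64)
    for i, a in enumerate(RESIDUES):
        for j, b in enumerate(RESIDUES):
            try:
                m[i, j] = int(pub[a, b])
            except (KeyError, IndexError):
                m[i, j] = 0
    xi = _IDX["X"]
    m[xi, :] = 0
    m[:, xi] = 0
    return m


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_IDX[c] for c in seq], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"non-amino-acid character in sequence: {exc}") from exc


def sw_score(query: str, target: str, matrix: str = "BLOSUM62",
             gap_open: int = 11, gap_extend: int = 1) -> int:
    """Optimal local alignment score (score only, vectorised over the query).

    Column-wise Gotoh with the vertical gap state recovered in closed form:
    because extending a gap from within another vertical gap never beats
    opening directly from its source cell, F[i, j] equals
    ``max_{k<i} H[k, j] - gap_open - (i-k) * gap_extend``, which is a running
    maximum over the already-final column scores.
    """
    if not query or not target:
        return 0
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be positive")
    sub = load_matrix(matrix)
    qi = encode(query)
    ti = encode(target)
    n = len(qi)
    idx = np.arange(n + 1, dtype=np.int64)
    h_prev = np.zeros(n + 1, dtype=np.int64)      # column j-1, rows 0..n
    e = np.full(n, NEG_INF, dtype=np.int64)       # horizontal gap, rows 1..n
    best = 0
    for t in ti:
        s = sub[qi, t]
        e = np.maximum(e - gap_extend, h_prev[1:] - gap_open - gap_extend)
        h0 = np.maximum(h_prev[:-1] + s, e)
        h0 = np.maximum(h0, 0)
        # vertical gaps via running max of (H + k*ge) down the column
        a = np.concatenate(([0], h0)) + idx * gap_extend
        f = np.maximum.accumulate(a)[:-1] - gap_open - idx[1:] * gap_extend
        h = np.maximum(h0, f)
        best = max(best, int(h.max()))
        h_prev = np.concatenate(([0], h))
    return best


@dataclass
class LocalAlignment:
    """One optimal Smith-Waterman alignment (1-based inclusive spans)."""

    score: int
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    aligned_query: str
    aligned_target: str

    @property
    def length(self) -> int:
        return len(self.aligned_query)


def local_align(query: str, target: str, matrix: str = "BLOSUM62",
                gap_open: int = 11, gap_extend: int = 1) -> LocalAlignment:
    """Optimal local alignment with traceback.

    Deterministic tie-breaking: among maximal cells the one with the smallest
    target end (then query end) wins, and the traceback prefers diagonal
    moves, then vertical (gap in target), then horizontal.
    """
    if not query or not target:
        return LocalAlignment(0, 0, 0, 0, 0, "", "")
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be positive")
    sub = load_matrix(matrix)
    qi = encode(query)
    ti = encode(target)
    n, m = len(qi), len(ti)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)
    for i in range(1, n + 1):
        row_s = sub[qi[i - 1], ti]
        for j in range(1, m + 1):
            E[i, j] = max(E[i, j - 1] - gap_extend,
                          H[i, j - 1] - gap_open - gap_extend)
            F[i, j] = max(F[i - 1, j] - gap_extend,
                          H[i - 1, j] - gap_open - gap_extend)
            H[i, j] = max(0, H[i - 1, j - 1] + row_s[j - 1], E[i, j], F[i, j])
    best = int(H.max())
    if best == 0:
        return LocalAlignment(0, 0, 0, 0, 0, "", "")
    # smallest target end, then smallest query end
    cells = np.argwhere(H == best)
    j_end, i_end = min((int(j), int(i)) for i, j in cells)
    qa, ta = [], []
    i, j = i_end, j_end
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0:
                break
            if H[i, j] == H[i - 1, j - 1] + sub[qi[i - 1], ti[j - 1]]:
                qa.append(query[i - 1])
                ta.append(target[j - 1])
                i -= 1
                j -= 1
                continue
            state = "F" if H[i, j] == F[i, j] else "E"
        if state == "F":
            qa.append(query[i - 1])
            ta.append("-")
            if F[i, j] == F[i - 1, j] - gap_extend:
                i -= 1
                continue
            i -= 1
            state = "H"
        else:  # E: gap in query
            qa.append("-")
            ta.append(target[j - 1])
            if E[i, j] == E[i, j - 1] - gap_extend:
                j -= 1
                continue
            j -= 1
            state = "H"
    return LocalAlignment(best, i + 1, i_end, j + 1, j_end,
                          "".join(reversed(qa)), "".join(reversed(ta)))


def global_align(a: str, b: str, matrix: str = "BLOSUM62",
                 gap_open: int = 11, gap_extend: int = 1
                 ) -> tuple[str, str, int]:
    """Optimal global (Needleman-Wunsch) alignment with affine gaps.

    Returns ``(aligned_a, aligned_b, score)``. Tie-breaking prefers a
    match/mismatch column over a gap, and a gap in ``b`` over a gap in ``a``.
    """
    if not a or not b:
        raise ValueError("global_align requires non-empty sequences")
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be positive")
    sub = load_matrix(matrix)
    ai = encode(a)
    bi = encode(b)
    n, m = len(ai), len(bi)
    H = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)  # gap in a (consume b)
    F = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)  # gap in b (consume a)
    H[0, 0] = 0
    for j in range(1, m + 1):
        E[0, j] = -gap_open - j * gap_extend
        H[0, j] = E[0, j]
    for i in range(1, n + 1):
        F[i, 0] = -gap_open - i * gap_extend
        H[i, 0] = F[i, 0]
    for i in range(1, n + 1):
        row_s = sub[ai[i - 1], bi]
        for j in range(1, m + 1):
            E[i, j] = max(E[i, j - 1] - gap_extend,
                          H[i, j - 1] - gap_open - gap_extend)
            F[i, j] = max(F[i - 1, j] - gap_extend,
                          H[i - 1, j] - gap_open - gap_extend)
            H[i, j] = max(H[i - 1, j - 1] + row_s[j - 1], F[i, j], E[i, j])
    aa, bb = [], []
    i, j = n, m
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + sub[ai[i - 1], bi[j - 1]]:
                aa.append(a[i - 1])
                bb.append(b[j - 1])
                i -= 1
                j -= 1
                continue
            if i > 0 and H[i, j] == F[i, j]:
                state = "F"
            else:
                state = "E"
            continue
        if state == "F":
            aa.append(a[i - 1])
            bb.append("-")
            if i > 1 and F[i, j] == F[i - 1, j] - gap_extend:
                i -= 1
                continue
            i -= 1
            state = "H"
        else:
            aa.append("-")
            bb.append(b[j - 1])
            if j > 1 and E[i, j] == E[i, j - 1] - gap_extend:
                j -= 1
                continue
            j -= 1
            state = "H"
    return "".join(reversed(aa)), "".join(reversed(bb)), int(H[n, m])
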