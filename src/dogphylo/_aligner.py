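"""Progressive multiple alignment for iterative-search hit sets.

A deliberately small aligner: k-mer distances feed a UPGMA guide tree and
profiles are merged by global profile-profile alignment with sum-of-pairs
BLOSUM62 scoring and affine gaps.  It is pluggable -- any callable mapping
{id: sequence} to an :class:`~dogphylo.seqs.Alignment` can replace it in
the search configuration.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage

from ._dp import profile_profile_path
from .models import AA_INDEX, AA_ORDER
from .seqs import Alignment

_B62 = None


def _blosum62() -> np.ndarray:
    global _B62
    if _B62 is None:
        m = substitution_matrices.load("BLOSUM62")
        S = np.zeros((20, 20))
        for i, a in enumerate(AA_ORDER):
            for j, b in enumerate(AA_ORDER):
                S[i, j] = m[a][b]
        _B62 = S
    return _B62


def _kmer_distance(seqs: list[str], k: int = 3) -> np.ndarray:
    sets = [
        {s[i : i + k] for i in range(max(len(s) - k + 1, 1))} for s in seqs
    ]
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = len(sets[i] & sets[j])
            denom = min(len(sets[i]), len(sets[j])) or 1
            D[i, j] = D[j, i] = 1.0 - shared / denom
    return D


def _freq_profile(rows: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-column residue frequencies (over non-gap) and gap fractions."""
    L = len(rows[0])
    F = np.zeros((L, 20))
    gaps = np.zeros(L)
    for s in rows:
        for j, c in enumerate(s):
            idx = AA_INDEX.get(c)
            if idx is None:
                gaps[j] += 1
            else:
                F[j, idx] += 1
    n = len(rows)
    denom = np.maximum(n - gaps, 1)
    return F / denom[:, None], gaps / n


def _merge(a_rows: list[str], b_rows: list[str], gopen: float, gext: float):
    FA, gA = _freq_profile(a_rows)
    FB, gB = _freq_profile(b_rows)
    S = _blosum62()
    colscore = (FA @ S) @ FB.T
    # columns that are mostly gaps should be cheap to align against anything
    colscore = colscore * (1.0 - gA)[:, None] * (1.0 - gB)[None, :]
    ai, bi = profile_profile_path(colscore, gopen, gext)
    out_a = ["".join(s[i] if i >= 0 else "-" for i in ai) for s in a_rows]
    out_b = ["".join(s[j] if j >= 0 else "-" for j in bi) for s in b_rows]
    return out_a + out_b


def align_sequences(
    seqs: dict[str, str], gap_open: float = 11.0, gap_extend: float = 1.0
) -> Alignment:
    """Progressive multiple alignment; deterministic for a given input order."""
    ids = list(seqs)
    if not ids:
        raise ValueError("no sequences to align")
    if len(ids) == 1:
        return Alignment(ids, [seqs[ids[0]]])
    raw = [seqs[i] for i in ids]
    D = _kmer_distance(raw)
    n = len(ids)
    cond = D[np.triu_indices(n, k=1)]
    Z = linkage(cond, method="average")
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [raw[i]]) for i in range(n)
    }
    nxt = n
    for a, b, _, _ in Z:
        ia, ra = clusters.pop(int(a))
        ib, rb = clusters.pop(int(b))
        merged = _merge(ra, rb, gap_open, gap_extend)
        clusters[nxt] = (ia + ib, merged)
        nxt += 1
    order, rows = clusters.popitem()[1]
    aligned = {ids[i]: r for i, r in zip(order, rows)}
    return Alignment(ids, [aligned[i] for i in ids])
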