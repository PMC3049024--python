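"""Numba dynamic-programming kernels for profile searches and alignment.

Two kernels:

* banded local profile-to-sequence alignment with affine, per-profile-column
  gap penalties (Smith-Waterman style, Gotoh three-state recursion);
* global profile-to-profile alignment with traceback, used by the
  progressive aligner.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e30


@njit(cache=True)
def _local_one(pscores, gopen, gext, codes, band):
    """Banded local alignment of one target; returns (score, jstart, jend).

    pscores: (L, n_alpha) per-column match scores; codes: target as ints.
    The band is centred on the scaled diagonal j ~ i * M / L.
    """
    L = pscores.shape[0]
    M = codes.shape[0]
    H_prev = np.full(M + 1, 0.0)
    E_prev = np.full(M + 1, NEG)  # gap in target (profile column skipped alone)
    Bh_prev = np.zeros(M + 1, dtype=np.int64)
    Be_prev = np.zeros(M + 1, dtype=np.int64)
    best = 0.0
    bj_end = 0
    bj_start = 0
    ratio = M / L
    for i in range(1, L + 1):
        center = int(i * ratio)
        jlo = center - band
        jhi = center + band
        if jlo < 1:
            jlo = 1
        if jhi > M:
            jhi = M
        H = np.full(M + 1, NEG)
        E = np.full(M + 1, NEG)
        Bh = np.zeros(M + 1, dtype=np.int64)
        Be = np.zeros(M + 1, dtype=np.int64)
        if jlo == 1:
            H[0] = 0.0
        F = NEG  # gap in profile (target residue consumed alone)
        Bf = 0
        for j in range(jlo, jhi + 1):
            # E: extend gap down (profile advances, target stays)
            e1 = H_prev[j] - gopen[i - 1]
            e2 = E_prev[j] - gext[i - 1]
            if e1 >= e2:
                E[j] = e1
                Be[j] = Bh_prev[j]
            else:
                E[j] = e2
                Be[j] = Be_prev[j]
            # F: extend gap right (target advances, profile stays)
            f1 = H[j - 1] - gopen[i - 1]
            f2 = F - gext[i - 1]
            if f1 >= f2:
                F = f1
                Bf = Bh[j - 1]
            else:
                F = f2
            # H: diagonal
            diag = H_prev[j - 1]
            bdiag = Bh_prev[j - 1]
            if diag < 0.0:
                diag = 0.0
                bdiag = j - 1
            s = diag + pscores[i - 1, codes[j - 1]]
            b = bdiag
            if E[j] > s:
                s = E[j]
                b = Be[j]
            if F > s:
                s = F
                b = Bf
            if s < 0.0:
                s = NEG
            H[j] = s
            Bh[j] = b
            if s > best:
                best = s
                bj_end = j
                bj_start = b
        H_prev = H
        E_prev = E
        Bh_prev = Bh
        Be_prev = Be
    return best, bj_start + 1, bj_end


@njit(cache=True)
def batch_local_scores(pscores, gopen, gext, codes_cat, offsets, band):
    """Local-alignment scores for a batch of targets (concatenated codes)."""
    n = offsets.shape[0] - 1
    scores = np.zeros(n)
    starts = np.zeros(n, dtype=np.int64)
    ends = np.zeros(n, dtype=np.int64)
    for t in range(n):
        codes = codes_cat[offsets[t] : offsets[t + 1]]
        if codes.shape[0] == 0:
            continue
        s, a, b = _local_one(pscores, gopen, gext, codes, band)
        scores[t] = s
        starts[t] = a
        ends[t] = b
    return scores, starts, ends


@njit(cache=True)
def profile_profile_path(colscore, gopen, gext):
    """Global affine alignment over a precomputed column-score matrix.

    Returns two int arrays (ai, bi) giving, per merged column, the source
    column in each profile or -1 for a gap.
    """
    LA, LB = colscore.shape
    H = np.full((LA + 1, LB + 1), NEG)
    E = np.full((LA + 1, LB + 1), NEG)  # gap in B (A advances)
    F = np.full((LA + 1, LB + 1), NEG)  # gap in A (B advances)
    PH = np.zeros((LA + 1, LB + 1), dtype=np.int8)  # 0 diag, 1 from E, 2 from F
    PE = np.zeros((LA + 1, LB + 1), dtype=np.int8)  # 0 open, 1 extend
    PF = np.zeros((LA + 1, LB + 1), dtype=np.int8)
    H[0, 0] = 0.0
    for i in range(1, LA + 1):
        e1 = H[i - 1, 0] - gopen
        e2 = E[i - 1, 0] - gext
        if e1 >= e2:
            E[i, 0] = e1
            PE[i, 0] = 0
        else:
            E[i, 0] = e2
            PE[i, 0] = 1
        H[i, 0] = E[i, 0]
        PH[i, 0] = 1
    for j in range(1, LB + 1):
        f1 = H[0, j - 1] - gopen
        f2 = F[0, j - 1] - gext
        if f1 >= f2:
            F[0, j] = f1
            PF[0, j] = 0
        else:
            F[0, j] = f2
            PF[0, j] = 1
        H[0, j] = F[0, j]
        PH[0, j] = 2
    for i in range(1, LA + 1):
        for j in range(1, LB + 1):
            e1 = H[i - 1, j] - gopen
            e2 = E[i - 1, j] - gext
            if e1 >= e2:
                E[i, j] = e1
                PE[i, j] = 0
            else:
                E[i, j] = e2
                PE[i, j] = 1
            f1 = H[i, j - 1] - gopen
            f2 = F[i, j - 1] - gext
            if f1 >= f2:
                F[i, j] = f1
                PF[i, j] = 0
            else:
                F[i, j] = f2
                PF[i, j] = 1
            s = H[i - 1, j - 1] + colscore[i - 1, j - 1]
            p = 0
            if E[i, j] > s:
                s = E[i, j]
                p = 1
            if F[i, j] > s:
                s = F[i, j]
                p = 2
            H[i, j] = s
            PH[i, j] = p
    # traceback
    ai = np.empty(LA + LB, dtype=np.int64)
    bi = np.empty(LA + LB, dtype=np.int64)
    k = 0
    i, j = LA, LB
    state = PH[i, j]
    while i > 0 or j > 0:
        if state == 0:
            ai[k] = i - 1
            bi[k] = j - 1
            i -= 1
            j -= 1
            k += 1
            state = PH[i, j] if (i > 0 or j > 0) else 0
        elif state == 1:
            ai[k] = i - 1
            bi[k] = -1
            nxt = PE[i, j]
            i -= 1
            k += 1
            state = PH[i, j] if nxt == 0 else 1
        else:
            ai[k] = -1
            bi[k] = j - 1
            nxt = PF[i, j]
            j -= 1
            k += 1
            state = PH[i, j] if nxt == 0 else 2
    return ai[:k][::-1].copy(), bi[:k][::-1].copy()
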