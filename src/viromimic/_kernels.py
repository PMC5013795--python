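"""Numba kernels backing the alignment engine.

Sequences are encoded as small integer codes (see ``align_core.ALPHABET``);
code 22 is a sentinel separating concatenated database sequences.  The
kernels are deliberately free of Python objects so the whole search is
compiled, deterministic, and single-threaded.
"""

from __future__ import annotations

import numpy as np
from numba import njit

SENTINEL = 22
NLETTERS = 22  # 20 aa + X + stop; sentinel excluded from words


@njit(cache=True)
def sw_full(a, b, S, gap_open, gap_extend):
    """Smith-Waterman with affine gaps, full DP with traceback pointers.

    A gap of length k costs ``gap_open + k * gap_extend``.  Tie-breaking when
    filling H prefers diagonal, then up (gap in b), then left (gap in a).
    Returns (best score, best_i, best_j, H, ptrH, ptrE, ptrF) where the
    pointer codes in ptrH are 0=stop, 1=diag, 2=up, 3=left and ptrE/ptrF
    record whether the gap state was opened (1) or extended (0).
    """
    n = a.shape[0]
    m = b.shape[0]
    NEG = np.int32(-(1 << 30))
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full((n + 1, m + 1), NEG, np.int32)
    F = np.full((n + 1, m + 1), NEG, np.int32)
    ptrH = np.zeros((n + 1, m + 1), np.uint8)
    ptrE = np.zeros((n + 1, m + 1), np.uint8)
    ptrF = np.zeros((n + 1, m + 1), np.uint8)
    best = np.int32(0)
    bi = 0
    bj = 0
    go_ge = np.int32(gap_open + gap_extend)
    ge = np.int32(gap_extend)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            e_open = H[i - 1, j] - go_ge
            e_ext = E[i - 1, j] - ge
            if e_open >= e_ext:
                E[i, j] = e_open
                ptrE[i, j] = 1
            else:
                E[i, j] = e_ext
                ptrE[i, j] = 0
            f_open = H[i, j - 1] - go_ge
            f_ext = F[i, j - 1] - ge
            if f_open >= f_ext:
                F[i, j] = f_open
                ptrF[i, j] = 1
            else:
                F[i, j] = f_ext
                ptrF[i, j] = 0
            h = H[i - 1, j - 1] + S[ai, b[j - 1]]
            p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            if h <= 0:
                h = 0
                p = 0
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, H, ptrH, ptrE, ptrF


@njit(cache=True)
def sw_score(a, b, S, gap_open, gap_extend):
    """Affine-gap Smith-Waterman best local score only (linear memory)."""
    n = a.shape[0]
    m = b.shape[0]
    NEG = np.int64(-(1 << 40))
    Hp = np.zeros(m + 1, np.int64)
    Ep = np.full(m + 1, NEG, np.int64)
    best = 0
    go_ge = gap_open + gap_extend
    for i in range(1, n + 1):
        ai = a[i - 1]
        h_diag = Hp[0]  # H[i-1][j-1]
        Hc = 0  # H[i][j-1]
        Fc = NEG
        for j in range(1, m + 1):
            e = max(Hp[j] - go_ge, Ep[j] - gap_extend)
            f = max(Hc - go_ge, Fc - gap_extend)
            h = h_diag + S[ai, b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            h_diag = Hp[j]
            Hp[j] = h
            Ep[j] = e
            Hc = h
            Fc = f
            if h > best:
                best = h
    return best


@njit(cache=True)
def word_codes(db, w):
    """Base-22 code of each length-w window of db; -1 where a sentinel intrudes."""
    n = db.shape[0]
    size = n - w + 1
    if size < 0:
        size = 0
    out = np.full(size, -1, np.int64)
    for i in range(size):
        code = 0
        ok = True
        for k in range(w):
            c = db[i + k]
            if c >= SENTINEL:
                ok = False
                break
            code = code * NLETTERS + c
        if ok:
            out[i] = code
    return out


@njit(cache=True)
def seed_scan(q, db, word_starts, word_pos, S, w, T, x_drop, min_keep,
              diag_cover, out):
    """One-hit seeded scan of query ``q`` against the concatenated database.

    For every query position, all words scoring >= T against the query word
    are enumerated (branch-and-bound DFS) and their database occurrences
    extended ungapped with x-drop termination.  A seed falling inside a
    region already extended on the same diagonal is skipped.  HSPs with
    score >= min_keep are written to ``out`` as rows
    (q_start, q_end, s_start, s_end, score) in 0-based half-open database
    coordinates.  Returns the number of rows, or -1 on overflow.
    """
    n_out = 0
    qlen = q.shape[0]
    N = db.shape[0]
    if qlen < w or N < w:
        return 0
    choice = np.empty(w, np.int64)
    partial = np.empty(w + 1, np.int64)
    codeacc = np.empty(w + 1, np.int64)
    maxsuf = np.empty(w + 1, np.int64)
    for qp in range(qlen - w + 1):
        maxsuf[w] = 0
        for k in range(w - 1, -1, -1):
            qc = q[qp + k]
            mx = S[qc, 0]
            for c in range(1, NLETTERS):
                s = S[qc, c]
                if s > mx:
                    mx = s
            maxsuf[k] = maxsuf[k + 1] + mx
        if maxsuf[0] < T:
            continue
        k = 0
        choice[0] = -1
        partial[0] = 0
        codeacc[0] = 0
        while k >= 0:
            choice[k] += 1
            if choice[k] >= NLETTERS:
                k -= 1
                continue
            sc = partial[k] + S[q[qp + k], choice[k]]
            if sc + maxsuf[k + 1] < T:
                continue
            code = codeacc[k] * NLETTERS + choice[k]
            if k < w - 1:
                k += 1
                choice[k] = -1
                partial[k] = sc
                codeacc[k] = code
                continue
            # complete word scoring sc >= T: visit database occurrences
            for idx in range(word_starts[code], word_starts[code + 1]):
                spos = word_pos[idx]
                d = qp - spos + N
                if diag_cover[d] >= spos:
                    continue
                # rightward x-drop extension
                cur = 0
                best_r = 0
                i = qp + w
                j = spos + w
                re_q = qp + w
                while i < qlen and j < N:
                    c = db[j]
                    if c == SENTINEL:
                        break
                    cur += S[q[i], c]
                    if cur > best_r:
                        best_r = cur
                        re_q = i + 1
                    elif best_r - cur > x_drop:
                        break
                    i += 1
                    j += 1
                # leftward x-drop extension
                cur = 0
                best_l = 0
                i = qp - 1
                j = spos - 1
                ls_q = qp
                while i >= 0 and j >= 0:
                    c = db[j]
                    if c == SENTINEL:
                        break
                    cur += S[q[i], c]
                    if cur > best_l:
                        best_l = cur
                        ls_q = i
                    elif best_l - cur > x_drop:
                        break
                    i -= 1
                    j -= 1
                total = sc + best_l + best_r
                se = spos + (re_q - qp)
                diag_cover[d] = se
                if total >= min_keep:
                    if n_out >= out.shape[0]:
                        return -1
                    out[n_out, 0] = ls_q
                    out[n_out, 1] = re_q
                    out[n_out, 2] = spos - (qp - ls_q)
                    out[n_out, 3] = se
                    out[n_out, 4] = total
                    n_out += 1
    return n_out
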