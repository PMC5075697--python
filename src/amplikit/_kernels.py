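"""Numba kernels for the dynamic-programming inner loops.

All kernels work on uint8 code arrays (IUPAC 4-bit masks) and an int64
16x16 substitution matrix.  Gap penalties are position dependent: a gap in
the query (consuming target symbols) is charged terminal rates on the first
and last query row, interior rates elsewhere; symmetrically for gaps in the
target.  Penalty vector layout (all non-negative int64):

    0 query-gap open, interior    4 target-gap open, interior
    1 query-gap extend, interior  5 target-gap extend, interior
    2 query-gap open, terminal    6 target-gap open, terminal
    3 query-gap extend, terminal  7 target-gap extend, terminal
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int64(-(1 << 40))

# move codes in traceback outputs
MOVE_DIAG = 0  # consume one query and one target symbol
MOVE_E = 1  # gap in query: consume target only
MOVE_F = 2  # gap in target: consume query only


@njit(cache=True)
def _rates(pens, edge):
    """(open, extend) picking terminal rates when ``edge`` is true."""
    if edge:
        return pens[2], pens[3]
    return pens[0], pens[1]


@njit(cache=True)
def gotoh_full(a, b, S, pens):
    """Full-matrix Gotoh with traceback.

    Returns (score, moves) where moves is a uint8 array of MOVE_* codes in
    alignment order.  Uses rolling score rows plus one byte per cell for
    the traceback.  Tie preference: diagonal, then gap-in-query, then
    gap-in-target, giving one canonical optimal alignment.
    """
    m = a.shape[0]
    n = b.shape[0]
    # traceback bits: 0-1 best-state at cell (0=M,1=E,2=F),
    #                 2 E-extends, 3 F-extends
    tb = np.zeros((m + 1, n + 1), dtype=np.uint8)
    Hp = np.empty(n + 1, dtype=np.int64)  # previous row, best of states
    Fp = np.empty(n + 1, dtype=np.int64)  # previous row, F state
    Hc = np.empty(n + 1, dtype=np.int64)
    Fc = np.empty(n + 1, dtype=np.int64)

    qo_t, qe_t = pens[2], pens[3]
    Hp[0] = 0
    Fp[0] = NEG
    e = NEG
    for j in range(1, n + 1):
        eo = Hp[j - 1] - qo_t - qe_t  # row 0: terminal query-gap rates
        ee = e - qe_t
        if ee > eo:
            e = ee
            tb[0, j] = 1 | 4
        else:
            e = eo
            tb[0, j] = 1
        Hp[j] = e
        Fp[j] = NEG

    for i in range(1, m + 1):
        qopen, qext = _rates(pens[:4], i == 0 or i == m)
        # column 0: terminal target-gap rates
        to0, te0 = pens[6], pens[7]
        fo = Hp[0] - to0 - te0
        fe = Fp[0] - te0
        if fe > fo:
            Fc[0] = fe
            tb[i, 0] = 2 | 8
        else:
            Fc[0] = fo
            tb[i, 0] = 2
        Hc[0] = Fc[0]
        e = NEG
        ai = a[i - 1]
        for j in range(1, n + 1):
            if j == n:
                topen, text = pens[6], pens[7]
            else:
                topen, text = pens[4], pens[5]
            mval = Hp[j - 1] + S[ai, b[j - 1]]
            flags = np.uint8(0)
            fo = Hp[j] - topen - text
            fe = Fp[j] - text
            if fe > fo:
                f = fe
                flags |= 8
            else:
                f = fo
            eo = Hc[j - 1] - qopen - qext
            ee = e - qext
            if ee > eo:
                e = ee
                flags |= 4
            else:
                e = eo
            if mval >= e and mval >= f:
                h = mval
                state = np.uint8(0)
            elif e >= f:
                h = e
                state = np.uint8(1)
            else:
                h = f
                state = np.uint8(2)
            tb[i, j] = flags | state
            Hc[j] = h
            Fc[j] = f
        for j in range(n + 1):
            Hp[j] = Hc[j]
            Fp[j] = Fc[j]

    score = Hp[n]
    # decode traceback
    moves = np.empty(m + n, dtype=np.uint8)
    k = m + n
    i = m
    j = n
    state = tb[i, j] & 3
    while i > 0 or j > 0:
        k -= 1
        if state == 0:
            moves[k] = MOVE_DIAG
            i -= 1
            j -= 1
            state = tb[i, j] & 3
        elif state == 1:
            moves[k] = MOVE_E
            extend = tb[i, j] & 4
            j -= 1
            if not extend:
                state = tb[i, j] & 3
        else:
            moves[k] = MOVE_F
            extend = tb[i, j] & 8
            i -= 1
            if not extend:
                state = tb[i, j] & 3
    return score, moves[k:]


@njit(cache=True)
def gotoh_forward(a, b, i1, i2, j1, j2, m, n, top_free, S, pens):
    """Forward score vectors for the divide-and-conquer aligner.

    Aligns query rows i1..i2 against target columns j1..j2 of the full
    problem (absolute coordinates select terminal vs interior gap rates).
    Returns (CC, DD): CC[jj] is the best score of a path from (i1,j1) to
    (i2,j1+jj) in any state; DD[jj] the best ending inside a vertical gap
    run (gap in the target, query symbols consumed), open charged.  With
    ``top_free`` a vertical gap run starting at the (i1,j1) corner is not
    charged its open penalty (it continues a run from the caller).
    """
    W = j2 - j1
    H = np.empty(W + 1, dtype=np.int64)
    F = np.empty(W + 1, dtype=np.int64)
    Hn = np.empty(W + 1, dtype=np.int64)
    Fn = np.empty(W + 1, dtype=np.int64)

    qopen, qext = _rates(pens[:4], i1 == 0 or i1 == m)
    H[0] = 0
    F[0] = NEG
    e = NEG
    for jj in range(1, W + 1):
        eo = H[jj - 1] - qopen - qext
        ee = e - qext
        e = ee if ee > eo else eo
        H[jj] = e
        F[jj] = NEG

    for i in range(i1 + 1, i2 + 1):
        qopen, qext = _rates(pens[:4], i == 0 or i == m)
        ai = a[i - 1]
        for jj in range(W + 1):
            j = j1 + jj
            topen, text = _rates(pens[4:], j == 0 or j == n)
            if jj == 0 and top_free and i == i1 + 1:
                fo = H[0] - text  # run starts at the corner: open waived
            else:
                fo = H[jj] - topen - text
            fe = F[jj] - text
            Fn[jj] = fe if fe > fo else fo
        e = NEG
        Hn[0] = Fn[0]
        for jj in range(1, W + 1):
            mval = H[jj - 1] + S[ai, b[j1 + jj - 1]]
            eo = Hn[jj - 1] - qopen - qext
            ee = e - qext
            e = ee if ee > eo else eo
            h = mval
            if e > h:
                h = e
            if Fn[jj] > h:
                h = Fn[jj]
            Hn[jj] = h
        for jj in range(W + 1):
            H[jj] = Hn[jj]
            F[jj] = Fn[jj]
    return H, F


@njit(cache=True)
def merge_offset_scan(fcodes, fquals, rcodes, rquals, score_eq, score_ne):
    """Best ungapped overlap of a forward read and a reverse-complemented
    reverse read.

    ``score_eq[q1, q2]`` / ``score_ne[q1, q2]`` are the per-column
    quality-weighted contributions for observed-equal / observed-different
    bases.  Offsets place the reverse-complement start ``d`` columns right
    of the forward start; d < 0 is a staggered arrangement.  Returns
    (best_d, best_score, n_diffs_at_best, best_overlap).  Ties prefer the
    smaller overlap.
    """
    lf = fcodes.shape[0]
    lr = rcodes.shape[0]
    best_d = -(10**9)
    best_score = -np.inf
    best_diffs = -1
    best_olen = -1
    for d in range(-(lr - 1), lf):
        lo = d if d > 0 else 0
        hi = d + lr if d + lr < lf else lf
        olen = hi - lo
        if olen < 1:
            continue
        total = 0.0
        ndiff = 0
        for p in range(lo, hi):
            fq = fquals[p]
            rq = rquals[p - d]
            if fcodes[p] == rcodes[p - d]:
                total += score_eq[fq, rq]
            else:
                total += score_ne[fq, rq]
                ndiff += 1
        better = total > best_score
        if not better and total == best_score and olen < best_olen:
            better = True
        if better:
            best_score = total
            best_d = d
            best_diffs = ndiff
            best_olen = olen
    return best_d, best_score, best_diffs, best_olen
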