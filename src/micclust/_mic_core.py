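"""Numerical kernels for the MIC grid search (numba-compiled).

All mutual-information arithmetic is in bits (base-2 logs), accumulated in
double precision.  Positions are indices into the sorted order of an axis;
cut candidates sit only between distinct values, so bins are well-defined
functions of the data and never split ties.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def best_mi_2x2(cum, candx, candy, n):
    """Exact maximum MI over all single-cut 2x2 grids.

    ``cum[i, j]`` counts points with x-order < i and y-order < j.
    """
    best = 0.0
    for ii in range(candx.shape[0]):
        i = candx[ii]
        for jj in range(candy.shape[0]):
            j = candy[jj]
            a = cum[i, j]
            b = i - a
            c = j - a
            d = n - i - j + a
            mi = 0.0
            if a > 0:
                mi += a / n * math.log2(a * n / (i * j))
            if b > 0:
                mi += b / n * math.log2(b * n / (i * (n - j)))
            if c > 0:
                mi += c / n * math.log2(c * n / ((n - i) * j))
            if d > 0:
                mi += d / n * math.log2(d * n / ((n - i) * (n - j)))
            if mi > best:
                best = mi
    return best


@njit(cache=True)
def _seg_term(pref, i, j, n, nx):
    # MI contribution of the y-segment (i, j]; additive across segments
    # because the x-marginal is fixed.
    seg = j - i
    tot = 0.0
    for a in range(nx):
        c = pref[a, j] - pref[a, i]
        if c > 0:
            colx = pref[a, n]
            tot += (c / n) * math.log2(c * n / (seg * colx))
    return tot


@njit(cache=True)
def dp_best_mi(pref, cand, ny):
    """Exact DP over placements of ny-1 cuts on the free axis.

    ``pref`` is the (nx, n+1) prefix-count matrix of fixed-axis bin
    membership in free-axis sorted order; ``cand`` the admissible cut
    positions.  Returns the maximal grid MI, or -1 if infeasible.
    """
    nx = pref.shape[0]
    n = pref.shape[1] - 1
    M = cand.shape[0]
    if ny - 1 > M:
        return -1.0
    NEG = -1e18
    D = np.full((ny - 1, M), NEG)
    for t in range(M):
        D[0, t] = _seg_term(pref, 0, cand[t], n, nx)
    for k in range(1, ny - 1):
        for t in range(k, M):
            best = NEG
            for s in range(k - 1, t):
                prev = D[k - 1, s]
                if prev > NEG / 2.0:
                    v = prev + _seg_term(pref, cand[s], cand[t], n, nx)
                    if v > best:
                        best = v
            D[k, t] = best
    best = NEG
    for t in range(ny - 2, M):
        prev = D[ny - 2, t]
        if prev > NEG / 2.0:
            v = prev + _seg_term(pref, cand[t], n, n, nx)
            if v > best:
                best = v
    return best


@njit(cache=True)
def _equifreq_cuts_nb(cand, n, nbins, out):
    """Snap ideal equifrequency boundaries to admissible cut positions.

    Mirrors the reference implementation in mic.py exactly.  Returns False
    when there are not enough candidates.
    """
    ncuts = nbins - 1
    if cand.shape[0] < ncuts:
        return False
    prev = -1
    for b in range(1, nbins):
        lo = prev + 1
        hi = cand.shape[0] - (ncuts - b)
        ideal = b * n / nbins
        i = np.searchsorted(cand, ideal)
        if i < lo:
            i = lo
        if i > hi - 1:
            i = hi - 1
        if i > lo and abs(cand[i - 1] - ideal) <= abs(cand[i] - ideal):
            i -= 1
        if i < lo:
            i = lo
        if i > hi - 1:
            i = hi - 1
        out[b - 1] = cand[i]
        prev = i
    return True


@njit(cache=True)
def _dp_orientation_nb(pos_fix, order_opt, cand_fix, cand_opt, n, nfix, nopt):
    """Equifrequency partition on the fixed axis, DP on the other (batch path)."""
    cuts = np.empty(nfix - 1, dtype=np.int64)
    if not _equifreq_cuts_nb(cand_fix, n, nfix, cuts):
        return 0.0
    if cand_opt.shape[0] < nopt - 1:
        return 0.0
    pref = np.zeros((nfix, n + 1), dtype=np.int64)
    for r in range(n):
        p = order_opt[r]
        b = np.searchsorted(cuts, pos_fix[p], side="right")
        for a in range(nfix):
            pref[a, r + 1] = pref[a, r]
        pref[b, r + 1] += 1
    val = dp_best_mi(pref, cand_opt, nopt)
    if val < 0.0:
        return 0.0
    return val


@njit(cache=True)
def _build_T(pref, cand, n, nfix):
    """Segment-term matrix over boundary positions [0, cand..., n].

    ``T[a, b]`` is the MI contribution of the free-axis segment between
    boundary a and boundary b; shared by every DP with this fixed partition.
    """
    M = cand.shape[0]
    T = np.zeros((M + 2, M + 2))
    for a in range(M + 1):
        ia = 0 if a == 0 else cand[a - 1]
        for b in range(a + 1, M + 2):
            jb = n if b == M + 1 else cand[b - 1]
            T[a, b] = _seg_term(pref, ia, jb, n, nfix)
    return T


@njit(cache=True)
def _dp_with_T(T, M, ny):
    """dp_best_mi with the segment terms precomputed (same arithmetic)."""
    if ny - 1 > M:
        return -1.0
    NEG = -1e18
    D = np.full((ny - 1, M), NEG)
    for t in range(M):
        D[0, t] = T[0, t + 1]
    for k in range(1, ny - 1):
        for t in range(k, M):
            best = NEG
            for s in range(k - 1, t):
                prev = D[k - 1, s]
                if prev > NEG / 2.0:
                    v = prev + T[s + 1, t + 1]
                    if v > best:
                        best = v
            D[k, t] = best
    best = NEG
    for t in range(ny - 2, M):
        prev = D[ny - 2, t]
        if prev > NEG / 2.0:
            v = prev + T[t + 1, M + 1]
            if v > best:
                best = v
    return best


@njit(cache=True)
def _orientation_pref_nb(pos_fix, order_opt, cand_fix, n, nfix):
    """Prefix-count matrix of the equifrequency fixed-axis partition, or None."""
    cuts = np.empty(nfix - 1, dtype=np.int64)
    if not _equifreq_cuts_nb(cand_fix, n, nfix, cuts):
        return np.zeros((0, 0), dtype=np.int64)
    pref = np.zeros((nfix, n + 1), dtype=np.int64)
    for r in range(n):
        p = order_opt[r]
        b = np.searchsorted(cuts, pos_fix[p], side="right")
        for a in range(nfix):
            pref[a, r + 1] = pref[a, r]
        pref[b, r + 1] += 1
    return pref


@njit(cache=True)
def mic_one_heuristic(x, y, shapes):
    """MIC of one pair via the scalable search (2x2 exhaustive for n <= 200,
    equifrequency/DP elsewhere).  Valid for n > 20 only; mirrors mic_score."""
    n = x.shape[0]
    ox = np.argsort(x, kind="mergesort")
    oy = np.argsort(y, kind="mergesort")
    posx = np.empty(n, dtype=np.int64)
    posy = np.empty(n, dtype=np.int64)
    for r in range(n):
        posx[ox[r]] = r
        posy[oy[r]] = r
    ncx = 0
    ncy = 0
    candx = np.empty(n - 1, dtype=np.int64)
    candy = np.empty(n - 1, dtype=np.int64)
    for r in range(1, n):
        if x[ox[r]] > x[ox[r - 1]]:
            candx[ncx] = r
            ncx += 1
        if y[oy[r]] > y[oy[r - 1]]:
            candy[ncy] = r
            ncy += 1
    cx = candx[:ncx]
    cy = candy[:ncy]
    cum = np.zeros((n + 1, n + 1), dtype=np.int64)
    for p in range(n):
        cum[posx[p] + 1, posy[p] + 1] = 1
    for i in range(1, n + 1):
        for j in range(1, n + 1):
            cum[i, j] += cum[i - 1, j] + cum[i, j - 1] - cum[i - 1, j - 1]
    S = shapes.shape[0]
    mi_shape = np.zeros(S)
    done = np.zeros(S, dtype=np.bool_)
    for s in range(S):
        if shapes[s, 0] == 2 and shapes[s, 1] == 2 and n <= 200:
            mi_shape[s] = best_mi_2x2(cum, cx, cy, n)
            done[s] = True
    # group DP work by (fixed axis, bin count): the segment-term matrix is
    # shared by every shape using that fixed partition
    for axis in range(2):
        if axis == 0:
            pos_fix, order_opt, cand_fix, cand_opt = posx, oy, cx, cy
        else:
            pos_fix, order_opt, cand_fix, cand_opt = posy, ox, cy, cx
        M = cand_opt.shape[0]
        maxfix = 0
        for s in range(S):
            if not done[s] and shapes[s, axis] > maxfix:
                maxfix = shapes[s, axis]
        for nfix in range(2, maxfix + 1):
            needed = False
            for s in range(S):
                if not done[s] and shapes[s, axis] == nfix:
                    needed = True
            if not needed:
                continue
            pref = _orientation_pref_nb(pos_fix, order_opt, cand_fix, n, nfix)
            if pref.shape[0] == 0:
                continue
            T = _build_T(pref, cand_opt, n, nfix)
            for s in range(S):
                if done[s] or shapes[s, axis] != nfix:
                    continue
                nopt = shapes[s, 1 - axis]
                val = _dp_with_T(T, M, nopt)
                if val > mi_shape[s]:
                    mi_shape[s] = val
    best = 0.0
    for s in range(S):
        mn = shapes[s, 0] if shapes[s, 0] < shapes[s, 1] else shapes[s, 1]
        sc = mi_shape[s] / math.log2(mn)
        if sc > best:
            best = sc
    if best > 1.0:
        best = 1.0
    return best


@njit(cache=True)
def mic_batch(blood, cancer, shapes):
    """Per-column MIC over paired (n, m) matrices via mic_one_heuristic."""
    n, m = blood.shape
    out = np.empty(m)
    for j in range(m):
        out[j] = mic_one_heuristic(blood[:, j].copy(), cancer[:, j].copy(), shapes)
    return out
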