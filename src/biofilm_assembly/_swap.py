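"""JIT-compiled kernels for marginal-preserving incidence randomization.

One null replicate is produced in three stages:

1. random sequential allocation of an integer matrix with the observed row
   and column sums (dealing a shuffled multiset of column labels to rows);
2. quasiswap moves on random 2x2 submatrices, each strictly reducing the
   number of super-binary entries, until the matrix is 0/1;
3. a burn-in of plain checkerboard (binary) swaps for extra mixing — a
   symmetric Markov chain whose stationary distribution is uniform over the
   feasible matrix set.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def seed_numba(seed: int) -> None:
    np.random.seed(seed)


@njit(cache=True)
def _deal_fill(row_sums, col_sums):
    """Integer matrix with the given marginals by random sequential allocation."""
    n = row_sums.shape[0]
    total = 0
    for j in range(col_sums.shape[0]):
        total += col_sums[j]
    labels = np.empty(total, dtype=np.int64)
    k = 0
    for j in range(col_sums.shape[0]):
        for _ in range(col_sums[j]):
            labels[k] = j
            k += 1
    # Fisher-Yates shuffle
    for i in range(total - 1, 0, -1):
        j = np.random.randint(0, i + 1)
        tmp = labels[i]
        labels[i] = labels[j]
        labels[j] = tmp
    m = np.zeros((n, col_sums.shape[0]), dtype=np.int64)
    k = 0
    for i in range(n):
        for _ in range(row_sums[i]):
            m[i, labels[k]] += 1
            k += 1
    return m


@njit(cache=True)
def _excess(m) -> int:
    e = 0
    for i in range(m.shape[0]):
        for j in range(m.shape[1]):
            if m[i, j] > 1:
                e += m[i, j] - 1
    return e


@njit(cache=True)
def _quasiswap_binarize(m, max_iter: int) -> int:
    """Quasiswap moves on random 2x2 submatrices until the matrix is binary.

    Applied moves never increase the number of super-binary entries; moves
    that keep it constant are accepted so the walk can escape configurations
    (frequent in dense matrices) where no single strictly-reducing move
    exists.  The submatrix is drawn so that one corner is a super-binary cell
    — a rejection-free variant of picking fully at random, since a 2x2 with
    no entry > 1 never yields an accepted move here.  Returns the number of
    attempts, or -1 when ``max_iter`` was hit.
    """
    n, t = m.shape
    # registry of super-binary cells with O(1) insert/remove
    cap = n * t
    sb_i = np.empty(cap, dtype=np.int64)
    sb_k = np.empty(cap, dtype=np.int64)
    sb_pos = np.full((n, t), -1, dtype=np.int64)
    n_sb = 0
    for i in range(n):
        for k in range(t):
            if m[i, k] > 1:
                sb_i[n_sb] = i
                sb_k[n_sb] = k
                sb_pos[i, k] = n_sb
                n_sb += 1
    it = 0
    while n_sb > 0:
        if it >= max_iter:
            return -1
        it += 1
        pick = np.random.randint(0, n_sb)
        i = sb_i[pick]
        k = sb_k[pick]
        j = np.random.randint(0, n)
        if j == i:
            continue
        l = np.random.randint(0, t)
        if l == k:
            continue
        a = m[i, k]
        b = m[i, l]
        c = m[j, k]
        d = m[j, l]
        if d <= 0:
            continue
        e_before = (
            (a - 1 if a > 1 else 0)
            + (b - 1 if b > 1 else 0)
            + (c - 1 if c > 1 else 0)
            + (d - 1 if d > 1 else 0)
        )
        # move a--, d--, b++, c++ (marginals preserved)
        na, nb, nc, nd = a - 1, b + 1, c + 1, d - 1
        e_after = (
            (na - 1 if na > 1 else 0)
            + (nb - 1 if nb > 1 else 0)
            + (nc - 1 if nc > 1 else 0)
            + (nd - 1 if nd > 1 else 0)
        )
        if e_after > e_before:
            continue
        m[i, k] = na
        m[i, l] = nb
        m[j, k] = nc
        m[j, l] = nd
        for (ri, rk, old, new) in (
            (i, k, a, na),
            (i, l, b, nb),
            (j, k, c, nc),
            (j, l, d, nd),
        ):
            was = old > 1
            now = new > 1
            if now and not was:
                sb_i[n_sb] = ri
                sb_k[n_sb] = rk
                sb_pos[ri, rk] = n_sb
                n_sb += 1
            elif was and not now:
                p = sb_pos[ri, rk]
                n_sb -= 1
                li, lk = sb_i[n_sb], sb_k[n_sb]
                sb_i[p] = li
                sb_k[p] = lk
                sb_pos[li, lk] = p
                sb_pos[ri, rk] = -1
    return it


@njit(cache=True)
def _binary_burnin(m, n_swaps: int) -> None:
    """Checkerboard swaps on a binary matrix (symmetric chain, uniform target)."""
    n, t = m.shape
    for _ in range(n_swaps):
        i = np.random.randint(0, n)
        j = np.random.randint(0, n)
        if i == j:
            continue
        k = np.random.randint(0, t)
        l = np.random.randint(0, t)
        if k == l:
            continue
        a = m[i, k]
        b = m[i, l]
        c = m[j, k]
        d = m[j, l]
        if a == 1 and d == 1 and b == 0 and c == 0:
            m[i, k] = 0
            m[i, l] = 1
            m[j, k] = 1
            m[j, l] = 0
        elif a == 0 and d == 0 and b == 1 and c == 1:
            m[i, k] = 1
            m[i, l] = 0
            m[j, k] = 0
            m[j, l] = 1


@njit(cache=True)
def null_replicate(row_sums, col_sums, burnin_factor: int, max_iter: int):
    """One quasiswap null incidence matrix with the given marginals.

    Returns (matrix, status); status is -1 when binarization did not finish
    within ``max_iter`` quasiswap attempts.
    """
    m = _deal_fill(row_sums, col_sums)
    status = _quasiswap_binarize(m, max_iter)
    if status < 0:
        return m, -1
    fill = 0
    for i in range(row_sums.shape[0]):
        fill += row_sums[i]
    _binary_burnin(m, burnin_factor * fill)
    return m, status
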