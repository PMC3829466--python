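"""Numba kernels for the circular binary segmentation scan and permutation test.

The maximal circular two-sample t statistic over arcs [i, j) of a segment of
length m is a monotone transform of

    Q(i, j) = (C_j - C_i)^2 * m / (k * (m - k)),   k = j - i,

where C is the prefix sum of mean-centred values:  t^2 = (m-2) Q / (SS - Q)
with SS the total centred sum of squares.  Permuting the values leaves m and
SS unchanged, so comparing permuted maxima with the observed maximum on the
Q scale is exactly equivalent to comparing t statistics.

Two exact accelerations keep plain permutation affordable:

* per-arc-width pruning: for width k, Q <= range(C)^2 * m / (k (m-k)), so a
  permutation scan can skip every width whose bound cannot reach the target;
* sequential early stop: once the exceedance count proves p > alpha the
  remaining permutations cannot change the accept/reject decision.

Both leave decisions and p-values identical to the naive full scan with the
same RNG stream.

Admissible arcs leave every nonempty flanking piece at least 2 probes long
(needed for a variance after the split): i in {0} + [2, ...], j in
[..., m-2] + {m}, and 2 <= j - i <= m - 2.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["max_arc_stat", "perm_exceed_count"]


@njit(cache=True)
def _centered_prefix(x):
    m = x.size
    mean = 0.0
    for t in range(m):
        mean += x[t]
    mean /= m
    C = np.empty(m + 1)
    C[0] = 0.0
    s = 0.0
    ss = 0.0
    for t in range(m):
        d = x[t] - mean
        s += d
        ss += d * d
        C[t + 1] = s
    return C, ss


@njit(cache=True)
def max_arc_stat(x):
    """Exhaustive arc scan: returns (i, j, q_max, ss).

    Ties in q are broken toward the smallest (i, then j); q_max < 0 signals
    that no admissible arc exists (m < 4).
    """
    m = x.size
    C, ss = _centered_prefix(x)
    best = -1.0
    bi = -1
    bj = -1
    for k in range(2, m - 1):
        w = m / (k * (m - k))
        for i in range(0, m - k + 1):
            j = i + k
            if i == 1 or m - j == 1:
                continue
            z = C[j] - C[i]
            q = z * z * w
            if q > best or (q == best and (i < bi or (i == bi and j < bj))):
                best = q
                bi = i
                bj = j
    return bi, bj, best, ss


@njit(cache=True)
def _any_arc_reaches(x, q_thresh):
    """True iff some admissible arc of x attains Q >= q_thresh (> 0)."""
    m = x.size
    C, _ = _centered_prefix(x)
    cmin = 0.0
    cmax = 0.0
    for t in range(m + 1):
        if C[t] < cmin:
            cmin = C[t]
        if C[t] > cmax:
            cmax = C[t]
    rng2 = (cmax - cmin) * (cmax - cmin)
    if rng2 * m / (2.0 * (m - 2.0)) < q_thresh:
        return False  # even the loosest admissible width cannot reach
    # widths with k*(m-k) <= A admit Q >= q_thresh; others are pruned
    A = rng2 * m / q_thresh
    disc = m * m - 4.0 * A
    if disc <= 0.0:
        k_lo = m  # no pruning possible: scan every width
        k_hi = 0
    else:
        root = np.sqrt(disc)
        k_lo = int(np.floor((m - root) / 2.0))
        k_hi = int(np.ceil((m + root) / 2.0))
    for k in range(2, m - 1):
        if k_lo < k < k_hi:
            continue
        w = m / (k * (m - k))
        zmin2 = q_thresh / w
        for i in range(0, m - k + 1):
            j = i + k
            if i == 1 or m - j == 1:
                continue
            z = C[j] - C[i]
            if z * z >= zmin2:
                return True
    return False


@njit(cache=True)
def perm_exceed_count(x, q_obs, n_perm, stop_above, seed):
    """Count permutations whose maximal arc Q reaches q_obs.

    Stops early (returning the running count and permutations done) as soon
    as the count exceeds ``stop_above``; pass stop_above >= n_perm for an
    exact full count.  The shuffle stream is seeded Fisher-Yates, so a given
    (x, seed) always sees the same permutation sequence.
    """
    m = x.size
    xp = x.copy()
    np.random.seed(seed)
    exceed = 0
    for p in range(n_perm):
        for t in range(m - 1, 0, -1):
            r = np.random.randint(0, t + 1)
            tmp = xp[t]
            xp[t] = xp[r]
            xp[r] = tmp
        if _any_arc_reaches(xp, q_obs):
            exceed += 1
            if exceed > stop_above:
                return exceed, p + 1
    return exceed, n_perm
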