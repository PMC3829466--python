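"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is written from first principles (plain loops over the
definitions) and deliberately shares no code with the package internals.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_max_arc(x: np.ndarray):
    """Exhaustive search for the arc [i, j) with maximal absolute pooled
    two-sample t statistic against its complement.

    Admissible arcs leave every nonempty flank >= 2 probes and both groups
    nonempty; ties go to the smallest (i, then j).  Returns (i, j, t).
    """
    m = len(x)
    best = (-1.0, None, None)
    for i in range(0, m - 1):
        if i == 1:
            continue
        for j in range(i + 2, m + 1):
            if (j - i) > m - 2 or (m - j) == 1:
                continue
            arc = x[i:j]
            rest = np.concatenate((x[:i], x[j:]))
            n1, n2 = len(arc), len(rest)
            ss = np.sum((arc - arc.mean()) ** 2) + np.sum((rest - rest.mean()) ** 2)
            if ss <= 1e-300:
                # zero within-group variance: infinite separation unless the
                # group means coincide too (fully constant segment)
                t = math.inf if abs(arc.mean() - rest.mean()) > 0 else 0.0
            else:
                sp2 = ss / (m - 2)
                t = abs(arc.mean() - rest.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
            if t > best[0]:
                best = (t, i, j)
    return best[1], best[2], best[0]


def oracle_lrs(x: np.ndarray, L: int, threshold: float, sigma: float):
    """Pick-global-max-then-remove-overlaps selection over all intervals of
    width <= L whose standardised sum exceeds the threshold."""
    N = len(x)
    cands = []
    for s in range(N):
        for e in range(s + 1, min(s + L, N) + 1):
            X = abs(np.sum(x[s:e])) / (math.sqrt(e - s) * sigma)
            if X > threshold:
                cands.append((X, s, e))
    picked = []
    while cands:
        best = max(cands, key=lambda c: (c[0], -c[1], -(c[2] - c[1])))
        picked.append((best[1], best[2]))
        cands = [c for c in cands if c[2] <= best[1] or c[1] >= best[2]]
    return sorted(picked)


def fused_lasso_objective(y, beta, lam1, lam2):
    beta = np.asarray(beta, dtype=float)
    return (
        float(np.sum((y - beta) ** 2))
        + lam1 * float(np.sum(np.abs(beta)))
        + lam2 * float(np.sum(np.abs(np.diff(beta))))
    )


def dp_fused_lasso(y: np.ndarray, lam1: float, lam2: float, step: float = 0.01):
    """Global minimum of the fused-lasso objective over a discrete level grid
    (dynamic programming over positions); exact up to grid resolution."""
    lo = min(0.0, float(np.min(y))) - 2 * step
    hi = max(0.0, float(np.max(y))) + 2 * step
    levels = np.arange(lo, hi + step, step)
    G = len(levels)
    cost = (y[0] - levels) ** 2 + lam1 * np.abs(levels)
    for t in range(1, len(y)):
        trans = cost[:, None] + lam2 * np.abs(levels[:, None] - levels[None, :])
        cost = trans.min(axis=0) + (y[t] - levels) ** 2 + lam1 * np.abs(levels)
    return float(cost.min())


def tv_kkt_violation(y: np.ndarray, x: np.ndarray, lam: float) -> float:
    """Maximal KKT violation of a candidate TV-denoising solution.

    x minimises (1/2)||y-x||^2 + lam*TV(x) iff the dual z (cumulative
    residuals z_j = sum_{t<=j}(y_t - x_t)) satisfies |z_j| <= lam for j < N-1,
    z_{N-1} = 0, and z_j = -lam*sign(x_{j+1} - x_j) wherever x jumps
    (stationarity of each coordinate, telescoped).
    """
    z = np.cumsum(y - x)
    viol = abs(z[-1])
    if len(z) > 1:
        viol = max(viol, max(0.0, float(np.max(np.abs(z[:-1]))) - lam))
    for j in range(len(y) - 1):
        d = x[j + 1] - x[j]
        if d > 1e-9:
            viol = max(viol, abs(z[j] + lam))
        elif d < -1e-9:
            viol = max(viol, abs(z[j] - lam))
    return viol


def best_subset_mbic(score_fn, candidates):
    """Exhaustive best-subset search over breakpoint candidates using the
    provided scoring callable; ties prefer fewer breakpoints."""
    best = (score_fn(()), 0, ())
    for r in range(1, len(candidates) + 1):
        for sub in itertools.combinations(candidates, r):
            s = score_fn(sub)
            if s > best[0] + 1e-12:
                best = (s, r, sub)
    return best[2], best[0]
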