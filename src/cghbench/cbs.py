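"""Circular binary segmentation (CBS) with permutation stopping, plus mBIC.

CBS hunts for the arc of a segment whose mean differs most from the rest of
the segment (the maximal circular two-sample t statistic), decides whether
the split is significant by permuting the probes, and recurses on the pieces
until no split is significant.  The p-value stopping rule can optionally be
followed by a modified-BIC backward selection that prunes the accepted
breakpoints; the mBIC machinery here is shared with the SaRa segmenter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._cbs_kernels import max_arc_stat, perm_exceed_count
from .types import ChangePointSet, ProbeSeries

__all__ = [
    "CbsConfig",
    "circular_max_stat",
    "permutation_pvalue",
    "cbs_segment",
    "mbic_score",
    "mbic_backward_select",
]

_STOP_RULES = ("pvalue", "mbic")


@dataclass(frozen=True)
class CbsConfig:
    """alpha: per-split significance level; n_perm: permutations per test."""

    alpha: float = 0.01
    n_perm: int = 10_000
    stop_rule: str = "pvalue"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.stop_rule not in _STOP_RULES:
            raise ValueError(f"stop_rule must be one of {_STOP_RULES}")


def _q_to_t(q: float, ss: float, m: int) -> float:
    if ss <= 0.0 or q <= 0.0:
        return 0.0
    resid = ss - q
    if resid <= 1e-12 * ss:  # (near-)perfect fit by the arc means
        resid = 1e-12 * ss
    return math.sqrt((m - 2) * q / resid)


def circular_max_stat(segment: np.ndarray) -> tuple[int, int, float]:
    """Arc (i, j) maximising the absolute circular two-sample t statistic.

    The arc [i, j) is compared against the rest of the segment with a pooled
    two-sample t; an arc touching an end encodes a single change point.
    Constant segments return t_max = 0.  Ties go to the smallest (i, then j).
    """
    x = np.ascontiguousarray(segment, dtype=float)
    if x.size < 4:
        raise ValueError("circular_max_stat needs at least 4 probes")
    i, j, q, ss = max_arc_stat(x)
    if ss <= 0.0 or q <= 0.0:
        # zero-variance convention; report the first admissible arc
        return 0, 2, 0.0
    return int(i), int(j), _q_to_t(q, ss, x.size)


def permutation_pvalue(segment: np.ndarray, t_obs: float, n_perm: int, seed: int) -> float:
    """p = (1 + #{perm with max stat >= t_obs}) / (1 + n_perm)."""
    x = np.ascontiguousarray(segment, dtype=float)
    if x.size < 4:
        raise ValueError("permutation_pvalue needs at least 4 probes")
    _, _, q_obs, ss = max_arc_stat(x)
    if ss <= 0.0 or t_obs <= 0.0:
        return 1.0
    # invert t_obs back to the Q scale used inside the kernel
    q_t = t_obs * t_obs * ss / (x.size - 2 + t_obs * t_obs)
    exceed, _ = perm_exceed_count(x, q_t, n_perm, n_perm + 1, seed)
    return (1 + exceed) / (1 + n_perm)


def _segment_seed(seed: int, lo: int, hi: int) -> int:
    return int(np.random.SeedSequence((seed, lo, hi)).generate_state(1)[0] % (2**31))


def cbs_segment(series: ProbeSeries, config: CbsConfig = CbsConfig()) -> ChangePointSet:
    """Recursive CBS on one chromosome.

    With ``stop_rule="pvalue"`` a split is accepted iff its permutation
    p-value is <= alpha; ``stop_rule="mbic"`` additionally prunes the
    accepted breakpoints by mBIC backward selection.
    """
    x = series.values
    N = x.size
    # accept iff exceedances <= e_max  <=>  (1+e)/(1+n_perm) <= alpha
    e_max = math.floor(config.alpha * (1 + config.n_perm) - 1.0 + 1e-9)
    found: list[int] = []
    stack: list[tuple[int, int]] = [(0, N)]
    while stack:
        lo, hi = stack.pop()
        m = hi - lo
        if m < 4:
            continue
        seg = np.ascontiguousarray(x[lo:hi])
        i, j, q, ss = max_arc_stat(seg)
        if ss <= 0.0 or q <= 0.0 or e_max < 0:
            continue
        exceed, _ = perm_exceed_count(
            seg, q, config.n_perm, e_max, _segment_seed(config.seed, lo, hi)
        )
        if exceed > e_max:
            continue  # not significant
        if i > 0:
            found.append(lo + i)
        if j < m:
            found.append(lo + j)
        stack.append((lo, lo + i))
        stack.append((lo + i, lo + j))
        stack.append((lo + j, hi))
    cps = ChangePointSet(np.asarray(sorted(found), dtype=int), N)
    if config.stop_rule == "mbic":
        cps = mbic_backward_select(series, cps)
    return cps


def _segment_rss(S: np.ndarray, S2: np.ndarray, lo: int, hi: int) -> float:
    n = hi - lo
    s = S[hi] - S[lo]
    return float(S2[hi] - S2[lo] - s * s / n)


def mbic_score(series: ProbeSeries, cps: ChangePointSet) -> float:
    """Modified-BIC score of a breakpoint configuration (higher is better).

    score = (N/2) ln(RSS_0 / RSS_m) - (1/2) sum_i ln(n_i / N) - m ln N,
    with RSS around per-segment means; score of the empty configuration is 0.
    """
    x = series.values
    N = x.size
    m = len(cps)
    if m == 0:
        return 0.0
    edges = np.concatenate(([0], cps.indices, [N]))
    if np.any(np.diff(edges) <= 0):
        raise ValueError("breakpoint configuration induces an empty segment")
    S = np.concatenate(([0.0], np.cumsum(x)))
    S2 = np.concatenate(([0.0], np.cumsum(x * x)))
    rss0 = _segment_rss(S, S2, 0, N)
    rssm = sum(_segment_rss(S, S2, int(a), int(b)) for a, b in zip(edges[:-1], edges[1:]))
    if rss0 <= 0.0:
        fit_gain = 0.0
    else:
        rssm = max(rssm, 1e-12 * rss0)
        fit_gain = 0.5 * N * math.log(rss0 / rssm)
    n_i = np.diff(edges)
    return fit_gain - 0.5 * float(np.sum(np.log(n_i / N))) - m * math.log(N)


def mbic_backward_select(series: ProbeSeries, candidates: ChangePointSet) -> ChangePointSet:
    """Backward elimination on the mBIC score.

    Walks the full elimination path -- at each step dropping the breakpoint
    whose removal yields the highest score, even when no removal improves it
    -- and returns the best-scoring configuration visited (ties go to the
    sparser configuration).  Stopping at the first non-improving removal
    would strand spurious breakpoint *pairs*: deleting one member of a pair
    bridging a short noise segment worsens the fit, deleting both restores
    it, so only the full path reaches the optimum and matches exhaustive
    best-subset selection on small instances.
    """
    N = series.n_probes
    kept = list(candidates.indices)
    best_cfg = list(kept)
    best_score = mbic_score(series, ChangePointSet(np.asarray(kept, dtype=int), N))
    while kept:
        step_score = -math.inf
        step_idx = -1
        for idx in range(len(kept)):
            trial = kept[:idx] + kept[idx + 1 :]
            s = mbic_score(series, ChangePointSet(np.asarray(trial, dtype=int), N))
            if s > step_score:
                step_score = s
                step_idx = idx
        kept.pop(step_idx)
        if step_score >= best_score:  # ties -> sparser configuration
            best_score = step_score
            best_cfg = list(kept)
    return ChangePointSet(np.asarray(best_cfg, dtype=int), N)
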