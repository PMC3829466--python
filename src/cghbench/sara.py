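"""SaRa: screening-and-ranking breakpoint detection with mBIC pruning.

A local diagnostic D_h(x) = (mean of the h probes right of x) - (mean of the
h probes left of x) peaks at change points.  Screening keeps positions whose
standardised |D| clears a threshold and is a local maximum within h probes;
running three bandwidths (1, 2, 3 times ln N) and pooling the candidates
covers segments of unknown width.  The pool is pruned to a final change-point
configuration by the same modified-BIC backward selection CBS uses, and
segments between the surviving breakpoints are called CNVs when their mean
log2 ratio is large relative to the profile's MAD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._robust import mad_scale
from .cbs import mbic_backward_select
from .lrs import _sigma_with_fallback
from .types import ChangePointSet, CNVCall, ProbeSeries

__all__ = [
    "SaraConfig",
    "default_windows",
    "local_diagnostic",
    "screen_candidates",
    "sara_detect",
    "segments_to_calls",
]


def default_windows(N: int) -> tuple[int, ...]:
    """Bandwidths ceil(ln N), 2 ceil(ln N), 3 ceil(ln N)."""
    h = math.ceil(math.log(N))
    return (h, 2 * h, 3 * h)


# two-sided normal quantile at alpha = 0.01: screening is deliberately
# pointwise-liberal -- mBIC backward selection does the real model selection,
# and a familywise (extreme-value) screen would starve it of candidates
DEFAULT_SCREEN_THRESHOLD = 2.576


@dataclass(frozen=True)
class SaraConfig:
    """windows: sliding-window bandwidths (None = 1-3 x ceil(ln N));
    screen_threshold: cutoff on the standardised diagnostic (default the
    two-sided normal 0.01 quantile); mag_mad_mult: MAD multiplier for the
    calling step."""

    windows: tuple[int, ...] | None = None
    screen_threshold: float = DEFAULT_SCREEN_THRESHOLD
    mag_mad_mult: float = 1.5
    seed: int = 0

    def resolved_windows(self, N: int) -> tuple[int, ...]:
        ws = self.windows if self.windows is not None else default_windows(N)
        ws = tuple(sorted(int(h) for h in ws))
        if not ws or ws[0] < 1:
            raise ValueError("windows must be >= 1")
        if 2 * ws[-1] >= N:
            raise ValueError("largest window must satisfy 2*h < N")
        return ws

    def resolved_threshold(self, N: int) -> float:
        if self.screen_threshold <= 0:
            raise ValueError("screen_threshold must be positive")
        return self.screen_threshold


def local_diagnostic(series: ProbeSeries, h: int) -> np.ndarray:
    """D[x] = mean(values[x, x+h)) - mean(values[x-h, x)).

    Returned as a length-N vector, defined for x in [h, N-h] and NaN
    elsewhere; linear in the input.
    """
    x = series.values
    N = x.size
    if h < 1 or 2 * h > N:
        raise ValueError(f"bandwidth h={h} out of range for N={N}")
    S = np.concatenate(([0.0], np.cumsum(x)))
    D = np.full(N, np.nan)
    pos = np.arange(h, N - h + 1)
    D[pos] = (S[pos + h] - S[pos]) / h - (S[pos] - S[pos - h]) / h
    return D


def screen_candidates(
    D: np.ndarray, h: int, threshold: float, sigma_hat: float
) -> list[int]:
    """Positions where the standardised diagnostic |D| * sqrt(h/2) / sigma
    exceeds the threshold and D is a signed local maximum within (x-h, x+h).

    Upward jumps (D > 0) compete only with other upward values and downward
    with downward: the two boundaries of a segment as narrow as h lie inside
    each other's windows with opposite-signed peaks, and unsigned |D|
    competition would silently drop the weaker boundary.  Plateau ties keep
    the leftmost position.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if sigma_hat <= 0:
        raise ValueError("sigma_hat must be positive")
    Dv = np.where(np.isnan(D), 0.0, D)
    scale = math.sqrt(h / 2.0) / sigma_hat
    out: list[int] = []
    for x in np.flatnonzero(np.abs(Dv) * scale > threshold):
        sign = 1.0 if Dv[x] > 0 else -1.0
        side = sign * Dv  # candidate's own sign direction
        lo = max(0, x - h + 1)
        left = side[lo:x]
        right = side[x + 1 : x + h]
        if (left.size == 0 or side[x] > left.max()) and (
            right.size == 0 or side[x] >= right.max()
        ):
            out.append(int(x))
    return out


def sara_detect(series: ProbeSeries, config: SaraConfig = SaraConfig()) -> ChangePointSet:
    """Pool screened candidates over all bandwidths, merge near-duplicates,
    prune by mBIC backward selection."""
    N = series.n_probes
    windows = config.resolved_windows(N)
    threshold = config.resolved_threshold(N)
    sigma = _sigma_with_fallback(series)
    if sigma <= 0.0:
        return ChangePointSet.empty(N)
    pooled: dict[int, tuple[float, float]] = {}  # x -> (std |D|, sign)
    for h in windows:
        D = local_diagnostic(series, h)
        scale = math.sqrt(h / 2.0) / sigma
        for x in screen_candidates(D, h, threshold, sigma):
            val = abs(D[x]) * scale
            if x not in pooled or val > pooled[x][0]:
                pooled[x] = (val, 1.0 if D[x] > 0 else -1.0)
    if not pooled:
        return ChangePointSet.empty(N)
    min_h = windows[0]
    # merge same-sign candidates closer than the smallest window: keep the
    # larger standardised diagnostic (earlier position on ties); opposite
    # signs are distinct change points and are never merged
    merged: list[tuple[int, float, float]] = []
    for x in sorted(pooled):
        v, sgn = pooled[x]
        if merged and x - merged[-1][0] < min_h and sgn == merged[-1][2]:
            if v > merged[-1][1]:
                merged[-1] = (x, v, sgn)
        else:
            merged.append((x, v, sgn))
    idx = np.asarray([x for x, _, _ in merged if 0 < x < N], dtype=int)
    return mbic_backward_select(series, ChangePointSet(idx, N))


def segments_to_calls(
    series: ProbeSeries, cps: ChangePointSet, mad_mult: float = 1.5
) -> list[CNVCall]:
    """Call every induced segment whose |mean| >= mad_mult * MAD(series)."""
    x = series.values
    cut = mad_mult * mad_scale(x)
    calls: list[CNVCall] = []
    for a, b in cps.segment_bounds():
        mag = float(np.mean(x[a:b]))
        # strict positivity guards the degenerate cut = 0 (zero-MAD) case
        if abs(mag) >= cut and abs(mag) > 0:
            calls.append(CNVCall(start=int(a), end=int(b), magnitude=mag, method="sara"))
    return calls
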