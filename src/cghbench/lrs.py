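"""Bounded-width scan (LRS) for sparse copy-number segments.

Germline CNVs are short and rare, so instead of comparing candidate segments
against the whole chromosome, the scan standardises the summed log2 ratio of
every interval no wider than L probes,

    X(s, e) = sum_{k in [s, e)} y_k / (sqrt(e - s) * sigma_hat),

and keeps non-overlapping intervals whose |X| clears an extreme-value
threshold sqrt(2 ln(N L)) calibrated to the ~N*L intervals scanned.  Calling
and breakpoint detection happen in one step: each kept interval is a CNV
call.  Aberrations wider than L are out of scope for the scan (a global
segmenter handles those).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .types import CNVCall, ProbeSeries

__all__ = [
    "LrsConfig",
    "sigma_estimate",
    "interval_stat",
    "lrs_threshold",
    "lrs_detect",
]


@dataclass(frozen=True)
class LrsConfig:
    """L: maximum interval width in probes; threshold/sigma_hat default to
    lrs_threshold(N, L) and a difference-based MAD estimate."""

    L: int = 100
    threshold: float | None = None
    sigma_hat: float | None = None
    merge_adjacent: bool = False

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.threshold is not None and self.threshold <= 0:
            raise ValueError("threshold must be positive")


def sigma_estimate(series: ProbeSeries) -> float:
    """Robust noise scale from first differences.

    MAD of successive differences divided by 0.6745 * sqrt(2): insensitive to
    the sparse mean shifts, consistent for the noise sd under i.i.d. normal
    noise.  Returns 0.0 (with a warning) for a constant series.
    """
    x = series.values
    if x.size < 2:
        raise ValueError("sigma_estimate needs at least 2 probes")
    d = np.diff(x)
    mad = float(np.median(np.abs(d - np.median(d))))
    if mad == 0.0:
        warnings.warn("degenerate series: difference MAD is zero", stacklevel=2)
        return 0.0
    return mad / (0.6745 * math.sqrt(2.0))


def _sigma_with_fallback(series: ProbeSeries) -> float:
    """MAD-based estimate, falling back to the sd of first differences for
    (near-)noiseless piecewise-constant input."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        s = sigma_estimate(series)
    if s > 0.0:
        return s
    d = np.diff(series.values)
    return float(np.std(d)) / math.sqrt(2.0)


def interval_stat(series: ProbeSeries, start: int, end: int, sigma_hat: float) -> float:
    """Standardised interval sum X for probes [start, end)."""
    if sigma_hat <= 0:
        raise ValueError("sigma_hat must be positive")
    if not (0 <= start < end <= series.n_probes):
        raise ValueError(f"invalid interval [{start}, {end})")
    s = float(np.sum(series.values[start:end]))
    return s / (math.sqrt(end - start) * sigma_hat)


def lrs_threshold(N: int, L: int) -> float:
    """Extreme-value default threshold sqrt(2 ln(N * L)) (natural log)."""
    if N * L < 2:
        raise ValueError("N * L must be >= 2")
    return math.sqrt(2.0 * math.log(N * L))


def lrs_detect(series: ProbeSeries, config: LrsConfig = LrsConfig()) -> list[CNVCall]:
    """Greedy scan: emit the interval with the largest |X|, drop everything
    overlapping it, repeat.  Ties go to the leftmost, then shortest interval.

    Returns non-overlapping calls sorted by start; ``score`` is |X| and
    ``magnitude`` the mean log2 ratio over the call.
    """
    x = series.values
    N = x.size
    L = min(config.L, N)
    thr = config.threshold if config.threshold is not None else lrs_threshold(N, config.L)
    sigma = config.sigma_hat if config.sigma_hat is not None else _sigma_with_fallback(series)
    if sigma <= 0.0:
        return []  # constant series: nothing to call
    S = np.concatenate(([0.0], np.cumsum(x)))
    cands: list[tuple[float, int, int]] = []
    for w in range(1, L + 1):
        X = (S[w:] - S[:-w]) / (math.sqrt(w) * sigma)
        hits = np.flatnonzero(np.abs(X) > thr)
        for i in hits:
            cands.append((abs(float(X[i])), int(i), w))
    # greedy by score; leftmost then shortest on ties
    cands.sort(key=lambda c: (-c[0], c[1], c[2]))
    occupied = np.zeros(N, dtype=bool)
    picked: list[tuple[int, int, float]] = []
    for score, s0, w in cands:
        if occupied[s0 : s0 + w].any():
            continue
        occupied[s0 : s0 + w] = True
        picked.append((s0, s0 + w, score))
    picked.sort()
    calls = [
        CNVCall(
            start=s0,
            end=e0,
            magnitude=float(np.mean(x[s0:e0])),
            score=score,
            method="lrs",
        )
        for s0, e0, score in picked
    ]
    if config.merge_adjacent:
        calls = _merge_adjacent(calls, x)
    return calls


def _merge_adjacent(calls: list[CNVCall], x: np.ndarray) -> list[CNVCall]:
    """Optionally merge same-sign calls separated by < 2 probes."""
    merged: list[CNVCall] = []
    for c in calls:
        if (
            merged
            and c.start - merged[-1].end < 2
            and math.copysign(1, c.magnitude) == math.copysign(1, merged[-1].magnitude)
        ):
            prev = merged.pop()
            merged.append(
                CNVCall(
                    start=prev.start,
                    end=c.end,
                    magnitude=float(np.mean(x[prev.start : c.end])),
                    score=max(prev.score, c.score),
                    method="lrs",
                )
            )
        else:
            merged.append(c)
    return merged
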