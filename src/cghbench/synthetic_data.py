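"""Simulated array-CGH profiles: sparse mean-shift segments in i.i.d. noise.

The generator emulates a flat diploid baseline (log2 ratio 0) carrying one
copy-number segment per width multiplier k, of width round(k * ln N), evenly
spaced along the chromosome, with noise drawn either from a standard normal
or from a heavy-tailed t(8) distribution rescaled to unit variance. This is
the canonical single-chromosome test bed for comparing segmentation methods:
the difficulty of each planted segment is summarised by the detectability
index T = sqrt(n) * (mu/sigma) / sqrt(2 ln N).
"""

from __future__ import annotations

import math

import numpy as np

from .types import ProbeSeries, SimulationConfig, SimulationTruth, TrueSegment

__all__ = [
    "segment_widths",
    "build_truth",
    "sample_noise",
    "simulate_profile",
    "detectability_index",
    "rep_rng",
]

# Var(t_df) = df/(df-2); rescale so both noise families have unit variance
_T8_SCALE = math.sqrt(6.0 / 8.0)


def segment_widths(N: int, width_multipliers) -> list[int]:
    """Planted widths round(k * ln N) for each multiplier k."""
    if N < 2:
        raise ValueError("N must be >= 2")
    return [int(round(k * math.log(N))) for k in sorted(width_multipliers)]


def build_truth(config: SimulationConfig) -> SimulationTruth:
    """Place one segment per width multiplier, separated by equal gaps.

    K segments get K+1 gaps of floor((N - sum(widths)) / (K+1)) probes; the
    integer remainder is appended to the last gap. Raises ValueError when the
    widths plus minimal gaps do not fit in N.
    """
    widths = segment_widths(config.N, config.width_multipliers)
    K = len(widths)
    free = config.N - sum(widths)
    gap = free // (K + 1)
    if free < K + 1 or gap < 1:
        raise ValueError(
            f"infeasible simulation: {K} segments of total width {sum(widths)} "
            f"do not fit in N={config.N} with nonempty gaps"
        )
    segs = []
    pos = gap
    for i, w in enumerate(widths):
        shift = config.mean_shift
        if config.alternate_signs and i % 2 == 1:
            shift = -shift
        segs.append(TrueSegment(start=pos, end=pos + w, mean_shift=shift))
        pos += w + gap
    return SimulationTruth(segments=tuple(segs))


def sample_noise(n: int, family: str, seed) -> np.ndarray:
    """n i.i.d. unit-variance deviates from the named family.

    ``seed`` may be an int or a numpy Generator / SeedSequence.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if family == "gaussian":
        return rng.standard_normal(n)
    if family == "student_t_df8":
        return rng.standard_t(8, size=n) * _T8_SCALE
    raise ValueError(f"unknown noise family {family!r}")


def rep_rng(seed: int, rep_index: int) -> np.random.Generator:
    """Independent, reproducible stream for replicate ``rep_index``."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(rep_index,)))


def mean_function(config: SimulationConfig, truth: SimulationTruth) -> np.ndarray:
    mu = np.zeros(config.N)
    for seg in truth.segments:
        mu[seg.start : seg.end] = seg.mean_shift
    return mu


def simulate_profile(
    config: SimulationConfig, rep_index: int = 0
) -> tuple[ProbeSeries, SimulationTruth]:
    """One simulated chromosome and its ground truth.

    The noise stream is derived deterministically from (config.seed,
    rep_index), so replicates are independent and each replicate is
    reproducible on its own.
    """
    truth = build_truth(config)
    mu = mean_function(config, truth)
    noise = sample_noise(config.N, config.noise_family, rep_rng(config.seed, rep_index))
    label = (
        f"sim(N={config.N},snr={config.snr},{config.noise_family},rep={rep_index})"
    )
    return ProbeSeries(values=mu + config.sigma * noise, label=label), truth


def detectability_index(n: int, snr: float, N: int) -> float:
    """T = sqrt(n) * snr / sqrt(2 ln N).

    The local-scan theory says power to detect an n-probe segment at
    signal-to-noise snr on an N-probe chromosome is governed by this index:
    T well above 1 is detectable, well below 1 is not.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if N < 2:
        raise ValueError("N must be >= 2")
    if snr <= 0:
        raise ValueError("snr must be positive")
    return math.sqrt(n) * snr / math.sqrt(2.0 * math.log(N))
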