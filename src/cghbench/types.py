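"""Shared containers for probe series, simulation truth, breakpoints and calls.

All coordinates are 0-based, half-open probe indices on a single chromosome:
a breakpoint at ``i`` separates probes ``[.., i)`` and ``[i, ..)``, and a call
or true segment ``[start, end)`` covers ``end - start`` probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ProbeSeries",
    "TrueSegment",
    "SimulationTruth",
    "SimulationConfig",
    "ChangePointSet",
    "CNVCall",
]

_NOISE_FAMILIES = ("gaussian", "student_t_df8")


@dataclass(frozen=True)
class ProbeSeries:
    """Ordered log2-ratio intensities for one chromosome.

    ``values[i]`` is the log2 ratio of probe ``i`` in genomic order.
    """

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("ProbeSeries requires a 1-D vector with >= 1 probe")
        if not np.all(np.isfinite(v)):
            raise ValueError("ProbeSeries values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n_probes(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.n_probes


@dataclass(frozen=True)
class TrueSegment:
    """A planted copy-number segment: probes [start, end) shifted by mean_shift."""

    start: int
    end: int
    mean_shift: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid segment bounds [{self.start}, {self.end})")
        if self.mean_shift == 0:
            raise ValueError("mean_shift must be nonzero")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth segment list for one simulated profile, sorted, non-overlapping."""

    segments: tuple[TrueSegment, ...]

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValueError("truth segments must be sorted and non-overlapping")
        object.__setattr__(self, "segments", segs)

    def boundaries(self) -> np.ndarray:
        """All true breakpoint indices (segment starts and ends), sorted unique."""
        b = sorted({s.start for s in self.segments} | {s.end for s in self.segments})
        return np.asarray(b, dtype=int)

    def __len__(self) -> int:
        return len(self.segments)


@dataclass(frozen=True)
class SimulationConfig:
    """Design of one simulated chromosome.

    Parameters
    ----------
    N : total probe count.
    snr : signal-to-noise ratio mu/sigma of each planted segment.
    sigma : noise standard deviation in log2-ratio units. Only the ratio
        snr = mu/sigma matters to scale-equivariant segmenters; the absolute
        scale matters to the fused-lasso 0.5 calling threshold. The default
        0.25 puts the SNR-3 shift (0.75) in the range of a one-copy gain.
    noise_family : "gaussian" or "student_t_df8" (heavy tailed; rescaled to
        unit variance so snr means the same thing in both families).
    width_multipliers : one segment is planted per multiplier k, of width
        round(k * ln N), evenly spaced along the chromosome.
    alternate_signs : if True, successive segments alternate gain/loss;
        default all gains.
    """

    N: int
    snr: float
    sigma: float = 0.25
    noise_family: str = "gaussian"
    width_multipliers: tuple[int, ...] = (1, 2, 3, 4, 5)
    n_reps: int = 1
    seed: int = 0
    alternate_signs: bool = False

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("N must be positive")
        if self.snr <= 0 or self.sigma <= 0:
            raise ValueError("snr and sigma must be positive")
        if self.noise_family not in _NOISE_FAMILIES:
            raise ValueError(
                f"unknown noise_family {self.noise_family!r}; "
                f"choose from {_NOISE_FAMILIES}"
            )
        mults = tuple(sorted(int(k) for k in self.width_multipliers))
        if not mults or any(k < 1 for k in mults):
            raise ValueError("width_multipliers must be a nonempty set of ints >= 1")
        object.__setattr__(self, "width_multipliers", mults)

    @property
    def mean_shift(self) -> float:
        return self.snr * self.sigma


@dataclass(frozen=True)
class ChangePointSet:
    """Sorted unique breakpoint indices, all strictly inside (0, N)."""

    indices: np.ndarray
    N: int

    def __post_init__(self) -> None:
        idx = np.asarray(sorted(set(int(i) for i in np.atleast_1d(self.indices))), dtype=int)
        if idx.size and (idx[0] <= 0 or idx[-1] >= self.N):
            raise ValueError("breakpoints must lie strictly inside (0, N)")
        object.__setattr__(self, "indices", idx)

    @classmethod
    def empty(cls, N: int) -> "ChangePointSet":
        return cls(np.empty(0, dtype=int), N)

    def segment_bounds(self) -> np.ndarray:
        """(m+1, 2) array of [start, end) bounds of the induced segments."""
        edges = np.concatenate(([0], self.indices, [self.N]))
        return np.column_stack((edges[:-1], edges[1:]))

    def __len__(self) -> int:
        return int(self.indices.size)

    def __iter__(self):
        return iter(self.indices.tolist())


@dataclass(frozen=True)
class CNVCall:
    """A called region [start, end) with its mean log2 ratio and detection score."""

    start: int
    end: int
    magnitude: float
    score: float = float("nan")
    method: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid call bounds [{self.start}, {self.end})")

    @property
    def width(self) -> int:
        return self.end - self.start


def call_boundaries(calls: Iterable[CNVCall]) -> np.ndarray:
    """Unique sorted breakpoint indices implied by a list of calls."""
    b: set[int] = set()
    for c in calls:
        b.add(c.start)
        b.add(c.end)
    return np.asarray(sorted(b), dtype=int)


def check_non_overlapping(calls: Sequence[CNVCall]) -> None:
    ordered = sorted(calls, key=lambda c: c.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValueError(f"overlapping calls [{a.start},{a.end}) and [{b.start},{b.end})")
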