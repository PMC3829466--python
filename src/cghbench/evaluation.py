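"""Benchmarking: detection power, false-positive breakpoints, pruning and
probe-level concordance.

Conventions mirror the simulation study this package reproduces:

* an aberration counts as detected when a reported breakpoint lies within 8
  probes (inclusive) of BOTH of its true boundaries;
* a reported breakpoint counts as a false positive when it is farther than 8
  probes from every true boundary;
* breakpoint methods (CBS, SaRa) are scored on their breakpoints, region
  methods (LRS, fused lasso) on both boundaries of each call;
* power is averaged over replicates and genome lengths per (method, width
  multiplier, SNR, noise family); false positives over everything per
  (method, noise family).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from ._robust import mad_scale
from .types import (
    CNVCall,
    ChangePointSet,
    ProbeSeries,
    SimulationConfig,
    SimulationTruth,
    call_boundaries,
    check_non_overlapping,
)

__all__ = [
    "EvaluationTable",
    "ConcordanceResult",
    "match_detection",
    "count_false_positives",
    "prune_calls",
    "probe_concordance",
    "run_benchmark",
    "run_method",
    "METHODS",
    "mad_scale",
]

logger = logging.getLogger(__name__)

DETECT_TOL = 8  # probes, inclusive


def _reported_boundaries(reported) -> np.ndarray:
    """Breakpoint indices from a ChangePointSet or a list of calls."""
    if isinstance(reported, ChangePointSet):
        return reported.indices
    return call_boundaries(reported)


def match_detection(truth_seg, reported, tol: int = DETECT_TOL) -> bool:
    """True iff some reported boundary lies within ``tol`` probes (inclusive)
    of the true start AND some boundary within ``tol`` of the true end."""
    if tol < 0:
        raise ValueError("tol must be >= 0")
    b = _reported_boundaries(reported)
    if b.size == 0:
        return False
    return bool(
        np.min(np.abs(b - truth_seg.start)) <= tol
        and np.min(np.abs(b - truth_seg.end)) <= tol
    )


def count_false_positives(reported, truth: SimulationTruth, tol: int = DETECT_TOL) -> int:
    """Number of reported breakpoints farther than ``tol`` from every true
    boundary."""
    if tol < 0:
        raise ValueError("tol must be >= 0")
    b = _reported_boundaries(reported)
    if b.size == 0:
        return 0
    tb = truth.boundaries()
    if tb.size == 0:
        return int(b.size)
    dist = np.min(np.abs(b[:, None] - tb[None, :]), axis=1)
    return int(np.sum(dist > tol))


def prune_calls(
    calls: Sequence[CNVCall],
    series: ProbeSeries,
    min_probes: int = 5,
    mad_mult: float = 1.5,
) -> list[CNVCall]:
    """Standard post-processing: keep calls at least ``min_probes`` wide
    (inclusive) whose |magnitude| reaches ``mad_mult`` times the profile MAD."""
    if min_probes <= 0 or mad_mult <= 0:
        raise ValueError("thresholds must be positive")
    cut = mad_mult * mad_scale(series.values)
    return [c for c in calls if c.width >= min_probes and abs(c.magnitude) >= cut]


@dataclass(frozen=True)
class ConcordanceResult:
    value: float
    n_probes_a: int
    n_probes_b: int
    n_shared: int


def _probe_set(calls: Sequence[CNVCall]) -> set[int]:
    check_non_overlapping(calls)
    s: set[int] = set()
    for c in calls:
        s.update(range(c.start, c.end))
    return s


def probe_concordance(
    calls_a: Sequence[CNVCall], calls_b: Sequence[CNVCall]
) -> ConcordanceResult:
    """Probes called by both methods divided by the geometric mean of the
    probes called by each; 0 when either set is empty.  Symmetric."""
    a = _probe_set(calls_a)
    b = _probe_set(calls_b)
    shared = len(a & b)
    if not a or not b:
        return ConcordanceResult(0.0, len(a), len(b), shared)
    return ConcordanceResult(
        shared / math.sqrt(len(a) * len(b)), len(a), len(b), shared
    )


# ---------------------------------------------------------------------------
# method registry: each runner maps a profile to (breakpoints, calls-or-None)


def _run_cbs(series, seed, n_perm=10_000, alpha=0.01, stop_rule="pvalue"):
    from .cbs import CbsConfig, cbs_segment

    cps = cbs_segment(
        series, CbsConfig(alpha=alpha, n_perm=n_perm, stop_rule=stop_rule, seed=seed)
    )
    return cps, None


def _run_cbs_mbic(series, seed, n_perm=10_000, alpha=0.01):
    return _run_cbs(series, seed, n_perm=n_perm, alpha=alpha, stop_rule="mbic")


def _run_sara(series, seed):
    from .sara import SaraConfig, sara_detect, segments_to_calls

    cps = sara_detect(series, SaraConfig(seed=seed))
    return cps, segments_to_calls(series, cps)


def _run_lrs(series, seed):
    from .lrs import LrsConfig, lrs_detect

    calls = lrs_detect(series, LrsConfig())
    return calls, calls


def _run_flasso(series, seed):
    from .fused_lasso import default_tuning, flsa_solve, threshold_segment

    lam1, lam2 = default_tuning(series)
    calls = threshold_segment(flsa_solve(series, lam1, lam2))
    return calls, calls


METHODS: dict[str, Callable] = {
    "cbs": _run_cbs,
    "cbs-mbic": _run_cbs_mbic,
    "sara": _run_sara,
    "lrs": _run_lrs,
    "flasso": _run_flasso,
}


def run_method(name: str, series: ProbeSeries, seed: int = 0, **kwargs):
    """Run one named segmenter; returns (reported, calls_or_None) where
    ``reported`` is what false-positive/power scoring uses."""
    if name not in METHODS:
        raise ValueError(f"unknown method {name!r}; choose from {sorted(METHODS)}")
    return METHODS[name](series, seed, **kwargs)


@dataclass(frozen=True)
class EvaluationTable:
    """power: long table (method, width_multiplier, snr, noise_family, power);
    fp_mean: (method, noise_family, fp_mean).  n_reps per factor combination."""

    power: pd.DataFrame
    fp_mean: pd.DataFrame
    n_reps: int


def run_benchmark(
    grid: Iterable[SimulationConfig],
    methods: Sequence[str],
    n_reps: int,
    seed: int,
    tol: int = DETECT_TOL,
    cbs_n_perm: int = 500,
) -> EvaluationTable:
    """Simulate every config x replicate, run every method, score power and
    false positives.

    All randomness derives from ``seed``: config index and replicate index
    key independent streams, so results are invariant to the order in which
    methods and replicates are processed.  A method failure on a replicate is
    logged and that (method, replicate) is excluded.
    """
    from .synthetic_data import simulate_profile

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    grid = list(grid)
    power_rows = []
    fp_rows = []
    for gi, cfg in enumerate(grid):
        cfg_seed = int(np.random.SeedSequence((seed, gi)).generate_state(1)[0] % 2**31)
        cfg = replace(cfg, seed=cfg_seed, n_reps=n_reps)
        mults = cfg.width_multipliers
        for rep in range(n_reps):
            series, truth = simulate_profile(cfg, rep)
            method_seed = int(
                np.random.SeedSequence((seed, gi, rep)).generate_state(1)[0] % 2**31
            )
            cbs_cps = None  # share the permutation pass between cbs and cbs-mbic
            for mname in methods:
                kwargs = {"n_perm": cbs_n_perm} if mname in ("cbs", "cbs-mbic") else {}
                try:
                    if mname == "cbs-mbic" and cbs_cps is not None:
                        from .cbs import mbic_backward_select

                        reported = mbic_backward_select(series, cbs_cps)
                    else:
                        reported, _calls = run_method(mname, series, method_seed, **kwargs)
                        if mname == "cbs":
                            cbs_cps = reported
                except Exception:  # pragma: no cover - defensive
                    logger.warning(
                        "method %s failed on config %d rep %d; excluded",
                        mname, gi, rep, exc_info=True,
                    )
                    continue
                for mult, seg in zip(mults, truth.segments):
                    power_rows.append(
                        {
                            "method": mname,
                            "width_multiplier": mult,
                            "snr": cfg.snr,
                            "noise_family": cfg.noise_family,
                            "N": cfg.N,
                            "detected": float(match_detection(seg, reported, tol)),
                        }
                    )
                fp_rows.append(
                    {
                        "method": mname,
                        "noise_family": cfg.noise_family,
                        "N": cfg.N,
                        "snr": cfg.snr,
                        "fp": float(count_false_positives(reported, truth, tol)),
                    }
                )
    power_df = (
        pd.DataFrame(power_rows)
        .groupby(["method", "width_multiplier", "snr", "noise_family"], as_index=False)
        .agg(power=("detected", "mean"), n=("detected", "size"))
    )
    fp_df = (
        pd.DataFrame(fp_rows)
        .groupby(["method", "noise_family"], as_index=False)
        .agg(fp_mean=("fp", "mean"), n=("fp", "size"))
    )
    return EvaluationTable(power=power_df, fp_mean=fp_df, n_reps=n_reps)
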