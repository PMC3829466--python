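"""Readers and writers: probe tables, truth tables, BED call files, config.

Probe tables are tab-delimited text with a ``chrom / position / log2ratio``
header (the layout of a normalised CGH array export); lines starting with
``#`` are comments.  Calls are written as BED (0-based, half-open genomic
intervals) with ``width_probes`` and ``magnitude`` extra columns.  All
writers put the generating seed/config in a leading comment so a run is
self-describing, and never embed timestamps, so equal seeds give
byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .types import (
    CNVCall,
    ProbeSeries,
    SimulationConfig,
    SimulationTruth,
    TrueSegment,
    check_non_overlapping,
)

__all__ = [
    "read_probe_table",
    "write_probe_table",
    "write_calls_bed",
    "read_calls_bed",
    "write_truth",
    "read_truth",
    "load_sim_config",
]

_PROBE_COLS = ("chrom", "position", "log2ratio")


def read_probe_table(
    path, chrom_filter: str | None = None
) -> dict[str, tuple[ProbeSeries, np.ndarray]]:
    """Parse a probe table into one ProbeSeries per chromosome (file order).

    Returns ``{chrom: (series, positions)}``; positions are retained so calls
    can be mapped back to genomic coordinates.  Non-monotone positions and
    non-numeric ratios are rejected with the offending line number.
    """
    path = Path(path)
    rows: list[tuple[str, int, float]] = []
    with path.open() as fh:
        header: list[str] | None = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.lower() for f in fields]
                missing = [c for c in _PROBE_COLS if c not in header]
                if missing:
                    raise ValueError(f"{path}: missing column(s) {missing} in header")
                idx = {c: header.index(c) for c in _PROBE_COLS}
                continue
            chrom = fields[idx["chrom"]]
            try:
                position = int(fields[idx["position"]])
                ratio = float(fields[idx["log2ratio"]])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed record: {exc}") from None
            if not math.isfinite(ratio):
                raise ValueError(f"{path}:{lineno}: non-finite log2ratio")
            if rows and rows[-1][0] == chrom and position <= rows[-1][1]:
                raise ValueError(
                    f"{path}:{lineno}: positions not strictly increasing on {chrom}"
                )
            rows.append((chrom, position, ratio))
    if header is None:
        raise ValueError(f"{path}: empty probe table")
    out: dict[str, tuple[ProbeSeries, np.ndarray]] = {}
    order: list[str] = []
    for chrom, _, _ in rows:
        if chrom not in out:
            order.append(chrom)
            out[chrom] = None  # type: ignore[assignment]
    for chrom in order:
        if chrom_filter is not None and chrom != chrom_filter:
            continue
        sel = [(p, r) for c, p, r in rows if c == chrom]
        pos = np.asarray([p for p, _ in sel], dtype=int)
        vals = np.asarray([r for _, r in sel], dtype=float)
        out[chrom] = (ProbeSeries(values=vals, label=chrom), pos)
    return {c: v for c, v in out.items() if v is not None}


def _header_comment(meta: Mapping | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def write_probe_table(
    path,
    series: ProbeSeries,
    chrom: str = "chr1",
    positions: np.ndarray | None = None,
    spacing: int = 1000,
    meta: Mapping | None = None,
) -> None:
    """Write a series as a probe table; default positions are evenly spaced."""
    if positions is None:
        positions = np.arange(series.n_probes) * spacing + 1
    with Path(path).open("w") as fh:
        fh.write(_header_comment(meta))
        fh.write("chrom\tposition\tlog2ratio\n")
        for p, v in zip(positions, series.values):
            fh.write(f"{chrom}\t{int(p)}\t{v:.6g}\n")


def write_truth(path, truth: SimulationTruth, meta: Mapping | None = None) -> None:
    with Path(path).open("w") as fh:
        fh.write(_header_comment(meta))
        fh.write("start\tend\tmean_shift\n")
        for seg in truth.segments:
            fh.write(f"{seg.start}\t{seg.end}\t{seg.mean_shift:.6g}\n")


def read_truth(path) -> SimulationTruth:
    df = pd.read_csv(path, sep="\t", comment="#")
    segs = tuple(
        TrueSegment(start=int(r.start), end=int(r.end), mean_shift=float(r.mean_shift))
        for r in df.itertuples()
    )
    return SimulationTruth(segments=segs)


def write_calls_bed(
    calls: Sequence[CNVCall],
    series_positions: np.ndarray,
    path,
    chrom: str = "chr1",
    meta: Mapping | None = None,
) -> None:
    """BED output: chrom, start, end, name=method, score, strand, plus
    width_probes and magnitude extra columns.

    Probe span [s, e) maps to [position[s], position[e-1] + 1); BED score is
    |scan score or magnitude| * 100 capped at 1000.
    """
    check_non_overlapping(calls)
    positions = np.asarray(series_positions, dtype=int)
    with Path(path).open("w") as fh:
        fh.write(_header_comment(meta))
        fh.write("# chrom\tstart\tend\tname\tscore\tstrand\twidth_probes\tmagnitude\n")
        for c in sorted(calls, key=lambda c: c.start):
            if c.end > positions.size:
                raise ValueError(f"call [{c.start},{c.end}) outside position range")
            raw = c.score if math.isfinite(c.score) else c.magnitude
            score = min(1000, int(round(abs(raw) * 100)))
            fh.write(
                f"{chrom}\t{positions[c.start]}\t{positions[c.end - 1] + 1}\t"
                f"{c.method or 'call'}\t{score}\t.\t{c.width}\t{c.magnitude:.6g}\n"
            )


def read_calls_bed(path, series_positions: np.ndarray) -> list[CNVCall]:
    """Re-read a BED written by write_calls_bed, mapping genomic spans back
    to probe indices."""
    positions = np.asarray(series_positions, dtype=int)
    calls: list[CNVCall] = []
    with Path(path).open() as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            start_bp, end_bp = int(f[1]), int(f[2])
            s = int(np.searchsorted(positions, start_bp))
            e = int(np.searchsorted(positions, end_bp - 1, side="right"))
            calls.append(
                CNVCall(
                    start=s,
                    end=e,
                    magnitude=float(f[7]),
                    score=float(f[4]) / 100.0,
                    method=f[3],
                )
            )
    return calls


def load_sim_config(path) -> SimulationConfig:
    """SimulationConfig from a YAML/JSON key-value file mirroring its fields."""
    with Path(path).open() as fh:
        data = yaml.safe_load(fh) or {}
    if "width_multipliers" in data:
        data["width_multipliers"] = tuple(data["width_multipliers"])
    return SimulationConfig(**data)


def sim_config_meta(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["width_multipliers"] = list(d["width_multipliers"])
    return d
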