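"""Coverage-at-threshold summaries, windowed mean depths, crossover check.

Coverage at t× is the fraction of genome bases sequenced to depth >= t
(zero-depth bases included in the denominator).  Window means tile the
genome with fixed-origin windows from coordinate 0; the trailing short
window is averaged over its actual length.  The crossover comparison
asks, at matched mean depth, where the short-insert library's coverage
curve overtakes the long-insert one — the empirical echo of the analytic
variance inequality: more variable coverage loses at thresholds below
the mean and wins above it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .library_sim import DepthTrack

__all__ = [
    "DEFAULT_THRESHOLDS",
    "CoverageSummary",
    "WindowMeans",
    "CrossoverComparison",
    "coverage_at",
    "window_means",
    "crossover_compare",
    "write_window_means",
    "read_window_means",
    "write_bedgraph",
    "read_bedgraph",
]

DEFAULT_THRESHOLDS = (1, 10, 20, 30, 40, 50)


@dataclass(frozen=True)
class CoverageSummary:
    thresholds: tuple[int, ...]
    fractions: tuple[float, ...]
    mean_depth: float

    def __post_init__(self) -> None:
        fr = np.asarray(self.fractions)
        if np.any(fr < 0) or np.any(fr > 1):
            raise ValueError("coverage fractions must lie in [0, 1]")
        if np.any(np.diff(fr) > 1e-15):
            raise ValueError("coverage fractions must be non-increasing in threshold")


@dataclass
class WindowMeans:
    window_size: int
    starts: np.ndarray
    means: np.ndarray
    genome_length: int

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.means = np.asarray(self.means, dtype=float)
        expected = -(-self.genome_length // self.window_size)  # ceil division
        if len(self.starts) != expected or len(self.means) != expected:
            raise ValueError("window count must equal ceil(genome length / window size)")

    @property
    def ends(self) -> np.ndarray:
        return np.minimum(self.starts + self.window_size, self.genome_length)


@dataclass(frozen=True)
class CrossoverComparison:
    """Per-threshold sign of (short - long) coverage and the flip interval."""

    thresholds: tuple[int, ...]
    short_fractions: tuple[float, ...]
    long_fractions: tuple[float, ...]
    differences: tuple[float, ...]
    signs: tuple[int, ...]
    crossover_interval: tuple[int, int] | None


def coverage_at(
    track: DepthTrack,
    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS,
    exclude_mask: np.ndarray | None = None,
) -> CoverageSummary:
    """Fraction of genome bases at depth >= t for each threshold.

    ``exclude_mask`` (e.g. gap bases) restricts both numerator and
    denominator to unmasked positions; by default the full genome length
    is the denominator.
    """
    if track.genome_length == 0:
        raise ValueError("empty depth track")
    thresholds = tuple(int(t) for t in thresholds)
    if any(t < 1 for t in thresholds):
        raise ValueError("thresholds must be positive integers")
    depth = track.depth
    if exclude_mask is not None:
        depth = depth[~np.asarray(exclude_mask, dtype=bool)]
        if len(depth) == 0:
            raise ValueError("all bases excluded")
    fractions = tuple(float(np.mean(depth >= t)) for t in thresholds)
    return CoverageSummary(
        thresholds=thresholds, fractions=fractions, mean_depth=float(depth.mean())
    )


def window_means(track: DepthTrack, window_size: int = 10_000) -> WindowMeans:
    """Mean per-base depth in fixed-origin tiling windows."""
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    n = track.genome_length
    starts = np.arange(0, n, window_size, dtype=np.int64)
    sums = np.add.reduceat(track.depth.astype(np.float64), starts)
    lengths = np.minimum(starts + window_size, n) - starts
    return WindowMeans(
        window_size=window_size, starts=starts, means=sums / lengths, genome_length=n
    )


def crossover_compare(
    short_summary: CoverageSummary,
    long_summary: CoverageSummary,
    matched_mean_depth: float | None = None,
    depth_rtol: float = 0.01,
) -> CrossoverComparison:
    """Compare coverage curves of depth-matched short/long libraries.

    Requires identical thresholds and mean depths within ``depth_rtol``
    of each other.  The crossover interval is the pair of adjacent
    thresholds between which sign(short - long) first flips from
    negative to positive; ``None`` when no flip occurs.
    """
    if short_summary.thresholds != long_summary.thresholds:
        raise ValueError("coverage summaries have different thresholds")
    ref = matched_mean_depth if matched_mean_depth is not None else long_summary.mean_depth
    for md in (short_summary.mean_depth, long_summary.mean_depth):
        if ref > 0 and abs(md - ref) / ref > depth_rtol:
            raise ValueError(
                f"mean depths not matched: {short_summary.mean_depth:.3f} vs "
                f"{long_summary.mean_depth:.3f} (reference {ref:.3f})"
            )
    diffs = tuple(s - l for s, l in zip(short_summary.fractions, long_summary.fractions))
    signs = tuple(int(np.sign(d)) for d in diffs)
    crossover = None
    nonzero = [(t, s) for t, s in zip(short_summary.thresholds, signs) if s != 0]
    for (t0, s0), (t1, s1) in zip(nonzero, nonzero[1:]):
        if s0 < 0 and s1 > 0:
            crossover = (t0, t1)
            break
    return CrossoverComparison(
        thresholds=short_summary.thresholds,
        short_fractions=short_summary.fractions,
        long_fractions=long_summary.fractions,
        differences=diffs,
        signs=signs,
        crossover_interval=crossover,
    )


# ---------------------------------------------------------------------------
# Text I/O
# ---------------------------------------------------------------------------


def write_window_means(wm: WindowMeans, path: str | Path, chrom: str = "chr1") -> None:
    pd.DataFrame(
        {"chrom": chrom, "start": wm.starts, "end": wm.ends, "mean_depth": wm.means}
    ).to_csv(path, sep="\t", index=False)


def read_window_means(path: str | Path) -> WindowMeans:
    df = pd.read_csv(path, sep="\t")
    starts = df["start"].to_numpy(dtype=np.int64)
    if len(starts) < 1:
        raise ValueError("empty window-means table")
    window_size = int(df["end"].iloc[0] - df["start"].iloc[0]) if len(df) == 1 else int(starts[1] - starts[0])
    return WindowMeans(
        window_size=window_size,
        starts=starts,
        means=df["mean_depth"].to_numpy(dtype=float),
        genome_length=int(df["end"].iloc[-1]),
    )


def write_bedgraph(track: DepthTrack, path: str | Path, chrom: str = "chr1") -> None:
    """Run-length-encoded per-base depth, 0-based half-open bedGraph."""
    depth = track.depth
    change = np.flatnonzero(np.diff(depth)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(depth)]))
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            fh.write(f"{chrom}\t{s}\t{e}\t{int(depth[s])}\n")


def read_bedgraph(path: str | Path, kind: str = "short_insert", sample_id: str = "sample") -> DepthTrack:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"], comment="#")
    n = int(df["end"].max())
    depth = np.zeros(n, dtype=np.int64)
    for s, e, v in zip(df["start"], df["end"], df["value"]):
        depth[s:e] = int(v)
    from .coverage_model import LibraryKind

    return DepthTrack(depth=depth, kind=LibraryKind(kind), sample_id=sample_id)
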