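"""Windowed depth-difference outlier detection and region annotation.

The per-window depth difference (short-insert minus long-insert mean
depth) is screened with a two-sided 3-standard-deviation rule: a window
is flagged when its difference deviates from the mean of all window
differences by more than ``sd_multiplier`` standard deviations.  Flagged
windows are then annotated by the region label containing the window
*start* coordinate against a BED track (centromere / gap / difficult),
mirroring how depth discrepancies between cell-free and genomic DNA
localize to alignment-hostile regions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage_metrics import WindowMeans

__all__ = [
    "LABEL_PRECEDENCE",
    "window_diff",
    "flag_outliers",
    "annotate",
    "AnnotationSummary",
    "write_window_table",
    "write_label_summary",
]

#: Most-specific-wins order when annotation intervals overlap.
LABEL_PRECEDENCE = ("centromere", "gap", "difficult")

TABLE_COLUMNS = ["start", "end", "mean_short", "mean_long", "diff"]


def window_diff(short_wm: WindowMeans, long_wm: WindowMeans) -> pd.DataFrame:
    """Per-window signed depth difference, short minus long.

    Both inputs must share the identical window grid.
    """
    if (
        short_wm.window_size != long_wm.window_size
        or short_wm.genome_length != long_wm.genome_length
        or not np.array_equal(short_wm.starts, long_wm.starts)
    ):
        raise ValueError("window grids do not match")
    return pd.DataFrame(
        {
            "start": short_wm.starts,
            "end": short_wm.ends,
            "mean_short": short_wm.means,
            "mean_long": long_wm.means,
            "diff": short_wm.means - long_wm.means,
        }
    )


def flag_outliers(
    table: pd.DataFrame, sd_multiplier: float = 3.0, robust: bool = False
) -> pd.DataFrame:
    """Two-sided SD rule on the signed difference distribution.

    The location/scale are computed over ALL windows (outliers included;
    no robust re-estimation) unless ``robust`` selects median/MAD.  A
    degenerate scale of zero flags nothing.  Adds ``z`` and ``outlier``
    columns; the rule is exactly reproducible from the emitted table.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 windows to estimate the difference spread")
    diffs = table["diff"].to_numpy(dtype=float)
    if robust:
        center = float(np.median(diffs))
        scale = float(1.4826 * np.median(np.abs(diffs - center)))
    else:
        center = float(diffs.mean())
        scale = float(diffs.std(ddof=0))
    out = table.copy()
    if scale == 0.0:
        out["z"] = 0.0
        out["outlier"] = False
    else:
        out["z"] = (diffs - center) / scale
        out["outlier"] = np.abs(diffs - center) > sd_multiplier * scale
    return out


@dataclass
class AnnotationSummary:
    """Counts and fractions of flagged windows per region label."""

    n_flagged: int
    counts: dict[str, int]
    fractions: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(
            {"n_flagged": self.n_flagged, "counts": self.counts, "fractions": self.fractions},
            indent=2,
            sort_keys=True,
        )


def _label_starts(starts: np.ndarray, regions: pd.DataFrame) -> np.ndarray:
    """Label each window start by its containing interval, precedence-aware."""
    labels = np.full(len(starts), "uncategorized", dtype=object)
    assigned_rank = np.full(len(starts), len(LABEL_PRECEDENCE) + 1)
    rank = {lab: i for i, lab in enumerate(LABEL_PRECEDENCE)}
    for row in regions.itertuples(index=False):
        inside = (starts >= row.start) & (starts < row.end)
        if not inside.any():
            continue
        r = rank.get(row.label, len(LABEL_PRECEDENCE))
        better = inside & (r < assigned_rank)
        labels[better] = row.label
        assigned_rank[better] = r
    return labels


def annotate(
    table: pd.DataFrame, regions: pd.DataFrame
) -> tuple[pd.DataFrame, AnnotationSummary]:
    """Annotate windows by the region containing their start coordinate.

    ``regions`` is a BED-like frame (chrom, start, end, label).  Windows
    whose start falls in no interval are labeled ``"uncategorized"``;
    when intervals overlap, the most specific label wins in the order
    centromere > gap > difficult.  The summary tallies labels over
    *flagged* windows only.
    """
    required = {"start", "end", "label"}
    if not required.issubset(regions.columns):
        raise ValueError(f"region track must have columns {sorted(required)}")
    if ((regions["end"] <= regions["start"]) | (regions["start"] < 0)).any():
        raise ValueError("malformed region track: need 0 <= start < end")
    out = table.copy()
    out["region"] = _label_starts(out["start"].to_numpy(dtype=np.int64), regions)
    if "outlier" in out.columns:
        flagged = out.loc[out["outlier"], "region"]
    else:
        flagged = out["region"].iloc[0:0]
    counts = flagged.value_counts().to_dict()
    total = int(len(flagged))
    fractions = {k: v / total for k, v in counts.items()} if total else {}
    return out, AnnotationSummary(n_flagged=total, counts={k: int(v) for k, v in counts.items()}, fractions=fractions)


def write_window_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_label_summary(summary: AnnotationSummary, path: str | Path) -> None:
    Path(path).write_text(summary.to_json() + "\n")
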