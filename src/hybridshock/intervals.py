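"""Genomic interval containers shared by the ATAC analysis and its simulator.

All coordinates here are 0-based, half-open (BED convention). GTF-style
1-based inclusive annotations are converted at the boundary by the callers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

PEAK_COLUMNS = ["chrom", "start", "end", "name", "score"]

#: narrowPeak is BED6+4: chrom start end name score strand signal pvalue qvalue summit
NARROWPEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "signalValue", "pValue", "qValue", "peak",
]


@dataclass
class PeakSet:
    """A scored set of genomic intervals (one ATAC peak call set).

    Parameters
    ----------
    df
        Columns ``chrom, start, end, name, score`` (0-based half-open).
    label
        Provenance, e.g. ``"parent_rep1"`` or ``"hybrid_consensus"``.
    """

    df: pd.DataFrame
    label: str = ""

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True).copy()
        for col in PEAK_COLUMNS:
            if col not in df.columns:
                if col == "name":
                    df["name"] = [f"peak_{i}" for i in range(len(df))]
                elif col == "score":
                    df["score"] = 0.0
                else:
                    raise ValueError(f"PeakSet requires column {col!r}")
        df = df[PEAK_COLUMNS]
        if len(df):
            if (df["start"] < 0).any():
                raise ValueError("negative interval coordinates")
            if (df["start"] >= df["end"]).any():
                raise ValueError("intervals must satisfy start < end")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def scores(self) -> np.ndarray:
        return self.df["score"].to_numpy(dtype=float)

    def trees(self) -> dict[str, IntervalTree]:
        """One interval tree per chromosome (half-open intervals)."""
        out: dict[str, IntervalTree] = {}
        for chrom, sub in self.df.groupby("chrom", sort=False):
            out[chrom] = IntervalTree.from_tuples(
                (s, e, i) for i, (s, e) in zip(sub.index, zip(sub["start"], sub["end"]))
            )
        return out

    def overlaps_mask(self, other: "PeakSet") -> np.ndarray:
        """Boolean per peak of ``self``: does it share >=1 base with any peak of ``other``."""
        trees = other.trees()
        mask = np.zeros(len(self.df), dtype=bool)
        for i, row in enumerate(self.df.itertuples(index=False)):
            tree = trees.get(row.chrom)
            if tree is not None and tree.overlap(row.start, row.end):
                mask[i] = True
        return mask

    def subset(self, mask: np.ndarray, label: str | None = None) -> "PeakSet":
        return PeakSet(self.df[np.asarray(mask, bool)], label=label or self.label)

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_narrowpeak(cls, path: str | Path, label: str = "") -> "PeakSet":
        df = pd.read_csv(path, sep="\t", header=None, names=NARROWPEAK_COLUMNS,
                         comment="#")
        return cls(df[PEAK_COLUMNS], label=label or Path(path).stem)

    def to_narrowpeak(self, path: str | Path) -> None:
        df = self.df.copy()
        df["strand"] = "."
        df["signalValue"] = df["score"].round(4)
        df["pValue"] = -1
        df["qValue"] = -1
        df["peak"] = ((df["end"] - df["start"]) // 2).astype(int)
        df["score"] = df["score"].round().astype(int)
        df[NARROWPEAK_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def merge_clusters(df: pd.DataFrame) -> Iterable[pd.DataFrame]:
    """Yield connected components of mutually overlapping intervals, per chromosome.

    Input must have columns chrom/start/end; a component is a maximal run of
    intervals where each overlaps the union of its predecessors (>=1 base).
    """
    for _, sub in df.sort_values(["chrom", "start", "end"]).groupby("chrom", sort=False):
        block_start = 0
        max_end = -1
        rows = sub.reset_index(drop=True)
        for i in range(len(rows)):
            s, e = rows.at[i, "start"], rows.at[i, "end"]
            if max_end >= 0 and s >= max_end:
                yield rows.iloc[block_start:i]
                block_start = i
                max_end = e
            else:
                max_end = max(max_end, e)
        if len(rows):
            yield rows.iloc[block_start:]


def coverage_from_peaks(peaks: PeakSet, height_scale: float = 0.1) -> pd.DataFrame:
    """Piecewise-constant coverage track implied by a peak set.

    Each peak contributes a box of height ``score * height_scale`` over its
    interval; overlaps add. Returns bedGraph-shaped rows (zero intervals
    omitted), suitable for :func:`hybridshock.io.write_bedgraph`.
    """
    records = []
    for chrom, sub in peaks.df.groupby("chrom", sort=False):
        events: dict[int, float] = {}
        for row in sub.itertuples(index=False):
            h = row.score * height_scale
            events[row.start] = events.get(row.start, 0.0) + h
            events[row.end] = events.get(row.end, 0.0) - h
        pos = sorted(events)
        level = 0.0
        for p, nxt in zip(pos, pos[1:] + [None]):
            level += events[p]
            if nxt is not None and level > 1e-12:
                records.append((chrom, p, nxt, level))
    return pd.DataFrame(records, columns=["chrom", "start", "end", "value"])
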