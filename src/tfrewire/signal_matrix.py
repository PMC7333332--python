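"""Genome binning and fold-change signal matrices.

Turns per-factor ChIP-seq fold-change tracks (bedGraph) and peak calls (BED)
into the bins x factors matrices that the differential graphical model
consumes, plus two peak-level statistics (Jaccard overlap and TSS proximity)
used when interpreting rewired factors.

All coordinates are 0-based, half-open (BED convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pyranges as pr

__all__ = [
    "BinGrid",
    "IntervalSet",
    "SignalMatrix",
    "make_bins",
    "filter_blacklist",
    "filter_by_peaks",
    "aggregate_signal",
    "average_replicates",
    "build_matrix",
    "jaccard_statistic",
    "tss_proximal_fraction",
    "read_bed",
    "read_bedgraph",
    "read_chrom_sizes",
]


@dataclass
class BinGrid:
    """An ordered tiling of the genome into fixed-width bins.

    The last bin of each chromosome may be shorter than ``bin_width`` when
    the chromosome length is not a multiple of the width.
    """

    chroms: np.ndarray  # str array, one entry per bin
    starts: np.ndarray  # int64
    ends: np.ndarray  # int64
    bin_width: int = 100

    def __len__(self) -> int:
        return len(self.starts)

    def __eq__(self, other) -> bool:
        if not isinstance(other, BinGrid):
            return NotImplemented
        return (
            self.bin_width == other.bin_width
            and np.array_equal(self.chroms, other.chroms)
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chroms, "start": self.starts, "end": self.ends}
        )

    def _pyranges(self) -> pr.PyRanges:
        return pr.PyRanges(
            pd.DataFrame(
                {
                    "Chromosome": self.chroms,
                    "Start": self.starts,
                    "End": self.ends,
                    "bin_index": np.arange(len(self)),
                }
            )
        )

    def subset(self, indices: np.ndarray) -> "BinGrid":
        indices = np.asarray(indices, dtype=np.int64)
        return BinGrid(
            chroms=self.chroms[indices],
            starts=self.starts[indices],
            ends=self.ends[indices],
            bin_width=self.bin_width,
        )


@dataclass
class IntervalSet:
    """A labelled collection of genomic intervals (peaks, blacklist, TSS)."""

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    label: str = "peaks"

    def __post_init__(self):
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if len(self.starts) and (self.starts < 0).any():
            raise ValueError("negative interval coordinates")
        if len(self.starts) and (self.ends < self.starts).any():
            raise ValueError("interval end precedes start")

    def __len__(self) -> int:
        return len(self.starts)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple], label: str = "peaks"
    ) -> "IntervalSet":
        recs = list(records)
        if not recs:
            return cls(np.array([], dtype=object), np.array([]), np.array([]), label)
        c, s, e = zip(*recs)
        return cls(np.array(c, dtype=object), np.array(s), np.array(e), label)

    def _pyranges(self) -> pr.PyRanges:
        return pr.PyRanges(
            pd.DataFrame(
                {"Chromosome": self.chroms, "Start": self.starts, "End": self.ends}
            )
        )


@dataclass
class SignalMatrix:
    """Bins x factors fold-change matrix for one condition.

    ``X[l, j]`` is the average fold-change signal of factor ``j`` in bin
    ``l``; bases without signal contribute 0, so the matrix has no missing
    entries. Column order must match between the two conditions that are
    compared downstream.
    """

    X: np.ndarray
    bin_grid: BinGrid
    factors: list[str]
    condition: int = 0

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.bin_grid), len(self.factors)):
            raise ValueError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.bin_grid)} bins x {len(self.factors)} factors"
            )

    @property
    def n_bins(self) -> int:
        return self.X.shape[0]

    @property
    def n_factors(self) -> int:
        return self.X.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        df = self.bin_grid.to_frame()
        for j, f in enumerate(self.factors):
            df[f] = self.X[:, j]
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | Path, condition: int = 0) -> "SignalMatrix":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        factors = [c for c in df.columns if c not in ("chrom", "start", "end")]
        grid = BinGrid(
            chroms=df["chrom"].to_numpy(dtype=object),
            starts=df["start"].to_numpy(dtype=np.int64),
            ends=df["end"].to_numpy(dtype=np.int64),
        )
        return cls(df[factors].to_numpy(float), grid, factors, condition)


# ---------------------------------------------------------------------------
# readers

def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))


def read_bed(path: str | Path, label: str = "peaks") -> IntervalSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2])
    if df.empty:
        return IntervalSet.from_records([], label)
    return IntervalSet(
        df[0].to_numpy(dtype=object),
        df[1].to_numpy(np.int64),
        df[2].to_numpy(np.int64),
        label,
    )


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "value"],
        float_precision="round_trip",
    )
    return df


# ---------------------------------------------------------------------------
# binning and filters

def make_bins(chrom_sizes: Mapping[str, int], bin_width: int = 100) -> BinGrid:
    """Tile each chromosome with fixed-width bins, truncating the last one."""
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    if not chrom_sizes:
        raise ValueError("empty chrom_sizes")
    chroms, starts, ends = [], [], []
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length {size}")
        edges = np.arange(0, size + bin_width, bin_width)
        edges = edges[edges <= size]
        if edges[-1] < size:
            edges = np.append(edges, size)
        starts.append(edges[:-1])
        ends.append(edges[1:])
        chroms.extend([chrom] * (len(edges) - 1))
    return BinGrid(
        chroms=np.array(chroms, dtype=object),
        starts=np.concatenate(starts),
        ends=np.concatenate(ends),
        bin_width=bin_width,
    )


def _overlapping_bin_indices(grid: BinGrid, intervals: IntervalSet) -> np.ndarray:
    """Indices of bins overlapping >= 1 bp with any interval."""
    if len(intervals) == 0 or len(grid) == 0:
        return np.array([], dtype=np.int64)
    hits = grid._pyranges().overlap(intervals._pyranges())
    if len(hits) == 0:
        return np.array([], dtype=np.int64)
    return np.sort(hits.df["bin_index"].to_numpy(np.int64))


def filter_blacklist(grid: BinGrid, blacklist: IntervalSet) -> BinGrid:
    """Drop every bin overlapping a blacklisted region by >= 1 bp."""
    bad = _overlapping_bin_indices(grid, blacklist)
    keep = np.setdiff1d(np.arange(len(grid)), bad)
    return grid.subset(keep)


def filter_by_peaks(grid: BinGrid, peak_sets: Sequence[IntervalSet]) -> BinGrid:
    """Keep bins overlapping >= 1 bp of at least one peak, pooled over all sets."""
    if not peak_sets:
        raise ValueError("at least one peak set is required")
    pooled = IntervalSet(
        np.concatenate([p.chroms for p in peak_sets]) if peak_sets else np.array([]),
        np.concatenate([p.starts for p in peak_sets]),
        np.concatenate([p.ends for p in peak_sets]),
        label="peaks",
    )
    if len(pooled) == 0:
        warnings.warn("all peak sets are empty; the filtered grid has no bins")
        return grid.subset(np.array([], dtype=np.int64))
    keep = _overlapping_bin_indices(grid, pooled)
    return grid.subset(keep)


# ---------------------------------------------------------------------------
# signal aggregation

def aggregate_signal(grid: BinGrid, track: pd.DataFrame | str | Path) -> np.ndarray:
    """Base-pair-weighted mean track value per bin; uncovered bases count as 0.

    ``track`` is a bedGraph table (chrom, start, end, value) or a path to
    one. Intervals on a chromosome must not overlap each other.
    """
    if not isinstance(track, pd.DataFrame):
        track = read_bedgraph(track)
    out = np.zeros(len(grid), dtype=float)
    if track.empty or len(grid) == 0:
        return out
    grid_order = np.arange(len(grid))
    for chrom, sub in track.groupby("chrom", sort=False):
        mask = grid.chroms == chrom
        if not mask.any():
            continue
        idx = grid_order[mask]
        b_starts = grid.starts[mask]
        b_ends = grid.ends[mask]
        sub = sub.sort_values("start")
        s = sub["start"].to_numpy(np.int64)
        e = sub["end"].to_numpy(np.int64)
        v = sub["value"].to_numpy(float)
        if len(s) > 1 and (s[1:] < e[:-1]).any():
            raise ValueError(f"overlapping bedGraph intervals on {chrom}")
        acc = np.zeros(len(idx), dtype=float)
        for si, ei, vi in zip(s, e, v):
            i0 = np.searchsorted(b_ends, si, side="right")
            i1 = np.searchsorted(b_starts, ei, side="left")
            if i1 <= i0:
                continue
            ov = np.minimum(ei, b_ends[i0:i1]) - np.maximum(si, b_starts[i0:i1])
            acc[i0:i1] += vi * ov
        out[idx] = acc / (b_ends - b_starts)
    return out


def average_replicates(vectors: Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise mean over replicate signal vectors."""
    if not vectors:
        raise ValueError("need at least one replicate vector")
    lengths = {len(v) for v in vectors}
    if len(lengths) != 1:
        raise ValueError(f"replicate vectors have mismatched lengths: {lengths}")
    return np.mean(np.stack([np.asarray(v, float) for v in vectors]), axis=0)


def build_matrix(
    grid: BinGrid,
    factor_tracks: Mapping[str, Sequence[pd.DataFrame | str | Path]],
    condition: int = 0,
) -> SignalMatrix:
    """Assemble the bins x factors matrix, averaging replicate tracks per factor."""
    factors = list(factor_tracks)
    cols = []
    for f in factors:
        reps = [aggregate_signal(grid, t) for t in factor_tracks[f]]
        cols.append(average_replicates(reps))
    X = np.column_stack(cols) if cols else np.zeros((len(grid), 0))
    return SignalMatrix(X=X, bin_grid=grid, factors=factors, condition=condition)


# ---------------------------------------------------------------------------
# peak statistics

def _merge(chroms, starts, ends):
    """Merge overlapping/adjacent-in-overlap intervals per chromosome."""
    out: dict[str, list[list[int]]] = {}
    order = np.lexsort((starts, chroms.astype(str)))
    for i in order:
        c, s, e = chroms[i], int(starts[i]), int(ends[i])
        lst = out.setdefault(c, [])
        if lst and s < lst[-1][1]:
            lst[-1][1] = max(lst[-1][1], e)
        else:
            lst.append([s, e])
    return out


def _total_len(merged: dict) -> int:
    return sum(e - s for lst in merged.values() for s, e in lst)


def jaccard_statistic(a: IntervalSet, b: IntervalSet) -> float:
    """Base-pair intersection over union of two interval sets, after merging.

    Raises when both sets are empty (the statistic is undefined, not 0).
    """
    if len(a) == 0 and len(b) == 0:
        raise ValueError("Jaccard statistic undefined: both interval sets are empty")
    ma = _merge(a.chroms, a.starts, a.ends)
    mb = _merge(b.chroms, b.starts, b.ends)
    la, lb = _total_len(ma), _total_len(mb)
    inter = 0
    for chrom in set(ma) & set(mb):
        ia, ib = ma[chrom], mb[chrom]
        i = j = 0
        while i < len(ia) and j < len(ib):
            s = max(ia[i][0], ib[j][0])
            e = min(ia[i][1], ib[j][1])
            if e > s:
                inter += e - s
            if ia[i][1] <= ib[j][1]:
                i += 1
            else:
                j += 1
    union = la + lb - inter
    if union == 0:
        raise ValueError("Jaccard statistic undefined: union has zero length")
    return inter / union


def tss_proximal_fraction(
    peaks: IntervalSet, tss: IntervalSet, window: int = 5000
) -> float:
    """Fraction of peaks within ``window`` bp of a TSS anchor (0 on overlap).

    TSS anchors are single-base records; the distance of a peak is the
    minimum over its bases to the nearest anchor base.
    """
    if len(peaks) == 0:
        raise ValueError("TSS-proximal fraction undefined: no peaks")
    if window <= 0:
        raise ValueError("window must be positive")
    tss_by_chrom: dict[str, np.ndarray] = {}
    for chrom in np.unique(tss.chroms.astype(str)):
        mask = tss.chroms == chrom
        tss_by_chrom[chrom] = np.sort(tss.starts[mask])
    n_close = 0
    for c, s, e in zip(peaks.chroms, peaks.starts, peaks.ends):
        pos = tss_by_chrom.get(c)
        if pos is None or len(pos) == 0:
            continue
        i = np.searchsorted(pos, s)
        dist = np.inf
        # nearest anchor at or after the peak start
        if i < len(pos):
            p = pos[i]
            dist = 0 if p < e else p - (e - 1)
        if i > 0:
            dist = min(dist, s - pos[i - 1])
        if dist <= window:
            n_close += 1
    return n_close / len(peaks)
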