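"""Fixed-width genome binning and per-bin element counting.

The 100 kb bin is the coarse-grain unit of the whole analysis: chromosomes are
tiled left to right with full-width bins plus one terminal partial bin, and
elements are assigned to bins by their midpoint (elements here — CGIs ~1 kb,
Alus ~300 bp, DHS 100-200 bp — are far smaller than the bin, so midpoint
assignment avoids double counting without losing anything). Terminal partial
bins and gap-dominated bins are flagged unusable and excluded from statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genome_model import ElementTrack, GenomeAssembly, InputError

DEFAULT_BIN_SIZE = 100_000


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width partition of an assembly.

    ``bins`` columns: chrom, start, end, full (bool). ``usable`` is the analysis
    mask: partial bins are unusable by default, gap masking clears further bins.
    """

    assembly: GenomeAssembly
    bin_size: int
    bins: pd.DataFrame
    usable: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def n_usable(self) -> int:
        return int(self.usable.sum())

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero((self.bins["chrom"] == chrom).to_numpy())
        if len(idx) == 0:
            raise KeyError(chrom)
        return slice(int(idx[0]), int(idx[-1]) + 1)


@dataclass(frozen=True)
class BinCounts:
    """Per-bin element counts for one track on a grid."""

    grid: BinGrid
    track_name: str
    counts: np.ndarray
    n_skipped: int = 0

    @property
    def usable_counts(self) -> np.ndarray:
        return self.counts[self.grid.usable]

    def __post_init__(self):
        if len(self.counts) != self.grid.n_bins:
            raise InputError("counts length does not match grid")


def make_bins(
    assembly: GenomeAssembly,
    bin_size: int = DEFAULT_BIN_SIZE,
    include_partial: bool = False,
) -> BinGrid:
    """Tile each chromosome with ``bin_size`` bins plus a terminal partial bin.

    Partial bins are flagged not-full and (unless ``include_partial``) unusable,
    so every usable bin shares the same denominator.
    """
    if bin_size <= 0:
        raise InputError("bin_size must be positive")
    if bin_size > max(l for _, l in assembly.chromosomes):
        warnings.warn("bin_size exceeds the longest chromosome; single-bin chromosomes")
    chroms, starts, ends, full = [], [], [], []
    for name, length in assembly.chromosomes:
        edges = list(range(0, length, bin_size)) + [length]
        for s, e in zip(edges[:-1], edges[1:]):
            chroms.append(name)
            starts.append(s)
            ends.append(e)
            full.append(e - s == bin_size)
    bins = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends, "full": full})
    usable = bins["full"].to_numpy().copy() if not include_partial else np.ones(len(bins), bool)
    return BinGrid(assembly, bin_size, bins, usable)


def mask_bins(grid: BinGrid, gap_track: ElementTrack | None, max_gap_fraction: float = 0.5) -> BinGrid:
    """Flag bins whose assembly-gap coverage exceeds ``max_gap_fraction`` unusable.

    With no gap track the mask is returned unchanged. The usable bins that remain
    are the analysis' "euchromatic" denominator.
    """
    if gap_track is None or len(gap_track) == 0:
        return grid
    gap_cov = np.zeros(grid.n_bins)
    starts = grid.bins["start"].to_numpy()
    ends = grid.bins["end"].to_numpy()
    for chrom, sub in gap_track.df.groupby("chrom", sort=False):
        try:
            sl = grid.chrom_slice(chrom)
        except KeyError:
            continue
        for gs, ge in zip(sub["start"], sub["end"]):
            lo = sl.start + int(np.searchsorted(ends[sl], gs, side="right"))
            hi = sl.start + int(np.searchsorted(starts[sl], ge, side="left"))
            for i in range(lo, min(hi, sl.stop)):
                gap_cov[i] += max(0, min(ge, ends[i]) - max(gs, starts[i]))
    frac = gap_cov / (ends - starts)
    usable = grid.usable & (frac <= max_gap_fraction)
    return replace(grid, usable=usable)


def count_elements(grid: BinGrid, track: ElementTrack, rule: str = "midpoint") -> BinCounts:
    """Count track elements per bin.

    midpoint (default): each element goes to the unique bin containing
    floor((start+end)/2). overlap: an element is counted once in every bin it
    intersects. Elements on chromosomes absent from the grid are skipped and
    tallied in ``n_skipped``.
    """
    if rule not in ("midpoint", "overlap"):
        raise InputError(f"unknown counting rule {rule!r}")
    counts = np.zeros(grid.n_bins, dtype=np.int64)
    n_skipped = 0
    starts = grid.bins["start"].to_numpy()
    ends = grid.bins["end"].to_numpy()
    for chrom, sub in track.df.groupby("chrom", sort=False):
        try:
            sl = grid.chrom_slice(chrom)
        except KeyError:
            n_skipped += len(sub)
            continue
        chrom_len = ends[sl.stop - 1]
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        if rule == "midpoint":
            mid = (s + e) // 2
            inside = mid < chrom_len
            n_skipped += int((~inside).sum())
            idx = sl.start + np.minimum(mid[inside] // grid.bin_size, sl.stop - sl.start - 1)
            np.add.at(counts, idx, 1)
        else:
            lo = sl.start + np.searchsorted(ends[sl], s, side="right")
            hi = sl.start + np.searchsorted(starts[sl], np.minimum(e, chrom_len), side="left")
            for l, h in zip(lo, hi):
                if l >= h:
                    n_skipped += 1
                else:
                    counts[l:h] += 1
    return BinCounts(grid, track.name, counts, n_skipped)


def filter_track_by_length(
    track: ElementTrack,
    min_len: int | None = None,
    max_len: int | None = None,
    top_fraction: float | None = None,
) -> ElementTrack:
    """Subset a track by element length.

    Absolute bounds are half-open: keep ``min_len <= length < max_len``. Passing
    ``top_fraction`` instead keeps the longest ``fraction`` of elements (e.g. 0.1
    = top decile, the default notion of "long L1"); ties broken by keeping the
    exact count via a length sort.
    """
    if top_fraction is not None:
        if not (0 < top_fraction <= 1):
            raise InputError("top_fraction must be in (0, 1]")
        k = max(1, int(round(top_fraction * len(track)))) if len(track) else 0
        if k == 0:
            return ElementTrack(track.name, track.df.iloc[0:0])
        order = np.argsort(track.lengths(), kind="mergesort")
        keep = np.zeros(len(track), bool)
        keep[order[-k:]] = True
        return track.subset(keep)
    lo = 0 if min_len is None else min_len
    hi = np.inf if max_len is None else max_len
    if lo >= hi:
        raise InputError(f"min_len {lo} >= max_len {hi}")
    lengths = track.lengths()
    return track.subset((lengths >= lo) & (lengths < hi))
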