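"""Fixed-width genome binning and differential histone-mark signal.

The genome is tiled with 1-kb bins by default (the average size of an
H3K27me3 peak), per-bin signal is the length-weighted mean per-base
coverage — optionally rescaled by an exogenous spike-in factor so samples
are quantitatively comparable — and bins are classified up/down/unchanged
between two conditions with a deterministic fold-change + floor rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genomic_core import GeneModel, GenomeLayout, PeakSet


class BinGrid:
    """Implicit tiling of a genome layout with fixed-width bins.

    Each chromosome contributes ceil(length / width) bins; the last bin is
    truncated at the chromosome end and retained, so bin classes always
    partition the full grid.
    """

    def __init__(self, layout: GenomeLayout, width: int = 1000):
        if width < 1:
            raise ValueError("bin width must be >= 1")
        self.layout = layout
        self.width = int(width)
        self._n_bins: dict[str, int] = {
            chrom: -(-length // self.width) for chrom, length in layout
        }
        self._offsets: dict[str, int] = {}
        total = 0
        for chrom, n in self._n_bins.items():
            self._offsets[chrom] = total
            total += n
        self.total_bins = total

    def n_bins(self, chrom: str) -> int:
        return self._n_bins[chrom]

    def offset(self, chrom: str) -> int:
        return self._offsets[chrom]

    def global_index(self, chrom: str, ordinal: int) -> int:
        if not 0 <= ordinal < self._n_bins[chrom]:
            raise IndexError(f"bin ordinal {ordinal} out of range for {chrom}")
        return self._offsets[chrom] + ordinal

    def bin_span(self, chrom: str, ordinal: int) -> tuple[int, int]:
        start = ordinal * self.width
        end = min(start + self.width, self.layout.length_of(chrom))
        return start, end

    def locate(self, global_index: int) -> tuple[str, int]:
        for chrom, off in self._offsets.items():
            if off <= global_index < off + self._n_bins[chrom]:
                return chrom, global_index - off
        raise IndexError(global_index)

    def bin_lengths(self) -> np.ndarray:
        lengths = np.full(self.total_bins, self.width, dtype=float)
        for chrom, length in self.layout:
            last = self._offsets[chrom] + self._n_bins[chrom] - 1
            rem = length - (self._n_bins[chrom] - 1) * self.width
            lengths[last] = rem
        return lengths

    def bins_overlapping(self, chrom: str, start: int, end: int) -> range:
        """Ordinals of bins sharing >= 1 bp with [start, end)."""
        if chrom not in self._n_bins or end <= start:
            return range(0)
        first = max(0, start // self.width)
        last = min(self._n_bins[chrom], -(-end // self.width))
        return range(first, last)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, _ in self.layout:
            for k in range(self._n_bins[chrom]):
                s, e = self.bin_span(chrom, k)
                rows.append((chrom, s, e))
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def make_grid(layout: GenomeLayout, width: int = 1000) -> BinGrid:
    """Tile a layout with fixed-width bins (1 kb default)."""
    return BinGrid(layout, width)


@dataclass
class SpikeInfo:
    """Per-sample read counts for spike-in normalization.

    ``reference_fraction`` is the nominal exogenous chromatin fraction (1%
    in the assay this models); the scale factor is
    reference_fraction * primary_reads / spike_reads, so a sample with
    proportionally more spike-in signal is scaled down.
    """

    primary_reads: int
    spike_reads: int
    reference_fraction: float = 0.01

    @property
    def scale(self) -> float:
        if self.spike_reads <= 0:
            raise ValueError("spike read count must be > 0 for normalization")
        return self.reference_fraction * self.primary_reads / self.spike_reads


@dataclass
class BinnedTrack:
    """Per-bin mean per-base signal on a grid, spike-scaled when requested."""

    grid: BinGrid
    values: np.ndarray
    library_size: int | None = None
    spike_scale: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.total_bins,):
            raise ValueError("values length must equal total bin count")


def bin_signal(
    coverage: pd.DataFrame,
    grid: BinGrid,
    spike: SpikeInfo | None = None,
) -> BinnedTrack:
    """Average bedGraph coverage into grid bins.

    Per-bin value = length-weighted mean per-base coverage over all bases of
    the bin (uncovered bases count as zero), multiplied by the spike scale
    when spike counts are supplied.
    """
    sums = np.zeros(grid.total_bins, dtype=float)
    width = grid.width
    for chrom, sub in coverage.groupby("chrom", sort=False):
        if chrom not in grid.layout:
            raise ValueError(f"bedGraph chromosome {chrom!r} not in layout")
        clen = grid.layout.length_of(chrom)
        if int(sub["end"].max()) > clen:
            raise ValueError(f"bedGraph interval crosses end of chromosome {chrom}")
        off = grid.offset(chrom)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        values = sub["value"].to_numpy()
        for s, e, v in zip(starts, ends, values):
            for k in range(s // width, -(-e // width)):
                bs = k * width
                ov = min(e, bs + width) - max(s, bs)
                sums[off + k] += v * ov
    values = sums / grid.bin_lengths()
    scale = spike.scale if spike is not None else 1.0
    library = spike.primary_reads if spike is not None else None
    return BinnedTrack(grid, values * scale, library, scale)


CLASS_NAMES = {1: "up", 0: "unchanged", -1: "down"}


@dataclass
class BinDiffResult:
    """Per-bin up/down/unchanged classification between two conditions."""

    grid: BinGrid
    ctrl: np.ndarray
    cond: np.ndarray
    codes: np.ndarray  # int8: +1 up, -1 down, 0 unchanged
    fc: float
    floor: float

    @property
    def up_mask(self) -> np.ndarray:
        return self.codes == 1

    @property
    def down_mask(self) -> np.ndarray:
        return self.codes == -1

    @property
    def n_up(self) -> int:
        return int(self.up_mask.sum())

    @property
    def n_down(self) -> int:
        return int(self.down_mask.sum())

    @property
    def n_unchanged(self) -> int:
        return int((self.codes == 0).sum())

    def fold(self) -> np.ndarray:
        """Condition / control ratio with the epsilon guard (finite everywhere)."""
        eps = self.floor / 100.0 if self.floor > 0 else 1e-9
        return self.cond / np.maximum(self.ctrl, eps)

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.to_frame()
        df["ctrl"] = self.ctrl
        df["cond"] = self.cond
        df["fold"] = self.fold()
        df["class"] = [CLASS_NAMES[c] for c in self.codes]
        return df


def classify_bins(
    track_ctrl: BinnedTrack,
    track_cond: BinnedTrack,
    fc: float = 2.0,
    floor: float = 0.01,
) -> BinDiffResult:
    """Classify each bin as up/down/unchanged with a fold-change + floor rule.

    A bin is "down" iff ctrl >= floor and ctrl / max(cond, eps) >= fc; "up"
    symmetrically; eps = floor/100 keeps ratios finite at empty bins.  The
    rule is the printed "FC2, min > 0.01" gene rule applied at bin level; no
    replicate-variance test is modelled.
    """
    if track_ctrl.grid is not track_cond.grid and not _same_grid(
        track_ctrl.grid, track_cond.grid
    ):
        raise ValueError("tracks are on different grids")
    if fc <= 1:
        raise ValueError("fc must be > 1")
    if floor < 0:
        raise ValueError("floor must be >= 0")
    eps = floor / 100.0 if floor > 0 else 1e-9
    ctrl, cond = track_ctrl.values, track_cond.values
    down = (ctrl >= floor) & (ctrl / np.maximum(cond, eps) >= fc)
    up = (cond >= floor) & (cond / np.maximum(ctrl, eps) >= fc)
    codes = np.zeros(ctrl.shape, dtype=np.int8)
    codes[up] = 1
    codes[down] = -1
    # a bin can satisfy both arms only if both values are below floor*fc with
    # one below floor; the masks are mutually exclusive by construction since
    # fc > 1 forces ctrl > cond for "down" and cond > ctrl for "up"
    return BinDiffResult(track_ctrl.grid, ctrl.copy(), cond.copy(), codes, fc, floor)


def _same_grid(a: BinGrid, b: BinGrid) -> bool:
    return a.width == b.width and a.layout == b.layout


def gene_bin_signal(
    track: BinnedTrack,
    gene: GeneModel,
    promoter_halfwidth: int = 2500,
    stat: str = "mean",
) -> float:
    """Gene-level signal: mean (or max) of bin values over the gene body plus
    its symmetric promoter window."""
    grid = track.grid
    if gene.chrom not in grid.layout:
        raise ValueError(f"gene {gene.gene_id} on unknown chromosome {gene.chrom!r}")
    start = max(0, min(gene.tx_start, gene.tss - promoter_halfwidth))
    end = min(
        grid.layout.length_of(gene.chrom),
        max(gene.tx_end, gene.tss + promoter_halfwidth),
    )
    ords = grid.bins_overlapping(gene.chrom, start, end)
    vals = track.values[grid.offset(gene.chrom) + ords.start : grid.offset(gene.chrom) + ords.stop]
    if len(vals) == 0:
        return 0.0
    return float(vals.max() if stat == "max" else vals.mean())


def rank_genes_by_change(
    track_ctrl: BinnedTrack,
    track_cond: BinnedTrack,
    genes: Sequence[GeneModel],
    fc: float = 2.0,
    floor: float = 0.01,
    promoter_halfwidth: int = 2500,
    stat: str = "mean",
) -> pd.DataFrame:
    """Rank genes by the change in their bin-level signal between conditions.

    Output columns gene_id/ctrl/cond/fold/log2_fold/direction, sorted by
    |log2 fold| descending with ties broken lexicographically by gene id.
    """
    eps = floor / 100.0 if floor > 0 else 1e-9
    rows = []
    for g in genes:
        c = gene_bin_signal(track_ctrl, g, promoter_halfwidth, stat)
        k = gene_bin_signal(track_cond, g, promoter_halfwidth, stat)
        fold = k / max(c, eps)
        if (k >= floor) and (k / max(c, eps) >= fc):
            direction = "up"
        elif (c >= floor) and (c / max(k, eps) >= fc):
            direction = "down"
        else:
            direction = "unchanged"
        rows.append((g.gene_id, c, k, fold, math.log2(max(fold, eps / 1e6)), direction))
    df = pd.DataFrame(
        rows, columns=["gene_id", "ctrl", "cond", "fold", "log2_fold", "direction"]
    )
    df["_abs"] = df["log2_fold"].abs()
    df = df.sort_values(["_abs", "gene_id"], ascending=[False, True], kind="mergesort")
    return df.drop(columns="_abs").reset_index(drop=True)


def bins_vs_peaks(
    diff: BinDiffResult,
    peaks: PeakSet,
    second_mark_diff: BinDiffResult | None = None,
) -> pd.DataFrame:
    """Per bin class, how many bins overlap (>= 1 bp) the given peaks.

    With a second mark's classification, also reports which fraction of the
    peak-overlapping bins are up/down in that second mark (the
    "down bins overlapping the oncogene and gaining the active mark" view).
    """
    grid = diff.grid
    overlapping = np.zeros(grid.total_bins, dtype=bool)
    for iv in peaks:
        if iv.chrom not in grid.layout:
            continue
        ords = grid.bins_overlapping(iv.chrom, iv.start, iv.end)
        off = grid.offset(iv.chrom)
        overlapping[off + ords.start : off + ords.stop] = True
    rows = []
    for code, name in ((-1, "down"), (0, "unchanged"), (1, "up")):
        mask = diff.codes == code
        n = int(mask.sum())
        n_ov = int((mask & overlapping).sum())
        row = {
            "class": name,
            "n_bins": n,
            "n_overlapping": n_ov,
            "fraction_overlapping": (n_ov / n) if n else 0.0,
        }
        if second_mark_diff is not None:
            sel = mask & overlapping
            n_sel = int(sel.sum())
            row["fraction_second_up"] = (
                int((sel & second_mark_diff.up_mask).sum()) / n_sel if n_sel else 0.0
            )
            row["fraction_second_down"] = (
                int((sel & second_mark_diff.down_mask).sum()) / n_sel if n_sel else 0.0
            )
        rows.append(row)
    return pd.DataFrame(rows)
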