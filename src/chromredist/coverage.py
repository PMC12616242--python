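"""Interval-arithmetic helpers over bedGraph coverage.

A bedGraph frame is indexed once per chromosome; window statistics are then
computed from interval overlaps without expanding the genome to per-base
arrays (uncovered bases count as zero coverage).
"""

from __future__ import annotations

import bisect
from typing import Mapping

import numpy as np
import pandas as pd


class CoverageIndex:
    """Per-chromosome sorted (start, end, value) arrays from a bedGraph frame."""

    def __init__(self, coverage: pd.DataFrame):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in coverage.groupby("chrom", sort=False):
            sub = sub.sort_values("start", kind="mergesort")
            self._by_chrom[str(chrom)] = (
                sub["start"].to_numpy(dtype=np.int64),
                sub["end"].to_numpy(dtype=np.int64),
                sub["value"].to_numpy(dtype=float),
            )

    def rows_in(self, chrom: str, start: int, end: int):
        """(starts, ends, values) of rows overlapping [start, end)."""
        if chrom not in self._by_chrom:
            z = np.empty(0)
            return z.astype(np.int64), z.astype(np.int64), z
        starts, ends, values = self._by_chrom[chrom]
        # rows are non-overlapping in well-formed bedGraph, so a window scan
        # from the first row ending after `start` suffices
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if hi <= lo:
            z = np.empty(0)
            return z.astype(np.int64), z.astype(np.int64), z
        return starts[lo:hi], ends[lo:hi], values[lo:hi]

    def window_mean(self, chrom: str, start: int, end: int) -> float:
        s, e, v = self.rows_in(chrom, start, end)
        if len(v) == 0:
            return 0.0
        ov = np.minimum(e, end) - np.maximum(s, start)
        return float((v * ov).sum() / (end - start))

    def window_max(self, chrom: str, start: int, end: int) -> float:
        """Max per-base coverage in the window; 0 if any base is uncovered."""
        s, e, v = self.rows_in(chrom, start, end)
        if len(v) == 0:
            return 0.0
        ov = np.minimum(e, end) - np.maximum(s, start)
        mx = float(v.max())
        if int(ov.sum()) < end - start:  # uncovered bases present
            mx = max(mx, 0.0)
        return mx

    def column_means(self, chrom: str, start: int, end: int, n_cols: int) -> np.ndarray:
        """Mean per-base coverage in ``n_cols`` equal windows across [start, end).

        (end - start) must be divisible by n_cols.
        """
        if (end - start) % n_cols != 0:
            raise ValueError("window length must be divisible by n_cols")
        colw = (end - start) // n_cols
        sums = np.zeros(n_cols, dtype=float)
        s, e, v = self.rows_in(chrom, start, end)
        for rs, re, rv in zip(s, e, v):
            a, b = max(rs, start), min(re, end)
            first = (a - start) // colw
            last = (b - 1 - start) // colw
            for k in range(first, last + 1):
                cs = start + k * colw
                ov = min(b, cs + colw) - max(a, cs)
                sums[k] += rv * ov
        return sums / colw

    def dense(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base coverage array for one window (zeros where uncovered)."""
        out = np.zeros(end - start, dtype=float)
        s, e, v = self.rows_in(chrom, start, end)
        for rs, re, rv in zip(s, e, v):
            out[max(rs, start) - start : min(re, end) - start] = rv
        return out
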