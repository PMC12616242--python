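"""Three-way peak modules, signal quantification, and peak-set comparison.

The three factor peak sets (the two demethylases and the fusion oncogene)
are merged into consensus regions; each region's membership pattern is the
subset of factors overlapping it, giving the seven Venn classes.  Because
the original Venn counts are peak-based and side-dependent, both
region-pattern counts and per-set peak counts are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageIndex
from .genomic_core import (
    GenomeLayout,
    Interval,
    PeakSet,
    intersect_sets,
    merge_with_sources,
)


@dataclass
class ModuleAssignment:
    """A merged consensus region with its factor membership pattern."""

    region: Interval
    membership: frozenset[str]
    contributors: dict[str, list[int]] = field(default_factory=dict)

    def pattern(self, order: Sequence[str]) -> str:
        return "-".join(l for l in order if l in self.membership)


def assign_modules(
    a: PeakSet, b: PeakSet, ef: PeakSet, layout: GenomeLayout | None = None
) -> list[ModuleAssignment]:
    """Merge three factor peak sets into consensus regions with memberships.

    Consensus regions are the connected components of the union of all
    peaks; membership is every set with >= 1 bp overlap (equivalently, with
    a contributing peak).
    """
    labels = [a.label or "A", b.label or "B", ef.label or "EF"]
    if len(set(labels)) != len(labels):
        raise ValueError("factor peak sets need distinct labels")
    sets = [PeakSet(list(s), l) for s, l in zip((a, b, ef), labels)]
    regions = merge_with_sources(sets, layout)
    return [
        ModuleAssignment(r.interval, frozenset(r.sources), dict(r.sources))
        for r in regions
    ]


def pattern_counts(
    assignments: Sequence[ModuleAssignment], order: Sequence[str]
) -> pd.DataFrame:
    """Region counts and per-set contributing-peak counts per Venn pattern."""
    rows: dict[str, dict] = {}
    for m in assignments:
        pat = m.pattern(order)
        row = rows.setdefault(
            pat, {"pattern": pat, "n_regions": 0, **{f"n_peaks_{l}": 0 for l in order}}
        )
        row["n_regions"] += 1
        for label, idxs in m.contributors.items():
            row[f"n_peaks_{label}"] += len(idxs)
    df = pd.DataFrame(list(rows.values()))
    if df.empty:
        return pd.DataFrame(
            columns=["pattern", "n_regions", *[f"n_peaks_{l}" for l in order]]
        )
    return df.sort_values("pattern", kind="mergesort").reset_index(drop=True)


def quantify_signal(
    regions: Sequence[Interval] | PeakSet,
    coverage: pd.DataFrame | CoverageIndex,
    stat: str = "max",
) -> np.ndarray:
    """Per-region max (default) or mean per-base coverage.

    The maximum mirrors the box-plot quantification that assigns each peak
    the strongest per-base signal in its span; the mean counts uncovered
    bases as zero.
    """
    if stat not in ("max", "mean"):
        raise ValueError("stat must be 'max' or 'mean'")
    index = coverage if isinstance(coverage, CoverageIndex) else CoverageIndex(coverage)
    out = np.empty(len(list(regions)), dtype=float)
    for i, iv in enumerate(regions):
        if stat == "max":
            out[i] = index.window_max(iv.chrom, iv.start, iv.end)
        else:
            out[i] = index.window_mean(iv.chrom, iv.start, iv.end)
    return out


def grouped_signal(
    assignments: Sequence[ModuleAssignment],
    coverage: pd.DataFrame | CoverageIndex,
    order: Sequence[str],
    stat: str = "max",
) -> pd.DataFrame:
    """Per-region signal with its Venn pattern, ready for box-plot summaries."""
    values = quantify_signal([m.region for m in assignments], coverage, stat)
    return pd.DataFrame(
        {
            "pattern": [m.pattern(order) for m in assignments],
            "value": values,
        }
    )


@dataclass
class SummitHeatmap:
    """Summit-centred signal matrix, rows ranked by log mean signal."""

    matrix: np.ndarray  # (n_peaks, n_cols) in input-peak order
    row_order: np.ndarray  # ranking: indices into peaks, strongest first
    clipped_rows: list[int]  # peaks whose window exceeded chromosome bounds

    @property
    def ranked_matrix(self) -> np.ndarray:
        return self.matrix[self.row_order]


def summit_heatmap(
    peaks: PeakSet,
    coverage: pd.DataFrame | CoverageIndex,
    flank: int,
    n_cols: int,
    library_size: int | None = None,
    layout: GenomeLayout | None = None,
) -> SummitHeatmap:
    """Signal matrix in ``n_cols`` windows across summit +/- flank per peak.

    Values are mean per-base coverage scaled by 1e6 / library_size (CPM
    style); rows are ranked by log(mean row signal + eps) descending with
    input order breaking ties, eps being 1e-6 of the global mean signal.
    Windows crossing a chromosome edge are clipped (out-of-range columns
    stay zero) and the row is flagged.
    """
    if flank < n_cols:
        raise ValueError("flank must be >= n_cols")
    if (2 * flank) % n_cols != 0:
        raise ValueError("2*flank must be divisible by n_cols")
    index = coverage if isinstance(coverage, CoverageIndex) else CoverageIndex(coverage)
    scale = 1e6 / library_size if library_size else 1.0
    n = len(peaks)
    mat = np.zeros((n, n_cols), dtype=float)
    colw = 2 * flank // n_cols
    clipped = []
    for i, iv in enumerate(peaks):
        c = iv.summit_position
        w0, w1 = c - flank, c + flank
        lo, hi = w0, w1
        if layout is not None:
            hi = min(hi, layout.length_of(iv.chrom))
        lo = max(lo, 0)
        if (lo, hi) != (w0, w1):
            clipped.append(i)
        if hi <= lo:
            continue
        # align the clipped span to whole columns of the nominal window
        first_col = (lo - w0) // colw
        last_col = (hi - 1 - w0) // colw
        for k in range(first_col, last_col + 1):
            cs, ce = w0 + k * colw, w0 + (k + 1) * colw
            s, e = max(cs, lo), min(ce, hi)
            if e > s:
                mat[i, k] = index.window_mean(iv.chrom, s, e) * (e - s) / colw
    mat *= scale
    row_mean = mat.mean(axis=1)
    eps = 1e-6 * (row_mean.mean() if n else 1.0) or 1e-12
    rank_key = np.log(row_mean + eps)
    row_order = np.argsort(-rank_key, kind="stable")
    return SummitHeatmap(mat, row_order, clipped)


@dataclass
class PeakClassComparison:
    """Three-class comparison of two peak sets (e.g. control vs knockout).

    Overlap classes are reported from both sides because class sizes differ
    per side: ``common_a`` are a-peaks overlapping >= 1 b-peak, ``common_b``
    the converse.
    """

    common_a: PeakSet
    common_b: PeakSet
    only_a: PeakSet
    only_b: PeakSet
    label_a: str
    label_b: str

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (f"{self.label_a}+/{self.label_b}+ ({self.label_a} side)", len(self.common_a)),
                (f"{self.label_a}+/{self.label_b}+ ({self.label_b} side)", len(self.common_b)),
                (f"{self.label_a}+/{self.label_b}-", len(self.only_a)),
                (f"{self.label_a}-/{self.label_b}+", len(self.only_b)),
            ],
            columns=["class", "n_peaks"],
        )


def compare_peak_sets(ctrl: PeakSet, cond: PeakSet) -> PeakClassComparison:
    """Partition two peak sets into common / ctrl-only / cond-only classes."""
    pairs = intersect_sets(ctrl, cond) if len(ctrl) and len(cond) else []
    hit_a = {i for i, _, _ in pairs}
    hit_b = {j for _, j, _ in pairs}
    la = ctrl.label or "ctrl"
    lb = cond.label or "cond"
    return PeakClassComparison(
        common_a=PeakSet([iv for i, iv in enumerate(ctrl) if i in hit_a], la),
        common_b=PeakSet([iv for j, iv in enumerate(cond) if j in hit_b], lb),
        only_a=PeakSet([iv for i, iv in enumerate(ctrl) if i not in hit_a], la),
        only_b=PeakSet([iv for j, iv in enumerate(cond) if j not in hit_b], lb),
        label_a=la,
        label_b=lb,
    )


def superenhancer_overlap(se: PeakSet, peaks: PeakSet) -> float:
    """Fraction of superenhancer intervals overlapping >= 1 peak."""
    if len(se) == 0:
        raise ValueError("superenhancer set is empty; fraction undefined")
    hit = {i for i, _, _ in intersect_sets(se, peaks)} if len(peaks) else set()
    return len(hit) / len(se)
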