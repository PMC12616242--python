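"""Five-class regulatory-element classification and peak genome distribution.

Regulatory elements are called from four histone-mark peak sets:

* active enhancer   — H3K27ac
* active promoter   — H3K27ac + H3K4me3
* poised enhancer   — H3K27me3 (outside promoter context)
* primed enhancer   — H3K4me1 without H3K27ac
* bivalent promoter — H3K27me3 + H3K4me3

Evaluation units are the merged union of all mark peaks, so a region
covered by several marks is classified once.  Promoter classes (which
require H3K4me3) outrank enhancer classes, bivalent outranks active, and
among enhancers poised outranks primed outranks active; the precedence
order is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import pandas as pd

from .genomic_core import (
    GeneModel,
    GenomeLayout,
    Interval,
    PeakSet,
    intersect_sets,
    merge_plain,
    merge_with_sources,
    overlaps_any,
    subtract_intervals,
)

REQUIRED_MARKS = ("H3K27ac", "H3K4me1", "H3K4me3", "H3K27me3")


class ElementClass(str, Enum):
    ACTIVE_ENHANCER = "active_enhancer"
    ACTIVE_PROMOTER = "active_promoter"
    POISED_ENHANCER = "poised_enhancer"
    PRIMED_ENHANCER = "primed_enhancer"
    BIVALENT_PROMOTER = "bivalent_promoter"
    UNCLASSIFIED = "unclassified"


def classify_mark_combination(
    marks: frozenset[str] | set[str], promoter_context: bool
) -> ElementClass:
    """Deterministic class for one combination of marks, first rule wins."""
    marks = set(marks)
    if "H3K27me3" in marks and "H3K4me3" in marks:
        return ElementClass.BIVALENT_PROMOTER
    if "H3K27ac" in marks and "H3K4me3" in marks:
        return ElementClass.ACTIVE_PROMOTER
    if "H3K27me3" in marks and not promoter_context:
        return ElementClass.POISED_ENHANCER
    if "H3K4me1" in marks and "H3K27ac" not in marks:
        return ElementClass.PRIMED_ENHANCER
    if "H3K27ac" in marks:
        return ElementClass.ACTIVE_ENHANCER
    return ElementClass.UNCLASSIFIED


@dataclass
class LabeledRegion:
    """A merged evaluation unit with its marks and assigned class."""

    interval: Interval
    marks: frozenset[str]
    promoter_context: bool
    element_class: ElementClass


def promoter_windows(
    genes: Sequence[GeneModel], halfwidth: int = 2500
) -> dict[str, list[tuple[int, int]]]:
    """Merged TSS +/- halfwidth windows per chromosome."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    if halfwidth <= 0:
        return per_chrom
    for g in genes:
        per_chrom.setdefault(g.chrom, []).append(g.promoter(halfwidth))
    return {c: merge_plain(w) for c, w in per_chrom.items()}


def classify_elements(
    marks: Mapping[str, PeakSet],
    genes: Sequence[GeneModel],
    promoter_halfwidth: int = 2500,
) -> list[LabeledRegion]:
    """Classify merged mark-peak regions into the five element classes.

    ``marks`` must contain all four histone marks (any set may be empty).
    Mark presence on a unit means >= 1 bp overlap with that mark's peaks;
    promoter context means >= 1 bp overlap with any TSS window.
    """
    missing = [m for m in REQUIRED_MARKS if m not in marks]
    if missing:
        raise ValueError(f"missing required mark peak sets: {missing}")
    mark_sets = [PeakSet(list(marks[m]), m) for m in REQUIRED_MARKS]
    regions = merge_with_sources(mark_sets)
    units = PeakSet([r.interval for r in regions], "units")

    present: list[set[str]] = [set() for _ in regions]
    for m, ps in zip(REQUIRED_MARKS, mark_sets):
        for ui, _, _ in intersect_sets(units, ps):
            present[ui].add(m)

    windows = promoter_windows(genes, promoter_halfwidth)
    out = []
    for reg, mk in zip(regions, present):
        iv = reg.interval
        in_prom = overlaps_any(iv.start, iv.end, windows.get(iv.chrom, []))
        cls = classify_mark_combination(mk, in_prom)
        out.append(LabeledRegion(iv, frozenset(mk), in_prom, cls))
    return out


def labeled_regions_to_peakset(regions: Sequence[LabeledRegion]) -> PeakSet:
    from dataclasses import replace

    return PeakSet(
        [replace(r.interval, name=r.element_class.value) for r in regions],
        "elements",
    )


def annotate_peakset_elements(
    peaks: PeakSet, regions: Sequence[LabeledRegion]
) -> tuple[list[ElementClass], pd.Series, pd.Series]:
    """Assign each query peak the class of the region it overlaps most.

    Returns (per-peak classes, class fractions over the peak set, fraction
    of each element class overlapped by >= 1 peak — the "percentage of total
    regulatory elements bound" view).
    """
    region_set = PeakSet([r.interval for r in regions], "regions")
    best_ov = [0] * len(peaks)
    best_cls = [ElementClass.UNCLASSIFIED] * len(peaks)
    hit = [False] * len(regions)
    for pi, ri, ov in intersect_sets(peaks, region_set):
        hit[ri] = True
        if ov > best_ov[pi]:
            best_ov[pi] = ov
            best_cls[pi] = regions[ri].element_class

    order = [c.value for c in ElementClass]
    counts = pd.Series(0, index=order, dtype=float)
    for cls in best_cls:
        counts[cls.value] += 1
    fractions = counts / len(peaks) if len(peaks) else counts

    cls_totals = pd.Series(0, index=order, dtype=float)
    cls_hit = pd.Series(0, index=order, dtype=float)
    for r, h in zip(regions, hit):
        cls_totals[r.element_class.value] += 1
        if h:
            cls_hit[r.element_class.value] += 1
    import numpy as np

    covered = pd.Series(
        np.divide(
            cls_hit.to_numpy(),
            cls_totals.to_numpy(),
            out=np.zeros(len(order)),
            where=cls_totals.to_numpy() > 0,
        ),
        index=order,
    )
    return best_cls, fractions, covered


@dataclass
class FeatureDistribution:
    """Peak fractions over promoter/genic/intergenic feature space."""

    promoter: float
    genic: float
    intergenic: float
    total_peaks: int

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "promoter": self.promoter,
                "genic": self.genic,
                "intergenic": self.intergenic,
            }
        )


def _feature_space(
    genes: Sequence[GeneModel], promoter_halfwidth: int
) -> tuple[dict[str, list[tuple[int, int]]], dict[str, list[tuple[int, int]]]]:
    """Per-chromosome promoter and genic interval lists.

    Promoter bases take precedence: genic space is the gene bodies minus all
    promoter windows (of any gene).
    """
    prom = promoter_windows(genes, promoter_halfwidth)
    bodies: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        bodies.setdefault(g.chrom, []).append((g.tx_start, g.tx_end))
    genic = {
        c: subtract_intervals(b, prom.get(c, [])) for c, b in bodies.items()
    }
    return prom, genic


def genome_distribution(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    promoter_halfwidth: int = 2500,
    layout: GenomeLayout | None = None,
) -> FeatureDistribution:
    """Promoter/genic/intergenic distribution with proportional counting.

    Each peak contributes total weight 1, split equally among the distinct
    feature categories it overlaps by >= 1 bp (a peak straddling promoter
    and genic space counts 1/2 in each).  Per-base category precedence is
    promoter > genic > intergenic.
    """
    prom, genic = _feature_space(genes, promoter_halfwidth)
    w = {"promoter": 0.0, "genic": 0.0, "intergenic": 0.0}
    for iv in peaks:
        cats = []
        p = prom.get(iv.chrom, [])
        g = genic.get(iv.chrom, [])
        if overlaps_any(iv.start, iv.end, p):
            cats.append("promoter")
        if overlaps_any(iv.start, iv.end, g):
            cats.append("genic")
        # intergenic if any base of the peak is outside promoter+genic space
        covered = merge_plain(list(p) + list(g))
        residue = subtract_intervals([(iv.start, iv.end)], covered)
        if residue:
            cats.append("intergenic")
        share = 1.0 / len(cats)
        for c in cats:
            w[c] += share
    n = len(peaks)
    if n == 0:
        return FeatureDistribution(0.0, 0.0, 0.0, 0)
    return FeatureDistribution(
        w["promoter"] / n, w["genic"] / n, w["intergenic"] / n, n
    )
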