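"""Peak-to-gene association and direct-target derivation.

Two association rules are implemented:

* promoter rule — a peak associates with a gene iff it overlaps the
  strand-aware span from 2.5 kb upstream of the TSS to the 3' end of the
  transcript;
* vicinity rule — iff the gap between peak and gene is at most 100 kb
  (0 when they overlap).  The gap is measured peak-boundary to
  gene-boundary by default; a TSS-anchored mode is available.

Direct targets are associated genes passing differential-expression
thresholds; under knockdown/knockout semantics, genes going down upon
depletion of a factor are that factor's activated targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .genomic_core import GeneModel, PeakSet


@dataclass
class TargetRule:
    mode: str = "vicinity"  # "promoter" or "vicinity"
    promoter_upstream: int = 2500
    vicinity_distance: int = 100_000
    anchor: str = "gene_body"  # "gene_body" or "tss" (vicinity rule only)

    def __post_init__(self):
        if self.mode not in ("promoter", "vicinity"):
            raise ValueError("mode must be 'promoter' or 'vicinity'")
        if self.anchor not in ("gene_body", "tss"):
            raise ValueError("anchor must be 'gene_body' or 'tss'")
        if self.promoter_upstream < 0 or self.vicinity_distance < 0:
            raise ValueError("distances must be >= 0")


@dataclass
class Associations:
    """Both directions of the peak-gene mapping, deduplicated."""

    peak_to_genes: dict[int, list[str]]
    gene_to_peaks: dict[str, list[int]]

    @property
    def genes(self) -> set[str]:
        return set(self.gene_to_peaks)


def _gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """bp gap between two half-open intervals; 0 when they overlap."""
    if a_end <= b_start:
        return b_start - a_end
    if b_end <= a_start:
        return a_start - b_end
    return 0


def associate_genes(
    peaks: PeakSet, genes: Sequence[GeneModel], rule: TargetRule
) -> Associations:
    """Map peaks to genes (and back) under the given rule."""
    p2g: dict[int, list[str]] = {}
    g2p: dict[str, list[int]] = {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for i, iv in enumerate(peaks):
        for g in by_chrom.get(iv.chrom, []):
            if rule.mode == "promoter":
                s, e = g.span_with_upstream(rule.promoter_upstream)
                hit = iv.start < e and s < iv.end
            else:
                if rule.anchor == "tss":
                    s, e = g.tss, g.tss + 1
                else:
                    s, e = g.tx_start, g.tx_end
                hit = _gap(iv.start, iv.end, s, e) <= rule.vicinity_distance
            if hit:
                p2g.setdefault(i, [])
                if g.gene_id not in p2g[i]:
                    p2g[i].append(g.gene_id)
                g2p.setdefault(g.gene_id, [])
                if i not in g2p[g.gene_id]:
                    g2p[g.gene_id].append(i)
    return Associations(p2g, g2p)


@dataclass
class DirectTargetSet:
    """Activated / repressed direct targets of a peak module."""

    activated: list[str]
    repressed: list[str]
    p_cut: float
    lfc_cut: float
    provenance: str = ""

    def __post_init__(self):
        overlap = set(self.activated) & set(self.repressed)
        if overlap:
            raise ValueError(f"genes in both lists: {sorted(overlap)}")


def _check_de_table(de_table: pd.DataFrame) -> None:
    for col in ("gene_id", "log2FC", "padj"):
        if col not in de_table.columns:
            raise ValueError(f"DE table missing column {col!r}")
    dup = de_table["gene_id"][de_table["gene_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicated gene ids in DE table: {sorted(set(dup))[:5]}")


def derive_direct_targets(
    associations: Associations,
    de_table: pd.DataFrame,
    p_cut: float = 0.05,
    lfc_cut: float = 1.0,
    knockdown_semantics: bool = True,
    provenance: str = "",
) -> DirectTargetSet:
    """Intersect associated genes with significance-passing DE genes.

    Under knockdown semantics (the factor was depleted), activated targets
    are the associated genes with padj < p_cut and log2FC <= -lfc_cut;
    repressed targets have log2FC >= +lfc_cut.  Without knockdown semantics
    the signs swap.  Genes absent from the DE table are excluded.
    """
    if p_cut <= 0 or lfc_cut <= 0:
        raise ValueError("cuts must be > 0")
    _check_de_table(de_table)
    sub = de_table[de_table["gene_id"].isin(associations.genes)]
    sig = sub[sub["padj"] < p_cut]
    down = sorted(sig.loc[sig["log2FC"] <= -lfc_cut, "gene_id"])
    up = sorted(sig.loc[sig["log2FC"] >= lfc_cut, "gene_id"])
    if knockdown_semantics:
        activated, repressed = down, up
    else:
        activated, repressed = up, down
    return DirectTargetSet(activated, repressed, p_cut, lfc_cut, provenance)


@dataclass
class SignRatio:
    frac_down: float
    frac_up: float
    n_significant: int


def downregulation_fraction(
    de_table: pd.DataFrame,
    p_cut: float = 0.01,
    lfc_cut: float = 0.5,
    expressed_floor: float | None = None,
    expression_col: str = "fpkm",
) -> SignRatio:
    """Fractions of down- vs upregulated genes among significant ones.

    Significance = padj < p_cut, |log2FC| >= lfc_cut and, when a floor is
    given, expression above it.  With no passing gene both fractions are
    reported as 0 with count 0.
    """
    _check_de_table(de_table)
    sub = de_table[(de_table["padj"] < p_cut) & (de_table["log2FC"].abs() >= lfc_cut)]
    if expressed_floor is not None:
        if expression_col not in de_table.columns:
            raise ValueError(f"no expression column {expression_col!r} in DE table")
        sub = sub[sub[expression_col] > expressed_floor]
    n = len(sub)
    if n == 0:
        return SignRatio(0.0, 0.0, 0)
    n_down = int((sub["log2FC"] < 0).sum())
    return SignRatio(n_down / n, (n - n_down) / n, n)
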