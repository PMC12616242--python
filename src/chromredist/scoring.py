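"""Metagene profiles and small closed-form scores.

Aggregate TSS-centred and gene-body profiles are strand-aware averages of
per-base coverage over a gene set, scaled CPM-style by 1e6 / library_size
and divided by the number of contributing genes.  The closed-form scores
are the semiquantitative IHC H-score (1*WSN + 2*MSN + 3*SSN over percent
weakly/moderately/strongly stained nuclei, range 0-300), the 2^-ddCt
RT-qPCR relative fold change, and ChIP-qPCR percent input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageIndex
from .genomic_core import GeneModel, GenomeLayout


@dataclass
class MetageneProfile:
    """Averaged signal profile over a gene set.

    ``positions`` are window centres: bp offsets from the TSS (negative =
    upstream on either strand) for TSS profiles, percent positions along
    the body for gene-body profiles.
    """

    positions: np.ndarray
    values: np.ndarray
    n_genes: int
    skipped_genes: list[str]

    def __post_init__(self):
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("profile axis must be strictly increasing")

    def argmin_position(self) -> float:
        return float(self.positions[int(np.argmin(self.values))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions, "value": self.values})


def tss_profile(
    coverage: pd.DataFrame | CoverageIndex,
    genes: Sequence[GeneModel],
    flank: int = 5000,
    step: int = 100,
    library_size: int | None = None,
    layout: GenomeLayout | None = None,
) -> MetageneProfile:
    """Average coverage in ``step``-bp windows across TSS +/- flank.

    Upstream is the negative axis for both strands (the − strand window is
    mirrored).  Windows truncated at a chromosome edge contribute their
    covered positions only, weighted by the number of genes covering each
    position.
    """
    if not genes:
        raise ValueError("gene set is empty")
    if flank % step != 0:
        raise ValueError("flank must be a multiple of step")
    index = coverage if isinstance(coverage, CoverageIndex) else CoverageIndex(coverage)
    n_cols = 2 * flank // step
    sums = np.zeros(n_cols, dtype=float)
    counts = np.zeros(n_cols, dtype=float)
    for g in genes:
        w0, w1 = g.tss - flank, g.tss + flank
        lo = max(w0, 0)
        hi = w1 if layout is None else min(w1, layout.length_of(g.chrom))
        if hi <= lo:
            continue
        cols = index.column_means(g.chrom, w0, w1, n_cols) if (lo, hi) == (w0, w1) else None
        for k in range(n_cols):
            cs, ce = w0 + k * step, w0 + (k + 1) * step
            if ce <= lo or cs >= hi:
                continue
            if cols is None:
                s, e = max(cs, lo), min(ce, hi)
                v = index.window_mean(g.chrom, s, e)
            else:
                v = cols[k]
            kk = k if g.strand == "+" else n_cols - 1 - k
            sums[kk] += v
            counts[kk] += 1
    scale = 1e6 / library_size if library_size else 1.0
    values = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0) * scale
    positions = np.arange(-flank, flank, step, dtype=float) + step / 2
    return MetageneProfile(positions, values, len(genes), [])


def gene_body_profile(
    coverage: pd.DataFrame | CoverageIndex,
    genes: Sequence[GeneModel],
    n_body_bins: int = 100,
    library_size: int | None = None,
) -> MetageneProfile:
    """Average coverage along gene bodies rescaled to ``n_body_bins``.

    Genes shorter than n_body_bins bases cannot be rescaled and are
    skipped; their ids are reported in ``skipped_genes``.
    """
    if n_body_bins < 10:
        raise ValueError("n_body_bins must be >= 10")
    index = coverage if isinstance(coverage, CoverageIndex) else CoverageIndex(coverage)
    sums = np.zeros(n_body_bins, dtype=float)
    skipped = []
    n_used = 0
    for g in genes:
        length = g.tx_end - g.tx_start
        if length < n_body_bins:
            skipped.append(g.gene_id)
            continue
        base = index.dense(g.chrom, g.tx_start, g.tx_end)
        if g.strand == "-":
            base = base[::-1]
        edges = (np.arange(n_body_bins + 1) * length) // n_body_bins
        binned = np.add.reduceat(base, edges[:-1]) / np.diff(edges)
        sums += binned
        n_used += 1
    scale = 1e6 / library_size if library_size else 1.0
    values = (sums / n_used if n_used else sums) * scale
    positions = (np.arange(n_body_bins) + 0.5) * 100.0 / n_body_bins
    return MetageneProfile(positions, values, n_used, skipped)


@dataclass
class HScoreInput:
    """Percentages of weakly/moderately/strongly stained nuclei."""

    wsn: float
    msn: float
    ssn: float

    def __post_init__(self):
        for name, v in (("WSN", self.wsn), ("MSN", self.msn), ("SSN", self.ssn)):
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be a percentage in [0, 100]")
        if self.wsn + self.msn + self.ssn > 100 + 1e-9:
            raise ValueError("stained-nuclei percentages sum to more than 100")


def h_score(wsn: float, msn: float, ssn: float) -> float:
    """Semiquantitative IHC histoscore: 1*WSN + 2*MSN + 3*SSN, in [0, 300]."""
    inp = HScoreInput(wsn, msn, ssn)
    return 1.0 * inp.wsn + 2.0 * inp.msn + 3.0 * inp.ssn


def ddct_fold_change(
    ct_target_cond: float,
    ct_hk_cond: float,
    ct_target_ctrl: float,
    ct_hk_ctrl: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct(target) - Ct(housekeeping) per condition; ddCt is the
    condition dCt minus the control dCt; the fold change is 2^-ddCt.
    """
    for v in (ct_target_cond, ct_hk_cond, ct_target_ctrl, ct_hk_ctrl):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_cond - ct_hk_cond) - (ct_target_ctrl - ct_hk_ctrl)
    return float(2.0 ** (-ddct))


def percent_input(ip_quantity: float, input_quantity: float, input_fraction: float) -> float:
    """ChIP-qPCR enrichment as percent of dilution-corrected input.

    ``input_fraction`` is the fraction of chromatin the input aliquot
    represents (e.g. 0.1 for a 10% input).
    """
    if input_quantity <= 0:
        raise ValueError("input quantity must be > 0")
    if not 0 < input_fraction <= 1:
        raise ValueError("input fraction must be in (0, 1]")
    if ip_quantity < 0:
        raise ValueError("IP quantity must be >= 0")
    return 100.0 * ip_quantity / (input_quantity / input_fraction)
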