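"""Synthetic cohort with planted ground truth for every pipeline stage.

The generator emulates the study design this package analyses: three
factors — two H3K27me3 demethylases (labels ``A``, ``B``) and the fusion
oncogene (``EF``) — co-occupy "module" sites whose Venn pattern determines
their GGAA motif class (A-containing modules sit on single motifs, B-EF
and EF-only modules on multimeric repeats); histone-mark peaks realize all
five regulatory-element classes; coverage tracks carry Poisson noise over
a shared per-bin intensity landscape with planted fold changes; a
differential-expression table is correlated with module vicinity under
knockout semantics; and spike-in read counts reflect known per-sample
exogenous fractions.

Everything is deterministic per seed and every planted feature is recorded
in a :class:`SyntheticTruth` that downstream recovery tests read back.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genomic_core import (
    GeneModel,
    GenomeLayout,
    Interval,
    PeakSet,
    write_bed,
    write_bedgraph,
    write_fasta,
    write_genes,
)

PATTERNS = ("A-B-EF", "A-EF", "B-EF", "A", "B", "EF")
FACTORS = ("A", "B", "EF")
MARKS = ("H3K27ac", "H3K4me1", "H3K4me3", "H3K27me3")

DEFAULT_MODULE_MIX = {
    "A-B-EF": 0.30,
    "A-EF": 0.20,
    "B-EF": 0.20,
    "A": 0.10,
    "B": 0.10,
    "EF": 0.10,
}

# A-containing modules carry the single GGAA consensus; the oncogene alone
# or with B sits on multimeric microsatellite repeats.
DEFAULT_GGAA_RULE = {
    "A-B-EF": "single",
    "A-EF": "single",
    "B-EF": "multimeric",
    "A": "single",
    "B": "single",
    "EF": "multimeric",
}

DEFAULT_MARK_RULE = {
    "active_enhancer": ("H3K27ac",),
    "active_promoter": ("H3K27ac", "H3K4me3"),
    "poised_enhancer": ("H3K27me3",),
    "primed_enhancer": ("H3K4me1",),
    "bivalent_promoter": ("H3K27me3", "H3K4me3"),
}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults model the structures the pipeline is designed to detect: a
    multi-chromosome toy genome whose background is GGAA/TTCC-free, module
    sites with a fixed Venn-pattern mix, 10% of bins with a planted 4-fold
    gain at mean per-base coverage 20, 1% spike-in chromatin per sample,
    and a DE table separated by construction from its null.
    """

    seed: int = 0
    n_chromosomes: int = 3
    chrom_length: int = 2_000_000
    n_genes: int = 60
    n_module_sites: int = 60
    module_mix: dict = field(default_factory=lambda: dict(DEFAULT_MODULE_MIX))
    ggaa_rule: dict = field(default_factory=lambda: dict(DEFAULT_GGAA_RULE))
    single_units: tuple[int, int] = (1, 1)
    multimeric_units: tuple[int, int] = (6, 12)
    mark_rule: dict = field(default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_MARK_RULE.items()})
    n_elements_per_class: int = 8
    bin_width: int = 1000
    subbin: int = 100
    bin_effect_fraction: float = 0.10
    bin_effect_fold: float = 4.0
    n_gene_effects: int = 12
    gene_effect_fold: float = 3.0
    mean_coverage: float = 20.0
    landscape_shape: float = 3.0
    spike_in_fraction: dict = field(default_factory=lambda: {"ctrl": 0.01, "cond": 0.01})
    reference_fraction: float = 0.01
    n_superenhancers: int = 100
    se_overlap_fraction: dict = field(default_factory=lambda: {"A": 0.23, "B": 0.35})
    de_effect_lfc: float = 2.0
    de_effect_p: float = 1e-6
    de_factor: str = "A"
    fraction_repressed: float = 0.2
    vicinity_distance: int = 100_000
    tss_depletion: bool = True
    tss_depletion_offset: int = -2000
    tss_depletion_depth: float = 0.8
    tss_depletion_sigma: float = 300.0
    tss_profile_coverage: float = 50.0

    def __post_init__(self):
        if abs(sum(self.module_mix.values()) - 1.0) > 1e-9:
            raise ValueError("module_mix proportions must sum to 1")
        if set(self.module_mix) - set(PATTERNS):
            raise ValueError(f"unknown module patterns: {set(self.module_mix) - set(PATTERNS)}")
        for lo, hi in (self.single_units, self.multimeric_units):
            if lo < 1 or hi < lo:
                raise ValueError("repeat-unit count ranges must satisfy 1 <= lo <= hi")
        for sample, f in self.spike_in_fraction.items():
            if not 0 < f < 1:
                raise ValueError(f"spike_in_fraction[{sample!r}] must be in (0, 1)")
        if self.chrom_length % self.subbin != 0:
            raise ValueError("chrom_length must be a multiple of the coverage sub-bin")
        if self.bin_width % self.subbin != 0:
            raise ValueError("bin_width must be a multiple of the coverage sub-bin")
        if self.de_factor not in FACTORS:
            raise ValueError(f"de_factor must be one of {FACTORS}")


@dataclass
class SyntheticTruth:
    """Ground truth of every planted feature, JSON round-trippable."""

    sites: list[dict]          # chrom/start/end/pattern/motif_class/units/strand
    bin_up_indices: list[int]  # global indices on the analysis grid
    bin_fold: float
    gene_effect_bin_indices: list[int]  # bins inside planted gene-level effects
    gene_roles: dict           # gene_id -> activated / repressed / null
    gene_site_distance: dict   # gene_id -> bp gap to nearest de_factor module
    gene_effects: dict         # gene_id -> planted coverage fold
    elements: list[dict]       # chrom/start/end/element_class
    se_overlap: dict           # factor label -> planted overlap fraction
    spike_fractions: dict
    tss_depletion_offset: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


@dataclass
class SyntheticCohort:
    """All emitted pieces of one synthetic dataset, in memory."""

    config: SyntheticConfig
    layout: GenomeLayout
    sequences: dict
    genes: list[GeneModel]
    factor_peaks: dict      # label -> PeakSet
    mark_peaks: dict        # mark -> PeakSet
    superenhancers: PeakSet
    tracks: dict            # sample -> bedGraph DataFrame
    spike: pd.DataFrame     # sample / primary_reads / spike_reads
    de_table: pd.DataFrame  # gene_id / log2FC / padj / fpkm
    truth: SyntheticTruth

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.sequences, out / "genome.fa")
        self.layout.to_tsv(out / "layout.tsv")
        write_genes(self.genes, out / "genes.tsv")
        for label, ps in self.factor_peaks.items():
            write_bed(ps, out / f"peaks_{label}.bed")
        for mark, ps in self.mark_peaks.items():
            write_bed(ps, out / f"marks_{mark}.bed")
        write_bed(self.superenhancers, out / "superenhancers.bed")
        for sample, df in self.tracks.items():
            write_bedgraph(df, out / f"{sample}.bedgraph")
        self.spike.to_csv(out / "spike.tsv", sep="\t", index=False)
        self.de_table.to_csv(out / "de.tsv", sep="\t", index=False)
        self.truth.to_json(out / "truth.json")


# ---------------------------------------------------------------------------
# planning
# ---------------------------------------------------------------------------

@dataclass
class _Site:
    chrom: str
    motif_start: int
    motif_end: int
    pattern: str
    motif_class: str
    units: int
    strand: str


def _largest_remainder_counts(mix: dict, n: int) -> dict:
    raw = {p: mix.get(p, 0.0) * n for p in PATTERNS}
    counts = {p: int(math.floor(v)) for p, v in raw.items()}
    short = n - sum(counts.values())
    for p in sorted(PATTERNS, key=lambda p: raw[p] - counts[p], reverse=True)[:short]:
        counts[p] += 1
    return counts


def _plan(config: SyntheticConfig, rng: np.random.Generator):
    """Lay out module sites, genes, element regions and superenhancers."""
    L = config.chrom_length
    half = L // 2
    margin = 20_000
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    per_chrom = -(-config.n_module_sites // config.n_chromosomes)
    spacing = (half - 2 * margin) // per_chrom
    if spacing < 5_000:
        raise ValueError("module sites exceed genome capacity; enlarge chromosomes")

    counts = _largest_remainder_counts(config.module_mix, config.n_module_sites)
    pattern_pool = [p for p in PATTERNS for _ in range(counts[p])]
    order = rng.permutation(len(pattern_pool))

    sites: list[_Site] = []
    for i in range(config.n_module_sites):
        chrom = chroms[i % config.n_chromosomes]
        k = i // config.n_chromosomes
        x = margin + k * spacing
        pattern = pattern_pool[order[i]]
        motif_class = config.ggaa_rule[pattern]
        lo, hi = (
            config.multimeric_units if motif_class == "multimeric" else config.single_units
        )
        units = int(rng.integers(lo, hi + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        sites.append(_Site(chrom, x, x + 4 * units, pattern, motif_class, units, strand))

    # genes: half paired with module sites in the first chromosome half,
    # half distal (>= 150 kb from every site) in the second half
    n_paired = min(config.n_genes // 2, config.n_module_sites)
    genes: list[GeneModel] = []
    for j in range(n_paired):
        s = sites[j]
        glen = int(rng.integers(4000, 8001))
        start = s.motif_start + 12_000
        strand = "+" if rng.random() < 0.5 else "-"
        if start + glen > L:
            raise ValueError("paired gene exceeds chromosome bounds")
        genes.append(GeneModel(f"gene{j:03d}", s.chrom, strand, start, start + glen))

    n_distal = config.n_genes - n_paired
    distal_spacing = 30_000
    distal_start = half + 150_000
    per_chrom_distal = -(-n_distal // config.n_chromosomes)
    if distal_start + per_chrom_distal * distal_spacing + 10_000 > half + 500_000:
        raise ValueError("distal genes exceed genome capacity")
    distal: list[GeneModel] = []
    for j in range(n_distal):
        chrom = chroms[j % config.n_chromosomes]
        k = j // config.n_chromosomes
        glen = int(rng.integers(4000, 8001))
        start = distal_start + k * distal_spacing
        strand = "+" if rng.random() < 0.5 else "-"
        distal.append(
            GeneModel(f"gene{n_paired + j:03d}", chrom, strand, start, start + glen)
        )
    genes.extend(distal)

    # element regions realizing the five classes: promoter classes sit on
    # distal gene TSSs, enhancer classes in a dedicated intergenic zone
    elements: list[dict] = []
    promoter_classes = [c for c, marks in config.mark_rule.items() if "H3K4me3" in marks]
    enhancer_classes = [c for c in config.mark_rule if c not in promoter_classes]
    prom_elements = [c for c in promoter_classes for _ in range(config.n_elements_per_class)]
    gene_cursor = config.n_gene_effects  # distal genes 0..n_gene_effects-1 host coverage effects
    if gene_cursor + len(prom_elements) > len(distal):
        raise ValueError("not enough distal genes to host promoter-class elements")
    for cls in prom_elements:
        g = distal[gene_cursor]
        gene_cursor += 1
        elements.append(
            {"chrom": g.chrom, "start": g.tss - 500, "end": g.tss + 500, "element_class": cls}
        )
    enh_zone = half + 500_000
    enh_spacing = 10_000
    idx = 0
    for cls in enhancer_classes:
        for _ in range(config.n_elements_per_class):
            chrom = chroms[idx % config.n_chromosomes]
            k = idx // config.n_chromosomes
            start = enh_zone + k * enh_spacing
            if start + 800 > L - 200_000:
                raise ValueError("element regions exceed genome capacity")
            elements.append(
                {"chrom": chrom, "start": start, "end": start + 800, "element_class": cls}
            )
            idx += 1

    # superenhancers: planted overlap fractions per factor, remainder far
    # from every factor peak
    se_regions: list[tuple[str, int, int, str]] = []  # chrom, start, end, group
    def _sites_with(factor: str, without: str) -> list[_Site]:
        return [
            s for s in sites
            if factor in s.pattern.split("-") and without not in s.pattern.split("-")
        ]

    groups = [("A", "B"), ("B", "A")]
    used = 0
    for factor, excl in groups:
        frac = config.se_overlap_fraction.get(factor, 0.0)
        n_grp = round(frac * config.n_superenhancers)
        host = _sites_with(factor, excl)
        if n_grp > 2 * len(host):
            raise ValueError(f"not enough {factor}-exclusive sites for superenhancer plan")
        for k in range(n_grp):
            s = host[k % len(host)]
            c = (s.motif_start + s.motif_end) // 2
            if k // len(host) == 0:
                se_regions.append((s.chrom, c - 350, c - 50, factor))
            else:
                se_regions.append((s.chrom, c + 50, c + 350, factor))
        used += n_grp
    far_zone = half + 700_000
    for k in range(config.n_superenhancers - used):
        chrom = chroms[k % config.n_chromosomes]
        j = k // config.n_chromosomes
        start = far_zone + j * 5_000
        if start + 2_000 > L:
            raise ValueError("background superenhancers exceed genome capacity")
        se_regions.append((chrom, start, start + 2_000, "none"))

    return chroms, sites, genes, distal, elements, se_regions


# ---------------------------------------------------------------------------
# stage 1: genome
# ---------------------------------------------------------------------------

_MOTIF_RE = re.compile(b"GGAA|TTCC")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _background_sequence(length: int, rng: np.random.Generator) -> bytearray:
    seq = bytearray(_BASES[rng.integers(0, 4, size=length)].tobytes())
    # scrub accidental GGAA/TTCC so planted motifs are the only runs;
    # breaking the second base cannot recreate the same motif in place and
    # the loop handles junctions with neighbours
    while True:
        hits = list(_MOTIF_RE.finditer(bytes(seq)))
        if not hits:
            return seq
        for m in hits:
            seq[m.start() + 1] = ord("C") if seq[m.start()] == ord("G") else ord("G")


def _build_sequences(config, chroms, sites, rng):
    sequences = {}
    for chrom in chroms:
        sequences[chrom] = _background_sequence(config.chrom_length, rng)
    for s in sites:
        unit = b"GGAA" if s.strand == "+" else b"TTCC"
        sequences[s.chrom][s.motif_start : s.motif_end] = unit * s.units
    return {c: seq.decode("ascii") for c, seq in sequences.items()}


# ---------------------------------------------------------------------------
# stage 2: peaks, superenhancers, tracks, spike-in
# ---------------------------------------------------------------------------

def _build_factor_peaks(config, sites, rng) -> dict:
    peaks = {f: [] for f in FACTORS}
    for i, s in enumerate(sites):
        members = s.pattern.split("-")
        for f in members:
            j1 = int(rng.integers(0, 31))
            j2 = int(rng.integers(0, 31))
            start = max(0, s.motif_start - 150 - j1)
            end = s.motif_end + 150 + j2
            summit = (s.motif_start + s.motif_end) // 2 - start
            peaks[f].append(
                Interval(s.chrom, start, end, name=f"{f}_{i:03d}", summit=summit)
            )
    return {f: PeakSet(ivs, f) for f, ivs in peaks.items()}


def _build_mark_peaks(config, elements, rng) -> dict:
    marks = {m: [] for m in MARKS}
    for k, el in enumerate(elements):
        for m in config.mark_rule[el["element_class"]]:
            j1 = int(rng.integers(0, 26))
            j2 = int(rng.integers(0, 26))
            marks[m].append(
                Interval(el["chrom"], el["start"] - j1, el["end"] + j2, name=f"{m}_{k:03d}")
            )
    return {m: PeakSet(ivs, m) for m, ivs in marks.items()}


def _gene_window(g: GeneModel, pad: int = 2500) -> tuple[int, int]:
    return max(0, min(g.tx_start, g.tss - pad)), max(g.tx_end, g.tss + pad)


def _plant_bin_indices(config, layout, genes, rng) -> np.ndarray:
    """Global 1-kb bin indices eligible for and chosen as planted up bins."""
    from .bins import make_grid

    grid = make_grid(layout, config.bin_width)
    blocked = np.zeros(grid.total_bins, dtype=bool)
    for g in genes:
        s, e = _gene_window(g)
        ords = grid.bins_overlapping(g.chrom, s - config.bin_width, e + config.bin_width)
        off = grid.offset(g.chrom)
        blocked[off + ords.start : off + ords.stop] = True
    candidates = np.flatnonzero(~blocked)
    n_plant = int(math.floor(config.bin_effect_fraction * grid.total_bins))
    if n_plant > len(candidates):
        raise ValueError("not enough gene-free bins for the requested planted fraction")
    chosen = rng.choice(candidates, size=n_plant, replace=False)
    return np.sort(chosen)


def _build_tracks(config, layout, genes, distal, up_bins, rng):
    """Poisson coverage per 100-bp sub-bin over a shared intensity landscape."""
    sub_per_bin = config.bin_width // config.subbin
    samples = list(config.spike_in_fraction)
    gene_effect_genes = distal[: config.n_gene_effects]

    tracks = {s: [] for s in samples}
    if config.tss_depletion:
        tracks["profile"] = []
    masses = {s: 0.0 for s in tracks}

    up_set = set(int(i) for i in up_bins)
    from .bins import make_grid

    grid = make_grid(layout, config.bin_width)
    for chrom, length in layout:
        n_sub = length // config.subbin
        n_bins = grid.n_bins(chrom)
        off = grid.offset(chrom)
        landscape = rng.gamma(
            config.landscape_shape, 1.0 / config.landscape_shape, size=n_bins
        )
        base_mean = config.mean_coverage * np.repeat(landscape, sub_per_bin)[:n_sub]

        fold = np.ones(n_sub, dtype=float)
        for b in range(n_bins):
            if off + b in up_set:
                fold[b * sub_per_bin : (b + 1) * sub_per_bin] = config.bin_effect_fold
        gene_fold = np.ones(n_sub, dtype=float)
        for g in gene_effect_genes:
            if g.chrom != chrom:
                continue
            s, e = _gene_window(g)
            gene_fold[s // config.subbin : -(-e // config.subbin)] = config.gene_effect_fold

        sub_starts = np.arange(n_sub, dtype=np.int64) * config.subbin
        for sample in samples:
            mean = base_mean if sample == "ctrl" else base_mean * fold * gene_fold
            values = rng.poisson(mean).astype(float)
            tracks[sample].append(_runlength_frame(chrom, sub_starts, config.subbin, values, length))
            masses[sample] += float(values.sum()) * config.subbin

        if config.tss_depletion:
            centers = sub_starts + config.subbin / 2.0
            dip = np.ones(n_sub, dtype=float)
            for g in genes:
                if g.chrom != chrom:
                    continue
                c = g.tss + (config.tss_depletion_offset if g.strand == "+" else -config.tss_depletion_offset)
                d = centers - c
                dip *= 1.0 - config.tss_depletion_depth * np.exp(
                    -(d ** 2) / (2.0 * config.tss_depletion_sigma ** 2)
                )
            values = rng.poisson(config.tss_profile_coverage * dip).astype(float)
            tracks["profile"].append(
                _runlength_frame(chrom, sub_starts, config.subbin, values, length)
            )
            masses["profile"] += float(values.sum()) * config.subbin

    frames = {s: pd.concat(parts, ignore_index=True) for s, parts in tracks.items()}

    spike_rows = []
    for sample in frames:
        f = config.spike_in_fraction.get(sample, config.reference_fraction)
        primary = int(masses[sample] // 100)  # 100-bp read equivalents
        spike_reads = int(rng.poisson(primary * f / (1.0 - f)))
        spike_rows.append((sample, primary, max(spike_reads, 1)))
    spike = pd.DataFrame(spike_rows, columns=["sample", "primary_reads", "spike_reads"])
    return frames, spike


def _runlength_frame(chrom, sub_starts, subbin, values, length) -> pd.DataFrame:
    """Run-length-merge equal adjacent sub-bin values into bedGraph rows."""
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(values)]))
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": sub_starts[starts],
            "end": np.minimum(ends * subbin, length),
            "value": values[starts],
        }
    )


# ---------------------------------------------------------------------------
# stage 3: differential expression
# ---------------------------------------------------------------------------

def _gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    if a[1] <= b[0]:
        return b[0] - a[1]
    if b[1] <= a[0]:
        return a[0] - b[1]
    return 0


def _gene_roles(config, sites, genes, rng):
    """Target status per gene: within the vicinity of a de_factor module."""
    factor_sites = [
        s for s in sites if config.de_factor in s.pattern.split("-")
    ]
    roles = {}
    distances = {}
    for g in genes:
        gaps = [
            _gap((g.tx_start, g.tx_end), (s.motif_start, s.motif_end))
            for s in factor_sites
            if s.chrom == g.chrom
        ]
        d = min(gaps) if gaps else -1
        distances[g.gene_id] = d
        if 0 <= d <= config.vicinity_distance:
            roles[g.gene_id] = (
                "repressed" if rng.random() < config.fraction_repressed else "activated"
            )
        else:
            roles[g.gene_id] = "null"
    return roles, distances


def _build_de_table(config, genes, roles, rng) -> pd.DataFrame:
    rows = []
    for g in genes:
        role = roles[g.gene_id]
        if role == "activated":
            lfc = -(config.de_effect_lfc + abs(rng.normal(0, 0.25)))
            padj = config.de_effect_p * rng.uniform(0.1, 1.0)
            fpkm = rng.uniform(20, 100)
        elif role == "repressed":
            lfc = config.de_effect_lfc + abs(rng.normal(0, 0.25))
            padj = config.de_effect_p * rng.uniform(0.1, 1.0)
            fpkm = rng.uniform(20, 100)
        else:
            lfc = float(np.clip(rng.normal(0, 0.25), -0.9, 0.9))
            padj = rng.uniform(0, 1)
            fpkm = rng.uniform(1, 100)
        rows.append((g.gene_id, lfc, padj, fpkm))
    return pd.DataFrame(rows, columns=["gene_id", "log2FC", "padj", "fpkm"])


def null_de_table(n_genes: int, seed: int) -> pd.DataFrame:
    """A pure-null DE table: uniform adjusted p, tight null fold changes."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "gene_id": [f"null{j:04d}" for j in range(n_genes)],
            "log2FC": np.clip(rng.normal(0, 0.25, n_genes), -0.9, 0.9),
            "padj": rng.uniform(0, 1, n_genes),
            "fpkm": rng.uniform(1, 100, n_genes),
        }
    )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _stage_rngs(seed: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(4)
    return [np.random.default_rng(c) for c in children]


def generate_genome(config: SyntheticConfig):
    """(sequences, layout, genes): toy genome with planted GGAA sites.

    The background is free of GGAA/TTCC outside planted motifs; genes are
    pairwise disjoint with generous spacing.  Deterministic per seed.
    """
    rng_plan, rng_seq, _, _ = _stage_rngs(config.seed)
    chroms, sites, genes, _, _, _ = _plan(config, rng_plan)
    layout = GenomeLayout((c, config.chrom_length) for c in chroms)
    sequences = _build_sequences(config, chroms, sites, rng_seq)
    return sequences, layout, genes


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate the full synthetic dataset with its truth record."""
    rng_plan, rng_seq, rng_track, rng_de = _stage_rngs(config.seed)
    chroms, sites, genes, distal, elements, se_regions = _plan(config, rng_plan)
    layout = GenomeLayout((c, config.chrom_length) for c in chroms)
    sequences = _build_sequences(config, chroms, sites, rng_seq)

    factor_peaks = _build_factor_peaks(config, sites, rng_track)
    mark_peaks = _build_mark_peaks(config, elements, rng_track)
    se = PeakSet(
        [Interval(c, s, e, name=f"SE_{i:03d}_{grp}") for i, (c, s, e, grp) in enumerate(se_regions)],
        "SE",
    )
    up_bins = _plant_bin_indices(config, layout, genes, rng_track)
    tracks, spike = _build_tracks(config, layout, genes, distal, up_bins, rng_track)

    from .bins import make_grid as _make_grid

    grid = _make_grid(layout, config.bin_width)
    effect_bins: set[int] = set()
    for g in distal[: config.n_gene_effects]:
        s, e = _gene_window(g)
        ords = grid.bins_overlapping(g.chrom, s, e)
        off = grid.offset(g.chrom)
        effect_bins.update(range(off + ords.start, off + ords.stop))

    roles, distances = _gene_roles(config, sites, genes, rng_de)
    de_table = _build_de_table(config, genes, roles, rng_de)

    truth = SyntheticTruth(
        sites=[
            {
                "chrom": s.chrom,
                "start": s.motif_start,
                "end": s.motif_end,
                "pattern": s.pattern,
                "motif_class": s.motif_class,
                "units": s.units,
                "strand": s.strand,
            }
            for s in sites
        ],
        bin_up_indices=[int(i) for i in up_bins],
        bin_fold=config.bin_effect_fold,
        gene_effect_bin_indices=sorted(effect_bins),
        gene_roles=roles,
        gene_site_distance=distances,
        gene_effects={
            g.gene_id: config.gene_effect_fold for g in distal[: config.n_gene_effects]
        },
        elements=elements,
        se_overlap=dict(config.se_overlap_fraction),
        spike_fractions=dict(config.spike_in_fraction),
        tss_depletion_offset=config.tss_depletion_offset,
    )
    return SyntheticCohort(
        config=config,
        layout=layout,
        sequences=sequences,
        genes=genes,
        factor_peaks=factor_peaks,
        mark_peaks=mark_peaks,
        superenhancers=se,
        tracks=tracks,
        spike=spike,
        de_table=de_table,
        truth=truth,
    )


def generate_peaks_and_tracks(config: SyntheticConfig):
    """(factor peaks, mark peaks, tracks, spike table) for a config's genome."""
    cohort = generate_cohort(config)
    return cohort.factor_peaks, cohort.mark_peaks, cohort.tracks, cohort.spike


def generate_de_table(config: SyntheticConfig) -> pd.DataFrame:
    """The cohort's DE table alone (same values as in the full cohort)."""
    return generate_cohort(config).de_table
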