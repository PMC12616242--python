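# Methods

## Scope and model

`chromredist` implements the downstream, post-alignment stages of a
ChIP-seq / RNA-seq integration study of fusion-oncogene chromatin
reprogramming.  Upstream steps — read alignment, peak calling, and
replicate-aware differential-binding or differential-expression model
fitting — are deliberately out of scope: peak sets, signal tracks and DE
tables are *inputs*, consumed as plain BED / bedGraph / TSV.  Everything
here is deterministic given its inputs; no statistical test with a
replicate variance model is fitted.

Coordinates are uniformly 0-based half-open.  Formats with other
conventions are converted at the I/O boundary, and chromosome names are
matched by exact string equality (the synthetic data controls its own
names, so no "chr" aliasing is attempted).

## Bin redistribution

The genome is tiled with fixed-width bins, 1 kb by default — the average
size of an H3K27me3 peak, which is the mark this analysis was designed
for.  The last bin of each chromosome is truncated and retained so the
class counts always partition the grid.  Per-bin signal is the
length-weighted mean per-base coverage (uncovered bases count as zero).

**Spike-in normalization.**  With exogenous chromatin added at a nominal
fraction f (1% in the assay modelled here), a sample's values are scaled
by f·R_primary / R_spike, where R are mapped read counts on the primary
and spike genomes.  A sample with proportionally more spike-in signal is
scaled down; multiplying one sample's coverage and spike reads by a
common constant leaves its normalized values unchanged.

**Differential classification.**  A bin is *down* iff
ctrl ≥ floor and ctrl / max(cond, ε) ≥ FC, and *up* symmetrically, with
FC = 2, floor = 0.01 and ε = floor/100.  The fold-change + floor rule is
used instead of a named significance test because the pipeline operates
on single tracks per condition; the floor suppresses calls driven by
near-zero signal and ε keeps ratios finite without introducing
pseudo-counts at signal scale.  Both thresholds are exposed.  Gene-level
ranking applies the same rule to the mean (optionally max) of bin values
over the gene body plus its symmetric ±2.5 kb promoter, sorted by
|log₂ fold| with lexicographic tie-breaks for full determinism.

## Regulatory-element classes

Evaluation units are the merged union of the four mark peak sets
(segment-anchored rather than peak-anchored, so a region covered by
several marks is classified exactly once).  Mark presence means ≥ 1 bp
overlap.  The precedence order — bivalent promoter > active promoter >
poised enhancer (non-promoter context) > primed enhancer > active
enhancer > unclassified — resolves regions carrying conflicting marks:
promoter classes (requiring H3K4me3) outrank enhancer classes, bivalency
outranks activity, and the primed definition's "without H3K27ac"
exclusion is applied literally.  Requiring poised enhancers to sit
outside promoter windows is a design decision (an H3K27me3-only region
inside a promoter window is left unclassified rather than mislabelled);
the pure decision function `classify_mark_combination` is exhaustively
checked against a 16-row truth table.

Promoter windows are symmetric TSS ± 2.5 kb — strand-aware in
derivation but symmetric in extent.  For the genome distribution, bases
are assigned with precedence promoter > genic > intergenic, and each
peak splits its unit weight equally among the distinct categories it
touches, so weights always sum to the peak count.

## Peak modules, comparison, and quantification

Module membership is defined on merged consensus regions (connected
components of the three-set union; book-ended intervals coalesce), not
on per-set peak identities — published Venn counts are peak-based and
side-dependent, so both region-pattern counts and per-set contributing
peak counts are reported.  Control-vs-knockout comparison reports the
common class from both sides for the same reason.  Per-region
quantification offers the maximum per-base value (box-plot style) and
the mean; summit heatmaps use the declared summit or the interval
midpoint as fallback, scale by 1e6/library_size, and rank rows by
log(mean + ε) with ε = 1e-6 of the global mean signal so all-zero rows
sort stably.

## GGAA scanning

The scanner reports every maximal run of exact consecutive GGAA units on
the forward strand and TTCC units as reverse-strand runs; runs on the
same strand can never overlap, opposite-strand runs can.  Exact matching
(no degenerate variants, no single-base interruptions) keeps the
operation deterministic and oracle-testable; interrupted-repeat
tolerance is a non-goal.  The single/multimeric boundary is not a
published number: the default threshold of 4 consecutive units
distinguishes isolated ETS sites from microsatellite-scale repeats and
is exposed as a parameter that analyses should report.

## Peak-to-gene association and targets

The vicinity rule measures the gap peak-boundary to gene-boundary (the
literal reading of "distance between peaks and genes"); a TSS-anchored
mode is available by flag.  The promoter rule spans 2.5 kb upstream of
the TSS (strand-aware) through the transcript's 3′ end.  Direct targets
intersect associated genes with a DE table using its supplied adjusted
p-values — no re-adjustment, since multiple-testing correction belongs
to the out-of-scope DE fit.  Under knockdown semantics, activated
targets are the associated genes that go down upon depletion.

## Profiles and scores

TSS profiles average per-base coverage (not read counts — the two are
indistinguishable in the source description; coverage was chosen and is
documented here) in fixed steps across TSS ± flank, strand-aware with
upstream on the negative axis, scaled CPM-style by 1e6/library_size and
divided by the gene count; axis positions are window centres.  Gene-body
profiles rescale each body to a fixed number of relative bins; genes
shorter than the bin count are skipped and reported, never silently
dropped.  H-score inputs are percentages (matching the printed 0–300
range), validated to be non-negative and to sum to ≤ 100.

## Synthetic cohort

The generator is first-class, tested code; its defaults are the study
conditions the acceptance checks run under.

* **Genome** — 3 chromosomes × 2 Mb.  The random background is scrubbed
  of every GGAA/TTCC occurrence so the planted motifs are the only runs;
  planting writes the motif on a random strand with probability 0.5.
* **Module sites** — 60 sites with Venn-pattern mix 30/20/20/10/10/10 %
  over {A-B-EF, A-EF, B-EF, A, B, EF}.  A-containing patterns receive a
  single GGAA unit; B-EF and EF-only receive 6–12 tandem units,
  mirroring the demethylase/oncogene motif partition the pipeline is
  meant to recover.  Factor peaks cover their site with ±150 bp flanks
  plus jitter.
* **Elements** — 8 regions per class; promoter classes are placed on
  distal gene TSSs, enhancer classes in a dedicated intergenic zone.
* **Coverage** — per 100-bp sub-bin Poisson counts (so 1-kb analysis
  bins exercise real averaging) around mean 20, modulated by a per-bin
  Gamma(3, 1/3) intensity landscape *shared between conditions*.  The
  landscape models the heterogeneous genomic distribution of a broad
  histone mark; without it two null conditions would be uncorrelated
  bin-to-bin, whereas real redistribution analyses start from highly
  correlated signal.  10% of gene-free bins get a 4-fold gain in the
  condition sample; 12 distal genes get a 3-fold gain over their
  body ± 2.5 kb; a dedicated profile track plants a Gaussian depletion
  (depth 0.8, σ 300 bp) centred 2 kb upstream of every TSS.
* **Spike-in** — per-sample spike reads are Poisson with mean
  R_primary · f/(1−f) for the configured fraction f (1% per sample by
  default), with R_primary derived from the emitted coverage mass.
* **DE table** — genes within 100 kb of a module containing the
  depleted factor receive |log₂FC| = 2 + |N(0, 0.25)| with adjusted
  p ≈ 1e-6 (sign negative for activated targets, positive for the 20%
  planted as repressed); null genes draw log₂FC from N(0, 0.25)
  truncated to (−0.9, 0.9) with uniform adjusted p, so the planted
  target sets are separated from the null by construction.  Adjusted p
  is emitted directly — the table is an input contract, not a model fit.
* **Superenhancers** — 100 regions, of which 23 are placed over
  A-exclusive sites and 35 over B-exclusive sites, the remainder in
  peak-free territory, so the overlap fractions are 23% and 35% exactly.

All stages draw from independent child streams of one seed
(`numpy.random.SeedSequence.spawn`), so every emitted file is
byte-deterministic per seed and the genome can be regenerated without
the tracks.

**What passing recovery tests does and does not show.**  The cohort has
no fragment-size or mappability structure, no read-level noise, no
replicate variability, near-uniform base composition, and planted
effects that are large relative to the Poisson noise at the default
coverage.  Recovery at 100% therefore validates the *correctness of the
computations* — binning, normalization, thresholds, set algebra,
scanning, association — not the statistical power of the thresholds on
real data, where effect sizes are smaller and noise is structured.

## Problem sizes

The default cohort (6 Mb, 6 000 bins, 60 sites, 60 genes, three coverage
tracks) generates in about a second and was chosen as the smallest scale
at which every planted structure is present in non-trivial numbers;
oracle-equivalence checks run on ≤ 100 kb toy genomes where per-base
reference computations are exact and cheap.  The scanner's reference
comparison uses 10 000 random 200-bp sequences.

## Known limitations

* bedGraph inputs are assumed non-overlapping within a track (standard
  bedGraph); overlapping rows are not merged.
* The bin classifier models no replicate variance; its floor/FC
  thresholds are conventions to be reported, not calibrated error rates.
* Summit-heatmap windows clipped at chromosome edges treat out-of-range
  bases as zero coverage and flag the row.
* The printed genome-wide bin total of an analysis depends entirely on
  the supplied layout; the package reports its own count
  (`BinGrid.total_bins`) rather than assuming any canonical assembly.
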