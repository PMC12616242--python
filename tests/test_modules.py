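"""Peak modules, signal quantification, heatmaps, and set comparison."""

import numpy as np
import pandas as pd
import pytest

from chromredist import (
    GenomeLayout,
    Interval,
    PeakSet,
    assign_modules,
    compare_peak_sets,
    pattern_counts,
    quantify_signal,
    summit_heatmap,
    superenhancer_overlap,
)
from chromredist.coverage import CoverageIndex

from conftest import dense_coverage_oracle, random_bedgraph, random_peakset


def modules_bitmap_oracle(sets, layout):
    """Pattern counts via per-base label bitmaps + connected components."""
    labels = [ps.label for ps in sets]
    maps = {
        chrom: np.zeros((len(sets), L), dtype=bool) for chrom, L in layout
    }
    for si, ps in enumerate(sets):
        for iv in ps:
            maps[iv.chrom][si, iv.start : iv.end] = True
    counts: dict[str, int] = {}
    for chrom, m in maps.items():
        any_cov = m.any(axis=0)
        # connected components of covered bases, by explicit walk
        runs = []
        i = 0
        L = len(any_cov)
        while i < L:
            if any_cov[i]:
                j = i
                while j < L and any_cov[j]:
                    j += 1
                runs.append((i, j))
                i = j
            else:
                i += 1
        for s, e in runs:
            members = [labels[si] for si in range(len(sets)) if m[si, s:e].any()]
            pat = "-".join(members)
            counts[pat] = counts.get(pat, 0) + 1
    return counts


class TestAssignModules:
    def make_sets(self, *interval_lists):
        return [
            PeakSet([Interval(*args) for args in ivs], lab)
            for ivs, lab in zip(interval_lists, ("A", "B", "EF"))
        ]

    def test_identical_sets_give_one_triple_region(self):
        a, b, ef = self.make_sets(
            [("chr1", 10, 20)], [("chr1", 10, 20)], [("chr1", 10, 20)]
        )
        out = assign_modules(a, b, ef)
        assert len(out) == 1
        assert out[0].membership == frozenset({"A", "B", "EF"})

    def test_disjoint_sets_give_singletons(self):
        a, b, ef = self.make_sets(
            [("chr1", 0, 10), ("chr1", 100, 110)],
            [("chr1", 200, 210), ("chr1", 300, 310)],
            [("chr2", 0, 10), ("chr2", 100, 110)],
        )
        out = assign_modules(a, b, ef)
        assert len(out) == 6
        assert all(len(m.membership) == 1 for m in out)

    @pytest.mark.parametrize("seed", range(6))
    def test_pattern_counts_match_bitmap_oracle(self, toy_layout, seed):
        rng = np.random.default_rng(seed)
        sets = [random_peakset(rng, toy_layout, 25, lab) for lab in ("A", "B", "EF")]
        out = assign_modules(*sets, layout=toy_layout)
        got = (
            pattern_counts(out, ["A", "B", "EF"])
            .set_index("pattern")["n_regions"]
            .to_dict()
        )
        assert got == modules_bitmap_oracle(sets, toy_layout)

    def test_permutation_equivariance(self, toy_layout):
        rng = np.random.default_rng(42)
        x = random_peakset(rng, toy_layout, 20, "A")
        y = random_peakset(rng, toy_layout, 20, "B")
        z = random_peakset(rng, toy_layout, 20, "EF")
        c1 = pattern_counts(assign_modules(x, y, z), ["A", "B", "EF"])
        # relabel: swap the roles of the first two sets
        x2 = PeakSet(list(y), "A")
        y2 = PeakSet(list(x), "B")
        c2 = pattern_counts(assign_modules(x2, y2, z), ["A", "B", "EF"])
        remap = {"A": "B", "B": "A", "EF": "EF"}
        def norm(df):
            out = {}
            for r in df.itertuples():
                key = frozenset(r.pattern.split("-"))
                out[key] = r.n_regions
            return out
        c1n = norm(c1)
        c2n = {
            frozenset(remap[p] for p in key): v for key, v in norm(c2).items()
        }
        assert c1n == c2n

    def test_planted_cohort_membership_recovery(self, cohort):
        out = assign_modules(
            cohort.factor_peaks["A"],
            cohort.factor_peaks["B"],
            cohort.factor_peaks["EF"],
            cohort.layout,
        )
        sites = sorted(cohort.truth.sites, key=lambda s: (s["chrom"], s["start"]))
        regions = sorted(out, key=lambda m: (m.region.chrom, m.region.start))
        assert len(regions) == len(sites)
        ok = sum(
            set(m.membership) == set(s["pattern"].split("-"))
            for m, s in zip(regions, sites)
        )
        assert ok / len(sites) >= 0.99


class TestQuantifySignal:
    def test_constant_track(self, toy_layout):
        cov = pd.DataFrame(
            [(c, 0, L, 7.0) for c, L in toy_layout],
            columns=["chrom", "start", "end", "value"],
        )
        regions = PeakSet([Interval("chr1", 100, 300), Interval("chr2", 0, 50)])
        assert np.allclose(quantify_signal(regions, cov, "max"), 7.0)
        assert np.allclose(quantify_signal(regions, cov, "mean"), 7.0)

    def test_stepped_region(self):
        cov = pd.DataFrame(
            [("chr1", 0, 5, 3.0), ("chr1", 5, 10, 7.0)],
            columns=["chrom", "start", "end", "value"],
        )
        region = PeakSet([Interval("chr1", 0, 10)])
        assert quantify_signal(region, cov, "max")[0] == 7.0
        assert quantify_signal(region, cov, "mean")[0] == 5.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_base_oracle_and_max_dominates_mean(self, toy_layout, seed):
        rng = np.random.default_rng(seed)
        cov = random_bedgraph(rng, toy_layout)
        regions = random_peakset(rng, toy_layout, 30)
        dense = dense_coverage_oracle(cov, toy_layout)
        mx = quantify_signal(regions, cov, "max")
        mn = quantify_signal(regions, cov, "mean")
        for k, iv in enumerate(regions):
            window = dense[iv.chrom][iv.start : iv.end]
            assert mx[k] == pytest.approx(window.max())
            assert mn[k] == pytest.approx(window.mean())
        assert (mx >= mn - 1e-12).all()


class TestSummitHeatmap:
    def test_constant_track_keeps_input_order(self, toy_layout):
        cov = pd.DataFrame(
            [("chr1", 0, 100_000, 4.0)], columns=["chrom", "start", "end", "value"]
        )
        peaks = PeakSet(
            [Interval("chr1", 10_000 * (k + 1), 10_000 * (k + 1) + 200) for k in range(5)]
        )
        hm = summit_heatmap(peaks, cov, flank=1000, n_cols=20)
        assert np.allclose(hm.matrix, 4.0)
        assert list(hm.row_order) == [0, 1, 2, 3, 4]

    def test_triangular_coverage_peaks_at_center_column(self):
        rows = [("chr1", 5000 + i * 10, 5010 + i * 10, float(100 - abs(i - 50)))
                for i in range(100)]
        cov = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
        peaks = PeakSet([Interval("chr1", 5400, 5600, summit=100)])
        hm = summit_heatmap(peaks, cov, flank=500, n_cols=10)
        assert int(np.argmax(hm.matrix[0])) in (4, 5)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_per_base_oracle(self, toy_layout, seed):
        rng = np.random.default_rng(seed)
        cov = random_bedgraph(rng, toy_layout)
        peaks = random_peakset(rng, toy_layout, 12, max_len=800)
        flank, n_cols, lib = 500, 10, 1_000_000
        hm = summit_heatmap(peaks, cov, flank, n_cols, library_size=lib)
        dense = dense_coverage_oracle(cov, toy_layout)
        for i, iv in enumerate(peaks):
            c = iv.summit_position
            for k in range(n_cols):
                s = c - flank + k * (2 * flank // n_cols)
                e = s + 2 * flank // n_cols
                window = dense[iv.chrom][max(s, 0) : e]
                expected = window.sum() / (e - s) * 1e6 / lib
                assert hm.matrix[i, k] == pytest.approx(expected, abs=1e-9)
        # ranking is by mean row signal, strongest first
        means = hm.matrix.mean(axis=1)
        assert (np.diff(means[hm.row_order]) <= 1e-12).all()


class TestComparePeakSets:
    def test_identity(self, toy_layout):
        rng = np.random.default_rng(0)
        ps = random_peakset(rng, toy_layout, 20, "ctrl")
        cmp = compare_peak_sets(ps, PeakSet(list(ps), "cond"))
        assert len(cmp.common_a) == len(ps) and len(cmp.common_b) == len(ps)
        assert len(cmp.only_a) == 0 and len(cmp.only_b) == 0

    def test_disjoint(self):
        a = PeakSet([Interval("chr1", 0, 10)], "ctrl")
        b = PeakSet([Interval("chr1", 100, 110)], "cond")
        cmp = compare_peak_sets(a, b)
        assert len(cmp.common_a) == 0 and len(cmp.common_b) == 0
        assert len(cmp.only_a) == 1 and len(cmp.only_b) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_partition_matches_all_pairs_oracle(self, toy_layout, seed):
        rng = np.random.default_rng(seed)
        a = random_peakset(rng, toy_layout, 30, "ctrl")
        b = random_peakset(rng, toy_layout, 30, "cond")
        cmp = compare_peak_sets(a, b)
        hit_a = {
            i for i, x in enumerate(a) if any(x.overlap(y) >= 1 for y in b)
        }
        assert len(cmp.common_a) == len(hit_a)
        assert len(cmp.common_a) + len(cmp.only_a) == len(a)
        assert len(cmp.common_b) + len(cmp.only_b) == len(b)


class TestSuperenhancerOverlap:
    def test_saturation_and_disjoint(self, toy_layout):
        se = PeakSet([Interval("chr1", 1000 * k, 1000 * k + 500) for k in range(10)])
        genome_wide = PeakSet([Interval("chr1", 0, 100_000)])
        assert superenhancer_overlap(se, genome_wide) == 1.0
        assert superenhancer_overlap(se, PeakSet([Interval("chr2", 0, 10)])) == 0.0

    def test_empty_se_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            superenhancer_overlap(PeakSet([]), PeakSet([Interval("chr1", 0, 10)]))

    def test_planted_fractions_recovered_exactly(self, cohort):
        se = cohort.superenhancers
        assert superenhancer_overlap(se, cohort.factor_peaks["A"]) == pytest.approx(
            cohort.truth.se_overlap["A"]
        )
        assert superenhancer_overlap(se, cohort.factor_peaks["B"]) == pytest.approx(
            cohort.truth.se_overlap["B"]
        )
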