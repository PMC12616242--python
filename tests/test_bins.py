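"""Binning, spike-in normalization, and differential bin classification."""

import numpy as np
import pandas as pd
import pytest

from chromredist import (
    GenomeLayout,
    Interval,
    PeakSet,
    bin_signal,
    bins_vs_peaks,
    classify_bins,
    make_grid,
    rank_genes_by_change,
)
from chromredist.bins import BinnedTrack, SpikeInfo
from chromredist.genomic_core import GeneModel

from conftest import dense_coverage_oracle, random_bedgraph, random_peakset


def uniform_coverage(layout, value):
    return pd.DataFrame(
        [(c, 0, L, float(value)) for c, L in layout],
        columns=["chrom", "start", "end", "value"],
    )


class TestMakeGrid:
    def test_ceiling_arithmetic_with_truncated_last_bin(self):
        grid = make_grid(GenomeLayout([("chr1", 2500)]), 1000)
        assert grid.total_bins == 3
        assert grid.bin_span("chr1", 2) == (2000, 2500)

    def test_width_equal_to_chromosome_length(self):
        grid = make_grid(GenomeLayout([("chr1", 5000), ("chr2", 700)]), 5000)
        assert grid.n_bins("chr1") == 1 and grid.n_bins("chr2") == 1

    def test_two_chromosome_bin_count(self):
        grid = make_grid(GenomeLayout([("chr1", 10_000), ("chr2", 5_500)]), 1000)
        assert grid.total_bins == 16
        assert grid.global_index("chr2", 0) == 10

    def test_bins_overlapping(self):
        grid = make_grid(GenomeLayout([("chr1", 10_000)]), 1000)
        assert list(grid.bins_overlapping("chr1", 500, 2500)) == [0, 1, 2]
        assert list(grid.bins_overlapping("chr1", 1000, 1001)) == [1]


class TestBinSignal:
    def test_uniform_coverage_gives_constant_bins(self, toy_layout):
        grid = make_grid(toy_layout, 1000)
        track = bin_signal(uniform_coverage(toy_layout, 5.0), grid)
        assert np.allclose(track.values, 5.0)

    def test_spike_scaling_halves_the_doubled_sample(self, toy_layout):
        grid = make_grid(toy_layout, 1000)
        cov = uniform_coverage(toy_layout, 5.0)
        a = bin_signal(cov, grid, SpikeInfo(10_000, 1000, 0.01))
        b = bin_signal(cov, grid, SpikeInfo(10_000, 2000, 0.01))
        assert np.allclose(b.values, a.values / 2)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_per_base_expansion_oracle(self, seed):
        layout = GenomeLayout([("chr1", 10_000)])
        rng = np.random.default_rng(seed)
        cov = random_bedgraph(rng, layout, n_rows=20, max_len=700)
        grid = make_grid(layout, 1000)
        track = bin_signal(cov, grid)
        dense = dense_coverage_oracle(cov, layout)["chr1"]
        expected = [dense[s:e].mean() for s, e in
                    (grid.bin_span("chr1", k) for k in range(grid.total_bins))]
        assert np.allclose(track.values, expected)

    def test_interval_beyond_chromosome_end_rejected(self, toy_layout):
        grid = make_grid(toy_layout, 1000)
        cov = pd.DataFrame(
            [("chr2", 49_000, 50_001, 1.0)],
            columns=["chrom", "start", "end", "value"],
        )
        with pytest.raises(ValueError, match="crosses end"):
            bin_signal(cov, grid)


def make_track(grid, values):
    return BinnedTrack(grid, np.asarray(values, dtype=float))


class TestClassifyBins:
    @pytest.fixture
    def grid(self):
        return make_grid(GenomeLayout([("chr1", 5000)]), 1000)

    def test_identical_tracks_all_unchanged(self, grid):
        t = make_track(grid, [1, 2, 3, 4, 5])
        diff = classify_bins(t, t)
        assert diff.n_up == 0 and diff.n_down == 0

    def test_fourfold_reduction_above_floor_is_down(self, grid):
        ctrl = make_track(grid, [0.04, 1, 1, 1, 1])
        cond = make_track(grid, [0.01, 1, 1, 1, 1])
        diff = classify_bins(ctrl, cond, fc=2, floor=0.01)
        assert diff.codes[0] == -1 and diff.n_down == 1

    def test_floor_suppresses_noise_calls(self, grid):
        ctrl = make_track(grid, [0.004, 1, 1, 1, 1])
        cond = make_track(grid, [0.001, 1, 1, 1, 1])
        assert classify_bins(ctrl, cond).n_down == 0

    def test_antisymmetric_under_condition_swap(self, grid):
        rng = np.random.default_rng(0)
        a = make_track(grid, rng.uniform(0, 3, 5))
        b = make_track(grid, rng.uniform(0, 3, 5))
        fwd = classify_bins(a, b)
        rev = classify_bins(b, a)
        assert np.array_equal(fwd.codes, -rev.codes)

    def test_classes_partition_the_grid(self, grid):
        rng = np.random.default_rng(1)
        diff = classify_bins(
            make_track(grid, rng.uniform(0, 3, 5)),
            make_track(grid, rng.uniform(0, 3, 5)),
        )
        assert diff.n_up + diff.n_down + diff.n_unchanged == grid.total_bins

    def test_grid_mismatch_rejected(self, grid):
        other = make_grid(GenomeLayout([("chr1", 5000)]), 500)
        with pytest.raises(ValueError, match="different grids"):
            classify_bins(make_track(grid, np.ones(5)), make_track(other, np.ones(10)))

    def test_spike_scale_invariance_under_joint_rescaling(self, toy_layout):
        """Multiplying coverage and spike reads by the same constant is a no-op."""
        grid = make_grid(toy_layout, 1000)
        rng = np.random.default_rng(2)
        cov = random_bedgraph(rng, toy_layout)
        t1 = bin_signal(cov, grid, SpikeInfo(10_000, 500, 0.01))
        cov3 = cov.assign(value=cov["value"] * 3)
        t3 = bin_signal(cov3, grid, SpikeInfo(10_000, 1500, 0.01))
        assert np.allclose(t1.values, t3.values)


class TestRankGenes:
    def test_all_zero_tracks_give_no_calls(self):
        grid = make_grid(GenomeLayout([("chr1", 20_000)]), 1000)
        genes = [GeneModel("g1", "chr1", "+", 5000, 9000)]
        t = make_track(grid, np.zeros(grid.total_bins))
        df = rank_genes_by_change(t, t, genes)
        assert (df["direction"] == "unchanged").all()

    def test_fourfold_gene_gain(self):
        grid = make_grid(GenomeLayout([("chr1", 20_000)]), 1000)
        genes = [GeneModel("g1", "chr1", "+", 5000, 8000)]
        ctrl = np.zeros(grid.total_bins)
        cond = np.zeros(grid.total_bins)
        # gene window spans promoter (2.5 kb up) through body: bins 2..7
        ctrl[2:8] = 0.1
        cond[2:8] = 0.4
        df = rank_genes_by_change(make_track(grid, ctrl), make_track(grid, cond), genes)
        row = df.iloc[0]
        assert row["direction"] == "up"
        assert row["fold"] == pytest.approx(4.0)

    def test_unknown_chromosome_rejected(self):
        grid = make_grid(GenomeLayout([("chr1", 20_000)]), 1000)
        t = make_track(grid, np.zeros(grid.total_bins))
        with pytest.raises(ValueError, match="unknown chromosome"):
            rank_genes_by_change(t, t, [GeneModel("g", "chrX", "+", 0, 100)])

    def test_sorted_by_absolute_log_fold_with_id_ties(self):
        grid = make_grid(GenomeLayout([("chr1", 30_000)]), 1000)
        genes = [
            GeneModel("b", "chr1", "+", 4000, 6000),
            GeneModel("a", "chr1", "+", 14000, 16000),
            GeneModel("c", "chr1", "+", 24000, 26000),
        ]
        ctrl = np.ones(grid.total_bins)
        cond = np.ones(grid.total_bins)
        cond[14:17] = 8.0  # gene "a": strongest change
        cond[4:7] = 2.0
        cond[24:27] = 2.0  # same |log2 fold| as "b": id breaks the tie
        df = rank_genes_by_change(make_track(grid, ctrl), make_track(grid, cond), genes)
        assert list(df["gene_id"]) == ["a", "b", "c"]


class TestBinsVsPeaks:
    @pytest.fixture
    def diff(self):
        grid = make_grid(GenomeLayout([("chr1", 10_000)]), 1000)
        ctrl = make_track(grid, np.ones(10))
        cond_values = np.ones(10)
        cond_values[:3] = 4.0
        return classify_bins(ctrl, make_track(grid, cond_values))

    def test_no_peaks_gives_zero_fractions(self, diff):
        df = bins_vs_peaks(diff, PeakSet([], "x"))
        assert (df["fraction_overlapping"] == 0).all()

    def test_saturating_peaks_give_fraction_one(self, diff):
        df = bins_vs_peaks(diff, PeakSet([Interval("chr1", 0, 10_000)]))
        occupied = df[df["n_bins"] > 0]
        assert (occupied["fraction_overlapping"] == 1).all()

    @pytest.mark.parametrize("seed", range(4))
    def test_counts_match_boolean_matrix_oracle(self, seed):
        layout = GenomeLayout([("chr1", 20_000)])
        grid = make_grid(layout, 1000)
        rng = np.random.default_rng(seed)
        ctrl = make_track(grid, rng.uniform(0.5, 2, grid.total_bins))
        cond = make_track(grid, rng.uniform(0.5, 2, grid.total_bins))
        diff = classify_bins(ctrl, cond)
        peaks = random_peakset(rng, layout, 10, max_len=1500)
        df = bins_vs_peaks(diff, peaks).set_index("class")
        # oracle: dense bin x peak overlap matrix
        overlap = np.zeros(grid.total_bins, dtype=bool)
        for k in range(grid.total_bins):
            s, e = grid.bin_span("chr1", k)
            overlap[k] = any(iv.start < e and s < iv.end for iv in peaks)
        for code, name in ((-1, "down"), (0, "unchanged"), (1, "up")):
            mask = diff.codes == code
            assert df.loc[name, "n_overlapping"] == int((mask & overlap).sum())

    def test_second_mark_fractions(self, diff):
        grid = diff.grid
        second = classify_bins(
            make_track(grid, np.ones(10)),
            make_track(grid, np.r_[np.full(5, 4.0), np.ones(5)]),
        )
        peaks = PeakSet([Interval("chr1", 0, 10_000)])
        df = bins_vs_peaks(diff, peaks, second).set_index("class")
        # the 3 "up" bins (0-2) all sit in second-mark up bins (0-4)
        assert df.loc["up", "fraction_second_up"] == 1.0
        assert df.loc["up", "fraction_second_down"] == 0.0
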