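import numpy as np
import pandas as pd
import pytest

from hdm.genome import ChromSizes, IntervalSet, make_windows
from hdm.methylation import (
    CpGCallTable,
    conversion_efficiency,
    conversion_gate,
    differential_methylation,
    export_bedgraph,
    read_bismark_cov,
    region_methylation,
    track_for_export,
    write_bismark_cov,
)
from tests.conftest import random_call_table
from tests.oracles import region_meth_bruteforce


def calls(*rows):
    return CpGCallTable(
        pd.DataFrame(rows, columns=["chrom", "pos", "meth_count", "total_count"])
    )


class TestRegionMethylation:
    def test_weighted_mean_arithmetic(self, toy_grid):
        t = calls(("c1", 100, 5, 10), ("c1", 200, 0, 10))
        track = region_methylation(t, toy_grid)
        assert track.percent[0] == pytest.approx(25.0)
        assert track.cov_sum[0] == 20

    def test_coverage_below_ten_masked(self, toy_grid):
        t = calls(("c1", 100, 4, 9))
        track = region_methylation(t, toy_grid, min_total_coverage=10)
        assert track.mask[0]
        assert np.isnan(track.percent[0])

    def test_coverage_exactly_ten_retained(self, toy_grid):
        t = calls(("c1", 100, 4, 10))
        track = region_methylation(t, toy_grid, min_total_coverage=10)
        assert not track.mask[0]

    def test_matches_bruteforce_accumulator(self, toy_sizes, rng):
        t = random_call_table(rng, toy_sizes, 400)
        grid = make_windows(toy_sizes, 2_500)
        track = region_methylation(t, grid)
        expected = region_meth_bruteforce(t.df, grid.windows_df())
        for i, (m, c) in enumerate(expected):
            assert track.meth_sum[i] == m
            assert track.cov_sum[i] == c

    def test_interval_regions(self, toy_sizes, rng):
        t = random_call_table(rng, toy_sizes, 300)
        regions = IntervalSet.from_tuples(
            [("c1", 0, 3_000), ("c1", 5_000, 9_000), ("c2", 1_000, 2_000)]
        )
        track = region_methylation(t, regions)
        expected = region_meth_bruteforce(t.df, regions.df)
        assert [(m, c) for m, c in zip(track.meth_sum, track.cov_sum)] == expected

    def test_boundary_cpg_counted_once(self, toy_grid):
        # a CpG exactly on a window boundary belongs to the right window
        t = calls(("c1", 2_500, 3, 10))
        track = region_methylation(t, toy_grid)
        assert track.cov_sum[0] == 0 and track.cov_sum[1] == 10

    def test_conservation_of_counts(self, toy_sizes, rng):
        t = random_call_table(rng, toy_sizes, 500)
        grid = make_windows(toy_sizes, 2_500)
        track = region_methylation(t, grid)
        assert track.meth_sum.sum() == t.df["meth_count"].sum()
        assert track.cov_sum.sum() == t.df["total_count"].sum()

    def test_order_invariance(self, toy_sizes, rng):
        t = random_call_table(rng, toy_sizes, 200)
        shuffled = CpGCallTable(t.df.sample(frac=1, random_state=1))
        grid = make_windows(toy_sizes, 2_500)
        a = region_methylation(t, grid)
        b = region_methylation(shuffled, grid)
        assert np.array_equal(a.meth_sum, b.meth_sum)

    def test_weighted_mean_within_percpg_range(self, toy_sizes, rng):
        t = random_call_table(rng, toy_sizes, 300)
        grid = make_windows(toy_sizes, 2_500)
        track = region_methylation(t, grid)
        df = t.df.assign(frac=lambda d: d.meth_count / d.total_count)
        for i in range(len(track)):
            if track.cov_sum[i] == 0:
                continue
            w = track.regions.iloc[i]
            sub = df[(df.chrom == w.chrom) & (df.pos >= w.start) & (df.pos < w.end)]
            p = track.percent[i] / 100
            assert sub.frac.min() - 1e-12 <= p <= sub.frac.max() + 1e-12


class TestDifferentialMethylation:
    def test_delta_in_points(self, toy_grid):
        a = region_methylation(calls(("c1", 10, 8, 10)), toy_grid)
        b = region_methylation(calls(("c1", 10, 6, 10)), toy_grid)
        d = differential_methylation(a, b)
        assert d.delta[0] == pytest.approx(20.0)

    def test_mask_propagates(self, toy_grid):
        a = region_methylation(calls(("c1", 10, 8, 9)), toy_grid, 10)  # masked
        b = region_methylation(calls(("c1", 10, 6, 10)), toy_grid, 10)
        d = differential_methylation(a, b)
        assert d.mask[0] and np.isnan(d.delta[0])

    def test_identical_tracks_zero(self, toy_grid, toy_sizes, rng):
        t = random_call_table(rng, toy_sizes, 200)
        a = region_methylation(t, toy_grid)
        d = differential_methylation(a, a)
        assert np.all((d.delta[~d.mask] == 0.0))

    def test_mismatched_regions_rejected(self, toy_sizes):
        a = region_methylation(calls(("c1", 10, 1, 2)), make_windows(toy_sizes, 2_500))
        b = region_methylation(calls(("c1", 10, 1, 2)), make_windows(toy_sizes, 5_000))
        with pytest.raises(ValueError):
            differential_methylation(a, b)


class TestExportTrack:
    def test_threshold_five_boundary(self, toy_grid, tmp_path):
        t = calls(("c1", 10, 2, 4), ("c1", 2_600, 3, 5))
        track = track_for_export(t, toy_grid)
        assert track.mask[0] and not track.mask[1]
        out = tmp_path / "track.bedGraph"
        export_bedgraph(track, out)
        lines = out.read_text().strip().split("\n")
        assert len(lines) == 1
        chrom, start, end, value = lines[0].split("\t")
        assert (chrom, start) == ("c1", "2500")
        assert value == "60.0"

    def test_bedgraph_sorted(self, toy_sizes, rng, tmp_path):
        t = random_call_table(rng, toy_sizes, 300)
        track = track_for_export(t, make_windows(toy_sizes, 2_500))
        out = tmp_path / "t.bedGraph"
        export_bedgraph(track, out)
        df = pd.read_csv(out, sep="\t", header=None, names=["chrom", "start", "end", "v"])
        assert df.sort_values(["chrom", "start"]).equals(df)


class TestConversionEfficiency:
    def test_all_unmethylated(self):
        assert conversion_efficiency(calls(("lambda", 5, 0, 500))) == 100.0

    def test_boundary_fails_strict_gate(self):
        eff = conversion_efficiency(calls(("lambda", 5, 1, 200)))
        assert eff == pytest.approx(99.5)
        assert not conversion_gate(eff)

    def test_perfect_conversion_passes_gate(self):
        eff = conversion_efficiency(calls(("lambda", 5, 0, 1_000)))
        assert conversion_gate(eff)

    def test_zero_coverage_error(self):
        empty = CpGCallTable(pd.DataFrame(columns=CpGCallTable.COLUMNS))
        with pytest.raises(ValueError):
            conversion_efficiency(empty)


class TestBismarkIO:
    def test_one_based_conversion_and_roundtrip(self, tmp_path, toy_sizes, rng):
        t = random_call_table(rng, toy_sizes, 100)
        p = tmp_path / "sample.cov"
        write_bismark_cov(t, p)
        back = read_bismark_cov(p)
        assert back == t
        # raw file is 1-based
        raw = pd.read_csv(p, sep="\t", header=None)
        assert (raw[1].to_numpy() == t.df["pos"].to_numpy() + 1).all()

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            calls(("c1", 5, 11, 10))
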