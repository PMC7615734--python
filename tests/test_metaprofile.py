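import numpy as np
import pandas as pd
import pytest

from hdm.chip import WindowCounts, normalize_coverage
from hdm.genome import ChromSizes, IntervalSet, make_windows
from hdm.methylation import CpGCallTable
from hdm.metaprofile import (
    CpGSignal,
    TrackSignal,
    decile_summary,
    order_and_cap,
    scaled_profile,
)


class ConstantSignal:
    """Uniform signal source with configurable per-bin coverage."""

    def __init__(self, value=1.0, coverage=1):
        self.value = value
        self.coverage = coverage

    def bin_value(self, chrom, start, end):
        return self.value

    def bin_coverage(self, chrom, start, end):
        return self.coverage


class DictSignal:
    """Signal defined by explicit (chrom, start, end) -> value lookups
    falling back to per-bp accumulation over a dense array."""

    def __init__(self, dense_by_chrom):
        self.dense = dense_by_chrom

    def bin_value(self, chrom, start, end):
        arr = self.dense[chrom]
        seg = arr[start:end]
        return float(seg.mean()) if len(seg) else np.nan

    def bin_coverage(self, chrom, start, end):
        arr = self.dense[chrom]
        return float(np.abs(arr[start:end]).sum())


def features(*rows):
    return IntervalSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    )


class TestScaledProfile:
    def test_flat_signal_gives_flat_profile(self):
        fts = features(("c1", 30_000, 50_000, "d1", 0, "."), ("c1", 80_000, 120_000, "d2", 0, "."))
        m = scaled_profile(ConstantSignal(1.0), fts, flank_bin=1_000)
        assert m.values.shape == (2, 80)
        assert np.allclose(m.values, 1.0)

    def test_minus_strand_mirrors_plus_strand(self):
        # signal elevated only in the genomic left half of the feature
        dense = {"c1": np.zeros(200_000)}
        dense["c1"][40_000:60_000] = 5.0  # 5' half for + strand
        src = DictSignal(dense)
        plus = features(("c1", 40_000, 80_000, "p", 0, "+"))
        minus = features(("c1", 40_000, 80_000, "m", 0, "-"))
        mp = scaled_profile(src, plus, flank_bin=500)
        mm = scaled_profile(src, minus, flank_bin=500)
        # plus: elevated in first 20 body bins (columns 20..39)
        assert np.allclose(mp.values[0, 20:40], 5.0)
        assert np.allclose(mp.values[0, 40:60], 0.0)
        # minus: mirrored into columns 40..59 (its 3' half in transcription order)
        assert np.allclose(mm.values[0, 40:60], 5.0)
        assert np.allclose(mm.values[0, 20:40], 0.0)
        # full profile is the mirror image
        assert np.allclose(mm.values[0], mp.values[0][::-1])

    def test_eighty_percent_zero_body_bins_excluded(self):
        # 32 of 40 body bins zero coverage triggers the >= 80% rule
        class PartialCoverage:
            def __init__(self, n_covered):
                self.n_covered = n_covered

            def bin_value(self, chrom, start, end):
                return 1.0

            def bin_coverage(self, chrom, start, end):
                # cover only the first n_covered body-bin spans
                return 1 if start < 10_000 + self.n_covered * 1_000 else 0

        fts = features(("c1", 10_000, 50_000, "d", 0, "."))
        dropped = scaled_profile(PartialCoverage(8), fts, flank_bin=1_000)
        kept = scaled_profile(PartialCoverage(9), fts, flank_bin=1_000)
        assert len(dropped.feature_ids) == 0  # 32/40 zero = excluded
        assert len(kept.feature_ids) == 1  # 31/40 zero = retained

    def test_short_feature_dropped_with_warning(self):
        fts = features(("c1", 100, 120, "tiny", 0, "."))
        with pytest.warns(UserWarning, match="shorter"):
            m = scaled_profile(ConstantSignal(), fts, flank_bin=100)
        assert len(m.feature_ids) == 0

    def test_flank_bins_off_chromosome_missing(self):
        cs = ChromSizes({"c1": 100_000})
        fts = features(("c1", 0, 40_000, "edge", 0, "."))
        m = scaled_profile(ConstantSignal(), fts, flank_bin=1_000, chrom_sizes=cs)
        assert np.isnan(m.values[0, :20]).all()  # upstream off the start
        assert np.isfinite(m.values[0, 20:]).all()

    def test_remainder_bp_to_leading_bins(self):
        # 40 body bins over 40,010 bp: first 10 bins are 1001 bp
        dense = {"c1": np.arange(200_000, dtype=float)}
        src = DictSignal(dense)
        fts = features(("c1", 50_000, 90_010, "r", 0, "+"))
        m = scaled_profile(src, fts, flank_bin=1_000)
        # bin means must be strictly increasing and consistent with bin spans
        body = m.values[0, 20:60]
        assert np.all(np.diff(body) > 0)
        assert body[0] == pytest.approx(np.mean(np.arange(50_000, 51_001)))

    def test_body_mean_matches_feature_aggregate(self, toy_sizes, rng):
        # consistency: mean of body-bin values equals the region mean for
        # a signal with complete, uniform-coverage CpGs
        rows = [("c1", p, 1 if p % 200 == 0 else 0, 1) for p in range(0, 10_000, 100)]
        calls = CpGCallTable(
            pd.DataFrame(rows, columns=["chrom", "pos", "meth_count", "total_count"])
        )
        src = CpGSignal(calls)
        fts = features(("c1", 1_000, 5_000, "d", 0, "."))
        m = scaled_profile(src, fts, n_body=40, flank_bin=250)
        body = m.values[0, 20:60]
        direct = src.bin_value("c1", 1_000, 5_000)
        assert np.nanmean(body) == pytest.approx(direct, abs=1.0)

    def test_planted_enrichment_recovered_by_body_flank_ratio(self):
        dense = {"c1": np.ones(500_000)}
        dense["c1"][100_000:200_000] = 4.0  # planted enrichment E=4
        src = DictSignal(dense)
        fts = features(("c1", 100_000, 200_000, "d", 0, "."))
        m = scaled_profile(src, fts, flank_bin=2_000)
        ratio = np.nanmean(m.body()) / np.nanmean(m.flanks())
        assert ratio == pytest.approx(4.0, rel=0.10)


class TestOrderAndCap:
    def test_rows_sorted_descending(self):
        m = _matrix(np.array([[1.0] * 80, [2.0] * 80, [3.0] * 80]), ["a", "b", "c"])
        ordered, _ = order_and_cap(m, np.array([3.0, 1.0, 2.0]))
        assert ordered.feature_ids == ["a", "c", "b"]

    def test_degenerate_equal_matrix_bounds(self):
        m = _matrix(np.full((3, 80), 7.0), list("abc"))
        _, (lo, hi) = order_and_cap(m, np.arange(3.0))
        assert lo == 7.0 and hi == 7.0

    def test_cap_is_ninety_percent_quantile(self, rng):
        vals = rng.normal(size=(50, 80))
        m = _matrix(vals, [str(i) for i in range(50)])
        _, (lo, hi) = order_and_cap(m, rng.normal(size=50))
        flat = np.sort(vals.ravel())
        assert lo == flat[0]
        assert hi == pytest.approx(np.quantile(flat, 0.90))


def _matrix(values, ids):
    from hdm.metaprofile import MetaProfileMatrix

    return MetaProfileMatrix(values, ids)


class TestPlotting:
    def test_heatmap_and_boxplot_render(self, rng, tmp_path):
        from hdm.metaprofile import plot_decile_boxes, plot_heatmap

        m = _matrix(rng.normal(size=(12, 80)), [str(i) for i in range(12)])
        out = tmp_path / "heatmap.png"
        plot_heatmap(m, out)
        assert out.stat().st_size > 0
        resp = rng.normal(size=100)
        s = decile_summary(resp, rng.normal(size=100))
        out2 = tmp_path / "deciles.png"
        plot_decile_boxes(s, resp, out2)
        assert out2.stat().st_size > 0


class TestDecileSummary:
    def test_even_split(self, rng):
        s = decile_summary(rng.normal(size=100), rng.normal(size=100))
        assert [len(g) for g in s.groups] == [10] * 10

    def test_remainder_rule(self, rng):
        s = decile_summary(rng.normal(size=103), rng.normal(size=103))
        assert [len(g) for g in s.groups] == [11, 11, 11] + [10] * 7

    def test_groups_partition_windows(self, rng):
        s = decile_summary(rng.normal(size=57), rng.normal(size=57))
        all_ids = np.concatenate(s.groups)
        assert sorted(all_ids) == list(range(57))

    def test_self_ranking_monotone_means(self):
        x = np.arange(100, dtype=float)
        s = decile_summary(x, x)
        means = s.summary["mean"].to_numpy()
        assert np.all(np.diff(means) > 0)

    def test_missing_windows_dropped(self):
        resp = np.array([1.0, np.nan, 3.0] * 10)
        rank = np.arange(30, dtype=float)
        s = decile_summary(resp, rank, n_groups=5)
        assert sum(len(g) for g in s.groups) == 20

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            decile_summary(np.ones(5), np.ones(5), n_groups=10)
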