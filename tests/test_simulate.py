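import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hdm.chip import normalize_coverage, spikein_scaling_factor
from hdm.genome import ChromSizes, IntervalSet, make_windows
from hdm.methylation import region_methylation
from hdm.simulate import (
    ChipEnrichmentModel,
    MethylationModel,
    SyntheticGenomeSpec,
    default_genome_spec,
    default_methylation_model,
    simulate_amplicon,
    simulate_chip,
    simulate_frap,
    simulate_wgbs,
)


@pytest.fixture(scope="module")
def spec():
    return default_genome_spec(0)


class TestGenomeSpec:
    def test_default_layout_valid(self, spec):
        assert spec.chrom_sizes.total_length == 20_000_000
        assert len(spec.k9_domains) == 6
        assert len(spec.k27_domains) == 4
        assert spec.k9_domains.non_overlapping

    def test_domain_outside_chromosome_rejected(self):
        with pytest.raises(ValueError):
            SyntheticGenomeSpec(
                chrom_sizes=ChromSizes({"c1": 1_000}),
                k9_domains=IntervalSet.from_tuples([("c1", 500, 2_000)]),
            )

    def test_domain_class_k9_wins_overlap(self, spec):
        # chr1 1.4-1.5 Mb is covered by both marks; K9 takes precedence
        cls = spec.domain_class("chr1", np.array([1_450_000]))
        assert cls[0] == 1
        assert spec.domain_class("chr1", np.array([1_850_000]))[0] == 2
        assert spec.domain_class("chr1", np.array([2_500_000]))[0] == 0


class TestSimulateWgbs:
    def test_same_seed_identical_tables(self, spec):
        model = default_methylation_model()
        t1, _ = simulate_wgbs(spec, model, seed=5)
        t2, _ = simulate_wgbs(spec, model, seed=5)
        for s in t1:
            assert t1[s].df.equals(t2[s].df)

    def test_zero_depth_empty_with_warning(self, spec):
        model = MethylationModel(sample_means={"WT": (0.8, 0.8, 0.8)}, mean_depth=0.0)
        with pytest.warns(UserWarning, match="depth 0"):
            tables, _ = simulate_wgbs(spec, model, seed=1)
        assert len(tables["WT"]) == 0

    def test_shared_cpg_positions_across_samples(self, spec):
        tables, _ = simulate_wgbs(spec, default_methylation_model(), seed=2)
        wt, ko = tables["WT"].df, tables["KO"].df
        # positions covered in both samples agree (independent Poisson
        # depths may zero out a site in one sample only)
        merged = wt.merge(ko, on=["chrom", "pos"], how="inner")
        assert len(merged) > 0.85 * min(len(wt), len(ko))

    def test_planted_differential_recovered_within_mc_error(self, spec):
        # WT 0.85 vs KO 0.55 inside K9 domains; the window-level
        # differential must land within 3 Monte-Carlo SDs
        model = default_methylation_model()
        tables, truth = simulate_wgbs(spec, model, seed=3)
        dom = spec.k9_domains
        wt = region_methylation(tables["WT"], dom)
        ko = region_methylation(tables["KO"], dom)
        n_cpgs = wt.cov_sum.sum() / model.mean_depth
        # binomial + beta-region sampling error of the domain mean
        mc_sd = 100 * np.sqrt(
            0.25 / (model.concentration + 1) / len(dom)
            + 0.25 / n_cpgs / model.mean_depth * 0
            + 0.85 * 0.15 / wt.cov_sum.sum()
        )
        observed = np.average(wt.percent - ko.percent, weights=wt.cov_sum)
        planted = 100 * (0.85 - 0.55)
        assert abs(observed - planted) <= 3 * mc_sd


class TestSimulateChip:
    def test_null_model_chip_matches_input_in_law(self, spec):
        model = ChipEnrichmentModel(fold={0: 1.0, 1: 1.0, 2: 1.0})
        grid = make_windows(spec.chrom_sizes, 2_500)
        counts, _, _ = simulate_chip(spec, model, grid, seed=4, samples=["A"])
        ks = sps.ks_2samp(counts["A"].counts, counts["A_input"].counts)
        assert ks.pvalue > 0.01

    def test_planted_fold_recovered(self, spec):
        model = ChipEnrichmentModel(fold={0: 1.0, 1: 4.0, 2: 1.0})
        grid = make_windows(spec.chrom_sizes, 2_500)
        counts, _, truth = simulate_chip(spec, model, grid, seed=5, samples=["A"])
        track = normalize_coverage(counts["A"], counts["A_input"])
        cls = np.asarray(truth["window_class"])
        ratio = np.nanmean(track.values[cls == 1]) / np.nanmean(track.values[cls == 0])
        assert ratio == pytest.approx(4.0, rel=0.10)

    def test_true_scaling_factor_recorded_and_recovered(self, spec):
        model = ChipEnrichmentModel(spike_fractions={"A": 0.02, "B": 0.04})
        grid = make_windows(spec.chrom_sizes, 25_000)
        _, spikes, truth = simulate_chip(spec, model, grid, seed=6)
        s = spikein_scaling_factor(spikes, "B", "A", "B_input", "A_input")
        assert s == pytest.approx(truth["true_scaling"]["B->A"])
        assert s == pytest.approx(2.0)

    def test_determinism(self, spec):
        model = ChipEnrichmentModel()
        grid = make_windows(spec.chrom_sizes, 25_000)
        c1, _, _ = simulate_chip(spec, model, grid, seed=7, samples=["A"])
        c2, _, _ = simulate_chip(spec, model, grid, seed=7, samples=["A"])
        assert np.array_equal(c1["A"].counts, c2["A"].counts)


class TestSimulateFrap:
    def test_full_immobile_no_recovery(self):
        from hdm.frap import normalize_trace

        traces, _ = simulate_frap(1.0, 0.05, noise_sd=0.0, n_cells=1, seed=1)
        curve = normalize_trace(traces[0])
        assert np.allclose(curve.norm2, 0.0)

    def test_fully_mobile_fast_recovery(self):
        from hdm.frap import immobile_fraction, normalize_trace

        traces, _ = simulate_frap(0.0, 1.0, noise_sd=0.0, n_cells=1, seed=1)
        curve = normalize_trace(traces[0])
        assert curve.norm2[-1] == pytest.approx(1.0, abs=1e-6)
        assert immobile_fraction(curve) == pytest.approx(0.0, abs=1e-6)

    def test_frame_layout(self):
        traces, _ = simulate_frap(0.3, 0.05, n_cells=1, seed=1)
        t = traces[0]
        assert t.n_pre == 5 and len(t.times) == 80
        assert t.times[5] == 0.0
        assert np.allclose(np.diff(t.times), 2.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_frap(1.5, 0.05)
        with pytest.raises(ValueError):
            simulate_frap(0.3, -1.0)


class TestSimulateAmplicon:
    def test_no_duplication_exact_unique_count(self):
        from hdm.amplicon import dedup_fragments

        _, frags, truth = simulate_amplicon(0.7, pcr_duplication_rate=0.0, seed=1)
        unique, _ = dedup_fragments(frags)
        assert len(unique) == truth["n_unique_fragments"]

    def test_fully_methylated_locus(self):
        from hdm.amplicon import fragment_methylation

        _, frags, _ = simulate_amplicon(1.0, n_unique_fragments=50, seed=2)
        results, agg, _ = fragment_methylation(frags)
        assert agg == 1.0
        assert all(r.mean == 1.0 for r in results)

    def test_polyg_pairs_injected_at_rate(self):
        pairs, _, truth = simulate_amplicon(0.5, polyg_rate=0.1, seed=3)
        from hdm.amplicon import polyg_filter

        _, removed = polyg_filter(pairs)
        assert removed == truth["n_polyg_pairs"]

    def test_determinism(self):
        p1, f1, _ = simulate_amplicon(0.6, seed=8)
        p2, f2, _ = simulate_amplicon(0.6, seed=8)
        assert [(p.pair_id, p.seq1) for p in p1] == [(p.pair_id, p.seq1) for p in p2]
        assert [(f.umi1, f.umi2) for f in f1] == [(f.umi1, f.umi2) for f in f2]
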