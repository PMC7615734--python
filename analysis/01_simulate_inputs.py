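"""Generate every synthetic input dataset with planted ground truth.

Writes, under results/data/: Bismark-coverage call tables for a
WT-like and a KO-like sample (KO loses methylation inside planted
H3K9me3 domains), per-window ChIP fragment counts with matched inputs
and spike-in read totals for two marks, FRAP intensity traces with a
known immobile fraction, amplicon read pairs with UMIs / PCR
duplicates / poly-G artifacts, and the truth JSONs that later stages
are scored against.
"""

import importlib
import json

import numpy as np

cfg = importlib.import_module("00_config")

from hdm.chip import write_window_counts
from hdm.genome import make_windows, write_bed, write_chrom_sizes
from hdm.methylation import write_bismark_cov
from hdm.simulate import (
    ChipEnrichmentModel,
    SyntheticGenomeSpec,
    default_genome_spec,
    default_methylation_model,
    frap_traces_to_frame,
    simulate_amplicon,
    simulate_chip,
    simulate_frap,
    simulate_wgbs,
)
from hdm.amplicon import write_call_strings, write_fastq_pairs


def main():
    rng = np.random.default_rng(cfg.SEED)
    sub = lambda: int(rng.integers(2**31))  # noqa: E731
    d = cfg.DATA_DIR
    d.mkdir(parents=True, exist_ok=True)

    spec = default_genome_spec(0)
    write_chrom_sizes(spec.chrom_sizes, d / "genome.chrom.sizes")
    write_bed(spec.k9_domains, d / "planted_k9_domains.bed")
    write_bed(spec.k27_domains, d / "planted_k27_domains.bed")
    write_bed(spec.transcripts, d / "transcripts.bed")
    write_bed(spec.blacklist, d / "blacklist.bed")

    # WGBS
    tables, truth = simulate_wgbs(spec, default_methylation_model(), seed=sub())
    for sample, table in tables.items():
        write_bismark_cov(table, d / f"wgbs_{sample}.cov")
    truth.to_json(d / "wgbs_truth.json")
    print(f"WGBS: {', '.join(f'{s}: {len(t):,} CpGs' for s, t in tables.items())}")

    # ChIP for the two marks on 25-kb bins (domain calling) plus
    # spike-in pair on 2.5-kb windows (quantitative comparison)
    grid25 = make_windows(spec.chrom_sizes, cfg.HMM_BIN_SIZE)
    for mark, domains in (("K9", spec.k9_domains), ("K27", spec.k27_domains)):
        mark_spec = SyntheticGenomeSpec(
            chrom_sizes=spec.chrom_sizes,
            cpg_spacing=spec.cpg_spacing,
            k9_domains=domains,
            transcripts=spec.transcripts,
            blacklist=spec.blacklist,
        )
        counts, spikes, truth = simulate_chip(
            mark_spec,
            ChipEnrichmentModel(fold={0: 1.0, 1: 4.0, 2: 1.0}),
            grid25,
            seed=sub(),
            samples=[mark],
        )
        for name, wc in counts.items():
            write_window_counts(wc, d / f"chip_{name}_counts.tsv")
        truth.to_json(d / f"chip_{mark}_truth.json")
        print(f"ChIP {mark}: {counts[mark].counts.sum():,} fragments")

    grid = make_windows(spec.chrom_sizes, cfg.WINDOW_SIZE)
    model = ChipEnrichmentModel(
        fold={0: 1.0, 1: 4.0, 2: 1.0}, spike_fractions={"A": 0.02, "B": 0.04}
    )
    counts, spikes, truth = simulate_chip(spec, model, grid, seed=sub())
    for name, wc in counts.items():
        write_window_counts(wc, d / f"chiprx_{name}_counts.tsv")
    with open(d / "chiprx_spikein.tsv", "w") as fh:
        fh.write("sample\tdm_reads\ttotal_reads\n")
        for s, (dm, tot) in spikes.records().items():
            fh.write(f"{s}\t{dm}\t{tot}\n")
    truth.to_json(d / "chiprx_truth.json")
    print("ChIP-Rx pair A/B written (planted 2x occupancy shift in spike fractions)")

    # FRAP: three biological replicates with different cell counts
    frames = []
    for rep, (n_cells, s) in enumerate([(3, sub()), (5, sub()), (10, sub())], 1):
        traces, truth = simulate_frap(
            immobile_fraction=0.3, rate=0.05, noise_sd=0.01, n_cells=n_cells, seed=s
        )
        for t in traces:
            t.replicate_id = f"rep{rep}"
        frames.append(frap_traces_to_frame(traces))
    import pandas as pd

    pd.concat(frames, ignore_index=True).to_csv(d / "frap_traces.tsv", sep="\t", index=False)
    truth.to_json(d / "frap_truth.json")
    print("FRAP: 3 replicates (3+5+10 cells), planted IF = 0.30, k = 0.05/s")

    # amplicon
    pairs, frags, truth = simulate_amplicon(
        locus_meth=0.7, n_cpgs=10, n_unique_fragments=500, seed=sub()
    )
    write_fastq_pairs(pairs, d / "amplicon_R1.fastq", d / "amplicon_R2.fastq")
    write_call_strings(frags, d / "amplicon_calls.tsv", n_cpgs=10)
    truth.to_json(d / "amplicon_truth.json")
    print(f"Amplicon: {len(pairs)} read pairs, planted methylation 0.70")


if __name__ == "__main__":
    main()
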