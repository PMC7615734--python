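"""Synthetic-data generators with planted ground truth.

Every pipeline input can be generated here with the statistical
structure the downstream analysis assumes, so each stage is testable
without external downloads:

- WGBS call tables: CpG positions from a homogeneous point process,
  per-CpG coverage ~ Poisson, methylated counts ~ Binomial with a
  region-level methylation probability drawn from a Beta model whose
  mean depends on the planted domain class (e.g. a KO-like sample with
  reduced methylation inside H3K9me3 domains).
- ChIP window counts: Negative Binomial with mean = background x fold
  enrichment of the window's domain class; matched input samples from
  background only; spike-in read totals consistent with stated
  exogenous-chromatin fractions.
- FRAP traces: exponential recovery (1-IF)(1-exp(-k t)) embedded in a
  raw bleached-ROI intensity with configurable bleach depth, overall
  photobleaching decay on the whole-cell trace, and Gaussian noise.
- Amplicon read pairs: unique fragments with independent 4-bp UMIs on
  both sides and Bernoulli CpG calls, PCR duplicates copying UMIs and
  calls, and injected poly-G artifact pairs.

All generators are pure functions of (parameters, seed) and record a
``SyntheticTruth`` before noise is applied.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from hdm.genome import ChromSizes, IntervalSet, WindowGrid
from hdm.methylation import CpGCallTable
from hdm.chip import WindowCounts, SpikeInTable
from hdm.frap import FrapTrace
from hdm.amplicon import ReadPair, UmiFragment

__all__ = [
    "SyntheticGenomeSpec",
    "MethylationModel",
    "ChipEnrichmentModel",
    "SyntheticTruth",
    "default_genome_spec",
    "simulate_wgbs",
    "simulate_chip",
    "simulate_frap",
    "simulate_amplicon",
]


@dataclass
class SyntheticGenomeSpec:
    """Toy genome layout: chromosomes, CpG density and planted features.

    Defaults give 2 chromosomes x 10 Mb with a CpG every ~100 bp — large
    enough for 25-kb HMM bins and multi-window domains, small enough
    for seconds-scale runs.
    """

    chrom_sizes: ChromSizes
    cpg_spacing: float = 100.0  # mean bp between CpGs
    k9_domains: IntervalSet = field(default_factory=IntervalSet.empty)
    k27_domains: IntervalSet = field(default_factory=IntervalSet.empty)
    transcripts: IntervalSet = field(default_factory=IntervalSet.empty)
    blacklist: IntervalSet = field(default_factory=IntervalSet.empty)

    def __post_init__(self):
        for name, s in (("k9_domains", self.k9_domains), ("k27_domains", self.k27_domains)):
            s.validate_against(self.chrom_sizes)
            if not s.non_overlapping:
                raise ValueError(f"{name} must be non-overlapping")
        self.transcripts.validate_against(self.chrom_sizes)
        self.blacklist.validate_against(self.chrom_sizes)

    def domain_class(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Class per position: 0 background, 1 = H3K9me3, 2 = K27-only."""
        cls = np.zeros(len(pos), dtype=np.int8)
        for label, s in ((2, self.k27_domains), (1, self.k9_domains)):
            starts, ends = s.arrays(chrom)
            if len(starts) == 0:
                continue
            j = np.searchsorted(starts, pos, side="right") - 1
            inside = (j >= 0) & (pos < ends[np.clip(j, 0, None)])
            cls[inside] = label  # K9 applied last: wins where marks overlap
        return cls


@dataclass
class MethylationModel:
    """Beta-Binomial methylation structure per sample and domain class.

    ``sample_means`` maps sample name -> (background, in-K9, in-K27only)
    methylation means; region-level probabilities are drawn from Beta
    distributions with those means and common ``concentration``.
    """

    sample_means: dict[str, tuple[float, float, float]]
    concentration: float = 100.0
    mean_depth: float = 20.0

    def __post_init__(self):
        for name, means in self.sample_means.items():
            if not all(0.0 <= m <= 1.0 for m in means):
                raise ValueError(f"methylation means for {name!r} outside [0,1]")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.mean_depth < 0:
            raise ValueError("mean depth must be >= 0")


@dataclass
class ChipEnrichmentModel:
    """Negative Binomial ChIP counts with domain-class fold enrichment.

    ``fold`` maps domain class index (0 background, 1 K9, 2 K27-only)
    to fold enrichment of the ChIP mean over ``background_mean``.
    ``dispersion`` is the NB alpha (var = mu + alpha mu^2).
    ``spike_fractions`` maps sample name -> exogenous read fraction.
    """

    background_mean: float = 50.0
    fold: dict[int, float] = field(default_factory=lambda: {0: 1.0, 1: 4.0, 2: 1.0})
    dispersion: float = 0.2
    spike_fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.background_mean <= 0:
            raise ValueError("background mean must be positive")
        if any(f <= 0 for f in self.fold.values()):
            raise ValueError("fold enrichments must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for name, f in self.spike_fractions.items():
            if not (0.0 < f < 1.0):
                raise ValueError(f"spike fraction for {name!r} outside (0,1)")


@dataclass
class SyntheticTruth:
    """Planted parameters recorded before noise, sufficient for scoring."""

    payload: dict

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.payload, fh, indent=2, default=_jsonable)

    def __getitem__(self, key):
        return self.payload[key]


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def default_genome_spec(seed: int = 0) -> SyntheticGenomeSpec:
    """The default toy genome: 2 x 10 Mb, CpG every ~100 bp.

    Six H3K9me3 domains of 200 kb - 1 Mb and four H3K27me3 domains, two
    of which partially overlap H3K9me3 domains, plus a small blacklist
    interval per chromosome. Layout is deterministic given the seed.
    """
    chrom_sizes = ChromSizes({"chr1": 10_000_000, "chr2": 10_000_000})
    # 25-kb-aligned placements keep planted domains commensurate with HMM bins
    k9 = IntervalSet.from_tuples(
        [
            ("chr1", 500_000, 1_500_000),
            ("chr1", 3_000_000, 3_400_000),
            ("chr1", 6_000_000, 6_200_000),
            ("chr2", 1_000_000, 1_800_000),
            ("chr2", 4_500_000, 5_100_000),
            ("chr2", 8_000_000, 8_300_000),
        ]
    )
    k27 = IntervalSet.from_tuples(
        [
            ("chr1", 1_400_000, 1_900_000),  # overlaps a K9 domain
            ("chr1", 7_500_000, 7_900_000),
            ("chr2", 2_500_000, 2_900_000),
            ("chr2", 5_000_000, 5_400_000),  # overlaps a K9 domain
        ]
    )
    rng = np.random.default_rng(seed)
    rows, strands = [], ["+", "-"]
    for chrom in chrom_sizes:
        starts = rng.integers(0, chrom_sizes[chrom] - 60_000, size=40)
        for i, s in enumerate(np.sort(starts)):
            rows.append(
                (chrom, int(s), int(s) + int(rng.integers(5_000, 50_000)), f"{chrom}_g{i}", 0, strands[int(rng.integers(2))])
            )
    tx = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    transcripts = IntervalSet(tx)
    blacklist = IntervalSet.from_tuples(
        [("chr1", 9_900_000, 10_000_000), ("chr2", 0, 100_000)]
    )
    return SyntheticGenomeSpec(
        chrom_sizes=chrom_sizes,
        cpg_spacing=100.0,
        k9_domains=k9,
        k27_domains=k27,
        transcripts=transcripts,
        blacklist=blacklist,
    )


def default_methylation_model() -> MethylationModel:
    """WT-like high methylation everywhere; KO-like sample loses most
    methylation inside H3K9me3 domains, some in K27-only domains."""
    return MethylationModel(
        sample_means={
            "WT": (0.85, 0.85, 0.80),
            "KO": (0.82, 0.55, 0.70),
        },
        concentration=100.0,
        mean_depth=20.0,
    )


def simulate_wgbs(
    spec: SyntheticGenomeSpec,
    model: MethylationModel,
    seed: int,
) -> tuple[dict[str, CpGCallTable], SyntheticTruth]:
    """Generate per-sample CpG call tables with planted domain effects.

    CpG positions are shared across samples (a homogeneous point
    process at the spec's density); per-CpG total counts are
    Poisson(mean_depth) and methylated counts Binomial(total, p) with p
    drawn per (region, sample) from the Beta model.
    """
    rng = np.random.default_rng(seed)
    positions: dict[str, np.ndarray] = {}
    classes: dict[str, np.ndarray] = {}
    for chrom, length in spec.chrom_sizes.items():
        n_exp = length / spec.cpg_spacing
        gaps = rng.exponential(spec.cpg_spacing, size=int(n_exp * 1.3) + 100)
        pos = np.unique(np.cumsum(gaps).astype(np.int64))
        pos = pos[pos < length]
        positions[chrom] = pos
        classes[chrom] = spec.domain_class(chrom, pos)

    if model.mean_depth == 0:
        warnings.warn("mean depth 0: generating empty call tables")

    # region-level Beta draws: one p per (chrom, region id, sample), where
    # region ids delimit runs of constant domain class
    tables: dict[str, CpGCallTable] = {}
    true_region_meth: dict[str, dict] = {s: {} for s in model.sample_means}
    for sample, means in model.sample_means.items():
        frames = []
        for chrom in spec.chrom_sizes:
            pos = positions[chrom]
            cls = classes[chrom]
            if len(pos) == 0 or model.mean_depth == 0:
                continue
            # runs of constant class = regions
            boundaries = np.nonzero(np.diff(cls))[0] + 1
            region_id = np.zeros(len(pos), dtype=np.int64)
            region_id[boundaries] = 1
            region_id = np.cumsum(region_id)
            n_regions = region_id[-1] + 1
            region_class = cls[np.searchsorted(region_id, np.arange(n_regions))]
            mu = np.array([means[c] for c in region_class])
            a = np.clip(mu * model.concentration, 1e-6, None)
            b = np.clip((1 - mu) * model.concentration, 1e-6, None)
            p_region = rng.beta(a, b)
            true_region_meth[sample][chrom] = {
                "region_class": region_class,
                "p": p_region,
            }
            p = p_region[region_id]
            total = rng.poisson(model.mean_depth, size=len(pos))
            meth = rng.binomial(total, p)
            keep = total > 0
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos[keep],
                        "meth_count": meth[keep],
                        "total_count": total[keep],
                    }
                )
            )
        if frames:
            tables[sample] = CpGCallTable(pd.concat(frames, ignore_index=True))
        else:
            tables[sample] = CpGCallTable(
                pd.DataFrame(columns=CpGCallTable.COLUMNS)
            )

    truth = SyntheticTruth(
        {
            "kind": "wgbs",
            "seed": seed,
            "sample_means": {k: list(v) for k, v in model.sample_means.items()},
            "mean_depth": model.mean_depth,
            "k9_domains": spec.k9_domains.df[["chrom", "start", "end"]].values.tolist(),
            "k27_domains": spec.k27_domains.df[["chrom", "start", "end"]].values.tolist(),
            "n_cpgs": {c: int(len(p)) for c, p in positions.items()},
        }
    )
    return tables, truth


def simulate_chip(
    spec: SyntheticGenomeSpec,
    model: ChipEnrichmentModel,
    grid: WindowGrid,
    seed: int,
    samples: list[str] | None = None,
) -> tuple[dict[str, WindowCounts], SpikeInTable, SyntheticTruth]:
    """Generate per-window NB ChIP counts plus matched inputs and spike-ins.

    ChIP window means are background x fold(domain class at the window
    midpoint); input samples draw from background only. Exogenous
    (spike) read totals are set so each sample's spike fraction matches
    the model. Sample names: '<name>' for ChIP, '<name>_input' for its
    input.
    """
    if samples is None:
        samples = list(model.spike_fractions) or ["chip"]
    rng = np.random.default_rng(seed)
    wdf = grid.windows_df()
    mid = ((wdf["start"] + wdf["end"]) // 2).to_numpy()
    cls = np.zeros(len(wdf), dtype=np.int8)
    for chrom in grid.chrom_sizes:
        m = (wdf["chrom"] == chrom).to_numpy()
        cls[m] = spec.domain_class(chrom, mid[m])
    fold = np.array([model.fold.get(int(c), 1.0) for c in cls])

    def _nb(mean_arr):
        if model.dispersion == 0:
            return rng.poisson(mean_arr)
        r = 1.0 / model.dispersion
        p = r / (r + mean_arr)
        return rng.negative_binomial(r, p)

    counts: dict[str, WindowCounts] = {}
    spike_records: dict[str, tuple[int, int]] = {}
    true_enrichment: dict[str, np.ndarray] = {}
    for sample in samples:
        chip_mean = model.background_mean * fold
        chip_counts = _nb(chip_mean)
        input_counts = _nb(np.full(len(wdf), model.background_mean))
        n_chip = int(chip_counts.sum())
        n_input = int(input_counts.sum())
        counts[sample] = WindowCounts(grid, chip_counts, n_chip, sample)
        counts[f"{sample}_input"] = WindowCounts(
            grid, input_counts, n_input, f"{sample}_input"
        )
        # spike read totals at a nominal library depth so stated fractions
        # are reproduced exactly (dm = f * T with T a round number)
        T = 10_000_000
        f_chip = model.spike_fractions.get(sample, 0.05)
        spike_records[sample] = (max(1, round(f_chip * T)), T)
        # inputs share a common spike fraction (unenriched chromatin)
        f_in = 0.05
        spike_records[f"{sample}_input"] = (max(1, round(f_in * T)), T)
        true_enrichment[sample] = fold

    spike_table = SpikeInTable(spike_records)

    # true scaling factor between each sample pair from the definition
    def _d(s):
        dm, tot = spike_records[s]
        return 1e7 * dm / tot

    true_scaling = {}
    for a in samples:
        for b in samples:
            if a != b:
                true_scaling[f"{a}->{b}"] = (_d(a) / _d(b)) / (
                    _d(f"{a}_input") / _d(f"{b}_input")
                )

    truth = SyntheticTruth(
        {
            "kind": "chip",
            "seed": seed,
            "background_mean": model.background_mean,
            "fold": {str(k): v for k, v in model.fold.items()},
            "dispersion": model.dispersion,
            "window_class": cls,
            "true_scaling": true_scaling,
            "spike_fractions": dict(model.spike_fractions),
        }
    )
    return counts, spike_table, truth


def simulate_frap(
    immobile_fraction: float,
    rate: float,
    bleach_depth: float = 0.6,
    photobleach_decay: float = 0.002,
    noise_sd: float = 0.01,
    n_cells: int = 10,
    seed: int = 0,
    n_pre: int = 5,
    n_post: int = 75,
    frame_interval: float = 2.0,
) -> tuple[list[FrapTrace], SyntheticTruth]:
    """Generate raw FRAP traces with known immobile fraction and rate.

    The underlying recovery is (1-IF)(1-exp(-k t)); the raw
    bleached-ROI intensity drops to ``1 - bleach_depth`` of its
    pre-bleach level at t=0 and recovers toward the mobile plateau,
    while both ROI and whole-cell traces decay with
    ``photobleach_decay`` (per second) to give the first normalization
    real work. Gaussian noise of ``noise_sd`` (relative) is added to
    both channels.
    """
    if not (0.0 <= immobile_fraction <= 1.0):
        raise ValueError("immobile fraction must be in [0,1]")
    if rate <= 0:
        raise ValueError("rate must be positive")
    if not (0.0 < bleach_depth <= 1.0):
        raise ValueError("bleach depth must be in (0,1]")
    rng = np.random.default_rng(seed)
    t_pre = np.arange(-n_pre, 0) * frame_interval
    t_post = np.arange(n_post) * frame_interval
    times = np.concatenate([t_pre, t_post])
    traces = []
    base_cell = 1000.0
    for c in range(n_cells):
        recovery = (1 - immobile_fraction) * (1 - np.exp(-rate * t_post))
        # normalized bleached-ROI signal: drops to (1-bleach_depth), recovers
        roi_norm = np.concatenate(
            [np.ones(n_pre), (1 - bleach_depth) + bleach_depth * recovery]
        )
        decay = np.exp(-photobleach_decay * (times - times[0]))
        roi = base_cell * roi_norm * decay
        cell = base_cell * decay
        if noise_sd > 0:
            roi = roi * (1 + rng.normal(0, noise_sd, size=len(times)))
            cell = cell * (1 + rng.normal(0, noise_sd, size=len(times)))
        roi = np.clip(roi, 1e-6, None)
        cell = np.clip(cell, 1e-6, None)
        traces.append(
            FrapTrace(
                times=times,
                roi=roi,
                cell=cell,
                n_pre=n_pre,
                cell_id=f"cell{c}",
                replicate_id="rep1",
            )
        )
    truth = SyntheticTruth(
        {
            "kind": "frap",
            "seed": seed,
            "immobile_fraction": immobile_fraction,
            "rate": rate,
            "bleach_depth": bleach_depth,
            "photobleach_decay": photobleach_decay,
            "noise_sd": noise_sd,
            "n_cells": n_cells,
        }
    )
    return traces, truth


def frap_traces_to_frame(traces: list[FrapTrace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        for i in range(len(tr.times)):
            rows.append(
                {
                    "frame": i,
                    "time_s": tr.times[i],
                    "roi_intensity": tr.roi[i],
                    "cell_intensity": tr.cell[i],
                    "cell_id": tr.cell_id,
                    "replicate_id": tr.replicate_id,
                }
            )
    return pd.DataFrame(rows)


_BASES = np.array(list("ACGT"))


def simulate_amplicon(
    locus_meth: float,
    n_cpgs: int = 10,
    n_unique_fragments: int = 500,
    pcr_duplication_rate: float = 0.5,
    polyg_rate: float = 0.02,
    seed: int = 0,
    amplicon_id: str = "amp1",
    read_len: int = 50,
) -> tuple[list[ReadPair], list[UmiFragment], SyntheticTruth]:
    """Generate amplicon read pairs with UMIs, duplicates and poly-G pairs.

    Each unique fragment gets independent 4-bp UMIs on both sides and
    per-CpG Bernoulli(locus_meth) calls (read 1 covers the first half
    of the CpGs, read 2 the rest). PCR duplicates copy a fragment's
    UMIs, key and calls. Poly-G artifact pairs (>= 90% G in read 2) are
    injected at ``polyg_rate`` of the total. Returns FASTQ-level pairs,
    aligned call-string fragments (duplicates included, poly-G pairs
    excluded — they would not align), and the truth.
    """
    if not (0.0 <= locus_meth <= 1.0):
        raise ValueError("locus methylation must be in [0,1]")
    if not (0.0 <= pcr_duplication_rate < 1.0):
        raise ValueError("duplication rate must be in [0,1)")
    rng = np.random.default_rng(seed)

    def _umi():
        return "".join(rng.choice(_BASES, size=4))

    def _seq(n):
        return "".join(rng.choice(_BASES, size=n))

    if n_unique_fragments > 256 * 256:
        raise ValueError("more unique fragments than 4-bp UMI pair combinations")
    fragments: list[UmiFragment] = []
    pairs: list[ReadPair] = []
    half = n_cpgs // 2
    qual = "I" * read_len
    used_umis: set[tuple[str, str]] = set()
    for i in range(n_unique_fragments):
        # distinct (umi1, umi2) per unique molecule so the planted unique
        # count is recoverable; 4-bp UMIs offer 65536 pair combinations
        umi1, umi2 = _umi(), _umi()
        while (umi1, umi2) in used_umis:
            umi1, umi2 = _umi(), _umi()
        used_umis.add((umi1, umi2))
        calls = rng.random(n_cpgs) < locus_meth
        calls1 = {j: ("Z" if calls[j] else "z") for j in range(half)}
        calls2 = {j: ("Z" if calls[j] else "z") for j in range(half, n_cpgs)}
        frag = UmiFragment(
            fragment_id=f"frag{i}",
            umi1=umi1,
            umi2=umi2,
            key=amplicon_id,
            calls1=calls1,
            calls2=calls2,
        )
        fragments.append(frag)
        pairs.append(
            ReadPair(
                pair_id=f"frag{i}",
                seq1=umi1 + _seq(read_len - 4),
                qual1=qual,
                seq2=umi2 + _seq(read_len - 4),
                qual2=qual,
            )
        )
    # PCR duplicates: each duplicate copies a uniformly chosen fragment
    n_dup = int(round(n_unique_fragments * pcr_duplication_rate / (1 - pcr_duplication_rate)))
    dup_sources = rng.integers(0, n_unique_fragments, size=n_dup)
    for d, src in enumerate(dup_sources):
        f = fragments[src]
        fragments.append(
            UmiFragment(
                fragment_id=f"dup{d}_{f.fragment_id}",
                umi1=f.umi1,
                umi2=f.umi2,
                key=f.key,
                calls1=dict(f.calls1),
                calls2=dict(f.calls2),
            )
        )
        p = pairs[src]
        pairs.append(
            ReadPair(
                pair_id=f"dup{d}_{p.pair_id}",
                seq1=p.seq1,
                qual1=p.qual1,
                seq2=p.seq2,
                qual2=p.qual2,
            )
        )
    # poly-G artifact pairs: read 2 is >= 90% G
    n_polyg = int(round(len(pairs) * polyg_rate))
    for g in range(n_polyg):
        n_non_g = max(0, int(read_len * 0.05))
        seq2 = "G" * (read_len - n_non_g) + _seq(n_non_g)
        pairs.append(
            ReadPair(
                pair_id=f"polyg{g}",
                seq1=_seq(read_len),
                qual1=qual,
                seq2=seq2,
                qual2=qual,
            )
        )
    order = rng.permutation(len(pairs))
    pairs = [pairs[i] for i in order]
    truth = SyntheticTruth(
        {
            "kind": "amplicon",
            "seed": seed,
            "locus_meth": locus_meth,
            "n_cpgs": n_cpgs,
            "n_unique_fragments": n_unique_fragments,
            "n_duplicates": n_dup,
            "n_polyg_pairs": n_polyg,
            "true_fragment_means": [
                sum(1 for c in list(f.calls1.values()) + list(f.calls2.values()) if c == "Z")
                / n_cpgs
                for f in fragments[:n_unique_fragments]
            ],
        }
    )
    return pairs, fragments, truth
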