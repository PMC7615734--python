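# Methods

This note documents the models, conventions and numerical choices
behind `hdm`, the way they would appear in a methods section, together
with what the synthetic-data generators do and do not emulate.

## Coordinates and interval arithmetic

All internal coordinates are 0-based half-open (BED convention); the
Bismark-coverage reader converts from 1-based input. Window grids tile
each chromosome without gaps; the trailing window may be shorter than
the nominal size and is retained — downstream coverage thresholds, not
the grid, decide what is analyzable. Overlap of ≥ 1 bp is sufficient
for a window to be excluded by a blacklist/gap interval and for a
fragment to be counted in a window (no fractional assignment).
Exclusion regions (assembly gaps, centromeres) are pooled by merging
intervals separated by ≤ 10 Mb, the convention for building a single
pericentromeric mask; merging is idempotent. Chromosome names are
matched by exact string equality; a validation helper warns about
names present in only one input rather than guessing at "chr"-prefix
harmonization.

## Windowed methylation

Region methylation is the coverage-weighted mean
`100 · Σ meth / Σ total` over CpGs whose position lies inside the
region (half-open containment, so a CpG on a window boundary belongs
to exactly one window). Windows below a coverage floor are **masked,
encoded as absent** — never as 0 %, which is data. Defaults: floor 10
for 2.5-kb analysis windows, 5 for exported bedGraph tracks, 0 for
domain-level means (no floor is stated for domains in the source
analyses; it is configurable). Differential tracks are simple
percentage-point differences with mask union. Bisulfite conversion
efficiency is `100 − 100 · Σ meth/Σ total` on the unmethylated
phage-λ spike-in contig, gated strictly at > 99.5 %.

## ChIP normalization and spike-in scaling

Per-window values are

    v_w = s · [(c_w + 0.5) · 10⁷ / N_chip] / [(i_w + 0.5) · 10⁷ / N_input]

The 0.5 offset guarantees strictly positive, finite output even at
zero input counts. Windows with zero raw counts in *every* sample of
the comparison set are dropped (evaluated on raw counts, before
normalization). The spike-in (ChIP-Rx) factor between conditions uses
exogenous-chromatin read proportions scaled per 10⁷ total mapped
reads; the denominator choice (total mapped = target + spike) is
configurable metadata. Which sample the factor applies to is a
convention: we designate a reference (factor 1) and scale all others
toward it, recording the factor in track metadata. Because the factor
is multiplicative, applying it before or after input normalization
yields the same value; we apply it after. The factor composes exactly
across sample chains, s(a→c) = s(a→b)·s(b→c).

## Domain segmentation

Normalized mean ChIP signal in 25-kb bins is segmented by a two-state
hidden Markov model with Gaussian emissions, fitted by Baum–Welch over
per-chromosome observation sequences (masked bins split sequences).
Initialization is deterministic — state means at the 25th/75th signal
percentiles, shared variance, sticky transitions (0.9 diagonal) — so
the seed matters only for degenerate inputs. Convergence is declared
at log-likelihood change < 10⁻⁴ or 500 iterations. One shared model is
fitted across chromosomes. The *enriched* state is the one with the
higher mean; maximal Viterbi runs of it become bin-aligned domains,
from which the merged exclusion mask is subtracted (all nonempty
remnants are kept). Input-normalized ratio tracks are heavy-tailed, so
the pipeline fits the HMM to log-transformed values (`log_transform`
flag); raw-scale emissions remain the default for already-symmetric
signals. The emission model of the original two-state approach is not
fully specified in the source analyses; Gaussian emissions are our
recorded assumption.

H3K27me3-only domains are H3K27me3 intervals with **zero overlap** to
any H3K9me3 interval — interval-level removal (1 bp of overlap
disqualifies the whole interval), the stricter reading of "did not
overlap". "Other" domains are the complement of the union of both
marks within the analyzable genome.

Domain sets are compared by bp-level Jaccard (undefined for two empty
sets) and an interval-count Fisher exact test whose fourth cell is the
genome-capacity approximation

    n22 = max(0, ⌊G / (L̄_a + L̄_b)⌋ − n11 − n12 − n21)

with G the analyzable genome length and L̄ the mean interval lengths.
This follows the approximation used by the standard interval Fisher
tool; it is an approximation, and the exact contingency table tested
is returned for audit.

## Metaprofiles and deciles

Each feature is rescaled to 40 body bins (remainder bp distributed one
per leading, i.e. 5′-most, bin) with 20 fixed-size flank bins on each
side (25 kb for domains, 250 bp for transcripts), oriented by strand
so columns always run 5′→3′. Flank bins off a chromosome end are
missing, not zero. A feature is dropped when ≥ 80 % of its body bins
have zero raw coverage in all samples of the analysis set, or when it
is shorter than the body bin count. Heatmap matrices are ordered by a
per-feature rank signal (descending) with display bounds from the
matrix minimum to the 90 % quantile of all values. Decile summaries
sort windows by (ranking value, window index) — a deterministic tie
break — and split them into contiguous groups of ⌈n/10⌉ or ⌊n/10⌋
(larger groups first). Transcript-model construction (choice of coding
transcripts, per-gene averaging) is the caller's responsibility; the
profile machinery takes one representative interval set.

## Statistics

Pearson correlations drop window pairs masked in either signal and
require ≥ 3 complete pairs and nonzero variance. Wilcoxon rank-sum
comparisons use midranks for ties, the exact null distribution for
min(n) ≤ 25 on tie-free data, and the tie/continuity-corrected normal
approximation otherwise. Gene-set enrichment is a two-sided Fisher
exact test on {DE, not-DE} × {in-domain, not}; gene→domain membership
uses ≥ 1 bp transcript overlap. Raw p-values are reported — each
analysis poses a single planned test — and p-values below 10⁻³⁰⁰ are
floored there. The exact Fisher test is conservative on small discrete
tables; its null rejection rate approaches nominal only when the table
margins are large, which is how the calibration checks are configured.

## FRAP

Traces carry 5 pre-bleach frames and post-bleach frames at 2-s
spacing; t = 0 is the first post-bleach frame (the source convention
leaves the origin undefined; pre-bleach frames carry negative times).
Two normalizations: photobleach correction against the whole-cell
signal anchored to the pre-bleach level,
`I_N(t) = [I_B(t)/I_C(t)] / [mean_pre(I_B)/mean_pre(I_C)]`, then a
shift placing the post-bleach minimum at 0 while keeping 1 fixed,
`I_N2 = (I_N − I_N_min)/(1 − I_N_min)`. The minimum is taken over
post-bleach frames only, so noisy pre-bleach frames cannot corrupt the
shift. The immobile fraction is `1 − mean(I_N2)` over the tail.
"The last 50 values, i.e. t = 100–150 s" is internally inconsistent at
2-s spacing (that window holds 26 frames); we follow the explicit time
window [100, 150] s by default and provide a last-k-frames mode. On
noise-free traces the estimator's bias is (1 − IF)·e^(−k·t_mid),
negligible once the tail sits ≥ 3 recovery half-lives after the
bleach. Replicates aggregate as the unweighted mean of replicate
means, with uncorrelated error propagation √(Σ SDᵢ²)/k, applied
identically per timepoint for mean recovery curves. Image
registration is upstream; traces are assumed motion-corrected.

## Amplicon calling

Pairs where either read is ≥ 90 % guanine are removed (inclusive
threshold — one-color chemistry emits *high-confidence* poly-G reads
when signal is absent). UMIs are the first 4 bases of each read (one
per side of the amplicon). Deduplication is the *unique* method:
exact identity of (UMI₁, UMI₂, alignment key), no error-correction or
clustering, first fragment in input order kept. Per fragment, calls
from the two reads merge by CpG position (a CpG covered by both reads
counts once; on conflict read 1 wins and the conflict is logged),
giving n_r called CpGs and m_r methylated calls. The locus aggregate
is the unweighted mean of fragment means m_r/n_r (fragments with
n_r = 0 excluded); a call-weighted mode (Σm_r/Σn_r) is available.
Bisulfite alignment is out of scope: the caller takes raw FASTQ
through filtering/UMI extraction, and aligned per-read call strings
for the downstream stages.

## Synthetic data: what it emulates, what it does not

The default toy genome is 2 chromosomes × 10 Mb with a CpG every
~100 bp, six H3K9me3 domains of 200 kb–1 Mb and four H3K27me3 domains,
two of which partially overlap H3K9me3 — large enough for 25-kb HMM
bins and multi-window domains, small enough for seconds-scale runs.
Domain placements are 25-kb-aligned so planted truth is commensurate
with the segmentation grid.

- **WGBS**: CpG positions from a homogeneous point process, shared
  across samples; coverage ~ Poisson(20); methylated counts ~
  Binomial with region-level probabilities from Beta distributions
  (concentration 100) whose means depend on domain class — WT-like
  (0.85, 0.85, 0.80) for (background, H3K9me3, H3K27me3-only) and
  KO-like (0.82, 0.55, 0.70), i.e. the knockout loses most methylation
  in constitutive heterochromatin, some in facultative, little
  elsewhere.
- **ChIP**: Negative Binomial window counts (dispersion 0.2, a
  plausible ChIP overdispersion; the source analyses state none) with
  mean = background (50) × fold (4 inside the mark's domains); inputs
  from background only. Spike-in read totals are constructed exactly
  from the stated exogenous fractions at a nominal 10⁷-read depth, so
  planted scaling factors are recovered exactly. A global occupancy
  shift is planted through the spike fractions alone, because
  per-sample depth normalization genuinely erases it — that is the
  phenomenon spike-in normalization exists to catch.
- **FRAP**: recovery (1−IF)(1−e^(−kt)) embedded in raw intensities
  with a configurable bleach depth (0.6) and whole-cell photobleaching
  decay, plus relative Gaussian noise. The raw-trace construction is
  invented so the first normalization has real work to do; the source
  analyses define only the correction, not a generative model.
- **Amplicon**: unique fragments carry *distinct* (UMI₁, UMI₂) pairs
  (4-bp UMIs offer only 65,536 pair combinations, so unconstrained
  draws would collide at ~2 per 500 fragments and make the planted
  unique count unrecoverable); duplicates copy UMIs and calls; poly-G
  pairs are injected at a set rate.

Not emulated: genomic sequence content and mappability structure,
non-CpG methylation, fragment-length and GC biases, UMI sequencing
errors (real pipelines see them; the unique method deliberately does
not correct them), cell movement in FRAP, and read alignment anywhere.
Passing tests therefore demonstrate correctness of the quantification
and inference machinery under the assumed statistical model, not
robustness to alignment artifacts or sequence-dependent biases.

## Problem sizes and determinism

All generators are pure functions of (parameters, seed). The test
suite and the acceptance script run the full pipeline on the default
toy genome (8,000 × 2.5-kb windows, 800 × 25-kb bins, ~200,000 CpGs
per sample), 10-cell FRAP experiments and 500-fragment amplicon
libraries — sizes at which every stage completes in seconds while
Monte-Carlo recovery bounds (e.g. planted immobile fraction within
±0.03, fold enrichment within 10 %) are comfortably attainable.

## Known limitations

- The two-state HMM assumes one shared emission model genome-wide;
  per-chromosome fitting is available by flag but untested against a
  planted per-chromosome heterogeneity scenario.
- The interval Fisher n22 term is a capacity approximation; treat its
  p-values as the standard tool would — useful for ranking, not as
  exact probabilities.
- Domain-level methylation applies no coverage floor by default; for
  very sparse data callers should set one.
- With few H3K27me3-only domains (the default toy genome yields two),
  rank-sum comparisons against that class are underpowered; the
  pipeline reports the p-value it gets rather than resizing the
  genome.
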