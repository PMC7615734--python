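"""Two-state HMM segmentation of binned ChIP signal into domains.

Broad heterochromatin domains (H3K9me3, H3K27me3) are called by
fitting a two-state Gaussian-emission hidden Markov model to normalized
ChIP signal in 25-kb bins, decoding with Viterbi, and taking maximal
runs of the enriched (higher-mean) state as domain intervals. Assembly
gaps and centromeres, pre-merged at 10 Mb, are subtracted from the
called intervals. Facultative-only (H3K27me3-only) domains are the
H3K27me3 intervals with no overlap to any H3K9me3 interval — removal
is interval-level: a single bp of overlap disqualifies the whole
interval.

Domain sets are compared with a bp-level Jaccard index and an
interval-count Fisher exact test whose fourth cell estimates the
genome's capacity for further non-overlapping interval pairs,
n22 = max(0, floor(G / (Lbar_a + Lbar_b)) - n11 - n12 - n21) — an
approximation, so the exact contingency table is returned for audit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM
from scipy import stats as sps

from hdm.genome import (
    ChromSizes,
    IntervalSet,
    WindowGrid,
    intersect,
    merge_exclusion_regions,
    subtract,
)

__all__ = [
    "BinnedSignal",
    "HmmModel",
    "DomainSet",
    "OverlapStats",
    "fit_hmm",
    "call_domains",
    "derive_k27_only",
    "derive_other_domains",
    "jaccard",
    "interval_fisher",
]

HMM_TOL = 1e-4
HMM_MAX_ITER = 500


@dataclass
class BinnedSignal:
    """Per-bin signal on a (typically 25-kb) window grid with a missing mask."""

    grid: WindowGrid
    values: np.ndarray
    mask: np.ndarray | None = None  # True = missing

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.grid.n_windows:
            raise ValueError("values length does not match grid")
        if self.mask is None:
            self.mask = np.isnan(self.values)
        self.mask = np.asarray(self.mask, dtype=bool) | np.isnan(self.values)
        if not np.isfinite(self.values[~self.mask]).all():
            raise ValueError("non-finite values outside mask")

    @classmethod
    def from_track(cls, track) -> "BinnedSignal":
        """Wrap a NormalizedChipTrack (dropped windows become missing bins)."""
        return cls(track.grid, track.values)

    def segments(self):
        """Contiguous unmasked runs, split at chromosome boundaries.

        Yields (chrom, first_bin_local_index, values) where the local
        index is the bin number within the chromosome.
        """
        df = self.grid.windows_df()
        for chrom in self.grid.chrom_sizes:
            ids = df.loc[df["chrom"] == chrom, "window_id"].to_numpy()
            vals = self.values[ids]
            miss = self.mask[ids]
            start = None
            for i in range(len(ids) + 1):
                if i < len(ids) and not miss[i]:
                    if start is None:
                        start = i
                else:
                    if start is not None:
                        yield chrom, start, vals[start:i]
                        start = None


@dataclass
class HmmModel:
    """Fitted two-state Gaussian HMM; state order is (background, enriched)."""

    means: np.ndarray  # ascending: means[1] is the enriched state
    variances: np.ndarray
    transmat: np.ndarray
    startprob: np.ndarray
    converged: bool
    n_iter: int
    log_transform: bool = False

    @property
    def enriched_state(self) -> int:
        return 1

    def _hmm(self) -> GaussianHMM:
        m = GaussianHMM(n_components=len(self.means), covariance_type="diag")
        m.means_ = self.means.reshape(-1, 1)
        m.covars_ = self.variances.reshape(-1, 1)
        m.transmat_ = self.transmat
        m.startprob_ = self.startprob
        m.n_features = 1
        return m

    def decode(self, values: np.ndarray) -> np.ndarray:
        x = np.log(values) if self.log_transform else values
        _, path = self._hmm().decode(x.reshape(-1, 1), algorithm="viterbi")
        return path

    def path_log_prob(self, values: np.ndarray, path: np.ndarray) -> float:
        """Joint log-probability of a state path and the observations."""
        x = np.log(values) if self.log_transform else values
        lp = np.log(self.startprob[path[0]])
        lp += sps.norm.logpdf(
            x, loc=self.means[path], scale=np.sqrt(self.variances[path])
        ).sum()
        lp += np.log(self.transmat[path[:-1], path[1:]]).sum()
        return float(lp)

    def to_dict(self) -> dict:
        return {
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "transmat": self.transmat.tolist(),
            "startprob": self.startprob.tolist(),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "log_transform": self.log_transform,
        }


@dataclass
class DomainSet:
    """Labelled non-overlapping genomic intervals.

    Labels: "H3K9me3", "H3K27me3-only", "other" (or any mark name for
    raw called sets). Intervals within a label are sorted and
    non-overlapping.
    """

    df: pd.DataFrame  # chrom, start, end, label

    def __post_init__(self):
        self.df = self.df.sort_values(["chrom", "start"], kind="stable").reset_index(
            drop=True
        )

    def intervals(self, label: str | None = None) -> IntervalSet:
        df = self.df if label is None else self.df[self.df["label"] == label]
        if df.empty:
            return IntervalSet.empty()
        return IntervalSet(df[["chrom", "start", "end"]].copy())

    def labels(self) -> list[str]:
        return list(dict.fromkeys(self.df["label"]))

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class OverlapStats:
    jaccard: float
    p_value: float
    odds_ratio: float
    contingency: np.ndarray  # the 2x2 table actually tested


def fit_hmm(
    signal: BinnedSignal,
    n_states: int = 2,
    seed: int = 0,
    log_transform: bool = False,
) -> HmmModel:
    """Baum-Welch fit of a Gaussian-emission HMM to binned signal.

    Masked bins split the observation sequences (one or more per
    chromosome). Initialization is deterministic: state means at the
    25th/75th percentiles of the signal (evenly spaced percentiles for
    n_states > 2), shared variance, sticky transitions. The seed only
    matters for degenerate data. Convergence: log-likelihood change
    < 1e-4 or 500 iterations.
    """
    seqs = [vals for _, _, vals in signal.segments()]
    if not seqs:
        raise ValueError("no unmasked bins")
    x = np.concatenate(seqs)
    if len(x) < 10 * n_states:
        raise ValueError(f"need >= {10 * n_states} unmasked bins, got {len(x)}")
    if log_transform:
        if (x <= 0).any():
            raise ValueError("log transform requires strictly positive signal")
        x = np.log(x)
        seqs = [np.log(s) for s in seqs]

    qs = np.linspace(25, 75, n_states)
    init_means = np.percentile(x, qs)
    var = max(float(np.var(x)), 1e-12)
    if np.ptp(init_means) < 1e-12:
        warnings.warn("signal is (near-)constant; HMM fit is degenerate")
        init_means = init_means + np.linspace(-1e-6, 1e-6, n_states)

    model = GaussianHMM(
        n_components=n_states,
        covariance_type="diag",
        n_iter=HMM_MAX_ITER,
        tol=HMM_TOL,
        init_params="",
        params="stmc",
        random_state=seed,
    )
    model.means_ = init_means.reshape(-1, 1)
    model.covars_ = np.full((n_states, 1), var)
    model.startprob_ = np.full(n_states, 1.0 / n_states)
    model.transmat_ = np.full((n_states, n_states), 0.1 / max(n_states - 1, 1))
    np.fill_diagonal(model.transmat_, 0.9)

    lengths = [len(s) for s in seqs]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(x.reshape(-1, 1), lengths)

    order = np.argsort(model.means_.ravel())
    means = model.means_.ravel()[order]
    variances = model.covars_.ravel()[order]
    transmat = model.transmat_[np.ix_(order, order)]
    startprob = model.startprob_[order]
    converged = bool(model.monitor_.converged)
    n_iter = int(model.monitor_.iter)
    if abs(means[1] - means[0]) < 1e-9 * max(1.0, abs(means[0])):
        warnings.warn("degenerate fit: state means are equal within tolerance")
    return HmmModel(means, variances, transmat, startprob, converged, n_iter, log_transform)


def call_domains(
    signal: BinnedSignal,
    model: HmmModel,
    exclusions: IntervalSet | None = None,
    label: str = "domain",
) -> DomainSet:
    """Viterbi-decode the signal and return enriched-state intervals.

    Maximal runs of the enriched state become bin-aligned intervals;
    exclusion regions (pre-merged, e.g. gaps+centromeres at 10 Mb) are
    subtracted and empty remnants dropped.
    """
    w = signal.grid.window_size
    rows = []
    for chrom, first_bin, vals in signal.segments():
        path = model.decode(vals)
        enriched = path == model.enriched_state
        i = 0
        while i < len(enriched):
            if enriched[i]:
                j = i
                while j + 1 < len(enriched) and enriched[j + 1]:
                    j += 1
                start = (first_bin + i) * w
                end = min((first_bin + j + 1) * w, signal.grid.chrom_sizes[chrom])
                rows.append((chrom, start, end))
                i = j + 1
            else:
                i += 1
    if not rows:
        return DomainSet(pd.DataFrame(columns=["chrom", "start", "end", "label"]))
    ivs = IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))
    if exclusions is not None and len(exclusions):
        ivs = subtract(ivs, exclusions)
    df = ivs.df[["chrom", "start", "end"]].copy()
    df["label"] = label
    return DomainSet(df)


def _interval_overlap_flags(a: IntervalSet, b: IntervalSet) -> np.ndarray:
    """For each interval of a: does it overlap any interval of b (>=1 bp)?"""
    if not b.non_overlapping:
        b = merge_exclusion_regions([b], 0)
    flags = np.zeros(len(a), dtype=bool)
    for k, row in enumerate(a.df.itertuples(index=False)):
        bs, be = b.arrays(row.chrom)
        i = np.searchsorted(be, row.start, side="right")
        flags[k] = i < len(bs) and bs[i] < row.end
    return flags


def derive_k27_only(k27: DomainSet | IntervalSet, k9: DomainSet | IntervalSet) -> DomainSet:
    """H3K27me3 intervals with zero overlap to any H3K9me3 interval.

    Interval-level exclusion: any bp of overlap removes the whole
    H3K27me3 interval.
    """
    k27_iv = k27.intervals() if isinstance(k27, DomainSet) else k27
    k9_iv = k9.intervals() if isinstance(k9, DomainSet) else k9
    if len(k27_iv) == 0:
        return DomainSet(pd.DataFrame(columns=["chrom", "start", "end", "label"]))
    keep = ~_interval_overlap_flags(k27_iv, k9_iv)
    df = k27_iv.df.loc[keep, ["chrom", "start", "end"]].copy()
    df["label"] = "H3K27me3-only"
    return DomainSet(df)


def derive_other_domains(
    k9: DomainSet | IntervalSet,
    k27: DomainSet | IntervalSet,
    chrom_sizes: ChromSizes,
    exclusions: IntervalSet | None = None,
) -> DomainSet:
    """Complement of (K9 union K27) within the analyzable genome."""
    k9_iv = k9.intervals() if isinstance(k9, DomainSet) else k9
    k27_iv = k27.intervals() if isinstance(k27, DomainSet) else k27
    genome = IntervalSet.from_tuples(
        [(name, 0, length) for name, length in chrom_sizes.items()]
    )
    if exclusions is not None and len(exclusions):
        genome = subtract(genome, exclusions)
    marked = merge_exclusion_regions([k9_iv, k27_iv], 0)
    other = subtract(genome, marked)
    df = other.df[["chrom", "start", "end"]].copy()
    df["label"] = "other"
    return DomainSet(df)


def jaccard(a: IntervalSet, b: IntervalSet) -> float:
    """Bp-level Jaccard index: |intersection| / |union|."""
    if len(a) == 0 and len(b) == 0:
        raise ValueError("Jaccard undefined for two empty sets")
    inter = intersect(a, b).total_bp
    union = merge_exclusion_regions([a, b], 0).total_bp
    return inter / union


def interval_fisher(
    a: IntervalSet, b: IntervalSet, chrom_sizes: ChromSizes
) -> OverlapStats:
    """Interval-count Fisher exact test of overlap between two domain sets.

    Contingency: n11 = a-intervals overlapping b; n12 = a-intervals not
    overlapping b; n21 = b-intervals not overlapping a; n22 estimates
    the remaining capacity of the genome for interval pairs,
    max(0, floor(G / (mean_len_a + mean_len_b)) - n11 - n12 - n21).
    The capacity estimate is an approximation; the table actually
    tested is returned for audit. Two-sided exact p.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("Fisher overlap test requires nonempty sets")
    a_flags = _interval_overlap_flags(a, b)
    b_flags = _interval_overlap_flags(b, a)
    n11 = int(a_flags.sum())
    n12 = len(a) - n11
    n21 = int((~b_flags).sum())
    mean_a = float((a.df["end"] - a.df["start"]).mean())
    mean_b = float((b.df["end"] - b.df["start"]).mean())
    g = chrom_sizes.total_length
    n22 = max(0, int(g // (mean_a + mean_b)) - n11 - n12 - n21)
    table = np.array([[n11, n12], [n21, n22]])
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    jac = jaccard(a, b)
    return OverlapStats(jaccard=jac, p_value=float(p), odds_ratio=float(odds), contingency=table)
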