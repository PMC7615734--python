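"""Recurring statistics: windowed Pearson correlations, two-sided
Wilcoxon rank-sum comparisons between domain classes, and Fisher
enrichment of gene sets in domains.

Raw p-values are reported without multiple-testing correction (each
analysis poses a single planned test); p-values below 1e-300 are
floored at that value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "GroupComparison",
    "OverlapStats2x2",
    "pearson_windows",
    "wilcoxon_domains",
    "gene_set_enrichment",
    "genes_in_domains",
]

P_FLOOR = 1e-300
EXACT_WILCOXON_MAX_N = 25


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass
class GroupComparison:
    labels: tuple[str, str]
    statistic: float
    p: float
    n: tuple[int, int]
    exact: bool


@dataclass
class OverlapStats2x2:
    odds_ratio: float
    p: float
    table: np.ndarray


def _floor_p(p: float) -> float:
    return max(float(p), P_FLOOR)


def pearson_windows(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Pearson correlation between two per-window signals.

    Windows masked (NaN) in either signal are dropped; needs >= 3
    complete pairs and nonzero variance in both. Two-sided p from the
    t distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("signals must align")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=_floor_p(res.pvalue), n=n)


def wilcoxon_domains(
    a: np.ndarray,
    b: np.ndarray,
    labels: tuple[str, str] = ("a", "b"),
    alternative: str = "two-sided",
) -> GroupComparison:
    """Wilcoxon rank-sum (Mann-Whitney U) comparison of two groups.

    Midranks handle ties. The exact null distribution is used for
    min(n_a, n_b) <= 25 on tie-free data, otherwise the normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (min(len(a), len(b)) <= EXACT_WILCOXON_MAX_N) and not has_ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    return GroupComparison(
        labels=labels,
        statistic=float(res.statistic),
        p=_floor_p(res.pvalue),
        n=(len(a), len(b)),
        exact=exact,
    )


def gene_set_enrichment(
    de_genes: set, universe: set, domain_genes: set
) -> OverlapStats2x2:
    """Fisher exact enrichment of a gene set within domain-overlapping genes.

    2x2 table {DE, not-DE} x {in-domain, not-in-domain} over the tested
    universe; two-sided exact p and odds ratio.
    """
    de_genes, universe, domain_genes = set(de_genes), set(universe), set(domain_genes)
    if not universe:
        raise ValueError("empty universe")
    if not de_genes:
        raise ValueError("empty DE gene set; no test")
    if not de_genes <= universe or not domain_genes <= universe:
        raise ValueError("gene sets must be subsets of the universe")
    n11 = len(de_genes & domain_genes)
    n12 = len(de_genes) - n11
    n21 = len(domain_genes) - n11
    n22 = len(universe) - n11 - n12 - n21
    table = np.array([[n11, n12], [n21, n22]])
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return OverlapStats2x2(odds_ratio=float(odds), p=_floor_p(p), table=table)


def genes_in_domains(transcripts, domains) -> set:
    """Gene ids whose transcript interval overlaps a domain by >= 1 bp.

    ``transcripts`` is an IntervalSet with a ``name`` column carrying
    the gene id; ``domains`` an IntervalSet.
    """
    from hdm.domains import _interval_overlap_flags

    flags = _interval_overlap_flags(transcripts, domains)
    if "name" not in transcripts.df.columns:
        raise ValueError("transcripts need a name column with gene ids")
    return set(transcripts.df.loc[flags, "name"])
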