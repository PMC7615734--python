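"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by enumeration or direct summation,
deliberately avoiding the code paths under test.
"""

import itertools
import math

import numpy as np


def fisher_exact_enumeration(table):
    """Two-sided Fisher exact p and odds ratio by hypergeometric sum.

    Enumerates all tables with the observed margins and sums the
    probabilities of tables at most as probable as the observed one.
    """
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_hyper(x):
        # P(X = x) for X ~ Hypergeom(n, r1, c1)
        return (
            math.lgamma(r1 + 1)
            - math.lgamma(x + 1)
            - math.lgamma(r1 - x + 1)
            + math.lgamma(r2 + 1)
            - math.lgamma(c1 - x + 1)
            - math.lgamma(r2 - c1 + x + 1)
            - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1))
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = log_hyper(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = log_hyper(x)
        if lp <= p_obs + 1e-9:
            total += math.exp(lp)
    odds = (a * d) / (b * c) if b * c > 0 else math.inf
    return min(total, 1.0), odds


def wilcoxon_exact_enumeration(a, b):
    """Two-sided rank-sum p by full enumeration of group labelings.

    Tie-free data only. The statistic is the rank sum of group a; the
    p-value is the fraction of labelings whose rank sum is at least as
    extreme (two-sided by distance from the mean rank sum).
    """
    pooled = sorted(a) + sorted(b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n_a = len(a)
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    obs = sum(ranks[v] for v in a)
    mean_rs = n_a * (len(pooled) + 1) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        rs = sum(i + 1 for i in combo)
        total += 1
        if abs(rs - mean_rs) >= abs(obs - mean_rs) - 1e-9:
            count += 1
    return count / total


def region_meth_bruteforce(calls_df, regions_df):
    """Per-region (meth_sum, cov_sum) by per-CpG scanning."""
    out = []
    for r in regions_df.itertuples(index=False):
        meth = cov = 0
        for c in calls_df.itertuples(index=False):
            if c.chrom == r.chrom and r.start <= c.pos < r.end:
                meth += c.meth_count
                cov += c.total_count
        out.append((meth, cov))
    return out


def overlap_count_bruteforce(fragments_df, windows_df):
    """Per-window fragment overlap count by pairwise checking."""
    counts = np.zeros(len(windows_df), dtype=int)
    for f in fragments_df.itertuples(index=False):
        for i, w in enumerate(windows_df.itertuples(index=False)):
            if f.chrom == w.chrom and f.start < w.end and w.start < f.end:
                counts[i] += 1
    return counts


def pearson_bruteforce(x, y):
    """Product-moment correlation from the covariance definition."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    cov = ((x - mx) * (y - my)).sum()
    return cov / math.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())


def binomial_interval(p, n_trials, n_fragments, level=0.99):
    """Central interval for the mean of n_fragments binomial fractions."""
    from scipy import stats

    sd = math.sqrt(p * (1 - p) / n_trials / n_fragments)
    z = stats.norm.ppf(0.5 + level / 2)
    return p - z * sd, p + z * sd
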