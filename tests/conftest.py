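import numpy as np
import pandas as pd
import pytest

from hdm.genome import ChromSizes, IntervalSet, make_windows
from hdm.methylation import CpGCallTable


@pytest.fixture
def toy_sizes():
    return ChromSizes({"c1": 10_000, "c2": 6_000})


@pytest.fixture
def toy_grid(toy_sizes):
    return make_windows(toy_sizes, 2_500)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_917)


def random_interval_set(rng, n, chrom_len=1_000, chroms=("c1", "c2")):
    rows = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, chrom_len - 1))
        end = int(rng.integers(start + 1, chrom_len + 1))
        rows.append((chrom, start, end))
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def bp_mask(iv_set, chrom, length):
    """Brute-force bp occupancy mask for one chromosome."""
    mask = np.zeros(length, dtype=bool)
    for row in iv_set.df.itertuples(index=False):
        if row.chrom == chrom:
            mask[row.start : row.end] = True
    return mask


def random_call_table(rng, chrom_sizes, n, max_cov=30):
    rows = []
    for chrom, length in chrom_sizes.items():
        k = n // len(chrom_sizes)
        pos = np.sort(rng.choice(length, size=min(k, length), replace=False))
        total = rng.integers(0, max_cov + 1, size=len(pos))
        meth = rng.binomial(total, 0.7)
        keep = total > 0
        for p, m, t in zip(pos[keep], meth[keep], total[keep]):
            rows.append((chrom, int(p), int(m), int(t)))
    return CpGCallTable(
        pd.DataFrame(rows, columns=["chrom", "pos", "meth_count", "total_count"])
    )
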