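"""Scaled metaprofiles over domains and transcripts, and decile summaries.

Each feature is rescaled to a fixed number of body bins (default 40)
flanked by fixed-size bins (default 20 each side; 25 kb for domains,
250 bp for transcripts), oriented 5'->3' so minus-strand features are
reversed. Features are dropped when >= 80% of their body bins have
zero raw coverage in every sample of the analysis set. Heatmap display
bounds run from the matrix minimum to the 90% quantile of the values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from hdm.genome import ChromSizes, IntervalSet

__all__ = [
    "MetaProfileMatrix",
    "DecileSummary",
    "CpGSignal",
    "TrackSignal",
    "scaled_profile",
    "order_and_cap",
    "decile_summary",
]

N_BODY = 40
N_FLANK = 20
ZERO_COVERAGE_DROP_FRACTION = 0.80
CAP_QUANTILE = 0.90


class CpGSignal:
    """Per-CpG methylation calls as a metaprofile signal source.

    Bin value is the coverage-weighted methylation percent over CpGs in
    the bin; bin coverage is the summed total read count.
    """

    def __init__(self, calls):
        self.calls = calls
        self._by_chrom = {
            chrom: (
                g["pos"].to_numpy(dtype=np.int64),
                g["meth_count"].to_numpy(dtype=np.int64),
                g["total_count"].to_numpy(dtype=np.int64),
            )
            for chrom, g in calls.df.groupby("chrom", sort=False)
        }

    def _range(self, chrom, start, end):
        if chrom not in self._by_chrom:
            return None
        pos, meth, total = self._by_chrom[chrom]
        i = np.searchsorted(pos, start, side="left")
        j = np.searchsorted(pos, end, side="left")
        return meth[i:j].sum(), total[i:j].sum()

    def bin_value(self, chrom, start, end):
        r = self._range(chrom, start, end)
        if r is None or r[1] == 0:
            return np.nan
        return 100.0 * r[0] / r[1]

    def bin_coverage(self, chrom, start, end):
        r = self._range(chrom, start, end)
        return 0 if r is None else int(r[1])


class TrackSignal:
    """Normalized per-window ChIP track as a metaprofile signal source.

    Bin value is the overlap-weighted mean of window values (dropped
    windows excluded); bin coverage is the overlap-weighted sum of raw
    window counts when counts are supplied, else the number of
    contributing windows.
    """

    def __init__(self, track, counts=None):
        self.track = track
        self.counts = counts

    def _overlaps(self, chrom, start, end):
        grid = self.track.grid
        if chrom not in grid.chrom_sizes:
            return None
        ids = grid.overlapping_ids(chrom, start, end)
        if len(ids) == 0:
            return None
        w = grid.window_size
        length = grid.chrom_sizes[chrom]
        first_id = grid.locate(chrom, 0)
        ws = (ids - first_id) * w
        we = np.minimum(ws + w, length)
        ov = np.minimum(we, end) - np.maximum(ws, start)
        return ids, ov

    def bin_value(self, chrom, start, end):
        r = self._overlaps(chrom, start, end)
        if r is None:
            return np.nan
        ids, ov = r
        vals = self.track.values[ids]
        ok = ~np.isnan(vals)
        if not ok.any():
            return np.nan
        return float(np.average(vals[ok], weights=ov[ok]))

    def bin_coverage(self, chrom, start, end):
        r = self._overlaps(chrom, start, end)
        if r is None:
            return 0
        ids, ov = r
        if self.counts is None:
            return int(len(ids))
        w = self.track.grid.window_size
        return float((self.counts.counts[ids] * ov / w).sum())


@dataclass
class MetaProfileMatrix:
    """features x (n_flank + n_body + n_flank) bins of signal.

    Columns run 5'->3': distal upstream, body (scaled), distal
    downstream. Missing values (e.g. flank bins off a chromosome end)
    are NaN. ``feature_ids`` indexes rows.
    """

    values: np.ndarray
    feature_ids: list
    n_body: int = N_BODY
    n_flank: int = N_FLANK
    flank_bin: int = 25_000

    @property
    def n_columns(self) -> int:
        return 2 * self.n_flank + self.n_body

    def body(self) -> np.ndarray:
        return self.values[:, self.n_flank : self.n_flank + self.n_body]

    def flanks(self) -> np.ndarray:
        return np.concatenate(
            [self.values[:, : self.n_flank], self.values[:, self.n_flank + self.n_body :]],
            axis=1,
        )

    def mean_profile(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.values, axis=0)

    def to_frame(self) -> pd.DataFrame:
        cols = (
            [f"up{k}" for k in range(self.n_flank)]
            + [f"body{k}" for k in range(self.n_body)]
            + [f"down{k}" for k in range(self.n_flank)]
        )
        return pd.DataFrame(self.values, index=self.feature_ids, columns=cols)


@dataclass
class DecileSummary:
    """Windows ranked and split into (near-)equal groups; response summarized."""

    groups: list[np.ndarray]  # window indices per group, ascending rank
    summary: pd.DataFrame  # per group: n, mean, q25, median, q75


def _feature_bins(chrom, start, end, strand, n_body, n_flank, flank_bin):
    """Column-ordered (start, end) genomic spans for one feature.

    Body is split into n_body bins; remainder bp go one each to the
    leading (5'-most) bins. Flank bins tile outward from the feature
    edges. Minus-strand features produce columns in reversed genomic
    order so column order follows transcription.
    """
    length = end - start
    base = length // n_body
    rem = length % n_body
    sizes = np.full(n_body, base, dtype=np.int64)
    sizes[:rem] += 1
    bins = []
    if strand == "-":
        edges = end - np.concatenate([[0], np.cumsum(sizes)])
        body = [(int(edges[i + 1]), int(edges[i])) for i in range(n_body)]
        up = [
            (end + (n_flank - k - 1) * flank_bin, end + (n_flank - k) * flank_bin)
            for k in range(n_flank)
        ]
        down = [(start - (k + 1) * flank_bin, start - k * flank_bin) for k in range(n_flank)]
    else:
        edges = start + np.concatenate([[0], np.cumsum(sizes)])
        body = [(int(edges[i]), int(edges[i + 1])) for i in range(n_body)]
        up = [
            (start - (n_flank - k) * flank_bin, start - (n_flank - k - 1) * flank_bin)
            for k in range(n_flank)
        ]
        down = [(end + k * flank_bin, end + (k + 1) * flank_bin) for k in range(n_flank)]
    bins.extend(up)
    bins.extend(body)
    bins.extend(down)
    return bins


def scaled_profile(
    source,
    features: IntervalSet,
    n_body: int = N_BODY,
    n_flank: int = N_FLANK,
    flank_bin: int = 25_000,
    coverage_sources: list | None = None,
    chrom_sizes: ChromSizes | None = None,
) -> MetaProfileMatrix:
    """Scaled feature profiles with fixed flanks.

    ``source`` provides bin_value/bin_coverage (CpGSignal for
    methylation, TrackSignal for normalized ChIP). ``coverage_sources``
    is the set of samples whose raw coverage drives the >= 80%
    zero-body-bin exclusion (defaults to [source]). Flank bins falling
    off a chromosome end are missing, not zero. Features shorter than
    n_body bp are dropped with a warning.
    """
    if flank_bin <= 0:
        raise ValueError("flank_bin must be positive")
    if coverage_sources is None:
        coverage_sources = [source]
    fdf = features.df
    ids = (
        fdf["name"].tolist()
        if "name" in fdf.columns
        else [f"feature_{i}" for i in range(len(fdf))]
    )
    strands = (
        fdf["strand"].tolist() if "strand" in fdf.columns else ["."] * len(fdf)
    )
    rows, kept_ids = [], []
    n_cols = 2 * n_flank + n_body
    for (row, fid, strand) in zip(fdf.itertuples(index=False), ids, strands):
        chrom, start, end = row.chrom, int(row.start), int(row.end)
        if end - start < n_body:
            warnings.warn(
                f"feature {fid} shorter than {n_body} bp; dropped", stacklevel=2
            )
            continue
        bins = _feature_bins(chrom, start, end, strand, n_body, n_flank, flank_bin)
        body_slice = slice(n_flank, n_flank + n_body)
        body_cov_zero = np.ones(n_body, dtype=bool)
        for src in coverage_sources:
            cov = np.array(
                [src.bin_coverage(chrom, s, e) for s, e in bins[body_slice]]
            )
            body_cov_zero &= cov == 0
        if body_cov_zero.sum() >= ZERO_COVERAGE_DROP_FRACTION * n_body:
            continue
        vals = np.full(n_cols, np.nan)
        chrom_len = (
            chrom_sizes[chrom]
            if chrom_sizes is not None and chrom in chrom_sizes
            else None
        )
        for j, (s, e) in enumerate(bins):
            if s < 0 or (chrom_len is not None and e > chrom_len):
                continue  # off-chromosome flank bin: missing
            if s >= e:
                continue
            vals[j] = source.bin_value(chrom, s, e)
        rows.append(vals)
        kept_ids.append(fid)
    values = np.array(rows) if rows else np.empty((0, n_cols))
    return MetaProfileMatrix(values, kept_ids, n_body, n_flank, flank_bin)


def order_and_cap(
    matrix: MetaProfileMatrix,
    rank_signal: np.ndarray,
    cap_quantile: float = CAP_QUANTILE,
) -> tuple[MetaProfileMatrix, tuple[float, float]]:
    """Sort rows descending by a per-feature rank signal; display bounds.

    Bounds run from the matrix minimum to the ``cap_quantile`` quantile
    of all (finite) values — the color-scale convention for broad-mark
    heatmaps.
    """
    rank_signal = np.asarray(rank_signal, dtype=float)
    if len(rank_signal) != len(matrix.feature_ids):
        raise ValueError("rank signal length mismatch")
    order = np.argsort(-rank_signal, kind="stable")
    ordered = MetaProfileMatrix(
        matrix.values[order],
        [matrix.feature_ids[i] for i in order],
        matrix.n_body,
        matrix.n_flank,
        matrix.flank_bin,
    )
    finite = matrix.values[np.isfinite(matrix.values)]
    lo = float(finite.min()) if len(finite) else np.nan
    hi = float(np.quantile(finite, cap_quantile)) if len(finite) else np.nan
    return ordered, (lo, hi)


def plot_heatmap(
    matrix: MetaProfileMatrix,
    path,
    bounds: tuple[float, float] | None = None,
    cmap: str = "viridis",
) -> None:
    """Render an ordered profile matrix as a heatmap image.

    ``bounds`` are the display limits from :func:`order_and_cap`
    (matrix minimum to the 90% quantile by default).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if bounds is None:
        finite = matrix.values[np.isfinite(matrix.values)]
        bounds = (float(finite.min()), float(np.quantile(finite, CAP_QUANTILE)))
    fig, ax = plt.subplots(figsize=(4, 6))
    im = ax.imshow(
        matrix.values, aspect="auto", vmin=bounds[0], vmax=bounds[1],
        cmap=cmap, interpolation="nearest",
    )
    for x in (matrix.n_flank - 0.5, matrix.n_flank + matrix.n_body - 0.5):
        ax.axvline(x, color="white", lw=0.5)
    ax.set_xlabel("bin (5' flank | scaled body | 3' flank)")
    ax.set_ylabel("feature")
    fig.colorbar(im, ax=ax, shrink=0.6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_decile_boxes(summary: DecileSummary, response: np.ndarray, path) -> None:
    """Boxplot of the response distribution per rank decile."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    response = np.asarray(response, dtype=float)
    data = [response[g] for g in summary.groups]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot(data, showfliers=False)
    ax.set_xlabel("rank decile")
    ax.set_ylabel("response")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def decile_summary(
    response: np.ndarray,
    ranking: np.ndarray,
    n_groups: int = 10,
) -> DecileSummary:
    """Rank windows and split into near-equal contiguous groups.

    Windows missing in either signal are dropped first; the stable sort
    is by (ranking, window index) ascending; the first n % n_groups
    groups take the extra element. Group summaries are quartiles, mean
    and size of the response.
    """
    response = np.asarray(response, dtype=float)
    ranking = np.asarray(ranking, dtype=float)
    if len(response) != len(ranking):
        raise ValueError("response and ranking must align")
    ok = np.isfinite(response) & np.isfinite(ranking)
    idx = np.nonzero(ok)[0]
    n = len(idx)
    if n < n_groups:
        raise ValueError(f"need >= {n_groups} windows, got {n}")
    order = idx[np.lexsort((idx, ranking[idx]))]
    base, rem = divmod(n, n_groups)
    sizes = [base + 1] * rem + [base] * (n_groups - rem)
    groups, start = [], 0
    for s in sizes:
        groups.append(order[start : start + s])
        start += s
    rows = []
    for g, members in enumerate(groups):
        vals = response[members]
        rows.append(
            {
                "group": g + 1,
                "n": len(members),
                "mean": float(vals.mean()),
                "q25": float(np.quantile(vals, 0.25)),
                "median": float(np.median(vals)),
                "q75": float(np.quantile(vals, 0.75)),
            }
        )
    return DecileSummary(groups, pd.DataFrame(rows))
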