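"""Per-window fragment counting and ChIP coverage normalization.

Counts per window are scaled to counts per 10 million mapped fragments
and divided by the equivalently scaled input, after adding an offset of
0.5 to every window so that input windows with zero reads cannot
produce infinities:

    v_w = s * [(c_w + 0.5) * 1e7 / N_chip] / [(i_w + 0.5) * 1e7 / N_input]

where ``s`` is an optional spike-in (ChIP-Rx) scaling factor. Windows
with zero raw counts in all samples of the comparison set are dropped
from analysis.

The spike-in factor between two conditions uses exogenous
(D. melanogaster) chromatin: with d(x) = 1e7 * dm_reads(x)/total_reads(x),

    s = [d(chip_a)/d(chip_b)] / [d(input_a)/d(input_b)]

and is applied multiplicatively to sample b's normalized track when
comparing b against reference a.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hdm.genome import IntervalSet, WindowGrid

__all__ = [
    "WindowCounts",
    "NormalizedChipTrack",
    "SpikeInTable",
    "count_fragments",
    "normalize_coverage",
    "spikein_scaling_factor",
    "mean_of_replicates",
    "all_zero_mask",
]

OFFSET = 0.5
PER_READS = 1e7


@dataclass
class WindowCounts:
    """Integer fragment counts per window of a grid."""

    grid: WindowGrid
    counts: np.ndarray  # len == grid.n_windows
    total_fragments: int  # sample total mapped fragments N
    sample: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != self.grid.n_windows:
            raise ValueError("counts length does not match grid")
        if (self.counts < 0).any():
            raise ValueError("negative counts")


@dataclass
class NormalizedChipTrack:
    """Input-normalized (optionally spike-scaled) per-window signal.

    ``values`` are NaN at dropped windows; retained values are strictly
    positive and finite (guaranteed by the 0.5 offset).
    """

    grid: WindowGrid
    values: np.ndarray
    chip_sample: str = ""
    input_sample: str = ""
    spike_factor: float = 1.0

    @property
    def dropped(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        out = self.grid.windows_df()
        out["value"] = self.values
        return out


class SpikeInTable:
    """Per-sample exogenous-genome and total mapped read counts."""

    def __init__(self, records: dict[str, tuple[int, int]] | pd.DataFrame):
        if isinstance(records, pd.DataFrame):
            records = {
                str(r.sample): (int(r.dm_reads), int(r.total_reads))
                for r in records.itertuples(index=False)
            }
        for name, (dm, total) in records.items():
            if not (0 < dm < total):
                raise ValueError(
                    f"sample {name!r}: need 0 < dm_reads < total_reads, got {dm}/{total}"
                )
        self._records = dict(records)

    def records(self) -> dict[str, tuple[int, int]]:
        return dict(self._records)

    def scaled_dm(self, sample: str) -> float:
        """Spike reads per 1e7 total mapped reads: d(x)."""
        dm, total = self._records[sample]
        return PER_READS * dm / total

    def __contains__(self, sample: str) -> bool:
        return sample in self._records

    def samples(self) -> list[str]:
        return list(self._records)


def count_fragments(fragments: IntervalSet, grid: WindowGrid) -> WindowCounts:
    """Count fragments overlapping each window by >= 1 bp.

    A fragment spanning k windows increments all k (no fractional
    assignment). The total mapped fragment count N is the number of
    input fragments.
    """
    counts = np.zeros(grid.n_windows, dtype=np.int64)
    df = fragments.df
    for chrom, g in df.groupby("chrom", sort=False):
        if chrom not in grid.chrom_sizes:
            continue
        length = grid.chrom_sizes[chrom]
        starts = np.clip(g["start"].to_numpy(dtype=np.int64), 0, length)
        ends = np.clip(g["end"].to_numpy(dtype=np.int64), 0, length)
        ok = starts < ends
        starts, ends = starts[ok], ends[ok]
        w = grid.window_size
        first = starts // w
        last = (ends - 1) // w
        off = grid.locate(chrom, np.zeros(1, dtype=np.int64))[0]
        span = last - first
        for k in range(int(span.max()) + 1 if len(span) else 0):
            sel = span >= k
            np.add.at(counts, off + first[sel] + k, 1)
    return WindowCounts(grid, counts, total_fragments=len(df))


def all_zero_mask(count_sets: list[WindowCounts]) -> np.ndarray:
    """True where raw counts are zero in every sample of the set.

    Evaluated on raw counts across all samples in the comparison,
    before any normalization.
    """
    if not count_sets:
        raise ValueError("empty sample set")
    stacked = np.stack([c.counts for c in count_sets])
    return (stacked == 0).all(axis=0)


def normalize_coverage(
    chip: WindowCounts,
    input_: WindowCounts,
    spike_factor: float = 1.0,
    drop_mask: np.ndarray | None = None,
) -> NormalizedChipTrack:
    """Offset, scale to counts per 10 million, and divide by input.

    ``drop_mask`` marks windows to exclude (typically the all-samples-
    zero mask plus blacklist/gap windows); when None, windows zero in
    both chip and input are dropped.
    """
    if chip.grid is not input_.grid and chip.grid.n_windows != input_.grid.n_windows:
        raise ValueError("chip and input are on different grids")
    if chip.total_fragments <= 0 or input_.total_fragments <= 0:
        raise ValueError("total mapped fragment counts must be positive")
    if spike_factor <= 0:
        raise ValueError("spike factor must be positive")
    chip_scaled = (chip.counts + OFFSET) * PER_READS / chip.total_fragments
    input_scaled = (input_.counts + OFFSET) * PER_READS / input_.total_fragments
    values = spike_factor * chip_scaled / input_scaled
    if drop_mask is None:
        drop_mask = all_zero_mask([chip, input_])
    values = np.where(drop_mask, np.nan, values)
    return NormalizedChipTrack(
        chip.grid,
        values,
        chip_sample=chip.sample,
        input_sample=input_.sample,
        spike_factor=spike_factor,
    )


def spikein_scaling_factor(
    table: SpikeInTable,
    chip_a: str,
    chip_b: str,
    input_a: str,
    input_b: str,
) -> float:
    """ChIP-Rx scaling factor between conditions a (reference) and b.

    Ratio of the per-1e7-scaled exogenous reads in the two ChIP samples
    over the corresponding input ratio. Multiply sample b's normalized
    track by the result to place it on sample a's scale. Composes
    exactly: s(a->c) = s(a->b) * s(b->c).
    """
    for s in (chip_a, chip_b, input_a, input_b):
        if s not in table:
            raise ValueError(f"sample {s!r} missing from spike-in table")
    return (table.scaled_dm(chip_a) / table.scaled_dm(chip_b)) / (
        table.scaled_dm(input_a) / table.scaled_dm(input_b)
    )


def mean_of_replicates(tracks: list[NormalizedChipTrack]) -> NormalizedChipTrack:
    """Per-window arithmetic mean of replicate tracks.

    Windows dropped in any replicate propagate as dropped.
    """
    if not tracks:
        raise ValueError("no tracks to average")
    n = tracks[0].grid.n_windows
    for t in tracks[1:]:
        if t.grid.n_windows != n:
            raise ValueError("tracks are on different grids")
    stacked = np.stack([t.values for t in tracks])
    values = stacked.mean(axis=0)  # NaN propagates
    return NormalizedChipTrack(
        tracks[0].grid,
        values,
        chip_sample="+".join(t.chip_sample for t in tracks if t.chip_sample),
        input_sample=tracks[0].input_sample,
        spike_factor=float(np.mean([t.spike_factor for t in tracks])),
    )


def read_window_counts(path, grid: WindowGrid, total_fragments: int, sample: str = "") -> WindowCounts:
    """Read a window-count TSV (window_id, chrom, start, end, count)."""
    df = pd.read_csv(path, sep="\t")
    counts = np.zeros(grid.n_windows, dtype=np.int64)
    counts[df["window_id"].to_numpy()] = df["count"].to_numpy()
    return WindowCounts(grid, counts, total_fragments, sample)


def write_window_counts(wc: WindowCounts, path) -> None:
    out = wc.grid.windows_df()
    out["count"] = wc.counts
    out.to_csv(path, sep="\t", index=False)


def write_normalized_track(track: NormalizedChipTrack, path) -> None:
    """TSV with metadata header lines (#chip=, #input=, #spike_factor=)."""
    with open(path, "w") as fh:
        fh.write(f"#chip={track.chip_sample}\n")
        fh.write(f"#input={track.input_sample}\n")
        fh.write(f"#spike_factor={track.spike_factor:.6g}\n")
        track.to_frame().to_csv(fh, sep="\t", index=False)
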