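"""Genomic coordinate types, window grids and interval arithmetic.

All coordinates are 0-based half-open (BED convention). Readers for
1-based formats (Bismark coverage) convert on input. Chromosome names
are matched by exact string equality; no "chr"-prefix normalization is
attempted, but :func:`check_chrom_names` reports names present in only
one of two inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChromSizes",
    "GenomicInterval",
    "IntervalSet",
    "WindowGrid",
    "make_windows",
    "merge_exclusion_regions",
    "subtract",
    "intersect",
    "filter_windows",
    "check_chrom_names",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "write_bed",
    "write_bedgraph",
]


class ChromSizes:
    """Ordered mapping of chromosome name to length in bp."""

    def __init__(self, entries: Mapping[str, int] | Iterable[tuple[str, int]]):
        items = list(entries.items()) if isinstance(entries, Mapping) else list(entries)
        names = [n for n, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in items:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self._entries: dict[str, int] = dict(items)

    def __getitem__(self, name: str) -> int:
        return self._entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def items(self):
        return self._entries.items()

    def names(self) -> list[str]:
        return list(self._entries)

    @property
    def total_length(self) -> int:
        return sum(self._entries.values())

    def __eq__(self, other) -> bool:
        return isinstance(other, ChromSizes) and list(self.items()) == list(other.items())

    def __repr__(self) -> str:
        return f"ChromSizes({self._entries!r})"


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


_IV_COLUMNS = ["chrom", "start", "end"]


class IntervalSet:
    """Sorted collection of genomic intervals.

    Backed by a pandas DataFrame with at least (chrom, start, end);
    optional columns (name, score, strand) survive round-trips but are
    ignored by the set operations. ``non_overlapping`` records whether
    the set is guaranteed free of intra-chromosome overlaps.
    """

    def __init__(self, df: pd.DataFrame, non_overlapping: bool | None = None):
        missing = [c for c in _IV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
        if len(df) and (df["start"] >= df["end"]).any():
            raise ValueError("intervals must satisfy start < end")
        if len(df) and (df["start"] < 0).any():
            raise ValueError("negative start coordinate")
        self.df = df
        if non_overlapping is None:
            non_overlapping = self._check_non_overlapping()
        self.non_overlapping = non_overlapping

    def _check_non_overlapping(self) -> bool:
        for _, g in self.df.groupby("chrom", sort=False):
            if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
                return False
        return True

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "IntervalSet":
        rows = [(iv.chrom, iv.start, iv.end, iv.strand) for iv in intervals]
        df = pd.DataFrame(rows, columns=_IV_COLUMNS + ["strand"])
        return cls(df)

    @classmethod
    def from_tuples(cls, tuples: Iterable[tuple]) -> "IntervalSet":
        """Build from (chrom, start, end[, strand]) tuples."""
        rows = list(tuples)
        if rows and len(rows[0]) >= 4:
            df = pd.DataFrame(
                [r[:4] for r in rows], columns=_IV_COLUMNS + ["strand"]
            )
        else:
            df = pd.DataFrame(rows, columns=_IV_COLUMNS)
        return cls(df)

    @classmethod
    def empty(cls) -> "IntervalSet":
        return cls(pd.DataFrame(columns=_IV_COLUMNS), non_overlapping=True)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        has_strand = "strand" in self.df.columns
        for row in self.df.itertuples(index=False):
            strand = getattr(row, "strand", ".") if has_strand else "."
            if strand not in ("+", "-"):
                strand = "."
            yield GenomicInterval(row.chrom, int(row.start), int(row.end), strand)

    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        g = self.df[self.df["chrom"] == chrom]
        return g["start"].to_numpy(dtype=np.int64), g["end"].to_numpy(dtype=np.int64)

    @property
    def total_bp(self) -> int:
        """Total covered bp; requires a non-overlapping set to be meaningful."""
        s = self if self.non_overlapping else merge_exclusion_regions([self], 0)
        return int((s.df["end"] - s.df["start"]).sum())

    def validate_against(self, chrom_sizes: ChromSizes) -> None:
        for row in self.df.itertuples(index=False):
            if row.chrom not in chrom_sizes:
                raise ValueError(f"unknown chromosome {row.chrom!r}")
            if row.end > chrom_sizes[row.chrom]:
                raise ValueError(
                    f"interval {row.chrom}:{row.start}-{row.end} exceeds "
                    f"chromosome length {chrom_sizes[row.chrom]}"
                )

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)}, non_overlapping={self.non_overlapping})"


class WindowGrid:
    """Non-overlapping tiling of a genome into fixed-size windows.

    Windows tile each chromosome without gaps; the final window on a
    chromosome may be shorter than ``window_size``. Window ids are dense
    integers in (chrom, start) order, bijective with (chrom, start).
    """

    def __init__(self, chrom_sizes: ChromSizes, window_size: int):
        if window_size <= 0:
            raise ValueError(f"window size must be >= 1, got {window_size}")
        self.chrom_sizes = chrom_sizes
        self.window_size = int(window_size)
        counts, offsets = {}, {}
        total = 0
        for name, length in chrom_sizes.items():
            n = -(-length // window_size)  # ceil division
            counts[name] = n
            offsets[name] = total
            total += n
        self._counts = counts
        self._offsets = offsets
        self.n_windows = total

    def __len__(self) -> int:
        return self.n_windows

    def windows_df(self) -> pd.DataFrame:
        """All windows as a DataFrame (window_id, chrom, start, end)."""
        frames = []
        for name, length in self.chrom_sizes.items():
            starts = np.arange(0, length, self.window_size, dtype=np.int64)
            ends = np.minimum(starts + self.window_size, length)
            frames.append(
                pd.DataFrame(
                    {
                        "window_id": self._offsets[name] + np.arange(len(starts)),
                        "chrom": name,
                        "start": starts,
                        "end": ends,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def interval_set(self) -> IntervalSet:
        return IntervalSet(self.windows_df()[_IV_COLUMNS].copy(), non_overlapping=True)

    def locate(self, chrom: str | np.ndarray, pos: np.ndarray | int):
        """Window id(s) containing position(s); positions are 0-based bp."""
        if isinstance(chrom, str):
            pos = np.asarray(pos, dtype=np.int64)
            if np.any((pos < 0) | (pos >= self.chrom_sizes[chrom])):
                raise ValueError("position outside chromosome")
            return self._offsets[chrom] + pos // self.window_size
        chrom = np.asarray(chrom)
        pos = np.asarray(pos, dtype=np.int64)
        out = np.empty(len(pos), dtype=np.int64)
        for name in np.unique(chrom):
            m = chrom == name
            out[m] = self.locate(str(name), pos[m])
        return out

    def window_bounds(self, window_id: int) -> GenomicInterval:
        for name in self.chrom_sizes:
            n = self._counts[name]
            off = self._offsets[name]
            if off <= window_id < off + n:
                start = (window_id - off) * self.window_size
                end = min(start + self.window_size, self.chrom_sizes[name])
                return GenomicInterval(name, start, end)
        raise IndexError(f"window id {window_id} out of range")

    def overlapping_ids(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Ids of all windows overlapping [start, end) by >= 1 bp."""
        if chrom not in self.chrom_sizes:
            return np.empty(0, dtype=np.int64)
        length = self.chrom_sizes[chrom]
        lo = max(start, 0)
        hi = min(end, length)
        if lo >= hi:
            return np.empty(0, dtype=np.int64)
        first = lo // self.window_size
        last = (hi - 1) // self.window_size
        return self._offsets[chrom] + np.arange(first, last + 1, dtype=np.int64)


def make_windows(chrom_sizes: ChromSizes, size: int) -> WindowGrid:
    """Tile the genome into non-overlapping windows of ``size`` bp.

    The trailing window on each chromosome is retained even when shorter
    than ``size``; downstream coverage thresholds remove under-covered
    windows rather than truncating the grid.
    """
    return WindowGrid(chrom_sizes, size)


def merge_exclusion_regions(
    sets: Sequence[IntervalSet], merge_distance: int = 10_000_000
) -> IntervalSet:
    """Union of interval sets with nearby intervals joined.

    Intervals separated by a gap of at most ``merge_distance`` bp are
    merged into one (``merge_distance=0`` joins only overlapping or
    bookended intervals). The default distance of 10 Mb is the
    convention used when pooling assembly gaps and centromeres into a
    single exclusion mask. Idempotent.
    """
    if merge_distance < 0:
        raise ValueError("merge_distance must be >= 0")
    frames = [s.df[_IV_COLUMNS] for s in sets if len(s)]
    if not frames:
        return IntervalSet.empty()
    df = pd.concat(frames, ignore_index=True).sort_values(
        ["chrom", "start", "end"], kind="stable"
    )
    out_rows = []
    for chrom, g in df.groupby("chrom", sort=False):
        starts = g["start"].to_numpy(dtype=np.int64)
        ends = g["end"].to_numpy(dtype=np.int64)
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s - cur_e <= merge_distance:
                cur_e = max(cur_e, e)
            else:
                out_rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out_rows.append((chrom, cur_s, cur_e))
    return IntervalSet(
        pd.DataFrame(out_rows, columns=_IV_COLUMNS), non_overlapping=True
    )


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Remove every bp of ``b`` from ``a``, splitting intervals as needed."""
    if len(b) == 0:
        return IntervalSet(a.df[_IV_COLUMNS].copy(), non_overlapping=a.non_overlapping)
    b_merged = b if b.non_overlapping else merge_exclusion_regions([b], 0)
    out_rows = []
    for row in a.df.itertuples(index=False):
        bs, be = b_merged.arrays(row.chrom)
        cur = int(row.start)
        end = int(row.end)
        # only b-intervals that can overlap [cur, end)
        i = int(np.searchsorted(be, cur, side="right"))
        while i < len(bs) and bs[i] < end:
            if bs[i] > cur:
                out_rows.append((row.chrom, cur, int(bs[i])))
            cur = max(cur, int(be[i]))
            i += 1
        if cur < end:
            out_rows.append((row.chrom, cur, end))
    if not out_rows:
        return IntervalSet.empty()
    return IntervalSet(pd.DataFrame(out_rows, columns=_IV_COLUMNS))


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Bp-level intersection of two interval sets."""
    if len(a) == 0 or len(b) == 0:
        return IntervalSet.empty()
    b_merged = b if b.non_overlapping else merge_exclusion_regions([b], 0)
    out_rows = []
    for row in a.df.itertuples(index=False):
        bs, be = b_merged.arrays(row.chrom)
        i = int(np.searchsorted(be, row.start, side="right"))
        while i < len(bs) and bs[i] < row.end:
            s = max(int(row.start), int(bs[i]))
            e = min(int(row.end), int(be[i]))
            if s < e:
                out_rows.append((row.chrom, s, e))
            i += 1
    if not out_rows:
        return IntervalSet.empty()
    return IntervalSet(pd.DataFrame(out_rows, columns=_IV_COLUMNS))


def filter_windows(grid: WindowGrid, exclusions: IntervalSet) -> np.ndarray:
    """Boolean mask of windows to EXCLUDE.

    A window overlapping any exclusion interval by >= 1 bp is marked
    True (excluded). Returns an array of length ``grid.n_windows``.
    """
    mask = np.zeros(grid.n_windows, dtype=bool)
    for row in exclusions.df.itertuples(index=False):
        ids = grid.overlapping_ids(row.chrom, int(row.start), int(row.end))
        mask[ids] = True
    return mask


def check_chrom_names(a: Iterable[str], b: Iterable[str]) -> tuple[set, set]:
    """Warn about chromosome names present in only one of two inputs."""
    sa, sb = set(a), set(b)
    only_a, only_b = sa - sb, sb - sa
    if only_a or only_b:
        warnings.warn(
            f"chromosome names present in only one input: "
            f"first-only={sorted(only_a)}, second-only={sorted(only_b)}",
            stacklevel=2,
        )
    return only_a, only_b


# ---------------------------------------------------------------------------
# Readers / writers


def read_chrom_sizes(path: str | Path) -> ChromSizes:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return ChromSizes(zip(df["chrom"].astype(str), df["length"].astype(int)))


def write_chrom_sizes(chrom_sizes: ChromSizes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in chrom_sizes.items():
            fh.write(f"{name}\t{length}\n")


def read_bed(path: str | Path) -> IntervalSet:
    """Read BED3/BED6 (tab-separated, half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names
    df["chrom"] = df["chrom"].astype(str)
    return IntervalSet(df)


def write_bed(s: IntervalSet, path: str | Path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in s.df.columns]
    s.df[cols].to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(
    df: pd.DataFrame, path: str | Path, value_col: str = "value", decimals: int = 1
) -> None:
    """Write (chrom, start, end, value) rows as bedGraph, sorted."""
    out = df[["chrom", "start", "end", value_col]].sort_values(
        ["chrom", "start"], kind="stable"
    )
    out = out.assign(**{value_col: out[value_col].round(decimals)})
    out.to_csv(path, sep="\t", header=False, index=False, float_format=f"%.{decimals}f")
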