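"""Weighted-mean methylation over windows, domains and regions.

The atomic input is a per-CpG call table (methylated / total read
counts, strand-merged). Region-level methylation is the coverage-
weighted mean 100 * sum(meth) / sum(total) over the CpGs contained in
each region; regions whose summed coverage falls below a threshold are
masked, and masked values are encoded as absent (NaN), never as 0 —
0% methylation is data, absence of coverage is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from hdm.genome import IntervalSet, WindowGrid, write_bedgraph

__all__ = [
    "CpGCallTable",
    "MethTrack",
    "DiffMethTrack",
    "region_methylation",
    "differential_methylation",
    "track_for_export",
    "conversion_efficiency",
    "read_bismark_cov",
    "write_bismark_cov",
]

# Coverage floor used for bedGraph/bigWig export; windows below it are
# dropped from the exported track.
EXPORT_MIN_COVERAGE = 5
# Coverage floor for analysis windows.
ANALYSIS_MIN_COVERAGE = 10
# Bisulfite conversion-efficiency QC gate (strict greater-than).
CONVERSION_GATE = 99.5


class CpGCallTable:
    """Per-CpG methylation calls: (chrom, pos, meth_count, total_count).

    Positions are 0-based bp, unique per chromosome, sorted by
    (chrom, pos). Counts satisfy 0 <= meth_count <= total_count.
    """

    COLUMNS = ["chrom", "pos", "meth_count", "total_count"]

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        df = df[self.COLUMNS].sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        if validate and len(df):
            if (df["meth_count"] > df["total_count"]).any():
                raise ValueError("meth_count exceeds total_count")
            if (df["meth_count"] < 0).any() or (df["pos"] < 0).any():
                raise ValueError("negative counts or positions")
            if df.duplicated(["chrom", "pos"]).any():
                raise ValueError("duplicate CpG positions")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, CpGCallTable) and self.df.equals(other.df)

    def restrict(self, chrom: str) -> "CpGCallTable":
        return CpGCallTable(self.df[self.df["chrom"] == chrom], validate=False)

    def __repr__(self) -> str:
        return f"CpGCallTable(n={len(self)})"


@dataclass
class MethTrack:
    """Per-region weighted methylation with a coverage mask.

    ``regions`` holds (chrom, start, end); ``meth_sum`` / ``cov_sum``
    the summed methylated / total counts; ``percent`` is
    100*meth_sum/cov_sum where unmasked and NaN where masked.
    """

    regions: pd.DataFrame
    meth_sum: np.ndarray
    cov_sum: np.ndarray
    mask: np.ndarray  # True = excluded by coverage
    min_total_coverage: int = 0

    @property
    def percent(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            p = 100.0 * self.meth_sum / self.cov_sum
        p = np.where(self.mask, np.nan, p)
        return p

    def to_frame(self) -> pd.DataFrame:
        out = self.regions.copy()
        out["percent"] = self.percent
        out["coverage"] = self.cov_sum
        return out

    def __len__(self) -> int:
        return len(self.regions)


@dataclass
class DiffMethTrack:
    """Per-region methylation difference (A - B) in percentage points."""

    regions: pd.DataFrame
    delta: np.ndarray  # NaN where masked
    mask: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        out = self.regions.copy()
        out["delta"] = self.delta
        return out

    def __len__(self) -> int:
        return len(self.regions)


def _regions_frame(regions: WindowGrid | IntervalSet) -> pd.DataFrame:
    if isinstance(regions, WindowGrid):
        return regions.windows_df()[["chrom", "start", "end"]]
    return regions.df[["chrom", "start", "end"]].reset_index(drop=True)


def _assign_regions(calls: CpGCallTable, regions: WindowGrid | IntervalSet) -> np.ndarray:
    """Region index for each CpG (-1 when outside every region).

    Membership is half-open containment: a CpG at pos belongs to the
    region with start <= pos < end. For interval sets the intervals
    must be sorted and non-overlapping so assignment is unambiguous.
    """
    df = calls.df
    idx = np.full(len(df), -1, dtype=np.int64)
    if isinstance(regions, WindowGrid):
        for chrom in df["chrom"].unique():
            if chrom not in regions.chrom_sizes:
                continue
            m = (df["chrom"] == chrom).to_numpy()
            pos = df.loc[m, "pos"].to_numpy(dtype=np.int64)
            inside = pos < regions.chrom_sizes[chrom]
            vals = np.full(m.sum(), -1, dtype=np.int64)
            vals[inside] = regions.locate(chrom, pos[inside])
            idx[m] = vals
        return idx
    if not regions.non_overlapping:
        raise ValueError("regions must be non-overlapping for unambiguous assignment")
    rdf = regions.df.reset_index(drop=True)
    for chrom in df["chrom"].unique():
        g = rdf[rdf["chrom"] == chrom]
        if g.empty:
            continue
        starts = g["start"].to_numpy(dtype=np.int64)
        ends = g["end"].to_numpy(dtype=np.int64)
        rix = g.index.to_numpy()
        m = (df["chrom"] == chrom).to_numpy()
        pos = df.loc[m, "pos"].to_numpy(dtype=np.int64)
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0) & (pos < ends[np.clip(j, 0, None)])
        vals = np.full(len(pos), -1, dtype=np.int64)
        vals[ok] = rix[j[ok]]
        idx[m] = vals
    return idx


def region_methylation(
    calls: CpGCallTable,
    regions: WindowGrid | IntervalSet,
    min_total_coverage: int = 0,
) -> MethTrack:
    """Coverage-weighted mean methylation per region.

    percent = 100 * sum(meth_count) / sum(total_count) over CpGs whose
    position lies inside the region (half-open). Regions with summed
    coverage below ``min_total_coverage`` are masked. The standard
    analysis threshold for 2.5-kb windows is 10; domain-level means
    default to no floor.
    """
    if min_total_coverage < 0:
        raise ValueError("min_total_coverage must be >= 0")
    rframe = _regions_frame(regions)
    n = len(rframe)
    meth = np.zeros(n, dtype=np.int64)
    cov = np.zeros(n, dtype=np.int64)
    if len(calls):
        idx = _assign_regions(calls, regions)
        ok = idx >= 0
        np.add.at(meth, idx[ok], calls.df["meth_count"].to_numpy()[ok])
        np.add.at(cov, idx[ok], calls.df["total_count"].to_numpy()[ok])
    mask = cov < min_total_coverage
    return MethTrack(rframe, meth, cov, mask, min_total_coverage)


def differential_methylation(a: MethTrack, b: MethTrack) -> DiffMethTrack:
    """Per-region methylation difference a - b in percentage points.

    Both tracks must be on the identical region set; the output is
    masked wherever either input is masked.
    """
    if len(a) != len(b) or not a.regions[["chrom", "start", "end"]].equals(
        b.regions[["chrom", "start", "end"]]
    ):
        raise ValueError("tracks are not on the same region set")
    mask = a.mask | b.mask
    delta = np.where(mask, np.nan, a.percent - b.percent)
    return DiffMethTrack(a.regions.copy(), delta, mask)


def track_for_export(calls: CpGCallTable, grid: WindowGrid) -> MethTrack:
    """Windowed methylation for track export (coverage floor of 5)."""
    return region_methylation(calls, grid, min_total_coverage=EXPORT_MIN_COVERAGE)


def export_bedgraph(track: MethTrack, path: str | Path) -> None:
    """Write unmasked windows as a sorted bedGraph with one decimal."""
    df = track.to_frame()
    df = df[~np.isnan(df["percent"])]
    df = df.rename(columns={"percent": "value"})
    write_bedgraph(df, path, value_col="value", decimals=1)


def conversion_efficiency(lambda_calls: CpGCallTable) -> float:
    """Bisulfite conversion efficiency from unmethylated spike-in calls.

    Restricted to the unmethylated (phage-lambda) spike-in contig,
    every methylated call is a conversion failure:
    efficiency = 100 - 100 * sum(meth) / sum(total). The QC gate
    requires strictly > 99.5%.
    """
    total = int(lambda_calls.df["total_count"].sum())
    if total == 0:
        raise ValueError("no coverage on spike-in contig; efficiency undefined")
    meth = int(lambda_calls.df["meth_count"].sum())
    return 100.0 - 100.0 * meth / total


def conversion_gate(efficiency: float, threshold: float = CONVERSION_GATE) -> bool:
    """Strict QC gate: passes only when efficiency > threshold."""
    return efficiency > threshold


def read_bismark_cov(path: str | Path) -> CpGCallTable:
    """Read a Bismark coverage file.

    Columns: chrom, start (1-based), end, %meth, count-methylated,
    count-unmethylated. Start is converted to a 0-based position.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "pct", "meth", "unmeth"],
    )
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str),
            "pos": df["start"].astype(np.int64) - 1,
            "meth_count": df["meth"].astype(np.int64),
            "total_count": (df["meth"] + df["unmeth"]).astype(np.int64),
        }
    )
    return CpGCallTable(out)


def write_bismark_cov(calls: CpGCallTable, path: str | Path) -> None:
    df = calls.df
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * df["meth_count"] / df["total_count"]
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"] + 1,
            "end": df["pos"] + 1,
            "pct": pct.fillna(0.0),
            "meth": df["meth_count"],
            "unmeth": df["total_count"] - df["meth_count"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")
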