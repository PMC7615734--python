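"""FRAP recovery-curve normalization and immobile-fraction estimation.

A trace holds the mean intensity of the bleached region I_B(t) and of
the whole nucleus I_C(t), with n_pre pre-bleach frames followed by
post-bleach frames at (typically) 2-s spacing. Two normalizations are
applied:

1. photobleach correction against the whole-cell signal, scaled so the
   pre-bleach level is 1:
       I_N(t) = [I_B(t)/I_C(t)] / [mean_pre(I_B)/mean_pre(I_C)]
2. a shift so the curve minimum is 0 while the pre-bleach level stays
   at 1 (bleaching is never 100% efficient, so raw minima differ
   between conditions):
       I_N2(t) = (I_N(t) - I_N_min) / (1 - I_N_min)

The immobile fraction is IF = 1 - I_N2(t -> inf), approximated by the
mean of I_N2 over a tail window (default t in [100, 150] s; a
last-k-frames mode is also provided). Replicate means are aggregated
as an unweighted mean with uncorrelated error propagation
sqrt(sum SD_i^2)/k.

Time origin: t = 0 at the first post-bleach frame; pre-bleach frames
carry negative times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FrapTrace",
    "FrapCurve",
    "FrapResult",
    "normalize_trace",
    "immobile_fraction",
    "aggregate_replicates",
    "read_frap_traces",
]

DEFAULT_TAIL_WINDOW = (100.0, 150.0)
N_PRE_DEFAULT = 5


@dataclass
class FrapTrace:
    """Raw ROI intensities for one cell."""

    times: np.ndarray  # seconds; strictly increasing; t=0 first post-bleach
    roi: np.ndarray  # bleached-ROI mean intensity I_B(t)
    cell: np.ndarray  # whole-nucleus mean intensity I_C(t)
    n_pre: int = N_PRE_DEFAULT
    cell_id: str = ""
    replicate_id: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.roi = np.asarray(self.roi, dtype=float)
        self.cell = np.asarray(self.cell, dtype=float)
        if not (len(self.times) == len(self.roi) == len(self.cell)):
            raise ValueError("trace arrays must align")
        if self.n_pre < 1:
            raise ValueError("need >= 1 pre-bleach frame")
        if len(self.times) - self.n_pre < 2:
            raise ValueError("need >= 2 post-bleach frames")
        if (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if (self.roi <= 0).any() or (self.cell <= 0).any():
            raise ValueError("intensities must be positive")


@dataclass
class FrapCurve:
    """Normalized recovery curve for one cell (post-bleach frames)."""

    times: np.ndarray
    norm1: np.ndarray  # photobleach-corrected I_N(t)
    norm2: np.ndarray  # min-shifted I_N2(t)
    norm_min: float  # I_N_min used in the shift
    cell_id: str = ""
    replicate_id: str = ""


@dataclass
class FrapResult:
    """Aggregate immobile fraction over replicates."""

    mean_if: float
    propagated_error: float
    replicate_means: list[float]
    replicate_sds: list[float]
    replicate_ns: list[int]


def normalize_trace(trace: FrapTrace) -> FrapCurve:
    """Double-normalize a FRAP trace.

    The first normalization divides out whole-cell photobleaching and
    sets the pre-bleach level to 1; the second shifts the post-bleach
    minimum to 0 keeping 1 fixed. The minimum is taken over post-bleach
    frames only.
    """
    pre_roi = trace.roi[: trace.n_pre].mean()
    pre_cell = trace.cell[: trace.n_pre].mean()
    norm1_all = (trace.roi / trace.cell) / (pre_roi / pre_cell)
    post = slice(trace.n_pre, None)
    t_post = trace.times[post]
    norm1 = norm1_all[post]
    nmin = float(norm1.min())
    if nmin >= 1:
        raise ValueError("no bleach detected: post-bleach minimum >= pre-bleach level")
    norm2 = (norm1 - nmin) / (1.0 - nmin)
    return FrapCurve(
        times=t_post,
        norm1=norm1,
        norm2=norm2,
        norm_min=nmin,
        cell_id=trace.cell_id,
        replicate_id=trace.replicate_id,
    )


def immobile_fraction(
    curve: FrapCurve,
    tail_window: tuple[float, float] = DEFAULT_TAIL_WINDOW,
    last_n_frames: int | None = None,
) -> float:
    """IF = 1 - mean of I_N2 over the recovery tail.

    By default the tail is the frames with t in ``tail_window``
    (inclusive); pass ``last_n_frames`` to use the final k frames
    instead.
    """
    if last_n_frames is not None:
        if last_n_frames < 2:
            raise ValueError("need >= 2 tail frames")
        tail = curve.norm2[-last_n_frames:]
    else:
        lo, hi = tail_window
        sel = (curve.times >= lo) & (curve.times <= hi)
        if sel.sum() < 2:
            raise ValueError("tail window contains < 2 frames")
        tail = curve.norm2[sel]
    return float(1.0 - tail.mean())


def aggregate_replicates(
    per_replicate: list[tuple[float, float, int]]
) -> FrapResult:
    """Combine per-replicate (mean IF, SD, n) summaries.

    Aggregate mean is the unweighted mean of replicate means; the error
    is propagated for uncorrelated replicates: sqrt(sum SD_i^2) / k.
    """
    if not per_replicate:
        raise ValueError("no replicates")
    means = [m for m, _, _ in per_replicate]
    sds = [s for _, s, _ in per_replicate]
    ns = [n for _, _, n in per_replicate]
    k = len(per_replicate)
    mean_if = float(np.mean(means))
    err = float(np.sqrt(np.sum(np.square(sds))) / k)
    return FrapResult(mean_if, err, means, sds, ns)


def mean_curve_with_error(
    curves_by_replicate: dict[str, list[FrapCurve]]
) -> pd.DataFrame:
    """Per-timepoint mean recovery curve with propagated error band.

    Within each replicate the per-cell curves are averaged (mean, SD);
    across replicates the same unweighted-mean / sqrt(sum SD^2)/k rule
    as for immobile fractions is applied per timepoint.
    """
    rep_means, rep_sds, times = [], [], None
    for curves in curves_by_replicate.values():
        stack = np.stack([c.norm2 for c in curves])
        if times is None:
            times = curves[0].times
        rep_means.append(stack.mean(axis=0))
        rep_sds.append(stack.std(axis=0, ddof=1) if len(curves) > 1 else np.zeros(stack.shape[1]))
    k = len(rep_means)
    mean = np.mean(rep_means, axis=0)
    err = np.sqrt(np.sum(np.square(rep_sds), axis=0)) / k
    return pd.DataFrame({"time_s": times, "mean_norm2": mean, "propagated_error": err})


def read_frap_traces(path, n_pre: int = N_PRE_DEFAULT) -> list[FrapTrace]:
    """Read traces from TSV: frame, time_s, roi_intensity, cell_intensity,
    cell_id, replicate_id."""
    df = pd.read_csv(path, sep="\t")
    traces = []
    for (rep, cell), g in df.groupby(["replicate_id", "cell_id"], sort=False):
        g = g.sort_values("frame")
        traces.append(
            FrapTrace(
                times=g["time_s"].to_numpy(),
                roi=g["roi_intensity"].to_numpy(),
                cell=g["cell_intensity"].to_numpy(),
                n_pre=n_pre,
                cell_id=str(cell),
                replicate_id=str(rep),
            )
        )
    return traces
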