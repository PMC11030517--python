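"""Synchrony statistics for trace sets: windowed deviation score,
pairwise zero-lag cross-correlation, sync fraction, spike-phase offsets,
and power-law scaling fits.

The deviation score quantifies how far one node's response departs from
the population-average response, per unit time. In a moving window whose
width equals the stimulus period T, every node's segment is linearly
rescaled to [0, 1]; the score of node i in that window is the absolute
area between its normalized segment and the population mean of the
normalized segments, divided by T. It is dimensionless, lies in [0, 1],
and approaches zero when all nodes synchronize perfectly. The same
operator applies unchanged to simulated voltage traces and to
calcium-recording-style response traces, because the window normalization
removes per-node affine scale and baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .qif import SpikeTrain

__all__ = [
    "TraceSet",
    "WindowConfig",
    "PairList",
    "SyncReport",
    "normalize_window",
    "deviation_score",
    "cross_correlation",
    "sync_fraction",
    "spike_phase_offset",
    "fit_scaling_exponent",
    "ScalingFit",
]


@dataclass
class TraceSet:
    """Per-node response series on a common uniform time grid.

    values is a DataFrame with one column per node (column name = node
    id); ``drive`` optionally carries the external forcing waveform on
    the same grid (excluded from all synchrony statistics); ``period``
    optionally records the stimulus period T.
    """

    times: np.ndarray
    values: pd.DataFrame
    period: float | None = None
    drive: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.values) != self.times.size:
            raise ValueError("times and values must have equal length")
        if self.times.size >= 2:
            steps = np.diff(self.times)
            if not np.allclose(steps, steps[0], rtol=1e-8, atol=0.0):
                raise ValueError("time grid must be uniform")
        if self.values.isna().any().any():
            raise ValueError("trace values must not contain missing entries")
        if self.drive is not None and len(self.drive) != self.times.size:
            raise ValueError("drive must share the time grid")

    @property
    def node_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    @property
    def dt(self) -> float:
        if self.times.size < 2:
            raise ValueError("need at least two samples for dt")
        return float(self.times[1] - self.times[0])

    def to_csv(self, path: str | Path, float_format: str = "%.10g") -> None:
        """Write as CSV: `time` column plus one column per node (and
        `drive` if present)."""
        df = self.values.copy()
        df.insert(0, "time", self.times)
        if self.drive is not None:
            df["drive"] = self.drive
        df.to_csv(path, index=False, float_format=float_format)

    @classmethod
    def from_csv(cls, path: str | Path, period: float | None = None) -> "TraceSet":
        df = pd.read_csv(path)
        if "time" not in df.columns:
            raise ValueError(f"{path}: trace file must contain a 'time' column")
        times = df.pop("time").to_numpy()
        drive = df.pop("drive").to_numpy() if "drive" in df.columns else None
        return cls(times=times, values=df, period=period, drive=drive)


@dataclass(frozen=True)
class WindowConfig:
    """Moving-window settings: width = stimulus period T; stride defaults
    to width/4."""

    width: float
    stride: float | None = None

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("window width must be positive")
        stride = self.stride if self.stride is not None else self.width / 4.0
        if not 0 < stride <= self.width:
            raise ValueError("require 0 < stride <= width")
        object.__setattr__(self, "stride", stride)


@dataclass
class PairList:
    """Neighbor pairs (node_i, node_j) with provenance.

    provenance is 'bridged' for pairs connected by patterned cell bridges
    and 'spatial_nearest' for nearest-in-space pairs of disconnected
    layouts.
    """

    pairs: pd.DataFrame  # columns: node_i, node_j, provenance

    def __post_init__(self) -> None:
        required = {"node_i", "node_j", "provenance"}
        if not required.issubset(self.pairs.columns):
            raise ValueError(f"pair table needs columns {sorted(required)}")
        pairs = self.pairs
        if (pairs["node_i"] == pairs["node_j"]).any():
            raise ValueError("self-pairs are not allowed")
        key = pairs.apply(
            lambda r: tuple(sorted((str(r["node_i"]), str(r["node_j"])))), axis=1
        )
        if key.duplicated().any():
            raise ValueError("duplicate pairs are not allowed")

    def __len__(self) -> int:
        return len(self.pairs)

    def to_csv(self, path: str | Path) -> None:
        self.pairs.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PairList":
        return cls(pd.read_csv(path))


@dataclass
class SyncReport:
    """Synchrony summary: per-node deviation scores, per-pair zero-lag
    correlations, and the fraction of pairs above the sync threshold."""

    node_scores: pd.Series
    pair_correlations: pd.DataFrame  # node_i, node_j, correlation
    sync_fraction: float
    threshold: float

    def summary(self) -> dict:
        return {
            "n_nodes": int(self.node_scores.size),
            "mean_deviation": float(self.node_scores.mean()),
            "sd_deviation": float(self.node_scores.std(ddof=1))
            if self.node_scores.size > 1
            else 0.0,
            "n_pairs": int(len(self.pair_correlations)),
            "mean_correlation": float(self.pair_correlations["correlation"].mean()),
            "sync_fraction": float(self.sync_fraction),
            "threshold": float(self.threshold),
        }


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------


def normalize_window(segment: np.ndarray) -> tuple[np.ndarray, bool]:
    """Affine-rescale one window segment to [0, 1].

    Returns (normalized, degenerate). A constant segment (max == min)
    maps to all zeros and is flagged degenerate instead of raising.
    """
    x = np.asarray(segment, dtype=float)
    if x.size < 2:
        raise ValueError("segment needs at least 2 samples")
    lo = x.min()
    rng = x.max() - lo
    if rng == 0:
        return np.zeros_like(x), True
    return (x - lo) / rng, False


def _window_layout(n_samples: int, width: float, stride: float, dt: float):
    """Sample counts for the moving window: (window length, hop, starts)."""
    n_w = int(round(width / dt)) + 1
    if n_w < 2:
        raise ValueError("window width must cover at least 2 samples")
    if n_w > n_samples:
        raise ValueError("window width exceeds record length")
    hop = max(1, int(round(stride / dt)))
    starts = range(0, n_samples - n_w + 1, hop)
    return n_w, hop, starts


def deviation_score(
    traces: TraceSet,
    window: WindowConfig,
    return_windows: bool = False,
):
    """Per-node windowed deviation from the population-average response.

    Within each window the segments of all nodes are rescaled to [0, 1]
    (:func:`normalize_window`); node i's window score is the trapezoidal
    integral of |R_iN - <R_N>_population| divided by the window width.
    The per-node score is the mean over windows, excluding windows where
    that node's segment is degenerate (constant). Degenerate segments
    still contribute their all-zero normalization to the population mean.

    With ``return_windows=True`` also returns the per-window score matrix
    (rows = window start times, columns = nodes, NaN where degenerate).
    """
    if traces.n_nodes < 2:
        raise ValueError("deviation score needs at least 2 nodes")
    values = traces.values.to_numpy(dtype=float)
    dt = traces.dt
    n_w, hop, starts = _window_layout(values.shape[0], window.width, window.stride, dt)
    width_t = (n_w - 1) * dt

    per_window = []
    start_times = []
    for s in starts:
        seg = values[s : s + n_w]  # (n_w, n_nodes)
        lo = seg.min(axis=0)
        rng = seg.max(axis=0) - lo
        degenerate = rng == 0
        safe = np.where(degenerate, 1.0, rng)
        norm = (seg - lo) / safe
        norm[:, degenerate] = 0.0
        pop = norm.mean(axis=1)
        score = np.trapezoid(np.abs(norm - pop[:, None]), dx=dt, axis=0) / width_t
        score[degenerate] = np.nan
        per_window.append(score)
        start_times.append(traces.times[s])

    win = np.array(per_window)  # (n_windows, n_nodes)
    with np.errstate(invalid="ignore"):
        node_scores = np.nanmean(win, axis=0)
    scores = pd.Series(node_scores, index=traces.values.columns, name="deviation")
    if return_windows:
        return scores, pd.DataFrame(
            win, index=pd.Index(start_times, name="window_start"),
            columns=traces.values.columns,
        )
    return scores


def cross_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Zero-lag Pearson correlation of two equal-length records."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant series")
    return float(np.corrcoef(x, y)[0, 1])


def sync_fraction(correlations: Sequence[float], threshold: float = 0.8) -> float:
    """Fraction of pairs whose correlation strictly exceeds threshold.

    The convention is strict: a pair at exactly the threshold does not
    count as well-synchronized.
    """
    corr = np.asarray(correlations, dtype=float)
    if corr.size == 0:
        raise ValueError("sync_fraction needs at least one pair")
    return float(np.mean(corr > threshold))


def spike_phase_offset(sa: SpikeTrain, sb: SpikeTrain, period: float) -> float:
    """Asymptotic spike-phase offset of two trains, folded to [0, T/2].

    Uses only spikes in the last third of the record (the first two
    thirds are treated as locking transient). For each late spike of
    train a, the circular distance modulo ``period`` to the nearest spike
    of train b is folded to [0, period/2]; the mean over late spikes is
    returned.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    ta, tb = sa.times, sb.times
    if ta.size == 0 or tb.size == 0:
        raise ValueError("need spikes in both trains")
    t_max = max(ta[-1], tb[-1])
    cut = 2.0 / 3.0 * t_max
    late_a = ta[ta >= cut]
    late_b = tb[tb >= cut]
    if late_a.size < 5 or late_b.size < 5:
        raise ValueError("need at least 5 post-transient spikes per train")
    idx = np.searchsorted(tb, late_a)
    idx0 = np.clip(idx - 1, 0, tb.size - 1)
    idx1 = np.clip(idx, 0, tb.size - 1)
    d = np.minimum(np.abs(late_a - tb[idx0]), np.abs(late_a - tb[idx1]))
    d = np.mod(d, period)
    folded = np.minimum(d, period - d)
    return float(folded.mean())


class ScalingFit(NamedTuple):
    exponent: float
    stderr: float


def fit_scaling_exponent(Ts: Sequence[float], mean_scores: Sequence[float]) -> ScalingFit:
    """Least-squares slope of log(score) vs log(T).

    A score proportional to T**-0.5 yields exponent -0.5 (the expected
    scaling when onset-delay variance grows linearly with the period).
    """
    Ts = np.asarray(Ts, dtype=float)
    scores = np.asarray(mean_scores, dtype=float)
    if Ts.size != scores.size:
        raise ValueError("Ts and mean_scores must have equal length")
    if Ts.size < 4:
        raise ValueError("need at least 4 period values for a scaling fit")
    if np.any(scores <= 0) or np.any(Ts <= 0):
        raise ValueError("scaling fit requires positive periods and scores")
    fit = linregress(np.log(Ts), np.log(scores))
    return ScalingFit(exponent=float(fit.slope), stderr=float(fit.stderr))
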