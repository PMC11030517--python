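"""Synthetic calcium-recording-style trace sets.

Emulates the structure of micropatterned-grid calcium recordings under a
square-wave ATP stimulus: each node responds to each stimulus onset after
a Poisson-distributed delay whose variance grows linearly with the
stimulus period T (the mechanism behind the ~T**-0.5 decay of the
deviation score), shaped by a calcium-transient-like double-exponential
kernel, with per-node amplitude heterogeneity and additive Gaussian
noise. Nodes sit on a grid of 20 um-radius circles with 30 um
edge-to-edge gaps; nearest-neighbor pairs are "bridged" independently
with probability p.

The generator deliberately does NOT emulate gap-junction coupling between
nodes (coupled dynamics come from the mechanistic network simulator) nor
any imaging artifacts; see the methods note for what this implies about
test coverage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import PairList, TraceSet

__all__ = [
    "StimulusSpec",
    "DelayModel",
    "KernelSpec",
    "DelayDraws",
    "SyntheticDataset",
    "make_stimulus",
    "sample_delays",
    "render_traces",
    "generate_dataset",
]

NODE_RADIUS_UM = 20.0
EDGE_GAP_UM = 30.0
CENTER_SPACING_UM = 2 * NODE_RADIUS_UM + EDGE_GAP_UM  # 70 um


@dataclass(frozen=True)
class StimulusSpec:
    """Square-wave stimulus: ON for duty*T then OFF, n_cycles repeats."""

    period: float  # T, seconds
    duty: float = 0.5
    n_cycles: int = 8
    sample_interval: float = 1.0  # seconds per sample

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if not 0 < self.duty < 1:
            raise ValueError("duty must lie in (0, 1)")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.period / self.sample_interval < 20:
            raise ValueError("need at least 20 samples per period")

    @property
    def times(self) -> np.ndarray:
        n = int(round(self.n_cycles * self.period / self.sample_interval))
        return np.arange(n) * self.sample_interval

    @property
    def onsets(self) -> np.ndarray:
        return np.arange(self.n_cycles) * self.period


@dataclass(frozen=True)
class DelayModel:
    """Onset delay dt ~ Poisson(rate_scale * T), in seconds.

    Variance equals the mean alpha*T, so the delay spread grows like
    sqrt(T) while the window grows like T — the origin of the T**-0.5
    deviation-score scaling.
    """

    rate_scale: float = 0.05  # alpha, per second

    def __post_init__(self) -> None:
        if self.rate_scale <= 0:
            raise ValueError("rate_scale must be positive")


@dataclass(frozen=True)
class KernelSpec:
    """Calcium-transient kernel: double exponential with rise < decay,
    peak-normalized to 1; per-node multiplicative amplitude jitter."""

    rise: float = 2.0  # seconds
    decay: float = 10.0  # seconds
    amplitude_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.rise <= 0 or self.decay <= 0:
            raise ValueError("rise and decay must be positive")
        if self.rise >= self.decay:
            raise ValueError("require rise < decay")
        if self.amplitude_sd < 0:
            raise ValueError("amplitude_sd must be non-negative")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        t_peak = (
            self.rise * self.decay / (self.decay - self.rise)
            * np.log(self.decay / self.rise)
        )
        peak = np.exp(-t_peak / self.decay) - np.exp(-t_peak / self.rise)
        tp = np.maximum(t, 0.0)
        out = np.where(t >= 0, np.exp(-tp / self.decay) - np.exp(-tp / self.rise), 0.0)
        return out / peak


@dataclass
class DelayDraws:
    """Per-node-per-cycle onset delays (seconds) plus clip bookkeeping."""

    delays: np.ndarray  # (n_nodes, n_cycles)
    n_clipped: int


@dataclass
class SyntheticDataset:
    """One generated recording: traces, grid layout, neighbor pairs,
    ground-truth delays, and a manifest that reproduces everything."""

    traces: TraceSet
    layout: pd.DataFrame  # node_id, row, col, x_um, y_um
    pairs: PairList
    delays: np.ndarray
    manifest: dict


def make_stimulus(spec: StimulusSpec) -> np.ndarray:
    """Binary square-wave stimulus sampled on the spec's time grid."""
    phase = np.mod(spec.times, spec.period)
    return (phase < spec.duty * spec.period).astype(float)


def sample_delays(
    n_nodes: int,
    n_cycles: int,
    delay: DelayModel,
    T: float,
    seed: int | np.random.Generator | None = None,
) -> DelayDraws:
    """Draw i.i.d. Poisson(alpha*T) onset delays per node per cycle.

    Delays are redrawn per cycle (activation timing noise is per
    stimulus, not a fixed node property) and clipped to the ON
    half-cycle; clip events are counted.
    """
    rng = np.random.default_rng(seed)
    mean = delay.rate_scale * T
    draws = rng.poisson(mean, size=(n_nodes, n_cycles)).astype(float)
    on_len = 0.5 * T
    n_clipped = int(np.sum(draws > on_len))
    return DelayDraws(delays=np.minimum(draws, on_len), n_clipped=n_clipped)


def render_traces(
    stimulus: StimulusSpec,
    delays: np.ndarray,
    kernel: KernelSpec,
    noise_sd: float = 0.005,
    seed: int | np.random.Generator | None = None,
) -> TraceSet:
    """Render node responses from stimulus onsets, delays and the kernel.

    Node i's response is 1.0 (fold-change baseline) plus its amplitude
    times the sum over cycles of kernel(t - onset_k - delay_ik), plus
    Gaussian noise of sd ``noise_sd``.
    """
    delays = np.asarray(delays, dtype=float)
    if delays.ndim != 2 or delays.shape[1] != stimulus.n_cycles:
        raise ValueError("delays must be (n_nodes, n_cycles)")
    rng = np.random.default_rng(seed)
    n_nodes = delays.shape[0]
    t = stimulus.times
    amplitudes = np.maximum(
        1.0 + kernel.amplitude_sd * rng.standard_normal(n_nodes), 0.05
    )
    values = np.empty((t.size, n_nodes))
    for i in range(n_nodes):
        resp = np.zeros_like(t)
        for k, onset in enumerate(stimulus.onsets):
            resp += kernel.evaluate(t - onset - delays[i, k])
        values[:, i] = 1.0 + amplitudes[i] * resp
    if noise_sd > 0:
        values += rng.normal(0.0, noise_sd, size=values.shape)
    df = pd.DataFrame(values, columns=[f"n{i:03d}" for i in range(n_nodes)])
    return TraceSet(times=t, values=df, period=stimulus.period)


def _grid_layout(rows: int, cols: int) -> pd.DataFrame:
    recs = [
        {
            "node_id": f"n{r * cols + c:03d}",
            "row": r,
            "col": c,
            "x_um": c * CENTER_SPACING_UM,
            "y_um": r * CENTER_SPACING_UM,
        }
        for r in range(rows)
        for c in range(cols)
    ]
    return pd.DataFrame(recs)


def _grid_pairs(rows: int, cols: int, p: float, rng: np.random.Generator) -> PairList:
    """Nearest-neighbor pairs: bridged independently at probability p;
    for p = 0 all nearest-neighbor pairs are emitted tagged
    spatial_nearest (disconnected layouts are still scored on pairs of
    nearest nodes in space)."""
    recs = []
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            for j in (i + 1 if c + 1 < cols else None, i + cols if r + 1 < rows else None):
                if j is None:
                    continue
                if p > 0 and rng.random() < p:
                    recs.append((f"n{i:03d}", f"n{j:03d}", "bridged"))
                elif p == 0:
                    recs.append((f"n{i:03d}", f"n{j:03d}", "spatial_nearest"))
    return PairList(pd.DataFrame(recs, columns=["node_i", "node_j", "provenance"]))


def generate_dataset(
    rows: int,
    cols: int,
    p: float,
    stimulus: StimulusSpec,
    delay: DelayModel | None = None,
    kernel: KernelSpec | None = None,
    noise_sd: float = 0.005,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> SyntheticDataset:
    """Generate a full synthetic recording (and optionally write files).

    Files written under ``outdir``: traces.csv (time + node columns),
    layout.csv, pairs.csv, and manifest.json capturing every parameter
    and seed so the dataset regenerates byte-identically.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    delay = delay or DelayModel()
    kernel = kernel or KernelSpec()
    ss = np.random.SeedSequence([seed])
    delay_ss, trace_ss, pair_ss = ss.spawn(3)
    n_nodes = rows * cols
    draws = sample_delays(
        n_nodes, stimulus.n_cycles, delay, stimulus.period,
        np.random.default_rng(delay_ss),
    )
    traces = render_traces(
        stimulus, draws.delays, kernel, noise_sd, np.random.default_rng(trace_ss)
    )
    pairs = _grid_pairs(rows, cols, p, np.random.default_rng(pair_ss))
    layout = _grid_layout(rows, cols)
    manifest = {
        "schema_version": 1,
        "rows": rows,
        "cols": cols,
        "p": p,
        "stimulus": asdict(stimulus),
        "delay": asdict(delay),
        "kernel": asdict(kernel),
        "noise_sd": noise_sd,
        "seed": seed,
        "n_clipped_delays": draws.n_clipped,
        "node_radius_um": NODE_RADIUS_UM,
        "edge_gap_um": EDGE_GAP_UM,
    }
    ds = SyntheticDataset(
        traces=traces, layout=layout, pairs=pairs, delays=draws.delays,
        manifest=manifest,
    )
    if outdir is not None:
        out = Path(outdir)
        try:
            out.mkdir(parents=True, exist_ok=True)
            traces.to_csv(out / "traces.csv")
            layout.to_csv(out / "layout.csv", index=False)
            pairs.to_csv(out / "pairs.csv")
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        except OSError as exc:
            raise OSError(f"failed writing synthetic dataset under {out}: {exc}") from exc
    return ds


def regenerate(manifest: dict, outdir: str | Path | None = None) -> SyntheticDataset:
    """Rebuild a dataset from its manifest alone (byte-identical files)."""
    return generate_dataset(
        rows=manifest["rows"],
        cols=manifest["cols"],
        p=manifest["p"],
        stimulus=StimulusSpec(**manifest["stimulus"]),
        delay=DelayModel(**manifest["delay"]),
        kernel=KernelSpec(**manifest["kernel"]),
        noise_sd=manifest["noise_sd"],
        seed=manifest["seed"],
        outdir=outdir,
    )
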