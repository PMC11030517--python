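"""Configuration-driven reproduction experiments and the trace-analysis
path.

Four model experiments mirror the study conditions:

- ``period_sweep``: uncoupled driven pairs (g = 0, g0 = 0.1), periods
  swept over {5, 10, 20, 50, 100, 200}, 1000 trials per period with
  intrinsic periods tau_1, tau_2 ~ Normal(T, T/10); mean deviation falls
  roughly like T**-0.5.
- ``coupling_sweep``: driven pairs at T = 20, g0 = 1/T, gap-junction
  coupling swept over g*T in {0, 0.5, 1, 2, 3}, 1000 trials; mean
  deviation rises with coupling (dynamic frustration).
- ``square_lattice``: 18x18 square lattice, T = 20, 8 drive periods,
  edge probability p in {0, 0.75}, 30 trials; more connectivity, more
  deviation.
- ``triangular_disruption``: 10x10 six-neighbor triangular lattice,
  disruption probability q in {0, 0.5}, 15 trials; more disruption, less
  deviation.

``analyze`` runs the synchrony metrics (deviation score, pairwise
zero-lag correlation, sync fraction at threshold 0.8) on any trace/pair
file pair, simulated or recorded. Trial counts are scaled by a
``scale`` factor for fast runs; effective counts are reported in outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import qif
from .metrics import (
    PairList,
    ScalingFit,
    SyncReport,
    TraceSet,
    WindowConfig,
    cross_correlation,
    deviation_score,
    fit_scaling_exponent,
    sync_fraction,
)
from .network import LatticeSpec, run_trials
from .qif import DriveParams, IntegratorConfig

__all__ = [
    "ExperimentConfig",
    "RunRecord",
    "exp_period_sweep",
    "exp_coupling_sweep",
    "exp_square_lattice",
    "exp_triangular_disruption",
    "analyze_recordings",
    "simulate_driven_pairs",
]

EXPERIMENTS = (
    "period_sweep",
    "coupling_sweep",
    "square_lattice",
    "triangular_disruption",
    "analyze",
    "synth",
)

_DEFAULT_TRIALS = {
    "period_sweep": 1000,
    "coupling_sweep": 1000,
    "square_lattice": 30,
    "triangular_disruption": 15,
}


class ExperimentConfig(BaseModel):
    """Validated experiment configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    experiment: Literal[
        "period_sweep",
        "coupling_sweep",
        "square_lattice",
        "triangular_disruption",
        "analyze",
        "synth",
    ]
    base_seed: int = 0
    scale: float = Field(default=1.0, gt=0)
    outdir: str | None = None

    # driven-pair sweeps
    T: float = Field(default=20.0, gt=0)
    T_grid: tuple[float, ...] = (5.0, 10.0, 20.0, 50.0, 100.0, 200.0)
    g0: float | None = None
    gT_grid: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 3.0)
    n_trials: int | None = None
    n_periods: float = Field(default=8.0, ge=1)

    # lattices
    rows: int = 18
    cols: int = 18
    p_values: tuple[float, ...] = (0.0, 0.75)
    q_values: tuple[float, ...] = (0.0, 0.5)
    g: float | None = None  # cell-cell coupling; default weak regime 1/(3T)

    # analyze
    trace_file: str | None = None
    pair_file: str | None = None
    threshold: float = 0.8

    # synth
    duty: float = 0.5
    n_cycles: int = 8
    sample_interval: float = 1.0
    p: float = 0.0
    noise_sd: float = 0.005
    rate_scale: float = 0.05

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.model_validate(data)

    def effective_trials(self) -> int:
        base = self.n_trials
        if base is None:
            base = _DEFAULT_TRIALS.get(self.experiment, 1)
        return max(1, int(round(base * self.scale)))

    def fingerprint(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunRecord:
    """Provenance of one experiment run: config hash, timings, outputs."""

    config_fingerprint: str
    timings: dict
    outputs: dict  # filename -> sha256

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "config_fingerprint": self.config_fingerprint,
                    "timings": self.timings,
                    "outputs": self.outputs,
                },
                indent=2,
            )
        )


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_outputs(outdir: str | Path | None, config: ExperimentConfig,
                   tables: dict[str, pd.DataFrame], summary: dict,
                   timings: dict) -> None:
    if outdir is None:
        return
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in tables.items():
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        written[path.name] = _checksum(path)
    spath = out / "summary.json"
    spath.write_text(json.dumps(summary, indent=2, default=float))
    written[spath.name] = _checksum(spath)
    RunRecord(config.fingerprint(), timings, written).to_json(out / "run_record.json")


# ---------------------------------------------------------------------------
# batched driven-pair machinery
# ---------------------------------------------------------------------------

_PAIR_BLOCK = np.array([[0.0, 1.0], [1.0, 0.0]])


def _sample_pair_periods(
    n_trials: int, T: float, rng: np.random.Generator
) -> np.ndarray:
    taus = rng.normal(T, T / 10.0, size=2 * n_trials)
    bad = taus <= T / 100.0
    while bad.any():
        taus[bad] = rng.normal(T, T / 10.0, size=int(bad.sum()))
        bad = taus <= T / 100.0
    return taus


def _pair_deviation_batch(
    trace_v: np.ndarray, dt: float, window: WindowConfig
) -> np.ndarray:
    """Per-trial mean deviation for a (L, n_trials, 2) trace block.

    Vectorized restatement of :func:`frustranet.metrics.deviation_score`
    for two-node populations; cross-checked against it in the test suite.
    """
    L = trace_v.shape[0]
    n_w = int(round(window.width / dt)) + 1
    hop = max(1, int(round(window.stride / dt)))
    width_t = (n_w - 1) * dt
    sums = np.zeros(trace_v.shape[1:])
    counts = np.zeros(trace_v.shape[1:])
    for s in range(0, L - n_w + 1, hop):
        seg = trace_v[s : s + n_w]
        lo = seg.min(axis=0)
        rng = seg.max(axis=0) - lo
        degenerate = rng == 0
        norm = (seg - lo) / np.where(degenerate, 1.0, rng)
        norm[:, degenerate] = 0.0
        pop = norm.mean(axis=2, keepdims=True)
        sc = np.trapezoid(np.abs(norm - pop), dx=dt, axis=0) / width_t
        ok = ~degenerate
        sums[ok] += sc[ok]
        counts[ok] += 1
    node_scores = np.divide(sums, counts, out=np.full_like(sums, np.nan),
                            where=counts > 0)
    return node_scores.mean(axis=1)


def simulate_driven_pairs(
    T: float,
    g: float,
    g0: float,
    n_trials: int,
    seed_pair: tuple[int, int],
    n_periods: float = 8.0,
    window: WindowConfig | None = None,
    chunk: int = 250,
) -> np.ndarray:
    """Simulate n_trials independent driven pairs; return per-trial mean
    deviation scores.

    Heterogeneous periods tau_1, tau_2 ~ Normal(T, T/10) per trial;
    initial voltages uniform on [0, 1); the drive unit starts at 0 and is
    shared (its trajectory is identical across trials). Trials are
    integrated jointly as a block-diagonal network in chunks.
    """
    window = window or WindowConfig(width=T)
    ss = np.random.SeedSequence(list(seed_pair))
    het_ss, ic_ss = ss.spawn(2)
    taus = _sample_pair_periods(n_trials, T, np.random.default_rng(het_ss))
    b_vals = np.asarray(qif.b_from_period(taus))
    v0 = np.random.default_rng(ic_ss).random(2 * n_trials)
    drive = DriveParams.from_period(T, g0)
    dt = min(T, float(taus.min())) / 1000.0
    cfg = IntegratorConfig(dt=dt)
    t_end = n_periods * T

    out = np.empty(n_trials)
    for start in range(0, n_trials, chunk):
        m = min(chunk, n_trials - start)
        sl = slice(2 * start, 2 * (start + m))
        adjacency = sp.kron(sp.identity(m), _PAIR_BLOCK, format="csr") if g > 0 else None
        _, trace, _ = qif.integrate_driven_system(
            b_vals[sl], adjacency, g, drive, v0[sl], 0.0, t_end, cfg=cfg
        )
        trace_v = trace[:, 1:].reshape(trace.shape[0], m, 2)
        out[start : start + m] = _pair_deviation_batch(trace_v, dt, window)
    return out


def simulate_pair_offsets(
    tau: float,
    gT: float,
    n_seeds: int,
    base_seed: int,
    n_periods: float = 60.0,
) -> np.ndarray:
    """Asymptotic spike-phase offsets (units of tau) for undriven
    identical pairs at coupling g = gT/tau, over random initial phases.

    All seeds are integrated jointly as a block-diagonal system with the
    drive coupling set to zero; offsets are measured on the last third of
    the record, folded to [0, tau/2].
    """
    from .metrics import spike_phase_offset
    from .qif import SpikeTrain

    b = qif.b_from_period(tau)
    v0 = np.random.default_rng(
        np.random.SeedSequence([base_seed, 17])
    ).random(2 * n_seeds)
    adjacency = sp.kron(sp.identity(n_seeds), _PAIR_BLOCK, format="csr")
    drive = DriveParams(b0=qif.b_from_period(tau), g0=0.0)
    _, _, spikes = qif.integrate_driven_system(
        np.full(2 * n_seeds, b),
        adjacency,
        gT / tau,
        drive,
        v0,
        0.0,
        n_periods * tau,
        cfg=IntegratorConfig(dt=tau / 1000.0),
        record_trace=False,
    )
    offs = np.empty(n_seeds)
    for k in range(n_seeds):
        sa, sb = SpikeTrain(spikes[1 + 2 * k]), SpikeTrain(spikes[2 + 2 * k])
        offs[k] = spike_phase_offset(sa, sb, tau) / tau
    return offs


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------


def exp_period_sweep(config: ExperimentConfig) -> tuple[pd.DataFrame, ScalingFit | None]:
    """Driving-period sweep for uncoupled driven pairs (g = 0).

    Returns (table with per-T mean/sd deviation, log-log scaling fit or
    None when the grid is too short for a fit).
    """
    if config.experiment != "period_sweep":
        raise ValueError("config.experiment must be 'period_sweep'")
    g0 = 0.1 if config.g0 is None else config.g0
    n_trials = config.effective_trials()
    t0 = time.perf_counter()
    rows = []
    for iT, T in enumerate(config.T_grid):
        devs = simulate_driven_pairs(
            T, 0.0, g0, n_trials, (config.base_seed, iT), config.n_periods
        )
        rows.append(
            {
                "T": T,
                "mean_deviation": devs.mean(),
                "sd_deviation": devs.std(ddof=1) if devs.size > 1 else 0.0,
                "n_trials": n_trials,
            }
        )
    table = pd.DataFrame(rows)
    fit = None
    if len(table) >= 4 and (table["mean_deviation"] > 0).all():
        fit = fit_scaling_exponent(table["T"], table["mean_deviation"])
    summary = {
        "experiment": "period_sweep",
        "g0": g0,
        "n_trials": n_trials,
        "exponent": None if fit is None else fit.exponent,
        "exponent_stderr": None if fit is None else fit.stderr,
    }
    _write_outputs(config.outdir, config, {"period_sweep": table}, summary,
                   {"total_s": time.perf_counter() - t0})
    return table, fit


def exp_coupling_sweep(config: ExperimentConfig) -> pd.DataFrame:
    """Gap-junction coupling sweep for driven pairs at fixed T.

    Heterogeneity and initial conditions are drawn once and shared across
    coupling values, so the sweep isolates the effect of g.
    """
    if config.experiment != "coupling_sweep":
        raise ValueError("config.experiment must be 'coupling_sweep'")
    T = config.T
    g0 = (1.0 / T) if config.g0 is None else config.g0
    n_trials = config.effective_trials()
    t0 = time.perf_counter()
    rows = []
    for gT in config.gT_grid:
        devs = simulate_driven_pairs(
            T, gT / T, g0, n_trials, (config.base_seed, 0), config.n_periods
        )
        rows.append(
            {
                "gT": gT,
                "g": gT / T,
                "mean_deviation": devs.mean(),
                "sd_deviation": devs.std(ddof=1) if devs.size > 1 else 0.0,
                "sem_deviation": devs.std(ddof=1) / np.sqrt(devs.size)
                if devs.size > 1
                else 0.0,
                "n_trials": n_trials,
            }
        )
    table = pd.DataFrame(rows)
    summary = {"experiment": "coupling_sweep", "T": T, "g0": g0, "n_trials": n_trials}
    _write_outputs(config.outdir, config, {"coupling_sweep": table}, summary,
                   {"total_s": time.perf_counter() - t0})
    return table


def _lattice_sweep(config: ExperimentConfig, topology: str,
                   sweep_values: Sequence[float]) -> tuple[pd.DataFrame, pd.DataFrame]:
    T = config.T
    g = config.g if config.g is not None else 1.0 / (3.0 * T)  # weak regime gT = 1/3
    g0 = config.g0 if config.g0 is not None else 1.0 / T
    n_trials = config.effective_trials()
    per_trial = []
    for value in sweep_values:
        spec = (
            LatticeSpec("square", config.rows, config.cols, p=value)
            if topology == "square"
            else LatticeSpec("triangular", config.rows, config.cols, q=value)
        )
        results = run_trials(
            spec, T, g, g0, n_trials, config.base_seed, n_periods=config.n_periods
        )
        for res in results:
            per_trial.append(
                {
                    "p_or_q": value,
                    "trial": res.trial,
                    "mean_deviation": res.mean_deviation,
                    "sd_deviation": res.sd_deviation,
                }
            )
    trial_table = pd.DataFrame(per_trial)
    agg = (
        trial_table.groupby("p_or_q")["mean_deviation"]
        .agg(["mean", "std"])
        .reset_index()
        .rename(columns={"mean": "mean_deviation", "std": "sd_deviation"})
    )
    agg["n_trials"] = n_trials
    return trial_table, agg


def exp_square_lattice(config: ExperimentConfig) -> pd.DataFrame:
    """18x18 square-lattice trials across edge probabilities p.

    Reports per-p aggregates and whether mean deviation at the largest p
    exceeds that at the smallest (connectivity-induced frustration)."""
    if config.experiment != "square_lattice":
        raise ValueError("config.experiment must be 'square_lattice'")
    t0 = time.perf_counter()
    trial_table, agg = _lattice_sweep(config, "square", config.p_values)
    agg = agg.rename(columns={"p_or_q": "p"})
    means = agg.set_index("p")["mean_deviation"]
    summary = {
        "experiment": "square_lattice",
        "T": config.T,
        "frustration_direction_ok": bool(
            means.loc[max(config.p_values)] > means.loc[min(config.p_values)]
        ),
    }
    _write_outputs(config.outdir, config,
                   {"square_lattice": agg, "square_lattice_trials": trial_table},
                   summary, {"total_s": time.perf_counter() - t0})
    return agg


def exp_triangular_disruption(config: ExperimentConfig) -> pd.DataFrame:
    """10x10 triangular-lattice trials across disruption probabilities q.

    Reports per-q aggregates and whether disruption lowers the mean
    deviation (synchrony rescue by removing gap junctions)."""
    if config.experiment != "triangular_disruption":
        raise ValueError("config.experiment must be 'triangular_disruption'")
    t0 = time.perf_counter()
    trial_table, agg = _lattice_sweep(config, "triangular", config.q_values)
    agg = agg.rename(columns={"p_or_q": "q"})
    means = agg.set_index("q")["mean_deviation"]
    summary = {
        "experiment": "triangular_disruption",
        "T": config.T,
        "rescue_direction_ok": bool(
            means.loc[max(config.q_values)] < means.loc[min(config.q_values)]
        ),
    }
    _write_outputs(config.outdir, config,
                   {"triangular_disruption": agg,
                    "triangular_disruption_trials": trial_table},
                   summary, {"total_s": time.perf_counter() - t0})
    return agg


def analyze_recordings(
    trace_file: str | Path,
    pair_file: str | Path,
    T: float,
    window: WindowConfig | None = None,
    threshold: float = 0.8,
    outdir: str | Path | None = None,
) -> SyncReport:
    """Score a recorded (or simulated) trace set: deviation per node,
    zero-lag correlation per neighbor pair, and the sync fraction at the
    given threshold."""
    if T <= 0:
        raise ValueError("T must be positive")
    traces = TraceSet.from_csv(trace_file, period=T)
    pairs = PairList.from_csv(pair_file)
    window = window or WindowConfig(width=T)
    scores = deviation_score(traces, window)
    known = set(traces.node_ids)
    corr_rows = []
    for _, row in pairs.pairs.iterrows():
        a, b = str(row["node_i"]), str(row["node_j"])
        if a not in known or b not in known:
            raise KeyError(
                f"pair ({a}, {b}) references node ids missing from {trace_file}"
            )
        corr_rows.append(
            {
                "node_i": a,
                "node_j": b,
                "correlation": cross_correlation(
                    traces.values[a].to_numpy(), traces.values[b].to_numpy()
                ),
            }
        )
    corr = pd.DataFrame(corr_rows)
    psync = sync_fraction(corr["correlation"].to_numpy(), threshold)
    report = SyncReport(
        node_scores=scores, pair_correlations=corr, sync_fraction=psync,
        threshold=threshold,
    )
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        scores.rename_axis("node_id").reset_index().to_csv(
            out / "node_scores.csv", index=False
        )
        corr.to_csv(out / "pair_correlations.csv", index=False)
        (out / "summary.json").write_text(json.dumps(report.summary(), indent=2))
    return report
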