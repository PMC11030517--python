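"""Lattice networks of driven, gap-junction-coupled QIF units.

Two layouts mirror the experimental geometries: a square lattice whose
nearest-neighbor edges are present independently with probability p
(micropatterned bridge probability), and a six-neighbor triangular
lattice in which each node is independently "disrupted" with probability
q — a disrupted node loses all its gap-junction edges but keeps receiving
the external drive (the drive models bath-applied ATP, which reaches
every cell). Boundaries are non-periodic: edge and corner nodes simply
have fewer neighbors, matching a finite field of view.

Heterogeneity enters through per-node intrinsic periods tau_i drawn from
Normal(T, T/10) and converted to drive parameters b_i via the analytic
period inverse.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import qif
from .metrics import TraceSet, WindowConfig, deviation_score
from .qif import DriveParams, IntegratorConfig, NeuronParams

__all__ = [
    "LatticeSpec",
    "NetworkModel",
    "TrialResult",
    "build_square_lattice",
    "build_triangular_lattice",
    "sample_heterogeneity",
    "diffusive_coupling",
    "integrate_network",
    "run_trials",
]


@dataclass(frozen=True)
class LatticeSpec:
    """Lattice layout: square with edge probability p, or triangular with
    node-disruption probability q."""

    topology: str  # "square" | "triangular"
    rows: int
    cols: int
    p: float | None = None
    q: float | None = None

    def __post_init__(self) -> None:
        if self.topology not in ("square", "triangular"):
            raise ValueError("topology must be 'square' or 'triangular'")
        if self.rows < 2 or self.cols < 2:
            raise ValueError("lattice dimensions must be >= 2")
        if self.topology == "square":
            if self.p is None or self.q is not None:
                raise ValueError("square lattice takes edge probability p only")
            if not 0 <= self.p <= 1:
                raise ValueError("p must lie in [0, 1]")
        else:
            if self.q is None or self.p is not None:
                raise ValueError("triangular lattice takes disruption probability q only")
            if not 0 <= self.q <= 1:
                raise ValueError("q must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols


@dataclass
class NetworkModel:
    """A lattice of QIF units with shared coupling g and common drive."""

    graph: nx.Graph
    b_values: np.ndarray
    g: float
    drive: DriveParams
    neuron: NeuronParams = field(default_factory=lambda: NeuronParams(b=1.0))

    def __post_init__(self) -> None:
        self.b_values = np.asarray(self.b_values, dtype=float)
        n = self.graph.number_of_nodes()
        if self.b_values.shape != (n,):
            raise ValueError("b_values must have one entry per node")
        if self.g < 0:
            raise ValueError("g must be non-negative")
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("self-loops are not allowed")


@dataclass
class TrialResult:
    """One lattice trial: per-node deviation scores plus aggregates."""

    trial: int
    seed: int
    node_scores: pd.Series
    mean_deviation: float
    sd_deviation: float
    config_fingerprint: str


def _flat_grid_graph(rows: int, cols: int) -> nx.Graph:
    G = nx.Graph()
    for r in range(rows):
        for c in range(cols):
            G.add_node(r * cols + c, row=r, col=c)
    return G


def build_square_lattice(
    rows: int, cols: int, p: float, seed: int | np.random.Generator | None = None
) -> nx.Graph:
    """Square lattice with each nearest-neighbor edge present with
    probability p (non-periodic boundaries).

    Candidate edges are visited in a fixed row-major order (right edge
    then down edge per node) with one uniform draw each, so for a fixed
    seed the edge sets are nested across p.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    G = _flat_grid_graph(rows, cols)
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if c + 1 < cols and rng.random() < p:
                G.add_edge(i, i + 1)
            if r + 1 < rows and rng.random() < p:
                G.add_edge(i, i + cols)
    return G


def _triangular_neighbors(r: int, c: int, rows: int, cols: int):
    """Row-offset triangular scheme: (r, c) neighbors are (r, c+-1),
    (r+-1, c) and (r+-1, c + (-1)**r); interior nodes have degree 6."""
    s = -1 if r % 2 else 1
    for rr, cc in ((r, c - 1), (r, c + 1), (r - 1, c), (r + 1, c),
                   (r - 1, c + s), (r + 1, c + s)):
        if 0 <= rr < rows and 0 <= cc < cols:
            yield rr, cc


def build_triangular_lattice(
    rows: int, cols: int, q: float, seed: int | np.random.Generator | None = None
) -> tuple[nx.Graph, set[int]]:
    """Six-neighbor triangular lattice with node disruption probability q.

    The full lattice is built first; each node is independently marked
    disrupted with probability q and all of its edges removed. Disrupted
    nodes stay in the graph (flagged via the 'disrupted' node attribute)
    and still receive the external drive.
    """
    if not 0 <= q <= 1:
        raise ValueError("q must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    G = _flat_grid_graph(rows, cols)
    for r in range(rows):
        for c in range(cols):
            for rr, cc in _triangular_neighbors(r, c, rows, cols):
                G.add_edge(r * cols + c, rr * cols + cc)
    disrupted = set(np.nonzero(rng.random(rows * cols) < q)[0].tolist())
    for node in disrupted:
        G.remove_edges_from(list(G.edges(node)))
    nx.set_node_attributes(G, {i: (i in disrupted) for i in G.nodes}, "disrupted")
    return G, disrupted


def sample_heterogeneity(
    n_nodes: int, T: float, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Per-node drive parameters b_i with periods tau_i ~ Normal(T, T/10).

    Draws are resampled while tau_i <= T/100 (guard against non-positive
    periods, vanishingly rare at sd = T/10) and inverted through the
    analytic period formula.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    rng = np.random.default_rng(seed)
    taus = rng.normal(T, T / 10.0, size=n_nodes)
    bad = taus <= T / 100.0
    while bad.any():
        taus[bad] = rng.normal(T, T / 10.0, size=int(bad.sum()))
        bad = taus <= T / 100.0
    return np.asarray(qif.b_from_period(taus))


def diffusive_coupling(adjacency, g: float, v: np.ndarray) -> np.ndarray:
    """Per-node gap-junction term g * sum_j A_ij (v_j - v_i).

    Sums to zero over nodes (diffusive conservation)."""
    import scipy.sparse as sp

    A = sp.csr_matrix(adjacency)
    deg = np.asarray(A.sum(axis=1)).ravel()
    return g * (A @ v - deg * v)


def integrate_network(
    model: NetworkModel,
    n_periods: float = 8,
    cfg: IntegratorConfig | None = None,
    v0: np.ndarray | None = None,
    u0: float = 0.0,
    seed: int | None = None,
) -> TraceSet:
    """Integrate the driven lattice for n_periods drive periods.

    Each node obeys dv_i/dt = b_i + v_i**2 + g * sum_j A_ij (v_j - v_i)
    + g0 * (u - v_i) with per-node reset; u is the shared drive unit.
    Initial voltages default to uniform draws on [v_reset, v_peak) from
    ``seed`` (or ``cfg.seed``). Returns a TraceSet over the nodes with
    the drive trace attached.
    """
    if n_periods < 1:
        raise ValueError("n_periods must be >= 1")
    n = model.graph.number_of_nodes()
    T = model.drive.period
    if v0 is None:
        rng_seed = seed if seed is not None else (cfg.seed if cfg else None)
        rng = np.random.default_rng(rng_seed)
        v0 = model.neuron.v_reset + rng.random(n) * (
            model.neuron.v_peak - model.neuron.v_reset
        )
    nodes = sorted(model.graph.nodes)
    adjacency = nx.to_scipy_sparse_array(model.graph, nodelist=nodes, format="csr")
    times, trace, _spikes = qif.integrate_driven_system(
        model.b_values,
        adjacency,
        model.g,
        model.drive,
        np.asarray(v0, dtype=float),
        u0,
        t_end=n_periods * T,
        cfg=cfg,
        v_reset=model.neuron.v_reset,
        v_peak=model.neuron.v_peak,
    )
    values = pd.DataFrame(trace[:, 1:], columns=[f"n{i:03d}" for i in nodes])
    return TraceSet(times=times, values=values, period=T, drive=trace[:, 0])


def _fingerprint(payload: dict) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_trials(
    lattice: LatticeSpec,
    T: float,
    g: float,
    g0: float,
    n_trials: int,
    base_seed: int,
    n_periods: float = 8,
    window: WindowConfig | None = None,
) -> list[TrialResult]:
    """Run repeated lattice trials and score synchrony per trial.

    Each trial draws a fresh lattice, fresh heterogeneity, and fresh
    initial conditions from deterministic child streams of
    ``(base_seed, trial)``; the three streams are independent, so e.g.
    changing p alone does not reshuffle the b_i draws. Deviation scores
    use a moving window of width T (stride T/4 by default) over the node
    traces.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    window = window or WindowConfig(width=T)
    fingerprint = _fingerprint(
        {
            "lattice": lattice,
            "T": T,
            "g": g,
            "g0": g0,
            "n_trials": n_trials,
            "base_seed": base_seed,
            "n_periods": n_periods,
            "window": (window.width, window.stride),
        }
    )
    drive = DriveParams.from_period(T, g0)
    results: list[TrialResult] = []
    for trial in range(n_trials):
        ss = np.random.SeedSequence([base_seed, trial])
        lat_ss, het_ss, ic_ss = ss.spawn(3)
        if lattice.topology == "square":
            G = build_square_lattice(
                lattice.rows, lattice.cols, lattice.p, np.random.default_rng(lat_ss)
            )
        else:
            G, _ = build_triangular_lattice(
                lattice.rows, lattice.cols, lattice.q, np.random.default_rng(lat_ss)
            )
        b_values = sample_heterogeneity(
            lattice.n_nodes, T, np.random.default_rng(het_ss)
        )
        rng_ic = np.random.default_rng(ic_ss)
        v0 = rng_ic.random(lattice.n_nodes)
        model = NetworkModel(
            graph=G, b_values=b_values, g=g, drive=drive, neuron=NeuronParams(b=1.0)
        )
        traces = integrate_network(model, n_periods=n_periods, v0=v0)
        scores = deviation_score(traces, window)
        results.append(
            TrialResult(
                trial=trial,
                seed=base_seed,
                node_scores=scores,
                mean_deviation=float(scores.mean()),
                sd_deviation=float(scores.std(ddof=1)),
                config_fingerprint=fingerprint,
            )
        )
    return results
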