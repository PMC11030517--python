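"""Quadratic integrate-and-fire (QIF) dynamics near the SNHO bifurcation.

The QIF neuron is the minimal excitable unit exhibiting a saddle-node
homoclinic orbit (SNHO) bifurcation: a voltage-like variable obeys

    dv/dt = b + v**2

until it reaches ``v_peak``, at which point it is reset to ``v_reset``.
For ``v_reset = 0``, ``v_peak = 1`` and ``b > 0`` the unit spikes tonically
with period ``tau = b**-0.5 * atan(b**-0.5)``; small positive ``b`` places
the unit close to the SNHO point ``(b, v_reset) = (0, 0)``, where diffusive
(gap-junction-like) coupling is known to favor anti-phase locking.

This module provides the single-unit, symmetric-pair and periodically
driven dynamics, the analytic period and its inverse, and regime
classification in the ``(b, v_reset)`` plane.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import brentq

__all__ = [
    "Regime",
    "NeuronParams",
    "PairParams",
    "DriveParams",
    "IntegratorConfig",
    "Trace",
    "SpikeTrain",
    "qif_period",
    "b_from_period",
    "classify_regime",
    "integrate_qif",
    "integrate_pair",
    "integrate_driven_pair",
    "integrate_driven_system",
]


class Regime(enum.Enum):
    """Dynamical regime of a QIF unit in the ``(b, v_reset)`` plane."""

    TONIC_SPIKING = "tonic_spiking"
    EXCITABLE = "excitable"
    RESET_ABOVE_SADDLE_SPIKING = "reset_above_saddle_spiking"
    ON_BIFURCATION = "on_bifurcation"


@dataclass(frozen=True)
class NeuronParams:
    """One excitable QIF unit.

    Parameters
    ----------
    b : drive parameter (time**-2). ``b > 0`` spikes tonically; ``b < 0``
        creates a stable rest state at ``-sqrt(-b)`` and a saddle at
        ``+sqrt(-b)``.
    v_reset : post-spike reset voltage (dimensionless).
    v_peak : spike/reset threshold (dimensionless).
    """

    b: float
    v_reset: float = 0.0
    v_peak: float = 1.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.v_peak):
            raise ValueError("v_peak must be finite")
        if not self.v_reset < self.v_peak:
            raise ValueError("require v_reset < v_peak")


@dataclass(frozen=True)
class PairParams:
    """Two QIF units with symmetric diffusive coupling g*(v_j - v_i)."""

    b1: float
    b2: float
    g: float
    v_reset: float = 0.0
    v_peak: float = 1.0

    def __post_init__(self) -> None:
        if self.g < 0:
            raise ValueError("coupling strength g must be non-negative")
        if not self.v_reset < self.v_peak:
            raise ValueError("require v_reset < v_peak")


@dataclass(frozen=True)
class DriveParams:
    """Periodic drive unit u: du/dt = b0 + u**2 with reset 1 -> 0.

    The drive spikes with period ``T = b0**-0.5 * atan(b0**-0.5)`` and
    couples one-way into each neuron with strength ``g0``.
    """

    b0: float
    g0: float

    def __post_init__(self) -> None:
        if self.b0 <= 0:
            raise ValueError("b0 must be positive (periodic drive)")
        if self.g0 < 0:
            raise ValueError("g0 must be non-negative")

    @property
    def period(self) -> float:
        return qif_period(self.b0)

    @classmethod
    def from_period(cls, T: float, g0: float) -> "DriveParams":
        """Build a drive with prescribed period T."""
        return cls(b0=b_from_period(T), g0=g0)


@dataclass(frozen=True)
class IntegratorConfig:
    """Fixed-step integrator settings.

    dt must satisfy ``dt <= tau_min / 200`` where ``tau_min`` is the
    smallest analytic period among tonically spiking units in the system;
    the default used throughout the package is ``tau_min / 1000``.
    """

    dt: float
    method: str = "rk4"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.method not in ("euler", "rk4"):
            raise ValueError("method must be 'euler' or 'rk4'")


@dataclass
class Trace:
    """Voltage samples of one unit on a uniform time grid."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class SpikeTrain:
    """Ordered reset-event (threshold-crossing) times of one unit."""

    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def intervals(self) -> np.ndarray:
        return np.diff(self.times)


# ---------------------------------------------------------------------------
# analytic period and inverse
# ---------------------------------------------------------------------------


def qif_period(b):
    """Spiking period of the QIF unit with v_reset = 0, v_peak = 1.

    tau(b) = b**-0.5 * atan(b**-0.5), the 0 -> 1 transit time of
    dv/dt = b + v**2 (strictly decreasing in b).
    """
    b_arr = np.asarray(b, dtype=float)
    if np.any(b_arr <= 0):
        raise ValueError("qif_period requires b > 0")
    rb = np.sqrt(b_arr)
    tau = np.arctan(1.0 / rb) / rb
    return float(tau) if np.isscalar(b) or b_arr.ndim == 0 else tau


def b_from_period(tau):
    """Invert tau(b) = b**-0.5 * atan(b**-0.5) by bracketed root-finding.

    Round-trips with :func:`qif_period` to relative tolerance better than
    1e-10 over tau in [0.1, 1000].
    """
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr <= 0):
        raise ValueError("b_from_period requires tau > 0")

    def _solve(t: float) -> float:
        # bracket the monotone-decreasing forward map
        lo = hi = 1.0
        while qif_period(hi) > t:
            hi *= 10.0
        while qif_period(lo) < t:
            lo /= 10.0
        return brentq(lambda b: qif_period(b) - t, lo, hi, xtol=1e-300, rtol=1e-15)

    if np.isscalar(tau) or tau_arr.ndim == 0:
        return _solve(float(tau_arr))
    return np.array([_solve(t) for t in tau_arr.ravel()]).reshape(tau_arr.shape)


def classify_regime(b: float, v_reset: float, v_peak: float = 1.0) -> Regime:
    """Classify a QIF unit in the (b, v_reset) bifurcation plane.

    For b < 0 the fixed points of b + v**2 are a stable rest state at
    -sqrt(-b) and a saddle at +sqrt(-b); the saddle-node line b = 0 and the
    homoclinic line v_reset = +sqrt(-b) are reported explicitly as
    ON_BIFURCATION rather than silently assigned to a neighboring regime.
    """
    if not v_reset < v_peak:
        raise ValueError("require v_reset < v_peak")
    if b > 0:
        return Regime.TONIC_SPIKING
    if b == 0:
        return Regime.ON_BIFURCATION
    saddle = math.sqrt(-b)
    if v_reset == saddle:
        return Regime.ON_BIFURCATION
    if v_reset < saddle:
        return Regime.EXCITABLE
    return Regime.RESET_ABOVE_SADDLE_SPIKING


# ---------------------------------------------------------------------------
# fixed-step integration with interpolated reset
# ---------------------------------------------------------------------------


def _integrate_reset_system(
    deriv: Callable[[float, np.ndarray], np.ndarray],
    y0: np.ndarray,
    t_end: float,
    dt: float,
    v_reset: np.ndarray,
    v_peak: np.ndarray,
    method: str = "rk4",
    record_trace: bool = True,
):
    """Integrate dy/dt = deriv(t, y) with per-component reset at v_peak.

    When a step carries a component across its v_peak, the crossing time is
    located by linear interpolation within the step and recorded as a
    spike; the component is set to v_reset at that instant and advanced
    over the step remainder with a single explicit Euler sub-step (error
    O(dt) confined to the reset step).
    """
    y = np.array(y0, dtype=float)
    n = y.size
    n_steps = int(round(t_end / dt))
    if n_steps < 1:
        raise ValueError("t_end must cover at least one step")
    times = np.arange(n_steps + 1) * dt
    trace = np.empty((n_steps + 1, n)) if record_trace else None
    if record_trace:
        trace[0] = y
    spike_t: list[list[float]] = [[] for _ in range(n)]

    rk4 = method == "rk4"
    half = 0.5 * dt
    sixth = dt / 6.0
    for k in range(n_steps):
        t = k * dt
        if rk4:
            k1 = deriv(t, y)
            k2 = deriv(t + half, y + half * k1)
            k3 = deriv(t + half, y + half * k2)
            k4 = deriv(t + dt, y + dt * k3)
            y_new = y + sixth * (k1 + 2.0 * (k2 + k3) + k4)
        else:
            y_new = y + dt * deriv(t, y)

        crossed = y_new >= v_peak
        if crossed.any():
            idx = np.nonzero(crossed)[0]
            frac = (v_peak[idx] - y[idx]) / (y_new[idx] - y[idx])
            frac = np.clip(frac, 0.0, 1.0)
            for j, f in zip(idx, frac):
                spike_t[j].append(t + f * dt)
            y_new[idx] = v_reset[idx]
            # advance the step remainder from the reset value
            d = deriv(t + dt, y_new)
            y_new[idx] += d[idx] * (1.0 - frac) * dt
        y = y_new
        if record_trace:
            trace[k + 1] = y

    spikes = [np.asarray(s) for s in spike_t]
    return times, trace, spikes


def _default_dt(periods: Sequence[float], t_end: float) -> float:
    """Default step: smallest analytic period / 1000 (or t_end/5000 if none)."""
    finite = [p for p in periods if p is not None and math.isfinite(p)]
    if finite:
        return min(finite) / 1000.0
    return t_end / 5000.0


def _check_dt(dt: float, periods: Sequence[float]) -> None:
    finite = [p for p in periods if p is not None and math.isfinite(p)]
    if finite and dt > min(finite) / 200.0:
        raise ValueError(
            f"dt={dt} too coarse: must be <= tau_min/200 = {min(finite) / 200.0}"
        )


def integrate_qif(
    params: NeuronParams,
    v0: float,
    t_end: float,
    cfg: IntegratorConfig | None = None,
) -> tuple[Trace, SpikeTrain]:
    """Integrate one QIF unit from v0; returns sampled trace and spikes."""
    if not (params.v_reset <= v0 < params.v_peak):
        raise ValueError("v0 must lie in [v_reset, v_peak)")
    tau = qif_period(params.b) if params.b > 0 else None
    if cfg is None:
        cfg = IntegratorConfig(dt=_default_dt([tau], t_end))
    _check_dt(cfg.dt, [tau])
    b = params.b

    def f(t, y):
        return b + y * y

    times, trace, spikes = _integrate_reset_system(
        f,
        np.array([v0]),
        t_end,
        cfg.dt,
        np.array([params.v_reset]),
        np.array([params.v_peak]),
        method=cfg.method,
    )
    return Trace(times, trace[:, 0]), SpikeTrain(spikes[0])


def integrate_pair(
    pair: PairParams,
    v0s: Sequence[float],
    t_end: float,
    cfg: IntegratorConfig | None = None,
) -> tuple[tuple[Trace, Trace], tuple[SpikeTrain, SpikeTrain]]:
    """Integrate the symmetric diffusively coupled pair.

    dv1/dt = b1 + v1**2 + g*(v2 - v1),  dv2/dt = b2 + v2**2 + g*(v1 - v2),
    each unit resetting independently; the partner sees the post-reset
    value from the crossing instant onward (purely diffusive coupling, no
    transmitted spike pulse).
    """
    v0s = np.asarray(v0s, dtype=float)
    if v0s.shape != (2,):
        raise ValueError("v0s must contain two initial voltages")
    taus = [qif_period(b) if b > 0 else None for b in (pair.b1, pair.b2)]
    if cfg is None:
        cfg = IntegratorConfig(dt=_default_dt(taus, t_end))
    _check_dt(cfg.dt, taus)
    b = np.array([pair.b1, pair.b2])
    g = pair.g

    def f(t, y):
        return b + y * y + g * (y[::-1] - y)

    times, trace, spikes = _integrate_reset_system(
        f,
        v0s,
        t_end,
        cfg.dt,
        np.full(2, pair.v_reset),
        np.full(2, pair.v_peak),
        method=cfg.method,
    )
    traces = (Trace(times, trace[:, 0]), Trace(times, trace[:, 1]))
    return traces, (SpikeTrain(spikes[0]), SpikeTrain(spikes[1]))


def integrate_driven_system(
    b_values: np.ndarray,
    adjacency: sp.spmatrix | np.ndarray | None,
    g: float,
    drive: DriveParams,
    v0: np.ndarray,
    u0: float,
    t_end: float,
    cfg: IntegratorConfig | None = None,
    v_reset: float = 0.0,
    v_peak: float = 1.0,
    record_trace: bool = True,
):
    """Integrate n diffusively coupled QIF units driven by one unit u.

    du/dt   = b0 + u**2                                   (u not fed back)
    dv_i/dt = b_i + v_i**2 + g * sum_j A_ij (v_j - v_i) + g0 * (u - v_i)

    The state vector is [u, v_0, ..., v_{n-1}]; u resets from 1 to 0 so
    its period equals the analytic formula. Returns
    ``(times, trace, spikes)`` where ``trace`` has one column per state
    component (or None if record_trace is False) and ``spikes`` is a list
    of spike-time arrays in state order.

    This is the single integration kernel shared by the driven pair,
    lattice networks, and batched trial ensembles (block-diagonal
    adjacency), so reductions between those cases are bit-exact.
    """
    b = np.asarray(b_values, dtype=float)
    v0 = np.asarray(v0, dtype=float)
    n = b.size
    if v0.shape != (n,):
        raise ValueError("v0 must match b_values in length")
    T = drive.period
    taus = [T] + [qif_period(bi) if bi > 0 else None for bi in b]
    if cfg is None:
        cfg = IntegratorConfig(dt=_default_dt(taus, t_end))
    _check_dt(cfg.dt, taus)

    b0 = drive.b0
    g0 = drive.g0
    A = None
    deg = None
    if g > 0 and adjacency is not None:
        A = sp.csr_matrix(adjacency)
        if A.shape != (n, n):
            raise ValueError("adjacency shape must be (n, n)")
        deg = np.asarray(A.sum(axis=1)).ravel()

    def f(t, y):
        u = y[0]
        v = y[1:]
        dv = b + v * v + g0 * (u - v)
        if A is not None:
            dv = dv + g * (A @ v - deg * v)
        du = b0 + u * u
        out = np.empty_like(y)
        out[0] = du
        out[1:] = dv
        return out

    y0 = np.concatenate(([u0], v0))
    vr = np.concatenate(([0.0], np.full(n, v_reset)))
    vp = np.concatenate(([1.0], np.full(n, v_peak)))
    return _integrate_reset_system(
        f, y0, t_end, cfg.dt, vr, vp, method=cfg.method, record_trace=record_trace
    )


def integrate_driven_pair(
    pair: PairParams,
    drive: DriveParams,
    v0s: Sequence[float],
    u0: float = 0.0,
    t_end: float | None = None,
    cfg: IntegratorConfig | None = None,
) -> tuple[tuple[Trace, Trace, Trace], tuple[SpikeTrain, SpikeTrain, SpikeTrain]]:
    """Integrate the driven coupled pair (u, v1, v2).

    Returns traces and spike trains ordered (u, v1, v2). The drive u is
    one-way coupled: it forces v1, v2 with strength g0 but is not
    influenced by them.
    """
    if t_end is None:
        t_end = 8.0 * drive.period
    v0s = np.asarray(v0s, dtype=float)
    if v0s.shape != (2,):
        raise ValueError("v0s must contain two initial voltages")
    adjacency = sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
    times, trace, spikes = integrate_driven_system(
        np.array([pair.b1, pair.b2]),
        adjacency,
        pair.g,
        drive,
        v0s,
        u0,
        t_end,
        cfg=cfg,
        v_reset=pair.v_reset,
        v_peak=pair.v_peak,
    )
    traces = tuple(Trace(times, trace[:, j]) for j in range(3))
    trains = tuple(SpikeTrain(s) for s in spikes)
    return traces, trains
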