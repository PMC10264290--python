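"""Pulsatile 0D network of parallel three-element Windkessel outlets.

The aorta is collapsed to a single pressure node fed by a prescribed
periodic inflow ``Q_in(t)`` and drained by N parallel WK3 branches, each a
proximal resistor ``R_p`` in series with a distal resistor ``R_d`` and
compliance ``C`` referenced to venous pressure. The branch states are the
capacitor pressures ``P_c,i``; the node pressure follows algebraically from
flow conservation:

    P(t) = (Q_in + sum_i P_c,i / R_p,i) / sum_i (1 / R_p,i)

so mass is conserved identically at every step. The branch ODEs

    C_i dP_c,i/dt = (P - P_c,i)/R_p,i - (P_c,i - P_ven)/R_d,i

are linear; they are integrated with backward Euler (unconditionally
stable), running whole cycles until systolic and diastolic node pressures
change by less than a relative threshold between consecutive cycles.

Units follow clinical convention: pressure mmHg, flow mL/s, resistance
mmHg/(mL/s), compliance mL/mmHg, time s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve

__all__ = [
    "WK3Params",
    "FlowWaveform",
    "WK3Network",
    "NetworkResult",
    "ConvergenceError",
    "assemble_network",
    "simulate",
    "cycle_summary",
    "wk3_impedance",
]


class ConvergenceError(RuntimeError):
    """Raised when the cyclic-periodicity criterion is not met in time.

    Carries the per-cycle systolic/diastolic history in ``cycle_history``.
    """

    def __init__(self, message: str, cycle_history: list[tuple[float, float]]):
        super().__init__(message)
        self.cycle_history = cycle_history


@dataclass(frozen=True)
class WK3Params:
    """Three-element Windkessel parameters for one (grouped) outlet.

    ``R_tot`` is split into a proximal part ``R_p = rho * R_tot`` and a
    distal part ``R_d = (1 - rho) * R_tot``; ``C`` sits across ``R_d``.
    """

    R_tot: float
    rho: float
    C: float

    def __post_init__(self) -> None:
        if self.R_tot <= 0:
            raise ValueError(f"R_tot must be > 0, got {self.R_tot}")
        if not 0.0 < self.rho < 1.0:
            raise ValueError(f"rho must be in (0, 1), got {self.rho}")
        if self.C <= 0:
            raise ValueError(f"C must be > 0, got {self.C}")

    @property
    def R_p(self) -> float:
        return self.rho * self.R_tot

    @property
    def R_d(self) -> float:
        # written as difference so R_p + R_d == R_tot exactly in floats
        return self.R_tot - self.rho * self.R_tot

    def scaled(self, r_factor: float = 1.0, c_factor: float = 1.0) -> "WK3Params":
        return WK3Params(self.R_tot * r_factor, self.rho, self.C * c_factor)


@dataclass
class FlowWaveform:
    """Periodic volumetric-flow waveform sampled over one cycle.

    ``times`` start at 0, are strictly increasing, and all lie in
    ``[0, period)``; the waveform is extended periodically (the sample at
    ``t = period`` is the sample at ``t = 0``).
    """

    times: np.ndarray
    flows: np.ndarray
    period: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.flows = np.asarray(self.flows, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.flows.shape:
            raise ValueError("times and flows must be 1-D arrays of equal length")
        if self.times.size < 1:
            raise ValueError("waveform needs at least one sample")
        if abs(self.times[0]) > 1e-12:
            raise ValueError("times must start at 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.period <= self.times[-1]:
            raise ValueError("period must exceed the last sample time")

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        """Periodic linear interpolation at arbitrary times."""
        return np.interp(
            np.mod(t, self.period), self.times, self.flows, period=self.period
        )

    @property
    def mean(self) -> float:
        """Cycle-mean flow (trapezoid over the periodically closed cycle)."""
        t = np.append(self.times, self.period)
        q = np.append(self.flows, self.flows[0])
        return float(np.trapezoid(q, t) / self.period)

    @property
    def stroke_volume(self) -> float:
        """Volume per cycle in mL."""
        return self.mean * self.period


@dataclass
class WK3Network:
    """One inlet node with N parallel WK3 branches to venous pressure."""

    names: list[str]
    params: list[WK3Params]
    venous_pressure: float = 0.0

    def __post_init__(self) -> None:
        if len(self.names) == 0:
            raise ValueError("network needs at least one outlet")
        if len(self.names) != len(self.params):
            raise ValueError("names and params length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("outlet names must be unique")

    @property
    def n_states(self) -> int:
        return len(self.params)


def assemble_network(
    outlets: list[tuple[str, WK3Params]], venous_pressure: float = 0.0
) -> WK3Network:
    """Build the parallel-WK3 network (one state per outlet)."""
    if not outlets:
        raise ValueError("empty outlet list")
    names = [n for n, _ in outlets]
    params = [p for _, p in outlets]
    return WK3Network(names=names, params=params, venous_pressure=venous_pressure)


@dataclass
class NetworkResult:
    """Final converged cycle of a network simulation.

    ``time`` spans one cycle (length ``n_steps + 1``, endpoints included);
    traces are aligned with it. ``cycle_history`` lists (P_s, P_d) per cycle.
    """

    time: np.ndarray
    inlet_pressure: np.ndarray
    outlet_flows: dict[str, np.ndarray]
    capacitor_pressures: dict[str, np.ndarray]
    inflow: np.ndarray
    cycles_run: int
    converged: bool
    cycle_history: list[tuple[float, float]] = field(default_factory=list)

    @property
    def systolic(self) -> float:
        return float(self.inlet_pressure.max())

    @property
    def diastolic(self) -> float:
        return float(self.inlet_pressure.min())

    @property
    def mean_pressure(self) -> float:
        t, p = self.time, self.inlet_pressure
        return float(np.trapezoid(p, t) / (t[-1] - t[0]))

    def mean_outlet_flows(self) -> dict[str, float]:
        t = self.time
        T = t[-1] - t[0]
        return {
            name: float(np.trapezoid(q, t) / T) for name, q in self.outlet_flows.items()
        }


def simulate(
    network: WK3Network,
    inflow: FlowWaveform,
    dt: float = 1e-3,
    convergence_threshold: float = 0.01,
    max_cycles: int = 50,
    initial_capacitor_pressure: float | np.ndarray = 0.0,
) -> NetworkResult:
    """Integrate the network to cyclic periodicity and return the final cycle.

    Backward Euler at step ``dt`` (adjusted to divide the period exactly if
    needed, within one part in 1e6). Cycles repeat until systolic and
    diastolic inlet pressures both change by less than
    ``convergence_threshold`` (relative) between consecutive cycles.

    Raises
    ------
    ConvergenceError
        If periodicity is not reached within ``max_cycles``; the exception
        carries the per-cycle (P_s, P_d) history.
    """
    if not 0.0 < convergence_threshold < 1.0:
        raise ValueError("convergence_threshold must be in (0, 1)")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    T = inflow.period
    n_steps = int(round(T / dt))
    if n_steps < 2:
        raise ValueError("dt too large for the waveform period")
    if abs(n_steps * dt - T) > 1e-6 * T:
        dt = T / n_steps  # resample so the grid tiles the period exactly

    p = network.params
    n = network.n_states
    a = np.array([1.0 / q.R_p for q in p])  # proximal conductances
    gd = np.array([1.0 / q.R_d for q in p])  # distal conductances
    c = np.array([q.C for q in p])
    S = a.sum()
    p_ven = network.venous_pressure

    # dx/dt = A x + b(t) with x the capacitor pressures (see module docstring)
    A = (np.outer(a, a) / S - np.diag(a + gd)) / c[:, None]
    lu = lu_factor(np.eye(n) - dt * A)

    t_nodes = dt * np.arange(n_steps + 1)
    q_in = np.asarray(inflow(t_nodes), dtype=float)
    b = (a[:, None] * q_in[None, :] / S + (gd * p_ven)[:, None]) / c[:, None]

    x = np.broadcast_to(
        np.asarray(initial_capacitor_pressure, dtype=float), (n,)
    ).copy()

    history: list[tuple[float, float]] = []
    x_traj = np.empty((n_steps + 1, n))
    for cycle in range(1, max_cycles + 1):
        x_traj[0] = x
        for k in range(1, n_steps + 1):
            x = lu_solve(lu, x + dt * b[:, k])
            x_traj[k] = x
        p_node = (q_in + x_traj @ a) / S
        p_s, p_d = float(p_node.max()), float(p_node.min())
        history.append((p_s, p_d))
        if cycle > 1:
            ps_prev, pd_prev = history[-2]
            ok_s = abs(p_s - ps_prev) < convergence_threshold * abs(ps_prev)
            ok_d = abs(p_d - pd_prev) < convergence_threshold * abs(pd_prev)
            if ok_s and ok_d:
                flows = a[None, :] * (p_node[:, None] - x_traj)
                return NetworkResult(
                    time=t_nodes,
                    inlet_pressure=p_node,
                    outlet_flows={nm: flows[:, i] for i, nm in enumerate(network.names)},
                    capacitor_pressures={
                        nm: x_traj[:, i].copy() for i, nm in enumerate(network.names)
                    },
                    inflow=q_in,
                    cycles_run=cycle,
                    converged=True,
                    cycle_history=history,
                )
    raise ConvergenceError(
        f"no cyclic periodicity within {max_cycles} cycles "
        f"(threshold {convergence_threshold:g})",
        history,
    )


def cycle_summary(result: NetworkResult) -> dict:
    """Per-outlet cycle-mean flows and inlet pressure summary of a run.

    Mean flows integrate the final cycle with the trapezoidal rule;
    systolic/diastolic are the extrema of the final-cycle inlet pressure.
    Returns a dict with a ``pandas.DataFrame`` under ``"outlets"``.
    """
    means = result.mean_outlet_flows()
    table = pd.DataFrame(
        {
            "outlet": list(means.keys()),
            "mean_flow_mL_s": list(means.values()),
        }
    )
    return {
        "outlets": table,
        "systolic_mmHg": result.systolic,
        "diastolic_mmHg": result.diastolic,
        "pulse_mmHg": result.systolic - result.diastolic,
        "mean_pressure_mmHg": result.mean_pressure,
        "total_mean_outflow_mL_s": float(sum(means.values())),
        "cycles_run": result.cycles_run,
    }


def wk3_impedance(params: WK3Params, omega: np.ndarray | float) -> np.ndarray | complex:
    """Complex input impedance of one WK3 at angular frequency ``omega``.

    ``Z(w) = R_p + R_d / (1 + j w R_d C)`` — the analytic oracle used to
    verify the time-domain integrator on single-harmonic inflows.
    """
    return params.R_p + params.R_d / (1.0 + 1j * np.asarray(omega) * params.R_d * params.C)
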