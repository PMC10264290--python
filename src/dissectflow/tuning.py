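"""Automatic calibration of WK3 outlet parameters.

The calibration problem: choose ``(R_tot, C)`` per outlet (``rho`` is fixed
per outlet class) so that the 0D network, driven by the prescribed inflow,
reproduces target cycle-mean outlet flows and target systolic/diastolic
inlet pressures.

At periodic steady state the capacitor carries no mean current, so each
outlet's cycle-mean flow is ``(Pbar - P_ven)/R_tot``: keeping
``R_tot,i`` proportional to ``1/Qbar_i`` satisfies the flow split by
construction at every iteration, reducing the problem to two scalars — a
global resistance scale (controls mean pressure) and a global compliance
scale (controls pulse pressure). These are alternated until both pressure
targets are met. Compliance is distributed as ``C_i ∝ 1/R_tot,i`` so all
outlets share one RC time constant, the structure evident in calibrated
parameter tables for this class of model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .outlet_targets import PressureTargets
from .zerod import FlowWaveform, WK3Network, WK3Params, assemble_network, simulate

__all__ = ["TuningSpec", "TuningReport", "tune", "wk3_from_anchor"]


@dataclass
class TuningSpec:
    """Inputs to WK3 calibration.

    ``rho`` may be a scalar (shared) or a per-outlet sequence. Flow targets
    must sum to the inflow cycle mean within 0.5% — otherwise no resistance
    set can satisfy both the split and the mean pressure and the spec is
    inconsistent.
    """

    outlet_names: list[str]
    target_flows: np.ndarray
    pressure_targets: PressureTargets
    rho: np.ndarray | float
    inflow: FlowWaveform
    venous_pressure: float = 0.0
    dt: float = 1e-3
    pressure_tol_mmHg: float = 1.0
    flow_tol_rel: float = 0.03
    max_iterations: int = 30
    # tuning needs tight cyclic periodicity: the mean-flow/resistance
    # identity holds only at true periodic steady state, so the production
    # 1% cycle criterion would alias transient drift into flow error
    sim_convergence_threshold: float = 1e-3
    max_cycles: int = 200

    def __post_init__(self) -> None:
        self.target_flows = np.asarray(self.target_flows, dtype=float)
        n = len(self.outlet_names)
        if self.target_flows.shape != (n,):
            raise ValueError("one target flow per outlet required")
        if np.any(self.target_flows <= 0):
            raise ValueError("target flows must be > 0")
        self.rho = np.broadcast_to(np.asarray(self.rho, dtype=float), (n,)).copy()
        if np.any((self.rho <= 0) | (self.rho >= 1)):
            raise ValueError("rho must lie in (0, 1)")
        if self.pressure_targets.pulse <= 0:
            raise ValueError("pulse pressure target must be > 0")
        total = self.target_flows.sum()
        if abs(total - self.inflow.mean) > 5e-3 * abs(total):
            raise ValueError(
                f"target flows sum to {total:.4f} mL/s but inflow cycle mean is "
                f"{self.inflow.mean:.4f} mL/s (must agree within 0.5%)"
            )


@dataclass
class TuningReport:
    converged: bool
    iterations: int
    systolic_mmHg: float
    diastolic_mmHg: float
    max_flow_rel_error: float
    max_pressure_abs_error_mmHg: float
    history: list[dict] = field(default_factory=list)


def tune(spec: TuningSpec) -> tuple[dict[str, WK3Params], TuningReport]:
    """Calibrate WK3 parameters against flow and pressure targets.

    Returns the per-outlet parameters and a convergence report; the
    parameters, re-simulated with :func:`dissectflow.zerod.simulate`,
    reproduce the targets within ``spec`` tolerances.

    Raises
    ------
    RuntimeError
        If the alternating scheme does not meet the pressure tolerances in
        ``max_iterations`` (the iteration trace rides on the exception).
    """
    q_t = spec.target_flows
    pt = spec.pressure_targets
    p_ven = spec.venous_pressure

    # (i) initial resistances: common perfusion pressure over target flows
    p_mean0 = pt.diastolic + pt.pulse / 3.0
    r_tot = (p_mean0 - p_ven) / q_t

    # (ii) total compliance from the 2-element estimate SV/PP, spread with
    # equal RC time constants (C_i ∝ 1/R_tot,i)
    c_tot = spec.inflow.stroke_volume / pt.pulse
    inv_r = 1.0 / r_tot
    c = c_tot * inv_r / inv_r.sum()

    history: list[dict] = []
    result = None
    for it in range(1, spec.max_iterations + 1):
        params = [WK3Params(r, rho, ci) for r, rho, ci in zip(r_tot, spec.rho, c)]
        net = assemble_network(list(zip(spec.outlet_names, params)), p_ven)
        result = simulate(
            net,
            spec.inflow,
            dt=spec.dt,
            convergence_threshold=spec.sim_convergence_threshold,
            max_cycles=spec.max_cycles,
            initial_capacitor_pressure=pt.diastolic,
        )
        err_s = pt.systolic - result.systolic
        err_d = pt.diastolic - result.diastolic
        history.append(
            {
                "iteration": it,
                "systolic_mmHg": result.systolic,
                "diastolic_mmHg": result.diastolic,
                "err_systolic_mmHg": err_s,
                "err_diastolic_mmHg": err_d,
            }
        )
        if max(abs(err_s), abs(err_d)) <= spec.pressure_tol_mmHg:
            break
        # global resistance scale drives the mean pressure implied by
        # matching both extrema; compliance scale drives pulse pressure
        p_mean_sim = result.mean_pressure
        p_mean_new = p_mean_sim + 0.5 * (err_s + err_d)
        f_r = max((p_mean_new - p_ven) / (p_mean_sim - p_ven), 0.05)
        f_c = max((result.systolic - result.diastolic) / pt.pulse, 0.05)
        r_tot = r_tot * f_r
        c = c * f_c
    else:
        raise RuntimeError(
            f"tuning did not converge in {spec.max_iterations} iterations; "
            f"trace: {history}"
        )

    means = result.mean_outlet_flows()
    q_sim = np.array([means[nm] for nm in spec.outlet_names])
    flow_err = float(np.max(np.abs(q_sim - q_t) / q_t))
    press_err = max(
        abs(result.systolic - pt.systolic), abs(result.diastolic - pt.diastolic)
    )
    report = TuningReport(
        converged=flow_err <= spec.flow_tol_rel and press_err <= spec.pressure_tol_mmHg,
        iterations=len(history),
        systolic_mmHg=result.systolic,
        diastolic_mmHg=result.diastolic,
        max_flow_rel_error=flow_err,
        max_pressure_abs_error_mmHg=float(press_err),
        history=history,
    )
    params_out = {
        nm: WK3Params(float(r), float(rho), float(ci))
        for nm, r, rho, ci in zip(spec.outlet_names, r_tot, spec.rho, c)
    }
    return params_out, report


def wk3_from_anchor(
    anchor: WK3Params,
    anchor_flow: float,
    target_flows: dict[str, float],
    rho: dict[str, float] | float | None = None,
) -> dict[str, WK3Params]:
    """Scale one calibrated outlet to a whole set via the tuning structure.

    Given an anchor outlet with known ``(R_tot, C)`` and target flow, other
    outlets at the same perfusion pressure follow from the inverse-flow /
    equal-time-constant structure:

        R_tot,i = R_a * Q_a / Q_i        (common perfusion pressure)
        C_i     = C_a * R_a / R_tot,i    (common RC time constant)

    ``rho`` defaults to the anchor's value for every outlet.
    """
    if anchor_flow <= 0:
        raise ValueError("anchor_flow must be > 0")
    out: dict[str, WK3Params] = {}
    for name, q in target_flows.items():
        if q <= 0:
            raise ValueError(f"target flow for {name!r} must be > 0")
        r_i = anchor.R_tot * anchor_flow / q
        c_i = anchor.C * anchor.R_tot / r_i
        rho_i = (
            anchor.rho
            if rho is None
            else (rho if isinstance(rho, float) else rho[name])
        )
        out[name] = WK3Params(r_i, rho_i, c_i)
    return out
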