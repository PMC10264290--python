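"""Flow, pressure and wall-shear metrics for dissection haemodynamics.

Plane flow is decomposed into forward and reverse parts by the sign of the
through-plane velocity; the cycle-averaged reverse/forward ratio across the
primary entry tear is the false-lumen ejection fraction (FLEF). Transmural
pressure (TMP) is the true-lumen minus false-lumen area-averaged pressure.
Wall-shear indices follow the standard definitions:

    TAWSS = (1/T) ∫ |tau| dt
    OSI   = 0.5 (1 - |∫ tau dt| / ∫ |tau| dt)
    ECAP  = OSI / TAWSS

with ECAP >= 1.4 1/Pa flagging thrombotic susceptibility. The module also
carries the Carreau–Yasuda viscosity law, a pulsatile transition-to-
turbulence check, and Bland–Altman agreement statistics for comparing
simulated velocities with 4D-flow measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inlet import MovingPlaneSeries, PlaneVelocityField

__all__ = [
    "LuminalPlanePair",
    "WSSHistory",
    "ViscosityModel",
    "ReynoldsReport",
    "plane_flow",
    "decompose",
    "rf_ratio",
    "cycle_rf",
    "flef",
    "tmp",
    "tawss_osi_ecap",
    "ecap_exceeds_threshold",
    "viscosity",
    "reynolds_check",
    "bland_altman",
    "velocity_errors",
    "ECAP_THRESHOLD_PER_PA",
]

#: ECAP level above which the wall is considered thrombosis-prone (1/Pa).
ECAP_THRESHOLD_PER_PA = 1.4


@dataclass
class LuminalPlanePair:
    """TL and FL area-averaged pressure traces on a common cycle grid."""

    times: np.ndarray
    p_tl: np.ndarray
    p_fl: np.ndarray
    period: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.p_tl = np.asarray(self.p_tl, dtype=float)
        self.p_fl = np.asarray(self.p_fl, dtype=float)
        if not (self.times.shape == self.p_tl.shape == self.p_fl.shape):
            raise ValueError("times, p_tl, p_fl must share one grid")
        if self.times.size < 2:
            raise ValueError("need at least 2 samples")
        span = self.times[-1] - self.times[0]
        if span > self.period * (1 + 1e-9):
            raise ValueError("grid must span at most one period")


@dataclass
class WSSHistory:
    """Per-node wall shear stress vector time series (Pa) on a uniform grid."""

    node_ids: np.ndarray
    times: np.ndarray
    tau: np.ndarray  # (n_nodes, n_times, 3)

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids)
        self.times = np.asarray(self.times, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.times.size < 2:
            raise ValueError("need at least 2 time samples")
        steps = np.diff(self.times)
        if np.any(np.abs(steps - steps[0]) > 1e-9 * max(steps[0], 1e-12)):
            raise ValueError("time grid must be uniform")
        if self.tau.shape != (self.node_ids.size, self.times.size, 3):
            raise ValueError("tau must be (n_nodes, n_times, 3)")


@dataclass(frozen=True)
class ViscosityModel:
    """Carreau–Yasuda shear-thinning blood viscosity.

    mu(gdot) = mu_inf + (mu0 - mu_inf) [1 + (lambda gdot)^a]^((n-1)/a)

    Defaults are the widely used whole-blood constants; all are editable
    config values, not physical truths.
    """

    mu0: float = 0.056  # Pa s, zero-shear viscosity
    mu_inf: float = 0.0035  # Pa s, infinite-shear viscosity
    lambda_s: float = 3.313  # s, relaxation time
    a: float = 2.0
    n: float = 0.3568
    density: float = 1056.0  # kg/m^3

    def __post_init__(self) -> None:
        if not self.mu0 > self.mu_inf > 0:
            raise ValueError("require mu0 > mu_inf > 0")
        if self.lambda_s <= 0 or self.a <= 0:
            raise ValueError("lambda and a must be > 0")
        if self.density <= 0:
            raise ValueError("density must be > 0")


@dataclass(frozen=True)
class ReynoldsReport:
    """Pulsatile-flow transition check: turbulent iff Re_p > Re_c."""

    reynolds_peak: float
    reynolds_critical: float
    womersley: float
    turbulent: bool


def plane_flow(field: PlaneVelocityField) -> float:
    """Net through-plane flow Q = sum (v·n) A, in mL/s."""
    return float((field.velocities @ field.normal) @ field.area_weights)


def decompose(field: PlaneVelocityField) -> tuple[float, float]:
    """Forward and reverse flow magnitudes (Q_F, Q_R), both >= 0, mL/s.

    Forward sums strictly positive through-plane projections and reverse
    the magnitudes of strictly negative ones, so Q = Q_F - Q_R; samples
    with exactly zero projection contribute to neither.
    """
    vn = field.velocities @ field.normal
    contrib = vn * field.area_weights
    q_f = float(contrib[vn > 0].sum())
    q_r = float(-contrib[vn < 0].sum())
    return q_f, q_r


def rf_ratio(q_f: float, q_r: float) -> float:
    """Instantaneous reverse/forward flow ratio R/F = Q_R / Q_F."""
    if q_f <= 0:
        raise ZeroDivisionError("R/F undefined where forward flow is zero")
    if q_r < 0:
        raise ValueError("Q_R must be >= 0")
    return q_r / q_f


def cycle_rf(
    series: MovingPlaneSeries, zero_forward: str = "exclude"
) -> float:
    """Cycle-averaged R/F: (1/T) ∫ (Q_R/Q_F) dt, trapezoid on the frame grid.

    The periodic closure appends the first frame at t0 + T. Instants with
    zero forward flow follow ``zero_forward``: ``"exclude"`` (default)
    drops them with a warning and averages over the remaining time span;
    ``"strict"`` raises.
    """
    qf = np.empty(len(series.frames))
    qr = np.empty(len(series.frames))
    for i, f in enumerate(series.frames):
        qf[i], qr[i] = decompose(f)
    t = series.timestamps
    # periodic closure
    t = np.append(t, t[0] + series.period)
    qf = np.append(qf, qf[0])
    qr = np.append(qr, qr[0])
    valid = qf > 0
    if not np.all(valid):
        if zero_forward == "strict":
            raise ZeroDivisionError("zero forward flow at some instants (strict mode)")
        if zero_forward != "exclude":
            raise ValueError(f"unknown zero_forward policy {zero_forward!r}")
        warnings.warn(
            f"{int((~valid).sum())} instants with zero forward flow excluded "
            "from the cycle R/F average",
            stacklevel=2,
        )
    t, qf, qr = t[valid], qf[valid], qr[valid]
    if t.size < 2:
        raise ValueError("too few valid instants for a cycle average")
    ratio = qr / qf
    return float(np.trapezoid(ratio, t) / (t[-1] - t[0]))


def flef(pet_series: MovingPlaneSeries, **kwargs) -> float:
    """False-lumen ejection fraction: cycle R/F across the primary entry
    tear, as a percentage."""
    return 100.0 * cycle_rf(pet_series, **kwargs)


def tmp(pair: LuminalPlanePair) -> tuple[float, float]:
    """Transmural pressure: (TMP_mean, TMP_max), both mmHg.

    TMP_mean is the trapezoid time average of P_TL - P_FL over the cycle
    (periodically closed when the grid stops short of one full period).
    TMP_max is the instantaneous value of largest absolute magnitude with
    its sign preserved; ties go to the earliest instant.
    """
    t = pair.times
    d = pair.p_tl - pair.p_fl
    span = t[-1] - t[0]
    if span < pair.period * (1 - 1e-9):
        t = np.append(t, t[0] + pair.period)
        d = np.append(d, d[0])
        span = pair.period
    mean = float(np.trapezoid(d, t) / span)
    i_max = int(np.argmax(np.abs(d)))  # argmax takes the earliest on ties
    return mean, float(d[i_max])


def tawss_osi_ecap(
    history: WSSHistory, ecap_threshold: float = ECAP_THRESHOLD_PER_PA
) -> pd.DataFrame:
    """Per-node TAWSS (Pa), OSI and ECAP (1/Pa) with degenerate-node flags.

    Integrals use the trapezoidal rule with periodic closure (the first
    sample is appended one period after the start). Nodes where the shear
    magnitude integrates to zero are 0/0 in the OSI formula; they get
    OSI = 0 and ECAP = 0 and ``degenerate = True``. ``exceeds_threshold``
    marks ECAP >= ``ecap_threshold``.
    """
    t = np.append(history.times, history.times[0] + _period_of(history))
    tau = np.concatenate([history.tau, history.tau[:, :1, :]], axis=1)
    T = t[-1] - t[0]
    mag = np.linalg.norm(tau, axis=2)
    int_mag = np.trapezoid(mag, t, axis=1)
    int_vec = np.trapezoid(tau, t, axis=1)
    tawss = int_mag / T
    degenerate = int_mag <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        osi = 0.5 * (1.0 - np.linalg.norm(int_vec, axis=1) / int_mag)
        ecap = osi / tawss
    osi = np.where(degenerate, 0.0, np.clip(osi, 0.0, 0.5))
    ecap = np.where(degenerate, 0.0, ecap)
    tawss = np.where(degenerate, 0.0, tawss)
    return pd.DataFrame(
        {
            "node_id": history.node_ids,
            "TAWSS_Pa": tawss,
            "OSI": osi,
            "ECAP_per_Pa": ecap,
            "degenerate": degenerate,
            "exceeds_threshold": ecap >= ecap_threshold,
        }
    )


def _period_of(history: WSSHistory) -> float:
    dt = history.times[1] - history.times[0]
    return float(history.times[-1] - history.times[0] + dt)


def ecap_exceeds_threshold(
    table: pd.DataFrame, threshold: float = ECAP_THRESHOLD_PER_PA
) -> pd.DataFrame:
    """Rows of a metric table whose ECAP reaches the threshold."""
    return table[table["ECAP_per_Pa"] >= threshold]


def viscosity(shear_rate: np.ndarray | float, model: ViscosityModel) -> np.ndarray | float:
    """Carreau–Yasuda dynamic viscosity (Pa s) at shear rate gdot (1/s)."""
    g = np.asarray(shear_rate, dtype=float)
    if np.any(g < 0):
        raise ValueError("shear rate must be >= 0")
    mu = model.mu_inf + (model.mu0 - model.mu_inf) * (
        1.0 + (model.lambda_s * g) ** model.a
    ) ** ((model.n - 1.0) / model.a)
    return mu if mu.ndim else float(mu)


def reynolds_check(
    peak_velocity: float,
    diameter: float,
    heart_rate: float,
    model: ViscosityModel,
    critical_coeff: float = 169.0,
    womersley_exponent: float = 0.83,
    strouhal_exponent: float = -0.27,
    critical_reynolds: float | None = None,
    nominal_shear_rate: float | None = None,
) -> ReynoldsReport:
    """Pulsatile transition-to-turbulence check.

    Re_p = rho V D / mu(gdot_nom) with the nominal shear rate V/D by
    default; the Womersley number is alpha = (D/2) sqrt(omega rho / mu).
    The critical Reynolds number follows the pulsatile-flow power-law
    correlation Re_c = K alpha^p St^q (St = f D / V), whose constants are
    configurable; a directly measured or literature Re_c may be supplied via
    ``critical_reynolds`` and overrides the correlation.
    """
    if min(peak_velocity, diameter, heart_rate) <= 0:
        raise ValueError("peak_velocity, diameter and heart_rate must be > 0")
    gdot = peak_velocity / diameter if nominal_shear_rate is None else nominal_shear_rate
    mu = float(viscosity(gdot, model))
    re_p = model.density * peak_velocity * diameter / mu
    omega = 2.0 * np.pi * heart_rate / 60.0
    alpha = (diameter / 2.0) * np.sqrt(omega * model.density / mu)
    if critical_reynolds is None:
        strouhal = (heart_rate / 60.0) * diameter / peak_velocity
        critical_reynolds = (
            critical_coeff * alpha**womersley_exponent * strouhal**strouhal_exponent
        )
    return ReynoldsReport(
        reynolds_peak=float(re_p),
        reynolds_critical=float(critical_reynolds),
        womersley=float(alpha),
        turbulent=bool(re_p > critical_reynolds),
    )


def bland_altman(
    values_a: np.ndarray, values_b: np.ndarray
) -> tuple[float, float, float, pd.DataFrame]:
    """Bland–Altman agreement: (bias, lower limit, upper limit, point pairs).

    Differences are a - b; limits of agreement are bias ± 1.96 sample
    standard deviations of the differences.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("values_a and values_b must be equal-length 1-D arrays")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    pairs = pd.DataFrame({"mean": (a + b) / 2.0, "difference": diff})
    return bias, bias - 1.96 * sd, bias + 1.96 * sd, pairs


def velocity_errors(
    v_model: np.ndarray, v_measured: np.ndarray, mean_inlet_velocity: float
) -> tuple[float, float]:
    """Peak and mean velocity-magnitude discrepancy, % of mean inlet velocity.

    peak = (max|v_model| - max|v_measured|) / v_inlet * 100
    mean = mean(|v_model| - |v_measured|) / v_inlet * 100 (signed)

    Inputs may be speed arrays (n,) or vector arrays (n, 3); vectors are
    reduced to magnitudes. The normalization by the mean inlet velocity at
    peak systole makes errors comparable across planes of different
    velocity scales.
    """
    if mean_inlet_velocity <= 0:
        raise ValueError("mean_inlet_velocity must be > 0")
    vm = np.asarray(v_model, dtype=float)
    vd = np.asarray(v_measured, dtype=float)
    if vm.ndim == 2:
        vm = np.linalg.norm(vm, axis=1)
    if vd.ndim == 2:
        vd = np.linalg.norm(vd, axis=1)
    if vm.shape != vd.shape:
        raise ValueError("model and measured sample sets must be co-registered")
    peak = (vm.max() - vd.max()) / mean_inlet_velocity * 100.0
    mean = float((vm - vd).mean()) / mean_inlet_velocity * 100.0
    return float(peak), float(mean)
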