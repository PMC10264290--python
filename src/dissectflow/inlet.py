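"""Mapping of 4D-flow velocity planes onto a static analysis plane.

The measurement plane moves and tilts over the cardiac cycle with aortic
compliance and heart motion. Each frame is mapped rigidly onto a static
reference plane: the best-fit plane (centroid plus orthogonal-regression
normal) is aligned with the reference plane's, and the residual in-plane
rotation is resolved by least-squares point alignment (orthogonal
Procrustes restricted to a rotation about the plane normal). Velocity
vectors are rotated with the points. Registered series are then resampled
in time — periodic, linear by default — to the solver timestep.

Coordinates are mm, velocities m/s, areas mm²; conveniently,
(m/s)·mm² is numerically mL/s, so plane flows need no unit factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import (
    CubicSpline,
    LinearNDInterpolator,
    NearestNDInterpolator,
)

from .zerod import FlowWaveform

__all__ = [
    "PlaneVelocityField",
    "MovingPlaneSeries",
    "RigidTransform",
    "fit_plane",
    "register_frame",
    "resample_time",
    "inflow_waveform",
    "mean_inlet_velocity",
    "peak_inlet_velocity",
    "interpolate_to_points",
    "net_flux_report",
]


@dataclass
class PlaneVelocityField:
    """Velocity samples on (or near) a plane at one instant.

    points : (n, 3) mm; velocities : (n, 3) m/s; area_weights : (n,) mm²;
    normal : unit vector; timestamp : s.
    """

    points: np.ndarray
    velocities: np.ndarray
    area_weights: np.ndarray
    normal: np.ndarray
    timestamp: float = 0.0
    out_of_plane_tol: float = 1.0  # mm

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.area_weights = np.asarray(self.area_weights, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        n = self.points.shape[0]
        if self.points.shape != (n, 3) or self.velocities.shape != (n, 3):
            raise ValueError("points and velocities must be (n, 3) arrays")
        if self.area_weights.shape != (n,):
            raise ValueError("area_weights must be (n,)")
        if np.any(self.area_weights <= 0):
            raise ValueError("area_weights must be > 0")
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-9:
            raise ValueError("normal must be a unit vector")
        if n >= 3:
            centroid, fit_n = fit_plane(self.points)
            dist = np.abs((self.points - centroid) @ fit_n)
            if dist.max() > self.out_of_plane_tol:
                raise ValueError(
                    f"points deviate {dist.max():.3g} mm from the best-fit plane "
                    f"(tolerance {self.out_of_plane_tol} mm)"
                )

    @property
    def total_area(self) -> float:
        return float(self.area_weights.sum())


@dataclass
class MovingPlaneSeries:
    """Ordered frames over one cardiac cycle of period ``period`` (s)."""

    frames: list[PlaneVelocityField]
    period: float

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("series needs at least one frame")
        ts = np.array([f.timestamp for f in self.frames])
        if np.any(np.diff(ts) <= 0):
            raise ValueError("frame timestamps must be strictly increasing")
        if ts[-1] >= self.period:
            raise ValueError("all frame timestamps must be < period")

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames])


@dataclass
class RigidTransform:
    """x -> rotation @ x + translation; applied to a frame by registration."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        return pts @ self.rotation.T + self.translation

    def apply_vectors(self, vec: np.ndarray) -> np.ndarray:
        return vec @ self.rotation.T


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and orthogonal-regression (total-least-squares) normal.

    The normal is the singular direction of least spread; its sign is
    arbitrary. Raises for degenerate (collinear) point sets.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("plane fit needs at least 3 points")
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    if s[1] < 1e-12 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) point set")
    return centroid, vt[2]


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector a onto unit vector b."""
    v = np.cross(a, b)
    cos = float(np.dot(a, b))
    s = np.linalg.norm(v)
    if s < 1e-15:
        if cos > 0:
            return np.eye(3)
        # 180 degrees: rotate about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-12:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return _axis_angle(axis, np.pi)
    axis = v / s
    return _axis_angle(axis, float(np.arctan2(s, cos)))


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    k = np.asarray(axis, dtype=float)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def register_frame(
    frame: PlaneVelocityField, reference: PlaneVelocityField
) -> tuple[PlaneVelocityField, RigidTransform]:
    """Rigidly map ``frame`` onto the reference plane.

    Plane-to-plane alignment (centroid + normal) followed by in-plane
    orthogonal-Procrustes rotation over corresponding points; velocities are
    rotated by the same rotation. Requires equal point counts (point
    correspondence across frames, as produced by a common sampling mask).
    """
    if frame.points.shape != reference.points.shape:
        raise ValueError("frame and reference must have corresponding points")
    c_f, n_f = fit_plane(frame.points)
    c_r, n_r = fit_plane(reference.points)
    # orient fitted normals along the stated ones so signs are deterministic
    if np.dot(n_f, frame.normal) < 0:
        n_f = -n_f
    if np.dot(n_r, reference.normal) < 0:
        n_r = -n_r
    R1 = _rotation_between(n_f, n_r)

    # residual in-plane rotation about n_r, closed-form 2-D Procrustes
    e1 = np.cross(n_r, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(n_r, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n_r, e1)
    X = (frame.points - c_f) @ R1.T
    Y = reference.points - c_r
    x1, x2 = X @ e1, X @ e2
    y1, y2 = Y @ e1, Y @ e2
    theta = float(np.arctan2(np.sum(x1 * y2 - x2 * y1), np.sum(x1 * y1 + x2 * y2)))
    R = _axis_angle(n_r, theta) @ R1
    t = c_r - R @ c_f
    transform = RigidTransform(rotation=R, translation=t)

    registered = PlaneVelocityField(
        points=transform.apply_points(frame.points),
        velocities=transform.apply_vectors(frame.velocities),
        area_weights=frame.area_weights.copy(),
        normal=n_r / np.linalg.norm(n_r),
        timestamp=frame.timestamp,
        out_of_plane_tol=frame.out_of_plane_tol,
    )
    return registered, transform


def resample_time(
    series: MovingPlaneSeries, dt: float, kind: str = "linear"
) -> MovingPlaneSeries:
    """Resample a registered series onto a uniform grid of step ``dt``.

    Periodic interpolation of per-point velocity components across frames
    (``kind`` = ``"linear"`` or ``"cubic"``, the latter a periodic cubic
    spline); the last-to-first interval wraps with period ``T``. Point
    positions and weights are taken from the first (registered reference)
    frame. The grid has ``ceil(T/dt)`` points at ``k*dt``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if len(series.frames) < 2:
        raise ValueError("resampling needs at least 2 frames")
    shape0 = series.frames[0].points.shape
    for f in series.frames[1:]:
        if f.points.shape != shape0:
            raise ValueError(
                "mismatched point counts across frames; register the series first"
            )
    T = series.period
    t_frames = series.timestamps
    vel = np.stack([f.velocities for f in series.frames])  # (nf, n, 3)
    n_out = int(np.ceil(T / dt))
    t_out = dt * np.arange(n_out)

    if kind == "linear":
        flat = vel.reshape(len(series.frames), -1)
        out = np.empty((n_out, flat.shape[1]))
        for j in range(flat.shape[1]):
            out[:, j] = np.interp(t_out, t_frames, flat[:, j], period=T)
        vel_out = out.reshape(n_out, *shape0)
    elif kind == "cubic":
        t_ext = np.append(t_frames, t_frames[0] + T)
        v_ext = np.concatenate([vel, vel[:1]], axis=0)
        spl = CubicSpline(t_ext, v_ext, axis=0, bc_type="periodic")
        vel_out = spl(t_out)
    else:
        raise ValueError(f"unknown interpolation kind {kind!r}")

    ref = series.frames[0]
    frames = [
        PlaneVelocityField(
            points=ref.points.copy(),
            velocities=vel_out[k],
            area_weights=ref.area_weights.copy(),
            normal=ref.normal.copy(),
            timestamp=float(t_out[k]),
            out_of_plane_tol=ref.out_of_plane_tol,
        )
        for k in range(n_out)
    ]
    return MovingPlaneSeries(frames=frames, period=T)


def _plane_flow(field: PlaneVelocityField) -> float:
    # (m/s)·mm² is numerically mL/s
    return float((field.velocities @ field.normal) @ field.area_weights)


def inflow_waveform(series: MovingPlaneSeries) -> FlowWaveform:
    """Net flow waveform Q(t) = sum over samples of (v·n)·A, in mL/s."""
    if series.frames[0].total_area <= 0:
        raise ValueError("zero total plane area")
    flows = np.array([_plane_flow(f) for f in series.frames])
    return FlowWaveform(times=series.timestamps, flows=flows, period=series.period)


def mean_inlet_velocity(frame: PlaneVelocityField) -> float:
    """Area-weighted mean velocity magnitude (m/s) at one instant."""
    if frame.total_area <= 0:
        raise ValueError("zero total plane area")
    speed = np.linalg.norm(frame.velocities, axis=1)
    return float((speed @ frame.area_weights) / frame.total_area)


def peak_inlet_velocity(series: MovingPlaneSeries) -> float:
    """Maximum pointwise velocity magnitude (m/s) over the cycle."""
    return max(
        float(np.linalg.norm(f.velocities, axis=1).max()) for f in series.frames
    )


def interpolate_to_points(
    frame: PlaneVelocityField, target_points: np.ndarray
) -> np.ndarray:
    """Velocities at arbitrary in-plane target points (mm).

    Linear interpolation on a triangulation of the in-plane coordinates,
    nearest-neighbour outside the convex hull.
    """
    centroid, n = fit_plane(frame.points)
    if np.dot(n, frame.normal) < 0:
        n = -n
    e1 = np.cross(n, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(n, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    uv = (frame.points - centroid) @ np.column_stack([e1, e2])
    uv_t = (np.asarray(target_points, dtype=float) - centroid) @ np.column_stack(
        [e1, e2]
    )
    lin = LinearNDInterpolator(uv, frame.velocities)
    out = lin(uv_t)
    bad = np.any(np.isnan(out), axis=1)
    if np.any(bad):
        near = NearestNDInterpolator(uv, frame.velocities)
        out[bad] = near(uv_t[bad])
    return out


def net_flux_report(series: MovingPlaneSeries) -> dict:
    """Diagnostic for measured data quality (weak velocity divergence).

    Reports the per-frame net flux, its cycle mean, and the cycle net
    volume; measured fields are not corrected.
    """
    wf = inflow_waveform(series)
    return {
        "net_flow_mL_s": wf.flows.copy(),
        "cycle_mean_mL_s": wf.mean,
        "cycle_net_volume_mL": wf.stroke_volume,
    }
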