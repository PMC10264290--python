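"""Synthetic inputs with analytically known ground truth.

Every input class the pipeline consumes can be generated here so the whole
chain is testable offline: a pulsatile aortic inflow waveform, moving-plane
velocity series with prescribed forward/reverse partitions and known rigid
motion, paired luminal pressure traces with known transmural pressure, and
wall-shear histories with closed-form TAWSS/OSI/ECAP.

Defaults emulate the study conditions: heart rate 94 bpm, 16 frames per
cardiac cycle (the 4D-flow acquisition), and a stroke volume of 69.9 mL so
the cycle-mean inflow (109.5 mL/s) sits at the scale of the calibrated
outlet flow totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inlet import MovingPlaneSeries, PlaneVelocityField, RigidTransform
from .zerod import FlowWaveform

__all__ = [
    "SynthSpec",
    "PlaneGroundTruth",
    "WSSGroundTruth",
    "PressureGroundTruth",
    "gen_inflow",
    "gen_plane_series",
    "gen_parabolic_frame",
    "gen_wss_history",
    "gen_pressure_pair",
]


@dataclass
class SynthSpec:
    """Generator parameters; a fixed seed gives identical outputs."""

    heart_rate: float = 94.0  # 1/min
    stroke_volume: float = 69.9  # mL
    n_harmonics: int = 8
    n_frames: int = 16  # temporal frames per cycle
    disc_radius: float = 15.0  # mm
    n_points: int = 400
    forward_speed: float = 0.8  # m/s, reference forward through-plane speed
    reverse_fraction: float = 0.2  # area fraction carrying reverse flow
    reverse_speed: float = 0.8  # m/s
    speed_modulation: float = 0.4  # relative sinusoidal modulation of speeds
    rotation_amplitude_deg: float = 5.0
    translation_amplitude: float = 2.0  # mm
    n_nodes: int = 30  # WSS nodes
    wss_scale: float = 2.0  # Pa
    tmp_offset: float = 2.0  # mmHg, prescribed mean TL-FL difference
    tmp_oscillation: float = 1.0  # mmHg
    noise_sd: float = 0.0  # optional Gaussian noise on velocities/pressures
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stroke_volume < 0:
            raise ValueError("stroke volume must be >= 0")
        if not 0.0 <= self.reverse_fraction <= 1.0:
            raise ValueError("reverse_fraction must lie in [0, 1]")
        if self.n_points < 3 or self.n_nodes < 3:
            raise ValueError("sample counts must be >= 3")

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate

    @property
    def mean_flow(self) -> float:
        """Cycle-mean flow SV * HR / 60, mL/s."""
        return self.stroke_volume * self.heart_rate / 60.0


@dataclass
class PlaneGroundTruth:
    """Exact per-frame forward/reverse flows and the applied rigid motions."""

    times: np.ndarray
    q_forward: np.ndarray  # mL/s
    q_reverse: np.ndarray  # mL/s
    transforms: list[RigidTransform] = field(default_factory=list)


@dataclass
class WSSGroundTruth:
    node_ids: np.ndarray
    tawss: np.ndarray
    osi: np.ndarray
    ecap: np.ndarray
    kind: np.ndarray  # "constant" | "reversing" | "intermediate"


@dataclass
class PressureGroundTruth:
    tmp_mean: float
    tmp_max: float


# systolic lobe occupies ~36% of the cycle with a small closure dip after it
_SYS_FRACTION = 0.36
_DIP_FRACTION = 0.12
_DIP_DEPTH = 0.12


def _waveform_shape(u: np.ndarray) -> np.ndarray:
    """Dimensionless aortic-like flow shape on phase u in [0, 1)."""
    y = np.zeros_like(u)
    sys = u < _SYS_FRACTION
    y[sys] = np.sin(np.pi * u[sys] / _SYS_FRACTION) ** 2
    dip = (~sys) & (u < _SYS_FRACTION + _DIP_FRACTION)
    y[dip] = -_DIP_DEPTH * np.sin(np.pi * (u[dip] - _SYS_FRACTION) / _DIP_FRACTION)
    return y


def gen_inflow(spec: SynthSpec, n_samples: int = 512) -> FlowWaveform:
    """Truncated-Fourier aortic-like inflow waveform.

    A non-negative systolic lobe followed by a small retrograde valve-
    closure dip, projected onto ``spec.n_harmonics`` harmonics and scaled
    to the prescribed cycle mean SV*HR/60. Zero harmonics yields constant
    flow at the mean.
    """
    T = spec.period
    u = np.arange(n_samples) / n_samples
    y = _waveform_shape(u)
    spectrum = np.fft.rfft(y)
    spectrum[spec.n_harmonics + 1 :] = 0.0
    y = np.fft.irfft(spectrum, n_samples)
    current_mean = y.mean()
    if spec.n_harmonics == 0 or abs(current_mean) < 1e-15:
        flows = np.full(n_samples, spec.mean_flow)
    else:
        flows = y * (spec.mean_flow / current_mean)
    return FlowWaveform(times=u * T, flows=flows, period=T)


def _disc_points(radius: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Sunflower-spiral disc sampling; returns (points xy, angles)."""
    k = np.arange(n) + 0.5
    r = radius * np.sqrt(k / n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = np.mod(k * golden, 2.0 * np.pi)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)]), theta


def _frame_transform(spec: SynthSpec, j: int) -> RigidTransform:
    phase = 2.0 * np.pi * j / spec.n_frames
    angle = np.deg2rad(spec.rotation_amplitude_deg) * np.sin(phase)
    ca, sa = np.cos(angle), np.sin(angle)
    rot = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])  # about in-plane x
    trans = spec.translation_amplitude * np.array(
        [np.sin(phase), np.cos(phase), np.sin(2 * phase)]
    )
    return RigidTransform(rotation=rot, translation=trans)


def gen_plane_series(
    spec: SynthSpec, apply_motion: bool = True
) -> tuple[MovingPlaneSeries, PlaneGroundTruth]:
    """Two-region disc velocity series with exact forward/reverse flows.

    A contiguous angular sector covering ``round(reverse_fraction * n)``
    of the equal-area samples carries reverse flow; with equal forward and
    reverse speeds the instantaneous R/F equals f/(1-f) where f is the
    realized area fraction. Frames are optionally carried through a known
    rigid motion (stored in the ground truth as the motion applied to the
    reference, so registration should recover its inverse). Gaussian noise
    (``noise_sd``, m/s) is added after ground truth is recorded.
    """
    rng = np.random.default_rng(spec.seed)
    T = spec.period
    xy, theta = _disc_points(spec.disc_radius, spec.n_points)
    points0 = np.column_stack([xy, np.zeros(len(xy))])
    normal0 = np.array([0.0, 0.0, 1.0])
    area = np.pi * spec.disc_radius**2 / spec.n_points
    weights = np.full(spec.n_points, area)

    n_rev = int(round(spec.reverse_fraction * spec.n_points))
    order = np.argsort(theta, kind="stable")
    reverse_mask = np.zeros(spec.n_points, dtype=bool)
    reverse_mask[order[:n_rev]] = True

    times = T * np.arange(spec.n_frames) / spec.n_frames
    mod = 1.0 + spec.speed_modulation * np.sin(2.0 * np.pi * times / T)
    frames: list[PlaneVelocityField] = []
    transforms: list[RigidTransform] = []
    qf = np.empty(spec.n_frames)
    qr = np.empty(spec.n_frames)
    for j in range(spec.n_frames):
        vz = np.where(
            reverse_mask, -spec.reverse_speed * mod[j], spec.forward_speed * mod[j]
        )
        # exact partition from the assigned areas, pre-noise and pre-motion
        qf[j] = float(vz[~reverse_mask].sum() * area)
        qr[j] = float(-vz[reverse_mask].sum() * area)
        vel = np.column_stack([np.zeros_like(vz), np.zeros_like(vz), vz])
        if spec.noise_sd > 0:
            vel = vel + rng.normal(0.0, spec.noise_sd, vel.shape)
        tf = (
            _frame_transform(spec, j)
            if apply_motion
            else RigidTransform(np.eye(3), np.zeros(3))
        )
        frames.append(
            PlaneVelocityField(
                points=tf.apply_points(points0),
                velocities=tf.apply_vectors(vel),
                area_weights=weights.copy(),
                normal=tf.apply_vectors(normal0),
                timestamp=float(times[j]),
                out_of_plane_tol=10.0,
            )
        )
        transforms.append(tf)
    truth = PlaneGroundTruth(
        times=times, q_forward=qf, q_reverse=qr, transforms=transforms
    )
    return MovingPlaneSeries(frames=frames, period=T), truth


def gen_parabolic_frame(
    radius_mm: float = 15.0, peak_speed: float = 1.0, n_points: int = 2000
) -> tuple[PlaneVelocityField, float]:
    """Poiseuille profile on a disc; returns the frame and the exact flow.

    v(r) = v_max (1 - r^2/R^2) through-plane, so Q = pi R^2 v_max / 2
    (numerically mL/s with mm and m/s).
    """
    xy, _ = _disc_points(radius_mm, n_points)
    r2 = (xy**2).sum(axis=1)
    vz = peak_speed * (1.0 - r2 / radius_mm**2)
    area = np.pi * radius_mm**2 / n_points
    frame = PlaneVelocityField(
        points=np.column_stack([xy, np.zeros(n_points)]),
        velocities=np.column_stack([np.zeros(n_points), np.zeros(n_points), vz]),
        area_weights=np.full(n_points, area),
        normal=np.array([0.0, 0.0, 1.0]),
    )
    q_exact = np.pi * radius_mm**2 * peak_speed / 2.0
    return frame, q_exact


def gen_wss_history(
    spec: SynthSpec, dt: float = 0.005
) -> tuple["WSSHistory", WSSGroundTruth]:
    """Wall-shear histories mixing three node archetypes.

    Constant-direction nodes (OSI 0), fully reversing sinusoids
    (OSI 0.5, TAWSS (2/pi) tau0), and offset sinusoids
    tau(t) = (m + o sin wt) e with o > m > 0, whose closed forms are

        TAWSS = (2/pi) (m asin(m/o) + sqrt(o^2 - m^2)),  OSI = (1 - m/TAWSS)/2.
    """
    from .metrics import WSSHistory  # local import avoids a cycle

    rng = np.random.default_rng(spec.seed + 1)
    T = spec.period
    # snap the interval so the uniform grid tiles the cycle exactly
    # (94 bpm at nominally 5 ms gives 128 samples of 4.99 ms)
    n_t = int(round(T / dt))
    dt = T / n_t
    times = dt * np.arange(n_t)
    omega = 2.0 * np.pi / T

    n = spec.n_nodes
    kinds = np.array([("constant", "reversing", "intermediate")[i % 3] for i in range(n)])
    tau = np.zeros((n, n_t, 3))
    tawss = np.empty(n)
    osi = np.empty(n)
    for i in range(n):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        if kinds[i] == "constant":
            mag = spec.wss_scale * (0.5 + rng.random())
            tau[i] = mag * direction
            tawss[i], osi[i] = mag, 0.0
        elif kinds[i] == "reversing":
            tau0 = spec.wss_scale * (0.5 + rng.random())
            tau[i] = np.outer(np.sin(omega * times), tau0 * direction)
            tawss[i], osi[i] = 2.0 * tau0 / np.pi, 0.5
        else:
            o = spec.wss_scale * (0.5 + rng.random())
            m = o * (0.2 + 0.6 * rng.random())  # 0 < m < o
            tau[i] = np.outer(m + o * np.sin(omega * times), direction)
            tw = (2.0 / np.pi) * (m * np.arcsin(m / o) + np.sqrt(o**2 - m**2))
            tawss[i] = tw
            osi[i] = 0.5 * (1.0 - m / tw)
    node_ids = np.arange(n)
    truth = WSSGroundTruth(
        node_ids=node_ids, tawss=tawss, osi=osi, ecap=osi / tawss, kind=kinds
    )
    return WSSHistory(node_ids=node_ids, times=times, tau=tau), truth


def gen_pressure_pair(
    spec: SynthSpec, n_samples: int = 128
) -> tuple["LuminalPlanePair", PressureGroundTruth]:
    """Paired TL/FL pressure traces with known transmural pressure.

    The luminal difference is d + a sin(2 pi t / T) on a common pulsatile
    baseline, so TMP_mean = d exactly and TMP_max = sign(d)(|d| + a) when
    d != 0 (for d = 0 the peak is +a, attained first at t = T/4 when the
    grid is a multiple of 4). Noise (``noise_sd``, mmHg) is added after
    ground truth is recorded.
    """
    from .metrics import LuminalPlanePair  # local import avoids a cycle

    rng = np.random.default_rng(spec.seed + 2)
    T = spec.period
    t = T * np.arange(n_samples) / n_samples
    base = 90.0 + 20.0 * np.sin(2.0 * np.pi * t / T - 0.3)
    d, a = spec.tmp_offset, spec.tmp_oscillation
    diff = d + a * np.sin(2.0 * np.pi * t / T)
    p_tl = base + diff / 2.0
    p_fl = base - diff / 2.0
    if spec.noise_sd > 0:
        p_tl = p_tl + rng.normal(0.0, spec.noise_sd, n_samples)
        p_fl = p_fl + rng.normal(0.0, spec.noise_sd, n_samples)
    tmp_max = np.sign(d) * (abs(d) + a) if d != 0 else a
    truth = PressureGroundTruth(tmp_mean=d, tmp_max=float(tmp_max))
    return LuminalPlanePair(times=t, p_tl=p_tl, p_fl=p_fl, period=T), truth
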