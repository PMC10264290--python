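"""Per-outlet flow and pressure targets for Windkessel calibration.

Measured mean branch flows within an anatomical group are converted to flow
fractions, and the fractions are re-scaled by the inter-plane flow loss of
the group so that measurement error at individual small branches does not
corrupt the total. Brachial cuff pressures are transformed to aortic-root
targets using the empirical peripheral-amplification relation
``P_s = 0.83 P'_s + 0.15 P'_d`` (diastolic pressure is carried through
unchanged, since it varies little along the arterial tree).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "BranchMeasurement",
    "OutletGroup",
    "PressureTargets",
    "branch_fractions",
    "target_flows",
    "aortic_pressure_targets",
    "rounded_pressure_targets",
    "minor_group_targets",
]

#: Coefficients of the brachial-to-aortic systolic transform.
SYSTOLIC_COEF = 0.83
DIASTOLIC_COEF = 0.15

_LUMINA = ("TL", "FL", "none")


@dataclass(frozen=True)
class BranchMeasurement:
    """A single branch with an optional measured mean flow.

    Parameters
    ----------
    name
        Unique label (e.g. ``"BT"``, ``"LSA"``).
    lumen
        Which lumen the branch originates from: ``"TL"``, ``"FL"`` or
        ``"none"`` (undissected aorta).
    measured_mean_flow
        Cycle-mean volumetric flow in mL/s, if measured. Minor branches
        below image resolution carry ``None`` and take literature values.
    """

    name: str
    lumen: str = "none"
    measured_mean_flow: float | None = None

    def __post_init__(self) -> None:
        if self.lumen not in _LUMINA:
            raise ValueError(f"lumen must be one of {_LUMINA}, got {self.lumen!r}")
        if self.measured_mean_flow is not None and self.measured_mean_flow < 0:
            raise ValueError(
                f"branch {self.name!r}: measured_mean_flow must be >= 0, "
                f"got {self.measured_mean_flow}"
            )


@dataclass
class OutletGroup:
    """A group of outlets sharing an inter-plane flow loss.

    ``fractions`` and ``targets`` are populated by :meth:`resolve` from the
    members' measured flows and the group flow loss.
    """

    name: str
    members: list[BranchMeasurement]
    group_flow_loss: float
    fractions: np.ndarray | None = field(default=None, repr=False)
    targets: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"group {self.name!r} has no members")
        if self.group_flow_loss < 0:
            raise ValueError(f"group {self.name!r}: flow loss must be >= 0")
        names = [m.name for m in self.members]
        if len(set(names)) != len(names):
            raise ValueError(f"group {self.name!r}: duplicate branch names")

    def resolve(self) -> "OutletGroup":
        """Fill fractions and per-member target flows from measurements."""
        flows = [m.measured_mean_flow for m in self.members]
        if any(q is None for q in flows):
            missing = [m.name for m in self.members if m.measured_mean_flow is None]
            raise ValueError(
                f"group {self.name!r}: members without measured flow: {missing}"
            )
        self.fractions = branch_fractions(flows)
        self.targets = target_flows(self.fractions, self.group_flow_loss)
        return self


@dataclass(frozen=True)
class PressureTargets:
    """Aortic-root pressure targets derived from a brachial measurement.

    All pressures in mmHg; ``pulse`` is systolic minus diastolic.
    """

    brachial_systolic: float
    brachial_diastolic: float
    systolic: float
    diastolic: float
    pulse: float

    def __post_init__(self) -> None:
        if not self.systolic > self.diastolic:
            raise ValueError(
                f"systolic ({self.systolic}) must exceed diastolic ({self.diastolic})"
            )
        if abs(self.pulse - (self.systolic - self.diastolic)) > 1e-9:
            raise ValueError("pulse pressure must equal systolic - diastolic")


def branch_fractions(group_measurements: Sequence[float]) -> np.ndarray:
    """Flow fraction of each branch within its group.

    ``phi_B = Qbar'_B / sum(Qbar')`` over the group. Fractions sum to 1.

    Raises
    ------
    ValueError
        If any flow is negative, or all flows are zero (undefined split).
    """
    q = np.asarray(group_measurements, dtype=float)
    if q.ndim != 1 or q.size == 0:
        raise ValueError("group_measurements must be a non-empty 1-D sequence")
    if np.any(q < 0):
        raise ValueError("measured flows must be >= 0")
    total = q.sum()
    if total <= 0:
        raise ValueError("all-zero group: flow split is undefined")
    return q / total


def target_flows(fractions: Sequence[float], group_flow_loss: float) -> np.ndarray:
    """Target mean flow per branch: ``Qbar_B = phi_B * Qbar'_Gamma``.

    The returned flows sum to ``group_flow_loss`` exactly.
    """
    phi = np.asarray(fractions, dtype=float)
    if group_flow_loss < 0:
        raise ValueError("group_flow_loss must be >= 0")
    if abs(phi.sum() - 1.0) > 1e-6:
        raise ValueError(f"fractions sum to {phi.sum():.9f}, expected 1 within 1e-6")
    return phi * group_flow_loss


def aortic_pressure_targets(
    brachial_systolic: float, brachial_diastolic: float
) -> PressureTargets:
    """Aortic-root systolic/diastolic targets from a brachial cuff reading.

    Systolic pressure amplifies peripherally, so the aortic value is
    reconstructed as ``0.83 P'_s + 0.15 P'_d``; diastolic is unchanged.
    Values are kept at full precision; use :func:`rounded_pressure_targets`
    for integer-mmHg presentation.
    """
    if not (brachial_systolic > brachial_diastolic > 0):
        raise ValueError(
            "require brachial_systolic > brachial_diastolic > 0, got "
            f"{brachial_systolic}/{brachial_diastolic}"
        )
    p_s = SYSTOLIC_COEF * brachial_systolic + DIASTOLIC_COEF * brachial_diastolic
    p_d = float(brachial_diastolic)
    return PressureTargets(
        brachial_systolic=float(brachial_systolic),
        brachial_diastolic=float(brachial_diastolic),
        systolic=p_s,
        diastolic=p_d,
        pulse=p_s - p_d,
    )


def rounded_pressure_targets(targets: PressureTargets) -> dict[str, int]:
    """Presentation helper: round targets to integer mmHg.

    Pulse is the difference of the rounded systolic and diastolic values so
    the printed triple stays self-consistent.
    """
    p_s = round(targets.systolic)
    p_d = round(targets.diastolic)
    return {"systolic_mmHg": p_s, "diastolic_mmHg": p_d, "pulse_mmHg": p_s - p_d}


def minor_group_targets(
    per_branch_literature_flows: Mapping[str, float],
    grouping: Mapping[str, Sequence[str]],
) -> dict[str, float]:
    """Group target flows for minor branches from per-branch literature flows.

    Minor branches (segmental arteries, IMA) sit below 4D-flow resolution,
    so their targets come from Doppler measurements in the literature; each
    group's target is the sum of its members' flows.

    Raises
    ------
    KeyError
        If a grouped branch has no literature flow entry (the message names
        the branch).
    ValueError
        If a group is empty.
    """
    out: dict[str, float] = {}
    for group, branches in grouping.items():
        if not branches:
            raise ValueError(f"group {group!r} is empty")
        total = 0.0
        for b in branches:
            if b not in per_branch_literature_flows:
                raise KeyError(f"no literature flow for branch {b!r} (group {group!r})")
            q = per_branch_literature_flows[b]
            if q < 0:
                raise ValueError(f"branch {b!r}: literature flow must be >= 0")
            total += q
        out[group] = total
    return out
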