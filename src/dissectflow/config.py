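"""Schema-validated study configuration.

One YAML file describes a study: outlet definitions per case (name, lumen,
group size, proximal fraction rho, target flow, optionally published WK3
parameters), brachial pressures, heart rate, solver and metric settings,
and viscosity constants. Unknown keys are rejected; units are part of
field names so no silent conversion can occur.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .metrics import ViscosityModel
from .zerod import WK3Params

__all__ = [
    "OutletConfig",
    "CaseConfig",
    "SolverConfig",
    "MetricConfig",
    "ViscosityConfig",
    "StudyConfig",
    "load_study",
    "load_packaged_study",
    "config_hash",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class OutletConfig(_Strict):
    name: str
    lumen: Literal["TL", "FL", "none"] = "none"
    rho: float = Field(gt=0, lt=1)
    n_branches: int = Field(default=1, ge=1)
    target_flow_mL_s: Optional[float] = Field(default=None, ge=0)
    measured_flow_mL_s: Optional[float] = Field(default=None, ge=0)
    cfd_flow_mL_s: Optional[float] = None
    R_tot_mmHg_per_mL_s: Optional[float] = Field(default=None, gt=0)
    C_mL_per_mmHg: Optional[float] = Field(default=None, gt=0)

    def wk3(self) -> WK3Params:
        """Published WK3 parameters, if the config carries them."""
        if self.R_tot_mmHg_per_mL_s is None or self.C_mL_per_mmHg is None:
            raise ValueError(f"outlet {self.name!r} carries no WK3 parameters")
        return WK3Params(self.R_tot_mmHg_per_mL_s, self.rho, self.C_mL_per_mmHg)


class CaseConfig(_Strict):
    outlets: list[OutletConfig]

    @model_validator(mode="after")
    def _unique_names(self) -> "CaseConfig":
        names = [o.name for o in self.outlets]
        if len(set(names)) != len(names):
            raise ValueError("outlet names must be unique within a case")
        return self

    def outlet(self, name: str) -> OutletConfig:
        for o in self.outlets:
            if o.name == name:
                return o
        raise KeyError(f"no outlet named {name!r}")

    def target_flows(self) -> dict[str, float]:
        out = {}
        for o in self.outlets:
            if o.target_flow_mL_s is None:
                raise ValueError(f"outlet {o.name!r} has no target flow")
            out[o.name] = o.target_flow_mL_s
        return out

    def network_outlets(self) -> list[tuple[str, WK3Params]]:
        return [(o.name, o.wk3()) for o in self.outlets]


class SolverConfig(_Strict):
    dt_s: float = Field(default=1e-3, gt=0)
    convergence_threshold: float = Field(default=0.01, gt=0, lt=1)
    max_cycles: int = Field(default=50, ge=2)
    venous_pressure_mmHg: float = 0.0


class MetricConfig(_Strict):
    wss_sampling_interval_s: float = Field(default=0.005, gt=0)
    ecap_threshold_per_Pa: float = Field(default=1.4, gt=0)


class ViscosityConfig(_Strict):
    mu0_Pa_s: float = 0.056
    mu_inf_Pa_s: float = 0.0035
    lambda_s: float = 3.313
    a: float = 2.0
    n: float = 0.3568
    density_kg_m3: float = 1056.0

    def model(self) -> ViscosityModel:
        return ViscosityModel(
            mu0=self.mu0_Pa_s,
            mu_inf=self.mu_inf_Pa_s,
            lambda_s=self.lambda_s,
            a=self.a,
            n=self.n,
            density=self.density_kg_m3,
        )


class MinorGroupConfig(_Strict):
    n_branches: int = Field(ge=1)
    total_flow_mL_s: float = Field(ge=0)


class StudyConfig(_Strict):
    name: str
    heart_rate_bpm: float = Field(gt=0)
    brachial_systolic_mmHg: float = Field(gt=0)
    brachial_diastolic_mmHg: float = Field(gt=0)
    cases: dict[str, CaseConfig]
    solver: SolverConfig = SolverConfig()
    metrics: MetricConfig = MetricConfig()
    viscosity: ViscosityConfig = ViscosityConfig()
    minor_branch_groups: dict[str, MinorGroupConfig] = {}
    seed: int = 0

    @model_validator(mode="after")
    def _pressure_order(self) -> "StudyConfig":
        if not self.brachial_systolic_mmHg > self.brachial_diastolic_mmHg:
            raise ValueError("brachial systolic must exceed diastolic")
        return self

    @property
    def period_s(self) -> float:
        return 60.0 / self.heart_rate_bpm

    def minor_branch_flows(self) -> dict[str, float]:
        """Per-branch literature flows, equal within each group."""
        flows: dict[str, float] = {}
        for group, cfg in self.minor_branch_groups.items():
            per = cfg.total_flow_mL_s / cfg.n_branches
            if cfg.n_branches == 1:
                flows[group] = per
            else:
                for i in range(1, cfg.n_branches + 1):
                    flows[f"{group}_{i}"] = per
        return flows

    def minor_grouping(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for group, cfg in self.minor_branch_groups.items():
            if cfg.n_branches == 1:
                out[group] = [group]
            else:
                out[group] = [f"{group}_{i}" for i in range(1, cfg.n_branches + 1)]
        return out


def load_study(path: str | Path) -> StudyConfig:
    """Load and schema-validate a study config YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return StudyConfig.model_validate(raw)


def load_packaged_study() -> StudyConfig:
    """The packaged chronic-dissection study fixture (cases D and D_min)."""
    ref = resources.files("dissectflow.data") / "tbad_case.yaml"
    return StudyConfig.model_validate(yaml.safe_load(ref.read_text()))


def config_hash(config: StudyConfig) -> str:
    """Short stable hash of a config, recorded in outputs for provenance."""
    payload = json.dumps(config.model_dump(), sort_keys=True, default=float)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
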