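import numpy as np
import pytest

from dissectflow.config import load_packaged_study
from dissectflow.outlet_targets import aortic_pressure_targets
from dissectflow.synth import SynthSpec, gen_inflow


@pytest.fixture(scope="session")
def study():
    return load_packaged_study()


@pytest.fixture(scope="session")
def pressure_targets(study):
    return aortic_pressure_targets(
        study.brachial_systolic_mmHg, study.brachial_diastolic_mmHg
    )


def inflow_matching(study, case: str):
    """Synthetic 94 bpm inflow whose cycle mean equals the case's total
    outlet target flow."""
    total = sum(study.cases[case].target_flows().values())
    spec = SynthSpec(
        heart_rate=study.heart_rate_bpm,
        stroke_volume=total * 60.0 / study.heart_rate_bpm,
    )
    return gen_inflow(spec)


@pytest.fixture(scope="session")
def inflow_case_d(study):
    return inflow_matching(study, "D")


@pytest.fixture(scope="session")
def inflow_case_dmin(study):
    return inflow_matching(study, "D_min")
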