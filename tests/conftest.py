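import pytest
from hypothesis import HealthCheck, settings

from adcrepeat.io import ROIMeasurement, TestRetestPair, pair_sessions
from adcrepeat.metrics import make_records
from adcrepeat.simulate import SyntheticConfig, generate_cohort

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


def make_pair(d1=109.0, d2=109.0, w1=50.0, w2=50.0, n1=2000, n2=2000,
              motion1=False, motion2=False, patient="P1",
              kind="whole_3d"):
    return TestRetestPair(
        ROIMeasurement(patient, kind, "test", n1, d1, w1, motion1),
        ROIMeasurement(patient, kind, "retest", n2, d2, w2, motion2),
    )


@pytest.fixture
def tumour_config():
    """Study-like cohort of 60 tumour ROIs (3 kinds x 20 patients), no
    motion."""
    return SyntheticConfig(
        n_patients=20,
        roi_kinds=("whole_3d", "slice_largest", "slice_solid"),
        motion_fraction=0.0, seed=11)


@pytest.fixture
def tumour_records(tumour_config):
    cohort = generate_cohort(tumour_config)
    return make_records(pair_sessions(cohort).pairs)
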