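import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cgmetrics import GlucoseTrace, RegularTrace, RunConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

START = np.datetime64("2024-01-01T00:00:00", "s")


@pytest.fixture
def cfg():
    return RunConfig()


def make_regular(values, interval_min=5.0, start=START, segment_ids=None, imputed=None):
    """Build a RegularTrace on a contiguous grid from raw values."""
    values = np.asarray(values, dtype=float)
    n = values.size
    step = np.timedelta64(int(interval_min * 60), "s")
    ts = start + np.arange(n) * step
    return RegularTrace(
        timestamps=ts,
        values=values,
        imputed=np.zeros(n, bool) if imputed is None else imputed,
        interval_min=interval_min,
        segment_ids=segment_ids,
    )


def make_trace(values, interval_min=5.0, start=START, subject_id="test"):
    """Build an observed GlucoseTrace on a contiguous grid."""
    values = np.asarray(values, dtype=float)
    step = np.timedelta64(int(interval_min * 60), "s")
    ts = start + np.arange(values.size) * step
    return GlucoseTrace(timestamps=ts, values=values, subject_id=subject_id)


@pytest.fixture
def make_regular_trace():
    return make_regular


@pytest.fixture
def make_glucose_trace():
    return make_trace
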