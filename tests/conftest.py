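import sys
from pathlib import Path

import numpy as np
import pytest

from wearloc import AlgorithmParams, DeviceRecording, default_schedule

# make tests/oracles.py importable regardless of rootdir
sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture
def params():
    """Default thresholds with the two-hour duration gate disabled."""
    return AlgorithmParams(enforce_min_duration=False)


@pytest.fixture
def short_schedule():
    """A 2.5-minute schedule: enough walking for every feature to define."""
    return default_schedule(150.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_recording(rng, n, device_id="dev", scale_acc=1.0, scale_gyro=150.0):
    """A recording of unstructured noise spanning all feature gates."""
    return DeviceRecording(
        device_id=device_id,
        acc=rng.normal(0.0, scale_acc, size=(n, 3)),
        gyro=rng.normal(0.0, scale_gyro, size=(n, 3)),
        sample_rate=59.5,
    )
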