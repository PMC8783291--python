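import numpy as np
import pytest

from wearvalid import protocol
from wearvalid.core import ActivitySchedule, Cluster, SensorStream, TaskWindow, VitalSign
from wearvalid.simulate import SyntheticCohortConfig, generate_cohort


@pytest.fixture(scope="session")
def schedule():
    """The default 17-task, 57-minute protocol schedule."""
    return protocol.default_schedule()


@pytest.fixture(scope="session")
def profiles():
    return protocol.default_profiles()


@pytest.fixture(scope="session")
def devices():
    return protocol.default_devices()


@pytest.fixture
def simple_schedule():
    """Two tasks with a 60 s transition gap: resting 120 s, walking 150 s."""
    return ActivitySchedule(
        [
            TaskWindow("rest", Cluster.RESTING, 0.0, 120.0),
            TaskWindow("walk", Cluster.WALKING, 180.0, 150.0),
        ]
    )


@pytest.fixture(scope="session")
def tiny_cohort(schedule, profiles, devices):
    """Three-participant default-device cohort shared across tests."""
    return generate_cohort(
        SyntheticCohortConfig(
            n_participants=3,
            schedule=schedule,
            profiles=profiles,
            devices=devices,
            seed=7,
        )
    )


def make_stream(t, values=None, *, period=10.0, vital=VitalSign.HR,
                participant="P01", device="dev"):
    t = np.asarray(t, dtype=float)
    if values is None:
        values = np.full(t.shape, 80.0)
    return SensorStream(
        participant_id=participant,
        device_id=device,
        vital_sign=vital,
        nominal_period_s=period,
        t=t,
        values=np.asarray(values, dtype=float),
    )
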