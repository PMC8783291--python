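"""Default study design: schedule, device models, physiology profiles.

These defaults describe a telemonitoring validation protocol: 20 volunteers
perform 17 standardized tasks (57 minutes of task time) grouped in six
activity clusters — resting, walking, metronome breathing, household chores,
stationary cycling, and recovery — while wearing three wearable sensors
(arm-worn on both arms, a chest patch, and a wrist tracker) alongside two
reference devices (a mobile metabolic system for HR/RR/SpO2 and skin
temperature loggers). The device parameters (storage periods, cluster-wise
bias and noise, dropout behavior) emulate the magnitudes such a study
reports; see docs/methods.md for the full rationale.
"""

from __future__ import annotations

from .core import ActivitySchedule, Cluster, TaskWindow, VitalSign
from .simulate import (
    ClusterTrend,
    DeviceModel,
    DropoutModel,
    ObservationChannel,
    PhysiologyProfile,
)

__all__ = [
    "default_schedule",
    "default_profiles",
    "default_devices",
    "default_registry",
    "DEVICE_PAIRS",
    "REFERENCE_DEVICES",
]

# Transition periods separate all tasks; longer ones follow intensive tasks.
_TRANSITION_S = 60.0
_LONG_TRANSITION_S = 120.0

# (task name, cluster, duration in minutes). 17 tasks, 57 minutes of task
# time, durations 2-10 min. Exact per-task durations of the original
# protocol are not published; this stand-in respects the cluster structure.
_DEFAULT_TASKS: list[tuple[str, Cluster, float]] = [
    ("lying_supine", Cluster.RESTING, 4),
    ("lying_side", Cluster.RESTING, 3),
    ("sitting", Cluster.RESTING, 4),
    ("standing", Cluster.RESTING, 2),
    ("walking_normal", Cluster.WALKING, 4),
    ("walking_slow", Cluster.WALKING, 3),
    ("stair_climbing", Cluster.WALKING, 2),
    ("breathing_6brpm", Cluster.BREATHING, 2),
    ("breathing_15brpm", Cluster.BREATHING, 2),
    ("breathing_20brpm", Cluster.BREATHING, 2),
    ("breathing_24brpm", Cluster.BREATHING, 2),
    ("preparing_food", Cluster.CHORES, 5),
    ("cleaning", Cluster.CHORES, 4),
    ("cycling", Cluster.CYCLING, 10),
    ("recovery_armchair", Cluster.RECOVERY, 3),
    ("recovery_couch", Cluster.RECOVERY, 3),
    ("recovery_sitting", Cluster.RECOVERY, 2),
]


def default_schedule() -> ActivitySchedule:
    """The default 17-task, 57-minute protocol schedule.

    Transitions of 60 s separate tasks (120 s after walking and cycling for
    physiological stabilization); transition periods never enter the
    analysis.
    """
    tasks: list[TaskWindow] = []
    t = _TRANSITION_S
    prev_cluster: Cluster | None = None
    for name, cluster, minutes in _DEFAULT_TASKS:
        if prev_cluster is not None:
            gap = (
                _LONG_TRANSITION_S
                if prev_cluster in (Cluster.WALKING, Cluster.CYCLING)
                and cluster != prev_cluster
                else _TRANSITION_S
            )
            t += gap
        tasks.append(TaskWindow(name, cluster, t, minutes * 60.0))
        t += minutes * 60.0
        prev_cluster = cluster
    return ActivitySchedule(tasks)


def default_profiles() -> dict[VitalSign, PhysiologyProfile]:
    """Ground-truth vital-sign trajectories per activity cluster.

    HR ramps to at least 120 bpm during cycling; RR follows the metronome
    sequence 6, 15, 20, 24 brpm exactly during the breathing cluster.
    """
    C = Cluster
    hr = PhysiologyProfile(
        vital=VitalSign.HR,
        trends={
            C.RESTING: ClusterTrend.constant(75, sd=3),
            C.WALKING: ClusterTrend.constant(95, sd=6),
            C.BREATHING: ClusterTrend.constant(78, sd=3),
            C.CHORES: ClusterTrend.constant(88, sd=5),
            C.CYCLING: ClusterTrend.ramp(85, 126, sd=4),
            C.RECOVERY: ClusterTrend.ramp(100, 78, sd=3),
        },
    )
    rr = PhysiologyProfile(
        vital=VitalSign.RR,
        trends={
            C.RESTING: ClusterTrend.constant(15, sd=1.5),
            C.WALKING: ClusterTrend.constant(18, sd=2),
            C.BREATHING: ClusterTrend.metronome((6, 15, 20, 24)),
            C.CHORES: ClusterTrend.constant(17, sd=2),
            C.CYCLING: ClusterTrend.constant(22, sd=2.5),
            C.RECOVERY: ClusterTrend.ramp(20, 15, sd=1.5),
        },
    )
    spo2 = PhysiologyProfile(
        vital=VitalSign.SPO2,
        trends={c: ClusterTrend.constant(98.2, sd=0.4) for c in C},
    )
    temp = PhysiologyProfile(
        vital=VitalSign.TEMP,
        trends={
            C.RESTING: ClusterTrend.constant(31.0, sd=0.1),
            C.WALKING: ClusterTrend.constant(31.2, sd=0.1),
            C.BREATHING: ClusterTrend.constant(31.3, sd=0.1),
            C.CHORES: ClusterTrend.constant(31.5, sd=0.1),
            C.CYCLING: ClusterTrend.ramp(31.5, 32.2, sd=0.1),
            C.RECOVERY: ClusterTrend.constant(32.0, sd=0.1),
        },
    )
    return {p.vital: p for p in (hr, rr, spo2, temp)}


def _by_cluster(
    resting=0.0, walking=0.0, breathing=0.0, chores=0.0, cycling=0.0,
    recovery=0.0,
) -> dict[Cluster, float]:
    return {
        Cluster.RESTING: resting,
        Cluster.WALKING: walking,
        Cluster.BREATHING: breathing,
        Cluster.CHORES: chores,
        Cluster.CYCLING: cycling,
        Cluster.RECOVERY: recovery,
    }


def _flat(rate: float) -> dict[Cluster, float]:
    return {c: rate for c in Cluster}


def _arm_sensor(side: str, hr_bias_cycling: float, hr_noise_cycling: float,
                hr_subject_sd: float, rr_bias: float, spo2_bias: float,
                temp_bias: float, temp_subject_sd: float) -> DeviceModel:
    """Arm-worn optical multi-sensor: HR/RR/SpO2 by PPG, temperature by
    thermistor; stores once per 10 s. PPG availability collapses with arm
    movement, so RR and especially SpO2 drop out heavily in active clusters.
    """
    return DeviceModel(
        device_id=f"arm_{side}",
        storage_period_s=10.0,
        channels={
            VitalSign.HR: ObservationChannel(
                vital=VitalSign.HR,
                bias=_by_cluster(walking=-8.0, chores=-1.0,
                                 cycling=hr_bias_cycling),
                noise_sd=_by_cluster(1.5, 18.0, 2.5, 4.0, hr_noise_cycling,
                                     1.5),
                subject_bias_sd=hr_subject_sd,
                resolution=1.0,
                noise_rho=0.85,
                dropout=DropoutModel(_flat(0.02), 2.08, 0.5),
            ),
            VitalSign.RR: ObservationChannel(
                vital=VitalSign.RR,
                bias=_by_cluster(-1.0, -2.5, rr_bias, -2.0, -3.0, -1.0),
                noise_sd=_by_cluster(2.5, 6.0, 4.7, 5.0, 6.0, 3.0),
                subject_bias_sd=2.0,
                resolution=1.0,
                noise_rho=0.85,
                dropout=DropoutModel(
                    _by_cluster(0.10, 0.80, 0.05, 0.30, 0.80, 0.10),
                    2.5, 1.0,
                ),
            ),
            VitalSign.SPO2: ObservationChannel(
                vital=VitalSign.SPO2,
                bias=_by_cluster(-2.0, -3.5, -2.0, -2.0, -1.5, spo2_bias),
                noise_sd=_by_cluster(1.5, 2.5, 1.5, 1.5, 1.5, 1.4),
                subject_bias_sd=0.8,
                resolution=1.0,
                noise_rho=0.85,
                dropout=DropoutModel(
                    _by_cluster(1.2, 4.0, 1.0, 4.0, 1.5, 0.8),
                    3.2, 1.2,
                ),
            ),
            VitalSign.TEMP: ObservationChannel(
                vital=VitalSign.TEMP,
                bias=_flat(temp_bias),
                noise_sd=_by_cluster(0.3, 0.4, 0.3, 0.35, 0.35, 0.35),
                subject_bias_sd=temp_subject_sd,
                resolution=0.1,
                noise_rho=0.6,
                dropout=DropoutModel(_flat(0.01), 2.08, 0.4),
            ),
        },
    )


def default_devices() -> list[DeviceModel]:
    """Device observation models for the 4 wearables and 2 reference types.

    Site differences in skin temperature (arm vs chest) are expressed as
    additive device biases against a single shared truth, so only pairwise
    differences between co-located devices are physically meaningful.
    """
    C = Cluster
    devices: list[DeviceModel] = [
        # Arm-worn multi-sensor, both arms (HR bias/LoA emulate the reported
        # cycling-cluster validity of an upper-arm PPG sensor).
        _arm_sensor("right", hr_bias_cycling=-4.2, hr_noise_cycling=9.0,
                    hr_subject_sd=11.0, rr_bias=-0.4, spo2_bias=-1.1,
                    temp_bias=2.2, temp_subject_sd=0.45),
        _arm_sensor("left", hr_bias_cycling=-5.3, hr_noise_cycling=13.0,
                    hr_subject_sd=11.5, rr_bias=0.1, spo2_bias=-1.3,
                    temp_bias=2.4, temp_subject_sd=0.7),
        # Chest patch: ECG-based HR/RR and chest thermistor, once per 4 s;
        # the most available and accurate wearable.
        DeviceModel(
            device_id="chest_patch",
            storage_period_s=4.0,
            channels={
                VitalSign.HR: ObservationChannel(
                    vital=VitalSign.HR,
                    bias=_by_cluster(cycling=0.1),
                    noise_sd=_by_cluster(1.5, 8.0, 2.0, 3.0, 5.5, 1.5),
                    subject_bias_sd=4.0,
                    resolution=1.0,
                    noise_rho=0.85,
                    dropout=DropoutModel(_flat(0.03), 2.08, 0.4),
                ),
                VitalSign.RR: ObservationChannel(
                    vital=VitalSign.RR,
                    bias=_by_cluster(breathing=-0.1, walking=-0.5,
                                     chores=-1.0),
                    noise_sd=_by_cluster(1.5, 2.0, 3.5, 3.0, 2.0, 1.8),
                    subject_bias_sd=1.5,
                    resolution=1.0,
                    noise_rho=0.85,
                    dropout=DropoutModel(_flat(0.03), 2.08, 0.4),
                ),
                VitalSign.TEMP: ObservationChannel(
                    vital=VitalSign.TEMP,
                    bias=_flat(2.9),
                    noise_sd=_flat(0.3),
                    subject_bias_sd=0.45,
                    resolution=0.1,
                    noise_rho=0.6,
                    dropout=DropoutModel(_flat(0.03), 2.08, 0.4),
                ),
            },
        ),
        # Wrist tracker: PPG heart rate only; stores at an activity-dependent
        # rate, emulated at its slowest advertised period (once per 5 s),
        # with frequent short dropout epochs.
        DeviceModel(
            device_id="wrist_tracker",
            storage_period_s=5.0,
            channels={
                VitalSign.HR: ObservationChannel(
                    vital=VitalSign.HR,
                    bias=_by_cluster(walking=-12.0, breathing=-1.0,
                                     chores=-4.0, cycling=-11.4),
                    noise_sd=_by_cluster(2.0, 15.0, 3.5, 7.0, 16.0, 2.0),
                    subject_bias_sd=14.5,
                    resolution=1.0,
                    noise_rho=0.85,
                    dropout=DropoutModel(_flat(2.56), 2.14, 0.25),
                ),
            },
        ),
        # Mobile metabolic reference: ECG heart rate, expired-volume
        # respiratory rate, ear-probe SpO2; once per 5 s.
        DeviceModel(
            device_id="metabolic_ref",
            storage_period_s=5.0,
            channels={
                VitalSign.HR: ObservationChannel(
                    vital=VitalSign.HR, bias=_flat(0.0),
                    noise_sd=_by_cluster(1.0, 2.5, 1.0, 1.5, 1.5, 1.0),
                    subject_bias_sd=0.0, resolution=1.0, noise_rho=0.6,
                    dropout=DropoutModel(_flat(0.01), 2.08, 0.3),
                ),
                VitalSign.RR: ObservationChannel(
                    vital=VitalSign.RR, bias=_flat(0.0),
                    noise_sd=_by_cluster(1.0, 1.5, 0.8, 1.5, 1.5, 1.0),
                    subject_bias_sd=0.0, resolution=0.5, noise_rho=0.6,
                    dropout=DropoutModel(_flat(0.01), 2.08, 0.3),
                ),
                VitalSign.SPO2: ObservationChannel(
                    vital=VitalSign.SPO2, bias=_flat(0.5),
                    noise_sd=_flat(0.4), subject_bias_sd=0.0,
                    resolution=1.0, noise_rho=0.6,
                    dropout=DropoutModel(_flat(0.02), 2.3, 0.5),
                ),
            },
        ),
    ]
    # Skin-temperature logger references at the three wearable sites,
    # once per 10 s with the logger's 0.5 degC resolution.
    for site, bias in (("right", -0.5), ("left", -0.5), ("chest", 2.4)):
        devices.append(
            DeviceModel(
                device_id=f"temp_logger_{site}",
                storage_period_s=10.0,
                channels={
                    VitalSign.TEMP: ObservationChannel(
                        vital=VitalSign.TEMP,
                        bias=_flat(bias),
                        noise_sd=_flat(0.1),
                        subject_bias_sd=0.0,
                        resolution=0.5,
                        dropout=None,
                    ),
                },
            )
        )
    del C
    return devices


#: The 12 analyzed wearable/reference combinations:
#: (wearable device, vital sign, reference device).
DEVICE_PAIRS: list[tuple[str, VitalSign, str]] = [
    ("arm_right", VitalSign.HR, "metabolic_ref"),
    ("arm_left", VitalSign.HR, "metabolic_ref"),
    ("chest_patch", VitalSign.HR, "metabolic_ref"),
    ("wrist_tracker", VitalSign.HR, "metabolic_ref"),
    ("arm_right", VitalSign.RR, "metabolic_ref"),
    ("arm_left", VitalSign.RR, "metabolic_ref"),
    ("chest_patch", VitalSign.RR, "metabolic_ref"),
    ("arm_right", VitalSign.SPO2, "metabolic_ref"),
    ("arm_left", VitalSign.SPO2, "metabolic_ref"),
    ("arm_right", VitalSign.TEMP, "temp_logger_right"),
    ("arm_left", VitalSign.TEMP, "temp_logger_left"),
    ("chest_patch", VitalSign.TEMP, "temp_logger_chest"),
]

REFERENCE_DEVICES: frozenset[str] = frozenset(
    {"metabolic_ref", "temp_logger_right", "temp_logger_left",
     "temp_logger_chest"}
)


def default_registry() -> dict[str, dict[VitalSign, float]]:
    """Device registry: nominal storage period per device and vital sign."""
    return {
        d.device_id: {v: d.storage_period_s for v in d.channels}
        for d in default_devices()
    }
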