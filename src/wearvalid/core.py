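"""Shared data model: vital signs, activity clusters, schedules, sensor streams.

Timestamps throughout the package are real-valued seconds from experiment
start; wall-clock time and clock drift are out of scope (devices are assumed
to have been synchronized before the experiment).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "VitalSign",
    "Cluster",
    "TaskWindow",
    "ActivitySchedule",
    "SensorStream",
    "ExclusionIntervals",
    "ConfigurationError",
    "DataError",
    "UNITS",
    "PHYSIOLOGICAL_RANGE",
]


class ConfigurationError(ValueError):
    """A run or device configuration is inconsistent or incomplete."""


class DataError(ValueError):
    """An input file or in-memory dataset violates a structural invariant."""


class VitalSign(str, enum.Enum):
    """The four continuously monitored vital signs."""

    HR = "HR"      # heart rate, beats per minute
    RR = "RR"      # respiratory rate, breaths per minute
    SPO2 = "SPO2"  # peripheral oxygen saturation, percent
    TEMP = "TEMP"  # skin temperature, degrees Celsius

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


UNITS: dict[VitalSign, str] = {
    VitalSign.HR: "bpm",
    VitalSign.RR: "brpm",
    VitalSign.SPO2: "%",
    VitalSign.TEMP: "degC",
}

#: Plausible physiological range per vital sign (used to validate simulation
#: profiles, not to censor observed data).
PHYSIOLOGICAL_RANGE: dict[VitalSign, tuple[float, float]] = {
    VitalSign.HR: (30.0, 220.0),
    VitalSign.RR: (4.0, 60.0),
    VitalSign.SPO2: (70.0, 100.0),
    VitalSign.TEMP: (25.0, 40.0),
}


class Cluster(str, enum.Enum):
    """The six activity clusters of the measurement protocol."""

    RESTING = "resting"
    WALKING = "walking"
    BREATHING = "breathing"
    CHORES = "chores"
    CYCLING = "cycling"
    RECOVERY = "recovery"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class TaskWindow:
    """One protocol task: a named, cluster-labeled time window."""

    name: str
    cluster: Cluster
    start_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise DataError(f"task {self.name!r}: duration must be > 0")
        object.__setattr__(self, "cluster", Cluster(self.cluster))

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    @property
    def n_minutes(self) -> int:
        """Number of minute bins; a partial trailing minute counts as one."""
        return int(np.ceil(self.duration_s / 60.0))


class ActivitySchedule:
    """Ordered, non-overlapping task windows; gaps are transition periods.

    Task windows are closed intervals ``[start, start + duration]`` for
    sample membership; when two tasks abut exactly, the shared boundary
    instant belongs to the later task.
    """

    def __init__(self, tasks: list[TaskWindow] | tuple[TaskWindow, ...]):
        tasks = tuple(tasks)
        for a, b in zip(tasks, tasks[1:]):
            if b.start_s < a.start_s:
                raise DataError(
                    f"tasks out of order: {b.name!r} starts before {a.name!r}"
                )
            if b.start_s < a.end_s:
                raise DataError(
                    f"overlapping task windows: {a.name!r} and {b.name!r}"
                )
        self.tasks = tasks

    def __len__(self) -> int:
        return len(self.tasks)

    def __iter__(self):
        return iter(self.tasks)

    @property
    def total_task_duration_s(self) -> float:
        return float(sum(t.duration_s for t in self.tasks))

    @property
    def clusters(self) -> list[Cluster]:
        """Distinct clusters in first-appearance order."""
        seen: list[Cluster] = []
        for t in self.tasks:
            if t.cluster not in seen:
                seen.append(t.cluster)
        return seen

    def windows(self, cluster: Cluster | None = None) -> list[TaskWindow]:
        if cluster is None:
            return list(self.tasks)
        cluster = Cluster(cluster)
        return [t for t in self.tasks if t.cluster == cluster]

    def locate(self, t: np.ndarray) -> np.ndarray:
        """Map timestamps to task indices (-1 for transition periods).

        Membership is closed on both edges; an instant shared by an end and
        the next start is assigned to the later task.
        """
        t = np.asarray(t, dtype=float)
        idx = np.full(t.shape, -1, dtype=int)
        for i, task in enumerate(self.tasks):
            inside = (t >= task.start_s) & (t <= task.end_s)
            idx[inside] = i  # later windows overwrite a shared boundary
        return idx

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "task": [t.name for t in self.tasks],
                "cluster": [t.cluster.value for t in self.tasks],
                "start_s": [t.start_s for t in self.tasks],
                "duration_s": [t.duration_s for t in self.tasks],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ActivitySchedule":
        required = {"task", "cluster", "start_s", "duration_s"}
        missing = required - set(frame.columns)
        if missing:
            raise DataError(f"schedule is missing columns: {sorted(missing)}")
        frame = frame.sort_values("start_s", kind="stable")
        tasks = [
            TaskWindow(
                name=str(r.task),
                cluster=Cluster(r.cluster),
                start_s=float(r.start_s),
                duration_s=float(r.duration_s),
            )
            for r in frame.itertuples()
        ]
        return cls(tasks)

    def __eq__(self, other) -> bool:
        return isinstance(other, ActivitySchedule) and self.tasks == other.tasks


@dataclass
class SensorStream:
    """One device's irregular time series of one vital sign for one participant.

    ``task`` and ``cluster`` label arrays are attached by
    :func:`wearvalid.alignment.window_by_tasks`; before windowing they are
    ``None``.
    """

    participant_id: str
    device_id: str
    vital_sign: VitalSign
    nominal_period_s: float
    t: np.ndarray
    values: np.ndarray
    unit: str = ""
    task: np.ndarray | None = None
    cluster: np.ndarray | None = None
    t_in_task_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vital_sign = VitalSign(self.vital_sign)
        if not self.unit:
            self.unit = UNITS[self.vital_sign]
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.nominal_period_s <= 0:
            raise ConfigurationError("nominal_period_s must be > 0")
        if self.t.shape != self.values.shape:
            raise DataError("timestamps and values differ in length")
        if self.t.size and not np.all(np.isfinite(self.values)):
            bad = int(np.flatnonzero(~np.isfinite(self.values))[0])
            raise DataError(f"non-finite value at row {bad}")
        if self.t.size > 1:
            d = np.diff(self.t)
            if np.any(d <= 0):
                bad = int(np.flatnonzero(d <= 0)[0]) + 1
                raise DataError(
                    f"timestamps not strictly increasing at row {bad} "
                    f"(t={self.t[bad]})"
                )

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def is_windowed(self) -> bool:
        return self.cluster is not None

    def subset(self, mask: np.ndarray) -> "SensorStream":
        """A copy restricted to ``mask``, preserving any labels."""
        return replace(
            self,
            t=self.t[mask],
            values=self.values[mask],
            task=None if self.task is None else self.task[mask],
            cluster=None if self.cluster is None else self.cluster[mask],
            t_in_task_s=(
                None if self.t_in_task_s is None else self.t_in_task_s[mask]
            ),
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "device_id": self.device_id,
                "vital_sign": self.vital_sign.value,
                "t_s": self.t,
                "value": self.values,
            }
        )
        if self.cluster is not None:
            frame["cluster"] = [c.value for c in self.cluster]
            frame["task"] = self.task
        return frame


@dataclass
class ExclusionIntervals:
    """Per-(participant, vital sign) intervals of implausible reference data.

    Intervals are half-open ``[start, end)``. The study's manual screening of
    reference plausibility is consumed here as a file-based input; no
    automated artifact detector is applied.
    """

    intervals: dict[tuple[str, VitalSign], list[tuple[float, float]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for key, spans in self.intervals.items():
            for lo, hi in spans:
                if not lo < hi:
                    raise DataError(
                        f"exclusion interval for {key} has start >= end "
                        f"({lo}, {hi})"
                    )

    def for_stream(self, stream: SensorStream) -> list[tuple[float, float]]:
        return self.intervals.get(
            (stream.participant_id, VitalSign(stream.vital_sign)), []
        )

    def __bool__(self) -> bool:
        return any(self.intervals.values())
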