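"""Reading and writing of streams, schedules, registries, and exclusions.

File formats (all plain text):

* streams — CSV with columns participant_id, device_id, vital_sign,
  t_s (seconds from experiment start), value; one stream per file via
  :func:`read_stream` / :func:`write_stream`, or many streams stacked in a
  single long CSV via :func:`read_streams` / :func:`write_streams`.
* schedule — CSV with columns task, cluster, start_s, duration_s.
* device registry — YAML mapping device_id -> {vital_sign: period_s}.
* exclusion intervals — CSV with columns participant_id, vital_sign,
  start_s, end_s (half-open intervals of discarded reference data).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    ActivitySchedule,
    ConfigurationError,
    DataError,
    ExclusionIntervals,
    SensorStream,
    VitalSign,
)

__all__ = [
    "read_stream",
    "read_streams",
    "write_stream",
    "write_streams",
    "read_schedule",
    "write_schedule",
    "read_registry",
    "write_registry",
    "read_exclusions",
    "write_exclusions",
    "apply_exclusions",
]

logger = logging.getLogger(__name__)

STREAM_COLUMNS = ["participant_id", "device_id", "vital_sign", "t_s", "value"]

Registry = dict[str, dict[VitalSign, float]]


def _lookup_period(registry: Registry, device_id: str, vital: VitalSign
                   ) -> float:
    if device_id not in registry:
        raise ConfigurationError(f"unknown device {device_id!r} in registry")
    periods = registry[device_id]
    if vital not in periods:
        raise ConfigurationError(
            f"device {device_id!r} has no registered period for "
            f"{vital.value}"
        )
    return float(periods[vital])


def _stream_from_frame(frame: pd.DataFrame, registry: Registry
                       ) -> SensorStream:
    participant = str(frame["participant_id"].iloc[0])
    device = str(frame["device_id"].iloc[0])
    vital = VitalSign(str(frame["vital_sign"].iloc[0]))
    return SensorStream(
        participant_id=participant,
        device_id=device,
        vital_sign=vital,
        nominal_period_s=_lookup_period(registry, device, vital),
        t=frame["t_s"].to_numpy(dtype=float),
        values=frame["value"].to_numpy(dtype=float),
    )


def read_stream(path: str | Path, registry: Registry,
                empty_key: tuple[str, str, str] | None = None
                ) -> SensorStream:
    """Read a single-stream CSV and validate it against the registry.

    An empty file yields an empty (valid) stream when ``empty_key`` =
    (participant_id, device_id, vital_sign) supplies the identity that the
    rows would otherwise carry; availability will then report 100% missing.
    """
    frame = pd.read_csv(path)
    missing = set(STREAM_COLUMNS) - set(frame.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    if frame.empty:
        if empty_key is None:
            raise DataError(
                f"{path}: empty stream file needs empty_key to identify "
                "participant/device/vital"
            )
        participant, device, vital = empty_key
        vital = VitalSign(vital)
        return SensorStream(
            participant_id=participant,
            device_id=device,
            vital_sign=vital,
            nominal_period_s=_lookup_period(registry, device, vital),
            t=np.empty(0),
            values=np.empty(0),
        )
    keys = frame[["participant_id", "device_id", "vital_sign"]
                 ].drop_duplicates()
    if len(keys) > 1:
        raise DataError(
            f"{path}: contains {len(keys)} streams; use read_streams()"
        )
    try:
        return _stream_from_frame(frame, registry)
    except DataError as err:
        raise DataError(f"{path}: {err}") from err


def read_streams(path: str | Path, registry: Registry) -> list[SensorStream]:
    """Read a long-format CSV holding many streams."""
    frame = pd.read_csv(path)
    missing = set(STREAM_COLUMNS) - set(frame.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    streams = []
    for _, sub in frame.groupby(
        ["participant_id", "device_id", "vital_sign"], sort=True
    ):
        try:
            streams.append(_stream_from_frame(sub, registry))
        except DataError as err:
            raise DataError(f"{path}: {err}") from err
    return streams


def write_stream(stream: SensorStream, path: str | Path) -> None:
    stream.to_frame()[STREAM_COLUMNS].to_csv(path, index=False)


def write_streams(streams: list[SensorStream], path: str | Path) -> None:
    frames = [s.to_frame()[STREAM_COLUMNS] for s in streams]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_schedule(path: str | Path) -> ActivitySchedule:
    """Read and validate a schedule CSV; logs the total task duration."""
    schedule = ActivitySchedule.from_frame(pd.read_csv(path))
    logger.info(
        "schedule %s: %d tasks, %.0f s of task time",
        path, len(schedule), schedule.total_task_duration_s,
    )
    return schedule


def write_schedule(schedule: ActivitySchedule, path: str | Path) -> None:
    schedule.to_frame().to_csv(path, index=False)


def read_registry(path: str | Path) -> Registry:
    """Read a YAML device registry: device_id -> {vital_sign: period_s}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: registry must be a mapping")
    registry: Registry = {}
    for device_id, periods in raw.items():
        if not isinstance(periods, dict):
            raise ConfigurationError(
                f"{path}: registry entry {device_id!r} must map vital signs "
                "to periods"
            )
        entry: dict[VitalSign, float] = {}
        for vital, period in periods.items():
            period = float(period)
            if period <= 0:
                raise ConfigurationError(
                    f"{path}: {device_id!r}/{vital}: period must be > 0"
                )
            entry[VitalSign(vital)] = period
        registry[str(device_id)] = entry
    return registry


def write_registry(registry: Registry, path: str | Path) -> None:
    raw = {
        device: {v.value: float(p) for v, p in periods.items()}
        for device, periods in registry.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)


def read_exclusions(path: str | Path) -> ExclusionIntervals:
    """Read reference-exclusion intervals from CSV."""
    frame = pd.read_csv(path)
    required = {"participant_id", "vital_sign", "start_s", "end_s"}
    missing = required - set(frame.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    intervals: dict[tuple[str, VitalSign], list[tuple[float, float]]] = {}
    for row in frame.itertuples():
        key = (str(row.participant_id), VitalSign(str(row.vital_sign)))
        intervals.setdefault(key, []).append(
            (float(row.start_s), float(row.end_s))
        )
    return ExclusionIntervals(intervals)


def write_exclusions(excl: ExclusionIntervals, path: str | Path) -> None:
    rows = [
        {"participant_id": pid, "vital_sign": vital.value,
         "start_s": lo, "end_s": hi}
        for (pid, vital), spans in excl.intervals.items()
        for lo, hi in spans
    ]
    pd.DataFrame(
        rows, columns=["participant_id", "vital_sign", "start_s", "end_s"]
    ).to_csv(path, index=False)


def apply_exclusions(
    stream: SensorStream, excl: ExclusionIntervals
) -> SensorStream:
    """Drop samples inside any half-open exclusion interval [start, end).

    Idempotent; an empty exclusion set returns the stream unchanged.
    """
    spans = excl.for_stream(stream)
    if not spans or len(stream) == 0:
        return stream
    keep = np.ones(len(stream), dtype=bool)
    for lo, hi in spans:
        keep &= ~((stream.t >= lo) & (stream.t < hi))
    if keep.all():
        return stream
    return stream.subset(keep)
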