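"""Missing-data quantification: expected counts, percentages, and epochs.

An *epoch* is a contiguous period in which a device stored no samples
although its nominal storage period expected them. Within each task window
the expected storage grid is t = start + k * period, k = 1..floor(D/period);
each gap between consecutive stored samples longer than the period yields
one epoch of duration (gap - period) containing floor(gap/period) - 1
missing samples. The same rule covers the window edges by bracketing the
stored samples with virtual sentinels one period outside the expected grid
(at the window start and at start + (K+1) * period), so a stream that is
absent for a whole task forms a single epoch spanning the task and the
conservation identity observed + missing = expected holds exactly for
grid-aligned streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ActivitySchedule, Cluster, SensorStream

__all__ = [
    "MissingEpoch",
    "AvailabilityReport",
    "expected_samples",
    "missing_percentage",
    "availability_percentage",
    "missing_epochs",
    "epoch_summary",
    "availability_report",
]

_EPS = 1e-9

#: Epoch-duration thresholds (seconds) reported by epoch_summary.
EPOCH_THRESHOLDS_S = (10.0, 30.0, 60.0)


@dataclass(frozen=True)
class MissingEpoch:
    """One contiguous missing-data period inside a task window."""

    task: str
    cluster: Cluster
    start_s: float
    duration_s: float
    n_missing: int


def expected_samples(
    schedule: ActivitySchedule,
    period_s: float,
    cluster: Cluster | None = None,
) -> int:
    """Expected stored-sample count: sum of floor(duration/period) over the
    selected task windows."""
    if period_s <= 0:
        raise ValueError("period_s must be > 0")
    return int(
        sum(
            int(np.floor(w.duration_s / period_s + _EPS))
            for w in schedule.windows(cluster)
        )
    )


def missing_percentage(observed: int, expected: int) -> float:
    """Percentage of missing data points out of the expected data points.

    Returns NaN (not applicable) when nothing was expected.
    """
    if expected < 0 or observed < 0:
        raise ValueError("counts must be non-negative")
    if expected == 0:
        return float("nan")
    pct = 100.0 * (expected - min(observed, expected)) / expected
    return pct


def availability_percentage(observed: int, expected: int) -> float:
    """Complement of missing_percentage: 100 * observed / expected."""
    pct = missing_percentage(observed, expected)
    return 100.0 - pct if np.isfinite(pct) else pct


def missing_epochs(
    stream: SensorStream, schedule: ActivitySchedule
) -> list[MissingEpoch]:
    """Inventory missing-data epochs of a stream, per task window."""
    period = stream.nominal_period_s
    epochs: list[MissingEpoch] = []
    for task in schedule:
        k_exp = int(np.floor(task.duration_s / period + _EPS))
        if k_exp == 0:
            continue
        inside = (stream.t >= task.start_s) & (stream.t <= task.end_s)
        ts = stream.t[inside]
        # sentinels one period outside the expected grid on both sides
        lo = task.start_s
        hi = task.start_s + (k_exp + 1) * period
        ts = np.concatenate(([lo], ts, [hi]))
        gaps = np.diff(ts)
        for j in np.flatnonzero(gaps > period + _EPS):
            gap = gaps[j]
            epochs.append(
                MissingEpoch(
                    task=task.name,
                    cluster=task.cluster,
                    start_s=float(ts[j] + period),
                    duration_s=float(gap - period),
                    n_missing=int(np.floor(gap / period + _EPS)) - 1,
                )
            )
    return epochs


def epoch_summary(
    epochs: list[MissingEpoch],
    thresholds_s: tuple[float, ...] = EPOCH_THRESHOLDS_S,
) -> pd.DataFrame:
    """Fractions of epochs at or below / above duration thresholds.

    Returns one row per threshold with counts and 2-decimal percentages;
    percentages are NaN (not applicable) when there are no epochs.
    """
    n = len(epochs)
    durations = np.array([e.duration_s for e in epochs])
    rows = []
    for thr in thresholds_s:
        n_le = int(np.sum(durations <= thr + _EPS)) if n else 0
        rows.append(
            {
                "threshold_s": thr,
                "n_epochs": n,
                "n_le": n_le,
                "n_gt": n - n_le,
                "pct_le": round(100.0 * n_le / n, 2) if n else float("nan"),
                "pct_gt": (
                    round(100.0 * (n - n_le) / n, 2) if n else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AvailabilityReport:
    """Expected/observed counts and missing epochs for one stream.

    ``frame`` holds one row per activity cluster plus an ``all`` row with
    columns: cluster, expected, observed, missing_pct (2-decimal).
    """

    participant_id: str
    device_id: str
    vital_sign: str
    frame: pd.DataFrame
    epochs: list[MissingEpoch] = field(default_factory=list)

    def epochs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "device_id": self.device_id,
                "vital_sign": self.vital_sign,
                "task": [e.task for e in self.epochs],
                "cluster": [e.cluster.value for e in self.epochs],
                "start_s": [e.start_s for e in self.epochs],
                "duration_s": [e.duration_s for e in self.epochs],
                "n_missing": [e.n_missing for e in self.epochs],
            }
        )


def availability_report(
    stream: SensorStream, schedule: ActivitySchedule
) -> AvailabilityReport:
    """Per-cluster and overall missing-data report for one stream."""
    period = stream.nominal_period_s
    idx = schedule.locate(stream.t)
    rows = []
    total_exp = 0
    total_obs = 0
    for cluster in schedule.clusters:
        exp = expected_samples(schedule, period, cluster)
        member = [i for i, t in enumerate(schedule.tasks)
                  if t.cluster == cluster]
        obs = int(np.isin(idx, member).sum())
        total_exp += exp
        total_obs += min(obs, exp)
        rows.append(
            {
                "cluster": cluster.value,
                "expected": exp,
                "observed": obs,
                "missing_pct": round(missing_percentage(obs, exp), 2),
            }
        )
    rows.append(
        {
            "cluster": "all",
            "expected": total_exp,
            "observed": total_obs,
            "missing_pct": round(
                missing_percentage(total_obs, total_exp), 2
            ),
        }
    )
    return AvailabilityReport(
        participant_id=stream.participant_id,
        device_id=stream.device_id,
        vital_sign=stream.vital_sign.value,
        frame=pd.DataFrame(rows),
        epochs=missing_epochs(stream, schedule),
    )
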