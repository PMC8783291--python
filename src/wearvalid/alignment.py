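"""Task windowing, nearest-neighbor pairing, and minute binning.

The pairing direction is wearable -> reference: every wearable sample whose
nearest-in-time reference sample lies within the shift cap contributes one
pair, and a reference sample may serve several wearable samples. No
interpolation or resampling to a common grid is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import (
    ActivitySchedule,
    Cluster,
    ConfigurationError,
    SensorStream,
    VitalSign,
)

__all__ = [
    "PairedSeries",
    "window_by_tasks",
    "pair_nearest",
    "assign_minutes",
    "pair_streams",
    "pairs_frame",
]

#: Default cap on the wearable-reference time shift: half the coarsest
#: storage period among the studied devices (10 s).
DEFAULT_MAX_SHIFT_S = 5.0

PAIR_COLUMNS = [
    "t_s", "wearable", "reference", "offset_s", "task", "cluster",
    "t_in_task_s", "minute_index",
]


@dataclass
class PairedSeries:
    """Wearable/reference sample pairs for one participant and vital sign.

    ``frame`` columns: t_s (wearable timestamp), wearable, reference,
    offset_s (wearable minus reference timestamp), task, cluster,
    t_in_task_s, minute_index (task-anchored; -1 until assigned).
    """

    participant_id: str
    vital_sign: VitalSign
    device_id: str
    reference_id: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.vital_sign = VitalSign(self.vital_sign)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def differences(self) -> np.ndarray:
        """Pairwise differences, wearable minus reference."""
        return (self.frame["wearable"] - self.frame["reference"]).to_numpy()

    def to_frame(self) -> pd.DataFrame:
        out = self.frame.copy()
        out.insert(0, "participant_id", self.participant_id)
        out.insert(1, "vital_sign", self.vital_sign.value)
        out.insert(2, "device_id", self.device_id)
        out.insert(3, "reference_id", self.reference_id)
        return out


def window_by_tasks(
    stream: SensorStream, schedule: ActivitySchedule
) -> SensorStream:
    """Restrict a stream to task windows and label samples by task/cluster.

    Samples in transition periods (between windows) are dropped. Window
    membership is closed on both edges; a sample on a shared boundary of
    abutting windows goes to the later window.
    """
    idx = schedule.locate(stream.t)
    keep = idx >= 0
    kept_idx = idx[keep]
    tasks = np.array([schedule.tasks[i].name for i in kept_idx], dtype=object)
    clusters = np.array(
        [schedule.tasks[i].cluster for i in kept_idx], dtype=object
    )
    starts = np.array([schedule.tasks[i].start_s for i in kept_idx])
    t_kept = stream.t[keep]
    return replace(
        stream,
        t=t_kept,
        values=stream.values[keep],
        task=tasks,
        cluster=clusters,
        t_in_task_s=t_kept - starts if t_kept.size else np.empty(0),
    )


def pair_nearest(
    wearable: SensorStream,
    reference: SensorStream,
    max_shift_s: float = DEFAULT_MAX_SHIFT_S,
) -> PairedSeries:
    """Pair each wearable sample with its nearest-in-time reference sample.

    Wearable samples with no reference within ``max_shift_s`` are omitted.
    Equidistant candidates resolve to the earlier reference sample, which is
    deterministic and independent of input chunking.
    """
    if VitalSign(wearable.vital_sign) != VitalSign(reference.vital_sign):
        raise ConfigurationError(
            f"cannot pair {wearable.vital_sign.value} with "
            f"{reference.vital_sign.value}"
        )
    if not wearable.is_windowed:
        raise ConfigurationError("wearable stream must be windowed first")
    if not reference.is_windowed:
        raise ConfigurationError("reference stream must be windowed first")
    empty = pd.DataFrame(columns=PAIR_COLUMNS)
    if len(wearable) == 0 or len(reference) == 0:
        return PairedSeries(
            wearable.participant_id, wearable.vital_sign,
            wearable.device_id, reference.device_id, empty,
        )
    rt = reference.t
    pos = np.searchsorted(rt, wearable.t)
    left = np.clip(pos - 1, 0, rt.size - 1)
    right = np.clip(pos, 0, rt.size - 1)
    d_left = np.abs(wearable.t - rt[left])
    d_right = np.abs(wearable.t - rt[right])
    # ties (d_left == d_right) resolve to the earlier (left) sample
    nearest = np.where(d_right < d_left, right, left)
    offset = wearable.t - rt[nearest]
    keep = np.abs(offset) <= max_shift_s
    frame = pd.DataFrame(
        {
            "t_s": wearable.t[keep],
            "wearable": wearable.values[keep],
            "reference": reference.values[nearest[keep]],
            "offset_s": offset[keep],
            "task": wearable.task[keep],
            "cluster": [c.value for c in wearable.cluster[keep]],
            "t_in_task_s": wearable.t_in_task_s[keep],
            "minute_index": -1,
        }
    )
    return PairedSeries(
        participant_id=wearable.participant_id,
        vital_sign=wearable.vital_sign,
        device_id=wearable.device_id,
        reference_id=reference.device_id,
        frame=frame,
    )


def assign_minutes(
    paired: PairedSeries, schedule: ActivitySchedule
) -> PairedSeries:
    """Assign task-anchored minute indices to pairs.

    minute_index = floor((t - task_start) / 60), clamped to the task's last
    minute bin so the single sample allowed on the closed window end joins
    the trailing (possibly partial) minute. Minutes never straddle tasks.
    """
    frame = paired.frame.copy()
    if len(frame):
        n_minutes = {t.name: t.n_minutes for t in schedule}
        idx = np.floor(frame["t_in_task_s"].to_numpy() / 60.0).astype(int)
        cap = np.array([n_minutes[t] - 1 for t in frame["task"]])
        frame["minute_index"] = np.minimum(idx, cap)
    return replace(paired, frame=frame)


def pair_streams(
    wearable: SensorStream,
    reference: SensorStream,
    schedule: ActivitySchedule,
    max_shift_s: float = DEFAULT_MAX_SHIFT_S,
) -> PairedSeries:
    """Window both streams, pair them, and assign minute indices."""
    w = wearable if wearable.is_windowed else window_by_tasks(
        wearable, schedule)
    r = reference if reference.is_windowed else window_by_tasks(
        reference, schedule)
    return assign_minutes(pair_nearest(w, r, max_shift_s), schedule)


def pairs_frame(paired: list[PairedSeries]) -> pd.DataFrame:
    """Pool PairedSeries across participants into one long DataFrame."""
    frames = [p.to_frame() for p in paired if len(p)]
    if not frames:
        return pd.DataFrame(
            columns=["participant_id", "vital_sign", "device_id",
                     "reference_id", *PAIR_COLUMNS]
        )
    return pd.concat(frames, ignore_index=True)
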