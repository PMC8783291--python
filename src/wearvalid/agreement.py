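"""Per-minute agreement statistics: median, MAD, and MAPE.

Statistics are computed per participant-minute (minutes anchored at task
starts) and then summarized per activity cluster — and over all tasks — as
the median and IQR over the pooled participant-minutes. MAD is the
unscaled median absolute deviation from the minute median. MAPE compares
minute medians of the wearable against minute medians of the reference,
restricted to paired samples so that availability differences do not bias
the accuracy estimate; the reference is always the denominator.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import ActivitySchedule, SensorStream

__all__ = [
    "minute_stats",
    "mape_per_minute",
    "stream_minute_summaries",
    "paired_minute_summaries",
    "summarize_cluster",
]

logger = logging.getLogger(__name__)

_MINUTE_KEYS = [
    "participant_id", "device_id", "vital_sign", "cluster", "task",
    "minute_index",
]


def minute_stats(values: np.ndarray) -> tuple[float, float]:
    """Sample median and unscaled MAD of one participant-minute.

    MAD = median(|x - median(x)|); zero iff at least half the values equal
    the median.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("minute_stats requires at least one value")
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med, mad


def mape_per_minute(
    wearable_minute_median: float, reference_minute_median: float
) -> float:
    """Absolute percentage error of a minute median against the reference.

    100 * |wearable - reference| / reference; the asymmetry is intended
    (the reference device is the accuracy denominator). A zero reference
    median is undefined and raises; callers exclude and log such minutes.
    """
    if reference_minute_median == 0:
        raise ZeroDivisionError(
            "reference minute median is zero; minute excluded from MAPE"
        )
    return 100.0 * abs(
        wearable_minute_median - reference_minute_median
    ) / abs(reference_minute_median)


def _minute_index(t_in_task: np.ndarray, n_minutes: np.ndarray) -> np.ndarray:
    idx = np.floor(np.asarray(t_in_task) / 60.0).astype(int)
    return np.minimum(idx, np.asarray(n_minutes) - 1)


def stream_minute_summaries(
    stream: SensorStream, schedule: ActivitySchedule
) -> pd.DataFrame:
    """Per-minute median and MAD of a single (windowed) sensor stream.

    One row per non-empty participant-minute: the Table-of-medians building
    block that is computed for wearables and reference devices alike.
    """
    if not stream.is_windowed:
        raise ValueError("stream must be windowed by tasks first")
    if len(stream) == 0:
        return pd.DataFrame(
            columns=_MINUTE_KEYS + ["median_value", "mad_value", "n_samples"]
        )
    n_minutes = {t.name: t.n_minutes for t in schedule}
    frame = pd.DataFrame(
        {
            "participant_id": stream.participant_id,
            "device_id": stream.device_id,
            "vital_sign": stream.vital_sign.value,
            "cluster": [c.value for c in stream.cluster],
            "task": stream.task,
            "minute_index": _minute_index(
                stream.t_in_task_s,
                np.array([n_minutes[t] for t in stream.task]),
            ),
            "value": stream.values,
        }
    )
    grouped = frame.groupby(_MINUTE_KEYS, sort=False)["value"]
    out = grouped.agg(
        median_value="median",
        mad_value=lambda x: float(np.median(np.abs(x - np.median(x)))),
        n_samples="size",
    ).reset_index()
    return out


def paired_minute_summaries(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-minute medians of paired wearable/reference samples, with APE.

    ``pairs`` is the pooled pairs frame (see alignment.pairs_frame). Output
    rows carry the wearable and reference minute medians, the wearable MAD,
    the pair count, and ape_pct; minutes whose reference median is zero are
    excluded from MAPE and logged.
    """
    cols = _MINUTE_KEYS + [
        "median_value", "mad_value", "ref_median", "n_samples", "ape_pct",
    ]
    if len(pairs) == 0:
        return pd.DataFrame(columns=cols)
    grouped = pairs.groupby(_MINUTE_KEYS, sort=False)
    out = grouped.agg(
        median_value=("wearable", "median"),
        mad_value=(
            "wearable",
            lambda x: float(np.median(np.abs(x - np.median(x)))),
        ),
        ref_median=("reference", "median"),
        n_samples=("wearable", "size"),
    ).reset_index()
    zero_ref = out["ref_median"] == 0
    if zero_ref.any():
        logger.warning(
            "%d participant-minute(s) excluded from MAPE: reference minute "
            "median is zero", int(zero_ref.sum()),
        )
    out["ape_pct"] = np.where(
        zero_ref,
        np.nan,
        100.0 * np.abs(out["median_value"] - out["ref_median"])
        / np.abs(out["ref_median"]),
    )
    return out[cols]


def summarize_cluster(
    minute_summaries: pd.DataFrame,
    value_col: str,
    statistic: str | None = None,
) -> pd.DataFrame:
    """Median and IQR of a per-minute statistic, per cluster and over all.

    Pools all participant-minutes within each (device, vital, cluster) cell
    and adds an ``all`` row per (device, vital) pooling every task minute.
    Quantiles use linear interpolation between order statistics. Cells with
    no usable minutes are reported as NaN (not applicable).
    """
    statistic = statistic or value_col
    rows: list[dict] = []

    def _summary(sub: pd.DataFrame, cluster: str) -> dict:
        x = sub[value_col].dropna().to_numpy()
        if x.size:
            q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
        else:
            q1 = med = q3 = float("nan")
        return {
            "cluster": cluster,
            "statistic": statistic,
            "median": med,
            "iqr_low": q1,
            "iqr_high": q3,
            "n_minutes": int(x.size),
        }

    for (device, vital), sub in minute_summaries.groupby(
        ["device_id", "vital_sign"], sort=False
    ):
        for cluster, csub in sub.groupby("cluster", sort=False):
            rows.append(
                {"device_id": device, "vital_sign": vital,
                 **_summary(csub, str(cluster))}
            )
        rows.append(
            {"device_id": device, "vital_sign": vital,
             **_summary(sub, "all")}
        )
    return pd.DataFrame(rows)
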