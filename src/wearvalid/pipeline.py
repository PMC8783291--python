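"""End-to-end orchestration: simulate or ingest, align, analyze, report.

A single :class:`RunConfig` drives the full pipeline: generate a synthetic
cohort (or read stream files), apply reference exclusions, window streams
to tasks, pair wearables with references, and produce the availability,
agreement, and validity tables together with figure-ready data and a run
log that records sample counts at every stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as wio
from . import protocol
from .agreement import (
    paired_minute_summaries,
    stream_minute_summaries,
    summarize_cluster,
)
from .alignment import pair_streams, pairs_frame, window_by_tasks
from .availability import availability_report, epoch_summary
from .core import (
    ActivitySchedule,
    Cluster,
    ConfigurationError,
    DataError,
    ExclusionIntervals,
    SensorStream,
    VitalSign,
)
from .simulate import SyntheticCohortConfig, generate_cohort
from .validity import (
    DEFAULT_SCOPE,
    BlandAltmanRM,
    ValidityScope,
    bland_altman_plotdata,
    minute_median_pairs,
    rmse,
    select_validity_pairs,
)

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "make_figures_data",
           "write_bundle"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    mode "simulate" generates the default synthetic cohort; mode "ingest"
    reads streams.csv, schedule.csv, registry.yaml and (optionally)
    exclusions.csv from ``data_dir``.
    """

    mode: str = "simulate"
    seed: int = 0
    n_participants: int = 20
    max_shift_s: float = 5.0
    data_dir: str | None = None
    schedule_file: str | None = None
    pct_decimals: int = 2
    value_decimals: int = 1
    cluster_map: dict[VitalSign, Cluster] = field(
        default_factory=lambda: dict(DEFAULT_SCOPE.cluster_map)
    )
    warmup_exclusion_s: dict[VitalSign, float] = field(
        default_factory=lambda: dict(DEFAULT_SCOPE.warmup_exclusion_s)
    )
    device_pairs: list[tuple[str, VitalSign, str]] = field(
        default_factory=lambda: list(protocol.DEVICE_PAIRS)
    )

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.max_shift_s <= 0:
            raise ConfigurationError("max_shift_s must be > 0")
        if self.mode == "ingest" and not self.data_dir:
            raise ConfigurationError("ingest mode requires data_dir")
        self.cluster_map = {
            VitalSign(v): Cluster(c) for v, c in self.cluster_map.items()
        }
        self.warmup_exclusion_s = {
            VitalSign(v): float(s)
            for v, s in self.warmup_exclusion_s.items()
        }
        self.device_pairs = [
            (w, VitalSign(v), r) for (w, v, r) in self.device_pairs
        ]

    @property
    def scope(self) -> ValidityScope:
        return ValidityScope(self.cluster_map, self.warmup_exclusion_s)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "seed": self.seed,
            "n_participants": self.n_participants,
            "max_shift_s": self.max_shift_s,
            "data_dir": self.data_dir,
            "schedule_file": self.schedule_file,
            "pct_decimals": self.pct_decimals,
            "value_decimals": self.value_decimals,
            "cluster_map": {
                v.value: c.value for v, c in self.cluster_map.items()
            },
            "warmup_exclusion_s": {
                v.value: s for v, s in self.warmup_exclusion_s.items()
            },
            "device_pairs": [
                [w, v.value, r] for (w, v, r) in self.device_pairs
            ],
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "device_pairs" in raw:
            raw["device_pairs"] = [
                (w, VitalSign(v), r) for w, v, r in raw["device_pairs"]
            ]
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(
                f"unknown config keys: {sorted(unknown)}"
            )
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class ReportBundle:
    """All pipeline outputs for one run."""

    config: RunConfig
    schedule: ActivitySchedule
    availability: pd.DataFrame       # long: per stream x cluster (+ "all")
    epochs: pd.DataFrame             # missing-epoch inventory
    epoch_fractions: pd.DataFrame    # per device/vital threshold summary
    minute_summaries: pd.DataFrame   # per-minute median/MAD, every sensor
    values_summary: pd.DataFrame     # cluster median/IQR of medians & MADs
    mape_minutes: pd.DataFrame       # per-minute paired medians with APE
    mape_summary: pd.DataFrame       # cluster median/IQR of APE
    validity: pd.DataFrame           # Bland-Altman + RMSE per combo/level
    pairs: dict[tuple[str, VitalSign], pd.DataFrame]
    log: list[str]


def _log(bundle_log: list[str], message: str) -> None:
    bundle_log.append(message)
    logger.info(message)


def _load_inputs(config: RunConfig):
    if config.mode == "simulate":
        schedule = (
            wio.read_schedule(config.schedule_file)
            if config.schedule_file
            else protocol.default_schedule()
        )
        cohort = generate_cohort(
            SyntheticCohortConfig(
                n_participants=config.n_participants,
                schedule=schedule,
                profiles=protocol.default_profiles(),
                devices=protocol.default_devices(),
                seed=config.seed,
            )
        )
        return schedule, cohort.streams, ExclusionIntervals()
    data_dir = Path(config.data_dir)
    schedule = wio.read_schedule(data_dir / "schedule.csv")
    registry = wio.read_registry(data_dir / "registry.yaml")
    streams = wio.read_streams(data_dir / "streams.csv", registry)
    excl_path = data_dir / "exclusions.csv"
    exclusions = (
        wio.read_exclusions(excl_path) if excl_path.exists()
        else ExclusionIntervals()
    )
    return schedule, streams, exclusions


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run the full availability / agreement / validity analysis."""
    log: list[str] = []
    schedule, streams, exclusions = _load_inputs(config)
    _log(log, f"mode={config.mode} seed={config.seed} "
              f"streams={len(streams)} tasks={len(schedule)} "
              f"task_time_s={schedule.total_task_duration_s:.0f}")

    reference_ids = {r for (_, _, r) in config.device_pairs}
    if exclusions:
        n_before = sum(len(s) for s in streams)
        streams = [
            wio.apply_exclusions(s, exclusions)
            if s.device_id in reference_ids else s
            for s in streams
        ]
        n_after = sum(len(s) for s in streams)
        _log(log, f"reference exclusions removed "
                  f"{n_before - n_after} samples")

    windowed: dict[tuple[str, str, VitalSign], SensorStream] = {}
    for s in streams:
        windowed[(s.participant_id, s.device_id, s.vital_sign)] = (
            window_by_tasks(s, schedule)
        )
    n_read = sum(len(s) for s in streams)
    n_win = sum(len(s) for s in windowed.values())
    _log(log, f"windowing: {n_read} samples read, {n_win} inside task "
              f"windows ({n_read - n_win} in transitions)")

    # --- availability ---------------------------------------------------
    avail_rows = []
    epoch_frames = []
    for s in streams:
        report = availability_report(s, schedule)
        frame = report.frame.copy()
        frame.insert(0, "participant_id", report.participant_id)
        frame.insert(1, "device_id", report.device_id)
        frame.insert(2, "vital_sign", report.vital_sign)
        avail_rows.append(frame)
        epoch_frames.append(report.epochs_frame())
    availability = pd.concat(avail_rows, ignore_index=True)
    epochs = pd.concat(epoch_frames, ignore_index=True)
    frac_rows = []
    for (device, vital), sub in epochs.groupby(
        ["device_id", "vital_sign"], sort=False
    ):
        from .availability import MissingEpoch
        eps = [
            MissingEpoch(r.task, Cluster(r.cluster), r.start_s, r.duration_s,
                         int(r.n_missing))
            for r in sub.itertuples()
        ]
        frac = epoch_summary(eps)
        frac.insert(0, "device_id", device)
        frac.insert(1, "vital_sign", vital)
        frac_rows.append(frac)
    epoch_fractions = (
        pd.concat(frac_rows, ignore_index=True) if frac_rows
        else pd.DataFrame()
    )
    _log(log, f"availability: {len(availability)} report rows, "
              f"{len(epochs)} missing epochs")

    # --- agreement ------------------------------------------------------
    minute_summaries = pd.concat(
        [stream_minute_summaries(s, schedule) for s in windowed.values()],
        ignore_index=True,
    )
    values_summary = pd.concat(
        [
            summarize_cluster(minute_summaries, "median_value", "median"),
            summarize_cluster(minute_summaries, "mad_value", "mad"),
        ],
        ignore_index=True,
    )

    # --- pairing --------------------------------------------------------
    participants = sorted({s.participant_id for s in streams})
    pairs: dict[tuple[str, VitalSign], pd.DataFrame] = {}
    mape_frames = []
    validity_rows = []
    for wearable_id, vital, reference_id in config.device_pairs:
        series = []
        missing_ref = 0
        for pid in participants:
            w = windowed.get((pid, wearable_id, vital))
            r = windowed.get((pid, reference_id, vital))
            if w is None:
                continue
            if r is None:
                missing_ref += 1
                continue
            series.append(pair_streams(w, r, schedule, config.max_shift_s))
        if missing_ref:
            _log(log, f"WARNING: {wearable_id}/{vital.value}: reference "
                      f"{reference_id} missing for {missing_ref} "
                      "participant(s); those participants skipped")
        if not series:
            _log(log, f"WARNING: {wearable_id}/{vital.value} vs "
                      f"{reference_id}: no data; combination skipped")
            continue
        pooled = pairs_frame(series)
        pairs[(wearable_id, vital)] = pooled
        n_w = sum(
            len(windowed[(p, wearable_id, vital)]) for p in participants
            if (p, wearable_id, vital) in windowed
        )
        _log(log, f"pairing {wearable_id}/{vital.value} vs {reference_id}: "
                  f"{n_w} wearable samples -> {len(pooled)} pairs")
        mape_frames.append(paired_minute_summaries(pooled))

        # --- validity ---------------------------------------------------
        scope = config.scope
        selected = select_validity_pairs(pooled, vital, scope)
        if not len(selected):
            _log(log, f"WARNING: {wearable_id}/{vital.value}: no pairs in "
                      f"{scope.cluster_for(vital).value}; validity skipped")
            continue
        try:
            res_s = BlandAltmanRM.from_pairs(
                selected, device_id=wearable_id, vital_sign=vital.value,
            ).fit()
            minutes = minute_median_pairs(selected)
            res_m = BlandAltmanRM.from_pairs(
                minutes, device_id=wearable_id, vital_sign=vital.value,
                level="minute",
            ).fit()
        except DataError as err:
            _log(log, f"WARNING: {wearable_id}/{vital.value}: {err}; "
                      "validity skipped")
            continue
        for res, frame in ((res_s, selected), (res_m, minutes)):
            row = res.to_dict()
            row["reference_id"] = reference_id
            row["cluster"] = scope.cluster_for(vital).value
            row["rmse"] = rmse(frame)
            validity_rows.append(row)

    mape_minutes = (
        pd.concat(mape_frames, ignore_index=True) if mape_frames
        else pd.DataFrame()
    )
    mape_summary = (
        summarize_cluster(mape_minutes, "ape_pct", "mape")
        if len(mape_minutes) else pd.DataFrame()
    )
    validity = pd.DataFrame(validity_rows)
    _log(log, f"validity: {len(validity)} result rows "
              f"({len(validity_rows) // 2} combinations x 2 levels)")

    return ReportBundle(
        config=config,
        schedule=schedule,
        availability=availability,
        epochs=epochs,
        epoch_fractions=epoch_fractions,
        minute_summaries=minute_summaries,
        values_summary=values_summary,
        mape_minutes=mape_minutes,
        mape_summary=mape_summary,
        validity=validity,
        pairs=pairs,
        log=log,
    )


def make_figures_data(bundle: ReportBundle) -> dict[str, pd.DataFrame]:
    """Figure-ready data tables (no rendering).

    * ``missing_boxplot`` — per-participant missing percentages per device,
      vital, and cluster (plus "all"), one row each.
    * ``ba_points_samples`` / ``ba_points_minute`` — Bland-Altman point
      clouds (mean vs difference) per combination, with the fitted bias and
      LoA lines merged in as columns.
    """
    figures: dict[str, pd.DataFrame] = {
        "missing_boxplot": bundle.availability[
            ["participant_id", "device_id", "vital_sign", "cluster",
             "missing_pct"]
        ].copy()
    }
    for level, key in (("samples", "ba_points_samples"),
                       ("minute", "ba_points_minute")):
        chunks = []
        for (device, vital), pooled in bundle.pairs.items():
            fit_rows = bundle.validity[
                (bundle.validity["device_id"] == device)
                & (bundle.validity["vital_sign"] == vital.value)
                & (bundle.validity["level"] == level)
            ]
            if fit_rows.empty:
                continue
            fit = fit_rows.iloc[0]
            selected = select_validity_pairs(
                pooled, vital, bundle.config.scope
            )
            if level == "minute":
                selected = minute_median_pairs(selected)
            points = bland_altman_plotdata(selected)
            points.insert(0, "device_id", device)
            points.insert(1, "vital_sign", vital.value)
            points["mean_difference"] = fit["mean_difference"]
            points["loa_low"] = fit["loa_low"]
            points["loa_high"] = fit["loa_high"]
            chunks.append(points)
        figures[key] = (
            pd.concat(chunks, ignore_index=True) if chunks
            else pd.DataFrame()
        )
    return figures


def _rounded(frame: pd.DataFrame, decimals_by_col: dict[str, int]
             ) -> pd.DataFrame:
    out = frame.copy()
    for col, decimals in decimals_by_col.items():
        if col in out.columns:
            out[col] = out[col].round(decimals)
    return out


def write_bundle(bundle: ReportBundle, out_dir: str | Path) -> None:
    """Write the report bundle as CSV/JSON files.

    Human-readable tables round percentages to ``pct_decimals`` and signal
    statistics to ``value_decimals``; the machine-readable validity JSON
    keeps full precision.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = bundle.config
    pct = cfg.pct_decimals
    val = cfg.value_decimals
    wio.write_schedule(bundle.schedule, out / "schedule.csv")
    bundle.availability.to_csv(out / "availability.csv", index=False)
    bundle.epochs.to_csv(out / "missing_epochs.csv", index=False)
    if len(bundle.epoch_fractions):
        bundle.epoch_fractions.to_csv(
            out / "epoch_fractions.csv", index=False
        )
    bundle.minute_summaries.to_csv(out / "minute_summaries.csv", index=False)
    _rounded(
        bundle.values_summary,
        {"median": val, "iqr_low": val, "iqr_high": val},
    ).to_csv(out / "values_summary.csv", index=False)
    if len(bundle.mape_summary):
        _rounded(
            bundle.mape_summary,
            {"median": pct, "iqr_low": pct, "iqr_high": pct},
        ).to_csv(out / "mape_summary.csv", index=False)
    if len(bundle.validity):
        _rounded(
            bundle.validity,
            {c: val for c in ("mean_difference", "total_sd", "loa_low",
                              "loa_high", "rmse")},
        ).to_csv(out / "validity.csv", index=False)
        with open(out / "validity.json", "w") as fh:
            json.dump(bundle.validity.to_dict(orient="records"), fh,
                      indent=2)
    for name, frame in make_figures_data(bundle).items():
        frame.to_csv(out / f"{name}.csv", index=False)
    with open(out / "run_log.json", "w") as fh:
        json.dump({"config": cfg.to_dict(), "log": bundle.log}, fh, indent=2)
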