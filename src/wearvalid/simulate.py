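"""Synthetic multi-device vital-sign cohort generator.

Generates (a) dense second-by-second ground-truth trajectories per vital
sign, driven by cluster-specific trends (constant level, linear ramp,
fixed metronome sequence) plus smooth physiological variability, and (b)
noisy device observations of those trajectories on each device's storage
grid, with cluster-dependent additive bias, Gaussian observation noise, a
per-participant random bias offset, value quantization, and dropout epochs
that delete contiguous runs of samples.

The generator emulates the statistical structure of a wearable validation
study (sample counts, agreement magnitudes, missingness patterns); it does
not model cardiorespiratory mechanics or raw ECG/PPG waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    PHYSIOLOGICAL_RANGE,
    ActivitySchedule,
    Cluster,
    ConfigurationError,
    SensorStream,
    VitalSign,
)

__all__ = [
    "ClusterTrend",
    "PhysiologyProfile",
    "DropoutModel",
    "ObservationChannel",
    "DeviceModel",
    "Truth",
    "SyntheticCohortConfig",
    "Cohort",
    "generate_truth",
    "observe",
    "generate_cohort",
    "storage_grid",
]

#: Lag-1 autocorrelation of the AR(1) physiological variability process.
_AR1_RHO = 0.95


@dataclass(frozen=True)
class ClusterTrend:
    """Trend of a vital sign within one activity cluster.

    kind:
      * ``constant`` — level plus variability.
      * ``ramp`` — linear from ``level`` to ``target`` over the cluster's
        total task time (monotone deterministic component).
      * ``metronome`` — the cluster's k-th task is held exactly at
        ``sequence[k]``; variability is suppressed so the paced rate is
        reproduced exactly.
    """

    kind: str
    level: float = 0.0
    target: float | None = None
    sequence: tuple[float, ...] | None = None
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "ramp", "metronome"):
            raise ConfigurationError(f"unknown trend kind {self.kind!r}")
        if self.kind == "ramp" and self.target is None:
            raise ConfigurationError("ramp trend requires a target level")
        if self.kind == "metronome" and not self.sequence:
            raise ConfigurationError("metronome trend requires a sequence")
        if self.sd < 0:
            raise ConfigurationError("variability sd must be >= 0")

    @classmethod
    def constant(cls, level: float, sd: float = 0.0) -> "ClusterTrend":
        return cls("constant", level=level, sd=sd)

    @classmethod
    def ramp(cls, start: float, target: float, sd: float = 0.0
             ) -> "ClusterTrend":
        return cls("ramp", level=start, target=target, sd=sd)

    @classmethod
    def metronome(cls, sequence: tuple[float, ...]) -> "ClusterTrend":
        return cls("metronome", sequence=tuple(float(x) for x in sequence))

    def levels(self) -> list[float]:
        if self.kind == "constant":
            return [self.level]
        if self.kind == "ramp":
            return [self.level, float(self.target)]
        return list(self.sequence or ())


@dataclass(frozen=True)
class PhysiologyProfile:
    """Per-cluster ground-truth trend description for one vital sign."""

    vital: VitalSign
    trends: dict[Cluster, ClusterTrend]

    def __post_init__(self) -> None:
        object.__setattr__(self, "vital", VitalSign(self.vital))
        lo, hi = PHYSIOLOGICAL_RANGE[self.vital]
        for cluster, trend in self.trends.items():
            for level in trend.levels():
                if not lo <= level <= hi:
                    raise ConfigurationError(
                        f"{self.vital.value} level {level} in cluster "
                        f"{Cluster(cluster).value} outside physiological "
                        f"range [{lo}, {hi}]"
                    )


@dataclass(frozen=True)
class DropoutModel:
    """Poisson missing-data epochs with log-normal durations.

    ``epoch_rate_per_min`` is per activity cluster; each epoch deletes all
    stored samples whose timestamps fall in ``[start, start + duration)``.
    Log-normal durations give the heavy right tail seen in practice (most
    epochs a few seconds, occasional ones of minutes).
    """

    epoch_rate_per_min: dict[Cluster, float]
    duration_log_mean: float
    duration_log_sd: float

    def __post_init__(self) -> None:
        for cluster, rate in self.epoch_rate_per_min.items():
            if rate < 0:
                raise ConfigurationError(
                    f"epoch rate for {Cluster(cluster).value} must be >= 0"
                )
        if self.duration_log_sd < 0:
            raise ConfigurationError("duration_log_sd must be >= 0")


@dataclass(frozen=True)
class ObservationChannel:
    """How one device observes one vital sign.

    stored value = truth + bias[cluster] + subject offset + N(0, sd[cluster]),
    quantized to ``resolution`` (0 disables quantization). The subject
    offset is drawn once per (participant, device, vital) from
    N(0, subject_bias_sd) and induces the between-subject component of
    paired differences.
    """

    vital: VitalSign
    bias: dict[Cluster, float] = field(default_factory=dict)
    noise_sd: dict[Cluster, float] = field(default_factory=dict)
    subject_bias_sd: float = 0.0
    resolution: float = 0.0
    dropout: DropoutModel | None = None
    #: Lag-1 autocorrelation of observation noise across consecutive stored
    #: samples within a task (0 = white noise). Wearable error is strongly
    #: autocorrelated in practice (posture, perfusion, contact), which is
    #: why minute medians barely narrow the limits of agreement.
    noise_rho: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "vital", VitalSign(self.vital))
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ConfigurationError("noise sd must be >= 0")
        if not 0.0 <= self.noise_rho < 1.0:
            raise ConfigurationError("noise_rho must be in [0, 1)")
        if self.subject_bias_sd < 0:
            raise ConfigurationError("subject_bias_sd must be >= 0")
        if self.resolution < 0:
            raise ConfigurationError("resolution must be >= 0")


@dataclass(frozen=True)
class DeviceModel:
    """A device: storage period plus one observation channel per vital."""

    device_id: str
    storage_period_s: float
    channels: dict[VitalSign, ObservationChannel]

    def __post_init__(self) -> None:
        if self.storage_period_s <= 0:
            raise ConfigurationError("storage period must be > 0")

    @property
    def vitals(self) -> set[VitalSign]:
        return set(self.channels)


@dataclass
class Truth:
    """Dense ground truth: one value per whole second inside task windows
    (window ends inclusive, so every storage-grid point is covered)."""

    vital: VitalSign
    schedule: ActivitySchedule
    t: np.ndarray
    values: np.ndarray

    def at(self, times: np.ndarray) -> np.ndarray:
        """Truth values at arbitrary in-window times (linear interpolation;
        exact at whole seconds)."""
        return np.interp(np.asarray(times, dtype=float), self.t, self.values)


def _cluster_elapsed(schedule: ActivitySchedule, cluster: Cluster):
    """Per-window (start offset within cluster task time, window) list."""
    out = []
    elapsed = 0.0
    for w in schedule.windows(cluster):
        out.append((elapsed, w))
        elapsed += w.duration_s
    return out, elapsed


def generate_truth(
    profile: PhysiologyProfile,
    schedule: ActivitySchedule,
    seed: int | np.random.Generator,
) -> Truth:
    """Generate the dense ground-truth trajectory for one vital sign.

    Variability is an AR(1) Gaussian process (lag-1 correlation 0.95,
    stationary sd = the trend's sd) added to the deterministic trend, then
    clipped to the physiological range. Metronome clusters carry no
    variability so the paced rates are reproduced exactly.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    for task in schedule:
        if task.cluster not in profile.trends:
            raise ConfigurationError(
                f"no {profile.vital.value} trend for cluster "
                f"{task.cluster.value}"
            )
    lo, hi = PHYSIOLOGICAL_RANGE[profile.vital]
    t_all: list[np.ndarray] = []
    v_all: list[np.ndarray] = []
    for cluster in schedule.clusters:
        trend = profile.trends[cluster]
        windows, total = _cluster_elapsed(schedule, cluster)
        if trend.kind == "metronome":
            seq = list(trend.sequence or ())
            if len(seq) != len(windows):
                raise ConfigurationError(
                    f"metronome sequence length {len(seq)} does not match "
                    f"{len(windows)} tasks in cluster {cluster.value}"
                )
        for k, (offset, w) in enumerate(windows):
            t = np.arange(np.ceil(w.start_s), np.floor(w.end_s) + 1.0)
            u = offset + (t - w.start_s)  # elapsed task time within cluster
            if trend.kind == "constant":
                base = np.full(t.shape, trend.level)
            elif trend.kind == "ramp":
                frac = u / total if total > 0 else 0.0
                base = trend.level + (float(trend.target) - trend.level) * frac
            else:  # metronome
                base = np.full(t.shape, trend.sequence[k])
            if trend.kind != "metronome" and trend.sd > 0:
                base = base + _ar1(rng, t.size, trend.sd, _AR1_RHO)
            t_all.append(t)
            v_all.append(np.clip(base, lo, hi))
    order = np.argsort([a[0] for a in t_all])
    t = np.concatenate([t_all[i] for i in order])
    v = np.concatenate([v_all[i] for i in order])
    return Truth(vital=profile.vital, schedule=schedule, t=t, values=v)


def _ar1(rng: np.random.Generator, n: int, sd: float, rho: float
         ) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    eps = rng.standard_normal(n)
    if rho == 0.0:
        return sd * eps
    x = np.empty(n)
    x[0] = eps[0]
    c = np.sqrt(1.0 - rho**2)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + c * eps[i]
    return sd * x


def storage_grid(start_s: float, duration_s: float, period_s: float
                 ) -> np.ndarray:
    """Storage timestamps of a device within one task window.

    Samples lie at ``start + k * period`` for k = 1..floor(duration/period)
    (no sample at the window start), so a window of duration D holds exactly
    floor(D / period) expected samples.
    """
    k = int(np.floor(duration_s / period_s + 1e-9))
    return start_s + period_s * np.arange(1, k + 1)


def observe(
    truth: Truth,
    device: DeviceModel,
    vital: VitalSign,
    seed: int | np.random.Generator,
    participant_id: str = "P01",
) -> SensorStream:
    """Observe a ground-truth trajectory through a device's storage model.

    Returns a :class:`SensorStream` on the device's storage grid inside task
    windows, with bias, noise, quantization, and dropout applied. Identical
    seed reproduces an identical stream.
    """
    vital = VitalSign(vital)
    if vital not in device.channels:
        raise ConfigurationError(
            f"device {device.device_id!r} does not cover {vital.value}"
        )
    if VitalSign(truth.vital) != vital:
        raise ConfigurationError(
            f"truth is for {truth.vital.value}, requested {vital.value}"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    channel = device.channels[vital]
    period = device.storage_period_s
    subject_offset = (
        rng.normal(0.0, channel.subject_bias_sd)
        if channel.subject_bias_sd > 0
        else 0.0
    )
    t_parts: list[np.ndarray] = []
    v_parts: list[np.ndarray] = []
    for task in truth.schedule:
        grid = storage_grid(task.start_s, task.duration_s, period)
        if grid.size == 0:
            continue
        vals = truth.at(grid)
        vals = vals + channel.bias.get(task.cluster, 0.0) + subject_offset
        sd = channel.noise_sd.get(task.cluster, 0.0)
        if sd > 0:
            vals = vals + _ar1(rng, grid.size, sd, channel.noise_rho)
        if channel.resolution > 0:
            vals = np.round(vals / channel.resolution) * channel.resolution
        keep = np.ones(grid.size, dtype=bool)
        if channel.dropout is not None:
            rate = channel.dropout.epoch_rate_per_min.get(task.cluster, 0.0)
            n_epochs = (
                rng.poisson(rate * task.duration_s / 60.0) if rate > 0 else 0
            )
            for _ in range(n_epochs):
                ep_start = rng.uniform(task.start_s, task.end_s)
                ep_dur = rng.lognormal(
                    channel.dropout.duration_log_mean,
                    channel.dropout.duration_log_sd,
                )
                keep &= ~((grid >= ep_start) & (grid < ep_start + ep_dur))
        t_parts.append(grid[keep])
        v_parts.append(vals[keep])
    t = np.concatenate(t_parts) if t_parts else np.empty(0)
    v = np.concatenate(v_parts) if v_parts else np.empty(0)
    return SensorStream(
        participant_id=participant_id,
        device_id=device.device_id,
        vital_sign=vital,
        nominal_period_s=period,
        t=t,
        values=v,
    )


@dataclass
class SyntheticCohortConfig:
    """Configuration of a synthetic validation cohort."""

    n_participants: int
    schedule: ActivitySchedule
    profiles: dict[VitalSign, PhysiologyProfile]
    devices: list[DeviceModel]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("need at least one participant")
        covered = {v for d in self.devices for v in d.vitals}
        missing = covered - set(self.profiles)
        if missing:
            raise ConfigurationError(
                "no physiology profile for vital sign(s): "
                + ", ".join(sorted(v.value for v in missing))
            )


@dataclass
class Cohort:
    """A generated cohort: one schedule, streams per (participant, device,
    vital), and the underlying truths for diagnostics."""

    schedule: ActivitySchedule
    streams: list[SensorStream]
    truths: dict[tuple[str, VitalSign], Truth]
    config: SyntheticCohortConfig

    @property
    def participant_ids(self) -> list[str]:
        seen: list[str] = []
        for s in self.streams:
            if s.participant_id not in seen:
                seen.append(s.participant_id)
        return seen

    def stream(self, participant_id: str, device_id: str, vital: VitalSign
               ) -> SensorStream:
        vital = VitalSign(vital)
        for s in self.streams:
            if (
                s.participant_id == participant_id
                and s.device_id == device_id
                and s.vital_sign == vital
            ):
                return s
        raise KeyError((participant_id, device_id, vital))


def generate_cohort(config: SyntheticCohortConfig) -> Cohort:
    """Generate a full synthetic cohort, deterministically from the seed.

    Per-participant sub-seeds are spawned from the master seed via
    ``numpy.random.SeedSequence``; within a participant, one child stream
    of randomness per vital-sign truth and one per (device, vital) channel,
    in a fixed sorted order, so any single stream is reproducible and the
    whole cohort is byte-identical across runs.
    """
    root = np.random.SeedSequence(config.seed)
    participant_seeds = root.spawn(config.n_participants)
    vitals = sorted(config.profiles, key=lambda v: v.value)
    device_channels = sorted(
        (d.device_id, v) for d in config.devices for v in d.vitals
    )
    devices_by_id = {d.device_id: d for d in config.devices}
    width = max(2, len(str(config.n_participants)))
    streams: list[SensorStream] = []
    truths: dict[tuple[str, VitalSign], Truth] = {}
    for i, pseed in enumerate(participant_seeds):
        pid = f"P{i + 1:0{width}d}"
        children = pseed.spawn(len(vitals) + len(device_channels))
        for v, child in zip(vitals, children[: len(vitals)]):
            truths[(pid, v)] = generate_truth(
                config.profiles[v], config.schedule,
                np.random.default_rng(child),
            )
        for (device_id, v), child in zip(
            device_channels, children[len(vitals):]
        ):
            streams.append(
                observe(
                    truths[(pid, v)],
                    devices_by_id[device_id],
                    v,
                    np.random.default_rng(child),
                    participant_id=pid,
                )
            )
    return Cohort(
        schedule=config.schedule, streams=streams, truths=truths,
        config=config,
    )
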