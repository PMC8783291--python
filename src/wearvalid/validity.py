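"""Concurrent validity: repeated-measures Bland-Altman analysis and RMSE.

With repeated measurement pairs per subject, the classic Bland-Altman
standard deviation of differences understates the pair-to-pair variance.
Here the variance of a difference is decomposed by one-way random-effects
ANOVA on the differences d_ij (subject i, pair j):

    MSW = sum_ij (d_ij - dbar_i)^2 / (N - k)
    MSB = sum_i n_i (dbar_i - dbar)^2 / (k - 1)
    m0  = (N - sum_i n_i^2 / N) / (k - 1)

    sigma2_w = MSW
    sigma2_b = max(0, (MSB - MSW) / m0)       (method-of-moments, clamped)
    total_sd = sqrt(sigma2_b + sigma2_w)
    LoA      = dbar +/- 1.96 * total_sd

The grand mean dbar is pair-weighted (the mean over all pairs), consistent
with the pooled RMSE. The normal 95% multiplier is used without a
small-sample t correction, and no confidence intervals around the LoA are
computed.

The model is exposed statsmodels-style: :class:`BlandAltmanRM` is built
from differences and subject labels (or from a pairs DataFrame) and
``fit()`` returns a :class:`BlandAltmanRMResults` with the estimates and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import Cluster, ConfigurationError, DataError, VitalSign

__all__ = [
    "ValidityScope",
    "DEFAULT_SCOPE",
    "BlandAltmanRM",
    "BlandAltmanRMResults",
    "select_validity_pairs",
    "rmse",
    "minute_median_pairs",
    "minute_level_validity",
    "bland_altman_plotdata",
]

#: Normal 95% limits-of-agreement multiplier.
LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class ValidityScope:
    """Which activity cluster, and which warm-up exclusion, per vital sign.

    The preselected clusters maximize physiological range at minimal
    movement artifact: HR during cycling, RR during metronome breathing,
    SpO2 and temperature during recovery. Because the wearables average RR
    over 45-60 s internally, the first 60 s of every breathing task are
    excluded from the RR validity analysis.
    """

    cluster_map: dict[VitalSign, Cluster]
    warmup_exclusion_s: dict[VitalSign, float]

    def cluster_for(self, vital: VitalSign) -> Cluster:
        vital = VitalSign(vital)
        if vital not in self.cluster_map:
            raise ConfigurationError(
                f"no validity cluster configured for {vital.value}"
            )
        return self.cluster_map[vital]


DEFAULT_SCOPE = ValidityScope(
    cluster_map={
        VitalSign.HR: Cluster.CYCLING,
        VitalSign.RR: Cluster.BREATHING,
        VitalSign.SPO2: Cluster.RECOVERY,
        VitalSign.TEMP: Cluster.RECOVERY,
    },
    warmup_exclusion_s={VitalSign.RR: 60.0},
)


def select_validity_pairs(
    pairs: pd.DataFrame,
    vital: VitalSign,
    scope: ValidityScope = DEFAULT_SCOPE,
) -> pd.DataFrame:
    """Restrict pooled pairs to the vital's preselected activity cluster,
    applying the warm-up exclusion at the start of each task if one is
    configured for this vital sign."""
    vital = VitalSign(vital)
    cluster = scope.cluster_for(vital)
    if len(pairs) == 0:
        return pairs
    out = pairs[
        (pairs["vital_sign"] == vital.value)
        & (pairs["cluster"] == cluster.value)
    ]
    warmup = scope.warmup_exclusion_s.get(vital, 0.0)
    if warmup > 0 and len(out):
        out = out[out["t_in_task_s"] >= warmup]
    return out.reset_index(drop=True)


@dataclass
class BlandAltmanRMResults:
    """Estimates from a repeated-measures Bland-Altman fit."""

    vital_sign: str
    device_id: str
    level: str  # "samples" or "minute"
    n_pairs: int
    n_subjects: int
    mean_difference: float
    sigma2_within: float
    sigma2_between: float
    msw: float
    msb: float
    m0: float
    rmse: float

    @property
    def total_sd(self) -> float:
        return float(np.sqrt(self.sigma2_between + self.sigma2_within))

    @property
    def loa_low(self) -> float:
        return self.mean_difference - LOA_MULTIPLIER * self.total_sd

    @property
    def loa_high(self) -> float:
        return self.mean_difference + LOA_MULTIPLIER * self.total_sd

    def to_dict(self) -> dict:
        return {
            "vital_sign": self.vital_sign,
            "device_id": self.device_id,
            "level": self.level,
            "n_pairs": self.n_pairs,
            "n_subjects": self.n_subjects,
            "mean_difference": self.mean_difference,
            "sigma2_within": self.sigma2_within,
            "sigma2_between": self.sigma2_between,
            "total_sd": self.total_sd,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "rmse": self.rmse,
        }

    def summary(self) -> str:
        """Human-readable summary table."""
        lines = [
            "Repeated-measures Bland-Altman",
            "=" * 46,
            f"{'device':<22}{self.device_id or '-':>24}",
            f"{'vital sign':<22}{self.vital_sign or '-':>24}",
            f"{'level':<22}{self.level:>24}",
            f"{'pairs (N)':<22}{self.n_pairs:>24d}",
            f"{'subjects (k)':<22}{self.n_subjects:>24d}",
            "-" * 46,
            f"{'mean difference':<22}{self.mean_difference:>24.3f}",
            f"{'within-subject var':<22}{self.sigma2_within:>24.3f}",
            f"{'between-subject var':<22}{self.sigma2_between:>24.3f}",
            f"{'total SD':<22}{self.total_sd:>24.3f}",
            f"{'95% LoA low':<22}{self.loa_low:>24.3f}",
            f"{'95% LoA high':<22}{self.loa_high:>24.3f}",
            f"{'RMSE':<22}{self.rmse:>24.3f}",
            "=" * 46,
        ]
        return "\n".join(lines)


class BlandAltmanRM:
    """Repeated-measures Bland-Altman model on paired differences.

    Parameters
    ----------
    differences : array-like
        Pairwise differences, wearable minus reference.
    subjects : array-like
        Subject (participant) label per difference.
    vital_sign, device_id, level : str, optional
        Metadata carried through to the results.
    """

    def __init__(
        self,
        differences,
        subjects,
        *,
        vital_sign: str = "",
        device_id: str = "",
        level: str = "samples",
    ):
        self.differences = np.asarray(differences, dtype=float)
        self.subjects = np.asarray(subjects)
        if self.differences.shape != self.subjects.shape:
            raise DataError("differences and subjects differ in length")
        if self.differences.size == 0:
            raise DataError("no measurement pairs")
        self.vital_sign = vital_sign
        self.device_id = device_id
        self.level = level

    @classmethod
    def from_pairs(
        cls,
        pairs: pd.DataFrame,
        *,
        wearable: str = "wearable",
        reference: str = "reference",
        subject: str = "participant_id",
        vital_sign: str = "",
        device_id: str = "",
        level: str = "samples",
    ) -> "BlandAltmanRM":
        """Build the model from a pairs DataFrame (wearable minus reference)."""
        if not vital_sign and "vital_sign" in pairs and len(pairs):
            vital_sign = str(pairs["vital_sign"].iloc[0])
        if not device_id and "device_id" in pairs and len(pairs):
            device_id = str(pairs["device_id"].iloc[0])
        return cls(
            (pairs[wearable] - pairs[reference]).to_numpy(),
            pairs[subject].to_numpy(),
            vital_sign=vital_sign,
            device_id=device_id,
            level=level,
        )

    def fit(self) -> BlandAltmanRMResults:
        """Estimate bias, variance components, limits of agreement, RMSE.

        Subjects contributing a single pair are permitted (they inform the
        between-subject mean square only); a single subject overall leaves
        the between-subject variance unidentifiable and raises.
        """
        d = self.differences
        labels, inverse = np.unique(self.subjects, return_inverse=True)
        k = labels.size
        n = d.size
        if k < 2:
            raise DataError(
                "repeated-measures Bland-Altman needs >= 2 subjects: "
                "between-subject variance is unidentifiable from one subject"
            )
        n_i = np.bincount(inverse)
        if n - k == 0:
            raise DataError(
                "every subject has a single pair; within-subject variance "
                "is unidentifiable (need >= 2 pairs for some subject)"
            )
        sums = np.bincount(inverse, weights=d)
        means_i = sums / n_i
        grand = float(d.mean())  # pair-weighted grand mean
        ssw = float(np.sum((d - means_i[inverse]) ** 2))
        msw = ssw / (n - k)
        msb = float(np.sum(n_i * (means_i - grand) ** 2)) / (k - 1)
        m0 = (n - float(np.sum(n_i**2)) / n) / (k - 1)
        sigma2_b = max(0.0, (msb - msw) / m0)
        return BlandAltmanRMResults(
            vital_sign=self.vital_sign,
            device_id=self.device_id,
            level=self.level,
            n_pairs=int(n),
            n_subjects=int(k),
            mean_difference=grand,
            sigma2_within=msw,
            sigma2_between=sigma2_b,
            msw=msw,
            msb=msb,
            m0=m0,
            rmse=float(np.sqrt(np.mean(d**2))),
        )


def rmse(pairs: pd.DataFrame) -> float:
    """Pooled root mean square error of wearable minus reference."""
    if len(pairs) == 0:
        return float("nan")
    d = (pairs["wearable"] - pairs["reference"]).to_numpy(dtype=float)
    return float(np.sqrt(np.mean(d**2)))


def minute_median_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Collapse pairs to one (wearable median, reference median) pair per
    participant-minute."""
    if len(pairs) == 0:
        return pairs
    keys = ["participant_id", "vital_sign", "device_id", "reference_id",
            "cluster", "task", "minute_index"]
    keys = [key for key in keys if key in pairs.columns]
    out = (
        pairs.groupby(keys, sort=False)
        .agg(wearable=("wearable", "median"),
             reference=("reference", "median"),
             n_samples=("wearable", "size"))
        .reset_index()
    )
    return out


def minute_level_validity(
    pairs: pd.DataFrame,
    vital: VitalSign,
    scope: ValidityScope = DEFAULT_SCOPE,
) -> BlandAltmanRMResults:
    """Minute-median repeated-measures Bland-Altman in the vital's
    preselected cluster (warm-up exclusion applied before aggregation)."""
    selected = select_validity_pairs(pairs, vital, scope)
    minutes = minute_median_pairs(selected)
    model = BlandAltmanRM.from_pairs(minutes, level="minute")
    results = model.fit()
    return replace(results, rmse=rmse(minutes))


def bland_altman_plotdata(
    pairs: pd.DataFrame,
    results: BlandAltmanRMResults | None = None,
) -> pd.DataFrame:
    """Bland-Altman plot points: mean of each pair vs difference.

    One row per pair with columns ``mean`` and ``difference`` (plus subject
    labels if present); the bias and LoA lines are attached in
    ``DataFrame.attrs['lines']`` when results are supplied. Rendering is
    left to the caller.
    """
    out = pd.DataFrame(
        {
            "mean": (pairs["wearable"] + pairs["reference"]) / 2.0,
            "difference": pairs["wearable"] - pairs["reference"],
        }
    )
    for col in ("participant_id", "cluster", "minute_index"):
        if col in pairs.columns:
            out[col] = pairs[col].to_numpy()
    if results is not None:
        out.attrs["lines"] = {
            "mean_difference": results.mean_difference,
            "loa_low": results.loa_low,
            "loa_high": results.loa_high,
        }
    return out
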