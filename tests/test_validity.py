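import numpy as np
import pandas as pd
import pytest

from wearvalid.core import ConfigurationError, DataError, VitalSign
from wearvalid.validity import (
    DEFAULT_SCOPE,
    BlandAltmanRM,
    bland_altman_plotdata,
    minute_median_pairs,
    minute_level_validity,
    rmse,
    select_validity_pairs,
)


def naive_variance_components(diffs, subjects):
    """Brute-force one-way ANOVA oracle, written with explicit loops."""
    groups = {}
    for d, s in zip(diffs, subjects):
        groups.setdefault(s, []).append(d)
    k = len(groups)
    n = len(diffs)
    grand = sum(diffs) / n
    ssw = sum((d - sum(g) / len(g)) ** 2 for g in groups.values() for d in g)
    msw = ssw / (n - k)
    msb = sum(
        len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups.values()
    ) / (k - 1)
    m0 = (n - sum(len(g) ** 2 for g in groups.values()) / n) / (k - 1)
    s2b = max(0.0, (msb - msw) / m0)
    total_sd = (s2b + msw) ** 0.5
    return grand, msw, s2b, total_sd


def make_pairs(wearable, reference, subjects, **extra):
    frame = pd.DataFrame(
        {
            "participant_id": subjects,
            "wearable": wearable,
            "reference": reference,
        }
    )
    for col, val in extra.items():
        frame[col] = val
    return frame


class TestBlandAltmanRM:
    def test_identity_pairs(self):
        res = BlandAltmanRM([0.0] * 4, ["A", "A", "B", "B"]).fit()
        assert res.mean_difference == 0.0
        assert res.total_sd == 0.0
        assert (res.loa_low, res.loa_high) == (0.0, 0.0)
        assert res.rmse == 0.0

    def test_two_subject_worked_example(self):
        """Subject A diffs {1,3}, subject B {5,7}: the one-way ANOVA gives
        MSW=2, MSB=16, m0=2, so sigma2_b=7 and LoA = 4 +/- 1.96*3."""
        res = BlandAltmanRM([1, 3, 5, 7], ["A", "A", "B", "B"]).fit()
        assert res.mean_difference == pytest.approx(4.0, abs=1e-10)
        assert res.sigma2_within == pytest.approx(2.0, abs=1e-10)
        assert res.sigma2_between == pytest.approx(7.0, abs=1e-10)
        assert res.total_sd == pytest.approx(3.0, abs=1e-10)
        assert res.loa_low == pytest.approx(4.0 - 1.96 * 3.0, abs=1e-10)
        assert res.loa_high == pytest.approx(4.0 + 1.96 * 3.0, abs=1e-10)

    def test_negative_component_clamped(self):
        res = BlandAltmanRM([0, 2, 0, 2], ["A", "A", "B", "B"]).fit()
        assert res.sigma2_between == 0.0
        assert res.total_sd == pytest.approx(np.sqrt(2.0))
        assert res.loa_low == pytest.approx(1 - 1.96 * np.sqrt(2.0))

    def test_single_subject_unidentifiable(self):
        with pytest.raises(DataError, match="2 subjects"):
            BlandAltmanRM([1, 2, 3], ["A", "A", "A"]).fit()

    def test_all_singletons_unidentifiable(self):
        with pytest.raises(DataError, match="single pair"):
            BlandAltmanRM([1, 2, 3], ["A", "B", "C"]).fit()

    def test_singleton_subjects_permitted(self):
        res = BlandAltmanRM([1, 3, 10], ["A", "A", "B"]).fit()
        assert res.n_subjects == 2
        assert res.sigma2_within == pytest.approx(2.0)

    def test_balanced_design_m0_equals_group_size(self):
        res = BlandAltmanRM(
            list(range(12)), ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        ).fit()
        assert res.m0 == pytest.approx(4.0)

    def test_matches_naive_oracle_on_random_data(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            k = rng.integers(2, 8)
            diffs, subjects = [], []
            for i in range(k):
                n_i = int(rng.integers(1, 12))
                diffs.extend(rng.normal(rng.normal(0, 3), 2, n_i).tolist())
                subjects.extend([f"S{i}"] * n_i)
            if len(diffs) == len(set(subjects)):
                continue  # all singletons: unidentifiable by construction
            res = BlandAltmanRM(diffs, subjects).fit()
            grand, msw, s2b, total_sd = naive_variance_components(
                diffs, subjects
            )
            assert res.mean_difference == pytest.approx(grand, rel=1e-10)
            assert res.sigma2_within == pytest.approx(msw, rel=1e-10)
            assert res.sigma2_between == pytest.approx(s2b, rel=1e-10,
                                                       abs=1e-12)
            assert res.total_sd == pytest.approx(total_sd, rel=1e-10)

    def test_vanishing_noise_leaves_between_subject_sd(self):
        # constant per-subject differences: total_sd -> sd of subject means
        diffs = [1.0] * 5 + [2.0] * 5 + [3.0] * 5
        subjects = ["A"] * 5 + ["B"] * 5 + ["C"] * 5
        res = BlandAltmanRM(diffs, subjects).fit()
        assert res.sigma2_within == 0.0
        assert res.total_sd == pytest.approx(np.std([1, 2, 3], ddof=1))

    def test_from_pairs_and_summary(self):
        pairs = make_pairs([101, 103, 95, 97], [100] * 4,
                           ["A", "A", "B", "B"], vital_sign="HR",
                           device_id="patch")
        res = BlandAltmanRM.from_pairs(pairs).fit()
        assert res.mean_difference == pytest.approx(-1.0)
        assert res.device_id == "patch"
        text = res.summary()
        assert "mean difference" in text and "95% LoA" in text


class TestRmse:
    def test_worked_example(self):
        pairs = make_pairs([1, 3, 5, 7], [0, 0, 0, 0], ["A"] * 4)
        assert rmse(pairs) == pytest.approx(np.sqrt(21.0))

    def test_identity_and_constant(self):
        assert rmse(make_pairs([5, 5], [5, 5], ["A", "A"])) == 0.0
        assert rmse(make_pairs([7, 7], [4, 4], ["A", "A"])) == 3.0

    def test_rmse_dominates_mean_difference(self):
        pairs = make_pairs([1, 9, 2, 8], [0, 0, 0, 0], list("AABB"))
        res = BlandAltmanRM.from_pairs(pairs).fit()
        assert res.rmse**2 >= res.mean_difference**2


class TestSelectValidityPairs:
    def frame(self):
        return pd.DataFrame(
            {
                "participant_id": "P01",
                "vital_sign": "HR",
                "cluster": ["resting", "cycling", "walking", "cycling"],
                "t_in_task_s": [10.0, 30.0, 10.0, 61.0],
                "task": "t",
                "minute_index": 0,
                "wearable": 1.0,
                "reference": 1.0,
            }
        )

    def test_only_preselected_cluster_kept(self):
        out = select_validity_pairs(self.frame(), VitalSign.HR)
        assert set(out["cluster"]) == {"cycling"}
        assert len(out) == 2

    def test_breathing_warmup_excluded_for_rr(self):
        frame = self.frame().assign(vital_sign="RR", cluster="breathing")
        out = select_validity_pairs(frame, VitalSign.RR)
        # first 60 s of each breathing task removed: 30 s gone, 61 s kept
        assert list(out["t_in_task_s"]) == [61.0]

    def test_no_warmup_for_heart_rate(self):
        out = select_validity_pairs(self.frame(), VitalSign.HR)
        assert 30.0 in set(out["t_in_task_s"])

    def test_empty_input(self):
        out = select_validity_pairs(self.frame().iloc[:0], VitalSign.HR)
        assert len(out) == 0

    def test_unmapped_vital_rejected(self):
        from wearvalid.validity import ValidityScope
        scope = ValidityScope(cluster_map={}, warmup_exclusion_s={})
        with pytest.raises(ConfigurationError):
            select_validity_pairs(self.frame(), VitalSign.HR, scope)


class TestMinuteLevel:
    def outlier_pairs(self):
        rows = []
        for subject, base in (("A", 100.0), ("B", 102.0)):
            for minute in range(2):
                for i in range(11):
                    rows.append(
                        {
                            "participant_id": subject,
                            "vital_sign": "HR",
                            "device_id": "w",
                            "reference_id": "r",
                            "cluster": "cycling",
                            "task": "cycling",
                            "t_in_task_s": minute * 60.0 + i * 5.0,
                            "minute_index": minute,
                            "wearable": base,
                            "reference": base,
                        }
                    )
        frame = pd.DataFrame(rows)
        # one gross outlier inside subject A's first minute
        frame.loc[5, "wearable"] = 300.0
        return frame

    def test_minute_medians_resist_outlier(self):
        frame = self.outlier_pairs()
        sample = BlandAltmanRM.from_pairs(frame).fit()
        minute = minute_level_validity(frame, VitalSign.HR)
        assert sample.mean_difference > 0.0  # outlier shifts the sample level
        assert minute.mean_difference == 0.0  # but not the minute medians
        assert minute.level == "minute"
        assert minute.n_pairs == 4

    def test_constant_minutes_collapse_to_sample_result(self):
        frame = self.outlier_pairs()
        frame["wearable"] = frame["reference"] + 2.0
        sample = BlandAltmanRM.from_pairs(frame).fit()
        minute = minute_level_validity(frame, VitalSign.HR)
        assert minute.mean_difference == pytest.approx(
            sample.mean_difference
        )
        assert minute.total_sd == pytest.approx(sample.total_sd)

    def test_minute_median_pairs_counts(self):
        out = minute_median_pairs(self.outlier_pairs())
        assert len(out) == 4
        assert set(out["n_samples"]) == {11}


class TestPlotData:
    def test_point_arithmetic(self):
        pairs = make_pairs([100.0], [90.0], ["A"])
        points = bland_altman_plotdata(pairs)
        assert points["mean"].iloc[0] == 95.0
        assert points["difference"].iloc[0] == 10.0

    def test_identity_points_on_zero_line(self):
        pairs = make_pairs([5, 6], [5, 6], ["A", "A"])
        assert (bland_altman_plotdata(pairs)["difference"] == 0.0).all()

    def test_row_conservation_and_lines(self):
        pairs = make_pairs([1, 3, 5, 7], [0, 0, 0, 0], list("AABB"))
        res = BlandAltmanRM.from_pairs(pairs).fit()
        points = bland_altman_plotdata(pairs, res)
        assert len(points) == res.n_pairs
        assert points.attrs["lines"]["mean_difference"] == res.mean_difference
        assert points.attrs["lines"]["loa_high"] == res.loa_high
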