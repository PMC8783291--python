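import numpy as np
import pandas as pd
import pytest

from wearvalid.availability import missing_epochs
from wearvalid.core import Cluster, ConfigurationError, VitalSign
from wearvalid.simulate import (
    ClusterTrend,
    DeviceModel,
    DropoutModel,
    ObservationChannel,
    PhysiologyProfile,
    SyntheticCohortConfig,
    generate_cohort,
    generate_truth,
    observe,
    storage_grid,
)


def flat_profile(vital=VitalSign.HR, level=80.0, sd=0.0):
    return PhysiologyProfile(
        vital=vital, trends={c: ClusterTrend.constant(level, sd=sd)
                             for c in Cluster}
    )


def plain_device(device_id="dev", period=10.0, vital=VitalSign.HR, **kw):
    channel = ObservationChannel(
        vital=vital,
        bias=kw.pop("bias", {}),
        noise_sd=kw.pop("noise_sd", {}),
        subject_bias_sd=kw.pop("subject_bias_sd", 0.0),
        resolution=kw.pop("resolution", 0.0),
        dropout=kw.pop("dropout", None),
        noise_rho=kw.pop("noise_rho", 0.0),
    )
    return DeviceModel(device_id, period, {vital: channel})


class TestGenerateTruth:
    def test_metronome_breathing_rates_exact(self, schedule, profiles):
        truth = generate_truth(profiles[VitalSign.RR], schedule, seed=11)
        expected = dict(zip(
            [w.name for w in schedule.windows(Cluster.BREATHING)],
            [6.0, 15.0, 20.0, 24.0],
        ))
        for w in schedule.windows(Cluster.BREATHING):
            inside = (truth.t >= w.start_s) & (truth.t <= w.end_s)
            assert set(truth.values[inside]) == {expected[w.name]}

    def test_cycling_reaches_target_heart_rate(self, schedule, profiles):
        truth = generate_truth(profiles[VitalSign.HR], schedule, seed=11)
        w = schedule.windows(Cluster.CYCLING)[0]
        inside = (truth.t >= w.start_s) & (truth.t <= w.end_s)
        assert truth.values[inside].max() >= 120.0

    def test_zero_variability_is_constant(self, schedule):
        truth = generate_truth(flat_profile(sd=0.0), schedule, seed=123)
        assert set(truth.values) == {80.0}

    def test_ramp_hits_target_within_cluster(self, schedule):
        trends = {c: ClusterTrend.constant(80.0) for c in Cluster}
        trends[Cluster.CYCLING] = ClusterTrend.ramp(85.0, 125.0, sd=0.0)
        truth = generate_truth(
            PhysiologyProfile(VitalSign.HR, trends), schedule, seed=0
        )
        w = schedule.windows(Cluster.CYCLING)[0]
        inside = (truth.t >= w.start_s) & (truth.t <= w.end_s)
        ramp = truth.values[inside]
        assert np.all(np.diff(ramp) >= 0)  # monotone
        assert ramp[-1] == pytest.approx(125.0)

    def test_truth_defined_at_every_whole_second(self, schedule, profiles):
        truth = generate_truth(profiles[VitalSign.HR], schedule, seed=1)
        n_expected = sum(int(w.duration_s) + 1 for w in schedule)
        assert truth.t.size == n_expected

    def test_missing_cluster_trend_is_config_error(self, schedule):
        trends = {Cluster.RESTING: ClusterTrend.constant(80.0)}
        with pytest.raises(ConfigurationError, match="cluster"):
            generate_truth(
                PhysiologyProfile(VitalSign.HR, trends), schedule, seed=0
            )

    def test_out_of_range_level_rejected(self):
        with pytest.raises(ConfigurationError, match="physiological"):
            flat_profile(level=300.0)

    def test_metronome_length_mismatch_rejected(self, schedule):
        trends = {c: ClusterTrend.constant(15.0) for c in Cluster}
        trends[Cluster.BREATHING] = ClusterTrend.metronome((6, 15))
        with pytest.raises(ConfigurationError, match="sequence"):
            generate_truth(
                PhysiologyProfile(VitalSign.RR, trends), schedule, seed=0
            )


class TestObserve:
    def test_identity_observation_equals_truth_on_grid(self, schedule):
        truth = generate_truth(flat_profile(sd=0.0), schedule, seed=0)
        stream = observe(truth, plain_device(), VitalSign.HR, seed=5)
        assert np.all(stream.values == 80.0)
        for w in schedule:
            expected = storage_grid(w.start_s, w.duration_s, 10.0)
            inside = (stream.t >= w.start_s) & (stream.t <= w.end_s)
            np.testing.assert_array_equal(stream.t[inside], expected)

    def test_storage_grid_count(self, schedule):
        # chest patch at 4 s over 57 min of tasks: 855 samples
        truth = generate_truth(flat_profile(sd=0.0), schedule, seed=0)
        stream = observe(truth, plain_device(period=4.0), VitalSign.HR, 1)
        assert len(stream) == 855

    def test_uncovered_vital_is_config_error(self, schedule):
        truth = generate_truth(flat_profile(vital=VitalSign.RR, level=15),
                               schedule, seed=0)
        with pytest.raises(ConfigurationError, match="cover"):
            observe(truth, plain_device(vital=VitalSign.HR), VitalSign.RR, 0)

    def test_bias_and_quantization(self, schedule):
        truth = generate_truth(flat_profile(level=80.3, sd=0.0), schedule, 0)
        dev = plain_device(bias={c: 0.45 for c in Cluster}, resolution=0.5)
        stream = observe(truth, dev, VitalSign.HR, seed=0)
        # 80.75 quantized to the 0.5 grid
        assert set(stream.values) <= {80.5, 81.0}
        assert np.all(np.mod(stream.values, 0.5) == 0)

    def test_same_seed_reproduces_stream(self, schedule):
        truth = generate_truth(flat_profile(sd=2.0), schedule, seed=3)
        dev = plain_device(
            noise_sd={c: 2.0 for c in Cluster},
            dropout=DropoutModel({c: 0.5 for c in Cluster}, 2.0, 0.5),
        )
        a = observe(truth, dev, VitalSign.HR, seed=42)
        b = observe(truth, dev, VitalSign.HR, seed=42)
        np.testing.assert_array_equal(a.t, b.t)
        np.testing.assert_array_equal(a.values, b.values)

    def test_forced_dropout_epoch_detected_downstream(self, simple_schedule):
        truth = generate_truth(flat_profile(sd=0.0), simple_schedule, 0)
        stream = observe(truth, plain_device(), VitalSign.HR, seed=0)
        # delete two consecutive samples (a 30 s gap on a 10 s grid)
        keep = ~np.isin(stream.t, [50.0, 60.0])
        broken = stream.subset(keep)
        epochs = missing_epochs(broken, simple_schedule)
        assert len(epochs) == 1
        assert epochs[0].duration_s == pytest.approx(20.0)
        assert epochs[0].n_missing == 2

    def test_subject_bias_constant_within_stream(self, schedule):
        truth = generate_truth(flat_profile(sd=0.0), schedule, seed=0)
        dev = plain_device(subject_bias_sd=5.0)
        stream = observe(truth, dev, VitalSign.HR, seed=9)
        offsets = np.unique(stream.values - 80.0)
        assert offsets.size == 1 and offsets[0] != 0.0


class TestGenerateCohort:
    def test_cohort_determinism(self, schedule, profiles, devices):
        config = SyntheticCohortConfig(2, schedule, profiles, devices, seed=5)
        a = generate_cohort(config)
        b = generate_cohort(config)
        fa = pd.concat([s.to_frame() for s in a.streams], ignore_index=True)
        fb = pd.concat([s.to_frame() for s in b.streams], ignore_index=True)
        pd.testing.assert_frame_equal(fa, fb)

    def test_one_stream_per_participant_device_vital(self, tiny_cohort):
        keys = {(s.participant_id, s.device_id, s.vital_sign)
                for s in tiny_cohort.streams}
        assert len(keys) == len(tiny_cohort.streams)
        n_channels = sum(len(d.channels) for d in tiny_cohort.config.devices)
        assert len(tiny_cohort.streams) == 3 * n_channels

    def test_no_dropout_patch_sample_count(self, schedule, profiles):
        dev = plain_device(device_id="patch", period=4.0)
        cohort = generate_cohort(
            SyntheticCohortConfig(2, schedule, profiles, [dev], seed=1)
        )
        assert all(len(s) == 855 for s in cohort.streams)

    def test_missing_profile_rejected(self, schedule, profiles):
        incomplete = {VitalSign.RR: profiles[VitalSign.RR]}
        with pytest.raises(ConfigurationError, match="profile"):
            SyntheticCohortConfig(
                1, schedule, incomplete, [plain_device()], seed=0
            )

    def test_conservation_of_grid_points(self, schedule, profiles):
        """stored + dropped = grid points, per stream."""
        dev = plain_device(
            dropout=DropoutModel({c: 1.0 for c in Cluster}, 2.5, 0.8),
        )
        cohort = generate_cohort(
            SyntheticCohortConfig(2, schedule, profiles, [dev], seed=2)
        )
        n_grid = sum(
            storage_grid(w.start_s, w.duration_s, 10.0).size
            for w in schedule
        )
        for s in cohort.streams:
            dropped = sum(e.n_missing for e in missing_epochs(s, schedule))
            assert len(s) + dropped == n_grid
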