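"""Speed computation, event detection, epoching, and reaction times."""

import numpy as np
import pandas as pd
import pytest

from betawheel import evaluation, kinematics, synthdata
from betawheel.config import EventDetectionConfig, KinematicsConfig, TaskConfig

FS = 500.0


def _single_trial_cues():
    return pd.DataFrame({"cue_type": ["start", "reverse", "stop"],
                         "direction": [1, -1, 0],
                         "time_s": [2.0, 6.0, 10.0],
                         "condition": ["predictable"] * 3})


class TestAngularSpeed:
    def test_constant_angle_gives_zero_speed(self):
        st = kinematics.angular_speed(np.full(1000, 33.0), FS)
        assert np.allclose(st.values, 0.0)

    def test_linear_ramp_recovers_slope(self):
        t = np.arange(500) / FS
        st = kinematics.angular_speed(360.0 * t, FS)
        assert np.allclose(st.values[30:-30], 360.0, atol=1e-6)

    def test_quantized_ramp_within_two_percent_of_true_speed(self):
        t = np.arange(1000) / FS
        angle = 400.0 * t
        quantized = np.round(angle / 0.1) * 0.1
        st = kinematics.angular_speed(quantized, FS, smoothing_window=0.05)
        oracle = kinematics.angular_speed(angle, FS, smoothing_window=0.05)
        mid = slice(50, -50)
        rel = np.abs(st.values[mid] - oracle.values[mid]) / 400.0
        assert rel.max() < 0.02

    def test_non_finite_sample_raises_with_index(self):
        a = np.zeros(100)
        a[42] = np.nan
        with pytest.raises(ValueError, match="42"):
            kinematics.angular_speed(a, FS)


class TestDetectEvents:
    def test_noiseless_trial_detected_within_20ms(self):
        cues = _single_trial_cues()
        kin = KinematicsConfig(speed_noise_sd=0.0, encoder_resolution=0.0)
        angle, truth, _ = synthdata.generate_wheel_trace(cues, kin, seed=1)
        speed = kinematics.angular_speed(angle, FS)
        events = kinematics.detect_events(speed, cues)
        merged = truth.merge(events, on=["cue_index", "event_type"],
                             suffixes=("_t", "_d"))
        assert len(merged) == 3
        assert (merged["time_s_d"] - merged["time_s_t"]).abs().max() <= 0.020

    def test_zero_speed_yields_empty_table(self):
        cues = _single_trial_cues()
        st = kinematics.SpeedTrace(np.zeros(10_000), FS, 0.05)
        events = kinematics.detect_events(st, cues)
        assert len(events) == 0

    def test_two_reversals_linked_to_their_cues(self):
        task = TaskConfig(condition="unpredictable", n_trials_per_block=5,
                          n_blocks=1, reversal_counts=((2, 1.0),), seed=8)
        cues = synthdata.generate_task_sequence(task)
        kin = KinematicsConfig()
        angle, truth, _ = synthdata.generate_wheel_trace(cues, kin, seed=8)
        speed = kinematics.angular_speed(angle, FS)
        events = kinematics.detect_events(speed, cues)
        rev = events[events.event_type == "reversal"]
        assert len(rev) == 10  # 5 trials x 2 reversals
        rev_cues = cues[cues.cue_type == "reverse"].index
        assert set(rev["cue_index"]) == set(rev_cues)

    def test_missing_cue_table_rejected(self):
        st = kinematics.SpeedTrace(np.zeros(100), FS, 0.05)
        with pytest.raises(ValueError):
            kinematics.detect_events(st, pd.DataFrame())

    def test_detection_sensitivity_and_timing_at_default_noise(self):
        res = evaluation.kinematics_recovery(n_subjects=3, n_trials_per_block=10,
                                             n_blocks=1, seed=13)
        assert res["sensitivity"] >= 0.99
        assert res["mean_abs_error_ms"] <= 20.0

    def test_timing_error_grows_with_speed_noise(self):
        errs = []
        for noise in (4.0, 40.0):
            cues = synthdata.generate_task_sequence(
                TaskConfig(condition="predictable", n_trials_per_block=20,
                           n_blocks=1))
            kin = KinematicsConfig(speed_noise_sd=noise)
            angle, truth, _ = synthdata.generate_wheel_trace(cues, kin, seed=5)
            speed = kinematics.angular_speed(angle, FS)
            events = kinematics.detect_events(speed, cues)
            m = truth.merge(events, on=["cue_index", "event_type"],
                            suffixes=("_t", "_d"))
            errs.append((m["time_s_d"] - m["time_s_t"]).abs().mean())
        assert errs[1] > errs[0]

    def test_every_detected_event_follows_its_cue(self, small_subject):
        speed = kinematics.angular_speed(small_subject.angle, FS)
        events = kinematics.detect_events(speed, small_subject.cues)
        cue_t = small_subject.cues["time_s"].to_numpy()
        assert (events["time_s"].to_numpy() > cue_t[events["cue_index"]]).all()


class TestEpoch:
    def test_window_arithmetic(self):
        sig = np.arange(12_000, dtype=float)[None, :]
        events = pd.DataFrame({"event_type": ["start"], "sample": [5000],
                               "time_s": [10.0], "cue_index": [0],
                               "condition": ["predictable"], "source": ["d"]})
        eps = kinematics.epoch(sig, events, span=4.0, sample_rate=FS)
        assert eps.data.shape == (1, 1, 2000)
        assert eps.data[0, 0, 0] == 4000 and eps.data[0, 0, -1] == 5999
        assert eps.times[0] == -2.0 and eps.times[eps.data.shape[-1] // 2] == 0.0

    def test_edge_trial_excluded_with_count(self):
        sig = np.zeros((1, 5000))
        events = pd.DataFrame({"event_type": ["start", "start"],
                               "sample": [250, 3000],
                               "time_s": [0.5, 6.0], "cue_index": [0, 1],
                               "condition": ["predictable"] * 2,
                               "source": ["d"] * 2})
        eps = kinematics.epoch(sig, events, span=4.0, sample_rate=FS)
        assert eps.n_trials == 1
        assert eps.metadata["n_excluded"].iloc[0] == 1

    def test_zero_usable_trials_raises(self):
        sig = np.zeros((1, 1000))
        events = pd.DataFrame({"event_type": ["start"], "sample": [100],
                               "time_s": [0.2], "cue_index": [0],
                               "condition": ["predictable"], "source": ["d"]})
        with pytest.raises(ValueError):
            kinematics.epoch(sig, events, span=4.0, sample_rate=FS)

    def test_full_predictable_block_epochs_every_trial(self):
        task = TaskConfig(condition="predictable", n_trials_per_block=12, n_blocks=1)
        cues = synthdata.generate_task_sequence(task)
        kin = KinematicsConfig()
        angle, truth, n = synthdata.generate_wheel_trace(cues, kin, seed=2)
        sig = np.zeros((1, n))
        for event_type in ("start", "reversal", "stop"):
            eps = kinematics.epoch(sig, truth, span=4.0, sample_rate=FS,
                                   event_type=event_type)
            assert eps.n_trials == 12


class TestReactionTimes:
    def test_rt_is_event_minus_cue(self):
        cues = pd.DataFrame({"cue_type": ["start"], "direction": [1],
                             "time_s": [10.0], "condition": ["predictable"]})
        events = pd.DataFrame({"event_type": ["start"], "sample": [5400],
                               "time_s": [10.8], "cue_index": [0],
                               "condition": ["predictable"], "source": ["d"]})
        rt, summary = kinematics.reaction_times(events, cues)
        assert rt["rt"].iloc[0] == pytest.approx(0.8)

    def test_event_preceding_cue_flagged_and_excluded(self):
        cues = pd.DataFrame({"cue_type": ["start"], "direction": [1],
                             "time_s": [10.0], "condition": ["predictable"]})
        events = pd.DataFrame({"event_type": ["start"], "sample": [4000],
                               "time_s": [8.0], "cue_index": [0],
                               "condition": ["predictable"], "source": ["d"]})
        rt, summary = kinematics.reaction_times(events, cues)
        assert len(rt) == 0 and summary.attrs["n_flagged"] == 1

    def test_recovered_unpredictable_start_mean(self):
        res = evaluation.kinematics_recovery(n_subjects=8, n_trials_per_block=18,
                                             n_blocks=1, seed=17)
        s = res["rt_summary"]
        row = s[(s.condition == "unpredictable") & (s.event_type == "start")].iloc[0]
        sem = row["std"] / np.sqrt(row["count"])
        assert abs(row["mean"] - 0.840) < 3 * sem


class TestAlignedSpeedAverage:
    def test_identical_trials_average_equals_single_trial(self):
        sig = np.zeros(20_000)
        samples = [4000, 9000, 14000]
        for s in samples:
            sig[s:s + 500] = 100.0
        st = kinematics.SpeedTrace(sig, FS, 0.05)
        events = pd.DataFrame({"event_type": ["start"] * 3, "sample": samples,
                               "time_s": [s / FS for s in samples],
                               "cue_index": [0, 1, 2],
                               "condition": ["predictable"] * 3,
                               "source": ["d"] * 3})
        times, avg = kinematics.aligned_speed_average(st, events, span=4.0)
        single = sig[samples[0] - 1000:samples[0] + 1000]
        assert np.allclose(avg, single)

    def test_movement_aligned_average_rises_at_zero(self, small_subject):
        det = EventDetectionConfig()
        speed = kinematics.angular_speed(small_subject.angle, FS)
        events = kinematics.detect_events(speed, small_subject.cues, det)
        times, avg = kinematics.aligned_speed_average(
            st := kinematics.SpeedTrace(np.abs(speed.values), FS, 0.05),
            events, span=4.0, event_type="start")
        pre = np.abs(avg[(times > -0.5) & (times < -0.1)]).mean()
        at = np.interp(0.15, times, avg)
        assert pre < det.amplitude_threshold / 2 and at > det.amplitude_threshold

    def test_cue_aligned_average_crosses_threshold_near_mean_rt(self, small_subject):
        det = EventDetectionConfig()
        speed = kinematics.angular_speed(small_subject.angle, FS)
        events = kinematics.detect_events(speed, small_subject.cues, det)
        starts = events[(events.event_type == "start")
                        & (events.condition == "predictable")]
        rt_mean = (starts["time_s"].to_numpy()
                   - small_subject.cues.loc[starts["cue_index"], "time_s"].to_numpy()
                   ).mean()
        times, avg = kinematics.aligned_speed_average(
            kinematics.SpeedTrace(np.abs(speed.values), FS, 0.05),
            events[events.condition == "predictable"], span=4.0,
            event_type="start", alignment="cue", cues=small_subject.cues)
        crossing = times[np.argmax(avg > det.amplitude_threshold)]
        assert abs(crossing - rt_mean) < 0.25
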