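"""Generator tests: task sequences, wheel kinematics, and neural signals."""

import numpy as np
import pandas as pd
import pytest

from betawheel import evaluation, spectral, synthdata
from betawheel.config import (
    ConfigurationError,
    CouplingSpec,
    EventGain,
    KinematicsConfig,
    OscillationSpec,
    TaskConfig,
    TFRSpec,
)


class TestTaskSequence:
    def test_predictable_block_has_fixed_cue_counts_and_spacing(self):
        cues = synthdata.generate_task_sequence(
            TaskConfig(condition="predictable", n_trials_per_block=36, n_blocks=1))
        counts = cues["cue_type"].value_counts()
        assert counts["start"] == 36 and counts["reverse"] == 36 and counts["stop"] == 36
        one = cues[cues["trial"] == 5].sort_values("time_s")
        gaps = np.diff(one["time_s"].to_numpy())
        assert np.allclose(gaps, 4.0)

    def test_unpredictable_reversal_expectation_is_one(self):
        cues = synthdata.generate_task_sequence(
            TaskConfig(condition="unpredictable", n_trials_per_block=10_000,
                       n_blocks=1, seed=3))
        n_rev = (cues["cue_type"] == "reverse").sum()
        # mean of uniform {0,1,2} is 1; SE = sqrt(2/3)/100
        assert abs(n_rev / 10_000 - 1.0) < 4 * np.sqrt(2 / 3) / 100

    def test_isi_mixture_fraction_within_binomial_ci(self):
        cues = synthdata.generate_task_sequence(
            TaskConfig(condition="unpredictable", n_trials_per_block=10_000,
                       n_blocks=1, seed=9))
        # inter-stimulus intervals within a trial (start->...->stop)
        isis = []
        for _, grp in cues.groupby(["block", "trial"]):
            isis.extend(np.diff(grp.sort_values("time_s")["time_s"].to_numpy()))
        isis = np.asarray(isis)
        frac = np.mean(np.isclose(isis, 4.0))
        half = 2.576 * np.sqrt(0.25 / isis.size)  # binomial 99% CI at p=0.5
        assert 0.5 - half <= frac <= 0.5 + half
        assert isis.min() >= 4.0 - 1e-9 and isis.max() <= 7.0 + 1e-9

    def test_invalid_probability_vector_rejected(self):
        with pytest.raises(ConfigurationError):
            TaskConfig(reversal_counts=((0, 0.5), (1, 0.2)))

    def test_unpredictable_isis_carry_no_serial_structure(self):
        cues = synthdata.generate_task_sequence(
            TaskConfig(condition="unpredictable", n_trials_per_block=500,
                       n_blocks=1, seed=5))
        isis = []
        for _, grp in cues.groupby(["block", "trial"]):
            isis.extend(np.diff(grp.sort_values("time_s")["time_s"].to_numpy()))
        isis = np.asarray(isis)
        x = isis - isis.mean()
        obs = np.corrcoef(x[:-1], x[1:])[0, 1]
        rng = np.random.default_rng(0)
        null = np.array([
            np.corrcoef(p[:-1], p[1:])[0, 1]
            for p in (rng.permutation(x) for _ in range(500))])
        p = (1 + np.sum(np.abs(null) >= abs(obs))) / 501
        assert p > 0.01


class TestWheelTrace:
    def test_fixed_reaction_time_places_start_event(self):
        cues = pd.DataFrame({"cue_type": ["start", "stop"], "direction": [1, 0],
                             "time_s": [10.0, 16.0],
                             "condition": ["predictable"] * 2})
        kin = KinematicsConfig(speed_noise_sd=0.0,
                               rt_mean={("predictable", "start"): 0.8,
                                        ("predictable", "stop"): 0.8},
                               rt_sd={("predictable", "start"): 1e-9,
                                      ("predictable", "stop"): 1e-9})
        _, truth, _ = synthdata.generate_wheel_trace(cues, kin, seed=0)
        assert truth.loc[truth.event_type == "start", "time_s"].iloc[0] == \
            pytest.approx(10.8, abs=1e-6)

    def test_steady_segment_speed_matches_target_within_quantization(self):
        cues = pd.DataFrame({"cue_type": ["start", "stop"], "direction": [1, 0],
                             "time_s": [2.0, 10.0],
                             "condition": ["predictable"] * 2})
        kin = KinematicsConfig(speed_noise_sd=0.0)
        angle, truth, n = synthdata.generate_wheel_trace(cues, kin, seed=1)
        fs = kin.sample_rate
        speed = np.gradient(angle) * fs
        steady = speed[int(4.5 * fs):int(7.5 * fs)]
        assert abs(steady.mean() - 400.0) < 1.0
        assert np.abs(steady - 400.0).max() <= kin.encoder_resolution * fs + 1e-6

    def test_rt_sample_mean_recovers_configured_mean(self):
        # ~1000 predictable start trials; configured mean 0.757, SD 0.154
        cues = synthdata.generate_task_sequence(
            TaskConfig(condition="predictable", n_trials_per_block=1000, n_blocks=1))
        kin = KinematicsConfig(speed_noise_sd=0.0)
        _, truth, _ = synthdata.generate_wheel_trace(cues, kin, seed=11)
        starts = truth[truth.event_type == "start"]
        rt = starts["time_s"].to_numpy() - cues.loc[starts["cue_index"], "time_s"].to_numpy()
        sem = 0.154 / np.sqrt(len(rt))
        assert abs(rt.mean() - 0.757) < 3 * sem

    def test_truth_events_lie_between_cue_and_next_cue(self, small_subject):
        truth = small_subject.truth_events
        cue_t = small_subject.cues["time_s"].to_numpy()
        for row in truth.itertuples():
            assert row.time_s > cue_t[row.cue_index]
            if row.cue_index + 1 < len(cue_t):
                assert row.time_s < cue_t[row.cue_index + 1]


class TestNeuralData:
    def test_stationary_channel_peaks_at_band_center(self, stationary_epochs):
        coeffs = spectral.mtm_fourier(stationary_epochs, TFRSpec(), bands=("low",))
        p = spectral.power_tfr(coeffs, "low", channel=0)
        peak = p.freqs[np.argmax(p.values.mean(axis=1))]
        assert abs(peak - 20.0) <= 3.125  # within the taper half-bandwidth
        # no envelope modulation: time course statistically flat
        tc = p.values[(p.freqs >= 13) & (p.freqs <= 30)].mean(axis=0)
        assert tc.std() / tc.mean() < 0.15

    def test_rebound_power_ratio_recovers_configured_gain(self):
        # oscillation-dominated channel: post/pre beta power ratio ~ gain 2.0
        spec = synthdata.ChannelSpec(
            name="ch", bg_psd_ref=1e-6,
            oscillations=[OscillationSpec(
                band="beta", band_center=20.0, radius=0.97, baseline_power=1.0,
                envelope_events={"stop": EventGain(2.0, onset=-0.1, duration=2.2,
                                                   ramp=0.05)})])
        data, _ = synthdata.simulate_epochs(500, [spec], event_type="stop",
                                            seed=21)
        eps = evaluation.epochs_from_array(data, event_type="stop")
        # per-trial band power via one multitaper pass
        coeffs = spectral.mtm_fourier(eps, TFRSpec(), bands=("low",))
        p = spectral.power_tfr(coeffs, "low", channel=0, average_trials=False)
        sel_f = (p.freqs >= 13) & (p.freqs <= 30)
        pre = p.values[:, sel_f][:, :, (p.times >= -1.4) & (p.times < -0.2)].mean((1, 2))
        post = p.values[:, sel_f][:, :, (p.times >= 0.2) & (p.times < 1.4)].mean((1, 2))
        ratio = post.mean() / pre.mean()
        se = np.sqrt(post.std(ddof=1) ** 2 / post.mean() ** 2 +
                     pre.std(ddof=1) ** 2 / pre.mean() ** 2) / np.sqrt(500) * ratio
        assert abs(ratio - 2.0) < max(4 * se, 0.05)

    def test_uncoupled_channels_show_only_estimator_bias_coherence(self):
        specs = [evaluation.stationary_channel("a"),
                 evaluation.stationary_channel("b")]
        data, _ = synthdata.simulate_epochs(60, specs, seed=31)
        eps = evaluation.epochs_from_array(data)
        coeffs = spectral.mtm_fourier(eps, TFRSpec(), bands=("low",))
        coh = spectral.coherence_tfr(coeffs, (0, 1))
        n_obs = 60 * 4
        assert (coh.values ** 2).mean() < 2.0 / n_obs

    def test_coupled_coherence_matches_analytic_shared_signal_value(self):
        res = evaluation.coherence_recovery(n_trials=500, seed=41)
        assert abs(res["estimate"] - res["analytic_band"]) < 0.02
        assert abs(res["estimate"] - res["analytic_point"]) < 0.05

    def test_unknown_coupling_role_raises(self):
        specs = [evaluation.stationary_channel("a")]
        bad = CouplingSpec(source="nope", target="a", band="beta")
        with pytest.raises(ConfigurationError):
            synthdata.simulate_epochs(5, specs, [bad], seed=0)

    def test_identical_seed_reproduces_bitwise(self, small_tasks):
        kin = KinematicsConfig()
        chans = synthdata.default_channel_specs()
        coups = synthdata.default_coupling_specs()
        subs = [synthdata.simulate_subject("s", small_tasks, kin, chans, coups,
                                           np.random.default_rng(99))
                for _ in range(2)]
        assert np.array_equal(subs[0].signals, subs[1].signals)
        assert np.array_equal(subs[0].angle, subs[1].angle)
        pd.testing.assert_frame_equal(subs[0].cues, subs[1].cues)
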