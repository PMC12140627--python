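"""Multitaper power/coherence against direct-DFT oracles and invariants."""

import numpy as np
import pytest

from betawheel import evaluation, spectral
from betawheel.config import TFRSpec

FS = 500.0


def _oracle_tfr(data, spec, fs=FS, band="low"):
    """Independent direct-DFT multitaper oracle (explicit loops, exp matrix)."""
    nwin = int(round(spec.window * fs))
    n_tapers = spec.n_tapers_low if band == "low" else spec.n_tapers_high
    brange = spec.low_band if band == "low" else spec.high_band
    from scipy.signal.windows import dpss
    tapers = dpss(nwin, NW=(n_tapers + 1) / 2.0, Kmax=n_tapers, norm=2)
    tapers = np.atleast_2d(tapers)
    step = spec.freq_step
    freqs = np.arange(np.ceil(brange[0] / step), np.floor(brange[1] / step) + 1) * step
    centers = np.arange(spec.analysis_span[0], spec.analysis_span[1] + spec.step / 2,
                        spec.step)
    centers = np.round(centers / spec.step) * spec.step
    n = data.shape[-1]
    t0 = -(n // 2) / fs
    tt = np.arange(nwin) / fs
    basis = np.exp(-2j * np.pi * freqs[:, None] * tt[None, :])  # (F, nwin)
    out = np.zeros((data.shape[0], len(freqs), len(centers)))
    for trial in range(data.shape[0]):
        for ci, c in enumerate(centers):
            s0 = int(round((c - t0) * fs)) - nwin // 2
            seg = data[trial, 0, s0:s0 + nwin]
            acc = 0.0
            for h in tapers:
                X = basis @ (seg * h)
                acc = acc + (2.0 / fs) * np.abs(X) ** 2
            out[trial, :, ci] = acc / n_tapers
    return freqs, centers, out


class TestTapers:
    @pytest.mark.parametrize("nwin,k", [(400, 4), (400, 7), (1000, 15)])
    def test_orthonormality(self, nwin, k):
        T = spectral.slepian_tapers(nwin, k)
        assert np.abs(T @ T.T - np.eye(k)).max() < 1e-10

    @pytest.mark.parametrize("k,expected_hw", [(4, 3.125), (7, 5.0)])
    def test_half_bandwidth_concentration(self, k, expected_hw):
        # energy of each taper concentrated within (K+1)/(2T) Hz of DC
        nwin = 400
        T = spectral.slepian_tapers(nwin, k)
        spec = np.abs(np.fft.rfft(T, n=8 * nwin)) ** 2
        freqs = np.fft.rfftfreq(8 * nwin, 1 / FS)
        inside = spec[:, freqs <= expected_hw].sum(axis=1) / spec.sum(axis=1)
        assert inside.min() > 0.90

    def test_invalid_taper_counts_rejected(self):
        with pytest.raises(ValueError):
            spectral.slepian_tapers(400, 0)
        with pytest.raises(ValueError):
            spectral.slepian_tapers(10, 10)


class TestMtmFourier:
    def test_pure_sine_matches_direct_dft_oracle(self):
        t = np.arange(2000) / FS
        data = np.sin(2 * np.pi * 20.0 * t)[None, None, :]
        spec = TFRSpec()
        eps = evaluation.epochs_from_array(data)
        coeffs = spectral.mtm_fourier(eps, spec, bands=("low",))
        p = spectral.power_tfr(coeffs, "low")
        freqs, centers, oracle = _oracle_tfr(data, spec)
        assert np.allclose(p.values, oracle[0], atol=1e-10)
        # concentration within the taper half-bandwidth of 20 Hz
        sel = np.abs(p.freqs - 20.0) <= 3.125
        assert p.values[sel].sum() / p.values.sum() > 0.90

    def test_white_noise_matches_oracle_and_is_flat(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((8, 1, 2000))
        spec = TFRSpec()
        eps = evaluation.epochs_from_array(data)
        coeffs = spectral.mtm_fourier(eps, spec, bands=("low",))
        p = spectral.power_tfr(coeffs, "low")
        freqs, centers, oracle = _oracle_tfr(data, spec)
        assert np.allclose(p.values, oracle.mean(axis=0), atol=1e-10)
        per_freq = p.values.mean(axis=1)
        # white noise PSD ~ 2/fs per Hz; sampling error shrinks with averaging
        assert np.abs(per_freq - 2.0 / FS).max() / (2.0 / FS) < 0.25

    def test_all_zero_input_gives_zero_coefficients(self):
        eps = evaluation.epochs_from_array(np.zeros((2, 1, 2000)))
        coeffs = spectral.mtm_fourier(eps, TFRSpec())
        assert not np.any(coeffs.coeffs["low"])
        assert not np.any(coeffs.coeffs["high"])

    def test_too_short_epoch_raises_with_required_span(self):
        eps = evaluation.epochs_from_array(np.zeros((1, 1, 900)))
        with pytest.raises(ValueError, match="span"):
            spectral.mtm_fourier(eps, TFRSpec())

    def test_quadratic_amplitude_scaling(self, stationary_epochs):
        spec = TFRSpec()
        c1 = spectral.mtm_fourier(stationary_epochs, spec, bands=("low",))
        doubled = evaluation.epochs_from_array(stationary_epochs.data * 2.0)
        c2 = spectral.mtm_fourier(doubled, spec, bands=("low",))
        p1 = spectral.power_tfr(c1, "low")
        p2 = spectral.power_tfr(c2, "low")
        assert np.allclose(p2.values, 4.0 * p1.values)

    def test_parseval_power_integral_equals_tapered_variance(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(400)
        tapers = spectral.slepian_tapers(400, 4)
        for h in tapers:
            X = np.fft.rfft(x * h)
            w = np.full(X.size, 2.0)
            w[0] = 1.0
            w[-1] = 1.0  # even length: Nyquist bin unduplicated
            integral = (w * np.abs(X) ** 2 / FS).sum() * (FS / 400)
            assert abs(integral / np.sum((x * h) ** 2) - 1.0) < 0.01


class TestCoherence:
    def test_self_coherence_is_one(self, stationary_epochs):
        coeffs = spectral.mtm_fourier(stationary_epochs, TFRSpec(), bands=("low",))
        coh = spectral.coherence_tfr(coeffs, (0, 0))
        assert np.allclose(coh.values, 1.0, atol=1e-12)

    def test_identical_channels_give_unit_coherence(self, stationary_epochs):
        data = np.repeat(stationary_epochs.data[:, :1], 2, axis=1)
        eps = evaluation.epochs_from_array(data)
        coeffs = spectral.mtm_fourier(eps, TFRSpec(), bands=("low",))
        coh = spectral.coherence_tfr(coeffs, (0, 1))
        assert np.allclose(coh.values, 1.0, atol=1e-12)

    def test_independent_noise_bias_scales_as_one_over_n(self):
        rng = np.random.default_rng(5)
        for n_trials in (15, 60):
            data = rng.standard_normal((n_trials, 2, 2000))
            eps = evaluation.epochs_from_array(data)
            coeffs = spectral.mtm_fourier(eps, TFRSpec(), bands=("low",))
            coh = spectral.coherence_tfr(coeffs, (0, 1))
            n_obs = n_trials * 4
            assert abs((coh.values ** 2).mean() - 1.0 / n_obs) < 0.5 / n_obs

    def test_single_observation_rejected(self):
        eps = evaluation.epochs_from_array(np.zeros((1, 2, 2000)))
        coeffs = spectral.mtm_fourier(eps, TFRSpec(), bands=("low",))
        coeffs.coeffs["low"] = coeffs.coeffs["low"][:, :1]
        with pytest.raises(ValueError):
            spectral.coherence_tfr(coeffs, (0, 1))

    def test_trial_permutation_invariance(self, stationary_epochs):
        spec = TFRSpec()
        coeffs = spectral.mtm_fourier(stationary_epochs, spec, bands=("low",))
        perm = np.random.default_rng(0).permutation(stationary_epochs.n_trials)
        shuffled = evaluation.epochs_from_array(stationary_epochs.data[perm])
        coeffs_p = spectral.mtm_fourier(shuffled, spec, bands=("low",))
        p = spectral.power_tfr(coeffs, "low")
        pp = spectral.power_tfr(coeffs_p, "low")
        assert np.allclose(p.values, pp.values)
        c = spectral.coherence_tfr(coeffs, (0, 1))
        cp = spectral.coherence_tfr(coeffs_p, (0, 1))
        assert np.allclose(c.values, cp.values)


class TestBaselineAndBands:
    def test_stationary_map_baseline_mean_is_one_prelog(self, stationary_epochs):
        coeffs = spectral.mtm_fourier(stationary_epochs, TFRSpec(), bands=("low",))
        raw = spectral.power_tfr(coeffs, "low")
        corr = spectral.baseline_correct(raw, (-1.6, 0.0))
        base_bins = (corr.times >= -1.6) & (corr.times < 0.0)
        ratio = (10 ** (corr.values[:, base_bins] / 10)).mean(axis=1)
        assert np.allclose(ratio, 1.0, atol=1e-9)

    def test_power_doubling_gives_3dB(self):
        vals = np.ones((5, 65))
        times = np.linspace(-1.6, 1.6, 65)
        vals[:, times >= 0] = 2.0
        tfr = spectral.TimeFrequencyMap(vals, np.arange(5) + 10.0, times, "power")
        corr = spectral.baseline_correct(tfr, (-1.6, 0.0))
        assert np.allclose(corr.values[:, times >= 0], 10 * np.log10(2), atol=1e-12)

    def test_coherence_equal_to_baseline_maps_to_zero(self):
        vals = np.full((5, 65), 0.37)
        times = np.linspace(-1.6, 1.6, 65)
        tfr = spectral.TimeFrequencyMap(vals, np.arange(5) + 10.0, times,
                                        "coherence")
        corr = spectral.baseline_correct(tfr, (-1.6, 0.0))
        assert np.allclose(corr.values, 0.0)

    def test_flat_db_map_has_zero_modulation(self):
        times = np.linspace(-1.6, 1.6, 65)
        tfr = spectral.TimeFrequencyMap(np.zeros((10, 65)),
                                        np.linspace(13, 30, 10), times,
                                        "power_dB", baseline=(-1.6, 0.0))
        bm = spectral.band_modulation(tfr)
        assert bm.modulation == 0.0

    def test_confined_rebound_diluted_by_window_fraction(self):
        times = np.round(np.arange(-1.6, 1.6 + 0.025, 0.05), 3)
        freqs = np.linspace(13, 30, 10)
        vals = np.zeros((10, times.size))
        active = (times >= 0.3) & (times < 1.0)
        vals[:, active] = 2.5
        tfr = spectral.TimeFrequencyMap(vals, freqs, times, "power_dB",
                                        baseline=(-1.6, 0.0))
        bm = spectral.band_modulation(tfr, "beta", (-1.6, 0.0), (0.0, 1.6))
        post_bins = (times >= 0.0) & (times < 1.6)
        expected = 2.5 * active.sum() / post_bins.sum()
        assert bm.modulation == pytest.approx(expected, rel=1e-9)

    def test_band_outside_grid_rejected(self):
        tfr = spectral.TimeFrequencyMap(np.zeros((5, 10)), np.linspace(5, 9, 5),
                                        np.linspace(-1, 1, 10), "power_dB")
        with pytest.raises(ValueError):
            spectral.band_modulation(tfr, (55.0, 90.0))

    def test_suppression_recovery_matches_propagated_expectation(self):
        res = evaluation.modulation_recovery(n_subjects=8, n_trials=24, seed=6)
        for key in ("start_contra", "stop_contra"):
            d = res[key]
            assert abs(d["mean"] - d["expected"]) < 4 * d["sem"]
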