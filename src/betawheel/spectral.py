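"""Multitaper time-frequency power and across-trial coherence.

Sliding-window Fourier coefficients are computed with discrete prolate
spheroidal (Slepian) tapers; a low band (5-45 Hz, 4 tapers) and a high band
(55-90 Hz, 7 tapers) are analyzed separately.  Power is expressed as
one-sided spectral density (input units^2 per Hz); coherence pools trials and
tapers as observations.  Baseline correction is decibel for power and
subtractive for coherence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import windows

from .config import BANDS, TFRSpec
from .kinematics import EpochSet


@dataclass
class TimeFrequencyMap:
    """(freq x time) or (trial x freq x time) power or coherence map."""

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    kind: str  # 'power', 'coherence', 'power_dB', 'coherence_change'
    baseline: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind == "power" and np.any(self.values < 0):
            raise ValueError("power must be non-negative")
        if self.kind == "coherence" and (
                np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-9)):
            raise ValueError("coherence must lie in [0, 1]")


@dataclass
class MTMCoeffs:
    """Complex multitaper coefficients per band.

    ``coeffs[band]`` has shape (trials, tapers, channels, freqs, times).
    """

    coeffs: dict
    freqs: dict
    times: np.ndarray
    sample_rate: float
    channel_names: list[str] | None = None


def slepian_tapers(window_samples: int, n_tapers: int) -> np.ndarray:
    """Unit-energy DPSS tapers with time-bandwidth set by n_tapers = 2*NW - 1.

    Returns an array of shape (n_tapers, window_samples).  The spectral
    half-bandwidth is (n_tapers + 1) / (2 * T) for a window of T seconds.
    """
    if n_tapers <= 0:
        raise ValueError("n_tapers must be positive")
    if n_tapers >= window_samples:
        raise ValueError("n_tapers must be smaller than the window length")
    nw = (n_tapers + 1) / 2.0
    tapers = windows.dpss(window_samples, NW=nw, Kmax=n_tapers, norm=2)
    return np.atleast_2d(tapers)


def _band_bins(band: tuple[float, float], freq_step: float, fs: float,
               nwin: int) -> tuple[np.ndarray, np.ndarray]:
    """Frequency grid (multiples of freq_step within band) and rfft bin ids."""
    rayleigh = fs / nwin
    freqs = np.arange(math.ceil(band[0] / freq_step), math.floor(band[1] / freq_step) + 1
                      ) * freq_step
    bins = np.round(freqs / rayleigh).astype(int)
    return freqs, bins


def mtm_fourier(epochs: EpochSet, spec: TFRSpec | None = None,
                bands: tuple[str, ...] = ("low", "high")) -> MTMCoeffs:
    """Sliding-window multitaper Fourier transform of event-locked epochs.

    Time bins run over ``spec.analysis_span`` in steps of ``spec.step``; a bin
    is computed only if its full window lies inside the epoch (no padding).
    Low and high bands use their own taper counts.
    """
    spec = spec or TFRSpec()
    fs = epochs.sample_rate
    data = epochs.data  # (trials, channels, time)
    nwin = int(round(spec.window * fs))
    half = nwin // 2
    centers = np.arange(spec.analysis_span[0], spec.analysis_span[1] + spec.step / 2,
                        spec.step)
    centers = np.round(centers / spec.step) * spec.step
    t0 = epochs.times[0]
    starts = np.round((centers - t0) * fs).astype(int) - half
    ok = (starts >= 0) & (starts + nwin <= data.shape[-1])
    if not ok.all():
        bad = centers[~ok]
        raise ValueError(
            f"epoch too short for an {spec.window:.3g} s window at centers "
            f"{bad.min():.3g}..{bad.max():.3g} s; need span >= "
            f"{spec.analysis_span[1] - spec.analysis_span[0] + spec.window:.3g} s")
    segs = np.stack([data[..., s:s + nwin] for s in starts], axis=2)
    # segs: (trials, channels, times, nwin)
    coeffs = {}
    freqs = {}
    band_tapers = {"low": spec.n_tapers_low, "high": spec.n_tapers_high}
    for band, n_tapers in ((b, band_tapers[b]) for b in bands):
        brange = spec.low_band if band == "low" else spec.high_band
        f, bins = _band_bins(brange, spec.freq_step, fs, nwin)
        tapers = slepian_tapers(nwin, n_tapers)
        out = np.empty(data.shape[:2] + (n_tapers, len(f), len(centers)),
                       dtype=complex)
        for k in range(n_tapers):
            X = np.fft.rfft(segs * tapers[k], axis=-1)
            out[:, :, k] = np.moveaxis(X[..., bins], -1, -2)
        # reorder to (trials, tapers, channels, freqs, times)
        coeffs[band] = np.swapaxes(out, 1, 2)
        freqs[band] = f
    return MTMCoeffs(coeffs=coeffs, freqs=freqs, times=centers, sample_rate=fs,
                     channel_names=epochs.channel_names)


def power_tfr(coeffs: MTMCoeffs, band: str = "low", channel: int = 0,
              average_trials: bool = True) -> TimeFrequencyMap:
    """Multitaper power: |X|^2 averaged over tapers (and optionally trials).

    Scaled as one-sided spectral density: 2 |X|^2 / fs with unit-energy
    tapers, so that power integrated over frequency matches the tapered
    signal variance (Parseval).
    """
    X = coeffs.coeffs[band][:, :, channel]  # (trials, tapers, freqs, times)
    p = (2.0 / coeffs.sample_rate) * (np.abs(X) ** 2)
    p = p.mean(axis=1)
    if average_trials:
        p = p.mean(axis=0)
    return TimeFrequencyMap(values=p, freqs=coeffs.freqs[band], times=coeffs.times,
                            kind="power")


def coherence_tfr(coeffs: MTMCoeffs, pair: tuple[int, int],
                  band: str = "low") -> TimeFrequencyMap:
    """Across-trial coherence: trials and tapers pooled as observations.

    ``|sum X conj(Y)| / sqrt(sum |X|^2 * sum |Y|^2)`` per time-frequency bin.
    """
    i, j = pair
    X = coeffs.coeffs[band][:, :, i]
    Y = coeffs.coeffs[band][:, :, j]
    n_obs = X.shape[0] * X.shape[1]
    if n_obs < 2:
        raise ValueError("coherence needs at least 2 observations (trials x tapers)")
    sxy = (X * np.conj(Y)).sum(axis=(0, 1))
    sxx = (np.abs(X) ** 2).sum(axis=(0, 1))
    syy = (np.abs(Y) ** 2).sum(axis=(0, 1))
    coh = np.abs(sxy) / np.sqrt(sxx * syy)
    return TimeFrequencyMap(values=coh, freqs=coeffs.freqs[band], times=coeffs.times,
                            kind="coherence")


def baseline_correct(tfr: TimeFrequencyMap,
                     baseline_window: tuple[float, float] = (-1.6, 0.0),
                     mode: str | None = None) -> TimeFrequencyMap:
    """Baseline-correct a raw map: dB for power, subtraction for coherence.

    The per-frequency baseline is the mean over bins whose center lies in
    ``[t0, t1)``.
    """
    if tfr.kind not in ("power", "coherence"):
        raise ValueError("map is already baseline-corrected")
    mode = mode or ("db" if tfr.kind == "power" else "subtract")
    mask = (tfr.times >= baseline_window[0]) & (tfr.times < baseline_window[1])
    if not mask.any():
        raise ValueError("no bins inside the baseline window")
    base = tfr.values[..., mask].mean(axis=-1, keepdims=True)
    if mode == "db":
        if np.any(base <= 0):
            raise ValueError("zero baseline power")
        vals = 10.0 * np.log10(tfr.values / base)
        kind = "power_dB"
    elif mode == "subtract":
        vals = tfr.values - base
        kind = "coherence_change"
    else:
        raise ValueError(f"unknown baseline mode {mode!r}")
    return TimeFrequencyMap(values=vals, freqs=tfr.freqs, times=tfr.times,
                            kind=kind, baseline=tuple(baseline_window))


@dataclass
class BandModulation:
    """Band- and window-averaged pre/post values of a corrected map."""

    pre: float
    post: float
    band: tuple[float, float]
    pre_window: tuple[float, float]
    post_window: tuple[float, float]

    @property
    def modulation(self) -> float:
        return self.post - self.pre


def band_modulation(tfr: TimeFrequencyMap, band="beta",
                    pre_window: tuple[float, float] = (-1.6, 0.0),
                    post_window: tuple[float, float] = (0.0, 1.6)) -> BandModulation:
    """Average a (corrected) map over a frequency band and pre/post windows."""
    lo, hi = BANDS[band] if isinstance(band, str) else band
    fmask = (tfr.freqs >= lo) & (tfr.freqs <= hi)
    if not fmask.any():
        raise ValueError(f"band {lo}-{hi} Hz outside the computed grid")
    out = []
    for win in (pre_window, post_window):
        tmask = (tfr.times >= win[0]) & (tfr.times < win[1])
        if not tmask.any():
            raise ValueError(f"window {win} outside the map span")
        out.append(float(tfr.values[..., fmask, :][..., tmask].mean()))
    return BandModulation(pre=out[0], post=out[1], band=(lo, hi),
                          pre_window=tuple(pre_window), post_window=tuple(post_window))


def segment_power(epochs: EpochSet, window: tuple[float, float], channel: int = 0,
                  half_bandwidth: float = 2.5) -> tuple[np.ndarray, np.ndarray]:
    """Whole-segment multitaper power spectrum over one time window.

    Used for the +-2 s pre/post contrasts (channel/ROI selection, Granger
    band summaries) that consume window-averaged spectra rather than the
    sliding TFR.  Returns ``(freqs, power)`` averaged over trials and tapers.
    """
    fs = epochs.sample_rate
    mask = (epochs.times >= window[0]) & (epochs.times < window[1])
    seg = epochs.data[:, channel, :][:, mask]
    nwin = seg.shape[-1]
    nw = max(1.0, half_bandwidth * nwin / fs)
    k = max(1, int(round(2 * nw - 1)))
    tapers = slepian_tapers(nwin, k)
    X = np.fft.rfft(seg[:, None, :] * tapers[None, :, :], axis=-1)
    p = (2.0 / fs) * (np.abs(X) ** 2)
    freqs = np.fft.rfftfreq(nwin, 1.0 / fs)
    return freqs, p.mean(axis=(0, 1))


def band_power(epochs: EpochSet, window: tuple[float, float], band="beta",
               channel: int = 0, half_bandwidth: float = 2.5) -> float:
    """Band-average of :func:`segment_power` (units^2/Hz)."""
    lo, hi = BANDS[band] if isinstance(band, str) else band
    freqs, p = segment_power(epochs, window, channel=channel,
                             half_bandwidth=half_bandwidth)
    sel = (freqs >= lo) & (freqs <= hi)
    return float(p[sel].mean())
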