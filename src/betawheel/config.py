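"""Configuration objects for every pipeline stage.

All tunable parameters live in plain dataclasses so that a run is fully
described by one YAML file.  Each config validates itself on construction;
invalid values raise :class:`ConfigurationError` early, before any data is
generated or touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, is_dataclass
from typing import Any

import yaml

# Canonical frequency bands (Hz).  Band edges follow common usage in the
# movement-disorders literature; the gamma range matches the analyzed
# 55-90 Hz grid which skips the 50 Hz line-noise region.
BETA = (13.0, 30.0)
LOW_BETA = (13.0, 20.0)
HIGH_BETA = (20.0, 30.0)
GAMMA = (55.0, 90.0)
BANDS = {"beta": BETA, "low_beta": LOW_BETA, "high_beta": HIGH_BETA, "gamma": GAMMA}

#: single sample rate (Hz) shared by the encoder trace and neural channels
DEFAULT_FS = 500.0


class ConfigurationError(ValueError):
    """Raised when a config object violates one of its invariants."""


@dataclass
class TaskConfig:
    """Cue-sequence parameters for one condition block structure.

    In the predictable condition every trial is start -> reverse -> stop with a
    fixed inter-cue interval.  In the unpredictable condition each trial draws
    its reversal count from ``reversal_counts`` and each inter-stimulus
    interval is either held at ``isi_fixed`` (with probability
    ``isi_fixed_fraction``) or drawn uniformly from ``isi_range``.
    """

    condition: str = "predictable"
    n_trials_per_block: int = 36
    n_blocks: int = 2
    isi_fixed: float = 4.0
    isi_range: tuple[float, float] = (4.0, 7.0)
    isi_fixed_fraction: float = 0.5
    reversal_counts: tuple[tuple[int, float], ...] = ((0, 1 / 3), (1, 1 / 3), (2, 1 / 3))
    pause_duration: float = 4.0
    lead_in: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in ("predictable", "unpredictable"):
            raise ConfigurationError(f"unknown condition {self.condition!r}")
        probs = [p for _, p in self.reversal_counts]
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigurationError("reversal probabilities must be >= 0 and sum to 1")
        if self.isi_range[0] > self.isi_range[1]:
            raise ConfigurationError("isi_range low must be <= high")
        if min(self.isi_fixed, self.pause_duration, self.isi_range[0]) <= 0:
            raise ConfigurationError("all durations must be > 0")
        if not 0.0 <= self.isi_fixed_fraction <= 1.0:
            raise ConfigurationError("isi_fixed_fraction must lie in [0, 1]")
        if self.n_trials_per_block < 1 or self.n_blocks < 1:
            raise ConfigurationError("trial and block counts must be >= 1")


# Reaction-time distribution defaults (seconds).  Start and stop means/SDs are
# the group values reported for this paradigm; reversal values are not printed
# anywhere and were chosen in the same range.
DEFAULT_RT_MEAN = {
    ("predictable", "start"): 0.757,
    ("predictable", "stop"): 0.824,
    ("predictable", "reversal"): 0.800,
    ("unpredictable", "start"): 0.840,
    ("unpredictable", "stop"): 0.889,
    ("unpredictable", "reversal"): 0.860,
}
DEFAULT_RT_SD = {
    ("predictable", "start"): 0.154,
    ("predictable", "stop"): 0.202,
    ("predictable", "reversal"): 0.180,
    ("unpredictable", "start"): 0.160,
    ("unpredictable", "stop"): 0.233,
    ("unpredictable", "reversal"): 0.190,
}


@dataclass
class KinematicsConfig:
    """Wheel-movement profile and encoder parameters.

    ``target_speed`` is the steady angular speed (deg/s) reached after a linear
    ramp of ``ramp_time`` seconds.  A reversal passes through zero speed with a
    short standstill of ``reversal_pause`` seconds centered on the ground-truth
    reversal event.  ``speed_noise_sd`` adds smooth, movement-gated speed
    fluctuations emulating human unsteadiness; the encoder quantizes the angle
    at ``encoder_resolution`` degrees.
    """

    target_speed: float = 400.0
    ramp_time: float = 0.25
    reversal_pause: float = 0.1
    rt_mean: dict = field(default_factory=lambda: dict(DEFAULT_RT_MEAN))
    rt_sd: dict = field(default_factory=lambda: dict(DEFAULT_RT_SD))
    encoder_resolution: float = 0.1
    sample_rate: float = DEFAULT_FS
    speed_noise_sd: float = 8.0
    noise_cutoff: float = 3.0

    def __post_init__(self) -> None:
        if self.target_speed <= 0:
            raise ConfigurationError("target_speed must be > 0")
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be > 0")
        if any(m <= 0 for m in self.rt_mean.values()) or any(
            s <= 0 for s in self.rt_sd.values()
        ):
            raise ConfigurationError("reaction-time means and SDs must be > 0")
        if self.ramp_time <= 0 or self.reversal_pause < 0:
            raise ConfigurationError("ramp_time must be > 0 and reversal_pause >= 0")


@dataclass
class EventGain:
    """Event-locked power modulation of one oscillation.

    ``gain`` is a power ratio relative to baseline (e.g. 0.5 for a -3 dB
    suppression), applied from ``onset`` to ``onset + duration`` seconds
    relative to the ground-truth event, with cosine on/off ramps of ``ramp``
    seconds.
    """

    gain: float
    onset: float = 0.0
    duration: float = 1.7
    ramp: float = 0.1

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ConfigurationError("gains must be > 0 (power ratios)")
        if self.duration <= 0:
            raise ConfigurationError("durations must be > 0")


@dataclass
class OscillationSpec:
    """One band-limited stochastic oscillation on a channel.

    The oscillation is a damped resonator (AR(2)) driven by white noise:
    ``band_center`` sets the resonance frequency and ``radius`` the pole
    radius (bandwidth ~ fs*(1-radius)/pi Hz).  ``baseline_power`` is the
    stationary variance of the component; ``envelope_events`` maps event types
    to :class:`EventGain` modulations.
    """

    band: str = "beta"
    band_center: float = 20.0
    radius: float = 0.97
    baseline_power: float = 1.0
    envelope_events: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.baseline_power <= 0:
            raise ConfigurationError("baseline_power must be > 0")
        if not 0 < self.radius < 1:
            raise ConfigurationError("resonator radius must lie in (0, 1)")


@dataclass
class ChannelSpec:
    """One synthetic channel: 1/f background plus oscillations.

    ``bg_psd_ref`` is the one-sided background power spectral density at
    ``bg_ref_freq`` Hz (units^2/Hz); the background falls off as
    f^-``bg_exponent``.
    """

    name: str
    oscillations: list = field(default_factory=list)
    bg_psd_ref: float = 0.02
    bg_ref_freq: float = 20.0
    bg_exponent: float = 1.5

    def __post_init__(self) -> None:
        if self.bg_psd_ref <= 0:
            raise ConfigurationError("background PSD must be > 0")


@dataclass
class CouplingSpec:
    """Directed, strictly lagged mixing of a band component between channels.

    The target receives ``strength`` times the source's band-limited component
    delayed by ``lag`` samples, so directed influence is source -> target by
    construction.  ``event_modulation`` maps ``(event_type, condition)`` to a
    multiplicative gain on the mixing coefficient around that event.
    """

    source: str = "M1_contra"
    target: str = "STN_contra"
    band: str = "beta"
    lag: int = 10
    strength: float = 0.4
    event_modulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise ConfigurationError("coupling lag must be >= 1 sample (strictly causal)")
        if self.strength < 0:
            raise ConfigurationError("coupling strength must be >= 0")


@dataclass
class EventDetectionConfig:
    """Thresholds for semi-automatic movement-event detection.

    An event requires the smoothed wheel speed to exceed
    ``amplitude_threshold`` (deg/s) continuously for ``duration_threshold``
    seconds.  Detected threshold crossings are back-projected to movement
    onset by walking to ``onset_floor`` deg/s, which keeps timing errors well
    below the smoothing window.
    """

    amplitude_threshold: float = 50.0
    duration_threshold: float = 0.3
    refractory: float = 0.5
    reversal_flank_window: float = 0.5
    onset_floor: float = 10.0
    smoothing_window: float = 0.05

    def __post_init__(self) -> None:
        for name in ("amplitude_threshold", "duration_threshold", "onset_floor",
                     "reversal_flank_window", "smoothing_window"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")


@dataclass
class TFRSpec:
    """Multitaper sliding-window time-frequency parameters.

    Two disjoint bands are analyzed with separate Slepian taper counts (the
    gap skips 50 Hz line noise).  With ``n_tapers = 2*NW - 1`` the spectral
    half-bandwidths are (4+1)/(2*0.8) = 3.125 Hz and (7+1)/(2*0.8) = 5 Hz.
    The 1.25 Hz grid step is the Rayleigh spacing of the 0.8 s window.
    """

    low_band: tuple[float, float] = (5.0, 45.0)
    n_tapers_low: int = 4
    high_band: tuple[float, float] = (55.0, 90.0)
    n_tapers_high: int = 7
    window: float = 0.8
    step: float = 0.05
    freq_step: float = 1.25
    analysis_span: tuple[float, float] = (-1.6, 1.6)
    baseline_window: tuple[float, float] = (-1.6, 0.0)

    def __post_init__(self) -> None:
        if self.window <= 0 or self.step <= 0 or self.step > self.window:
            raise ConfigurationError("need 0 < step <= window")
        if self.low_band[1] >= self.high_band[0]:
            raise ConfigurationError("low and high bands must be disjoint")
        if self.n_tapers_low < 1 or self.n_tapers_high < 1:
            raise ConfigurationError("taper counts must be >= 1")


@dataclass
class ClusterTestConfig:
    """Cluster-based permutation test parameters (group level).

    Bins with |t| above the two-sided critical value at
    ``cluster_forming_alpha`` are grouped by adjacency separately per sign;
    cluster mass (sum of t) is compared against the permutation null of the
    per-sign maximum, with the two-sided ``cluster_alpha`` split as 0.025 per
    tail.
    """

    cluster_forming_alpha: float = 0.05
    cluster_alpha: float = 0.05
    n_permutations: int = 1000
    adjacency: str = "4-neighbor"
    seed: int | None = None

    def __post_init__(self) -> None:
        for a in (self.cluster_forming_alpha, self.cluster_alpha):
            if not 0.0 < a < 1.0:
                raise ConfigurationError("alphas must lie in (0, 1)")
        if self.n_permutations < 100:
            raise ConfigurationError("n_permutations must be >= 100")
        if self.adjacency not in ("4-neighbor", "8-neighbor"):
            raise ConfigurationError("adjacency must be 4-neighbor or 8-neighbor")


@dataclass
class GrangerConfig:
    """Nonparametric spectral Granger-causality settings.

    Cross-spectra use the post-event window with +-``half_bandwidth`` Hz
    multitaper smoothing (15 tapers for a 2 s window at 4 Hz).  The Wilson
    spectral factorization iterates to a relative residual below ``tol``.
    """

    window: tuple[float, float] = (0.0, 2.0)
    half_bandwidth: float = 4.0
    tol: float = 1e-8
    max_iter: int = 100
    diag_loading: float = 1e-10

    def __post_init__(self) -> None:
        if self.window[1] <= self.window[0]:
            raise ConfigurationError("Granger window must have positive length")
        if self.tol <= 0 or self.max_iter < 1:
            raise ConfigurationError("need tol > 0 and max_iter >= 1")


@dataclass
class RunConfig:
    """Top-level configuration of a full analysis run."""

    seed: int = 0
    n_subjects: int = 20
    out_dir: str = "betawheel_out"
    stages: tuple[str, ...] = (
        "synthdata", "kinematics", "spectral", "clusterstats", "connectivity", "stats",
    )
    task_predictable: TaskConfig = field(
        default_factory=lambda: TaskConfig(condition="predictable"))
    task_unpredictable: TaskConfig = field(
        default_factory=lambda: TaskConfig(condition="unpredictable"))
    kinematics: KinematicsConfig = field(default_factory=KinematicsConfig)
    detection: EventDetectionConfig = field(default_factory=EventDetectionConfig)
    tfr: TFRSpec = field(default_factory=TFRSpec)
    cluster: ClusterTestConfig = field(default_factory=ClusterTestConfig)
    granger: GrangerConfig = field(default_factory=GrangerConfig)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        unknown = set(self.stages) - {
            "synthdata", "kinematics", "spectral", "clusterstats", "connectivity", "stats"}
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")


def _coerce(cls: type, value: Any) -> Any:
    """Recursively build dataclasses from plain dicts/lists (YAML output)."""
    if is_dataclass(cls) and isinstance(value, dict):
        kwargs = {}
        fmap = {f.name: f for f in fields(cls)}
        for key, val in value.items():
            if key not in fmap:
                raise ConfigurationError(f"unknown field {key!r} for {cls.__name__}")
            ftype = fmap[key].type
            target = _FIELD_CLASSES.get((cls.__name__, key))
            if target is not None and isinstance(val, dict):
                val = _coerce(target, val)
            elif isinstance(val, list):
                val = tuple(tuple(v) if isinstance(v, list) else v for v in val)
            elif isinstance(val, dict) and key in ("rt_mean", "rt_sd"):
                # YAML stores the (condition, event) keys as "condition:event"
                val = {tuple(k.split(":")) if isinstance(k, str) else k: v
                       for k, v in val.items()}
            kwargs[key] = val
        return cls(**kwargs)
    return value


_FIELD_CLASSES = {
    ("RunConfig", "task_predictable"): TaskConfig,
    ("RunConfig", "task_unpredictable"): TaskConfig,
    ("RunConfig", "kinematics"): KinematicsConfig,
    ("RunConfig", "detection"): EventDetectionConfig,
    ("RunConfig", "tfr"): TFRSpec,
    ("RunConfig", "cluster"): ClusterTestConfig,
    ("RunConfig", "granger"): GrangerConfig,
}


def load_config(path: str, cls: type = RunConfig):
    """Load a config dataclass from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return _coerce(cls, raw)


def save_config(cfg: Any, path: str) -> None:
    """Write a config dataclass to YAML."""

    def _plain(obj):
        if is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: _plain(getattr(obj, f.name)) for f in fields(obj)}
        if isinstance(obj, (list, tuple)):
            return [_plain(v) for v in obj]
        if isinstance(obj, dict):
            return {(":".join(map(str, k)) if isinstance(k, tuple) else k): _plain(v)
                    for k, v in obj.items()}
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(_plain(cfg), fh, sort_keys=False)
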