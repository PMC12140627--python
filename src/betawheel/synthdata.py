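"""Synthetic cohort generator for the wheel-turning paradigm.

Emulates a two-condition cued wheel-turning task: cue sequences (predictable
start/reverse/stop at fixed 4 s spacing vs. unpredictable reversal counts and
jittered inter-stimulus intervals), rotary-encoder kinematics (ramps, smooth
reversals through zero, halts, quantization, movement-gated speed noise) and
multi-channel neural recordings with known ground truth: 1/f background plus
stochastically driven damped-resonator oscillations whose amplitude envelopes
follow event-locked gains, and strictly lagged directed coupling between
channels.

Everything is reproducible from a single integer seed; per-subject and
per-stage random streams are spawned from :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import (
    DEFAULT_FS,
    ChannelSpec,
    ConfigurationError,
    CouplingSpec,
    EventGain,
    KinematicsConfig,
    OscillationSpec,
    TaskConfig,
)

logger = logging.getLogger(__name__)

EVENT_FOR_CUE = {"start": "start", "reverse": "reversal", "stop": "stop"}

#: canonical channel roles; physical sides are mapped to contra/ipsi by the
#: subject's moving hand
ROLES = ("STN_contra", "STN_ipsi", "M1_contra", "M1_ipsi", "MSMC_contra", "MSMC_ipsi")


def role_to_side(role: str, hand: str) -> str:
    """Physical channel label (area_L / area_R) for a contra/ipsi role."""
    area, lat = role.split("_")
    contra_side = "L" if hand == "right" else "R"
    side = contra_side if lat == "contra" else ("R" if contra_side == "L" else "L")
    return f"{area}_{side}"


def role_index(channel_names: list[str], hand: str) -> dict[str, int]:
    """Map contra/ipsi roles to channel indices of a side-labelled recording."""
    return {role: channel_names.index(role_to_side(role, hand)) for role in ROLES
            if role_to_side(role, hand) in channel_names}


# ---------------------------------------------------------------------------
# default phenomenology: event-locked gains (power ratios) per channel role
# ---------------------------------------------------------------------------

def _db(x: float) -> float:
    """Convert dB to a power ratio."""
    return 10.0 ** (x / 10.0)


def default_channel_specs(
    suppression_db: float = -3.0,
    rebound_db_contra: float = 2.5,
    rebound_db_ipsi: float = 1.0,
    reversal_db_cortex: float = -1.0,
    reversal_db_stn: float = 1.0,
    gamma_start_db: float = 1.5,
    gamma_stop_db: float = -1.0,
    beta_power: float = 1.0,
    gamma_power: float = 0.15,
    bg_psd_ref: float = 0.004,
) -> list[ChannelSpec]:
    """Study-default oscillation specs for the six channel roles.

    The defaults encode the qualitative phenomenology of the paradigm:
    bilateral beta suppression at movement start, a contralaterally dominant
    beta rebound after stop, brief reversal-related beta modulations
    (cortical decrease, subthalamic increase), and a contralateral
    subthalamic gamma increase at start.  The numeric modulation depths are
    free generator parameters; recovery tests compare estimates against these
    configured values, never against any published group statistic.
    """
    specs = []
    for role in ROLES:
        contra = role.endswith("_contra")
        area = role.split("_")[0]
        beta_env = {
            "start": EventGain(_db(suppression_db), onset=0.0, duration=1.7),
            "stop": EventGain(_db(rebound_db_contra if contra else rebound_db_ipsi),
                              onset=0.0, duration=1.7),
        }
        if area in ("M1", "MSMC"):
            beta_env["reversal"] = EventGain(_db(reversal_db_cortex), onset=0.0,
                                             duration=0.8)
        elif contra:
            beta_env["reversal"] = EventGain(_db(reversal_db_stn), onset=0.0,
                                             duration=0.5)
        oscs = [OscillationSpec(band="beta", band_center=20.0, radius=0.97,
                                baseline_power=beta_power, envelope_events=beta_env)]
        if role == "STN_contra":
            oscs.append(OscillationSpec(
                band="gamma", band_center=65.0, radius=0.95,
                baseline_power=gamma_power,
                envelope_events={
                    "start": EventGain(_db(gamma_start_db), onset=0.0, duration=0.8),
                    "stop": EventGain(_db(gamma_stop_db), onset=0.0, duration=0.8),
                }))
        specs.append(ChannelSpec(name=role, oscillations=oscs, bg_psd_ref=bg_psd_ref))
    return specs


def default_coupling_specs(strength: float = 0.35) -> list[CouplingSpec]:
    """Cortex -> STN beta coupling, stronger event-locked in the unpredictable
    condition (post-stop most of all), mirroring the coherence phenomenology."""
    mod = {
        ("start", "predictable"): 0.70,
        ("start", "unpredictable"): 0.85,
        ("stop", "predictable"): 1.20,
        ("stop", "unpredictable"): 1.45,
        ("reversal", "predictable"): 1.05,
        ("reversal", "unpredictable"): 1.20,
    }
    out = []
    for hemi in ("contra", "ipsi"):
        out.append(CouplingSpec(source=f"M1_{hemi}", target=f"STN_{hemi}",
                                band="beta", lag=10, strength=strength,
                                event_modulation=dict(mod)))
        out.append(CouplingSpec(source=f"MSMC_{hemi}", target=f"STN_{hemi}",
                                band="beta", lag=12, strength=0.6 * strength,
                                event_modulation=dict(mod)))
    return out


# ---------------------------------------------------------------------------
# task sequences
# ---------------------------------------------------------------------------

def generate_task_sequence(cfg: TaskConfig, rng: np.random.Generator | None = None,
                           t0: float | None = None) -> pd.DataFrame:
    """Generate the cue table for all blocks of one condition.

    Returns a DataFrame with columns ``block, trial, cue_type, direction,
    time_s, condition`` ordered by time.  ``cue_type`` is one of
    ``start/reverse/stop``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    counts = [int(k) for k, _ in cfg.reversal_counts]
    probs = [p for _, p in cfg.reversal_counts]

    def draw_isi() -> float:
        if rng.random() < cfg.isi_fixed_fraction:
            return cfg.isi_fixed
        return float(rng.uniform(*cfg.isi_range))

    rows = []
    t = cfg.lead_in if t0 is None else t0
    for block in range(cfg.n_blocks):
        for trial in range(cfg.n_trials_per_block):
            if cfg.condition == "predictable":
                n_rev = 1
                direction = 1  # always clockwise start
                isis = [cfg.isi_fixed] * (n_rev + 1)
            else:
                n_rev = int(rng.choice(counts, p=probs))
                direction = int(rng.choice([1, -1]))
                isis = [draw_isi() for _ in range(n_rev + 1)]
            rows.append((block, trial, "start", direction, t))
            d = direction
            for isi in isis[:-1]:
                t += isi
                d = -d
                rows.append((block, trial, "reverse", d, t))
            t += isis[-1]
            rows.append((block, trial, "stop", 0, t))
            t += cfg.pause_duration
    cues = pd.DataFrame(rows, columns=["block", "trial", "cue_type", "direction",
                                       "time_s"])
    cues["condition"] = cfg.condition
    cues.index.name = "cue_index"
    return cues


def generate_session(task_cfgs: list[TaskConfig],
                     rng: np.random.Generator | None = None,
                     block_gap: float = 10.0) -> pd.DataFrame:
    """Concatenate the cue tables of several conditions into one session.

    Blocks of the different conditions are appended in order with a
    ``block_gap`` second break between them; cue indices are renumbered
    globally.
    """
    if rng is None:
        rng = np.random.default_rng(task_cfgs[0].seed)
    parts = []
    t = task_cfgs[0].lead_in
    for cfg in task_cfgs:
        part = generate_task_sequence(cfg, rng=rng, t0=t)
        t = float(part["time_s"].iloc[-1]) + cfg.pause_duration + block_gap
        parts.append(part)
    cues = pd.concat(parts, ignore_index=True)
    cues.index.name = "cue_index"
    return cues


# ---------------------------------------------------------------------------
# wheel kinematics
# ---------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      upper: float | None = None, lower: float = 0.05,
                      max_tries: int = 1000) -> float:
    """Sample a reaction time, resampling outside (lower, upper)."""
    for _ in range(max_tries):
        x = float(rng.normal(mean, sd))
        if x > lower and (upper is None or x < upper):
            return x
    logger.warning("reaction-time resampling exhausted; clipping to bounds")
    return float(np.clip(mean, lower, upper if upper is not None else mean))


def generate_wheel_trace(cues: pd.DataFrame, kin: KinematicsConfig,
                         rng: np.random.Generator | None = None,
                         seed: int | None = None,
                         tail: float = 4.0):
    """Integrate a smooth speed profile into an encoder angle trace.

    For every cue a reaction time is drawn from a truncated normal with the
    condition- and event-specific mean/SD; movement onset, reversal turning
    point, and final halt occur at ``cue time + RT`` (the ground-truth event
    times).  Speed ramps linearly to ``+-target_speed``, reversals pass
    through zero with a standstill of ``reversal_pause`` centered on the
    event, and stops decay to zero.  The returned angle trace is quantized at
    the encoder resolution.

    Returns ``(angle, truth_events, n_samples)`` where ``truth_events`` is a
    DataFrame with ``event_type, time_s, sample, cue_index, condition,
    source='ground_truth'``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    fs = kin.sample_rate
    n = int(math.ceil((float(cues["time_s"].iloc[-1]) + tail) * fs))
    tgrid = np.arange(n) / fs

    anchors_t: list[float] = [0.0]
    anchors_v: list[float] = [0.0]
    truth_rows = []
    cue_times = cues["time_s"].to_numpy()
    for i, row in enumerate(cues.itertuples()):
        event = EVENT_FOR_CUE[row.cue_type]
        cond = row.condition
        next_gap = (cue_times[i + 1] - cue_times[i]) if i + 1 < len(cue_times) else None
        upper = None if next_gap is None else next_gap - kin.ramp_time - 0.2
        rt = _truncated_normal(rng, kin.rt_mean[(cond, event)],
                               kin.rt_sd[(cond, event)], upper=upper)
        te = row.time_s + rt
        v = kin.target_speed
        if event == "start":
            anchors_t += [te, te + kin.ramp_time]
            anchors_v += [0.0, v * row.direction]
        elif event == "reversal":
            half = kin.reversal_pause / 2.0
            prev_v = anchors_v[-1]
            anchors_t += [te - half - kin.ramp_time, te - half, te + half,
                          te + half + kin.ramp_time]
            anchors_v += [prev_v, 0.0, 0.0, v * row.direction]
        else:  # stop
            prev_v = anchors_v[-1]
            anchors_t += [te - kin.ramp_time, te]
            anchors_v += [prev_v, 0.0]
        truth_rows.append((event, te, int(round(te * fs)), i, cond))

    anchors_t.append(tgrid[-1] + 1.0)
    anchors_v.append(0.0)
    order = np.argsort(anchors_t, kind="stable")
    speed = np.interp(tgrid, np.asarray(anchors_t)[order], np.asarray(anchors_v)[order])

    if kin.speed_noise_sd > 0:
        b, a = sps.butter(2, kin.noise_cutoff / (fs / 2.0))
        raw = sps.lfilter(b, a, rng.standard_normal(n))
        raw *= kin.speed_noise_sd / max(raw.std(), 1e-12)
        # noise only while the hand moves: the finger is still otherwise
        gate = (np.abs(speed) > 1.0).astype(float)
        speed = speed + raw * gate

    angle = np.cumsum(speed) / fs
    if kin.encoder_resolution > 0:
        angle = np.round(angle / kin.encoder_resolution) * kin.encoder_resolution
    truth = pd.DataFrame(truth_rows, columns=["event_type", "time_s", "sample",
                                              "cue_index", "condition"])
    truth["source"] = "ground_truth"
    return angle, truth, n


# ---------------------------------------------------------------------------
# neural signal components
# ---------------------------------------------------------------------------

def ar2_coefficients(f0: float, radius: float, fs: float) -> tuple[float, float]:
    """AR(2) coefficients of a damped resonator at ``f0`` Hz."""
    a1 = 2.0 * radius * math.cos(2.0 * math.pi * f0 / fs)
    a2 = -(radius ** 2)
    return a1, a2


def ar2_stationary_variance(a1: float, a2: float, drive_var: float = 1.0) -> float:
    """Closed-form stationary variance of an AR(2) process."""
    return drive_var * (1 - a2) / ((1 + a2) * ((1 - a2) ** 2 - a1 ** 2))


def ar2_psd(freqs: np.ndarray, f0: float, radius: float, fs: float,
            variance: float) -> np.ndarray:
    """One-sided PSD (units^2/Hz) of the resonator scaled to ``variance``."""
    a1, a2 = ar2_coefficients(f0, radius, fs)
    drive = variance / ar2_stationary_variance(a1, a2)
    z = np.exp(-2j * np.pi * np.asarray(freqs, float) / fs)
    h = 1.0 / (1.0 - a1 * z - a2 * z * z)
    return 2.0 * drive / fs * np.abs(h) ** 2


def background_psd(freqs: np.ndarray, spec: ChannelSpec) -> np.ndarray:
    """One-sided PSD of the 1/f^alpha background of a channel."""
    f = np.asarray(freqs, float)
    out = np.zeros_like(f)
    pos = f > 0
    out[pos] = spec.bg_psd_ref * (f[pos] / spec.bg_ref_freq) ** (-spec.bg_exponent)
    return out


def _ar2_series(shape: tuple[int, ...], osc: OscillationSpec, fs: float,
                rng: np.random.Generator, burn: int = 1000) -> np.ndarray:
    """Stationary AR(2) oscillation, batched over leading axes."""
    a1, a2 = ar2_coefficients(osc.band_center, osc.radius, fs)
    drive_sd = math.sqrt(osc.baseline_power / ar2_stationary_variance(a1, a2))
    w = rng.standard_normal(shape[:-1] + (shape[-1] + burn,)) * drive_sd
    x = sps.lfilter([1.0], [1.0, -a1, -a2], w, axis=-1)
    return x[..., burn:]


def _background_series(shape: tuple[int, ...], spec: ChannelSpec, fs: float,
                       rng: np.random.Generator) -> np.ndarray:
    """1/f^alpha background noise via spectral shaping of white noise.

    The shaping gain is fixed analytically so the realized PSD matches
    :func:`background_psd` in expectation (no per-realization renormalizing).
    """
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    gain = np.zeros_like(freqs)
    pos = freqs > 0
    # PSD_x = |g|^2 * sigma_w^2 / fs (two-sided); want 2|g|^2/fs = background_psd
    gain[pos] = np.sqrt(background_psd(freqs, spec)[pos] * fs / 2.0)
    w = rng.standard_normal(shape)
    return np.fft.irfft(np.fft.rfft(w, axis=-1) * gain, n=n, axis=-1)


def modulation_envelope(tgrid: np.ndarray, events: pd.DataFrame,
                        envelope_events: dict, fs: float) -> np.ndarray:
    """Multiplicative amplitude envelope from event-locked power gains.

    Each :class:`EventGain` contributes a plateau of ``sqrt(gain)`` between
    ``onset`` and ``onset + duration`` (relative to its event) with raised-
    cosine transitions of ``ramp`` seconds.
    """
    env = np.ones_like(tgrid)
    if not len(events):
        return env
    for row in events.itertuples():
        gain_spec = envelope_events.get(row.event_type)
        if gain_spec is None:
            continue
        amp = math.sqrt(gain_spec.gain)
        t_on = row.time_s + gain_spec.onset
        t_off = t_on + gain_spec.duration
        w = _plateau(tgrid, t_on, t_off, gain_spec.ramp)
        env *= 1.0 + (amp - 1.0) * w
    return env


def _plateau(t: np.ndarray, t_on: float, t_off: float, ramp: float) -> np.ndarray:
    """0->1->0 window with raised-cosine edges of width ``ramp``."""
    w = np.zeros_like(t)
    if ramp <= 0:
        w[(t >= t_on) & (t < t_off)] = 1.0
        return w
    up = np.clip((t - t_on) / ramp, 0.0, 1.0)
    down = np.clip((t_off - t) / ramp, 0.0, 1.0)
    return (0.5 - 0.5 * np.cos(np.pi * up)) * (0.5 - 0.5 * np.cos(np.pi * down))


def mean_envelope_power(envelope_events: dict, event_type: str,
                        t_lo: float, t_hi: float, fs: float = DEFAULT_FS,
                        event_time: float = 0.0,
                        weights: np.ndarray | None = None) -> float:
    """Expected power multiplier of an oscillation averaged over a window.

    Truth-propagation helper: evaluates the squared amplitude envelope of a
    single event of ``event_type`` at ``event_time`` and averages it over
    ``[t_lo, t_hi)``.  ``weights`` (e.g. the mean squared taper profile of a
    multitaper estimate) turn the plain average into the effective temporal
    weighting of a windowed power estimate.
    """
    t = np.arange(t_lo, t_hi, 1.0 / fs)
    ev = pd.DataFrame({"event_type": [event_type], "time_s": [event_time]})
    env = modulation_envelope(t, ev, envelope_events, fs) ** 2
    if weights is None:
        return float(np.mean(env))
    w = np.asarray(weights, dtype=float)[: env.size]
    return float(np.sum(env[: w.size] * w) / np.sum(w))


# ---------------------------------------------------------------------------
# continuous recordings and cohorts
# ---------------------------------------------------------------------------

def generate_neural_data(cues: pd.DataFrame, events: pd.DataFrame,
                         channel_specs: list[ChannelSpec],
                         coupling_specs: list[CouplingSpec],
                         n_samples: int, fs: float,
                         rng: np.random.Generator | None = None,
                         seed: int | None = None):
    """Generate the multi-channel recording for one subject.

    Each channel is 1/f background plus its band-limited oscillations with
    event-locked amplitude envelopes.  Coupled targets additionally receive a
    lagged, scaled copy of the source's (enveloped) band component, optionally
    gated by event- and condition-dependent gains, so that directed influence
    is strictly source -> target.

    Returns ``(signals, channel_names)`` with ``signals`` of shape
    ``(n_channels, n_samples)``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if events["sample"].max() >= n_samples or events["sample"].min() < 0:
        raise ValueError("events must lie within the recording")
    names = [c.name for c in channel_specs]
    tgrid = np.arange(n_samples) / fs
    components: dict[tuple[str, str], np.ndarray] = {}
    signals = np.zeros((len(names), n_samples))
    for ci, cspec in enumerate(channel_specs):
        sig = _background_series((n_samples,), cspec, fs, rng)
        for osc in cspec.oscillations:
            env = modulation_envelope(tgrid, events, osc.envelope_events, fs)
            comp = _ar2_series((n_samples,), osc, fs, rng) * env
            components[(cspec.name, osc.band)] = comp
            sig = sig + comp
        signals[ci] = sig
    for coup in coupling_specs:
        key = (coup.source, coup.band)
        if key not in components or coup.target not in names:
            raise ConfigurationError(
                f"coupling references unknown channel/band {coup.source}/{coup.band}"
                f" -> {coup.target}")
        src = components[key]
        lagged = np.concatenate([np.zeros(coup.lag), src[:-coup.lag]])
        gate = np.ones(n_samples)
        if coup.event_modulation:
            gate = _coupling_gate(tgrid, events, coup.event_modulation)
        signals[names.index(coup.target)] += coup.strength * gate * lagged
    return signals, names


def _coupling_gate(tgrid: np.ndarray, events: pd.DataFrame,
                   event_modulation: dict) -> np.ndarray:
    """Multiplicative gain profile on a coupling coefficient."""
    gate = np.ones_like(tgrid)
    for row in events.itertuples():
        gain = event_modulation.get((row.event_type, row.condition))
        if gain is None:
            continue
        w = _plateau(tgrid, row.time_s, row.time_s + 2.0, 0.1)
        gate *= 1.0 + (gain - 1.0) * w
    return gate


@dataclass
class SubjectRecording:
    """One synthetic subject: signals, encoder trace, cue and truth tables."""

    subject_id: str
    signals: np.ndarray  # (channels, samples)
    channel_names: list[str]
    angle: np.ndarray  # (samples,)
    sample_rate: float
    cues: pd.DataFrame
    truth_events: pd.DataFrame
    hand: str  # 'left' or 'right'

    def __post_init__(self) -> None:
        if self.signals.shape[1] != self.angle.shape[0]:
            raise ValueError("all channel arrays must have the same length")
        cue_samples = (self.cues["time_s"].to_numpy() * self.sample_rate)
        if not np.all(np.diff(cue_samples) > 0):
            raise ValueError("cue samples must be strictly increasing")


@dataclass
class CohortRecording:
    """A list of synthetic subjects plus the generating parameters."""

    subjects: list[SubjectRecording]
    sample_rate: float
    params: dict = field(default_factory=dict)


def simulate_subject(subject_id: str,
                     task_cfgs: list[TaskConfig],
                     kin: KinematicsConfig,
                     channel_specs: list[ChannelSpec],
                     coupling_specs: list[CouplingSpec],
                     rng: np.random.Generator) -> SubjectRecording:
    """Simulate one subject's full session (all conditions)."""
    hand = "right" if rng.random() < 0.5 else "left"
    cues = generate_session(task_cfgs, rng=rng)
    angle, truth, n = generate_wheel_trace(cues, kin, rng=rng)
    signals, names = generate_neural_data(cues, truth, channel_specs,
                                          coupling_specs, n, kin.sample_rate,
                                          rng=rng)
    # label channels by physical side; contra/ipsi is re-derived from the hand
    names = [role_to_side(r, hand) if r in ROLES else r for r in names]
    return SubjectRecording(subject_id=subject_id, signals=signals,
                            channel_names=names, angle=angle,
                            sample_rate=kin.sample_rate, cues=cues,
                            truth_events=truth, hand=hand)


def simulate_cohort(n_subjects: int = 20,
                    task_cfgs: list[TaskConfig] | None = None,
                    kin: KinematicsConfig | None = None,
                    channel_specs: list[ChannelSpec] | None = None,
                    coupling_specs: list[CouplingSpec] | None = None,
                    seed: int = 0) -> CohortRecording:
    """Simulate a cohort with per-subject independent random streams."""
    if task_cfgs is None:
        task_cfgs = [TaskConfig(condition="predictable"),
                     TaskConfig(condition="unpredictable")]
    kin = kin or KinematicsConfig()
    channel_specs = channel_specs if channel_specs is not None else default_channel_specs()
    coupling_specs = (coupling_specs if coupling_specs is not None
                      else default_coupling_specs())
    seeds = np.random.SeedSequence(seed).spawn(n_subjects)
    subjects = []
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        subjects.append(simulate_subject(f"sub-{i:02d}", task_cfgs, kin,
                                         channel_specs, coupling_specs, rng))
    return CohortRecording(subjects=subjects, sample_rate=kin.sample_rate,
                           params={"seed": seed, "n_subjects": n_subjects})


# ---------------------------------------------------------------------------
# fast event-locked epoch simulator (for Monte-Carlo suites)
# ---------------------------------------------------------------------------

def simulate_epochs(n_trials: int,
                    channel_specs: list[ChannelSpec],
                    coupling_specs: list[CouplingSpec] | None = None,
                    event_type: str = "start",
                    condition: str = "predictable",
                    span: float = 4.0,
                    fs: float = DEFAULT_FS,
                    rng: np.random.Generator | None = None,
                    seed: int | None = None):
    """Simulate event-locked epochs directly (event at t=0, span +-span/2).

    Equivalent to epoching the continuous generator around well-separated
    events, but batched over trials for speed.  Returns ``(data, names)``
    with ``data`` of shape ``(n_trials, n_channels, n_samples)``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    coupling_specs = coupling_specs or []
    n = int(round(span * fs))
    tgrid = (np.arange(n) - n // 2) / fs
    ev = pd.DataFrame({"event_type": [event_type], "time_s": [0.0],
                       "condition": [condition]})
    names = [c.name for c in channel_specs]
    data = np.zeros((n_trials, len(names), n))
    components: dict[tuple[str, str], np.ndarray] = {}
    for ci, cspec in enumerate(channel_specs):
        sig = _background_series((n_trials, n), cspec, fs, rng)
        for osc in cspec.oscillations:
            env = modulation_envelope(tgrid, ev, osc.envelope_events, fs)
            comp = _ar2_series((n_trials, n), osc, fs, rng) * env
            components[(cspec.name, osc.band)] = comp
            sig = sig + comp
        data[:, ci] = sig
    for coup in coupling_specs:
        key = (coup.source, coup.band)
        if key not in components or coup.target not in names:
            raise ConfigurationError(
                f"coupling references unknown channel/band {coup.source}/{coup.band}")
        src = components[key]
        lagged = np.concatenate([np.zeros((n_trials, coup.lag)),
                                 src[:, :-coup.lag]], axis=1)
        gate = _coupling_gate(tgrid, ev, coup.event_modulation)
        data[:, names.index(coup.target)] += coup.strength * gate * lagged
    return data, names


def analytic_coherence(freq: float, coupling: CouplingSpec,
                       source_spec: ChannelSpec, target_spec: ChannelSpec,
                       fs: float = DEFAULT_FS, gate: float = 1.0) -> float:
    """Analytic coherence of the shared-signal model at one frequency.

    For ``y = c * x_lagged + n`` with the coupled band component as shared
    signal:  coh = c*So / sqrt((So + Bx) * (c^2*So + Sy_own + By)) where So is
    the source oscillation PSD and B the background PSDs, Sy_own the target's
    own oscillation PSD at ``freq``.
    """
    f = np.array([freq])

    def osc_psd(spec: ChannelSpec, band: str) -> float:
        tot = 0.0
        for osc in spec.oscillations:
            if band is None or osc.band == band:
                tot += float(ar2_psd(f, osc.band_center, osc.radius, fs,
                                     osc.baseline_power)[0])
        return tot

    c = coupling.strength * gate
    so = osc_psd(source_spec, coupling.band)
    sx_total = osc_psd(source_spec, None) + float(background_psd(f, source_spec)[0])
    sy_total = (c ** 2) * so + float(background_psd(f, target_spec)[0]) \
        + osc_psd(target_spec, None)
    return c * so / math.sqrt(sx_total * sy_total)
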