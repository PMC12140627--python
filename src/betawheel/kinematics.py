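"""Wheel kinematics: speed traces, movement-event detection, epoching, and
behavioral summaries.

Time convention: seconds relative to the aligning event, event at 0; sample
indices are 0-based; windows are half-open ``[t0, t1)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import EventDetectionConfig
from .synthdata import EVENT_FOR_CUE

logger = logging.getLogger(__name__)


@dataclass
class SpeedTrace:
    """Angular speed in deg/s on the encoder clock."""

    values: np.ndarray
    sample_rate: float
    smoothing_window: float


@dataclass
class EpochSet:
    """Event-locked trials: ``data`` is (trials, channels, time)."""

    data: np.ndarray
    times: np.ndarray
    sample_rate: float
    alignment: str  # 'movement' or 'cue'
    event_type: str | None
    metadata: pd.DataFrame
    channel_names: list[str] | None = None

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def angular_speed(angle: np.ndarray, sample_rate: float,
                  smoothing_window: float = 0.05) -> SpeedTrace:
    """First temporal derivative of the rotation angle, smoothed.

    Central finite differences scaled to deg/s, then moving-average smoothed
    over ``smoothing_window`` seconds.  The sign encodes turning direction.
    """
    angle = np.asarray(angle, dtype=float)
    if angle.size < 2:
        raise ValueError("angle trace must have at least 2 samples")
    bad = np.flatnonzero(~np.isfinite(angle))
    if bad.size:
        raise ValueError(f"non-finite angle sample at index {bad[0]}")
    speed = np.gradient(angle) * sample_rate
    w = max(1, int(round(smoothing_window * sample_rate)))
    if w > 1:
        speed = ndimage.uniform_filter1d(speed, size=w, mode="nearest")
    return SpeedTrace(values=speed, sample_rate=sample_rate,
                      smoothing_window=smoothing_window)


def _first_sustained_run(mask: np.ndarray, min_len: int) -> int | None:
    """Index of the first True run of at least ``min_len`` samples."""
    if not mask.any():
        return None
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    starts, ends = idx[::2], idx[1::2]
    for s, e in zip(starts, ends):
        if e - s >= min_len:
            return int(s)
    return None


def _walk_back_to_floor(speed: np.ndarray, start: int, lo: int, floor: float) -> int:
    j = start
    while j > lo and abs(speed[j - 1]) > floor:
        j -= 1
    return j


def _walk_forward_to_floor(speed: np.ndarray, start: int, hi: int, floor: float) -> int:
    j = start
    while j < hi - 1 and abs(speed[j]) > floor:
        j += 1
    return j


def detect_events(speed: SpeedTrace, cues: pd.DataFrame,
                  cfg: EventDetectionConfig | None = None) -> pd.DataFrame:
    """Detect movement start, reversal, and stop from the speed trace.

    Each cue defines a search window up to the next cue.  A *start* is the
    first sustained supra-threshold excursion, back-projected to movement
    onset (the last sub-floor sample).  A *stop* is the first sustained
    sub-threshold run after supra-threshold movement, projected forward to
    standstill.  A *reversal* is the zero crossing flanked by supra-threshold
    speed of opposite signs within the flank window; the event is placed at
    the midpoint of the sub-floor standstill.  Events that violate the cue
    ordering are dropped with a logged reason (a deterministic stand-in for
    manual correction).
    """
    if cues is None or not len(cues):
        raise ValueError("a cue table is required for event detection")
    v = speed.values
    if v.size == 0:
        raise ValueError("empty speed trace")
    cfg = cfg or EventDetectionConfig()
    fs = speed.sample_rate
    dur = int(round(cfg.duration_threshold * fs))
    flank = int(round(cfg.reversal_flank_window * fs))
    cue_samples = np.round(cues["time_s"].to_numpy() * fs).astype(int)
    rows = []
    for i, row in enumerate(cues.itertuples()):
        lo = cue_samples[i]
        hi = cue_samples[i + 1] if i + 1 < len(cue_samples) else v.size
        lo = max(0, min(lo, v.size))
        hi = max(lo, min(hi, v.size))
        if hi - lo < 2:
            continue
        seg = v[lo:hi]
        ev = EVENT_FOR_CUE[row.cue_type]
        sample = None
        if ev == "start":
            s = _first_sustained_run(np.abs(seg) > cfg.amplitude_threshold, dur)
            if s is not None:
                sample = _walk_back_to_floor(v, lo + s, lo, cfg.onset_floor)
        elif ev == "stop":
            above = np.abs(seg) > cfg.amplitude_threshold
            # first falling edge followed by a sustained sub-threshold run
            edges = np.flatnonzero(above[:-1] & ~above[1:]) + 1
            for e in edges:
                run_end = min(e + dur, seg.size)
                if not above[e:run_end].any() and run_end - e >= min(dur, seg.size - e):
                    sample = _walk_forward_to_floor(v, lo + e, hi, cfg.onset_floor)
                    break
        else:  # reversal
            sample = _detect_reversal(v, lo, hi, cfg, flank)
        if sample is not None:
            rows.append((ev, int(sample), float(sample / fs), i,
                         row.condition, "detected"))
    events = pd.DataFrame(rows, columns=["event_type", "sample", "time_s",
                                         "cue_index", "condition", "source"])
    # ordering-based rejection: within the cue order, event samples must be
    # strictly increasing (each start precedes its reversals and stop)
    keep = np.ones(len(events), dtype=bool)
    last = -1
    for j, s in enumerate(events["sample"].to_numpy()):
        if s <= last:
            keep[j] = False
            logger.warning("dropping out-of-order %s event at sample %d",
                           events["event_type"].iloc[j], s)
        else:
            last = s
    return events.loc[keep].reset_index(drop=True)


def _detect_reversal(v: np.ndarray, lo: int, hi: int,
                     cfg: EventDetectionConfig, flank: int) -> int | None:
    """Zero crossing flanked by opposite-sign supra-threshold speed."""
    seg = v[lo:hi]
    sign_changes = np.flatnonzero(np.signbit(seg[:-1]) != np.signbit(seg[1:]))
    for k in sign_changes:
        a0 = max(0, k - flank)
        b1 = min(seg.size, k + 1 + flank)
        before = seg[a0:k + 1]
        after = seg[k + 1:b1]
        if before.size == 0 or after.size == 0:
            continue
        pre_sign = np.sign(before[np.argmax(np.abs(before))])
        if (np.any(pre_sign * before > cfg.amplitude_threshold)
                and np.any(-pre_sign * after > cfg.amplitude_threshold)):
            # midpoint of the sub-floor standstill around the crossing
            a = lo + k
            while a > lo and abs(v[a - 1]) <= cfg.onset_floor:
                a -= 1
            b = lo + k
            while b < hi - 1 and abs(v[b + 1]) <= cfg.onset_floor:
                b += 1
            return (a + b) // 2
    return None


def epoch(signals: np.ndarray, events: pd.DataFrame, span: float = 4.0,
          alignment: str = "movement", sample_rate: float = 500.0,
          event_type: str | None = None, condition: str | None = None,
          cues: pd.DataFrame | None = None,
          channel_names: list[str] | None = None) -> EpochSet:
    """Cut event-locked trials of ``span`` seconds out of a recording.

    ``alignment='movement'`` centers on the event samples,
    ``alignment='cue'`` on the linked cue times (requires ``cues``).
    Out-of-bounds trials are excluded with the count logged.
    """
    sig = np.atleast_2d(np.asarray(signals))
    n = sig.shape[1]
    sel = events
    if event_type is not None:
        sel = sel[sel["event_type"] == event_type]
    if condition is not None:
        sel = sel[sel["condition"] == condition]
    if alignment == "movement":
        anchors = sel["sample"].to_numpy()
    elif alignment == "cue":
        if cues is None:
            raise ValueError("cue alignment requires the cue table")
        anchors = np.round(
            cues["time_s"].to_numpy()[sel["cue_index"].to_numpy()] * sample_rate
        ).astype(int)
    else:
        raise ValueError("alignment must be 'movement' or 'cue'")
    half = int(round(span * sample_rate / 2.0))
    w = 2 * half
    starts = anchors - half
    ok = (starts >= 0) & (starts + w <= n)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("excluded %d trials overlapping the recording edge", n_excluded)
    starts = starts[ok]
    if starts.size == 0:
        raise ValueError("zero usable trials after edge exclusion")
    data = np.stack([sig[:, s:s + w] for s in starts])
    times = (np.arange(w) - half) / sample_rate
    meta = sel.loc[ok].reset_index(drop=True)
    meta["n_excluded"] = n_excluded
    return EpochSet(data=data, times=times, sample_rate=sample_rate,
                    alignment=alignment, event_type=event_type, metadata=meta,
                    channel_names=channel_names)


def reaction_times(events: pd.DataFrame, cues: pd.DataFrame):
    """Reaction time per event: event time minus linked cue time.

    Negative RTs (event preceding its cue) are flagged and excluded.  Returns
    ``(rt_table, summary)`` where summary holds mean and SD per
    condition x event type.
    """
    if events["cue_index"].isna().any():
        raise ValueError("every event must be linked to a cue")
    cue_times = cues["time_s"].to_numpy()
    rt = events.copy()
    rt["rt"] = rt["time_s"].to_numpy() - cue_times[rt["cue_index"].to_numpy()]
    flagged = int((rt["rt"] < 0).sum())
    if flagged:
        logger.warning("excluding %d events preceding their cue", flagged)
    rt = rt[rt["rt"] >= 0].reset_index(drop=True)
    rt.attrs["n_flagged"] = flagged
    summary = (rt.groupby(["condition", "event_type"])["rt"]
               .agg(["mean", "std", "count"]).reset_index())
    summary.attrs["n_flagged"] = flagged
    return rt, summary


def aligned_speed_average(speed: SpeedTrace, events: pd.DataFrame,
                          span: float = 4.0, alignment: str = "movement",
                          event_type: str | None = None,
                          cues: pd.DataFrame | None = None):
    """Trial-average speed time course around events (or cues)."""
    eps = epoch(speed.values, events, span=span, alignment=alignment,
                sample_rate=speed.sample_rate, event_type=event_type, cues=cues)
    return eps.times, eps.data[:, 0, :].mean(axis=0)
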