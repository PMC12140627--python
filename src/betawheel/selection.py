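"""Data-driven selection of the analyzed LFP channel and cortical grid points.

The subthalamic channel is the bipolar derivation with the strongest combined
beta suppression (at movement start) and beta rebound (after stop); cortical
candidate grid points are ranked by the absolute post-minus-pre beta contrast
averaged over subjects and the three event types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import EpochSet
from .spectral import band_power


def bipolar_montage(contacts: np.ndarray, labels: list[str],
                    pairs: list[tuple[str, str]]):
    """Re-reference contacts to bipolar channels (differences of pairs).

    Works on (contacts, samples) or (trials, contacts, samples) arrays.
    Returns ``(derived, pair_labels)``.
    """
    contacts = np.asarray(contacts)
    if contacts.shape[-2] < 2:
        raise ValueError("need at least 2 contacts")
    index = {lab: k for k, lab in enumerate(labels)}
    out = []
    names = []
    for a, b in pairs:
        if a not in index or b not in index:
            raise ValueError(f"unknown contact in pair ({a}, {b})")
        out.append(contacts[..., index[a], :] - contacts[..., index[b], :])
        names.append(f"{a}-{b}")
    return np.stack(out, axis=-2), names


@dataclass
class SelectionScore:
    candidate: str
    suppression: float  # dB, start post-pre (expected <= 0)
    rebound: float  # dB, stop post-pre (expected >= 0)

    @property
    def combined(self) -> float:
        return abs(self.suppression) + abs(self.rebound)


def _contrast_db(epochs: EpochSet, channel: int,
                 pre: tuple[float, float] = (-2.0, 0.0),
                 post: tuple[float, float] = (0.0, 2.0),
                 band="beta") -> float:
    """Post-minus-pre beta power contrast (dB) from window-averaged spectra."""
    p_pre = band_power(epochs, pre, band=band, channel=channel)
    p_post = band_power(epochs, post, band=band, channel=channel)
    return 10.0 * np.log10(p_post / p_pre)


def select_lfp_channel(candidates: list[str], start_epochs: EpochSet,
                       stop_epochs: EpochSet):
    """Pick the bipolar channel with the strongest suppression plus rebound.

    Scores each candidate by |start modulation| + |stop modulation| of beta
    power (post 0-2 s vs pre -2-0 s); ties break deterministically by label
    order.  Returns ``(winner_label, scores_table)``.
    """
    if not candidates:
        raise ValueError("no candidate channels")
    if start_epochs.n_trials == 0 or stop_epochs.n_trials == 0:
        raise ValueError("no epochs for selection")
    scores = []
    for k, name in enumerate(candidates):
        scores.append(SelectionScore(
            candidate=name,
            suppression=_contrast_db(start_epochs, k),
            rebound=_contrast_db(stop_epochs, k),
        ))
    best = max(range(len(scores)),
               key=lambda k: (scores[k].combined, -k))  # first label wins ties
    table = pd.DataFrame([{
        "candidate": s.candidate, "suppression_db": s.suppression,
        "rebound_db": s.rebound, "combined": s.combined,
        "selected": i == best,
    } for i, s in enumerate(scores)])
    return candidates[best], table


def select_roi(modulations: np.ndarray, grid: np.ndarray | None = None,
               n_neighbors: int = 6):
    """Pick the grid point with the strongest absolute beta contrast.

    ``modulations`` is (candidates, subjects, events) of post-minus-pre band
    contrasts; the score is the absolute value averaged over subjects and
    events.  If grid coordinates (candidates, ndim) are given, the peak's
    ``n_neighbors`` nearest grid points are returned as the ROI neighborhood.

    Returns ``(peak_index, roi_indices, scores)``.
    """
    m = np.asarray(modulations, dtype=float)
    if m.ndim == 2:
        m = m[:, :, None]
    if m.ndim != 3:
        raise ValueError("modulations must be (candidates, subjects[, events])")
    scores = np.abs(m).mean(axis=(1, 2))
    peak = int(np.argmax(scores))
    roi = np.array([peak])
    if grid is not None:
        grid = np.asarray(grid, dtype=float)
        if grid.shape[0] != m.shape[0]:
            raise ValueError("grid does not match the candidate set")
        d = np.linalg.norm(grid - grid[peak], axis=1)
        roi = np.argsort(d, kind="stable")[: n_neighbors + 1]
    return peak, roi, scores
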