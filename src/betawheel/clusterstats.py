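"""Cluster-based permutation testing of time-frequency maps across subjects.

A one-sample t statistic is computed per (frequency, time) bin across
subjects; bins exceeding the two-sided critical value at the cluster-forming
alpha are grouped by grid adjacency separately per sign, and the cluster mass
(sum of t values) is compared against the permutation distribution of the
per-sign maximum mass under random per-subject sign flips.  The two-sided
cluster alpha is split across tails (0.025 per tail); the observed statistic
is included in the permutation distribution, so p >= 1/(n_permutations + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .config import ClusterTestConfig

_ADJACENCY = {
    "4-neighbor": np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]),
    "8-neighbor": np.ones((3, 3), dtype=int),
}


@dataclass
class Cluster:
    bins: np.ndarray  # boolean mask on the (freq, time) grid
    t_sum: float
    sign: int
    p_value: float


@dataclass
class ClusterResult:
    clusters: list
    t_map: np.ndarray
    sig_mask: np.ndarray
    freqs: np.ndarray | None = None
    times: np.ndarray | None = None
    config: ClusterTestConfig | None = None


def baseline_contrast_maps(subject_maps: list[np.ndarray]) -> np.ndarray:
    """Stack per-subject baseline-corrected maps into (subjects, freq, time).

    Under the null of no modulation every bin of a corrected map has zero
    expectation, which is what the sign-flip permutation scheme assumes.
    """
    if len(subject_maps) < 2:
        raise ValueError("need at least 2 subjects (t undefined for one)")
    shapes = {np.asarray(m).shape for m in subject_maps}
    if len(shapes) != 1:
        raise ValueError(f"mismatched map grids: {sorted(shapes)}")
    return np.stack([np.asarray(m, dtype=float) for m in subject_maps])


def _t_stat(stack: np.ndarray) -> np.ndarray:
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    return mean / (sd / np.sqrt(n) + np.finfo(float).tiny)


def _cluster_sums(t: np.ndarray, thr: float, structure: np.ndarray):
    """Connected supra-threshold clusters per sign: (labels, sums, signs)."""
    out = []
    for sign in (1, -1):
        mask = (sign * t) > thr
        labels, n = ndimage.label(mask, structure=structure)
        if n:
            sums = ndimage.sum_labels(t, labels, index=np.arange(1, n + 1))
            for k in range(n):
                out.append((labels == k + 1, float(sums[k]), sign))
    return out


def cluster_permutation_test(stack: np.ndarray,
                             cfg: ClusterTestConfig | None = None,
                             freqs: np.ndarray | None = None,
                             times: np.ndarray | None = None,
                             rng: np.random.Generator | None = None) -> ClusterResult:
    """Group-level cluster permutation test of a (subjects, freq, time) stack.

    Returns every supra-threshold cluster with its mass and permutation p
    value; ``sig_mask`` marks bins of clusters significant at
    ``cluster_alpha/2`` per tail.  No supra-threshold bins is a valid result
    with an empty cluster list.
    """
    cfg = cfg or ClusterTestConfig()
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (subjects, freq, time)")
    n = stack.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    thr = stats.t.ppf(1.0 - cfg.cluster_forming_alpha / 2.0, df=n - 1)
    structure = _ADJACENCY[cfg.adjacency]

    t_obs = _t_stat(stack)
    observed = _cluster_sums(t_obs, thr, structure)

    # permutation null of the per-sign maximum cluster mass; sign-flip t can
    # be computed from flipped means alone because sum of squares is invariant
    flat = stack.reshape(n, -1)
    sumsq = (flat ** 2).sum(axis=0)
    shape = stack.shape[1:]
    max_pos = np.zeros(cfg.n_permutations)
    max_neg = np.zeros(cfg.n_permutations)
    chunk = max(1, min(cfg.n_permutations, 20_000_000 // max(flat.size, 1)))
    done = 0
    while done < cfg.n_permutations:
        m = min(chunk, cfg.n_permutations - done)
        signs = rng.choice([-1.0, 1.0], size=(m, n))
        means = (signs @ flat) / n
        var = (sumsq[None, :] - n * means ** 2) / (n - 1)
        t_perm = means / (np.sqrt(var / n) + np.finfo(float).tiny)
        for i in range(m):
            sums = _cluster_sums(t_perm[i].reshape(shape), thr, structure)
            pos = [s for _, s, sign in sums if sign > 0]
            neg = [s for _, s, sign in sums if sign < 0]
            max_pos[done + i] = max(pos) if pos else 0.0
            max_neg[done + i] = -min(neg) if neg else 0.0
        done += m

    clusters = []
    sig_mask = np.zeros(shape, dtype=bool)
    tail_alpha = cfg.cluster_alpha / 2.0
    for bins, t_sum, sign in observed:
        null = max_pos if sign > 0 else max_neg
        # observed statistic included in the permutation distribution
        p = (1.0 + np.sum(null >= abs(t_sum))) / (cfg.n_permutations + 1.0)
        clusters.append(Cluster(bins=bins, t_sum=t_sum, sign=sign, p_value=float(p)))
        if p <= tail_alpha:
            sig_mask |= bins
    clusters.sort(key=lambda c: abs(c.t_sum), reverse=True)
    return ClusterResult(clusters=clusters, t_map=t_obs, sig_mask=sig_mask,
                         freqs=freqs, times=times, config=cfg)


def report_clusters(result: ClusterResult, **meta) -> pd.DataFrame:
    """Tabulate clusters: sign, mass, p, and frequency/time extents."""
    rows = []
    for c in result.clusters:
        fidx, tidx = np.nonzero(c.bins)
        row = dict(meta)
        row.update({
            "sign": "pos" if c.sign > 0 else "neg",
            "t_sum": c.t_sum,
            "p_value": c.p_value,
            "significant": c.p_value <= (result.config.cluster_alpha / 2.0
                                         if result.config else 0.025),
            "n_bins": int(c.bins.sum()),
        })
        if result.freqs is not None:
            row["freq_lo"] = float(result.freqs[fidx.min()])
            row["freq_hi"] = float(result.freqs[fidx.max()])
        if result.times is not None:
            row["time_lo"] = float(result.times[tidx.min()])
            row["time_hi"] = float(result.times[tidx.max()])
        rows.append(row)
    columns = list(meta.keys()) + ["sign", "t_sum", "p_value", "significant",
                                   "n_bins"]
    if result.freqs is not None:
        columns += ["freq_lo", "freq_hi"]
    if result.times is not None:
        columns += ["time_lo", "time_hi"]
    return pd.DataFrame(rows, columns=columns)
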