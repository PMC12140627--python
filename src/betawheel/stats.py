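"""Behavioral and band-summary inference.

Paired t tests with one-sided p values and paired Cohen's d (d = t / sqrt(n)),
partial eta squared from F and its degrees of freedom, univariate repeated-
measures ANOVA (via pingouin), and the hemispheric lateralization index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats


@dataclass
class PairedTestResult:
    t: float
    df: int
    p_one_sided: float
    p_two_sided: float
    d: float
    n: int
    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float


@dataclass
class RmAnovaResult:
    """Per-effect F, degrees of freedom, p, and partial eta squared."""

    effects: pd.DataFrame  # columns: effect, F, df_effect, df_error, p, eta_p_sq


def paired_t(x, y, sided: str = "two") -> PairedTestResult:
    """Paired t test on x - y with effect size.

    ``p_one_sided`` is the t-distribution tail beyond the observed statistic
    in its own direction; ``d`` is the paired Cohen's d, mean(diff)/SD(diff),
    identical to t/sqrt(n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D paired samples")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of differences; t undefined")
    t = diff.mean() / (sd / math.sqrt(n))
    df = n - 1
    p_two = 2.0 * sstats.t.sf(abs(t), df)
    p_one = sstats.t.sf(abs(t), df)
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    return PairedTestResult(t=float(t), df=df, p_one_sided=float(p_one),
                            p_two_sided=float(p_two), d=float(t / math.sqrt(n)),
                            n=n, mean_x=float(x.mean()), mean_y=float(y.mean()),
                            sd_x=float(x.std(ddof=1)), sd_y=float(y.std(ddof=1)))


def cohen_d_from_t(t: float, n: int) -> float:
    """Paired-sample Cohen's d from the t statistic: d = t / sqrt(n)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return t / math.sqrt(n)


def partial_eta_squared(F: float, df_effect: int, df_error: int) -> float:
    """Partial eta squared: F*df_effect / (F*df_effect + df_error)."""
    if F < 0:
        raise ValueError("F must be >= 0")
    if df_effect < 1 or df_error < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return F * df_effect / (F * df_effect + df_error)


def one_sided_p_from_t(t: float, df: int) -> float:
    """One-sided p of a t statistic (tail beyond |t|)."""
    return float(sstats.t.sf(abs(t), df))


def rm_anova(data, dv: str = "value", within=("condition", "movement"),
             subject: str = "subject") -> RmAnovaResult:
    """Univariate one- or two-way repeated-measures ANOVA.

    ``data`` is either a long DataFrame or a (subject x levelsA x levelsB)
    array.  The design must be complete and balanced.  Partial eta squared is
    recomputed from F and the degrees of freedom for every effect.
    """
    import pingouin as pg

    if isinstance(data, np.ndarray):
        if data.ndim == 2:
            data = data[:, :, None]
        ns, na, nb = data.shape
        idx = pd.MultiIndex.from_product(
            [range(ns), [f"a{i}" for i in range(na)], [f"b{j}" for j in range(nb)]],
            names=[subject, within[0], within[1] if len(within) > 1 else "_b"])
        data = pd.DataFrame({dv: data.ravel()}, index=idx).reset_index()
        within = list(within[:1]) + ([within[1]] if len(within) > 1 and nb > 1 else [])
        if nb == 1:
            data = data.drop(columns=["_b"] if "_b" in data else [])
    within = [w for w in within if w in data.columns]
    counts = data.groupby([subject] + within, observed=True)[dv].count()
    n_cells = int(np.prod([data[w].nunique() for w in within]))
    per_subject = counts.groupby(level=0).count()
    if (counts.min() < 1 or counts.nunique() != 1
            or (per_subject != n_cells).any()):
        raise ValueError("design must be complete and balanced (missing cells)")
    aov = pg.rm_anova(data=data, dv=dv, within=within if len(within) > 1 else within[0],
                      subject=subject, detailed=True)
    rows = []
    if "ddof1" in aov.columns:  # two-way layout
        for _, r in aov.iterrows():
            F = float(r["F"])
            df1, df2 = int(r["ddof1"]), int(r["ddof2"])
            rows.append({
                "effect": r["Source"], "F": F, "df_effect": df1,
                "df_error": df2, "p": float(r["p_unc"]),
                "eta_p_sq": partial_eta_squared(F, df1, df2),
            })
    else:  # one-way layout: Error stratum carries the error df
        df2 = int(aov.loc[aov["Source"] == "Error", "DF"].iloc[0])
        for _, r in aov[aov["Source"] != "Error"].iterrows():
            F = float(r["F"])
            df1 = int(r["DF"])
            rows.append({
                "effect": r["Source"], "F": F, "df_effect": df1,
                "df_error": df2, "p": float(r["p_unc"]),
                "eta_p_sq": partial_eta_squared(F, df1, df2),
            })
    return RmAnovaResult(effects=pd.DataFrame(rows))


def lateralization_index(contra, ipsi):
    """Lateralization of modulation magnitude across hemispheres.

    LI = (|contra| - |ipsi|) / (|contra| + |ipsi|): 0 means bilateral,
    positive means contralateral-dominant.  Works on scalars or arrays;
    undefined entries (both magnitudes zero) are returned as NaN.
    """
    c = np.abs(np.asarray(contra, dtype=float))
    i = np.abs(np.asarray(ipsi, dtype=float))
    denom = c + i
    with np.errstate(invalid="ignore", divide="ignore"):
        li = np.where(denom > 0, (c - i) / np.where(denom > 0, denom, 1.0), np.nan)
    if np.isscalar(contra) or (np.ndim(contra) == 0 and np.ndim(ipsi) == 0):
        return float(li) if not np.isnan(li) else float("nan")
    return li


def round_half_away(x: float, decimals: int = 3) -> float:
    """Round half away from zero (the convention used for printed statistics)."""
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor
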