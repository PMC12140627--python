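"""End-to-end orchestration of the wheel-turning analysis.

``run_full_analysis`` generates (or loads) a cohort, detects movement events
from the encoder trace, epochs the neural channels, computes multitaper
power/coherence maps and band modulations, runs group cluster permutation
tests, estimates time-reversed Granger contrasts, and performs the behavioral
and band-summary statistics.  All artifacts (event tables, RT summaries,
cluster and Granger tables, a machine-readable summary) are written as CSV
and JSON; all randomness flows from the single top-level seed.
"""

from __future__ import annotations

import json
import logging
import os
import numpy as np
import pandas as pd

from . import clusterstats, connectivity, io, kinematics, spectral, stats, synthdata
from .config import ClusterTestConfig, RunConfig
from .synthdata import ROLES, role_index

logger = logging.getLogger(__name__)

AREAS = ("STN", "M1", "MSMC")
EVENTS = ("start", "reversal", "stop")
CONDITIONS = ("predictable", "unpredictable")
PAIRS = (("M1_contra", "STN_contra"), ("MSMC_contra", "STN_contra"),
         ("M1_ipsi", "STN_ipsi"), ("MSMC_ipsi", "STN_ipsi"))


def _subject_events(sub, det_cfg):
    speed = kinematics.angular_speed(sub.angle, sub.sample_rate,
                                     det_cfg.smoothing_window)
    events = kinematics.detect_events(speed, sub.cues, det_cfg)
    return speed, events


def run_full_analysis(cfg: RunConfig, out_dir: str | None = None,
                      cohort: synthdata.CohortRecording | None = None) -> dict:
    """Run the configured stages and return the report bundle as a dict.

    The returned dict contains DataFrames (event tables, RT and modulation
    summaries, cluster and Granger tables) and a JSON-serializable
    ``summary``.  When ``out_dir`` is given all artifacts are also written to
    disk.
    """
    out_dir = out_dir or cfg.out_dir
    os.makedirs(out_dir, exist_ok=True)
    report: dict = {"config_seed": cfg.seed}
    ss = np.random.SeedSequence(cfg.seed)
    stage_seeds = {name: s for name, s in zip(
        ("synthdata", "cluster"), ss.spawn(2))}

    if cohort is None:
        logger.info("stage synthdata: simulating %d subjects", cfg.n_subjects)
        cohort = synthdata.simulate_cohort(
            n_subjects=cfg.n_subjects,
            task_cfgs=[cfg.task_predictable, cfg.task_unpredictable],
            kin=cfg.kinematics,
            seed=int(stage_seeds["synthdata"].generate_state(1)[0] % (2 ** 31)))
        if "synthdata" in cfg.stages and out_dir:
            io.save_cohort(cohort, os.path.join(out_dir, "cohort"))
    report["n_subjects"] = len(cohort.subjects)
    if set(cfg.stages) == {"synthdata"}:
        _write_summary(report, out_dir)
        return report

    # ------------------------------------------------------------------ events
    logger.info("stage kinematics: event detection and reaction times")
    speeds, all_events, rt_tables = {}, {}, []
    for sub in cohort.subjects:
        speed, events = _subject_events(sub, cfg.detection)
        speeds[sub.subject_id] = speed
        all_events[sub.subject_id] = events
        rt, _ = kinematics.reaction_times(events, sub.cues)
        rt["subject"] = sub.subject_id
        rt_tables.append(rt)
    rt_all = pd.concat(rt_tables, ignore_index=True)
    rt_subject = (rt_all.groupby(["subject", "condition", "event_type"])["rt"]
                  .mean().reset_index())
    report["rt_summary"] = (rt_all.groupby(["condition", "event_type"])["rt"]
                            .agg(["mean", "std", "count"]).reset_index())
    events_out = pd.concat(
        [t.assign(subject=s) for s, t in all_events.items()], ignore_index=True)
    report["events"] = events_out
    if out_dir:
        events_out.to_csv(os.path.join(out_dir, "events.csv"), index=False)
        report["rt_summary"].to_csv(os.path.join(out_dir, "rt_summary.csv"),
                                    index=False)

    if "kinematics" in cfg.stages and set(cfg.stages) <= {"synthdata", "kinematics"}:
        _write_summary(report, out_dir)
        return report

    # ------------------------------------------------------- spectral analysis
    logger.info("stage spectral: multitaper power, coherence, band modulations")
    tfr = cfg.tfr
    power_maps: dict = {}  # (subject, role, event) -> dB map
    coh_maps: dict = {}  # (subject, pair, event, condition) -> corrected map
    mod_rows = []
    for sub in cohort.subjects:
        roles = role_index(sub.channel_names, sub.hand)
        events = all_events[sub.subject_id]
        for event_type in EVENTS:
            try:
                eps = kinematics.epoch(sub.signals, events, span=4.0,
                                       sample_rate=sub.sample_rate,
                                       event_type=event_type,
                                       channel_names=sub.channel_names)
            except ValueError:
                logger.warning("no usable %s trials for %s", event_type,
                               sub.subject_id)
                continue
            coeffs = spectral.mtm_fourier(eps, tfr, bands=("low",))
            for role, ch in roles.items():
                raw = spectral.power_tfr(coeffs, "low", channel=ch)
                corr = spectral.baseline_correct(raw, tfr.baseline_window)
                power_maps[(sub.subject_id, role, event_type)] = corr
            for src_role, dst_role in PAIRS:
                if src_role not in roles or dst_role not in roles:
                    continue
                coh = spectral.coherence_tfr(coeffs, (roles[src_role],
                                                      roles[dst_role]))
                corr = spectral.baseline_correct(coh, tfr.baseline_window,
                                                 mode="subtract")
                coh_maps[(sub.subject_id, (src_role, dst_role), event_type,
                          "pooled")] = corr
            # per-condition band modulations for the predictability contrasts
            for condition in CONDITIONS:
                sel = eps.metadata["condition"] == condition
                if sel.sum() < 2:
                    continue
                sub_eps = kinematics.EpochSet(
                    data=eps.data[sel.to_numpy()], times=eps.times,
                    sample_rate=eps.sample_rate, alignment=eps.alignment,
                    event_type=event_type, metadata=eps.metadata[sel],
                    channel_names=eps.channel_names)
                ccoeffs = spectral.mtm_fourier(sub_eps, tfr, bands=("low",))
                for role, ch in roles.items():
                    raw = spectral.power_tfr(ccoeffs, "low", channel=ch)
                    corr = spectral.baseline_correct(raw, tfr.baseline_window)
                    bm = spectral.band_modulation(corr, "beta")
                    mod_rows.append({
                        "subject": sub.subject_id, "area": role,
                        "event": event_type, "condition": condition,
                        "pre": bm.pre, "post": bm.post,
                        "modulation": bm.modulation,
                    })
    modulations = pd.DataFrame(mod_rows)
    report["band_modulations"] = modulations
    if out_dir and len(modulations):
        modulations.to_csv(os.path.join(out_dir, "band_modulations.csv"),
                           index=False)

    # ------------------------------------------------------ cluster statistics
    cluster_tables = []
    if "clusterstats" in cfg.stages and len(cohort.subjects) >= 2:
        logger.info("stage clusterstats: group permutation tests")
        cl_seed = int(stage_seeds["cluster"].generate_state(1)[0] % (2 ** 31))
        for role in ROLES:
            for event_type in EVENTS:
                maps = [power_maps[k] for k in power_maps
                        if k[1] == role and k[2] == event_type]
                if len(maps) < 2:
                    continue
                stack = clusterstats.baseline_contrast_maps([m.values for m in maps])
                ccfg = ClusterTestConfig(
                    n_permutations=cfg.cluster.n_permutations,
                    adjacency=cfg.cluster.adjacency,
                    cluster_forming_alpha=cfg.cluster.cluster_forming_alpha,
                    cluster_alpha=cfg.cluster.cluster_alpha,
                    seed=cl_seed)
                res = clusterstats.cluster_permutation_test(
                    stack, ccfg, freqs=maps[0].freqs, times=maps[0].times)
                cluster_tables.append(clusterstats.report_clusters(
                    res, area=role, event=event_type, measure="power"))
        clusters = (pd.concat(cluster_tables, ignore_index=True)
                    if cluster_tables else pd.DataFrame())
        report["clusters"] = clusters
        if out_dir:
            clusters.to_csv(os.path.join(out_dir, "clusters.csv"), index=False)

    # ----------------------------------------------------------------- Granger
    if "connectivity" in cfg.stages:
        logger.info("stage connectivity: time-reversed Granger causality")
        granger_rows = []
        for sub in cohort.subjects:
            roles = role_index(sub.channel_names, sub.hand)
            events = all_events[sub.subject_id]
            for event_type in EVENTS:
                try:
                    eps = kinematics.epoch(sub.signals, events, span=4.0,
                                           sample_rate=sub.sample_rate,
                                           event_type=event_type,
                                           channel_names=sub.channel_names)
                except ValueError:
                    continue
                for src_role, dst_role in PAIRS:
                    if src_role not in roles or dst_role not in roles:
                        continue
                    contrast = connectivity.time_reversal_contrast(
                        eps, (roles[src_role], roles[dst_role]),
                        cfg.granger, bands=("beta",))
                    t = contrast.table.copy()
                    t["subject"] = sub.subject_id
                    t["event"] = event_type
                    t["pair"] = f"{src_role}->{dst_role}"
                    granger_rows.append(t)
        granger = (pd.concat(granger_rows, ignore_index=True)
                   if granger_rows else pd.DataFrame())
        report["granger"] = granger
        if out_dir and len(granger):
            granger.to_csv(os.path.join(out_dir, "granger.csv"), index=False)

    # -------------------------------------------------------------- statistics
    summary: dict = {"seed": cfg.seed, "n_subjects": len(cohort.subjects)}
    if "stats" in cfg.stages:
        logger.info("stage stats: behavioral and band-summary inference")
        summary["reaction_times"] = _rt_stats(rt_subject)
        if len(modulations):
            summary["lateralization"] = _lateralization(modulations)
            summary["predictability"] = _predictability(modulations)
        if "granger" in report and len(report["granger"]):
            summary["granger"] = _granger_stats(report["granger"])
    if "clusters" in report and len(report["clusters"]):
        sig = report["clusters"][report["clusters"]["significant"]]
        summary["n_significant_clusters"] = int(len(sig))
    report["summary"] = summary
    _write_summary(report, out_dir)
    return report


def _rt_stats(rt_subject: pd.DataFrame) -> dict:
    """Condition contrasts and rmANOVA on per-subject mean reaction times."""
    out: dict = {"means": {}}
    for (cond, ev), grp in rt_subject.groupby(["condition", "event_type"]):
        out["means"][f"{cond}_{ev}"] = float(grp["rt"].mean())
    wide = rt_subject.pivot_table(index="subject", columns=["condition", "event_type"],
                                  values="rt")
    for ev in ("start", "stop"):
        try:
            x = wide[("predictable", ev)].to_numpy()
            y = wide[("unpredictable", ev)].to_numpy()
            res = stats.paired_t(x, y)
            out[f"paired_t_{ev}"] = {"t": res.t, "df": res.df,
                                     "p_one_sided": res.p_one_sided, "d": res.d}
        except (KeyError, ValueError):
            continue
    try:
        aov = stats.rm_anova(rt_subject.rename(columns={"rt": "value",
                                                        "event_type": "movement"}),
                             dv="value", within=("condition", "movement"),
                             subject="subject")
        out["rm_anova"] = aov.effects.to_dict(orient="records")
    except Exception as exc:  # degenerate small designs
        logger.warning("rmANOVA skipped: %s", exc)
    return out


def _lateralization(modulations: pd.DataFrame) -> dict:
    """Mean LI per area for suppression (start) and rebound (stop)."""
    out = {}
    pooled = (modulations.groupby(["subject", "area", "event"])["modulation"]
              .mean().reset_index())
    for area in AREAS:
        for event, label in (("start", "suppression"), ("stop", "rebound")):
            sel = pooled[pooled["event"] == event]
            contra = sel[sel["area"] == f"{area}_contra"].set_index("subject")
            ipsi = sel[sel["area"] == f"{area}_ipsi"].set_index("subject")
            common = contra.index.intersection(ipsi.index)
            if len(common) == 0:
                continue
            li = stats.lateralization_index(
                contra.loc[common, "modulation"].to_numpy(),
                ipsi.loc[common, "modulation"].to_numpy())
            li = li[np.isfinite(li)]
            if li.size:
                out[f"{area}_{label}"] = float(np.mean(li))
    return out


def _predictability(modulations: pd.DataFrame) -> dict:
    """Predictable vs unpredictable contrast of beta modulations."""
    out = {}
    wide = modulations.pivot_table(index="subject", columns="condition",
                                   values="modulation", aggfunc="mean")
    if {"predictable", "unpredictable"} <= set(wide.columns) and len(wide) >= 2:
        try:
            res = stats.paired_t(wide["predictable"].to_numpy(),
                                 wide["unpredictable"].to_numpy())
            out["paired_t_modulation"] = {"t": res.t, "df": res.df,
                                          "p_one_sided": res.p_one_sided,
                                          "d": res.d}
        except ValueError:
            pass
    return out


def _granger_stats(granger: pd.DataFrame) -> dict:
    """Group test of the time-reversal delta per pair and direction."""
    out = {}
    beta = granger[granger["band"] == "beta"]
    per_subject = (beta.groupby(["subject", "source", "target"])["delta"]
                   .mean().reset_index())
    for (src, dst), grp in per_subject.groupby(["source", "target"]):
        d = grp["delta"].to_numpy()
        entry = {"mean_delta": float(d.mean()), "n": int(d.size)}
        if d.size >= 2 and d.std(ddof=1) > 0:
            res = stats.paired_t(d, np.zeros_like(d))
            entry.update({"t": res.t, "p_one_sided": res.p_one_sided})
        out[f"{src}->{dst}"] = entry
    return out


def _write_summary(report: dict, out_dir: str | None) -> None:
    if not out_dir:
        return
    summary = report.get("summary", {k: v for k, v in report.items()
                                     if isinstance(v, (int, float, str))})
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)


def validate_against_truth(cohort: synthdata.CohortRecording,
                           report: dict,
                           rt_tolerance_sem: float = 3.0) -> pd.DataFrame:
    """Compare recovered quantities against the generator's ground truth.

    Produces a table of configured vs estimated values (reaction-time means,
    event-timing errors, Granger direction) with a pass flag at the declared
    tolerance.  Requires the cohort's stored truth tables.
    """
    rows = []
    from .config import DEFAULT_RT_MEAN

    if "rt_summary" not in report:
        raise ValueError("report carries no recovered quantities")
    rt = report["rt_summary"]
    for _, r in rt.iterrows():
        key = (r["condition"], r["event_type"])
        if key not in DEFAULT_RT_MEAN:
            continue
        sem = r["std"] / np.sqrt(max(r["count"], 1))
        err = abs(r["mean"] - DEFAULT_RT_MEAN[key])
        rows.append({"quantity": f"rt_mean_{key[0]}_{key[1]}",
                     "configured": DEFAULT_RT_MEAN[key],
                     "estimated": float(r["mean"]),
                     "tolerance": rt_tolerance_sem * sem,
                     "pass": bool(err <= rt_tolerance_sem * sem)})
    if "events" in report:
        detected = report["events"]
        errors = []
        for sub in cohort.subjects:
            truth = sub.truth_events
            det = detected[detected["subject"] == sub.subject_id]
            merged = truth.merge(det, on=["cue_index", "event_type"],
                                 suffixes=("_true", "_det"), how="inner")
            errors.append((merged["time_s_det"] - merged["time_s_true"]).to_numpy())
        if errors:
            err = np.abs(np.concatenate(errors))
            rows.append({"quantity": "event_timing_abs_error_s",
                         "configured": 0.0,
                         "estimated": float(err.mean()) if err.size else np.nan,
                         "tolerance": 0.020,
                         "pass": bool(err.size and err.mean() <= 0.020)})
    if "granger" in report and len(report["granger"]):
        beta = report["granger"][report["granger"]["band"] == "beta"]
        fwd = beta[beta["source"].str.startswith(("M1", "MSMC"))]
        mean_delta = float(fwd["delta"].mean())
        rows.append({"quantity": "granger_cortex_to_stn_delta",
                     "configured": 0.0, "estimated": mean_delta,
                     "tolerance": 0.0, "pass": bool(mean_delta > 0)})
    return pd.DataFrame(rows)
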