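"""On-disk formats: HDF5 for arrays, CSV side-cars for tables, YAML for config.

A cohort is stored as a directory bundle: ``cohort.h5`` holds the per-subject
signal and encoder arrays (one group per subject, with ``sample_rate``,
``hand`` and channel names as attributes) while cue and ground-truth event
tables live next to it as plain CSV files.
"""

from __future__ import annotations

import json
import os

import h5py
import numpy as np
import pandas as pd

from .synthdata import CohortRecording, SubjectRecording


def save_cohort(cohort: CohortRecording, out_dir: str, dtype=np.float32) -> str:
    """Write a cohort bundle; returns the path to the HDF5 container."""
    os.makedirs(out_dir, exist_ok=True)
    h5path = os.path.join(out_dir, "cohort.h5")
    with h5py.File(h5path, "w") as fh:
        fh.attrs["sample_rate"] = cohort.sample_rate
        fh.attrs["n_subjects"] = len(cohort.subjects)
        for sub in cohort.subjects:
            g = fh.create_group(sub.subject_id)
            g.create_dataset("signals", data=sub.signals.astype(dtype),
                             compression="gzip", compression_opts=1)
            g.create_dataset("angle", data=sub.angle.astype(dtype),
                             compression="gzip", compression_opts=1)
            g.attrs["sample_rate"] = sub.sample_rate
            g.attrs["hand"] = sub.hand
            g.attrs["channel_names"] = json.dumps(sub.channel_names)
            sub.cues.to_csv(os.path.join(out_dir, f"{sub.subject_id}_cues.csv"),
                            index_label="cue_index")
            sub.truth_events.to_csv(
                os.path.join(out_dir, f"{sub.subject_id}_events.csv"), index=False)
    meta = pd.DataFrame([{"subject_id": s.subject_id, "hand": s.hand}
                         for s in cohort.subjects])
    meta.to_csv(os.path.join(out_dir, "subjects.csv"), index=False)
    return h5path


def load_cohort(out_dir: str) -> CohortRecording:
    """Read a cohort bundle written by :func:`save_cohort`."""
    h5path = os.path.join(out_dir, "cohort.h5")
    subjects = []
    with h5py.File(h5path, "r") as fh:
        fs = float(fh.attrs["sample_rate"])
        for sid in sorted(fh.keys()):
            g = fh[sid]
            cues = pd.read_csv(os.path.join(out_dir, f"{sid}_cues.csv"),
                               index_col="cue_index")
            events = pd.read_csv(os.path.join(out_dir, f"{sid}_events.csv"))
            subjects.append(SubjectRecording(
                subject_id=sid,
                signals=np.asarray(g["signals"], dtype=float),
                channel_names=json.loads(g.attrs["channel_names"]),
                angle=np.asarray(g["angle"], dtype=float),
                sample_rate=float(g.attrs["sample_rate"]),
                cues=cues,
                truth_events=events,
                hand=str(g.attrs["hand"]),
            ))
    return CohortRecording(subjects=subjects, sample_rate=fs)


def save_tfr(tfr, path: str) -> None:
    """Store a time-frequency map as HDF5 (values + axes + metadata attrs)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("values", data=tfr.values)
        fh.create_dataset("freqs", data=tfr.freqs)
        fh.create_dataset("times", data=tfr.times)
        fh.attrs["kind"] = tfr.kind
        if tfr.baseline is not None:
            fh.attrs["baseline"] = list(tfr.baseline)


def load_tfr(path: str):
    from .spectral import TimeFrequencyMap

    with h5py.File(path, "r") as fh:
        baseline = tuple(fh.attrs["baseline"]) if "baseline" in fh.attrs else None
        return TimeFrequencyMap(values=np.asarray(fh["values"]),
                                freqs=np.asarray(fh["freqs"]),
                                times=np.asarray(fh["times"]),
                                kind=str(fh.attrs["kind"]), baseline=baseline)
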