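"""Delimited-text and array-container I/O for pipeline artifacts.

Timecourses, metadata, label sequences and results tables are tab-
delimited text with header rows; windowed-FNC arrays use a portable
``.npz`` container with a JSON sidecar carrying offsets, penalty, subject
and condition so any language can interpret them.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ComponentTimecourse, NuisanceSet, StateSequence, WindowedFNC
from .simulate import Cohort

SEP = "\t"


def write_timecourse(tc: ComponentTimecourse, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(tc.data, columns=tc.component_names)
    df.to_csv(path, sep=SEP, index=False, float_format="%.10g")
    return path


def read_timecourse(
    path: str | Path,
    tr_seconds: float = 2.0,
    run_condition: str = "rest_pre",
    subject_id: str = "",
) -> ComponentTimecourse:
    df = pd.read_csv(path, sep=SEP)
    return ComponentTimecourse(
        data=df.to_numpy(dtype=float),
        tr_seconds=tr_seconds,
        run_condition=run_condition,
        subject_id=subject_id,
        component_names=list(df.columns),
    )


def read_nuisance(path: str | Path) -> NuisanceSet:
    df = pd.read_csv(path, sep=SEP)
    return NuisanceSet(regressors=df.to_numpy(dtype=float), labels=list(df.columns))


def timecourse_filename(subject_id: str, condition: str) -> str:
    return f"{subject_id}_{condition}_timecourse.tsv"


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """One timecourse matrix per run, a metadata table, and a ground-truth bundle."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for subject in cohort.subjects:
        for cond, tc in subject.runs.items():
            write_timecourse(tc, out_dir / timecourse_filename(subject.subject_id, cond))
    cohort.metadata().to_csv(out_dir / "cohort_metadata.tsv", sep=SEP, index=False)
    truth = {
        "designated_state": cohort.config.designated_state,
        "effect_size": cohort.config.effect_size,
        "n_states": cohort.config.n_states,
        "tr_seconds": cohort.config.tr_seconds,
        "subjects": {
            s.subject_id: {
                "effect_size": s.truth.effect_size,
                "state_sequences": {
                    cond: seq.tolist() for cond, seq in s.truth.state_sequences.items()
                },
            }
            for s in cohort.subjects
        },
    }
    (out_dir / "cohort_truth.json").write_text(json.dumps(truth))
    return out_dir


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=SEP)


def write_wfnc(wfnc: WindowedFNC, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{wfnc.subject_id}_{wfnc.condition}_fnc"
    np.savez(out_dir / f"{stem}.npz", z=wfnc.z, offsets=wfnc.offsets)
    sidecar = {
        "subject_id": wfnc.subject_id,
        "condition": wfnc.condition,
        "lambda_used": wfnc.lambda_used,
        "width": wfnc.width,
        "sigma": wfnc.sigma,
        "n_windows": int(wfnc.n_windows),
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
    return out_dir / f"{stem}.npz"


def read_wfnc(npz_path: str | Path) -> WindowedFNC:
    npz_path = Path(npz_path)
    sidecar = json.loads(npz_path.with_suffix(".json").read_text())
    arrays = np.load(npz_path)
    return WindowedFNC(
        z=arrays["z"],
        offsets=arrays["offsets"],
        lambda_used=sidecar["lambda_used"],
        subject_id=sidecar["subject_id"],
        condition=sidecar["condition"],
        width=sidecar["width"],
        sigma=sidecar["sigma"],
    )


def write_sequences(sequences: list[StateSequence], path: str | Path) -> Path:
    rows = []
    for seq in sequences:
        for w, label in enumerate(seq.labels):
            rows.append(
                {
                    "subject_id": seq.subject_id,
                    "condition": seq.condition,
                    "window_index": w,
                    "state": int(label),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep=SEP, index=False)
    return Path(path)


def read_sequences(path: str | Path) -> list[StateSequence]:
    df = pd.read_csv(path, sep=SEP)
    out = []
    for (subject, condition), grp in df.groupby(["subject_id", "condition"], sort=False):
        grp = grp.sort_values("window_index")
        out.append(
            StateSequence(
                labels=grp["state"].to_numpy(), subject_id=subject, condition=condition
            )
        )
    return out


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    df.to_csv(path, sep=SEP, index=False, float_format="%.10g")
    return Path(path)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=SEP)
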