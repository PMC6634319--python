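"""Tidy-CSV interchange formats for schedules, samples, reports and traces.

These plain-text tables are the import/export contract of the pipeline:
``schedule.csv`` (one row per trial), ``samples.csv`` (one row per eye
sample), ``reports.csv`` (one row per probe), ``behaviour.csv`` (one row
per trial) and ``clean.csv`` (one row per 20 Hz grid point).  Floats are
written with a fixed format so identical inputs round-trip byte-identically.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .behaviour import BehaviouralLog
from .design import CueWord, SessionSchedule, TrialSpec, VERTICAL
from .preprocess import CleanSession
from .pupil import RawPupilRecording
from .states import ProbeReport

FLOAT_FMT = "%.6f"

_VAL_SHORT = {"neutral": "neu", "positive": "pos", "negative": "neg"}
_VAL_LONG = {v: k for k, v in _VAL_SHORT.items()}


def schedule_frame(schedule: SessionSchedule) -> pd.DataFrame:
    probe_set = set(schedule.probe_after)
    rows = []
    for t in schedule.trials:
        rows.append(
            {
                "subject_id": schedule.subject_id,
                "trial_index": t.index,
                "stimulus": "V" if t.stimulus == VERTICAL else "H",
                "word_id": t.cue.word_id if t.cue else "NA",
                "word_text": t.cue.text if t.cue else "NA",
                "valence": _VAL_SHORT[t.cue.valence] if t.cue else "NA",
                "probe_after": int(t.index in probe_set),
            }
        )
    return pd.DataFrame(rows)


def frame_to_schedule(df: pd.DataFrame) -> SessionSchedule:
    df = df.sort_values("trial_index")
    trials = []
    probes = []
    for row in df.itertuples(index=False):
        cue = None
        if row.word_id != "NA":
            cue = CueWord(
                word_id=str(row.word_id),
                text=str(row.word_text),
                valence=_VAL_LONG[str(row.valence)],
            )
        trials.append(
            TrialSpec(
                index=int(row.trial_index),
                stimulus=VERTICAL if row.stimulus == "V" else "horizontal",
                cue=cue,
            )
        )
        if int(row.probe_after):
            probes.append(int(row.trial_index))
    return SessionSchedule(
        subject_id=str(df["subject_id"].iloc[0]), trials=trials, probe_after=probes
    )


def samples_frame(rec: RawPupilRecording) -> pd.DataFrame:
    frames = []
    n_trials = rec.n_trials
    spt = len(rec.times)
    trial_idx = np.repeat(np.arange(n_trials), spt)
    t_s = np.tile(rec.times, n_trials)
    for eye in rec.eyes:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": rec.subject_id,
                    "trial_index": trial_idx,
                    "t_s": t_s,
                    "eye": eye,
                    "diameter_mm": rec.diameter[eye].ravel(),
                    "valid": rec.valid[eye].ravel().astype(int),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def frame_to_recording(df: pd.DataFrame) -> RawPupilRecording:
    df = df.sort_values(["eye", "trial_index", "t_s"])
    eyes = sorted(df["eye"].unique())
    n_trials = int(df["trial_index"].max()) + 1
    first = df[df["eye"] == eyes[0]]
    spt = len(first) // n_trials
    times = first["t_s"].to_numpy()[:spt]
    rec = RawPupilRecording(subject_id=str(df["subject_id"].iloc[0]), times=times)
    for eye in eyes:
        sub = df[df["eye"] == eye]
        rec.diameter[eye] = sub["diameter_mm"].to_numpy().reshape(n_trials, spt)
        rec.valid[eye] = sub["valid"].to_numpy().astype(bool).reshape(n_trials, spt)
    return rec


def reports_frame(subject_id: str, reports: Sequence[ProbeReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": subject_id,
                "probe_index": r.probe_index,
                "category": r.category,
                "spontaneity": r.spontaneity,
                "trigger_type": r.trigger_type,
                "trigger_word_id": r.trigger_word_id or "NA",
            }
            for r in reports
        ]
    )


def frame_to_reports(df: pd.DataFrame) -> list[ProbeReport]:
    return [
        ProbeReport(
            probe_index=int(r.probe_index),
            category=str(r.category),
            spontaneity=str(r.spontaneity),
            trigger_type=str(r.trigger_type),
            trigger_word_id=None if r.trigger_word_id == "NA" else str(r.trigger_word_id),
        )
        for r in df.sort_values("probe_index").itertuples(index=False)
    ]


def behaviour_frame(log: BehaviouralLog) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": log.subject_id,
            "trial_index": np.arange(len(log.key_press)),
            "key_press": log.key_press.astype(int),
        }
    )


def clean_frame(clean: CleanSession) -> pd.DataFrame:
    n_trials, n_grid = clean.traces.shape
    return pd.DataFrame(
        {
            "subject_id": clean.subject_id,
            "trial_index": np.repeat(np.arange(n_trials), n_grid),
            "grid_index": np.tile(np.arange(n_grid), n_trials),
            "t_s": np.tile(clean.times, n_trials),
            "diameter_mm": clean.traces.ravel(),
            "excluded": np.repeat(clean.excluded.astype(int), n_grid),
        }
    )


def frame_to_clean(df: pd.DataFrame) -> CleanSession:
    df = df.sort_values(["trial_index", "grid_index"])
    n_trials = int(df["trial_index"].max()) + 1
    n_grid = int(df["grid_index"].max()) + 1
    traces = df["diameter_mm"].to_numpy().reshape(n_trials, n_grid)
    excluded = df["excluded"].to_numpy().reshape(n_trials, n_grid)[:, 0].astype(bool)
    # loss fractions are not carried by clean.csv; excluded is the decision
    loss = np.where(excluded, 1.0, 0.0)
    return CleanSession(
        subject_id=str(df["subject_id"].iloc[0]),
        traces=traces,
        excluded=excluded,
        loss_fraction=loss,
    )


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FMT, lineterminator="\n")
    return path
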