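"""Cohort-level generation: many subjects from one master seed.

All subjects share the fixed trial schedule (the published task used one
fixed sequence for everyone); attentional states, pupil noise, artifacts and
behaviour are drawn from per-subject streams derived deterministically from
the master seed, so a cohort is fully reproducible from (n_subjects, seed,
parameter set).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .behaviour import BehaviouralLog, BehaviourParams, generate_behaviour
from .design import DesignParams, SessionSchedule, generate_schedule
from .pupil import PupilGenParams, RawPupilRecording, generate_pupil_recording
from .states import LatentStateTrace, ProbeReport, StateParams, generate_latent_states


@dataclass
class SubjectData:
    schedule: SessionSchedule
    latent: LatentStateTrace
    reports: list[ProbeReport]
    recording: RawPupilRecording
    behaviour: BehaviouralLog


@dataclass
class Cohort:
    seed: int
    subjects: dict[str, SubjectData] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.subjects)

    def to_dir(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the four tidy CSV tables for the whole cohort."""
        out = Path(out_dir)
        tables = {
            "schedule": pd.concat(
                [io.schedule_frame(s.schedule) for s in self.subjects.values()],
                ignore_index=True,
            ),
            "samples": pd.concat(
                [io.samples_frame(s.recording) for s in self.subjects.values()],
                ignore_index=True,
            ),
            "reports": pd.concat(
                [
                    io.reports_frame(sid, s.reports)
                    for sid, s in self.subjects.items()
                ],
                ignore_index=True,
            ),
            "behaviour": pd.concat(
                [io.behaviour_frame(s.behaviour) for s in self.subjects.values()],
                ignore_index=True,
            ),
        }
        return {
            name: io.write_csv(df, out / f"{name}.csv") for name, df in tables.items()
        }


def subject_seed(master_seed: int, subject_index: int, stream: int) -> list[int]:
    """Deterministic per-subject, per-stream seed material."""
    return [int(master_seed), int(subject_index), int(stream)]


def generate_subject(
    master_seed: int,
    subject_index: int,
    schedule: SessionSchedule,
    state_params: StateParams | None = None,
    pupil_params: PupilGenParams | None = None,
    behaviour_params: BehaviourParams | None = None,
) -> SubjectData:
    sid = f"s{subject_index:02d}"
    sched = SessionSchedule(
        subject_id=sid, trials=schedule.trials, probe_after=list(schedule.probe_after)
    )
    # streams: 1 = states, 2 = pupil, 3 = behaviour (0 reserved for the schedule)
    s_states, s_pupil, s_behav = (
        _fold(subject_seed(master_seed, subject_index, k)) for k in (1, 2, 3)
    )
    latent, reports = generate_latent_states(sched, state_params, seed=s_states)
    recording = generate_pupil_recording(sched, latent, pupil_params, seed=s_pupil)
    behaviour = generate_behaviour(sched, latent, behaviour_params, seed=s_behav)
    return SubjectData(
        schedule=sched,
        latent=latent,
        reports=reports,
        recording=recording,
        behaviour=behaviour,
    )


def _fold(material: list[int]) -> int:
    """Fold seed material into one 31-bit stream seed (stable across runs)."""
    h = 0
    for m in material:
        h = (h * 1_000_003 + m + 0x9E3779B9) % (2**31 - 1)
    return h


def generate_cohort(
    n_subjects: int,
    seed: int,
    design: DesignParams | None = None,
    state_params: StateParams | None = None,
    pupil_params: PupilGenParams | None = None,
    behaviour_params: BehaviourParams | None = None,
) -> Cohort:
    """Generate a full cohort (default design: the published 42-subject task)."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    base_schedule = generate_schedule(seed, design, subject_id="s00")
    cohort = Cohort(seed=seed)
    for i in range(n_subjects):
        sub = generate_subject(
            seed, i, base_schedule, state_params, pupil_params, behaviour_params
        )
        cohort.subjects[sub.schedule.subject_id] = sub
    return cohort
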