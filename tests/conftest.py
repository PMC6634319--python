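from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pupilmw.cohort import generate_cohort
from pupilmw.design import DesignParams, SessionSchedule, TrialSpec, CueWord, generate_schedule
from pupilmw.states import LatentStateTrace

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# a shrunken but structurally complete session design for fast Monte-Carlo:
# 160 trials, 8 targets, 30 cue-words (10 per valence), 4 probes, mean gap 40
SMALL_DESIGN = DesignParams(
    n_trials=160, n_targets=8, n_cues=30, n_per_valence=10, n_probes=4
)


@pytest.fixture(scope="session")
def schedule() -> SessionSchedule:
    return generate_schedule(1)


@pytest.fixture(scope="session")
def small_cohort():
    """Six subjects on the shrunken design, default pupil parameters."""
    return generate_cohort(6, 11, design=SMALL_DESIGN)


def flat_latent(n_trials: int) -> LatentStateTrace:
    return LatentStateTrace(state_per_trial=["on_task"] * n_trials, episodes=[])


def toy_schedule(
    n_trials: int = 12,
    targets: tuple[int, ...] = (),
    cues: dict[int, str] | None = None,
    probes: tuple[int, ...] = (),
    subject_id: str = "t01",
) -> SessionSchedule:
    """Hand-built miniature schedule for unit tests (cues: trial -> valence)."""
    cues = cues or {}
    trials = []
    for i in range(n_trials):
        cue = None
        if i in cues:
            cue = CueWord(word_id=f"w{i:03d}", text=f"cue{i}", valence=cues[i])
        trials.append(
            TrialSpec(
                index=i,
                stimulus="vertical" if i in targets else "horizontal",
                cue=cue,
            )
        )
    return SessionSchedule(subject_id=subject_id, trials=trials, probe_after=list(probes))
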