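"""Key-press behaviour on the vigilance task (misses and false alarms)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import VERTICAL, SessionSchedule
from .states import LatentStateTrace


@dataclass(frozen=True)
class BehaviourParams:
    """Per-trial response probabilities.

    Defaults reproduce the published near-ceiling performance: on average
    0.33 misses out of 68 targets and 0.79 false alarms per session.
    """

    p_miss: float = 0.33 / 68
    p_false_alarm: float = 0.79 / 1052  # per non-target trial

    def __post_init__(self) -> None:
        for name in ("p_miss", "p_false_alarm"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")


@dataclass
class BehaviouralLog:
    """Key presses per trial with derived miss / false-alarm counts."""

    subject_id: str
    key_press: np.ndarray  # bool, (n_trials,)
    is_target: np.ndarray  # bool, (n_trials,)

    @property
    def misses(self) -> int:
        return int(np.sum(self.is_target & ~self.key_press))

    @property
    def false_alarms(self) -> int:
        return int(np.sum(~self.is_target & self.key_press))


def generate_behaviour(
    schedule: SessionSchedule,
    latent: LatentStateTrace | None = None,
    params: BehaviourParams | None = None,
    seed: int = 0,
) -> BehaviouralLog:
    """Sample the key-press log for one session.

    The latent trace is accepted for interface symmetry with the other
    generators; performance on this undemanding task is near-perfect
    regardless of attentional state, as observed in the study.
    """
    p = params or BehaviourParams()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBE4A]))
    is_target = np.array([tr.stimulus == VERTICAL for tr in schedule.trials])
    u = rng.random(schedule.n_trials)
    press = np.where(is_target, u >= p.p_miss, u < p.p_false_alarm)
    return BehaviouralLog(
        subject_id=schedule.subject_id, key_press=press, is_target=is_target
    )
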