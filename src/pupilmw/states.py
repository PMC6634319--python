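"""Latent attentional states and thought-probe self-reports.

The generator assigns each probe a report category (on-task, spontaneous or
intentional mind wandering, external distraction, task-related thought, blank
mind) from a configurable mixture, then constructs a latent state trace
consistent with the reports: every mind-wandering (MW) report is backed by a
contiguous MW episode ending at the trial immediately preceding the probe.
Spontaneous MW episodes are triggered by an on-screen cue-word with
probability ``p_cue_trigger``; the named cue marks the episode onset, at a
trigger-to-probe lag drawn to match the published mean of about 9 trials.

Reports are a pure function of the latent trace (``derive_reports``); the
generator itself calls it, so regenerating reports from states reproduces
them exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .design import SessionSchedule

ON_TASK = "on_task"
MW_SPONTANEOUS = "mw_spontaneous"
MW_INTENTIONAL = "mw_intentional"
EXTERNAL_DISTRACTION = "external_distraction"
TASK_RELATED = "task_related"
BLANK = "blank"
STATES = (ON_TASK, MW_SPONTANEOUS, MW_INTENTIONAL, EXTERNAL_DISTRACTION, TASK_RELATED, BLANK)

TRIGGER_CUE = "cue_word"
TRIGGER_OWN = "own_thoughts"
TRIGGER_ENV = "environment"
TRIGGER_NONE = "none"


@dataclass(frozen=True)
class MWEpisode:
    """A contiguous run of mind-wandering trials ending at a probe."""

    onset_trial: int
    offset_trial: int
    spontaneity: str  # spontaneous | deliberate
    trigger_type: str  # cue_word | own_thoughts | environment | none
    trigger_word_id: Optional[str]
    dilation_amplitude: float  # mm, sustained pupil dilation during the episode


@dataclass
class LatentStateTrace:
    """Ground-truth attentional state per trial plus the MW episode list."""

    state_per_trial: list[str]
    episodes: list[MWEpisode] = field(default_factory=list)

    def episode_at(self, trial: int) -> Optional[MWEpisode]:
        for ep in self.episodes:
            if ep.onset_trial <= trial <= ep.offset_trial:
                return ep
        return None


@dataclass(frozen=True)
class ProbeReport:
    """Self-report given at one thought-probe (about the pre-probe trial)."""

    probe_index: int
    category: str  # one of STATES
    spontaneity: str  # spontaneous | deliberate | unsure | not_applicable
    trigger_type: str
    trigger_word_id: Optional[str]


@dataclass(frozen=True)
class StateParams:
    """Report-category mixture and episode-shape parameters.

    Default category probabilities are per-subject report rates out of 28
    probes (on-task 7.36, spontaneous MW 9.57, intentional MW 2.10; the
    remainder split evenly over distraction / task-related / blank).
    ``p_cue_trigger`` defaults to the published fraction of spontaneous MW
    episodes attributed to a specific cue-word (212/402).
    """

    p_on_task: float = 7.36 / 28
    p_mw_spontaneous: float = 9.57 / 28
    p_mw_intentional: float = 2.10 / 28
    p_external_distraction: float = (28 - 7.36 - 9.57 - 2.10) / 28 / 3
    p_task_related: float = (28 - 7.36 - 9.57 - 2.10) / 28 / 3
    p_blank: float = (28 - 7.36 - 9.57 - 2.10) / 28 / 3
    p_cue_trigger: float = 212 / 402
    p_own_thoughts_given_noncue: float = 0.6
    p_environment_given_noncue: float = 0.2
    trigger_lag_mean_trials: float = 9.0
    episode_mean_trials: float = 6.0  # non-cue-triggered episode length
    mw_dilation_mm: float = 0.1
    mw_dilation_between_sd: float = 0.02  # subject-level amplitude spread

    def probabilities(self) -> np.ndarray:
        p = np.array(
            [
                self.p_on_task,
                self.p_mw_spontaneous,
                self.p_mw_intentional,
                self.p_external_distraction,
                self.p_task_related,
                self.p_blank,
            ]
        )
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("category probabilities must lie in [0, 1]")
        if not np.isclose(p.sum(), 1.0, atol=1e-8):
            raise ValueError(f"category probabilities sum to {p.sum():.6f}, not 1")
        return p / p.sum()


def derive_reports(schedule: SessionSchedule, latent: LatentStateTrace) -> list[ProbeReport]:
    """Deterministically derive probe reports from the latent state trace.

    The report concerns the trial immediately preceding the probe (the
    ``probe_after`` trial itself).  MW reports inherit spontaneity and
    trigger from the episode containing that trial; all other categories
    have no trigger and spontaneity "not_applicable".
    """
    reports = []
    for k, p in enumerate(schedule.probe_after):
        state = latent.state_per_trial[p]
        if state in (MW_SPONTANEOUS, MW_INTENTIONAL):
            ep = latent.episode_at(p)
            if ep is None:
                raise ValueError(f"MW state at trial {p} has no covering episode")
            reports.append(
                ProbeReport(
                    probe_index=k,
                    category=state,
                    spontaneity=ep.spontaneity,
                    trigger_type=ep.trigger_type,
                    trigger_word_id=ep.trigger_word_id,
                )
            )
        else:
            reports.append(
                ProbeReport(
                    probe_index=k,
                    category=state,
                    spontaneity="not_applicable",
                    trigger_type=TRIGGER_NONE,
                    trigger_word_id=None,
                )
            )
    return reports


def generate_latent_states(
    schedule: SessionSchedule,
    params: StateParams | None = None,
    seed: int = 0,
) -> tuple[LatentStateTrace, list[ProbeReport]]:
    """Sample a latent state trace and its probe reports for one session."""
    sp = params or StateParams()
    probs = sp.probabilities()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x57A7E]))

    n = schedule.n_trials
    state = [ON_TASK] * n
    episodes: list[MWEpisode] = []
    cue_trials = schedule.cue_indices

    # subject-level dilation amplitude (between-subject variability)
    amp = max(
        0.0, sp.mw_dilation_mm + rng.normal(0.0, sp.mw_dilation_between_sd)
    )

    categories = rng.choice(len(STATES), size=len(schedule.probe_after), p=probs)
    prev_probe = -1
    for k, p in enumerate(schedule.probe_after):
        cat = STATES[categories[k]]
        if cat in (MW_SPONTANEOUS, MW_INTENTIONAL):
            onset, trig_type, trig_word = _sample_episode_onset(
                rng, sp, cat, p, prev_probe, cue_trials, schedule
            )
            spont = "spontaneous" if cat == MW_SPONTANEOUS else "deliberate"
            ep = MWEpisode(
                onset_trial=onset,
                offset_trial=p,
                spontaneity=spont,
                trigger_type=trig_type,
                trigger_word_id=trig_word,
                dilation_amplitude=amp,
            )
            episodes.append(ep)
            for t in range(onset, p + 1):
                state[t] = cat
        elif cat != ON_TASK:
            state[p] = cat
        prev_probe = p

    latent = LatentStateTrace(state_per_trial=state, episodes=episodes)
    reports = derive_reports(schedule, latent)
    return latent, reports


def _lag_weights(lags: np.ndarray, target_mean: float) -> np.ndarray:
    """Sampling weights over the available cue lags.

    An exponential decay rate is solved by bisection so the conditional
    expected lag equals ``target_mean`` whenever the available lags allow it
    (falling back to the nearest achievable: all mass on the closest cue if
    every lag exceeds the target, uniform if the target exceeds their mean).
    """
    lags = np.asarray(lags, dtype=float)
    w = np.zeros(len(lags))
    if target_mean <= lags.min():
        w[np.argmin(lags)] = 1.0
        return w
    if target_mean >= lags.mean():
        return np.full(len(lags), 1.0 / len(lags))
    lo, hi = 0.0, 50.0
    for _ in range(60):
        r = 0.5 * (lo + hi)
        w = np.exp(-r * (lags - lags.min()))
        w /= w.sum()
        if float(w @ lags) > target_mean:
            lo = r
        else:
            hi = r
    return w


def _sample_episode_onset(
    rng: np.random.Generator,
    sp: StateParams,
    category: str,
    probe_trial: int,
    prev_probe: int,
    cue_trials: np.ndarray,
    schedule: SessionSchedule,
) -> tuple[int, str, Optional[str]]:
    """Onset trial and trigger for one MW episode ending at ``probe_trial``.

    Episodes never span an earlier probe (that probe reported something
    else), so onsets are clipped to ``prev_probe + 1``.  Intentional MW
    carries no cue trigger.
    """
    lo = prev_probe + 1
    cue_triggered = category == MW_SPONTANEOUS and rng.random() < sp.p_cue_trigger
    if cue_triggered:
        # the episode starts on the trial after the word: the participant
        # reads the cue during its trial, the thought unfolds from the next
        window = cue_trials[(cue_trials >= lo) & (cue_trials <= probe_trial - 1)]
        if len(window) > 0:
            lags = probe_trial - window
            w = _lag_weights(lags, sp.trigger_lag_mean_trials)
            cue_trial = int(rng.choice(window, p=w))
            word = schedule.cue_at(cue_trial)
            assert word is not None
            return cue_trial + 1, TRIGGER_CUE, word.word_id
        # no cue available since the previous probe: fall back to an
        # internally-triggered episode
    dur = int(rng.geometric(1.0 / sp.episode_mean_trials))
    onset = max(lo, probe_trial - dur + 1)
    if category == MW_INTENTIONAL:
        return onset, TRIGGER_NONE, None
    u = rng.random()
    if u < sp.p_own_thoughts_given_noncue:
        return onset, TRIGGER_OWN, None
    if u < sp.p_own_thoughts_given_noncue + sp.p_environment_given_noncue:
        return onset, TRIGGER_ENV, None
    return onset, TRIGGER_NONE, None
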