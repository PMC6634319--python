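"""Vigilance-task session design: trial schedule, cue-words and thought-probes.

A session is a fixed sequence of 2-s trials, each showing a pattern of white
horizontal bars (non-target) or vertical bars (target) on a black background.
A task-irrelevant verbal cue (a short word-phrase of neutral, positive or
negative valence) is superimposed on a subset of non-target trials.  At fixed
points the task halts and a thought-probe asks what the participant was
thinking about immediately before the interruption.

The default design constants reproduce the published task: 1120 trials,
68 targets separated by 9-31 trials, 210 cue-words (70 per valence) and
28 probes whose mean separation is exactly 40 trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

HORIZONTAL = "horizontal"
VERTICAL = "vertical"
VALENCES = ("neutral", "positive", "negative")


@dataclass(frozen=True)
class CueWord:
    """A task-irrelevant verbal cue shown under the fixation point."""

    word_id: str
    text: str
    valence: str  # neutral | positive | negative


@dataclass(frozen=True)
class TrialSpec:
    """One 2-s trial: bar stimulus plus an optional cue-word."""

    index: int
    stimulus: str  # horizontal | vertical
    cue: Optional[CueWord] = None


@dataclass(frozen=True)
class DesignParams:
    """Counts and spacings that define the session layout."""

    n_trials: int = 1120
    trial_dur_s: float = 2.0
    n_targets: int = 68
    target_gap_min: int = 9
    target_gap_max: int = 31
    n_cues: int = 210
    n_per_valence: int = 70
    n_probes: int = 28
    probe_gap_mean: int = 40
    probe_gap_sd: float = 7.5
    # the fixed sequence places a cue on the 4th trial before a probe with
    # this probability (the level reported by the confound check, ~75%)
    p_cue_before_probe: float = 0.75

    def validate(self) -> None:
        if self.n_per_valence * 3 != self.n_cues:
            raise ValueError(
                f"n_cues={self.n_cues} must be 3 * n_per_valence={self.n_per_valence}"
            )
        if self.target_gap_min < 1 or self.target_gap_max < self.target_gap_min:
            raise ValueError("target gap bounds must satisfy 1 <= min <= max")
        # 68 targets at the minimum spacing must fit before the final trial,
        # which is reserved for the last probe.
        if self.n_targets * self.target_gap_min > self.n_trials - 1:
            raise ValueError(
                f"{self.n_targets} targets with minimum gap {self.target_gap_min} "
                f"do not fit in {self.n_trials} trials"
            )
        if self.n_cues > self.n_trials - self.n_targets:
            raise ValueError(
                f"{self.n_cues} cue-words do not fit on "
                f"{self.n_trials - self.n_targets} non-target trials"
            )
        if self.n_probes * 2 > self.n_trials:
            raise ValueError("too many probes for the session length")


@dataclass
class SessionSchedule:
    """The fixed trial sequence for one subject.

    ``probe_after`` holds 0-based trial indices: a probe interrupts the task
    immediately after that trial.  Probe gaps are counted from session start
    (position -1), so 28 gaps summing to 1120 put the last probe after the
    final trial and make the mean gap exactly 40.
    """

    subject_id: str
    trials: list[TrialSpec]
    probe_after: list[int] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def target_indices(self) -> np.ndarray:
        return np.array(
            [t.index for t in self.trials if t.stimulus == VERTICAL], dtype=int
        )

    @property
    def cue_indices(self) -> np.ndarray:
        return np.array([t.index for t in self.trials if t.cue is not None], dtype=int)

    def probe_gaps(self) -> np.ndarray:
        """Trial gaps between consecutive probes, counting from session start."""
        pos = np.asarray(self.probe_after, dtype=int)
        return np.diff(np.concatenate(([-1], pos)))

    def cue_at(self, trial_index: int) -> Optional[CueWord]:
        return self.trials[trial_index].cue


def _sample_target_positions(rng: np.random.Generator, p: DesignParams) -> np.ndarray:
    """Target trial indices with every inter-target gap in [gap_min, gap_max].

    Gaps (including the lead-in from session start) are drawn uniformly, then
    decremented at random until the last target fits before the final trial;
    this keeps each gap within bounds while meeting the total-length budget.
    """
    gaps = rng.integers(p.target_gap_min, p.target_gap_max + 1, size=p.n_targets)
    # final trial index reserved for the last probe -> last target <= n_trials - 2
    budget = p.n_trials - 1
    excess = int(gaps.sum()) - budget
    while excess > 0:
        shrinkable = np.flatnonzero(gaps > p.target_gap_min)
        take = rng.choice(shrinkable)
        step = min(excess, int(gaps[take] - p.target_gap_min))
        # shrink one gap at a time to keep the distribution close to uniform
        gaps[take] -= min(step, 3)
        excess = int(gaps.sum()) - budget
    return np.cumsum(gaps) - 1


def _sample_probe_positions(
    rng: np.random.Generator, p: DesignParams, target_set: set[int]
) -> np.ndarray:
    """Probe positions with mean gap exactly ``probe_gap_mean``.

    Gaps ~ round(N(mean, sd)) are rescaled by unit steps until they sum to
    n_probes * mean exactly; probes landing on target trials are nudged off
    (the probe-after trial is never a target).
    """
    total = p.n_probes * p.probe_gap_mean
    if total > p.n_trials:
        raise ValueError(
            f"{p.n_probes} probes with mean gap {p.probe_gap_mean} need "
            f"{total} trials, session has {p.n_trials}"
        )
    lo, hi = 3, 2 * p.probe_gap_mean - 3
    gaps = np.clip(
        np.rint(rng.normal(p.probe_gap_mean, p.probe_gap_sd, size=p.n_probes)),
        lo,
        hi,
    ).astype(int)
    diff = total - int(gaps.sum())
    step = 1 if diff > 0 else -1
    while diff != 0:
        adjustable = np.flatnonzero((gaps + step >= lo) & (gaps + step <= hi))
        gaps[rng.choice(adjustable)] += step
        diff -= step
    pos = np.cumsum(gaps) - 1
    # nudge probes off target trials; interior shifts leave the gap sum intact
    for i in range(len(pos)):
        for shift in (0, -1, 1, -2, 2, -3, 3):
            cand = pos[i] + shift
            prev_ok = i == 0 or cand > pos[i - 1] + 1
            next_ok = i == len(pos) - 1 or cand < pos[i + 1] - 1
            if cand not in target_set and 0 <= cand < p.n_trials and prev_ok and next_ok:
                pos[i] = cand
                break
        else:  # pragma: no cover - never reached with default spacing
            raise RuntimeError("could not place probe off a target trial")
    return pos


def generate_schedule(
    seed: int,
    config: DesignParams | None = None,
    subject_id: str = "s01",
) -> SessionSchedule:
    """Generate one session schedule.

    Deterministic for a given (seed, config).  Cue-words are placed on
    non-target trials only, so the strong pupil response to word onsets never
    coincides with a target's light response.
    """
    p = config or DesignParams()
    p.validate()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5C4ED]))

    targets = _sample_target_positions(rng, p)
    target_set = set(int(i) for i in targets)
    probes = _sample_probe_positions(rng, p, target_set)

    # cues favour the 4th trial before a probe, then fill uniformly; an
    # exact count is placed (the emulated task is one fixed sequence, so the
    # placement proportion is a design constant, not a per-probe coin flip)
    candidates = sorted(
        {int(q) - 3 for q in probes if q - 3 >= 0 and (q - 3) not in target_set}
    )
    n_forced = min(
        int(round(p.p_cue_before_probe * p.n_probes)), len(candidates), p.n_cues
    )
    forced = sorted(rng.choice(candidates, size=n_forced, replace=False).tolist())
    rest = np.array(
        [i for i in range(p.n_trials) if i not in target_set and i not in set(forced)],
        dtype=int,
    )
    fill = rng.choice(rest, size=p.n_cues - len(forced), replace=False)
    cue_trials = np.sort(np.concatenate([np.array(forced, dtype=int), fill]))
    valences = np.repeat(VALENCES, p.n_per_valence)
    rng.shuffle(valences)

    cue_by_trial: dict[int, CueWord] = {}
    for k, (tr, val) in enumerate(zip(cue_trials, valences)):
        cue_by_trial[int(tr)] = CueWord(
            word_id=f"w{k:03d}", text=f"cue_{val[:3]}_{k:03d}", valence=str(val)
        )

    trials = [
        TrialSpec(
            index=i,
            stimulus=VERTICAL if i in target_set else HORIZONTAL,
            cue=cue_by_trial.get(i),
        )
        for i in range(p.n_trials)
    ]
    return SessionSchedule(
        subject_id=subject_id, trials=trials, probe_after=[int(x) for x in probes]
    )
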