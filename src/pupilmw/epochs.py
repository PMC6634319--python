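"""Event-locked epoching of cleaned pupil traces.

Three data sets feed the inference stage:

* cue-aligned epochs — trials 0, 1, 2 after each cue-word, baseline-corrected
  to the mean diameter of the cue trial itself, labelled MW trigger /
  emotional non-trigger / control;
* probe-aligned epochs — trials 3, 2, 1 before each thought-probe,
  baseline-corrected to the trial immediately preceding the probe, labelled
  by the report (spontaneous MW / on-task / other);
* within-trial light responses — the bar-evoked constriction, mean of the
  trace over 0.5-1.0 s after subtracting the first-250 ms baseline, under
  selection rules that keep cue-words from contaminating the baseline.

Scalar summaries take the mean corrected diameter over the half of each
trial farthest from the reference window (last second for cue-aligned,
first second for probe-aligned).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design import SessionSchedule
from .preprocess import CleanSession
from .states import MW_SPONTANEOUS, ON_TASK, TRIGGER_CUE, ProbeReport

logger = logging.getLogger(__name__)

MW_TRIGGER = "mw_trigger"
EMOTIONAL_NONTRIGGER = "emotional_nontrigger"
CONTROL = "control"
EXCLUDED = "excluded"

COND_MW = "MW"
COND_OT = "OT"
COND_OTHER = "other"

# half-open grid windows on the 40-point 20 Hz grid
FIRST_250MS = slice(0, 5)
FIRST_SECOND = slice(0, 20)
LAST_SECOND = slice(20, 40)
PLR_WINDOW = slice(10, 20)  # 0.5-1.0 s, where the light response peaks


@dataclass(frozen=True)
class CueLabel:
    subject_id: str
    trial_index: int
    word_id: str
    valence: str
    label: str  # mw_trigger | emotional_nontrigger | control | excluded


@dataclass
class Epoch:
    """Baseline-corrected traces around one reference event."""

    subject_id: str
    reference_id: str  # cue word_id or probe index tag
    condition: str
    positions: tuple[int, ...]  # trial offsets, in trace order
    corrected: np.ndarray  # (len(positions), 40), reference-window mean == 0
    baseline_mm: float


def classify_cues(
    schedule: SessionSchedule, reports: Sequence[ProbeReport]
) -> list[CueLabel]:
    """Assign each cue occurrence to the three analysis classes.

    * ``mw_trigger`` — named by the participant as the trigger of a
      spontaneous-MW report at a later probe;
    * ``emotional_nontrigger`` — positive/negative cue, not a trigger, whose
      nearest following probe reports on-task;
    * ``control`` — neither an MW trigger nor an emotional cue whose nearest
      following or preceding probe reports on-task;
    * ``excluded`` — everything else (triggers of intentional MW, emotional
      cues preceded but not followed by an on-task report, triggers naming
      an unknown word).
    """
    probe_pos = np.asarray(schedule.probe_after, dtype=int)
    cue_trial_by_word = {
        t.cue.word_id: t.index for t in schedule.trials if t.cue is not None
    }

    spontaneous_triggers: set[str] = set()
    other_triggers: set[str] = set()
    for rep in reports:
        if rep.trigger_type == TRIGGER_CUE and rep.trigger_word_id is not None:
            wid = rep.trigger_word_id
            if wid not in cue_trial_by_word:
                logger.warning(
                    "report at probe %d names unknown cue %r; ignored",
                    rep.probe_index, wid,
                )
                continue
            if rep.category == MW_SPONTANEOUS and rep.spontaneity == "spontaneous":
                spontaneous_triggers.add(wid)
            else:
                other_triggers.add(wid)

    cat_by_probe = {k: rep.category for k, rep in enumerate(reports)}
    labels = []
    for tr in schedule.trials:
        if tr.cue is None:
            continue
        wid, val, t = tr.cue.word_id, tr.cue.valence, tr.index
        nxt = np.searchsorted(probe_pos, t)  # first probe with probe_after >= t
        following_ot = nxt < len(probe_pos) and cat_by_probe[nxt] == ON_TASK
        preceding_ot = nxt > 0 and cat_by_probe[nxt - 1] == ON_TASK
        emotional = val in ("positive", "negative")

        if wid in spontaneous_triggers:
            label = MW_TRIGGER
        elif wid in other_triggers:
            label = EXCLUDED
        elif emotional and following_ot:
            label = EMOTIONAL_NONTRIGGER
        elif emotional and preceding_ot:
            label = EXCLUDED
        else:
            label = CONTROL
        labels.append(
            CueLabel(
                subject_id=schedule.subject_id,
                trial_index=t,
                word_id=wid,
                valence=val,
                label=label,
            )
        )
    return labels


def _build_epoch(
    clean: CleanSession,
    trials: Sequence[int],
    positions: Sequence[int],
    baseline_pos: int,
    subject_id: str,
    reference_id: str,
    condition: str,
) -> Optional[Epoch]:
    """Baseline-corrected epoch over the given trials, or None if any trial
    is missing or excluded by QC."""
    n = len(clean)
    for t in trials:
        if t < 0 or t >= n or clean.excluded[t]:
            return None
    traces = clean.traces[list(trials)]
    baseline = float(np.mean(traces[list(positions).index(baseline_pos)]))
    return Epoch(
        subject_id=subject_id,
        reference_id=reference_id,
        condition=condition,
        positions=tuple(positions),
        corrected=traces - baseline,
        baseline_mm=baseline,
    )


def _summaries_frame(epochs: Sequence[Epoch], window: slice) -> pd.DataFrame:
    rows = [
        {
            "subject_id": ep.subject_id,
            "reference_id": ep.reference_id,
            "condition": ep.condition,
            "position": float(pos),
            "value_mm": float(np.mean(ep.corrected[i, window])),
        }
        for ep in epochs
        for i, pos in enumerate(ep.positions)
    ]
    return pd.DataFrame(
        rows, columns=["subject_id", "reference_id", "condition", "position", "value_mm"]
    )


def epoch_cue_aligned(
    clean: CleanSession,
    cue_labels: Sequence[CueLabel],
) -> tuple[list[Epoch], pd.DataFrame]:
    """Cue-aligned epochs (positions 0, 1, 2 after the word).

    Baseline is the mean diameter over the cue trial (position 0); an epoch
    is kept only if the cue trial and both following trials carry usable
    recordings.  Summary values average the last second of each trial, the
    half farthest from the reference.  Cues labelled ``excluded`` emit no
    epoch.
    """
    epochs: list[Epoch] = []
    dropped = 0
    for lab in cue_labels:
        if lab.label == EXCLUDED:
            continue
        ep = _build_epoch(
            clean,
            trials=[lab.trial_index, lab.trial_index + 1, lab.trial_index + 2],
            positions=[0, 1, 2],
            baseline_pos=0,
            subject_id=lab.subject_id,
            reference_id=lab.word_id,
            condition=lab.label,
        )
        if ep is None:
            dropped += 1
        else:
            epochs.append(ep)
    if dropped:
        logger.info("cue-aligned: dropped %d epochs failing the QC rule", dropped)
    return epochs, _summaries_frame(epochs, LAST_SECOND)


def epoch_probe_aligned(
    clean: CleanSession,
    schedule: SessionSchedule,
    reports: Sequence[ProbeReport],
) -> tuple[list[Epoch], pd.DataFrame]:
    """Probe-aligned epochs (positions 3, 2, 1 before the probe).

    Position 1 is the trial immediately preceding the probe and provides the
    baseline; all three preceding trials must carry usable recordings.
    Condition is MW for spontaneous mind wandering, OT for on-task, and
    "other" for everything else (including intentional MW).  Summaries
    average the first second of each trial.
    """
    epochs: list[Epoch] = []
    dropped = 0
    for k, rep in enumerate(reports):
        p = schedule.probe_after[k]
        if rep.category == MW_SPONTANEOUS and rep.spontaneity == "spontaneous":
            cond = COND_MW
        elif rep.category == ON_TASK:
            cond = COND_OT
        else:
            cond = COND_OTHER
        ep = _build_epoch(
            clean,
            trials=[p - 2, p - 1, p],
            positions=[3, 2, 1],
            baseline_pos=1,
            subject_id=schedule.subject_id,
            reference_id=f"probe{k:02d}",
            condition=cond,
        )
        if ep is None:
            dropped += 1
        else:
            epochs.append(ep)
    if dropped:
        logger.info("probe-aligned: dropped %d epochs failing the QC rule", dropped)
    return epochs, _summaries_frame(epochs, FIRST_SECOND)


def _constriction(trace: np.ndarray) -> float:
    """Mean of (trace - first-250 ms baseline) over the 0.5-1.0 s window."""
    baseline = float(np.mean(trace[FIRST_250MS]))
    return float(np.mean(trace[PLR_WINDOW] - baseline))


def _has_cue(schedule: SessionSchedule, trial: int) -> bool:
    return 0 <= trial < schedule.n_trials and schedule.trials[trial].cue is not None


MODE_MW_VS_OT = "mw_vs_ot"
MODE_TARGET = "target_vs_nontarget"


def extract_light_responses(
    clean: CleanSession,
    schedule: SessionSchedule,
    reports: Sequence[ProbeReport],
    mode: str = MODE_MW_VS_OT,
) -> pd.DataFrame:
    """Bar-evoked constriction amplitudes under the selection rules.

    ``mw_vs_ot``: the last trial before each probe reporting spontaneous MW
    or on-task.  ``target_vs_nontarget``: every target trial versus the last
    non-target trial preceding it.  In both modes a candidate is dropped if
    the trial itself or its predecessor carries a cue-word (which would
    shift the baseline and mask the light response), or if its recording is
    excluded by QC.
    """
    rows = []

    def usable(t: int) -> bool:
        return (
            0 <= t < len(clean)
            and not clean.excluded[t]
            and not _has_cue(schedule, t)
            and not _has_cue(schedule, t - 1)
        )

    if mode == MODE_MW_VS_OT:
        for k, rep in enumerate(reports):
            if rep.category == MW_SPONTANEOUS and rep.spontaneity == "spontaneous":
                group = COND_MW
            elif rep.category == ON_TASK:
                group = COND_OT
            else:
                continue
            t = schedule.probe_after[k]
            if usable(t):
                rows.append((schedule.subject_id, t, group, _constriction(clean.traces[t])))
    elif mode == MODE_TARGET:
        target_idx = schedule.target_indices
        target_set = set(int(i) for i in target_idx)
        for t in target_idx:
            if usable(int(t)):
                rows.append(
                    (schedule.subject_id, int(t), "target", _constriction(clean.traces[t]))
                )
            prev = int(t) - 1
            while prev >= 0 and prev in target_set:
                prev -= 1
            if prev >= 0 and usable(prev):
                rows.append(
                    (schedule.subject_id, prev, "nontarget", _constriction(clean.traces[prev]))
                )
    else:
        raise ValueError(f"unknown light-response mode {mode!r}")
    return pd.DataFrame(
        rows, columns=["subject_id", "trial_index", "group", "constriction_mm"]
    )


def cue_placement_check(
    sessions: Sequence[tuple[SessionSchedule, Sequence[ProbeReport]]],
) -> pd.DataFrame:
    """Probability that a cue-word occupies the 4th trial before a probe.

    A confound check: if cue-words were unevenly placed before MW versus
    on-task probes, baseline differences could masquerade as MW dilation.
    Returns per-category across-subject mean and standard error, plus the
    per-subject fractions.
    """
    per_subject: dict[str, dict[str, float]] = {}
    for schedule, reports in sessions:
        counts = {COND_MW: [0, 0], COND_OT: [0, 0], COND_OTHER: [0, 0]}
        for k, rep in enumerate(reports):
            if rep.category == MW_SPONTANEOUS and rep.spontaneity == "spontaneous":
                cat = COND_MW
            elif rep.category == ON_TASK:
                cat = COND_OT
            else:
                cat = COND_OTHER
            fourth = schedule.probe_after[k] - 3
            if fourth < 0:
                continue
            counts[cat][1] += 1
            if _has_cue(schedule, fourth):
                counts[cat][0] += 1
        per_subject[schedule.subject_id] = {
            cat: (c[0] / c[1] if c[1] else np.nan) for cat, c in counts.items()
        }

    rows = []
    for cat in (COND_MW, COND_OT, COND_OTHER):
        fr = np.array([v[cat] for v in per_subject.values()], dtype=float)
        fr = fr[~np.isnan(fr)]
        rows.append(
            {
                "category": cat,
                "mean": float(np.mean(fr)) if fr.size else np.nan,
                "se": float(np.std(fr, ddof=1) / np.sqrt(fr.size)) if fr.size > 1 else np.nan,
                "n_subjects": int(fr.size),
            }
        )
    return pd.DataFrame(rows)
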