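"""Cohort-level analyses: preprocessing fan-out, the three event-locked
analyses and their inference.

Epochs pool across subjects at the trial level; the subject enters the
mixed model as a random intercept.  The cue-aligned and probe-aligned
analyses fit the condition x position interaction model and follow up with
two-condition single-position contrasts; the light-response analyses
compare constriction amplitudes between groups with a mixed-model F test,
a pooled two-sample t test and a JZS Bayes factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .bayes import BayesResult, bayes_factor_t
from .cohort import Cohort
from .epochs import (
    COND_MW,
    COND_OT,
    CONTROL,
    EMOTIONAL_NONTRIGGER,
    MODE_MW_VS_OT,
    MODE_TARGET,
    MW_TRIGGER,
    Epoch,
    classify_cues,
    cue_placement_check,
    epoch_cue_aligned,
    epoch_probe_aligned,
    extract_light_responses,
)
from .lmm import (
    FTestResult,
    LMMSpec,
    RandomInterceptLMM,
    RandomInterceptLMMResults,
    anova_interaction,
    fit_lmm,
    posthoc_pairwise,
    split_half,
    two_sample_t,
)
from .preprocess import CleanSession, PreprocessOptions, preprocess_session


@dataclass
class AlignedAnalysis:
    """Result bundle for one event-locked LMM analysis."""

    summaries: pd.DataFrame
    epochs: list[Epoch]
    fit: RandomInterceptLMMResults
    interaction: FTestResult
    posthocs: dict[str, FTestResult] = field(default_factory=dict)
    split_half: dict[str, FTestResult] = field(default_factory=dict)


@dataclass
class LightAnalysis:
    """Result bundle for one light-response comparison."""

    responses: pd.DataFrame
    group_sizes: dict[str, int]
    f_test: FTestResult
    t: float
    df: int
    p: float
    bayes: BayesResult


def preprocess_cohort(
    cohort: Cohort, options: PreprocessOptions | None = None
) -> tuple[dict[str, CleanSession], list[dict]]:
    cleans: dict[str, CleanSession] = {}
    qcs: list[dict] = []
    for sid, sub in cohort.subjects.items():
        clean, qc = preprocess_session(sub.recording, options)
        cleans[sid] = clean
        qcs.append(qc)
    return cleans, qcs


def cue_aligned_analysis(
    cohort: Cohort,
    cleans: dict[str, CleanSession],
    reml: bool = False,
    with_posthocs: bool = True,
    with_split_half: bool = True,
) -> AlignedAnalysis:
    """Cue-aligned interaction analysis across the whole cohort."""
    all_epochs: list[Epoch] = []
    frames = []
    for sid, sub in cohort.subjects.items():
        labels = classify_cues(sub.schedule, sub.reports)
        eps, summ = epoch_cue_aligned(cleans[sid], labels)
        all_epochs.extend(eps)
        frames.append(summ)
    summaries = pd.concat(frames, ignore_index=True)
    spec = LMMSpec(reference=CONTROL)
    fit = fit_lmm(summaries, spec, reml=reml)
    out = AlignedAnalysis(
        summaries=summaries,
        epochs=all_epochs,
        fit=fit,
        interaction=anova_interaction(fit),
    )
    if with_posthocs:
        pairs = [
            (MW_TRIGGER, EMOTIONAL_NONTRIGGER),
            (MW_TRIGGER, CONTROL),
            (EMOTIONAL_NONTRIGGER, CONTROL),
        ]
        for a, b in pairs:
            for pos in (1.0, 2.0):
                key = f"{a}_vs_{b}@{pos:g}"
                try:
                    out.posthocs[key] = posthoc_pairwise(
                        summaries, (b, a), pos, spec, reml
                    )
                except ValueError:
                    # a sparse cohort can leave a condition empty at a position
                    continue
    if with_split_half:
        halves = split_half(summaries, spec, reml=reml)
        out.split_half = {name: ft for name, (_, ft) in halves.items()}
    return out


def probe_aligned_analysis(
    cohort: Cohort,
    cleans: dict[str, CleanSession],
    reml: bool = False,
    with_posthocs: bool = True,
) -> AlignedAnalysis:
    """Probe-aligned interaction analysis (MW / OT / other)."""
    all_epochs: list[Epoch] = []
    frames = []
    for sid, sub in cohort.subjects.items():
        eps, summ = epoch_probe_aligned(cleans[sid], sub.schedule, sub.reports)
        all_epochs.extend(eps)
        frames.append(summ)
    summaries = pd.concat(frames, ignore_index=True)
    spec = LMMSpec(reference="other")
    fit = fit_lmm(summaries, spec, reml=reml)
    out = AlignedAnalysis(
        summaries=summaries,
        epochs=all_epochs,
        fit=fit,
        interaction=anova_interaction(fit),
    )
    if with_posthocs:
        for a, b in [(COND_MW, COND_OT), (COND_MW, "other"), (COND_OT, "other")]:
            for pos in (2.0, 3.0):
                key = f"{a}_vs_{b}@{pos:g}"
                try:
                    out.posthocs[key] = posthoc_pairwise(
                        summaries, (b, a), pos, spec, reml
                    )
                except ValueError:
                    continue
    return out


def _light_group_f(
    responses: pd.DataFrame, groups: tuple[str, str], reml: bool = False
) -> FTestResult:
    """Mixed-model F test of the group difference in constriction (df2 = n-2)."""
    a, b = groups
    sub = responses[responses["group"].isin([a, b])]
    x = np.column_stack([np.ones(len(sub)), (sub["group"] == b).astype(float)])
    model = RandomInterceptLMM(
        endog=sub["constriction_mm"].to_numpy(dtype=float),
        exog=x,
        groups=sub["subject_id"].to_numpy(),
        exog_names=["Intercept", f"G[{b}]"],
    )
    return model.fit(reml=reml).f_test([1], term=f"{b} - {a}")


def light_response_analysis(
    cohort: Cohort,
    cleans: dict[str, CleanSession],
    mode: str = MODE_MW_VS_OT,
    reml: bool = False,
) -> LightAnalysis:
    """Light-response comparison: MW vs OT probes, or target vs non-target."""
    frames = [
        extract_light_responses(cleans[sid], sub.schedule, sub.reports, mode)
        for sid, sub in cohort.subjects.items()
    ]
    responses = pd.concat(frames, ignore_index=True)
    groups = (COND_MW, COND_OT) if mode == MODE_MW_VS_OT else ("target", "nontarget")
    a, b = groups
    xa = responses.loc[responses["group"] == a, "constriction_mm"].to_numpy()
    xb = responses.loc[responses["group"] == b, "constriction_mm"].to_numpy()
    t, df, p = two_sample_t(xa, xb)
    return LightAnalysis(
        responses=responses,
        group_sizes={a: len(xa), b: len(xb)},
        f_test=_light_group_f(responses, groups, reml=reml),
        t=t,
        df=df,
        p=p,
        bayes=bayes_factor_t(t, len(xa), len(xb)),
    )


def cue_placement_analysis(cohort: Cohort) -> pd.DataFrame:
    return cue_placement_check(
        [(sub.schedule, sub.reports) for sub in cohort.subjects.values()]
    )
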