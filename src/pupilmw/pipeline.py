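"""End-to-end pipeline: simulate -> preprocess -> epoch -> analyze -> report.

A run is driven by a ``RunConfig`` (serializable to YAML, archived verbatim
next to the outputs).  Every stage logs the SHA-256 of the files it writes
into a run manifest; rerunning with the same config yields identical
digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from . import io
from .analysis import (
    AlignedAnalysis,
    LightAnalysis,
    cue_aligned_analysis,
    cue_placement_analysis,
    light_response_analysis,
    preprocess_cohort,
    probe_aligned_analysis,
)
from .behaviour import BehaviourParams
from .cohort import generate_cohort
from .design import DesignParams
from .epochs import MODE_MW_VS_OT, MODE_TARGET
from .preprocess import PreprocessOptions
from .pupil import PupilGenParams
from .report import make_trace_report
from .states import StateParams

logger = logging.getLogger(__name__)

ALL_ANALYSES = ("cue", "probe", "light", "target")


def _from_dict(cls, d: dict | None):
    if d is None:
        return cls()
    names = {f.name for f in fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    return cls(**d)


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    seed: int = 0
    n_subjects: int = 42
    out_dir: str = "pupilmw_run"
    analyses: tuple[str, ...] = ALL_ANALYSES
    design: DesignParams = field(default_factory=DesignParams)
    states: StateParams = field(default_factory=StateParams)
    pupil: PupilGenParams = field(default_factory=PupilGenParams)
    behaviour: BehaviourParams = field(default_factory=BehaviourParams)
    preprocess: PreprocessOptions = field(default_factory=PreprocessOptions)
    reml: bool = False
    render_figures: bool = True

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs: dict[str, Any] = {}
        for key, sub in (
            ("design", DesignParams),
            ("states", StateParams),
            ("pupil", PupilGenParams),
            ("behaviour", BehaviourParams),
            ("preprocess", PreprocessOptions),
        ):
            kwargs[key] = _from_dict(sub, d.get(key))
        for key in ("seed", "n_subjects", "out_dir", "reml", "render_figures"):
            if key in d:
                kwargs[key] = d[key]
        if "analyses" in d:
            kwargs["analyses"] = tuple(d["analyses"])
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _ftest_dict(ft) -> dict:
    return {"term": ft.term, "F": ft.fvalue, "df1": ft.df1, "df2": ft.df2, "p": ft.pvalue}


def _aligned_dict(res: AlignedAnalysis) -> dict:
    return {
        "n_epochs": len(res.epochs),
        "n_obs": int(res.fit.nobs),
        "condition_counts": {
            str(k): int(v) // 3
            for k, v in res.summaries["condition"].value_counts().items()
        },
        "coefficients": {
            str(k): float(v) for k, v in res.fit.fe_params.items()
        },
        "se": {str(k): float(v) for k, v in res.fit.bse().items()},
        "sigma2_u": float(res.fit.sigma2_u),
        "sigma2_e": float(res.fit.sigma2_e),
        "loglik": float(res.fit.llf),
        "interaction": _ftest_dict(res.interaction),
        "posthocs": {k: _ftest_dict(v) for k, v in res.posthocs.items()},
        "split_half": {k: _ftest_dict(v) for k, v in res.split_half.items()},
    }


def _light_dict(res: LightAnalysis) -> dict:
    return {
        "group_sizes": res.group_sizes,
        "group_means_mm": {
            str(g): float(m)
            for g, m in res.responses.groupby("group")["constriction_mm"]
            .mean()
            .items()
        },
        "f_test": _ftest_dict(res.f_test),
        "t": res.t,
        "df": res.df,
        "p": res.p,
        "bf10": res.bayes.bf10,
        "prior_scale": res.bayes.prior_scale,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run manifest.

    The manifest lists every output file with its SHA-256, the QC summary
    and a digest of the analysis results; it is also written to
    ``manifest.json`` in the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict[str, Any] = {"seed": config.seed, "n_subjects": config.n_subjects,
                                "files": {}, "stages": []}

    def record(stage: str, paths: dict[str, Path]) -> None:
        manifest["stages"].append(stage)
        for name, p in paths.items():
            manifest["files"][str(Path(p).relative_to(out))] = _sha256(Path(p))
        logger.info("stage %s: wrote %d files", stage, len(paths))

    try:
        cohort = generate_cohort(
            config.n_subjects, config.seed, config.design, config.states,
            config.pupil, config.behaviour,
        )
        record("simulate", cohort.to_dir(out))

        cleans, qcs = preprocess_cohort(cohort, config.preprocess)
        import pandas as pd

        clean_df = pd.concat(
            [io.clean_frame(c) for c in cleans.values()], ignore_index=True
        )
        qc_path = out / "qc.json"
        qc_path.write_text(json.dumps(qcs, indent=1, sort_keys=True))
        record(
            "preprocess",
            {"clean": io.write_csv(clean_df, out / "clean.csv"), "qc": qc_path},
        )

        results: dict[str, Any] = {}
        epoch_sets = {}
        single_subject = config.n_subjects < 2
        if single_subject:
            results["skipped"] = (
                "mixed-model analyses need >= 2 subjects; only simulation "
                "and preprocessing were run"
            )
        if "cue" in config.analyses and not single_subject:
            res = cue_aligned_analysis(cohort, cleans, reml=config.reml)
            results["cue"] = _aligned_dict(res)
            epoch_sets["cue_aligned"] = res.epochs
            io.write_csv(res.summaries, out / "epochs_cue.csv")
        if "probe" in config.analyses and not single_subject:
            res = probe_aligned_analysis(cohort, cleans, reml=config.reml)
            results["probe"] = _aligned_dict(res)
            epoch_sets["probe_aligned"] = res.epochs
            io.write_csv(res.summaries, out / "epochs_probe.csv")
            placement = cue_placement_analysis(cohort)
            io.write_csv(placement, out / "cue_placement.csv")
            results["cue_placement"] = {
                row["category"]: {"mean": row["mean"], "se": row["se"]}
                for _, row in placement.iterrows()
            }
        light_frames = []
        for which, mode, key in (
            ("light", MODE_MW_VS_OT, "light_mw_vs_ot"),
            ("target", MODE_TARGET, "light_target_vs_nontarget"),
        ):
            if which not in config.analyses or single_subject:
                continue
            try:
                res = light_response_analysis(cohort, cleans, mode, config.reml)
            except ValueError as exc:
                # a tiny cohort can leave a comparison group nearly empty
                results[key] = {"skipped": str(exc)}
                logger.warning("analysis %s skipped: %s", key, exc)
                continue
            results[key] = _light_dict(res)
            light_frames.append(res.responses.assign(mode=mode))
        if light_frames:
            io.write_csv(
                pd.concat(light_frames, ignore_index=True), out / "light_responses.csv"
            )

        behaviour_summary = {
            "mean_misses": float(
                pd.Series([s.behaviour.misses for s in cohort.subjects.values()]).mean()
            ),
            "mean_false_alarms": float(
                pd.Series(
                    [s.behaviour.false_alarms for s in cohort.subjects.values()]
                ).mean()
            ),
        }
        results["behaviour"] = behaviour_summary
        results_path = out / "results.json"
        results_path.write_text(json.dumps(results, indent=1, sort_keys=True))
        analyze_files = {"results": results_path}
        for name in ("epochs_cue", "epochs_probe", "cue_placement", "light_responses"):
            p = out / f"{name}.csv"
            if p.exists():
                analyze_files[name] = p
        record("analyze", analyze_files)

        if epoch_sets:
            written = make_trace_report(
                epoch_sets, out, per_subject=False, render=config.render_figures
            )
            record(
                "report",
                {f"{k}_{kind}": p for k, d in written.items() for kind, p in d.items()},
            )
    except Exception as exc:
        stage = manifest["stages"][-1] if manifest["stages"] else "simulate"
        raise RuntimeError(
            f"pipeline halted after stage {stage!r}: {exc}"
        ) from exc

    manifest["digest"] = hashlib.sha256(
        json.dumps(manifest["files"], sort_keys=True).encode()
    ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
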