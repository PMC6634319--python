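"""Per-condition mean +/- s.e. trace tables and figures.

Mirrors the study's trace figures: thick line = mean across epochs (trial
level), thin band = standard error across epochs; one panel per analysis.
Tables are pure functions of the epoch set, so regenerating them from
archived epochs is bit-identical.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .epochs import Epoch
from .preprocess import GRID_TIMES


def trace_table(epochs: Sequence[Epoch], per_subject: bool = False) -> pd.DataFrame:
    """Mean and s.e. of the corrected trace per (condition, time point).

    Times are continuous across positions (position * 2 s + grid time for
    cue-aligned epochs; for probe-aligned epochs positions count backwards
    and the caller's position ordering is preserved as laid out in the
    epoch).  With ``per_subject`` the epochs are first averaged within
    subject and the s.e. is across subjects.
    """
    if not epochs:
        raise ValueError("no epochs to summarize")
    n_pos = len(epochs[0].positions)
    rows = []
    for cond in sorted({e.condition for e in epochs}):
        sel = [e for e in epochs if e.condition == cond]
        stack = np.stack([e.corrected.ravel() for e in sel])  # (n_epochs, n_pos*40)
        if per_subject:
            subj = np.array([e.subject_id for e in sel])
            stack = np.stack(
                [stack[subj == s].mean(axis=0) for s in np.unique(subj)]
            )
        mean = stack.mean(axis=0)
        if stack.shape[0] > 1:
            se = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
        else:
            se = np.full(stack.shape[1], np.nan)
        t_rel = np.concatenate(
            [2.0 * k + GRID_TIMES for k in range(n_pos)]
        )
        positions = np.repeat([epochs[0].positions[k] for k in range(n_pos)], len(GRID_TIMES))
        for tr, pos, m, s in zip(t_rel, positions, mean, se):
            rows.append(
                {
                    "condition": cond,
                    "position": int(pos),
                    "t_s": float(tr),
                    "mean_mm": float(m),
                    "se_mm": float(s),
                    "n": int(stack.shape[0]),
                }
            )
    return pd.DataFrame(rows)


def plot_traces(
    table: pd.DataFrame, out_path: str | Path, title: str = ""
) -> Path:
    """Render a trace table to a figure (PNG or SVG by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for cond, sub in table.groupby("condition"):
        sub = sub.sort_values("t_s")
        ax.plot(sub["t_s"], sub["mean_mm"], lw=2, label=f"{cond} (n={sub['n'].iloc[0]})")
        ax.fill_between(
            sub["t_s"],
            sub["mean_mm"] - sub["se_mm"],
            sub["mean_mm"] + sub["se_mm"],
            alpha=0.25,
            lw=0,
        )
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("time from reference (s)")
    ax.set_ylabel("baseline-corrected pupil diameter (mm)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def make_trace_report(
    epochs_by_analysis: dict[str, Sequence[Epoch]],
    out_dir: str | Path,
    per_subject: bool = False,
    render: bool = True,
) -> dict[str, dict[str, Path]]:
    """Write mean +/- s.e. trace CSVs (and figures) for each analysis."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, dict[str, Path]] = {}
    for name, epochs in epochs_by_analysis.items():
        table = trace_table(list(epochs), per_subject=per_subject)
        csv_path = out / f"traces_{name}.csv"
        table.to_csv(csv_path, index=False, float_format="%.6f", lineterminator="\n")
        written[name] = {"csv": csv_path}
        if render:
            written[name]["figure"] = plot_traces(
                table, out / f"traces_{name}.png", title=name.replace("_", " ")
            )
    return written
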