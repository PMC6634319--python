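"""Artifact rejection and resampling of raw pupil traces.

Each 2-s trial is cleaned independently: the two eyes are averaged sample by
sample (a sample is lost only when both eyes are invalid), samples outside
the trial's central 90% interval — below its 5th or above its 95th valid-
sample percentile — are masked, and the retained samples are linearly
interpolated onto a fixed 40-point 20 Hz grid (bin centres 0.025 + k*0.05 s).
A trial losing more than 60% of its 60 raw time-points is flagged excluded.
The percentile rule deliberately retains trials containing a short blink:
only the artifactual samples are removed, the trial itself survives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .pupil import RawPupilRecording

N_RAW = 60
N_GRID = 40
GRID_TIMES = 0.025 + 0.05 * np.arange(N_GRID)
LOSS_THRESHOLD = 0.60

CENTRAL_90 = "central_90"
UPPER_90 = "upper_90"


@dataclass(frozen=True)
class PreprocessOptions:
    artifact_rule: str = CENTRAL_90  # central_90 masks both tails, upper_90 the top only
    loss_threshold: float = LOSS_THRESHOLD


@dataclass
class MaskedSeries:
    """One trial's raw series with hardware validity and artifact mask.

    ``valid`` records tracker validity and is never altered by masking;
    ``keep`` marks the samples retained after artifact rejection.  Because
    the percentile interval is always computed over the valid samples,
    re-masking a masked series reproduces it exactly (idempotence).
    """

    times: np.ndarray
    values: np.ndarray
    valid: np.ndarray
    keep: np.ndarray


@dataclass
class CleanPupilTrace:
    """One trial's cleaned 20 Hz trace."""

    subject_id: str
    trial_index: int
    times: np.ndarray  # (40,) grid times in s
    diameter_mm: np.ndarray  # (40,) nan everywhere if excluded with no data
    excluded: bool
    loss_fraction: float


class CleanSession:
    """Cleaned traces for a whole session, list-like over trials."""

    def __init__(
        self,
        subject_id: str,
        traces: np.ndarray,
        excluded: np.ndarray,
        loss_fraction: np.ndarray,
    ):
        self.subject_id = subject_id
        self.traces = traces  # (n_trials, 40)
        self.excluded = excluded.astype(bool)
        self.loss_fraction = loss_fraction
        self.times = GRID_TIMES.copy()

    def __len__(self) -> int:
        return self.traces.shape[0]

    def __getitem__(self, i: int) -> CleanPupilTrace:
        return CleanPupilTrace(
            subject_id=self.subject_id,
            trial_index=i,
            times=self.times,
            diameter_mm=self.traces[i],
            excluded=bool(self.excluded[i]),
            loss_fraction=float(self.loss_fraction[i]),
        )

    def __iter__(self) -> Iterator[CleanPupilTrace]:
        return (self[i] for i in range(len(self)))

    @property
    def excluded_fraction(self) -> float:
        return float(np.mean(self.excluded))


def combine_eyes(
    diameter: dict[str, np.ndarray], valid: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample mean of the valid eyes; invalid only where every eye is.

    Accepts (..., n_samples) arrays so a whole session can be combined in
    one call.
    """
    eyes = list(diameter)
    if not eyes:
        raise ValueError("no eyes in recording")
    vals = np.stack([np.asarray(diameter[e], dtype=float) for e in eyes])
    ok = np.stack([np.asarray(valid[e], dtype=bool) for e in eyes])
    n_ok = ok.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n_ok > 0, np.sum(vals * ok, axis=0) / np.maximum(n_ok, 1), np.nan)
    return mean, n_ok > 0


def _row_percentile(values: np.ndarray, valid: np.ndarray, q: float) -> np.ndarray:
    """Per-row percentile over valid samples, linear-interpolation definition
    (identical to ``np.percentile``).  Rows with no valid sample give nan."""
    work = np.where(valid, values, np.inf)  # invalid sorts to the end
    srt = np.sort(work, axis=1)
    m = valid.sum(axis=1)
    out = np.full(values.shape[0], np.nan)
    rows = m > 0
    if rows.any():
        pos = (q / 100.0) * (m[rows] - 1)
        lo = np.floor(pos).astype(int)
        hi = np.minimum(lo + 1, m[rows] - 1)
        frac = pos - lo
        r = np.flatnonzero(rows)
        out[rows] = srt[r, lo] * (1.0 - frac) + srt[r, hi] * frac
    return out


def reject_artifacts(
    values: np.ndarray | MaskedSeries,
    valid: np.ndarray | None = None,
    rule: str = CENTRAL_90,
    times: np.ndarray | None = None,
) -> np.ndarray | MaskedSeries:
    """Percentile-based artifact rejection, per trial.

    Percentiles are computed over the valid samples of each trial (linear
    interpolation definition); samples strictly outside the interval are
    masked, boundary values are kept.  Already-invalid samples stay masked;
    original values are never modified.

    Given raw arrays — (n_samples,) or (n_trials, n_samples) plus a validity
    mask — returns the boolean keep-mask.  Given a :class:`MaskedSeries`,
    returns a new :class:`MaskedSeries`; because validity is untouched, the
    operation is idempotent on its own output.
    """
    if isinstance(values, MaskedSeries):
        series = values
        keep = reject_artifacts(series.values, series.valid, rule=rule)
        return MaskedSeries(
            times=series.times, values=series.values, valid=series.valid, keep=keep
        )
    if valid is None:
        raise TypeError("valid mask required when passing raw arrays")
    v = np.atleast_2d(np.asarray(values, dtype=float))
    ok = np.atleast_2d(np.asarray(valid, dtype=bool))
    if rule == CENTRAL_90:
        lo = _row_percentile(v, ok, 5.0)[:, None]
        hi = _row_percentile(v, ok, 95.0)[:, None]
        with np.errstate(invalid="ignore"):
            inside = (v >= lo) & (v <= hi)
    elif rule == UPPER_90:
        hi = _row_percentile(v, ok, 90.0)[:, None]
        with np.errstate(invalid="ignore"):
            inside = v <= hi
    else:
        raise ValueError(f"unknown artifact rule {rule!r}")
    keep = ok & inside
    return keep.reshape(np.shape(values)) if np.ndim(values) == 1 else keep


def interpolate_trial(
    times: np.ndarray,
    values: np.ndarray,
    keep: np.ndarray,
    subject_id: str = "",
    trial_index: int = 0,
    loss_threshold: float = LOSS_THRESHOLD,
) -> CleanPupilTrace:
    """Linearly interpolate retained samples onto the 20 Hz grid.

    Edge gaps take the nearest retained value (constant extension).  The
    excluded flag applies the strict >60% loss rule over the trial's raw
    time-point count.
    """
    times = np.asarray(times, dtype=float)
    keep = np.asarray(keep, dtype=bool)
    n_raw = len(times)
    loss = 1.0 - keep.sum() / n_raw
    excluded = loss > loss_threshold
    if keep.sum() == 0:
        grid = np.full(N_GRID, np.nan)
    else:
        grid = np.interp(GRID_TIMES, times[keep], np.asarray(values, float)[keep])
    return CleanPupilTrace(
        subject_id=subject_id,
        trial_index=trial_index,
        times=GRID_TIMES.copy(),
        diameter_mm=grid,
        excluded=bool(excluded),
        loss_fraction=float(loss),
    )


def _interp_block(values: np.ndarray, keep: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Linear interpolation of every trial onto the 20 Hz grid at once.

    Equivalent to calling ``np.interp`` per trial on its retained samples
    (nearest-value extension at the edges); rows with nothing retained give
    nan.  Relies on the raw samples being uniformly spaced so grid times can
    be bracketed by index arithmetic.
    """
    n, m = values.shape
    dt = times[1] - times[0]
    g = (GRID_TIMES - times[0]) / dt  # grid positions in raw-sample units
    idx = np.arange(m)
    prev = np.maximum.accumulate(np.where(keep, idx, -1), axis=1)
    nxt = np.minimum.accumulate(np.where(keep, idx, m + 1)[:, ::-1], axis=1)[:, ::-1]
    j0 = np.clip(np.floor(g).astype(int), 0, m - 1)
    j1 = j0 + 1
    p = prev[:, j0]
    q = np.where(j1 <= m - 1, nxt[:, np.minimum(j1, m - 1)], m + 1)
    vp = np.take_along_axis(values, np.clip(p, 0, m - 1), axis=1)
    vq = np.take_along_axis(values, np.clip(q, 0, m - 1), axis=1)
    have_p, have_q = p >= 0, q <= m - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        w = (g[None, :] - p) / (q - p)
        out = np.where(
            have_p & have_q,
            vp + (vq - vp) * w,
            np.where(have_p, vp, np.where(have_q, vq, np.nan)),
        )
    return out


def preprocess_session(
    raw: RawPupilRecording,
    options: PreprocessOptions | None = None,
) -> tuple[CleanSession, dict]:
    """Clean a whole session and report QC.

    Returns the cleaned traces and a QC summary with the per-subject
    excluded-trial fraction and loss statistics.
    """
    opt = options or PreprocessOptions()
    vals, ok = combine_eyes(raw.diameter, raw.valid)
    keep = reject_artifacts(vals, ok, rule=opt.artifact_rule)
    n_trials, n_raw = vals.shape

    loss = 1.0 - keep.sum(axis=1) / n_raw
    excluded = loss > opt.loss_threshold
    traces = _interp_block(vals, keep, raw.times)
    clean = CleanSession(raw.subject_id, traces, excluded, loss)
    qc = {
        "subject_id": raw.subject_id,
        "n_trials": int(n_trials),
        "n_excluded": int(excluded.sum()),
        "excluded_fraction": float(excluded.mean()),
        "mean_loss_fraction": float(loss.mean()),
        "artifact_rule": opt.artifact_rule,
    }
    return clean, qc
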