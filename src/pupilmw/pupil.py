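"""Synthetic 30 Hz binocular pupil recordings in millimetres.

The trace is additive: a subject baseline, minus an impulse-response
(gamma-family) constriction for every bar and word onset — word onsets drive
a larger constriction than the bars because the white text adds luminance —
plus a saturating dilation during mind-wandering episodes (linear ramp to the
episode's amplitude, sustained to the episode offset, symmetric ramp-down
after), plus AR(1) drift and white measurement noise per eye.  Blinks and
tracker dropouts mark samples invalid and depress the flanking samples, the
artifact shape the percentile-based cleaning stage is designed to catch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .design import SessionSchedule
from .states import LatentStateTrace


@dataclass(frozen=True)
class PupilGenParams:
    """Generative parameters for the pupil trace (all sizes in mm)."""

    baseline_mm: float = 4.0
    kernel_n: float = 10.1  # gamma shape of the pupillary impulse response
    kernel_tmax_s: float = 0.93  # response peak latency
    bar_constriction_mm: float = 0.10
    word_constriction_mm: float = 0.25  # word onsets constrict more than bars
    mw_ramp_s: float = 2.0  # dilation rise time at episode onset
    noise_sd_mm: float = 0.02  # stationary sd of the AR(1) drift, per eye
    white_sd_mm: float = 0.01  # white measurement noise, per eye
    ar1_coef: float = 0.97  # AR(1) coefficient at the 30 Hz sample rate
    blink_rate_per_min: float = 12.0
    blink_dur_s: float = 0.2
    dropout_rate_per_min: float = 1.2  # binocular tracking losses
    dropout_dur_s: float = 1.5
    flank_drop_mm: float = 1.5  # artifactual dip on samples flanking a loss
    flank_samples: int = 2
    sample_rate_hz: float = 30.0
    target_constriction_scale: float = 1.0  # vertical-bar amplitude multiplier
    mw_constriction_scale: float = 1.0  # light-response gain during MW

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.bar_constriction_mm < 0 or self.word_constriction_mm < 0:
            raise ValueError("constriction amplitudes must be non-negative")
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must lie in [0, 1)")


@dataclass
class RawPupilRecording:
    """Per-trial 30 Hz samples for both eyes of one session."""

    subject_id: str
    times: np.ndarray  # (60,) within-trial sample times, [0, 2)
    diameter: dict[str, np.ndarray] = field(default_factory=dict)  # eye -> (n_trials, 60)
    valid: dict[str, np.ndarray] = field(default_factory=dict)  # eye -> bool (n_trials, 60)

    @property
    def n_trials(self) -> int:
        return next(iter(self.diameter.values())).shape[0]

    @property
    def eyes(self) -> list[str]:
        return list(self.diameter)


def pupil_kernel(t, params: PupilGenParams | None = None) -> np.ndarray:
    """Pupillary impulse response, unit peak at ``kernel_tmax_s``.

    h(t) = (t / tmax)^n * exp(n * (1 - t / tmax)); h(0) = 0 and the single
    interior maximum sits exactly at t = tmax.
    """
    p = params or PupilGenParams()
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("pupil_kernel is defined for t >= 0 only")
    ratio = t / p.kernel_tmax_s
    with np.errstate(divide="ignore"):
        logh = np.where(ratio > 0, p.kernel_n * (np.log(ratio) + 1.0 - ratio), -np.inf)
    return np.exp(logh, where=np.isfinite(logh), out=np.zeros_like(logh))


def _mw_dilation_series(
    t: np.ndarray, latent: LatentStateTrace, trial_dur: float, ramp_s: float
) -> np.ndarray:
    """Sustained dilation: ramp up over ``ramp_s`` from episode onset, hold
    to the episode offset, symmetric ramp-down after."""
    out = np.zeros_like(t)
    for ep in latent.episodes:
        t0 = ep.onset_trial * trial_dur
        t1 = (ep.offset_trial + 1) * trial_dur
        up = np.clip((t - t0) / ramp_s, 0.0, 1.0) if ramp_s > 0 else (t >= t0).astype(float)
        down = np.clip((t - t1) / ramp_s, 0.0, 1.0) if ramp_s > 0 else (t >= t1).astype(float)
        out += ep.dilation_amplitude * (up - down)
    return out


def _place_losses(
    rng: np.random.Generator,
    valid: np.ndarray,
    values: np.ndarray,
    n_events: int,
    dur_samples: int,
    flank: int,
    flank_drop: float,
) -> None:
    """Mark loss windows invalid and depress the flanking valid samples."""
    n = valid.shape[-1]
    if n_events <= 0:
        return
    starts = rng.integers(0, max(1, n - dur_samples), size=n_events)
    for s in np.sort(starts):
        e = min(n, s + dur_samples)
        valid[..., s:e] = False
        for fs, fe in (((s - flank), s), (e, e + flank)):
            fs, fe = max(0, fs), min(n, fe)
            if fe > fs:
                drop = flank_drop * rng.uniform(0.6, 1.0)
                values[..., fs:fe] -= drop


def generate_pupil_recording(
    schedule: SessionSchedule,
    latent: LatentStateTrace,
    params: PupilGenParams | None = None,
    seed: int = 0,
) -> RawPupilRecording:
    """Synthesize the binocular 30 Hz recording for one session.

    Both eyes share the stimulus-driven signal and the MW dilation;
    AR(1) + white noise are drawn independently per eye.  Blinks and
    dropouts are binocular (shared validity), as produced by a real
    head-fixed tracker.
    """
    p = params or PupilGenParams()
    if len(latent.state_per_trial) != schedule.n_trials:
        raise ValueError("schedule and latent trace cover different trial counts")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB0B1]))

    fs = p.sample_rate_hz
    spt = int(round(2.0 * fs))  # samples per trial
    n_trials = schedule.n_trials
    n = n_trials * spt
    # bin-centred sample times: the 33 ms integration window of a 30 Hz
    # tracker is stamped at its centre, so samples bracket the 20 Hz grid
    t = (np.arange(n) + 0.5) / fs

    # stimulus-driven constriction: one impulse per trial onset
    amps = np.zeros(n)
    for tr in schedule.trials:
        a = p.bar_constriction_mm
        if tr.stimulus == "vertical":
            a *= p.target_constriction_scale
        if tr.cue is not None:
            a += p.word_constriction_mm
        if p.mw_constriction_scale != 1.0 and latent.state_per_trial[tr.index] in (
            "mw_spontaneous",
            "mw_intentional",
        ):
            a *= p.mw_constriction_scale
        amps[tr.index * spt] = a
    kern_t = np.arange(int(round(4.0 * fs))) / fs
    kern = pupil_kernel(kern_t, p)
    constriction = np.convolve(amps, kern)[:n]

    signal = p.baseline_mm - constriction + _mw_dilation_series(t, latent, 2.0, p.mw_ramp_s)

    minutes = n / fs / 60.0
    n_blinks = rng.poisson(p.blink_rate_per_min * minutes)
    n_drops = rng.poisson(p.dropout_rate_per_min * minutes)

    rec = RawPupilRecording(
        subject_id=schedule.subject_id, times=(np.arange(spt) + 0.5) / fs
    )
    shared_valid = np.ones(n, dtype=bool)
    shared_dip = np.zeros(n)
    _place_losses(
        rng, shared_valid, shared_dip, n_blinks,
        max(1, int(round(p.blink_dur_s * fs))), p.flank_samples, p.flank_drop_mm,
    )
    _place_losses(
        rng, shared_valid, shared_dip, n_drops,
        max(1, int(round(p.dropout_dur_s * fs))), p.flank_samples, p.flank_drop_mm,
    )

    for eye in ("L", "R"):
        if p.noise_sd_mm > 0:
            innov_sd = p.noise_sd_mm * np.sqrt(1.0 - p.ar1_coef**2)
            drift = lfilter([1.0], [1.0, -p.ar1_coef], rng.normal(0.0, innov_sd, size=n))
        else:
            drift = 0.0
        white = rng.normal(0.0, p.white_sd_mm, size=n) if p.white_sd_mm > 0 else 0.0
        vals = signal + drift + white + shared_dip
        np.clip(vals, 0.2, None, out=vals)
        rec.diameter[eye] = vals.reshape(n_trials, spt)
        rec.valid[eye] = shared_valid.copy().reshape(n_trials, spt)
    return rec
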