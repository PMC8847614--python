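"""Synthetic eye-tracking sessions with ground-truth event labels.

Generates complete sessions (gaze + pupil at the tracker's sample rate,
per-trial event metadata, hidden ground truth) whose statistical
structure matches the study conditions: 34 subjects x 160 trials,
four surprise levels, a 1900-ms foreperiod, bimodal anticipatory-saccade
latencies, condition-wise visually-guided latency and peak-velocity
means, condition-specific foreperiod pupil dilation, blinks and
fixational gaze noise.

Conventions
-----------
* Saccade "onset" in the ground truth is the time at which the analytic
  velocity profile crosses the 22 deg/s detection criterion -- the same
  convention a velocity-threshold detector (and the tracker used in the
  study) reports.  The waveform's motion start is earlier by a
  closed-form offset.
* Configured condition means are means of the *measured* quantities:
  the generator solves for the pre-truncation location of the
  visually-guided latency distribution so that the post-truncation mean
  equals the configured mean.
* Gaze noise is slow fixational drift (AR(1), ~1 s time constant) plus
  a small white tracker jitter; white noise of the full 0.1 deg sd
  would swamp a 22 deg/s velocity criterion at 500 Hz.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal, stats
from scipy.optimize import brentq

from gazesurprise.task import (
    CONDITIONS,
    Condition,
    CueLayout,
    ScreenGeometry,
    TrialSchedule,
    draw_trial,
)

#: Velocity criterion of the downstream detector (deg/s); waveform
#: synthesis refuses peaks at or below it (they would be undetectable).
VELOCITY_CRITERION = 22.0

#: Trace span relative to the trial clock (cue onset = 0).
TRACE_START_MS = -500.0
RESPONSE_WINDOW_MS = 1200.0


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic-session generator.

    Defaults are the condition parameters of the study: latency and
    peak-velocity means per surprise level, their subject/residual
    variance components, the pooled anticipatory incidence with
    per-condition incidence-rate ratios, the foreperiod pupil plateau
    per condition, and the bimodal anticipatory latency structure.
    """

    n_subjects: int = 34
    trials_per_condition: int = 40
    sample_rate: float = 500.0

    # visually-guided saccades
    latency_mean_by_condition: tuple[float, ...] = (215.8, 233.5, 244.8, 247.8)
    latency_subject_sd: float = math.sqrt(1621.30)      # ms
    latency_residual_sd: float = math.sqrt(2939.17)     # ms
    latency_floor_ms: float = 100.0
    peak_velocity_mean_by_condition: tuple[float, ...] = (402.8, 385.6, 384.5, 382.2)
    velocity_subject_sd: float = math.sqrt(4148.97)     # deg/s
    velocity_residual_sd: float = math.sqrt(4467.71)    # deg/s

    # anticipatory saccades
    anticipatory_rate_overall: float = 0.055
    anticipatory_irr_by_condition: tuple[float, ...] = (1.0, 1 / 3.91, 1 / 5.50, 1 / 5.82)
    anticipatory_early_weight: float = 32.0 / 182.0     # mode counts 32 : 150
    anticipatory_early_window_ms: tuple[float, float] = (0.0, 500.0)
    anticipatory_late_window_ms: tuple[float, float] = (1000.0, 1900.0)
    anticipatory_amp_mean_early: float = 11.7           # deg
    anticipatory_amp_mean_late: float = 12.9            # deg
    anticipatory_amp_sd_early: float = 2.8              # deg (95% CI width, n=32)
    anticipatory_amp_sd_late: float = 2.9               # deg (95% CI width, n=150)

    # pupil
    pupil_baseline_mm: float = 4.0
    pupil_baseline_subject_sd: float = 0.5              # mm, removed by baseline correction
    pupil_fp_effect_by_condition: tuple[float, ...] = (0.24, 0.08, 0.09, 0.05)
    pupil_subject_effect_sd: float = 0.10               # mm, shared FP dilation
    pupil_noise_sd: float = 0.5                         # mm, stationary AR(1) sd
    pupil_noise_rho: float = 0.995                      # per-sample at 500 Hz
    pupil_ramp_start_ms: float = 500.0                  # after WS offset
    pupil_ramp_end_ms: float = 800.0

    # blinks and gaze noise
    blink_rate: float = 0.1                             # events/s
    blink_duration_range_ms: tuple[float, float] = (100.0, 300.0)
    gaze_noise_sd: float = 0.1                          # deg, drift sd per axis
    gaze_drift_tau_ms: float = 1000.0
    gaze_jitter_sd: float = 0.01                        # deg, white

    # memory control task
    memory_trials_per_mi: int = 5
    memory_accuracy_by_mi: tuple[float, ...] = (0.982, 0.965, 0.929, 0.982)
    memory_subject_sd: float = math.sqrt(2.79)          # logit scale

    bright_cue: bool = False                            # metadata flag only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.n_subjects < 1 or self.trials_per_condition < 1:
            raise ValueError("cohort sizes must be positive")
        for name in ("latency_subject_sd", "latency_residual_sd",
                     "velocity_subject_sd", "velocity_residual_sd",
                     "pupil_noise_sd", "blink_rate", "gaze_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(m < 100.0 for m in self.latency_mean_by_condition):
            raise ValueError("latency means must be >= 100 ms")
        irr = self.anticipatory_irr_by_condition
        if irr[0] != 1.0 or any(not (0.0 < r <= 1.0) for r in irr):
            raise ValueError("anticipatory relative rates must be in (0, 1] with SU1 == 1")
        if not (0.0 <= self.anticipatory_rate_overall < 1.0):
            raise ValueError("anticipatory_rate_overall must be in [0, 1)")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sample_rate

    def anticipatory_rate_by_condition(self) -> tuple[float, ...]:
        """Per-condition anticipatory probabilities from the pooled rate and IRRs.

        With balanced conditions the pooled rate is the mean of the four
        per-condition rates ``r_k = r_1 * irr_k``, so
        ``r_1 = 4 * pooled / sum(irr)``.
        """
        s = sum(self.anticipatory_irr_by_condition)
        r1 = len(self.anticipatory_irr_by_condition) * self.anticipatory_rate_overall / s
        return tuple(r1 * r for r in self.anticipatory_irr_by_condition)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)


# --------------------------------------------------------------------------
# saccade waveform
# --------------------------------------------------------------------------

def _velocity_crossing_offset(peak_velocity: float, duration_ms: float,
                              criterion: float = VELOCITY_CRITERION) -> float:
    """Time from motion start to the criterion crossing of a raised-cosine profile."""
    c = 1.0 - 2.0 * criterion / peak_velocity
    return duration_ms / (2.0 * math.pi) * math.acos(c)


@dataclass(frozen=True)
class SaccadeWaveform:
    """A raised-cosine-velocity saccade in closed form.

    The velocity profile is ``v(t) = Vp/2 * (1 - cos(2*pi*t/D))`` over
    the movement duration ``D = 2*A/Vp`` (mean speed of a raised cosine
    is half its peak, which forces the duration).  Displacement is the
    exact integral, so the end-to-end amplitude equals ``A`` to machine
    precision.
    """

    amplitude: float                 # deg
    direction: tuple[float, float]   # unit vector
    peak_velocity: float             # deg/s
    start_ms: float                  # motion start

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.peak_velocity <= VELOCITY_CRITERION:
            raise ValueError(
                "peak velocity must exceed the 22 deg/s detection criterion")
        n = math.hypot(*self.direction)
        if not math.isclose(n, 1.0, rel_tol=1e-9):
            object.__setattr__(self, "direction",
                               (self.direction[0] / n, self.direction[1] / n))

    @property
    def duration_ms(self) -> float:
        return 2.0 * self.amplitude / self.peak_velocity * 1000.0

    @property
    def crossing_offset_ms(self) -> float:
        """Motion start -> 22 deg/s crossing delay."""
        return _velocity_crossing_offset(self.peak_velocity, self.duration_ms)

    @property
    def onset_ms(self) -> float:
        """Detector-convention onset: the 22 deg/s velocity crossing."""
        return self.start_ms + self.crossing_offset_ms

    @property
    def offset_ms(self) -> float:
        """Detector-convention offset: the downward 22 deg/s crossing."""
        return self.start_ms + self.duration_ms - self.crossing_offset_ms

    def path_length(self, t_ms: np.ndarray) -> np.ndarray:
        """Scalar displacement along the saccade direction at times ``t_ms``."""
        t = np.asarray(t_ms, dtype=float) - self.start_ms
        d = self.duration_ms
        u = np.clip(t, 0.0, d)
        vp = self.peak_velocity / 1000.0  # deg/ms
        return vp / 2.0 * (u - d / (2.0 * math.pi) * np.sin(2.0 * math.pi * u / d))

    def displacement(self, t_ms: np.ndarray) -> np.ndarray:
        """(n, 2) displacement vectors at times ``t_ms``."""
        s = self.path_length(t_ms)
        return s[:, None] * np.asarray(self.direction)[None, :]


def synthesize_saccade_waveform(
    amplitude: float,
    direction: tuple[float, float],
    peak_velocity: float,
    onset_ms: float,
    sample_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a raised-cosine saccade displacement time series.

    Parameters
    ----------
    amplitude : float
        Saccade amplitude in deg (> 0).
    direction : (float, float)
        Movement direction (normalised internally).
    peak_velocity : float
        Peak velocity in deg/s; must exceed the 22 deg/s detection
        criterion, otherwise the event would be undetectable by design.
    onset_ms : float
        Motion start on the trial clock.
    sample_rate : float
        Samples per second.

    Returns
    -------
    t : ndarray
        Sample times (ms) covering the movement.
    xy : ndarray, shape (n, 2)
        Displacement from the pre-saccade position at each sample.
    """
    wf = SaccadeWaveform(amplitude=amplitude, direction=tuple(direction),
                         peak_velocity=peak_velocity, start_ms=onset_ms)
    dt = 1000.0 / sample_rate
    n = int(math.ceil(wf.duration_ms / dt)) + 1
    t = onset_ms + np.arange(n) * dt
    return t, wf.displacement(t)


# --------------------------------------------------------------------------
# latency truncation correction
# --------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(41)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def _truncnorm_mean(loc: np.ndarray, scale: float, lower: float) -> np.ndarray:
    a = (lower - loc) / scale
    phi = stats.norm.pdf(a)
    tail = stats.norm.sf(a)
    return loc + scale * phi / np.maximum(tail, 1e-300)


@lru_cache(maxsize=32)
def _solve_latency_location(target_mean: float, subject_sd: float,
                            residual_sd: float, floor: float) -> float:
    """Pre-truncation latency location whose post-truncation mean is ``target_mean``.

    Truncation at the classification floor acts per trial on
    ``location + subject_intercept + residual``; the marginal mean over
    subjects is integrated with Gauss-Hermite quadrature.
    """
    b = _GH_NODES * subject_sd

    def marginal_mean(mu: float) -> float:
        return float(np.sum(_GH_WEIGHTS * _truncnorm_mean(mu + b, residual_sd, floor)))

    f = lambda mu: marginal_mean(mu) - target_mean
    lo, hi = target_mean - 6.0 * residual_sd, target_mean + residual_sd
    return brentq(f, lo, hi, xtol=1e-9)


# --------------------------------------------------------------------------
# noise processes
# --------------------------------------------------------------------------

def _ar1(n: int, sd: float, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) series of length ``n`` with marginal sd ``sd``."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    innov = rng.standard_normal(n) * sd * math.sqrt(1.0 - rho * rho)
    x0 = rng.standard_normal() * sd
    out, _ = signal.lfilter([1.0], [1.0, -rho], innov, zi=[rho * x0])
    return out


def _gaze_noise(n: int, cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """(n, 2) fixational drift + tracker jitter."""
    rho = math.exp(-cfg.dt_ms / cfg.gaze_drift_tau_ms)
    out = np.empty((n, 2))
    for k in range(2):
        out[:, k] = _ar1(n, cfg.gaze_noise_sd, rho, rng)
        if cfg.gaze_jitter_sd > 0:
            out[:, k] += rng.standard_normal(n) * cfg.gaze_jitter_sd
    return out


# --------------------------------------------------------------------------
# pupil trace
# --------------------------------------------------------------------------

def _transient(t_ms: np.ndarray, onset: float, amp: float,
               duration: float) -> np.ndarray:
    """Compactly supported pupil transient: a raised-cosine bump.

    Peaks ``duration/2`` ms after ``onset`` and is exactly zero outside
    [onset, onset + duration], so luminance responses do not bleed into
    the baseline or analysis windows.
    """
    u = (np.asarray(t_ms, float) - onset) / duration
    out = np.zeros_like(u)
    inside = (u > 0.0) & (u < 1.0)
    out[inside] = amp * np.sin(np.pi * u[inside]) ** 2
    return out


def synthesize_pupil_trace(
    t_ms: np.ndarray,
    schedule: TrialSchedule,
    effect_mm: float,
    baseline_mm: float,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pupil diameter (mm) over a trial.

    Baseline plus AR(1) noise, a condition-independent luminance
    transient after cue onset and after the warning stimulus, and the
    condition effect ramping in from ``pupil_ramp_start_ms`` after WS
    offset to its plateau at ``pupil_ramp_end_ms``, held through the
    imperative stimulus.

    Parameters
    ----------
    effect_mm : float
        Plateau dilation of this trial's condition (plus any subject
        dilation intercept), reached over the 800-1900 ms foreperiod
        window.
    """
    t = np.asarray(t_ms, dtype=float)
    p = np.full(t.shape, baseline_mm)
    # luminance transients: biphasic cue response, WS flash response
    # (the latter starts at WS offset -- the pupil light reflex lags the
    # 50-ms flash -- and dies out 550 ms later, before the analysis window)
    p += _transient(t, schedule.cue_onset, -0.30, 800.0)
    p += _transient(t, schedule.cue_onset + 300.0, 0.10, 1500.0)
    p += _transient(t, schedule.ws_offset, -0.15, 550.0)
    # condition effect: linear ramp then plateau
    ramp0 = schedule.ws_offset + cfg.pupil_ramp_start_ms
    ramp1 = schedule.ws_offset + cfg.pupil_ramp_end_ms
    frac = np.clip((t - ramp0) / (ramp1 - ramp0), 0.0, 1.0)
    p += effect_mm * frac
    p += _ar1(len(t), cfg.pupil_noise_sd, cfg.pupil_noise_rho, rng)
    return p


# --------------------------------------------------------------------------
# blinks
# --------------------------------------------------------------------------

def inject_blinks(
    t_ms: np.ndarray,
    valid: np.ndarray,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    """Mark blink gaps invalid; returns the (start, end) spans in ms.

    Blink onsets are a Poisson process at ``blink_rate`` events/s;
    each gap lasts uniformly 100-300 ms.  All samples strictly inside
    a span are flagged invalid in ``valid`` (in place).
    """
    if cfg.blink_rate <= 0:
        return []
    span_s = (t_ms[-1] - t_ms[0]) / 1000.0
    n_blinks = rng.poisson(cfg.blink_rate * span_s)
    blinks: list[tuple[float, float]] = []
    lo, hi = cfg.blink_duration_range_ms
    for _ in range(n_blinks):
        start = rng.uniform(t_ms[0], t_ms[-1])
        dur = rng.uniform(lo, hi)
        end = min(start + dur, t_ms[-1])
        valid[(t_ms >= start) & (t_ms <= end)] = False
        blinks.append((float(start), float(end)))
    blinks.sort()
    return blinks


# --------------------------------------------------------------------------
# trial and session generation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectEffects:
    """Random intercepts of one subject, shared across that subject's trials."""

    latency: float       # ms
    velocity: float      # deg/s
    pupil_baseline: float  # mm
    pupil_dilation: float  # mm
    memory_logit: float


def draw_subject_effects(cfg: GeneratorConfig,
                         rng: np.random.Generator) -> SubjectEffects:
    return SubjectEffects(
        latency=rng.standard_normal() * cfg.latency_subject_sd,
        velocity=rng.standard_normal() * cfg.velocity_subject_sd,
        pupil_baseline=rng.standard_normal() * cfg.pupil_baseline_subject_sd,
        pupil_dilation=rng.standard_normal() * cfg.pupil_subject_effect_sd,
        memory_logit=rng.standard_normal() * cfg.memory_subject_sd,
    )


def _draw_anticipatory_onset(cfg: GeneratorConfig,
                             rng: np.random.Generator) -> tuple[str, float]:
    """Draw (mode, foreperiod-relative onset ms) from the bimodal mixture.

    Early mode: uniform over the first 500 ms of the foreperiod
    (impulsive responses to WS extinction).  Late mode: linearly
    increasing density over 1000-1900 ms (rising temporal expectation
    of the imperative stimulus).
    """
    if rng.random() < cfg.anticipatory_early_weight:
        lo, hi = cfg.anticipatory_early_window_ms
        return "early", float(rng.uniform(lo, hi))
    lo, hi = cfg.anticipatory_late_window_ms
    return "late", float(lo + (hi - lo) * math.sqrt(rng.random()))


@dataclass
class TrialData:
    """One generated trial: samples, schedule, cue layout and hidden truth."""

    trial_id: int
    condition: Condition
    layout: CueLayout
    schedule: TrialSchedule
    t_ms: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    pupil_mm: np.ndarray
    valid: np.ndarray
    ground_truth: dict


def _draw_peak_velocity(cfg: GeneratorConfig, cond_idx: int,
                        effects: SubjectEffects,
                        rng: np.random.Generator) -> float:
    v = (cfg.peak_velocity_mean_by_condition[cond_idx] + effects.velocity
         + rng.standard_normal() * cfg.velocity_residual_sd)
    return max(v, 100.0)


def generate_trial(
    cfg: GeneratorConfig,
    effects: SubjectEffects,
    condition: Condition,
    rng: np.random.Generator,
    trial_id: int = 0,
    geometry: ScreenGeometry | None = None,
) -> TrialData:
    """Generate one trial's gaze and pupil traces plus ground truth.

    With the condition's anticipatory probability the trial contains a
    single anticipatory saccade (onset from the bimodal foreperiod
    mixture, amplitude from the mode's distribution, aimed at a random
    cued box); otherwise it contains a single visually-guided saccade
    at IS onset + latency, aimed at the target box centre.
    """
    geometry = geometry or ScreenGeometry()
    cond_idx = condition.n_cued - 1
    schedule = TrialSchedule.standard(iti_duration=rng.uniform(2000.0, 2500.0))
    layout = draw_trial(condition, rng)

    dt = cfg.dt_ms
    t_end = schedule.is_onset + RESPONSE_WINDOW_MS
    n = int(round((t_end - TRACE_START_MS) / dt))
    t = TRACE_START_MS + np.arange(n) * dt

    gaze = _gaze_noise(n, cfg, rng)

    rates = cfg.anticipatory_rate_by_condition()
    saccades: list[dict] = []
    if rng.random() < rates[cond_idx]:
        mode, fp_onset = _draw_anticipatory_onset(cfg, rng)
        if mode == "early":
            amp = rng.standard_normal() * cfg.anticipatory_amp_sd_early \
                + cfg.anticipatory_amp_mean_early
        else:
            amp = rng.standard_normal() * cfg.anticipatory_amp_sd_late \
                + cfg.anticipatory_amp_mean_late
        amp = float(np.clip(amp, 2.0, 20.0))
        goal_idx = sorted(layout.cued_box_indices)[
            rng.integers(len(layout.cued_box_indices))]
        gx, gy = geometry.box_centers[goal_idx]
        norm = math.hypot(gx, gy)
        direction = (gx / norm, gy / norm)
        vp = _draw_peak_velocity(cfg, cond_idx, effects, rng)
        crossing = schedule.ws_offset + fp_onset
        wf = SaccadeWaveform(amplitude=amp, direction=direction,
                             peak_velocity=vp, start_ms=0.0)
        wf = SaccadeWaveform(amplitude=amp, direction=direction,
                             peak_velocity=vp,
                             start_ms=crossing - wf.crossing_offset_ms)
        gaze += wf.displacement(t)
        saccades.append({
            "klass": "anticipatory",
            "mode": mode,
            "onset_ms": wf.onset_ms,
            "offset_ms": wf.offset_ms,
            "motion_start_ms": wf.start_ms,
            "amplitude": amp,
            "peak_velocity": vp,
            "latency_re_is": wf.onset_ms - schedule.is_onset,
            "goal_box": int(goal_idx),
        })
    else:
        loc = _solve_latency_location(
            cfg.latency_mean_by_condition[cond_idx],
            cfg.latency_subject_sd, cfg.latency_residual_sd,
            cfg.latency_floor_ms)
        mu = loc + effects.latency
        a = (cfg.latency_floor_ms - mu) / cfg.latency_residual_sd
        b = (RESPONSE_WINDOW_MS - 50.0 - mu) / cfg.latency_residual_sd
        latency = float(stats.truncnorm.rvs(
            a, b, loc=mu, scale=cfg.latency_residual_sd, random_state=rng))
        tx, ty = geometry.box_centers[layout.target_box_index]
        amp = math.hypot(tx, ty)
        direction = (tx / amp, ty / amp)
        vp = _draw_peak_velocity(cfg, cond_idx, effects, rng)
        crossing = schedule.is_onset + latency
        probe = SaccadeWaveform(amplitude=amp, direction=direction,
                                peak_velocity=vp, start_ms=0.0)
        wf = SaccadeWaveform(amplitude=amp, direction=direction,
                             peak_velocity=vp,
                             start_ms=crossing - probe.crossing_offset_ms)
        gaze += wf.displacement(t)
        saccades.append({
            "klass": "visually_guided",
            "mode": "n/a",
            "onset_ms": wf.onset_ms,
            "offset_ms": wf.offset_ms,
            "motion_start_ms": wf.start_ms,
            "amplitude": amp,
            "peak_velocity": vp,
            "latency_re_is": latency,
            "goal_box": int(layout.target_box_index),
        })

    pupil = synthesize_pupil_trace(
        t, schedule,
        effect_mm=cfg.pupil_fp_effect_by_condition[cond_idx] + effects.pupil_dilation,
        baseline_mm=cfg.pupil_baseline_mm + effects.pupil_baseline,
        cfg=cfg, rng=rng)

    valid = np.ones(n, dtype=bool)
    blinks = inject_blinks(t, valid, cfg, rng)
    x = gaze[:, 0].copy()
    y = gaze[:, 1].copy()
    p = pupil.copy()
    x[~valid] = np.nan
    y[~valid] = np.nan
    p[~valid] = np.nan

    return TrialData(
        trial_id=trial_id, condition=condition, layout=layout,
        schedule=schedule, t_ms=t, x_deg=x, y_deg=y, pupil_mm=p, valid=valid,
        ground_truth={
            "trial_id": trial_id,
            "condition": condition.n_cued,
            "saccades": saccades,
            "blinks": [list(b) for b in blinks],
        },
    )


@dataclass
class SubjectSession:
    """All trials of one synthetic subject."""

    subject_id: str
    effects: SubjectEffects
    trials: list[TrialData]

    def samples_frame(self) -> pd.DataFrame:
        frames = []
        for tr in self.trials:
            frames.append(pd.DataFrame({
                "trial_id": np.full(len(tr.t_ms), tr.trial_id, dtype=np.int32),
                "t_ms": tr.t_ms,
                "x_deg": tr.x_deg,
                "y_deg": tr.y_deg,
                "pupil_mm": tr.pupil_mm,
                "valid": tr.valid,
            }))
        return pd.concat(frames, ignore_index=True)

    def events(self) -> list[dict]:
        return [{
            "trial_id": tr.trial_id,
            "n_cued": tr.condition.n_cued,
            "cued_box_indices": sorted(tr.layout.cued_box_indices),
            "target_box_index": tr.layout.target_box_index,
            "schedule": tr.schedule.to_dict(),
        } for tr in self.trials]

    def ground_truth(self) -> list[dict]:
        return [tr.ground_truth for tr in self.trials]


@dataclass
class SyntheticSession:
    """A full synthetic cohort."""

    config: GeneratorConfig
    subjects: list[SubjectSession]


def _subject_rng(cfg: GeneratorConfig, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(subject_index,)))


def generate_subject(cfg: GeneratorConfig, subject_index: int,
                     geometry: ScreenGeometry | None = None) -> SubjectSession:
    """Generate one subject's session (deterministic given config.seed)."""
    rng = _subject_rng(cfg, subject_index)
    effects = draw_subject_effects(cfg, rng)
    cond_seq = np.repeat(np.arange(4), cfg.trials_per_condition)
    rng.shuffle(cond_seq)
    trials = [
        generate_trial(cfg, effects, CONDITIONS[c], rng,
                       trial_id=i, geometry=geometry)
        for i, c in enumerate(cond_seq)
    ]
    return SubjectSession(subject_id=f"sub-{subject_index:02d}",
                          effects=effects, trials=trials)


def generate_session(cfg: GeneratorConfig,
                     geometry: ScreenGeometry | None = None) -> SyntheticSession:
    """Generate the full cohort; bit-identical under a fixed seed."""
    subjects = [generate_subject(cfg, i, geometry)
                for i in range(cfg.n_subjects)]
    return SyntheticSession(config=cfg, subjects=subjects)


def generate_memory_task(cfg: GeneratorConfig) -> pd.DataFrame:
    """Synthetic spatial working-memory control task.

    Each subject performs ``memory_trials_per_mi`` trials per memory
    load (1-4 cued locations to recall); per-load accuracies default to
    the study's values.  Subject heterogeneity enters as a logit-scale
    random intercept.

    Returns a tidy frame with columns subject, mi, correct.
    """
    rows = []
    base_logit = [math.log(a / (1.0 - a)) for a in cfg.memory_accuracy_by_mi]
    for i in range(cfg.n_subjects):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1, i)))
        b = rng.standard_normal() * cfg.memory_subject_sd
        for mi in range(1, 5):
            p = 1.0 / (1.0 + math.exp(-(base_logit[mi - 1] + b)))
            correct = rng.random(cfg.memory_trials_per_mi) < p
            for c in correct:
                rows.append((f"sub-{i:02d}", mi, int(c)))
    return pd.DataFrame(rows, columns=["subject", "mi", "correct"])


def generate_foreperiod_pupil(
    cfg: GeneratorConfig,
    conditions: tuple[int, ...] = (1, 2, 3, 4),
    seed_offset: int = 0,
) -> pd.DataFrame:
    """Fast path: foreperiod pupil epochs only (no gaze traces).

    Generates per-trial pupil samples from 100 ms before WS offset to
    IS onset, with the same noise, subject-effect, blink and condition
    structure as the full trials.  Used by permutation-test power and
    calibration studies where full sessions would be wasteful.

    Returns a tidy frame: subject, trial, condition, t_ms (epoch clock,
    0 = WS offset), pupil_mm, valid.
    """
    schedule = TrialSchedule.standard()
    dt = cfg.dt_ms
    t_abs = np.arange(schedule.ws_offset - 100.0, schedule.is_onset, dt)
    frames = []
    trial_counter = 0
    for i in range(cfg.n_subjects):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(2, seed_offset, i)))
        effects = draw_subject_effects(cfg, rng)
        for n_cued in conditions:
            for _ in range(cfg.trials_per_condition):
                pupil = synthesize_pupil_trace(
                    t_abs, schedule,
                    effect_mm=cfg.pupil_fp_effect_by_condition[n_cued - 1]
                    + effects.pupil_dilation,
                    baseline_mm=cfg.pupil_baseline_mm + effects.pupil_baseline,
                    cfg=cfg, rng=rng)
                valid = np.ones(len(t_abs), dtype=bool)
                inject_blinks(t_abs, valid, cfg, rng)
                p = pupil.copy()
                p[~valid] = np.nan
                frames.append(pd.DataFrame({
                    "subject": f"sub-{i:02d}",
                    "trial": trial_counter,
                    "condition": n_cued,
                    "t_ms": t_abs - schedule.ws_offset,
                    "pupil_mm": p,
                    "valid": valid,
                }))
                trial_counter += 1
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# disk format
# --------------------------------------------------------------------------

def write_session(session: SyntheticSession, out_dir: str | Path,
                  include_ground_truth: bool = True) -> None:
    """Write a session to disk: per-subject samples.csv + events.json.

    Ground truth goes to a separate ground_truth.json so the analysis
    pipeline can be run blind to it.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(
        json.dumps(session.config.to_dict(), indent=1, sort_keys=True))
    for subj in session.subjects:
        d = out / subj.subject_id
        d.mkdir(exist_ok=True)
        subj.samples_frame().to_csv(d / "samples.csv", index=False)
        (d / "events.json").write_text(json.dumps(subj.events(), indent=1))
        if include_ground_truth:
            (d / "ground_truth.json").write_text(
                json.dumps(subj.ground_truth(), indent=1))


def read_subject(subject_dir: str | Path) -> tuple[pd.DataFrame, list[dict]]:
    """Read one subject's samples and events from disk."""
    d = Path(subject_dir)
    samples = pd.read_csv(d / "samples.csv")
    events = json.loads((d / "events.json").read_text())
    return samples, events
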