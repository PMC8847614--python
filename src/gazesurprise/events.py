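"""Saccade detection, classification and trial exclusion.

Detection follows the velocity/acceleration criterion pair used in the
study (22 deg/s and 3800 deg/s^2, OR-combined), with event boundaries
taken at the surrounding 22 deg/s velocity crossings.  Detected
saccades are classified by their onset relative to the warning-stimulus
(WS) offset and imperative-stimulus (IS) onset:

* anticipatory -- onset after WS offset and earlier than 100 ms after
  IS onset;
* visually guided -- latency re IS onset in [100, 1000] ms;
* everything else (cue-epoch movements, latencies > 1000 ms) is flagged
  excluded.

Trial-level exclusions for the visually-guided analyses: latency
> 1000 ms, a visually-guided saccade executed after an anticipatory
one, or landing in the wrong target box.  Anticipatory saccades are
retained for the count analyses regardless.  An automated artifact
proxy flags trials with more than 20% invalid (blink) samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gazesurprise.task import ScreenGeometry, TrialSchedule

VELOCITY_THRESHOLD = 22.0        # deg/s
ACCELERATION_THRESHOLD = 3800.0  # deg/s^2
ANTICIPATORY_BOUNDARY_MS = 100.0
MAX_LATENCY_MS = 1000.0
MERGE_GAP_MS = 20.0
MIN_DURATION_MS = 6.0
SMOOTH_SAMPLES = 5
LANDING_WINDOW_MS = 50.0
ARTIFACT_INVALID_FRACTION = 0.20

EARLY_MODE_MS = (0.0, 500.0)     # foreperiod-relative onset of the early mode
LATE_MODE_MS = 1000.0            # beyond this: late mode


@dataclass
class KinematicSeries:
    """Speed and acceleration magnitudes derived from a gaze trace."""

    t_ms: np.ndarray
    speed: np.ndarray          # deg/s, >= 0 (NaN within blink gaps)
    acceleration: np.ndarray   # deg/s^2, signed rate of change of speed


@dataclass
class Saccade:
    """A detected saccadic event."""

    onset_ms: float
    offset_ms: float
    latency_re_is: float       # signed; negative = before IS onset
    amplitude: float           # deg, start -> end Euclidean distance
    peak_velocity: float       # deg/s
    landing: tuple[float, float] | None = None
    landing_box: int | None = None
    klass: str = "unclassified"
    anticipatory_mode: str = "n/a"
    in_analysis_epoch: bool = True


@dataclass
class TrialOutcome:
    """Per-trial result of detection, classification and exclusion."""

    trial_id: int
    kept: bool
    exclusion_reason: str      # none | late_latency | after_anticipatory |
                               # wrong_box | artifact | no_response
    saccades: list[Saccade] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.kept == (self.exclusion_reason == "none")


def compute_kinematics(t_ms: np.ndarray, x_deg: np.ndarray,
                       y_deg: np.ndarray) -> KinematicSeries:
    """Speed and acceleration from a uniformly sampled gaze trace.

    Position is smoothed with a 5-sample moving average, velocity is
    the central difference of the smoothed position (one-sided at the
    ends), speed its magnitude, and acceleration the central difference
    of speed.  Invalid (NaN) samples propagate to nearby kinematic
    samples, masking blink gaps from detection.
    """
    t = np.asarray(t_ms, dtype=float)
    if len(t) < SMOOTH_SAMPLES:
        raise ValueError("need at least 5 samples")
    dts = np.diff(t)
    if not np.allclose(dts, dts[0], rtol=0, atol=1e-6):
        raise ValueError("non-uniform sample timestamps")
    dt_s = dts[0] / 1000.0

    kern = np.ones(SMOOTH_SAMPLES) / SMOOTH_SAMPLES
    half = SMOOTH_SAMPLES // 2
    # edge-replicated padding: zero-padding would fabricate velocities at
    # the trace ends where gaze is far from the origin
    xs = np.convolve(np.pad(np.asarray(x_deg, float), half, mode="edge"),
                     kern, mode="valid")
    ys = np.convolve(np.pad(np.asarray(y_deg, float), half, mode="edge"),
                     kern, mode="valid")

    def _cdiff(v: np.ndarray) -> np.ndarray:
        out = np.empty_like(v)
        out[1:-1] = (v[2:] - v[:-2]) / (2.0 * dt_s)
        out[0] = (v[1] - v[0]) / dt_s
        out[-1] = (v[-1] - v[-2]) / dt_s
        return out

    vx, vy = _cdiff(xs), _cdiff(ys)
    speed = np.hypot(vx, vy)
    accel = _cdiff(speed)
    return KinematicSeries(t_ms=t, speed=speed, acceleration=accel)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, stop) index pairs of True runs."""
    if not mask.any():
        return []
    m = mask.astype(np.int8)
    d = np.diff(np.concatenate(([0], m, [0])))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), stops.tolist()))


def detect_saccades(kin: KinematicSeries, x_deg: np.ndarray,
                    y_deg: np.ndarray) -> list[Saccade]:
    """Detect saccades; returns unclassified events.

    Candidate samples exceed the velocity criterion (22 deg/s) OR the
    absolute acceleration criterion (3800 deg/s^2).  Each candidate run
    is extended to the surrounding 22 deg/s speed crossings, runs
    closer than 20 ms are merged, and events shorter than 6 ms are
    dropped.  Amplitude is the Euclidean start-to-end displacement and
    peak velocity the maximum in-event speed.  A fully masked (blink)
    trace yields an empty list.
    """
    speed, accel, t = kin.speed, kin.acceleration, kin.t_ms
    finite = np.isfinite(speed)
    above = finite & (speed > VELOCITY_THRESHOLD)
    cand = above | (finite & np.isfinite(accel)
                    & (np.abs(accel) > ACCELERATION_THRESHOLD))
    if not cand.any():
        return []

    n = len(t)
    spans: list[list[int]] = []
    for s0, s1 in _runs(cand):
        # extend to the surrounding velocity crossings
        while s0 > 0 and above[s0 - 1]:
            s0 -= 1
        while s1 < n - 1 and above[s1 + 1]:
            s1 += 1
        if spans and (t[s0] - t[spans[-1][1]]) < MERGE_GAP_MS:
            spans[-1][1] = max(spans[-1][1], s1)
        else:
            spans.append([s0, s1])

    out: list[Saccade] = []
    for s0, s1 in spans:
        if t[s1] - t[s0] < MIN_DURATION_MS:
            continue
        x0, y0 = _nearest_finite(x_deg, y_deg, s0, forward=True)
        x1, y1 = _nearest_finite(x_deg, y_deg, s1, forward=False)
        amp = float(np.hypot(x1 - x0, y1 - y0))
        pv = float(np.nanmax(speed[s0:s1 + 1]))
        out.append(Saccade(onset_ms=float(t[s0]), offset_ms=float(t[s1]),
                           latency_re_is=np.nan, amplitude=amp,
                           peak_velocity=pv))
    return out


def _nearest_finite(x: np.ndarray, y: np.ndarray, i: int,
                    forward: bool) -> tuple[float, float]:
    step = 1 if forward else -1
    j = i
    while 0 <= j < len(x):
        if np.isfinite(x[j]) and np.isfinite(y[j]):
            return float(x[j]), float(y[j])
        j += step
    return float("nan"), float("nan")


def classify_saccades(saccades: list[Saccade],
                      schedule: TrialSchedule) -> list[Saccade]:
    """Assign class and anticipatory mode from onset times (in place).

    Saccades with onset at or before WS offset belong to the cue/test
    epoch: they are flagged out of analysis and classed ``excluded``.
    """
    for s in saccades:
        s.latency_re_is = s.onset_ms - schedule.is_onset
        if s.onset_ms <= schedule.ws_offset:
            s.klass = "excluded"
            s.anticipatory_mode = "n/a"
            s.in_analysis_epoch = False
        elif s.latency_re_is < ANTICIPATORY_BOUNDARY_MS:
            s.klass = "anticipatory"
            fp_onset = s.onset_ms - schedule.ws_offset
            if EARLY_MODE_MS[0] <= fp_onset < EARLY_MODE_MS[1]:
                s.anticipatory_mode = "early"
            elif fp_onset > LATE_MODE_MS:
                s.anticipatory_mode = "late"
            else:
                s.anticipatory_mode = "intermediate"
        elif s.latency_re_is <= MAX_LATENCY_MS:
            s.klass = "visually_guided"
            s.anticipatory_mode = "n/a"
        else:
            s.klass = "excluded"
            s.anticipatory_mode = "n/a"
    return saccades


def assign_landing_box(saccade: Saccade, geometry: ScreenGeometry,
                       t_ms: np.ndarray, x_deg: np.ndarray,
                       y_deg: np.ndarray) -> int | None:
    """Landing position (mean gaze over 50 ms post-offset) and its box.

    Returns the index of the box whose rectangle contains the landing
    point, or None; also stores both on the saccade.
    """
    sel = (t_ms >= saccade.offset_ms) & (t_ms < saccade.offset_ms + LANDING_WINDOW_MS)
    if not sel.any():
        sel = t_ms >= saccade.offset_ms
    with np.errstate(invalid="ignore"):
        lx = float(np.nanmean(x_deg[sel])) if sel.any() else float("nan")
        ly = float(np.nanmean(y_deg[sel])) if sel.any() else float("nan")
    saccade.landing = (lx, ly)
    saccade.landing_box = (None if not np.isfinite(lx)
                           else geometry.box_at((lx, ly)))
    return saccade.landing_box


def apply_exclusions(trial_id: int, saccades: list[Saccade],
                     schedule: TrialSchedule, target_box: int,
                     artifact: bool = False) -> TrialOutcome:
    """Trial-level exclusion rules for the visually-guided analyses.

    A trial is kept only if it is artifact-free and its (first)
    visually-guided saccade has latency <= 1000 ms, is not preceded by
    an anticipatory saccade, and lands in the scheduled target box.
    Anticipatory saccades are retained in ``saccades`` regardless, for
    the count analyses.
    """
    if artifact:
        return TrialOutcome(trial_id, False, "artifact", saccades)
    anticipatory = [s for s in saccades if s.klass == "anticipatory"]
    vg = [s for s in saccades if s.klass == "visually_guided"]
    if anticipatory:
        return TrialOutcome(trial_id, False, "after_anticipatory", saccades)
    if not vg:
        late = [s for s in saccades
                if s.klass == "excluded" and s.in_analysis_epoch
                and s.latency_re_is > MAX_LATENCY_MS]
        reason = "late_latency" if late else "no_response"
        return TrialOutcome(trial_id, False, reason, saccades)
    first = min(vg, key=lambda s: s.onset_ms)
    if first.landing_box != target_box:
        return TrialOutcome(trial_id, False, "wrong_box", saccades)
    return TrialOutcome(trial_id, True, "none", saccades)


def process_trial(t_ms: np.ndarray, x_deg: np.ndarray, y_deg: np.ndarray,
                  valid: np.ndarray, schedule: TrialSchedule,
                  target_box: int, trial_id: int = 0,
                  geometry: ScreenGeometry | None = None) -> TrialOutcome:
    """Full per-trial chain: kinematics -> detect -> classify -> exclude."""
    geometry = geometry or ScreenGeometry()
    artifact = bool(np.mean(~np.asarray(valid, bool)) > ARTIFACT_INVALID_FRACTION)
    kin = compute_kinematics(t_ms, x_deg, y_deg)
    saccades = detect_saccades(kin, np.asarray(x_deg, float),
                               np.asarray(y_deg, float))
    classify_saccades(saccades, schedule)
    for s in saccades:
        assign_landing_box(s, geometry, np.asarray(t_ms, float),
                           np.asarray(x_deg, float), np.asarray(y_deg, float))
    return apply_exclusions(trial_id, saccades, schedule, target_box,
                            artifact=artifact)


def process_subject(samples: pd.DataFrame, events: list[dict],
                    subject_id: str = "sub-00",
                    geometry: ScreenGeometry | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the detection chain over one subject's session.

    Parameters
    ----------
    samples : DataFrame
        Columns trial_id, t_ms, x_deg, y_deg, pupil_mm, valid.
    events : list of dict
        Per-trial metadata (schedule, cue layout, target box) in the
        session format written by the generator.

    Returns
    -------
    saccades : DataFrame
        One row per detected saccade.
    trials : DataFrame
        One row per trial with the kept flag and exclusion reason.
    """
    geometry = geometry or ScreenGeometry()
    by_trial = dict(tuple(samples.groupby("trial_id", sort=True)))
    sacc_rows, trial_rows = [], []
    for ev in events:
        tid = ev["trial_id"]
        tr = by_trial[tid]
        schedule = TrialSchedule.from_dict(ev["schedule"])
        outcome = process_trial(
            tr["t_ms"].to_numpy(), tr["x_deg"].to_numpy(),
            tr["y_deg"].to_numpy(), tr["valid"].to_numpy(),
            schedule, ev["target_box_index"], trial_id=tid, geometry=geometry)
        n_anticipatory = sum(s.klass == "anticipatory" for s in outcome.saccades)
        vg = [s for s in outcome.saccades if s.klass == "visually_guided"]
        first_vg = min(vg, key=lambda s: s.onset_ms) if vg else None
        trial_rows.append({
            "subject": subject_id,
            "trial_id": tid,
            "condition": ev["n_cued"],
            "kept": outcome.kept,
            "exclusion_reason": outcome.exclusion_reason,
            "n_saccades": len(outcome.saccades),
            "n_anticipatory": n_anticipatory,
            "vg_latency": first_vg.latency_re_is if first_vg else np.nan,
            "vg_peak_velocity": first_vg.peak_velocity if first_vg else np.nan,
            "target_box": ev["target_box_index"],
        })
        for s in outcome.saccades:
            sacc_rows.append({
                "subject": subject_id,
                "trial_id": tid,
                "condition": ev["n_cued"],
                "onset_ms": s.onset_ms,
                "offset_ms": s.offset_ms,
                "latency_re_is": s.latency_re_is,
                "amplitude": s.amplitude,
                "peak_velocity": s.peak_velocity,
                "landing_x": s.landing[0] if s.landing else np.nan,
                "landing_y": s.landing[1] if s.landing else np.nan,
                "landing_box": -1 if s.landing_box is None else s.landing_box,
                "klass": s.klass,
                "anticipatory_mode": s.anticipatory_mode,
                "in_analysis_epoch": s.in_analysis_epoch,
            })
    saccades = pd.DataFrame(sacc_rows)
    trials = pd.DataFrame(trial_rows)
    return saccades, trials
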