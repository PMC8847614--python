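"""Pupillometric preprocessing.

The chain is order-fixed and deterministic: blink interpolation (linear,
bridging from 70 ms before each gap to 70 ms after), averaging into
50-ms bins, a 3-bin running median filter, subtractive baseline
correction against the 100 ms preceding epoch onset, and window
averaging (by default the 800-1900 ms foreperiod window, where the
surprise effect plateaus).

Two task epochs are defined: the cue period (2000 ms, epoch onset =
cue onset) and the foreperiod (1900 ms, epoch onset = WS offset).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from gazesurprise.task import TrialSchedule

BIN_MS = 50.0
BLINK_PAD_MS = 70.0
BASELINE_MS = 100.0
MEDIAN_KERNEL_BINS = 3
WINDOW_DEFAULT = (800.0, 1900.0)

EPOCH_SPANS_MS = {"cue": 2000.0, "foreperiod": 1900.0}


class EpochUnusable(ValueError):
    """Raised when an epoch has no usable pupil samples (all-blink, or
    a missing baseline window)."""


@dataclass
class PupilEpoch:
    """Raw pupil samples of one trial epoch plus its baseline window."""

    trial_id: int
    epoch: str                # "cue" or "foreperiod"
    t0: float                 # epoch onset on the trial clock (ms)
    t_ms: np.ndarray          # absolute sample times, [t0 - 100, t0 + span)
    raw: np.ndarray           # pupil (mm), NaN within blink gaps
    valid: np.ndarray


@dataclass
class BinnedPupil:
    """50-ms-binned pupil series on the epoch clock."""

    bin_centers: np.ndarray   # ms from epoch onset
    value: np.ndarray         # mm

    def copy(self) -> "BinnedPupil":
        return BinnedPupil(self.bin_centers.copy(), self.value.copy())


def extract_epoch(t_ms: np.ndarray, pupil_mm: np.ndarray, valid: np.ndarray,
                  schedule: TrialSchedule, epoch: str = "foreperiod",
                  trial_id: int = 0) -> PupilEpoch:
    """Slice one trial's samples into an epoch (with its baseline window)."""
    if epoch == "foreperiod":
        t0 = schedule.ws_offset
    elif epoch == "cue":
        t0 = schedule.cue_onset
    else:
        raise ValueError(f"unknown epoch {epoch!r}")
    span = EPOCH_SPANS_MS[epoch]
    sel = (t_ms >= t0 - BASELINE_MS) & (t_ms < t0 + span)
    return PupilEpoch(trial_id=trial_id, epoch=epoch, t0=t0,
                      t_ms=np.asarray(t_ms, float)[sel],
                      raw=np.asarray(pupil_mm, float)[sel],
                      valid=np.asarray(valid, bool)[sel])


def interpolate_blinks(t_ms: np.ndarray, values: np.ndarray,
                       valid: np.ndarray | None = None) -> np.ndarray:
    """Linearly bridge blink gaps, padded by 70 ms on each side.

    Samples within [gap start - 70 ms, gap end + 70 ms] are replaced by
    the straight line joining the nearest valid samples outside that
    window; gaps at the series edges are filled with the nearest valid
    value.  Returns a series with no invalid samples.

    Raises
    ------
    EpochUnusable
        If no valid sample remains to anchor the interpolation.
    """
    t = np.asarray(t_ms, float)
    v = np.asarray(values, float).copy()
    bad = ~np.asarray(valid, bool) if valid is not None else ~np.isfinite(v)
    if not bad.any():
        return v
    # dilate each invalid run by the pad width
    replace = bad.copy()
    idx = np.flatnonzero(bad)
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[splits + 1]))
    stops = np.concatenate((idx[splits], [idx[-1]]))
    for s0, s1 in zip(starts, stops):
        replace |= (t >= t[s0] - BLINK_PAD_MS) & (t <= t[s1] + BLINK_PAD_MS)
    anchors = ~replace & np.isfinite(v)
    if not anchors.any():
        raise EpochUnusable("no valid pupil samples to anchor interpolation")
    v[replace] = np.interp(t[replace], t[anchors], v[anchors])
    return v


def bin_and_filter(t_rel_ms: np.ndarray, values: np.ndarray) -> BinnedPupil:
    """Average into 50-ms bins, then apply a 3-bin running median.

    ``t_rel_ms`` is time from epoch onset; every bin in the covered
    span must contain at least one sample (always true at 500 Hz).
    Edge bins use truncated median windows.
    """
    t = np.asarray(t_rel_ms, float)
    v = np.asarray(values, float)
    n_bins = int(np.ceil((t.max() + 1e-9) / BIN_MS))
    which = np.minimum((t / BIN_MS).astype(int), n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    if (counts == 0).any():
        raise ValueError("empty 50-ms bin: sampling too sparse")
    sums = np.bincount(which, weights=v, minlength=n_bins)
    binned = sums / counts
    half = MEDIAN_KERNEL_BINS // 2
    filtered = np.array([
        np.median(binned[max(0, i - half):i + half + 1])
        for i in range(n_bins)
    ])
    centers = (np.arange(n_bins) + 0.5) * BIN_MS
    return BinnedPupil(bin_centers=centers, value=filtered)


def baseline_correct(binned: BinnedPupil,
                     baseline_samples: np.ndarray) -> BinnedPupil:
    """Subtract the mean of the 100-ms pre-epoch window from every bin."""
    b = np.asarray(baseline_samples, float)
    b = b[np.isfinite(b)]
    if len(b) == 0:
        raise EpochUnusable("baseline window has no valid samples")
    return BinnedPupil(bin_centers=binned.bin_centers.copy(),
                       value=binned.value - b.mean())


def window_mean(binned: BinnedPupil, lo: float = WINDOW_DEFAULT[0],
                hi: float = WINDOW_DEFAULT[1]) -> float:
    """Mean of the bins whose centres lie in [lo, hi) ms."""
    sel = (binned.bin_centers >= lo) & (binned.bin_centers < hi)
    if not sel.any():
        raise ValueError(f"no bins in window [{lo}, {hi}) ms")
    return float(binned.value[sel].mean())


def preprocess_epoch(epoch: PupilEpoch) -> BinnedPupil:
    """Full chain on one epoch: interpolate -> bin -> median -> baseline."""
    series = interpolate_blinks(epoch.t_ms, epoch.raw, epoch.valid)
    in_epoch = epoch.t_ms >= epoch.t0
    binned = bin_and_filter(epoch.t_ms[in_epoch] - epoch.t0, series[in_epoch])
    return baseline_correct(binned, series[~in_epoch])


def process_session_pupil(samples: pd.DataFrame, events: list[dict],
                          subject_id: str = "sub-00",
                          epoch: str = "foreperiod"
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the pupil chain over one subject's session.

    Returns
    -------
    bins : DataFrame
        Columns subject, trial_id, condition, bin_center_ms, value_mm.
    windows : DataFrame
        Columns subject, trial_id, condition, window_mean_mm (800-1900
        ms window); trials with unusable epochs are dropped.
    """
    by_trial = dict(tuple(samples.groupby("trial_id", sort=True)))
    bin_rows, win_rows = [], []
    for ev in events:
        tid = ev["trial_id"]
        tr = by_trial[tid]
        schedule = TrialSchedule.from_dict(ev["schedule"])
        ep = extract_epoch(tr["t_ms"].to_numpy(), tr["pupil_mm"].to_numpy(),
                           tr["valid"].to_numpy(), schedule, epoch=epoch,
                           trial_id=tid)
        try:
            binned = preprocess_epoch(ep)
        except EpochUnusable:
            continue
        bin_rows.append(pd.DataFrame({
            "subject": subject_id,
            "trial_id": tid,
            "condition": ev["n_cued"],
            "bin_center_ms": binned.bin_centers,
            "value_mm": binned.value,
        }))
        win_rows.append({
            "subject": subject_id,
            "trial_id": tid,
            "condition": ev["n_cued"],
            "window_mean_mm": window_mean(binned),
        })
    bins = (pd.concat(bin_rows, ignore_index=True)
            if bin_rows else pd.DataFrame(
                columns=["subject", "trial_id", "condition",
                         "bin_center_ms", "value_mm"]))
    return bins, pd.DataFrame(win_rows)


def process_epoch_frame(epochs: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pupil chain over a tidy epoch frame (the generator's fast path).

    ``epochs`` has columns subject, trial, condition, t_ms (epoch clock,
    baseline at negative times), pupil_mm, valid.
    """
    bin_rows, win_rows = [], []
    for (subj, tid, cond), g in epochs.groupby(
            ["subject", "trial", "condition"], sort=True):
        t = g["t_ms"].to_numpy()
        try:
            series = interpolate_blinks(t, g["pupil_mm"].to_numpy(),
                                        g["valid"].to_numpy())
            in_epoch = t >= 0
            binned = bin_and_filter(t[in_epoch], series[in_epoch])
            binned = baseline_correct(binned, series[~in_epoch])
        except EpochUnusable:
            continue
        bin_rows.append(pd.DataFrame({
            "subject": subj, "trial_id": tid, "condition": cond,
            "bin_center_ms": binned.bin_centers, "value_mm": binned.value,
        }))
        win_rows.append({"subject": subj, "trial_id": tid, "condition": cond,
                         "window_mean_mm": window_mean(binned)})
    return pd.concat(bin_rows, ignore_index=True), pd.DataFrame(win_rows)
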