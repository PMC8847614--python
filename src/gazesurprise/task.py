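"""Experimental design of the spatial expected-surprise task.

A trial cues ``n`` of four horizontally arranged boxes as possible
future target locations.  The target probability at each cued box is
``1/n`` and the expected surprise of the upcoming imperative stimulus
is the Shannon information ``-log2(1/n)`` in bits.  After the cue, a
central warning stimulus (WS) starts a fixed 1900-ms foreperiod ended
by the imperative stimulus (IS) in one of the cued boxes, to which the
subject saccades.

Coordinate frame: degrees of visual angle, fixation at the origin,
+x rightward, +y upward.  Boxes are indexed 0..3 left to right.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

N_BOXES = 4

#: Foreperiod between WS offset and IS onset (ms); constant by design.
FOREPERIOD_MS = 1900.0

#: Cue presentation duration (ms).
CUE_DURATION_MS = 2000.0

#: Warning / imperative stimulus durations (ms).
WS_DURATION_MS = 50.0
IS_DURATION_MS = 50.0

#: Empty test boxes shown between cue offset and WS onset (ms).
TEST_ARRAY_MS = 1000.0

#: Inter-trial interval bounds (ms); duration 2250 +/- 250.
ITI_RANGE_MS = (2000.0, 2500.0)

_VALID_N = (1, 2, 3, 4)


def target_probability(n_cued: int) -> float:
    """Probability of the target appearing at any one of ``n_cued`` cued boxes.

    Parameters
    ----------
    n_cued : int
        Number of cued boxes, in {1, 2, 3, 4}.

    Returns
    -------
    float
        Exactly ``1 / n_cued``.
    """
    if n_cued not in _VALID_N:
        raise ValueError(f"n_cued must be one of {_VALID_N}, got {n_cued!r}")
    return 1.0 / n_cued


def surprise_bits(n_cued: int) -> float:
    """Expected surprise (Shannon information) of the target location, in bits.

    ``SU_n = -log2 P(TB_n) = log2(n_cued)``; 0 bits when a single box is
    cued (the target location is certain), 2 bits when all four are.
    """
    if n_cued not in _VALID_N:
        raise ValueError(f"n_cued must be one of {_VALID_N}, got {n_cued!r}")
    return -math.log2(target_probability(n_cued)) + 0.0


@dataclass(frozen=True)
class Condition:
    """A surprise level: number of cued boxes, target probability, surprise."""

    n_cued: int
    p_target: float = field(init=False)
    surprise_bits: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "p_target", target_probability(self.n_cued))
        object.__setattr__(self, "surprise_bits", surprise_bits(self.n_cued))

    @property
    def label(self) -> str:
        return f"SU{self.n_cued}"


#: The four conditions of the study, SU1..SU4.
CONDITIONS = tuple(Condition(n) for n in _VALID_N)


@dataclass(frozen=True)
class ScreenGeometry:
    """Box layout in fixation-centred degrees of visual angle.

    Default centres put the four boxes in a horizontal row 15 deg above
    fixation, giving eccentricities of 15.3-17.3 deg (the boxes sit at
    an approximate distance of 17 deg in the study's display).
    """

    box_width: float = 5.7
    box_height: float = 4.3
    box_centers: tuple[tuple[float, float], ...] = (
        (-8.55, 15.0),
        (-2.85, 15.0),
        (2.85, 15.0),
        (8.55, 15.0),
    )
    fixation: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.box_centers) != N_BOXES:
            raise ValueError("exactly 4 box centers required")
        xs = [c[0] for c in self.box_centers]
        if sorted(xs) != xs:
            raise ValueError("boxes must be ordered left to right")
        for i in range(N_BOXES - 1):
            if xs[i + 1] - xs[i] < self.box_width:
                raise ValueError("boxes overlap horizontally")
        for cx, cy in self.box_centers:
            ecc = math.hypot(cx, cy)
            if not (15.0 <= ecc <= 18.0):
                raise ValueError(f"box eccentricity {ecc:.2f} outside [15, 18] deg")

    def eccentricity(self, box: int) -> float:
        cx, cy = self.box_centers[box]
        return math.hypot(cx, cy)

    def contains(self, box: int, point: tuple[float, float]) -> bool:
        """Whether ``point`` lies inside the rectangle of ``box``."""
        cx, cy = self.box_centers[box]
        return (
            abs(point[0] - cx) <= self.box_width / 2.0
            and abs(point[1] - cy) <= self.box_height / 2.0
        )

    def box_at(self, point: tuple[float, float]) -> int | None:
        """Index of the box containing ``point``, or None."""
        for i in range(N_BOXES):
            if self.contains(i, point):
                return i
        return None


@dataclass(frozen=True)
class TrialSchedule:
    """Event timestamps of one trial, in ms on the trial's own clock."""

    cue_onset: float
    cue_offset: float
    ws_onset: float
    ws_offset: float
    is_onset: float
    is_offset: float
    iti_duration: float

    @property
    def foreperiod(self) -> float:
        return self.is_onset - self.ws_offset

    def __post_init__(self) -> None:
        if not math.isclose(self.cue_offset - self.cue_onset, CUE_DURATION_MS):
            raise ValueError("cue duration must be 2000 ms")
        if not math.isclose(self.ws_offset - self.ws_onset, WS_DURATION_MS):
            raise ValueError("WS duration must be 50 ms")
        if not math.isclose(self.is_offset - self.is_onset, IS_DURATION_MS):
            raise ValueError("IS duration must be 50 ms")
        if not math.isclose(self.foreperiod, FOREPERIOD_MS):
            raise ValueError("foreperiod must be 1900 ms")
        if not (ITI_RANGE_MS[0] <= self.iti_duration <= ITI_RANGE_MS[1]):
            raise ValueError("ITI duration outside [2000, 2500] ms")

    @classmethod
    def standard(cls, iti_duration: float = 2250.0) -> "TrialSchedule":
        """The study timeline with cue onset at t = 0."""
        cue_onset = 0.0
        cue_offset = cue_onset + CUE_DURATION_MS
        ws_onset = cue_offset + TEST_ARRAY_MS
        ws_offset = ws_onset + WS_DURATION_MS
        is_onset = ws_offset + FOREPERIOD_MS
        return cls(
            cue_onset=cue_onset,
            cue_offset=cue_offset,
            ws_onset=ws_onset,
            ws_offset=ws_offset,
            is_onset=is_onset,
            is_offset=is_onset + IS_DURATION_MS,
            iti_duration=iti_duration,
        )

    def to_dict(self) -> dict:
        return {
            "cue_onset": self.cue_onset,
            "cue_offset": self.cue_offset,
            "ws_onset": self.ws_onset,
            "ws_offset": self.ws_offset,
            "is_onset": self.is_onset,
            "is_offset": self.is_offset,
            "iti_duration": self.iti_duration,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrialSchedule":
        return cls(**{k: float(d[k]) for k in (
            "cue_onset", "cue_offset", "ws_onset", "ws_offset",
            "is_onset", "is_offset", "iti_duration")})


def enumerate_cue_layouts(n_cued: int) -> list[frozenset[int]]:
    """All contiguous placements of ``n_cued`` cued boxes.

    One cued box can occupy any of the 4 positions; two cued boxes any
    of the 3 contiguous pairs (left / middle / right); three cued boxes
    either of the 2 contiguous triples (mostly left / mostly right);
    four cued boxes only the full set.
    """
    if n_cued not in _VALID_N:
        raise ValueError(f"n_cued must be one of {_VALID_N}, got {n_cued!r}")
    return [
        frozenset(range(start, start + n_cued))
        for start in range(N_BOXES - n_cued + 1)
    ]


@dataclass(frozen=True)
class CueLayout:
    """A realized cue: condition, which boxes are cued and which holds the target."""

    condition: Condition
    cued_box_indices: frozenset[int]
    target_box_index: int

    def __post_init__(self) -> None:
        if len(self.cued_box_indices) != self.condition.n_cued:
            raise ValueError("number of cued boxes must match the condition")
        if self.target_box_index not in self.cued_box_indices:
            raise ValueError("target must be one of the cued boxes")
        idx = sorted(self.cued_box_indices)
        if idx != list(range(idx[0], idx[0] + len(idx))):
            raise ValueError("cued boxes must be contiguous")
        if not all(0 <= i < N_BOXES for i in idx):
            raise ValueError("box indices out of range")


def draw_trial(condition: Condition, rng: np.random.Generator) -> CueLayout:
    """Draw a cue layout uniformly and a target uniformly among cued boxes."""
    layouts = enumerate_cue_layouts(condition.n_cued)
    layout = layouts[rng.integers(len(layouts))]
    target = sorted(layout)[rng.integers(len(layout))]
    return CueLayout(condition=condition, cued_box_indices=layout,
                     target_box_index=target)
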