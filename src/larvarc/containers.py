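"""Core in-memory containers: stimulus traces, behaviour tracks, fluorescence
traces and two-choice count rows.

Conventions used throughout the package:

* frame indices are 0-based and windows are half-open ``[start, end)``;
* a behavioural session has a single frame clock shared by the stimulus and
  every animal's track (the LED flicker is synchronized to acquisition);
* the binary LED state is stored as 0/1 and encoded as -1/+1 for analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .errors import FormatError, IntegrityError, ParameterError

__all__ = [
    "BehaviorState",
    "StimulusTrace",
    "BehaviorTrack",
    "FluorescenceTrace",
    "ChoiceAssayResult",
]


class BehaviorState(IntEnum):
    """The two larval navigation states: forward crawling vs reorientation."""

    RUN = 0
    TURN = 1

    @classmethod
    def from_label(cls, label: str) -> "BehaviorState":
        try:
            return cls[label]
        except KeyError:
            raise FormatError(
                f"unknown behaviour state {label!r}; expected one of "
                f"{[s.name for s in cls]}"
            ) from None


@dataclass(frozen=True)
class StimulusTrace:
    """Frame-indexed binary LED state at a fixed frame rate.

    ``led_state`` holds 0 (OFF) / 1 (ON) per frame for a contiguous frame
    range starting at frame 0.
    """

    led_state: np.ndarray
    frame_rate_hz: float = 4.0

    def __post_init__(self) -> None:
        state = np.asarray(self.led_state)
        if state.ndim != 1 or state.size == 0:
            raise FormatError("led_state must be a non-empty 1-D array")
        if not np.isin(state, (0, 1)).all():
            raise FormatError("led_state must contain only 0 (OFF) and 1 (ON)")
        if self.frame_rate_hz <= 0:
            raise ParameterError("frame_rate_hz must be > 0")
        object.__setattr__(self, "led_state", state.astype(np.uint8))

    @property
    def n_frames(self) -> int:
        return self.led_state.size

    @property
    def frame_index(self) -> np.ndarray:
        return np.arange(self.n_frames)

    def encoded(self) -> np.ndarray:
        """Return the +-1 encoded signal (ON -> +1, OFF -> -1)."""
        return self.led_state.astype(np.float64) * 2.0 - 1.0


@dataclass(frozen=True)
class BehaviorTrack:
    """Per-animal frame-indexed RUN/TURN state sequence.

    ``state`` holds :class:`BehaviorState` codes; ``valid`` marks frames where
    the tracker had the animal (state values at invalid frames are
    meaningless).  ``frame_start`` anchors the track on the session frame
    clock; simulated and typical tracked sessions start at frame 0.
    """

    animal_id: str
    state: np.ndarray
    valid: np.ndarray | None = None
    frame_start: int = 0

    def __post_init__(self) -> None:
        state = np.asarray(self.state)
        if state.ndim != 1 or state.size == 0:
            raise FormatError("state must be a non-empty 1-D array")
        if not np.isin(state, (int(BehaviorState.RUN), int(BehaviorState.TURN))).all():
            raise FormatError("state codes must be RUN (0) or TURN (1)")
        valid = self.valid
        if valid is None:
            valid = np.ones(state.size, dtype=bool)
        valid = np.asarray(valid, dtype=bool)
        if valid.shape != state.shape:
            raise IntegrityError(
                f"valid flags length {valid.size} != state length {state.size} "
                f"for animal {self.animal_id!r}"
            )
        object.__setattr__(self, "state", state.astype(np.uint8))
        object.__setattr__(self, "valid", valid)

    @property
    def n_frames(self) -> int:
        return self.state.size

    @property
    def frame_index(self) -> np.ndarray:
        return self.frame_start + np.arange(self.n_frames)


@dataclass(frozen=True)
class FluorescenceTrace:
    """Raw fluorescence intensity series with protocol window annotations.

    The imaging protocol is wash / stimulation / wash: ``n_pre_frames`` of
    washing substance, ``n_stim_frames`` of tastant application and
    ``n_post_frames`` of wash again, at ``frame_period_ms`` per frame.
    """

    roi_id: str
    intensity: np.ndarray
    frame_period_ms: float = 85.0
    n_pre_frames: int = 100
    n_stim_frames: int = 200
    n_post_frames: int = 100

    def __post_init__(self) -> None:
        intensity = np.asarray(self.intensity, dtype=np.float64)
        if intensity.ndim != 1:
            raise FormatError("intensity must be a 1-D array")
        if not np.isfinite(intensity).all():
            raise FormatError(f"non-finite intensity in trace {self.roi_id!r}")
        if (intensity < 0).any():
            raise FormatError(f"negative intensity in trace {self.roi_id!r}")
        expected = self.n_pre_frames + self.n_stim_frames + self.n_post_frames
        if intensity.size != expected:
            raise FormatError(
                f"trace {self.roi_id!r} has {intensity.size} frames; window "
                f"annotations require {expected} "
                f"({self.n_pre_frames}+{self.n_stim_frames}+{self.n_post_frames})"
            )
        if min(self.n_pre_frames, self.n_stim_frames, self.n_post_frames) <= 0:
            raise ParameterError("window frame counts must be positive")
        if self.frame_period_ms <= 0:
            raise ParameterError("frame_period_ms must be > 0")
        object.__setattr__(self, "intensity", intensity)

    @property
    def n_frames(self) -> int:
        return self.intensity.size

    @property
    def stim_slice(self) -> slice:
        """Half-open frame slice of the stimulation window."""
        return slice(self.n_pre_frames, self.n_pre_frames + self.n_stim_frames)


@dataclass(frozen=True)
class ChoiceAssayResult:
    """Larva counts from one two-choice plate.

    Animals are released on a neutral midline zone between a stimulus
    substrate and a control substrate and counted per side after a fixed
    time; animals still in the neutral zone are counted separately.
    """

    assay_id: str
    n_stimulus_side: int
    n_control_side: int
    n_neutral: int = 0
    group: str = ""

    def __post_init__(self) -> None:
        for name in ("n_stimulus_side", "n_control_side", "n_neutral"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")

    @property
    def n_total(self) -> int:
        return self.n_stimulus_side + self.n_control_side + self.n_neutral
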