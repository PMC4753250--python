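"""Acquisition configuration shared by all pipeline stages.

Behavioural sessions are recorded at a fixed camera frame rate (4 Hz in the
assay this package models) with the LED stimulus synchronized to image
acquisition, so stimulus and behaviour share a single frame clock.  Calcium
imaging runs on its own clock (85 ms per frame).  The configuration object
holds both clocks plus the analysis grid parameters (step-response bin width
and triggered-average window) and the base random seed.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, replace
from pathlib import Path

from .errors import ParameterError

__all__ = ["AcquisitionConfig", "load_config"]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Frame clocks and analysis grid for one experimental session.

    Parameters
    ----------
    frame_rate_hz
        Behavioural video frame rate in Hz.  The LED stimulus is assumed to
        be updated once per video frame.
    frame_period_ms
        Calcium-imaging frame period in milliseconds.
    step_bin_s
        Width of the time bins used for step-response transition
        probabilities, in seconds.  Must be an integer multiple of the
        behavioural frame period.
    ta_window_s
        Length of the pre-event window over which triggered averages are
        computed, in seconds.
    seed
        Base seed for all stochastic components.
    """

    frame_rate_hz: float = 4.0
    frame_period_ms: float = 85.0
    step_bin_s: float = 0.25
    ta_window_s: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ParameterError(f"frame_rate_hz must be > 0, got {self.frame_rate_hz}")
        if self.frame_period_ms <= 0:
            raise ParameterError(f"frame_period_ms must be > 0, got {self.frame_period_ms}")
        if self.step_bin_s <= 0:
            raise ParameterError(f"step_bin_s must be > 0, got {self.step_bin_s}")
        if self.ta_window_s <= 0:
            raise ParameterError(f"ta_window_s must be > 0, got {self.ta_window_s}")
        if self.seed < 0:
            raise ParameterError(f"seed must be non-negative, got {self.seed}")
        n_frames = self.step_bin_s * self.frame_rate_hz
        if not math.isclose(n_frames, round(n_frames), rel_tol=0, abs_tol=1e-9):
            raise ParameterError(
                f"step_bin_s={self.step_bin_s} is not an integer multiple of the "
                f"frame period 1/{self.frame_rate_hz} s"
            )

    @property
    def frame_dt_s(self) -> float:
        """Behavioural frame period in seconds."""
        return 1.0 / self.frame_rate_hz

    @property
    def step_bin_frames(self) -> int:
        """Step-response bin width in frames."""
        return round(self.step_bin_s * self.frame_rate_hz)

    @property
    def ta_window_frames(self) -> int:
        """Triggered-average window length in frames (lags 0..window)."""
        return round(self.ta_window_s * self.frame_rate_hz)

    def with_(self, **kwargs) -> "AcquisitionConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def load_config(path: str | Path) -> AcquisitionConfig:
    """Read an :class:`AcquisitionConfig` from a TOML file.

    Keys may live at the top level or under an ``[acquisition]`` table;
    unknown keys are ignored so the same file can carry module-specific
    sections.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    table = raw.get("acquisition", raw)
    fields = {k: table[k] for k in (
        "frame_rate_hz", "frame_period_ms", "step_bin_s", "ta_window_s", "seed",
    ) if k in table}
    return AcquisitionConfig(**fields)
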