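"""Readers and writers for the tabular session artifacts.

All on-disk formats are plain tab-separated text with a one-line header, so
every artifact is inspectable and diffable.  The writers emit a canonical
form (fixed column order, integer-coded flags, ``\\n`` line endings) and the
readers accept exactly that form, which makes read/write round-trips
byte-identical.

Schemas
-------
tracks.tsv    animal_id, frame, state (RUN/TURN), valid (0/1)
stimulus.tsv  frame, led_state (0/1)
traces.tsv    roi_id, frame, intensity
choice.tsv    assay_id, group, n_stimulus_side, n_control_side, n_neutral
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import AcquisitionConfig
from .containers import (
    BehaviorState,
    BehaviorTrack,
    ChoiceAssayResult,
    FluorescenceTrace,
    StimulusTrace,
)
from .errors import FormatError, IntegrityError

__all__ = [
    "read_tracks", "write_tracks",
    "read_stimulus", "write_stimulus",
    "read_traces", "write_traces",
    "read_choice", "write_choice",
]

_CSV_KW = dict(sep="\t", index=False, lineterminator="\n")


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:  # malformed delimited text
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


def read_tracks(path: str | Path, config: AcquisitionConfig | None = None) -> list[BehaviorTrack]:
    """Read per-animal RUN/TURN tracks from a tracks TSV.

    One :class:`BehaviorTrack` is returned per ``animal_id``, frames sorted.
    Each animal's frames must form a contiguous range (lost-tracking periods
    are rows with ``valid=0``, not missing rows).  Unknown state labels,
    duplicate (animal, frame) rows and frame gaps are rejected.
    """
    df = _read_table(path, ("animal_id", "frame", "state"))
    if "valid" not in df.columns:
        df = df.assign(valid=1)
    if df.duplicated(subset=["animal_id", "frame"]).any():
        dup = df[df.duplicated(subset=["animal_id", "frame"])].iloc[0]
        raise IntegrityError(
            f"{path}: duplicate row for animal {dup['animal_id']!r} "
            f"frame {dup['frame']}"
        )
    tracks = []
    for animal_id, sub in df.groupby("animal_id", sort=True):
        sub = sub.sort_values("frame")
        frames = sub["frame"].to_numpy()
        if frames.size > 1 and (np.diff(frames) != 1).any():
            raise IntegrityError(f"{path}: frame gap in track of animal {animal_id!r}")
        state = np.array(
            [BehaviorState.from_label(s) for s in sub["state"].astype(str)],
            dtype=np.uint8,
        )
        tracks.append(BehaviorTrack(
            animal_id=str(animal_id),
            state=state,
            valid=sub["valid"].to_numpy().astype(bool),
            frame_start=int(frames[0]),
        ))
    return tracks


def write_tracks(path: str | Path, tracks: Iterable[BehaviorTrack]) -> None:
    """Write tracks in the canonical TSV form (sorted by animal, frame)."""
    frames = []
    for t in sorted(tracks, key=lambda t: t.animal_id):
        frames.append(pd.DataFrame({
            "animal_id": t.animal_id,
            "frame": t.frame_index,
            "state": [BehaviorState(s).name for s in t.state],
            "valid": t.valid.astype(int),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, **_CSV_KW)


def read_stimulus(path: str | Path, config: AcquisitionConfig | None = None) -> StimulusTrace:
    """Read a frame-indexed LED log into a :class:`StimulusTrace`.

    Frames must be contiguous from the first listed frame and states binary.
    """
    df = _read_table(path, ("frame", "led_state"))
    df = df.sort_values("frame")
    frames = df["frame"].to_numpy()
    if frames.size > 1 and (np.diff(frames) != 1).any():
        raise IntegrityError(f"{path}: gap in stimulus frame index")
    led = df["led_state"].to_numpy()
    if not np.isin(led, (0, 1)).all():
        raise FormatError(f"{path}: led_state must be 0 or 1")
    rate = config.frame_rate_hz if config is not None else 4.0
    return StimulusTrace(led_state=led, frame_rate_hz=rate)


def write_stimulus(path: str | Path, trace: StimulusTrace) -> None:
    pd.DataFrame({
        "frame": trace.frame_index,
        "led_state": trace.led_state.astype(int),
    }).to_csv(path, **_CSV_KW)


def read_traces(
    path: str | Path,
    n_pre_frames: int = 100,
    n_stim_frames: int = 200,
    n_post_frames: int | None = None,
    frame_period_ms: float = 85.0,
) -> list[FluorescenceTrace]:
    """Read fluorescence traces (long format: roi_id, frame, intensity).

    Window annotations are supplied by the caller; ``n_post_frames=None``
    infers the post-stimulus window from the trace length.
    """
    df = _read_table(path, ("roi_id", "frame", "intensity"))
    traces = []
    for roi_id, sub in df.groupby("roi_id", sort=True):
        sub = sub.sort_values("frame")
        frames = sub["frame"].to_numpy()
        if frames.size > 1 and (np.diff(frames) != 1).any():
            raise IntegrityError(f"{path}: frame gap in trace {roi_id!r}")
        intensity = sub["intensity"].to_numpy(dtype=float)
        n_post = n_post_frames
        if n_post is None:
            n_post = intensity.size - n_pre_frames - n_stim_frames
        traces.append(FluorescenceTrace(
            roi_id=str(roi_id),
            intensity=intensity,
            frame_period_ms=frame_period_ms,
            n_pre_frames=n_pre_frames,
            n_stim_frames=n_stim_frames,
            n_post_frames=n_post,
        ))
    return traces


def write_traces(path: str | Path, traces: Iterable[FluorescenceTrace]) -> None:
    frames = []
    for t in sorted(traces, key=lambda t: t.roi_id):
        frames.append(pd.DataFrame({
            "roi_id": t.roi_id,
            "frame": np.arange(t.n_frames),
            "intensity": t.intensity,
        }))
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, float_format="%.6f", **_CSV_KW)


def read_choice(path: str | Path) -> list[ChoiceAssayResult]:
    """Read two-choice count rows."""
    df = _read_table(path, ("assay_id", "n_stimulus_side", "n_control_side", "n_neutral"))
    if "group" not in df.columns:
        df = df.assign(group="")
    if df.duplicated(subset=["assay_id"]).any():
        raise IntegrityError(f"{path}: duplicate assay_id")
    return [
        ChoiceAssayResult(
            assay_id=str(r.assay_id),
            n_stimulus_side=int(r.n_stimulus_side),
            n_control_side=int(r.n_control_side),
            n_neutral=int(r.n_neutral),
            group=str(r.group),
        )
        for r in df.itertuples()
    ]


def write_choice(path: str | Path, assays: Iterable[ChoiceAssayResult]) -> None:
    pd.DataFrame([{
        "assay_id": a.assay_id,
        "group": a.group,
        "n_stimulus_side": a.n_stimulus_side,
        "n_control_side": a.n_control_side,
        "n_neutral": a.n_neutral,
    } for a in assays]).to_csv(path, **_CSV_KW)
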