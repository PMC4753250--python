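"""Reverse correlation of run/turn transitions against the LED stimulus.

The two computations here are:

* **Triggered averages** — for every behavioural transition of one kind
  (run->turn or turn->run), extract the +-1-encoded stimulus over a fixed
  window preceding (and including) the frame on which the new state begins,
  and average across events.  Under white-noise (Bernoulli) stimulation this
  event-triggered average estimates the stimulus filter driving the
  transition hazard.

* **Step-response transition probabilities** — around a single OFF->ON
  stimulus step, the per-time-bin probability of initiating a transition
  (number of animals initiating, divided by the animals present in the
  arena), the pre-step baseline probability, and a binomial z-test comparing
  the peak post-step bin against baseline, with the normal-approximation
  validity rule ``n p >= 5`` and ``n (1-p) >= 5`` evaluated at the peak.

Conventions: the event frame is the first frame of the *new* state; lag 0
of the triggered average is the stimulus on that initiation frame, negative
lags reach back in time.  Events whose pre-event window extends before the
session start are excluded (not zero-padded) and counted in the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

from .config import AcquisitionConfig
from .containers import BehaviorState, BehaviorTrack, StimulusTrace
from .errors import ConfigurationError, InsufficientDataError, IntegrityError, ParameterError

__all__ = [
    "TransitionKind",
    "TransitionEvent",
    "TriggeredAverage",
    "StepResponse",
    "encode_stimulus",
    "detect_transitions",
    "triggered_average",
    "step_transition_probability",
    "revcorr_report",
    "RevcorrReport",
]

logger = logging.getLogger(__name__)


class TransitionKind(Enum):
    RUN_TO_TURN = "RUN_TO_TURN"
    TURN_TO_RUN = "TURN_TO_RUN"


@dataclass(frozen=True)
class TransitionEvent:
    """One behavioural state change; ``frame`` is the first frame of the new
    state on the session clock."""

    animal_id: str
    frame: int
    kind: TransitionKind


@dataclass(frozen=True)
class TriggeredAverage:
    """Mean +-1 stimulus over the pre-event lag window for one event kind.

    ``lags_s`` runs from ``-window`` to 0 (the initiation frame);
    ``n_excluded`` counts events dropped for lacking a full pre-event
    window.  ``sem`` is the standard error of the per-lag mean; see
    :func:`triggered_average` for the two available estimators.
    """

    kind: TransitionKind
    lags_s: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_events: int
    n_excluded: int = 0
    sem_method: str = "cluster"


@dataclass(frozen=True)
class StepResponse:
    """Binned transition probabilities around a stimulus step.

    ``probability[j]`` is the fraction of arena animals initiating a
    transition of the requested kind in bin j; ``n_at_risk[j]`` the animals
    with at least one tracked frame in bin j.  ``z_stat``/``p_value``
    compare the peak post-step bin against the mean pre-step baseline under
    the normal approximation to the binomial, and ``valid`` records whether
    ``n p >= 5`` and ``n (1-p) >= 5`` hold at the peak.
    """

    kind: TransitionKind
    bin_start_s: np.ndarray
    probability: np.ndarray
    n_at_risk: np.ndarray
    n_initiating: np.ndarray
    baseline_probability: float
    peak_bin: int
    peak_probability: float
    z_stat: float
    p_value: float
    valid: bool
    alternative: str


def encode_stimulus(trace: StimulusTrace) -> np.ndarray:
    """Encode the LED log as +-1: ON -> +1, OFF -> -1."""
    return trace.encoded()


def detect_transitions(track: BehaviorTrack) -> list[TransitionEvent]:
    """Find all state changes between consecutive *valid* frames.

    A change whose flanking frames straddle an invalid (lost-tracking) gap
    is discarded: with the animal untracked, the initiation frame is
    unknown.  A track with fewer than two valid frames yields no events.
    """
    state, valid = track.state, track.valid
    if state.size < 2:
        return []
    changed = (state[1:] != state[:-1]) & valid[1:] & valid[:-1]
    idx = np.nonzero(changed)[0] + 1
    events = []
    for i in idx:
        kind = (
            TransitionKind.RUN_TO_TURN
            if state[i] == BehaviorState.TURN
            else TransitionKind.TURN_TO_RUN
        )
        events.append(TransitionEvent(track.animal_id, track.frame_start + int(i), kind))
    return events


def triggered_average(
    stimulus: StimulusTrace,
    events: list[TransitionEvent],
    kind: TransitionKind,
    window_s: float | None = None,
    config: AcquisitionConfig | None = None,
    sem_method: str = "cluster",
) -> TriggeredAverage:
    """Event-triggered stimulus average for one transition kind.

    ``mean[l]`` averages the encoded stimulus at ``event_frame + lag`` over
    all usable events, for lags ``-W..0`` frames (W = window in frames).
    Events starting before frame W lack a full window and are excluded.

    SEM estimators
    --------------
    ``sem_method="cluster"`` (default): one-way cluster-robust standard
    error treating events that share an initiation frame as one cluster.
    All animals in the arena see the *same* LED sequence, so events that
    coincide on a frame contribute identical stimulus samples at every lag;
    the naive across-event formula treats those duplicates as independent
    and understates the uncertainty of the mean.  The cluster estimator is
    calibrated in that regime and reduces to the plain formula when no
    events coincide.

    ``sem_method="event"``: sample SD across events divided by sqrt(n),
    the classical formula (appropriate when events are sparse relative to
    frames).

    Raises :class:`InsufficientDataError` when no usable event remains.
    """
    if config is None:
        config = AcquisitionConfig(frame_rate_hz=stimulus.frame_rate_hz)
    if window_s is None:
        window_s = config.ta_window_s
    if sem_method not in ("cluster", "event"):
        raise ParameterError(f"unknown sem_method {sem_method!r}")
    w = round(window_s * stimulus.frame_rate_hz)
    if w < 1:
        raise ParameterError("window_s must cover at least one frame")

    frames = np.array([e.frame for e in events if e.kind == kind], dtype=np.int64)
    n_kind = frames.size
    usable = frames[(frames >= w) & (frames < stimulus.n_frames)]
    n_excluded = n_kind - usable.size
    if usable.size == 0:
        raise InsufficientDataError(
            f"no {kind.value} event with a full {window_s} s pre-event window"
        )

    enc = stimulus.encoded()
    lags = np.arange(-w, 1)
    windows = enc[usable[:, None] + lags[None, :]]  # (n_events, w+1)
    mean = windows.mean(axis=0)
    n = usable.size

    if n == 1:
        sem = np.zeros_like(mean)
    elif sem_method == "event":
        sem = windows.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        uniq, counts = np.unique(usable, return_counts=True)
        uwin = enc[uniq[:, None] + lags[None, :]]
        resid = counts[:, None] * (uwin - mean[None, :])
        sem = np.sqrt((resid ** 2).sum(axis=0)) / n

    return TriggeredAverage(
        kind=kind,
        lags_s=lags / stimulus.frame_rate_hz,
        mean=mean,
        sem=sem,
        n_events=n,
        n_excluded=n_excluded,
        sem_method=sem_method,
    )


def _step_onset(stimulus: StimulusTrace) -> int:
    """Frame index of the single OFF->ON step; validates the step shape."""
    led = stimulus.led_state.astype(np.int8)
    diffs = np.diff(led)
    rises = np.nonzero(diffs == 1)[0]
    falls = np.nonzero(diffs == -1)[0]
    if falls.size > 0 or rises.size > 1:
        raise ParameterError("stimulus is not a single OFF->ON step")
    if rises.size == 0:
        if led[0] == 1:
            return 0  # constant ON: onset at session start
        raise ParameterError("stimulus never turns ON; not a step")
    return int(rises[0]) + 1


def step_transition_probability(
    tracks: list[BehaviorTrack],
    stimulus: StimulusTrace,
    kind: TransitionKind = TransitionKind.RUN_TO_TURN,
    config: AcquisitionConfig | None = None,
    baseline_window_s: float | None = None,
    alternative: str = "greater",
) -> StepResponse:
    """Per-bin transition probabilities around a stimulus step with the
    peak-vs-baseline z-test.

    probability[j] = (# animals initiating a ``kind`` transition in bin j)
    / (# animals tracked in bin j).  The baseline is the mean probability
    over the pre-step bins (optionally restricted to the last
    ``baseline_window_s`` seconds before the step).  The z statistic
    compares the *peak* post-step bin probability p_hat against the
    baseline p0:  z = (p_hat - p0) / sqrt(p0 (1 - p0) / n), with n the
    peak-bin denominator.  ``alternative`` is "greater" (one-sided increase,
    the default, matching an aversion hypothesis) or "two-sided".

    The peak bin is chosen as the maximum post-step probability; that
    selection is implicit in the test and is reported via ``peak_bin``.
    """
    if not tracks:
        raise ParameterError("no animals supplied")
    if config is None:
        config = AcquisitionConfig(frame_rate_hz=stimulus.frame_rate_hz)
    if alternative not in ("greater", "two-sided"):
        raise ParameterError(f"unknown alternative {alternative!r}")
    b = config.step_bin_frames
    n_frames = stimulus.n_frames
    for t in tracks:
        if t.frame_start != 0 or t.n_frames != n_frames:
            raise IntegrityError(
                f"track {t.animal_id!r} does not cover the stimulus frame "
                "range; stimulus and behaviour must share one frame clock"
            )
    onset = _step_onset(stimulus)
    n_bins = n_frames // b
    if n_bins < 1:
        raise ConfigurationError("bin width exceeds session length")
    bin_start = np.arange(n_bins) * b

    # pre-step bins end at or before the onset frame
    pre = np.nonzero(bin_start + b <= onset)[0]
    if pre.size == 0:
        raise ConfigurationError("no complete pre-step bin before the stimulus onset")
    if baseline_window_s is not None:
        k = max(1, round(baseline_window_s / config.step_bin_s))
        pre = pre[-k:]
    post = np.nonzero(bin_start >= onset)[0]
    if post.size == 0:
        raise ConfigurationError("no post-step bin after the stimulus onset")

    n_initiating = np.zeros(n_bins, dtype=np.int64)
    n_at_risk = np.zeros(n_bins, dtype=np.int64)
    for track in tracks:
        v = track.valid[: n_bins * b].reshape(n_bins, b)
        n_at_risk += v.any(axis=1)
        ev_frames = [e.frame for e in detect_transitions(track) if e.kind == kind]
        if ev_frames:
            bins = np.unique(np.asarray(ev_frames) // b)
            bins = bins[bins < n_bins]
            n_initiating[bins] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        probability = np.where(n_at_risk > 0, n_initiating / np.maximum(n_at_risk, 1), 0.0)
    baseline = float(probability[pre].mean())

    peak_local = int(np.argmax(probability[post]))
    peak_bin = int(post[peak_local])
    p_hat = float(probability[peak_bin])
    n_peak = int(n_at_risk[peak_bin])

    if n_peak == 0 or baseline <= 0.0 or baseline >= 1.0:
        # z-test undefined without a usable baseline; report and flag invalid
        z = float("nan")
        p_value = float("nan")
    else:
        z = (p_hat - baseline) / np.sqrt(baseline * (1.0 - baseline) / n_peak)
        if alternative == "greater":
            p_value = float(stats.norm.sf(z))
        else:
            p_value = float(2.0 * stats.norm.sf(abs(z)))

    valid = bool(
        np.isfinite(z)
        and n_peak * p_hat >= 5.0
        and n_peak * (1.0 - p_hat) >= 5.0
    )

    return StepResponse(
        kind=kind,
        bin_start_s=bin_start / stimulus.frame_rate_hz,
        probability=probability,
        n_at_risk=n_at_risk,
        n_initiating=n_initiating,
        baseline_probability=baseline,
        peak_bin=peak_bin,
        peak_probability=p_hat,
        z_stat=float(z),
        p_value=p_value,
        valid=valid,
        alternative=alternative,
    )


@dataclass(frozen=True)
class RevcorrReport:
    """Both triggered averages for one session plus event accounting."""

    ta_run_to_turn: TriggeredAverage | None
    ta_turn_to_run: TriggeredAverage | None
    n_events: dict
    n_excluded: dict
    n_animals: int


def revcorr_report(
    tracks: list[BehaviorTrack],
    stimulus: StimulusTrace,
    config: AcquisitionConfig | None = None,
    window_s: float | None = None,
    sem_method: str = "cluster",
) -> RevcorrReport:
    """Compute both transition-kind triggered averages for a session.

    A kind with no usable events yields ``None`` for its average (flagged,
    not fatal), so single-animal or short sessions still produce a report.
    """
    if config is None:
        config = AcquisitionConfig(frame_rate_hz=stimulus.frame_rate_hz)
    events: list[TransitionEvent] = []
    for t in tracks:
        events.extend(detect_transitions(t))
    tas: dict[TransitionKind, TriggeredAverage | None] = {}
    n_events, n_excluded = {}, {}
    for kind in TransitionKind:
        try:
            ta = triggered_average(stimulus, events, kind, window_s, config, sem_method)
        except InsufficientDataError:
            logger.warning("no usable %s events in session", kind.value)
            ta = None
        tas[kind] = ta
        n_events[kind.value] = ta.n_events if ta else 0
        n_excluded[kind.value] = (
            ta.n_excluded if ta else sum(e.kind == kind for e in events)
        )
    return RevcorrReport(
        ta_run_to_turn=tas[TransitionKind.RUN_TO_TURN],
        ta_turn_to_run=tas[TransitionKind.TURN_TO_RUN],
        n_events=n_events,
        n_excluded=n_excluded,
        n_animals=len(tracks),
    )
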