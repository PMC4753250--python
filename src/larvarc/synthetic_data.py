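"""Synthetic-data generators: stimulus programs, virtual larva populations
with known stimulus filters, calcium traces and two-choice counts.

The behavioural generator is a linear-nonlinear hazard model of larval
navigation.  Each animal is an independent two-state (RUN/TURN) chain on the
session frame clock.  The per-frame probability of switching out of a run is

    P(run -> turn at frame t) = clip( lambda_rt * dt * exp( sum_l k_l s_{t-l} ) )

where ``s`` is the +-1 encoded LED stimulus, ``k`` the stimulus filter over
lags ``0..L-1`` frames, ``lambda_rt`` the baseline hazard (per second) and
``dt`` the frame period.  The turn -> run hazard uses the same filter scaled
by ``turn_filter_sign`` (default -1: a stimulus that promotes turning also
prolongs turns, the signature of an aversive input).  Under a Bernoulli
(white) stimulus the event-triggered stimulus average of this model is a
monotone (tanh-like) image of the filter, which is what makes filter
recovery by reverse correlation a meaningful end-to-end check.

Stimulus history before the session start is imputed as OFF (-1), matching
dark rearing before the assay.

All generators are pure functions of their parameters and a seed.  Distinct
random streams are derived from the seed with ``np.random.default_rng([seed,
stream])`` so that, e.g., the stimulus and the population draws of one
session are independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import AcquisitionConfig
from .containers import BehaviorState, BehaviorTrack, ChoiceAssayResult, FluorescenceTrace, StimulusTrace
from .errors import ParameterError

__all__ = [
    "LNPModelParams",
    "SimulationSpec",
    "CalciumSimParams",
    "exponential_filter",
    "generate_bernoulli_stimulus",
    "generate_step_stimulus",
    "generate_stimulus",
    "simulate_population",
    "simulate_session",
    "simulate_calcium_trace",
    "simulate_two_choice",
]

logger = logging.getLogger(__name__)

# per-frame hazard cap; keeps extreme-parameter simulations runnable
_HAZARD_CLIP = 1.0 - 1e-6

# sub-stream labels for seed derivation
_STREAM_STIMULUS = 1
_STREAM_POPULATION = 2
_STREAM_CALCIUM = 3
_STREAM_CHOICE = 4


def exponential_filter(
    amplitude: float = 0.3,
    tau_s: float = 1.0,
    duration_s: float = 2.5,
    frame_rate_hz: float = 4.0,
) -> np.ndarray:
    """Causal exponentially decaying stimulus filter ``k_l = A exp(-l dt/tau)``.

    ``amplitude`` is the log-hazard gain at lag 0 per unit of the +-1
    stimulus; positive amplitude on the run->turn hazard means the ON state
    promotes turning (an aversive drive).
    """
    n = round(duration_s * frame_rate_hz)
    if n < 1:
        raise ParameterError("filter duration must cover at least one frame")
    lags = np.arange(n)
    return amplitude * np.exp(-lags / (tau_s * frame_rate_hz))


@dataclass(frozen=True)
class LNPModelParams:
    """Parameters of the linear-nonlinear hazard navigation model.

    Baseline hazards are per-second rates of leaving the current state in
    the absence of stimulus drive; defaults (0.1 /s out of runs, 0.5 /s out
    of turns) give ~10 s runs and ~2 s turns, typical of freely crawling
    third-instar larvae.  ``filter_kernel`` is the stimulus filter over lags
    0..L-1 frames (log-hazard gain per unit +-1 stimulus); the default zero
    kernel yields stimulus-independent behaviour.
    """

    baseline_run_to_turn_hazard: float = 0.1
    baseline_turn_to_run_hazard: float = 0.5
    filter_kernel: np.ndarray = field(default_factory=lambda: np.zeros(1))
    nonlinearity: str = "exponential"
    turn_filter_sign: float = -1.0

    def __post_init__(self) -> None:
        if self.baseline_run_to_turn_hazard < 0 or self.baseline_turn_to_run_hazard < 0:
            raise ParameterError("baseline hazards must be >= 0")
        if self.nonlinearity != "exponential":
            raise ParameterError(f"unsupported nonlinearity {self.nonlinearity!r}")
        kernel = np.asarray(self.filter_kernel, dtype=np.float64)
        if kernel.ndim != 1 or kernel.size < 1:
            raise ParameterError("filter_kernel must be a 1-D array of length >= 1")
        if not np.isfinite(kernel).all():
            raise ParameterError("filter_kernel must be finite")
        object.__setattr__(self, "filter_kernel", kernel)

    @classmethod
    def aversive(
        cls,
        amplitude: float = 0.3,
        tau_s: float = 1.0,
        duration_s: float = 2.5,
        frame_rate_hz: float = 4.0,
        **kwargs,
    ) -> "LNPModelParams":
        """Model with an exponentially decaying aversive filter (light ON
        promotes turn initiation and suppresses turn completion)."""
        return cls(
            filter_kernel=exponential_filter(amplitude, tau_s, duration_s, frame_rate_hz),
            **kwargs,
        )


@dataclass(frozen=True)
class SimulationSpec:
    """Size and stimulus program of one simulated behavioural session.

    Defaults mirror the arena assay this package models: ~120 animals per
    curve, Bernoulli p=0.5 flicker synchronized to 4 Hz acquisition.
    """

    n_animals: int = 120
    duration_s: float = 600.0
    stimulus_kind: str = "bernoulli"
    bernoulli_p: float = 0.5
    step_onset_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ParameterError("n_animals must be >= 1")
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be > 0")
        if self.stimulus_kind not in ("bernoulli", "step", "constant"):
            raise ParameterError(f"unknown stimulus_kind {self.stimulus_kind!r}")
        if self.stimulus_kind == "bernoulli" and not 0.0 < self.bernoulli_p < 1.0:
            raise ParameterError(f"bernoulli_p must be in (0, 1), got {self.bernoulli_p}")
        if self.seed < 0:
            raise ParameterError("seed must be non-negative")

    def n_frames(self, config: AcquisitionConfig) -> int:
        return round(self.duration_s * config.frame_rate_hz)


@dataclass(frozen=True)
class CalciumSimParams:
    """Parameters of the synthetic calcium-imaging trace generator.

    A trace is a baseline ``f0_level`` under multiplicative per-frame
    photobleaching ``bleach_rate``, plus (for responders) a double-exponential
    transient of peak ``response_amplitude * f0_level`` starting at
    stimulation onset, plus Gaussian noise.  Window counts default to the
    wash / stimulation / wash protocol: 100 + 200 + 100 frames at 85 ms.
    """

    f0_level: float = 100.0
    response_amplitude: float = 0.5
    bleach_rate: float = 0.9995
    noise_sd: float = 2.0
    n_pre_frames: int = 100
    n_stim_frames: int = 200
    n_post_frames: int = 100
    rise_tau_frames: float = 5.0
    decay_tau_frames: float = 40.0
    frame_period_ms: float = 85.0

    def __post_init__(self) -> None:
        if self.f0_level <= 0:
            raise ParameterError("f0_level must be > 0")
        if not 0 < self.bleach_rate <= 1:
            raise ParameterError("bleach_rate must be in (0, 1]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.rise_tau_frames <= 0 or self.decay_tau_frames <= 0:
            raise ParameterError("transient time constants must be > 0")
        if self.rise_tau_frames >= self.decay_tau_frames:
            raise ParameterError("rise_tau_frames must be < decay_tau_frames")

    @property
    def n_frames(self) -> int:
        return self.n_pre_frames + self.n_stim_frames + self.n_post_frames

    def transient_shape(self) -> np.ndarray:
        """Unit-peak double-exponential transient sampled from stimulation
        onset to the end of the trace."""
        t = np.arange(self.n_stim_frames + self.n_post_frames, dtype=np.float64)
        tr, td = self.rise_tau_frames, self.decay_tau_frames
        h = np.exp(-t / td) - np.exp(-t / tr)
        # continuous-time peak value used for normalization
        t_star = tr * td / (td - tr) * np.log(td / tr)
        h_max = np.exp(-t_star / td) - np.exp(-t_star / tr)
        return h / h_max


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def generate_bernoulli_stimulus(spec: SimulationSpec, config: AcquisitionConfig) -> StimulusTrace:
    """I.i.d. per-frame ON/OFF stimulus: the simplest white (flat-spectrum)
    process.  P(ON) = ``spec.bernoulli_p`` independently at every frame."""
    if spec.stimulus_kind != "bernoulli":
        raise ParameterError(f"spec.stimulus_kind is {spec.stimulus_kind!r}, not 'bernoulli'")
    rng = _rng(spec.seed, _STREAM_STIMULUS)
    led = (rng.random(spec.n_frames(config)) < spec.bernoulli_p).astype(np.uint8)
    return StimulusTrace(led_state=led, frame_rate_hz=config.frame_rate_hz)


def generate_step_stimulus(spec: SimulationSpec, config: AcquisitionConfig) -> StimulusTrace:
    """OFF before ``spec.step_onset_s``, ON from the onset frame onwards."""
    if spec.stimulus_kind != "step":
        raise ParameterError(f"spec.stimulus_kind is {spec.stimulus_kind!r}, not 'step'")
    if not 0 <= spec.step_onset_s < spec.duration_s:
        raise ParameterError(
            f"step_onset_s={spec.step_onset_s} outside [0, {spec.duration_s})"
        )
    n = spec.n_frames(config)
    onset = round(spec.step_onset_s * config.frame_rate_hz)
    led = np.zeros(n, dtype=np.uint8)
    led[onset:] = 1
    return StimulusTrace(led_state=led, frame_rate_hz=config.frame_rate_hz)


def generate_stimulus(spec: SimulationSpec, config: AcquisitionConfig) -> StimulusTrace:
    """Dispatch on ``spec.stimulus_kind`` (constant = always ON)."""
    if spec.stimulus_kind == "bernoulli":
        return generate_bernoulli_stimulus(spec, config)
    if spec.stimulus_kind == "step":
        return generate_step_stimulus(spec, config)
    led = np.ones(spec.n_frames(config), dtype=np.uint8)
    return StimulusTrace(led_state=led, frame_rate_hz=config.frame_rate_hz)


def stimulus_drive(params: LNPModelParams, stimulus: StimulusTrace) -> np.ndarray:
    """Filtered stimulus ``g_t = sum_l k_l s_{t-l}`` with pre-session history
    imputed as OFF (-1)."""
    enc = stimulus.encoded()
    k = params.filter_kernel
    padded = np.concatenate([np.full(k.size - 1, -1.0), enc]) if k.size > 1 else enc
    return np.correlate(padded, k[::-1], mode="valid")


def simulate_population(
    params: LNPModelParams,
    spec: SimulationSpec,
    stimulus: StimulusTrace,
) -> list[BehaviorTrack]:
    """Simulate ``spec.n_animals`` independent two-state chains under the
    shared session stimulus.

    Each animal starts in RUN at frame 0.  At frame t >= 1 the probability
    that the animal switches state (the new state beginning at t) is the
    clipped per-frame hazard evaluated with the stimulus drive at t.  Frames
    where the unclipped hazard reaches 1 are clipped to just below 1; if
    more than 1% of frame hazards clip, a warning is logged.
    """
    n_frames = round(spec.duration_s * stimulus.frame_rate_hz)
    if stimulus.n_frames < n_frames:
        raise ParameterError(
            f"stimulus has {stimulus.n_frames} frames; spec requires {n_frames}"
        )
    dt = 1.0 / stimulus.frame_rate_hz
    g = stimulus_drive(params, stimulus)[:n_frames]
    p_rt = params.baseline_run_to_turn_hazard * dt * np.exp(g)
    p_tr = params.baseline_turn_to_run_hazard * dt * np.exp(params.turn_filter_sign * g)
    n_clip = int((p_rt >= 1).sum() + (p_tr >= 1).sum())
    if n_clip > 0.01 * 2 * n_frames:
        logger.warning(
            "hazard*dt >= 1 before clipping at %d of %d frame hazards; "
            "results near the clip are saturated", n_clip, 2 * n_frames,
        )
    p_rt = np.clip(p_rt, 0.0, _HAZARD_CLIP)
    p_tr = np.clip(p_tr, 0.0, _HAZARD_CLIP)

    rng = _rng(spec.seed, _STREAM_POPULATION)
    states = np.empty((spec.n_animals, n_frames), dtype=np.uint8)
    states[:, 0] = BehaviorState.RUN
    u = rng.random((spec.n_animals, n_frames))
    run = int(BehaviorState.RUN)
    for t in range(1, n_frames):
        prev = states[:, t - 1]
        p_leave = np.where(prev == run, p_rt[t], p_tr[t])
        flip = u[:, t] < p_leave
        states[:, t] = np.where(flip, 1 - prev, prev)

    return [
        BehaviorTrack(animal_id=f"a{i:04d}", state=states[i])
        for i in range(spec.n_animals)
    ]


def simulate_session(
    params: LNPModelParams,
    spec: SimulationSpec,
    config: AcquisitionConfig,
) -> tuple[StimulusTrace, list[BehaviorTrack], dict]:
    """Generate stimulus + population for one session.

    Returns the stimulus, the tracks, and a ground-truth dictionary
    (JSON-serializable) recording the generative parameters for recovery
    tests.
    """
    stimulus = generate_stimulus(spec, config)
    tracks = simulate_population(params, spec, stimulus)
    truth = {
        "filter_kernel": params.filter_kernel.tolist(),
        "baseline_run_to_turn_hazard": params.baseline_run_to_turn_hazard,
        "baseline_turn_to_run_hazard": params.baseline_turn_to_run_hazard,
        "turn_filter_sign": params.turn_filter_sign,
        "nonlinearity": params.nonlinearity,
        "n_animals": spec.n_animals,
        "duration_s": spec.duration_s,
        "stimulus_kind": spec.stimulus_kind,
        "bernoulli_p": spec.bernoulli_p,
        "step_onset_s": spec.step_onset_s,
        "frame_rate_hz": config.frame_rate_hz,
        "seed": spec.seed,
    }
    return stimulus, tracks, truth


def simulate_calcium_trace(
    params: CalciumSimParams,
    responder: bool,
    seed: int,
    roi_id: str = "roi",
) -> FluorescenceTrace:
    """One synthetic fluorescence trace.

    intensity[t] = f0 * bleach^t  (+ responder transient)  + noise, clipped
    at 0 to keep intensities physical.
    """
    if responder and params.response_amplitude < 0:
        raise ParameterError("response_amplitude must be >= 0 for a responder")
    rng = _rng(seed, _STREAM_CALCIUM)
    t = np.arange(params.n_frames, dtype=np.float64)
    intensity = params.f0_level * params.bleach_rate ** t
    if responder:
        transient = params.f0_level * params.response_amplitude * params.transient_shape()
        intensity[params.n_pre_frames:] += transient
    if params.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, params.noise_sd, size=params.n_frames)
    intensity = np.maximum(intensity, 0.0)
    return FluorescenceTrace(
        roi_id=roi_id,
        intensity=intensity,
        frame_period_ms=params.frame_period_ms,
        n_pre_frames=params.n_pre_frames,
        n_stim_frames=params.n_stim_frames,
        n_post_frames=params.n_post_frames,
    )


def simulate_two_choice(
    true_p_stimulus_side: float,
    n_larvae: int = 30,
    n_assays: int = 15,
    p_neutral: float = 0.1,
    seed: int = 0,
    group: str = "",
) -> list[ChoiceAssayResult]:
    """Multinomial side counts for a batch of two-choice plates.

    Per assay the ``n_larvae`` animals fall into (neutral, stimulus side,
    control side) with probabilities (p_neutral, (1-p_neutral)*p,
    (1-p_neutral)*(1-p)) where p = ``true_p_stimulus_side``.
    """
    if not 0.0 <= true_p_stimulus_side <= 1.0:
        raise ParameterError("true_p_stimulus_side must be in [0, 1]")
    if not 0.0 <= p_neutral <= 1.0:
        raise ParameterError("p_neutral must be in [0, 1]")
    if n_larvae < 1 or n_assays < 1:
        raise ParameterError("n_larvae and n_assays must be >= 1")
    rng = _rng(seed, _STREAM_CHOICE)
    probs = [
        p_neutral,
        (1.0 - p_neutral) * true_p_stimulus_side,
        (1.0 - p_neutral) * (1.0 - true_p_stimulus_side),
    ]
    counts = rng.multinomial(n_larvae, probs, size=n_assays)
    prefix = f"{group}_" if group else ""
    return [
        ChoiceAssayResult(
            assay_id=f"{prefix}assay{i:03d}",
            n_stimulus_side=int(c[1]),
            n_control_side=int(c[2]),
            n_neutral=int(c[0]),
            group=group,
        )
        for i, c in enumerate(counts)
    ]
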