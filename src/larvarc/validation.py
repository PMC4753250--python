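"""End-to-end synthetic benchmarks of the analysis chain.

Because raw behavioural and imaging recordings of the original assays are
not available, the pipeline is validated against its own generative model:
simulate populations with a *known* stimulus filter, run the full analysis,
and check that the known structure is recovered.  Each function here runs
one benchmark at its stated study conditions and returns plain numbers, so
the same code backs both the test suite and ``scripts/acceptance.py``.

Study conditions (fixed, not tuning knobs): 120 animals per session, 600 s
at 4 Hz under Bernoulli p=0.5 flicker for triggered-average benchmarks;
60 s sessions with a light step at 30 s for step-response benchmarks; the
100/200/100-frame imaging protocol; 30 larvae x 15 plates for two-choice
benchmarks.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .calcium import compute_dff, test_response
from .choice_stats import assay_pi, compare_groups
from .config import AcquisitionConfig
from .containers import StimulusTrace
from .revcorr import (
    TransitionKind,
    detect_transitions,
    step_transition_probability,
    triggered_average,
)
from .synthetic_data import (
    CalciumSimParams,
    LNPModelParams,
    SimulationSpec,
    simulate_calcium_trace,
    simulate_session,
    simulate_two_choice,
)

__all__ = [
    "brute_force_triggered_average",
    "ta_oracle_check",
    "null_ta_coverage",
    "filter_recovery",
    "step_aversion",
    "dff_closed_form",
    "dff_gain_invariance",
    "water_test_type1",
    "choice_null_rejection",
    "choice_power",
]


# ----------------------------------------------------------------- oracle --

def brute_force_triggered_average(stimulus, events, kind, window_s, sem_method="cluster"):
    """Naive per-event reference implementation of the triggered average.

    Plain Python loops over events and lags; exists solely as an
    independent check of the vectorized implementation.  Returns
    (mean, sem, n_events) or None when no event is usable.
    """
    w = round(window_s * stimulus.frame_rate_hz)
    enc = stimulus.encoded()
    windows = []
    frames = []
    for e in events:
        if e.kind != kind:
            continue
        if e.frame < w or e.frame >= stimulus.n_frames:
            continue
        windows.append([enc[e.frame + lag] for lag in range(-w, 1)])
        frames.append(e.frame)
    if not windows:
        return None
    arr = np.array(windows)
    n = arr.shape[0]
    mean = arr.mean(axis=0)
    if n == 1:
        sem = np.zeros_like(mean)
    elif sem_method == "event":
        sem = arr.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        sem = np.empty_like(mean)
        for j in range(arr.shape[1]):
            sums: dict[int, float] = {}
            for f, row in zip(frames, arr):
                sums[f] = sums.get(f, 0.0) + (row[j] - mean[j])
            # clusters in frame order; numpy reduction so the comparison is
            # insensitive only to how the clusters were accumulated
            per_cluster = np.array([sums[f] for f in sorted(sums)])
            sem[j] = np.sqrt(np.sum(per_cluster ** 2)) / n
    return mean, sem, n


def ta_oracle_check(n_fixtures: int = 20, seed: int = 0) -> dict:
    """Compare the vectorized triggered average against the brute-force
    loop over randomized small sessions.

    Returns the max absolute differences separately for the mean, the event
    count, and each SEM estimator.  The mean, count and across-event SEM
    are expected to agree bit-exactly; the cluster SEM may differ by an ulp
    because the oracle accumulates clusters in a different order.
    """
    cfg = AcquisitionConfig()
    worst = {"mean": 0.0, "n_events": 0.0, "sem_event": 0.0, "sem_cluster": 0.0}
    rng = np.random.default_rng([seed, 101])
    for i in range(n_fixtures):
        duration = float(rng.integers(60, 120))
        spec = SimulationSpec(
            n_animals=int(rng.integers(3, 10)),
            duration_s=duration,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        params = LNPModelParams.aversive(amplitude=float(rng.uniform(0.0, 0.4)))
        stim, tracks, _ = simulate_session(params, spec, cfg)
        events = [e for t in tracks for e in detect_transitions(t)]
        window_s = float(rng.choice([5.0, 10.0, 20.0]))
        for kind in TransitionKind:
            for method in ("event", "cluster"):
                ref = brute_force_triggered_average(stim, events, kind, window_s, method)
                if ref is None:
                    continue
                ta = triggered_average(stim, events, kind, window_s, cfg, method)
                worst["mean"] = max(worst["mean"], float(np.max(np.abs(ta.mean - ref[0]))))
                worst[f"sem_{method}"] = max(
                    worst[f"sem_{method}"], float(np.max(np.abs(ta.sem - ref[1]))))
                worst["n_events"] = max(worst["n_events"], float(abs(ta.n_events - ref[2])))
    return worst


# ------------------------------------------------------- TA calibration --

def null_ta_coverage(n_sessions: int = 500, seed: int = 0) -> tuple[float, int]:
    """Coverage of zero by the +-1.96 SEM band of triggered averages from
    stimulus-independent (zero-filter) populations.

    Returns (coverage_percent, n_sessions).  Calibrated analysis gives
    ~95% pooled over lags, sessions and both transition kinds.
    """
    cfg = AcquisitionConfig()
    params = LNPModelParams()  # zero kernel
    base = np.random.default_rng([seed, 102]).integers(0, 2**31 - 1, size=n_sessions)
    inside = []
    for s in range(n_sessions):
        spec = SimulationSpec(seed=int(base[s]))
        stim, tracks, _ = simulate_session(params, spec, cfg)
        events = [e for t in tracks for e in detect_transitions(t)]
        for kind in TransitionKind:
            ta = triggered_average(stim, events, kind, config=cfg)
            inside.append(np.abs(ta.mean) <= 1.96 * ta.sem)
    return 100.0 * float(np.mean(np.concatenate(inside))), n_sessions


# -------------------------------------------------------- filter recovery --

def _aligned_kernel(params: LNPModelParams, n_lags: int, sign: float = 1.0) -> np.ndarray:
    """Ground-truth filter laid out on the TA lag axis: index l = lag -l
    frames, zero-padded beyond the kernel support."""
    k = np.zeros(n_lags)
    m = min(n_lags, params.filter_kernel.size)
    k[:m] = sign * params.filter_kernel[:m]
    return k


def filter_recovery(n_reps: int = 20, seed: int = 0, compare_window_s: float = 5.0) -> dict:
    """Recover a known aversive filter by reverse correlation.

    For each replicate: simulate 120 animals x 600 s under Bernoulli p=0.5
    with the default aversive filter, compute both triggered averages, and
    correlate the run->turn TA over lags [-compare_window_s, 0] with the
    (time-reversed, aligned) true filter.  Also checks the opposing-trend
    signature: near lag 0 the run->turn TA deviates positive and the
    turn->run TA negative.
    """
    cfg = AcquisitionConfig()
    params = LNPModelParams.aversive()
    base = np.random.default_rng([seed, 103]).integers(0, 2**31 - 1, size=n_reps)
    n_lags = round(compare_window_s * cfg.frame_rate_hz) + 1
    truth = _aligned_kernel(params, n_lags)
    rs, opposing = [], []
    for rep in range(n_reps):
        spec = SimulationSpec(seed=int(base[rep]))
        stim, tracks, _ = simulate_session(params, spec, cfg)
        events = [e for t in tracks for e in detect_transitions(t)]
        ta_rt = triggered_average(stim, events, TransitionKind.RUN_TO_TURN, config=cfg)
        ta_tr = triggered_average(stim, events, TransitionKind.TURN_TO_RUN, config=cfg)
        rec = ta_rt.mean[::-1][:n_lags]  # index l = lag -l frames
        rs.append(float(stats.pearsonr(rec, truth)[0]))
        near0 = slice(-5, None)  # lags -1..0 s at 4 Hz
        opposing.append(
            float(np.mean(ta_rt.mean[near0])) > 0 > float(np.mean(ta_tr.mean[near0]))
        )
    rs = np.array(rs)
    return {
        "median_r": float(np.median(rs)),
        "frac_r_above_0p9": float(np.mean(rs > 0.9)),
        "opposing_trend_frac": float(np.mean(opposing)),
        "n_reps": n_reps,
    }


# ---------------------------------------------------------- step response --

def step_aversion(n_reps: int = 20, seed: int = 0) -> dict:
    """Step-response benchmark: aversive population under a light step.

    120 animals, 60 s sessions with the step at 30 s.  A replicate succeeds
    when the peak post-step run->turn bin probability beats the pre-step
    baseline with one-sided p < 0.01 and the normal-approximation validity
    rule holds at the peak.
    """
    cfg = AcquisitionConfig()
    params = LNPModelParams.aversive()
    base = np.random.default_rng([seed, 104]).integers(0, 2**31 - 1, size=n_reps)
    success, peaks, baselines, zs = [], [], [], []
    for rep in range(n_reps):
        spec = SimulationSpec(
            stimulus_kind="step", duration_s=60.0, step_onset_s=30.0, seed=int(base[rep]),
        )
        stim, tracks, _ = simulate_session(params, spec, cfg)
        sr = step_transition_probability(tracks, stim, TransitionKind.RUN_TO_TURN, cfg)
        success.append(sr.valid and sr.p_value < 0.01)
        peaks.append(sr.peak_probability)
        baselines.append(sr.baseline_probability)
        zs.append(sr.z_stat)
    return {
        "success_frac": float(np.mean(success)),
        "mean_peak_probability": float(np.mean(peaks)),
        "mean_baseline_probability": float(np.mean(baselines)),
        "median_z": float(np.median(zs)),
        "n_reps": n_reps,
    }


# ----------------------------------------------------------------- dF/F ---

def dff_closed_form(amplitude: float = 0.5) -> dict:
    """Noise-free responder trace: measured dF/F vs its closed form.

    With no noise and no bleaching the peak intensity is f0 * (1 +
    amplitude * max_t h(t)) with h the unit-peak sampled transient, so
    dF/F(%) = 100 * amplitude * max_t h(t).
    """
    params = CalciumSimParams(
        response_amplitude=amplitude, noise_sd=0.0, bleach_rate=1.0,
    )
    trace = simulate_calcium_trace(params, responder=True, seed=0)
    res = compute_dff(trace)
    h = params.transient_shape()[: params.n_stim_frames]
    expected = 100.0 * amplitude * float(h.max())
    return {
        "dff_percent": res.dff_percent,
        "expected_percent": expected,
        "abs_error": abs(res.dff_percent - expected),
    }


def dff_gain_invariance(n_traces: int = 100, seed: int = 0) -> float:
    """Max change in dF/F (%) under multiplicative rescaling of random
    traces.  dF/F is a ratio, so a detector-gain change must not move it."""
    rng = np.random.default_rng([seed, 105])
    worst = 0.0
    for i in range(n_traces):
        params = CalciumSimParams(
            response_amplitude=float(rng.uniform(0.0, 1.0)),
            noise_sd=float(rng.uniform(0.0, 5.0)),
            bleach_rate=float(rng.uniform(0.998, 1.0)),
        )
        trace = simulate_calcium_trace(params, responder=bool(rng.integers(2)),
                                       seed=int(rng.integers(0, 2**31 - 1)))
        gain = float(rng.uniform(0.1, 10.0))
        scaled = type(trace)(
            roi_id=trace.roi_id,
            intensity=trace.intensity * gain,
            frame_period_ms=trace.frame_period_ms,
            n_pre_frames=trace.n_pre_frames,
            n_stim_frames=trace.n_stim_frames,
            n_post_frames=trace.n_post_frames,
        )
        d0 = compute_dff(trace).dff_percent
        d1 = compute_dff(scaled).dff_percent
        worst = max(worst, abs(d1 - d0))
    return worst


def water_test_type1(n_reps: int = 1000, n_pairs: int = 8, seed: int = 0,
                     alpha: float = 0.05) -> tuple[float, int]:
    """Type-I error of the water-baseline signed-rank test.

    Both samples are water-only (non-responder) traces, so every rejection
    is a false positive.  Returns (rejection_rate, n_reps); a calibrated
    test sits near alpha (the exact signed-rank test at n=8 is slightly
    conservative because of its discrete null).
    """
    params = CalciumSimParams()
    base = np.random.default_rng([seed, 106]).integers(0, 2**31 - 1, size=(n_reps, 2 * n_pairs))
    rejections = 0
    for rep in range(n_reps):
        dff = [
            compute_dff(simulate_calcium_trace(params, responder=False, seed=int(s))).dff_percent
            for s in base[rep]
        ]
        res = test_response(np.array(dff[:n_pairs]), np.array(dff[n_pairs:]), paired=True)
        rejections += res.p_value < alpha
    return rejections / n_reps, n_reps


# ------------------------------------------------------------ two-choice --

def choice_null_rejection(n_reps: int = 1000, n_assays: int = 15, seed: int = 0,
                          alpha: float = 0.05) -> tuple[float, int]:
    """Type-I error of the group comparison on indifferent populations:
    both groups drawn with true side preference p = 0.5."""
    base = np.random.default_rng([seed, 107]).integers(0, 2**31 - 1, size=(n_reps, 2))
    rejections = 0
    for rep in range(n_reps):
        a = [assay_pi(x) for x in simulate_two_choice(0.5, n_assays=n_assays, seed=int(base[rep, 0]))]
        b = [assay_pi(x) for x in simulate_two_choice(0.5, n_assays=n_assays, seed=int(base[rep, 1]))]
        res = compare_groups(np.array(a), np.array(b))
        rejections += res.p_value < alpha
    return rejections / n_reps, n_reps


def choice_power(n_reps: int = 200, n_assays: int = 15, seed: int = 0,
                 alpha: float = 0.05) -> dict:
    """Power of the group comparison at a strong-preference scenario:
    true p = 0.75 vs 0.5 with 30 larvae per plate, 15 plates per group.
    Also reports how often the preferring group's median PI is positive."""
    base = np.random.default_rng([seed, 108]).integers(0, 2**31 - 1, size=(n_reps, 2))
    rejections = 0
    median_positive = 0
    for rep in range(n_reps):
        a = [assay_pi(x) for x in simulate_two_choice(0.75, n_assays=n_assays, seed=int(base[rep, 0]))]
        b = [assay_pi(x) for x in simulate_two_choice(0.5, n_assays=n_assays, seed=int(base[rep, 1]))]
        res = compare_groups(np.array(a), np.array(b))
        rejections += res.p_value < alpha
        median_positive += np.median(a) > 0
    return {
        "power": rejections / n_reps,
        "median_pi_positive_frac": median_positive / n_reps,
        "n_reps": n_reps,
    }
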