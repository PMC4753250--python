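"""Tests of the stimulus, population, calcium and two-choice generators."""

import numpy as np
import pytest
from scipy import stats

from larvarc import (
    AcquisitionConfig,
    CalciumSimParams,
    LNPModelParams,
    ParameterError,
    SimulationSpec,
)
from larvarc.containers import BehaviorState
from larvarc.synthetic_data import (
    generate_bernoulli_stimulus,
    generate_step_stimulus,
    simulate_calcium_trace,
    simulate_population,
    simulate_two_choice,
)
from larvarc.choice_stats import assay_pi


@pytest.fixture
def cfg():
    return AcquisitionConfig()


class TestBernoulliStimulus:
    def test_white_process_statistics(self, cfg):
        """p=0.5 flicker: near-zero mean and vanishing autocorrelation."""
        n = 100_000
        spec = SimulationSpec(duration_s=n / 4.0, seed=3)
        enc = generate_bernoulli_stimulus(spec, cfg).encoded()
        assert abs(enc.mean()) < 0.01  # 3-sigma binomial bound at n=1e5
        centred = enc - enc.mean()
        denom = np.dot(centred, centred)
        for lag in range(1, 11):
            acf = np.dot(centred[:-lag], centred[lag:]) / denom
            assert abs(acf) < 3.0 / np.sqrt(n)

    def test_on_fraction_matches_p(self, cfg):
        spec = SimulationSpec(duration_s=25_000.0, bernoulli_p=0.3, seed=5)
        led = generate_bernoulli_stimulus(spec, cfg).led_state
        assert stats.binomtest(int(led.sum()), led.size, 0.3).pvalue > 0.01

    def test_extreme_p_nearly_all_on(self, cfg):
        spec = SimulationSpec(duration_s=250.0, bernoulli_p=0.999, seed=0)
        led = generate_bernoulli_stimulus(spec, cfg).led_state
        assert led.mean() > 0.99

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_p_outside_open_interval_rejected(self, p):
        with pytest.raises(ParameterError):
            SimulationSpec(bernoulli_p=p)


class TestStepStimulus:
    def test_onset_splits_session(self, cfg):
        spec = SimulationSpec(stimulus_kind="step", duration_s=60.0, step_onset_s=30.0)
        led = generate_step_stimulus(spec, cfg).led_state
        assert led[:120].sum() == 0
        assert led[120:].all()

    def test_onset_zero_is_all_on(self, cfg):
        spec = SimulationSpec(stimulus_kind="step", duration_s=10.0, step_onset_s=0.0)
        assert generate_step_stimulus(spec, cfg).led_state.all()

    def test_exactly_one_sign_change(self, cfg):
        spec = SimulationSpec(stimulus_kind="step", duration_s=60.0, step_onset_s=17.5)
        enc = generate_step_stimulus(spec, cfg).encoded()
        assert (np.diff(np.sign(enc)) != 0).sum() == 1

    def test_onset_outside_duration_rejected(self, cfg):
        spec = SimulationSpec(stimulus_kind="step", duration_s=60.0, step_onset_s=60.0)
        with pytest.raises(ParameterError):
            generate_step_stimulus(spec, cfg)


class TestPopulation:
    def test_zero_kernel_recovers_baseline_hazard(self, cfg):
        """Stimulus-independent population: empirical run->turn rate within
        3 SE of the 0.1 /s baseline (Poisson count error)."""
        spec = SimulationSpec(seed=11)
        stim = generate_bernoulli_stimulus(spec, cfg)
        tracks = simulate_population(LNPModelParams(), spec, stim)
        states = np.stack([t.state for t in tracks])
        run_prev = states[:, :-1] == BehaviorState.RUN
        events = int((run_prev & (states[:, 1:] == BehaviorState.TURN)).sum())
        run_time_s = run_prev.sum() * cfg.frame_dt_s
        rate = events / run_time_s
        se = np.sqrt(events) / run_time_s
        assert abs(rate - 0.1) < 3 * se

    def test_zero_hazard_never_turns(self, cfg):
        spec = SimulationSpec(n_animals=20, duration_s=100.0, seed=1)
        stim = generate_bernoulli_stimulus(spec, cfg)
        params = LNPModelParams(baseline_run_to_turn_hazard=0.0)
        tracks = simulate_population(params, spec, stim)
        assert all((t.state == BehaviorState.RUN).all() for t in tracks)

    def test_same_seed_is_deterministic(self, cfg):
        spec = SimulationSpec(n_animals=10, duration_s=60.0, seed=42)
        stim = generate_bernoulli_stimulus(spec, cfg)
        a = simulate_population(LNPModelParams.aversive(), spec, stim)
        b = simulate_population(LNPModelParams.aversive(), spec, stim)
        assert all(np.array_equal(x.state, y.state) for x, y in zip(a, b))

    def test_run_lengths_are_exponential(self, cfg):
        """Stimulus-independent run durations follow the memoryless law with
        mean 1/lambda_rt (KS on ~1e4 interior runs, alpha=0.01).

        On the frame grid the sojourn is geometric; sub-frame jitter maps it
        exactly onto the exponential with the frame-hazard rate
        -ln(1 - lambda dt)/dt, against which KS applies cleanly.  The mean
        duration itself is checked against 1/lambda_rt.
        """
        spec = SimulationSpec(n_animals=200, duration_s=600.0, seed=13)
        stim = generate_bernoulli_stimulus(spec, cfg)
        tracks = simulate_population(LNPModelParams(), spec, stim)
        lengths = []
        for t in tracks:
            is_run = np.concatenate([[0], (t.state == BehaviorState.RUN).astype(int), [0]])
            d = np.diff(is_run)
            starts, ends = np.nonzero(d == 1)[0], np.nonzero(d == -1)[0]
            # interior runs only: the censored first/last sojourns bias the law
            for s, e in zip(starts, ends):
                if s > 0 and e < t.n_frames:
                    lengths.append(e - s)
        lengths = np.asarray(lengths, dtype=float)
        assert lengths.size > 8_000
        durations_s = lengths * cfg.frame_dt_s
        se = durations_s.std(ddof=1) / np.sqrt(lengths.size)
        assert abs(durations_s.mean() - 10.0) < 3 * se

        p_frame = 0.1 * cfg.frame_dt_s
        scale = cfg.frame_dt_s / -np.log1p(-p_frame)
        jitter = np.random.default_rng(0).random(lengths.size)
        d_stat = stats.kstest((lengths - jitter) * cfg.frame_dt_s,
                              "expon", args=(0, scale)).statistic
        assert d_stat < 1.63 / np.sqrt(lengths.size)  # KS critical value, alpha=0.01

    def test_nan_kernel_rejected(self):
        with pytest.raises(ParameterError):
            LNPModelParams(filter_kernel=np.array([0.1, np.nan]))

    def test_saturating_hazard_logs_warning(self, cfg, caplog):
        spec = SimulationSpec(n_animals=2, duration_s=30.0, seed=0)
        stim = generate_bernoulli_stimulus(spec, cfg)
        params = LNPModelParams(baseline_run_to_turn_hazard=50.0)
        with caplog.at_level("WARNING", logger="larvarc.synthetic_data"):
            simulate_population(params, spec, stim)
        assert any("clip" in r.message for r in caplog.records)


class TestCalciumTraces:
    def test_noise_free_nonresponder_is_constant(self):
        params = CalciumSimParams(noise_sd=0.0, bleach_rate=1.0)
        trace = simulate_calcium_trace(params, responder=False, seed=0)
        assert np.allclose(trace.intensity, params.f0_level)

    def test_same_seed_identical(self):
        params = CalciumSimParams()
        a = simulate_calcium_trace(params, True, seed=9)
        b = simulate_calcium_trace(params, True, seed=9)
        assert np.array_equal(a.intensity, b.intensity)

    def test_negative_amplitude_responder_rejected(self):
        params = CalciumSimParams(response_amplitude=-0.5)
        with pytest.raises(ParameterError):
            simulate_calcium_trace(params, responder=True, seed=0)

    def test_protocol_window_defaults(self):
        trace = simulate_calcium_trace(CalciumSimParams(), False, 0)
        assert trace.n_frames == 400
        assert trace.stim_slice == slice(100, 300)


class TestTwoChoice:
    def test_counts_conserved(self):
        for assay in simulate_two_choice(0.3, n_larvae=30, n_assays=50, seed=2):
            assert assay.n_total == 30

    def test_complete_preference_gives_pi_one(self):
        assays = simulate_two_choice(1.0, p_neutral=0.0, n_assays=20, seed=3)
        assert all(assay_pi(a) == 1.0 for a in assays)

    def test_indifference_gives_zero_mean_pi(self):
        assays = simulate_two_choice(0.5, p_neutral=0.0, n_assays=10_000, seed=4)
        pis = np.array([assay_pi(a) for a in assays])
        se = pis.std(ddof=1) / np.sqrt(pis.size)
        assert abs(pis.mean()) < 3 * se

    def test_invalid_probability_rejected(self):
        with pytest.raises(ParameterError):
            simulate_two_choice(1.5)
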