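"""Tests of transition detection, triggered averages and the step response."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from larvarc import (
    AcquisitionConfig,
    ConfigurationError,
    InsufficientDataError,
    IntegrityError,
    LNPModelParams,
    ParameterError,
    SimulationSpec,
    StimulusTrace,
    TransitionEvent,
    TransitionKind,
)
from larvarc.revcorr import (
    detect_transitions,
    encode_stimulus,
    revcorr_report,
    step_transition_probability,
    triggered_average,
)
from larvarc.synthetic_data import generate_step_stimulus, simulate_session
from larvarc.validation import brute_force_triggered_average

from conftest import make_track

RT = TransitionKind.RUN_TO_TURN
TR = TransitionKind.TURN_TO_RUN


class TestEncodeStimulus:
    def test_on_off_mapping(self):
        trace = StimulusTrace(np.array([1, 0, 1], dtype=np.uint8))
        assert encode_stimulus(trace).tolist() == [1.0, -1.0, 1.0]

    def test_all_off_is_minus_one(self):
        trace = StimulusTrace(np.zeros(5, dtype=np.uint8))
        assert (encode_stimulus(trace) == -1.0).all()

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=200))
    def test_mean_is_affine_in_on_fraction(self, bits):
        trace = StimulusTrace(np.array(bits, dtype=np.uint8))
        assert encode_stimulus(trace).mean() == pytest.approx(2 * np.mean(bits) - 1)


class TestDetectTransitions:
    def test_run_turn_run_sequence(self):
        events = detect_transitions(make_track("RRRTTR"))
        assert [(e.frame, e.kind) for e in events] == [(3, RT), (5, TR)]

    def test_constant_run_has_no_events(self):
        assert detect_transitions(make_track("RRRRRR")) == []

    def test_change_across_invalid_gap_discarded(self):
        assert detect_transitions(make_track("RR??T")) == []

    def test_change_with_valid_flanks_kept_after_gap(self):
        events = detect_transitions(make_track("RR??TT"))
        assert events == []  # the R->T change itself straddles the gap
        events = detect_transitions(make_track("RR?RTT"))
        assert [(e.frame, e.kind) for e in events] == [(4, RT)]

    def test_single_frame_track_has_no_events(self):
        assert detect_transitions(make_track("R")) == []

    def test_frame_start_offsets_event_frames(self):
        track = make_track("RRT")
        shifted = type(track)(animal_id="a", state=track.state, valid=track.valid,
                              frame_start=100)
        assert detect_transitions(shifted)[0].frame == 102


class TestTriggeredAverage:
    def test_constant_on_stimulus(self, constant_on_stimulus):
        events = [TransitionEvent("a", f, RT) for f in (100, 200, 300)]
        ta = triggered_average(constant_on_stimulus, events, RT, window_s=5.0)
        assert (ta.mean == 1.0).all()
        assert (ta.sem == 0.0).all()
        assert ta.n_events == 3
        assert ta.lags_s[0] == -5.0 and ta.lags_s[-1] == 0.0

    def test_single_event_returns_its_window(self):
        rng = np.random.default_rng(1)
        stim = StimulusTrace(rng.integers(0, 2, 100, dtype=np.uint8))
        ta = triggered_average(stim, [TransitionEvent("a", 50, RT)], RT, window_s=2.0)
        assert np.array_equal(ta.mean, stim.encoded()[42:51])
        assert (ta.sem == 0.0).all()

    def test_events_without_full_window_excluded_and_counted(self, constant_on_stimulus):
        events = [TransitionEvent("a", 3, RT), TransitionEvent("a", 100, RT)]
        ta = triggered_average(constant_on_stimulus, events, RT, window_s=5.0)
        assert ta.n_events == 1
        assert ta.n_excluded == 1

    def test_no_usable_events_raises(self, constant_on_stimulus):
        with pytest.raises(InsufficientDataError):
            triggered_average(constant_on_stimulus, [TransitionEvent("a", 2, RT)],
                              RT, window_s=5.0)

    @pytest.mark.parametrize("sem_method", ["cluster", "event"])
    def test_matches_brute_force_loop(self, config, sem_method):
        """Vectorized implementation vs naive per-event loop on a simulated
        50+-event session."""
        spec = SimulationSpec(n_animals=6, duration_s=120.0, seed=5)
        stim, tracks, _ = simulate_session(LNPModelParams.aversive(), spec, config)
        events = [e for t in tracks for e in detect_transitions(t)]
        assert len(events) >= 50
        for kind in TransitionKind:
            ta = triggered_average(stim, events, kind, 10.0, config, sem_method)
            mean, sem, n = brute_force_triggered_average(stim, events, kind, 10.0, sem_method)
            assert np.array_equal(ta.mean, mean)
            assert np.allclose(ta.sem, sem, rtol=0, atol=1e-15)
            assert ta.n_events == n

    def test_mean_bounded_and_sem_nonnegative(self, config):
        spec = SimulationSpec(n_animals=4, duration_s=90.0, seed=8)
        stim, tracks, _ = simulate_session(LNPModelParams.aversive(), spec, config)
        events = [e for t in tracks for e in detect_transitions(t)]
        ta = triggered_average(stim, events, RT, config=config)
        assert (np.abs(ta.mean) <= 1.0).all()
        assert (ta.sem >= 0.0).all()


def _step_session(n_animals=120, duration_s=40.0, onset_s=20.0, cfg=None):
    cfg = cfg or AcquisitionConfig()
    spec = SimulationSpec(stimulus_kind="step", n_animals=n_animals,
                          duration_s=duration_s, step_onset_s=onset_s)
    return generate_step_stimulus(spec, cfg), cfg


def _constant_run_tracks(n_animals, n_frames):
    return [make_track("R" * n_frames, f"a{i}") for i in range(n_animals)]


class TestStepResponse:
    def test_no_events_reported_invalid(self):
        stim, cfg = _step_session()
        sr = step_transition_probability(_constant_run_tracks(120, 160), stim, RT, cfg)
        assert (sr.probability == 0.0).all()
        assert np.isnan(sr.z_stat)
        assert not sr.valid

    def test_single_turner_probability_is_one_over_n(self):
        stim, cfg = _step_session()
        tracks = _constant_run_tracks(119, 160)
        tracks.append(make_track("R" * 90 + "T" * 70, "turner"))
        sr = step_transition_probability(tracks, stim, RT, cfg)
        # frame 90 -> bin 90 (0.25 s bins = 1 frame at 4 Hz)
        assert sr.probability[90] == pytest.approx(1 / 120)

    def test_np_rule_flags_small_peak_invalid(self):
        """Peak with 4/120 turners: n*p = 4 < 5 -> normal approximation
        invalid, even though z is computable."""
        stim, cfg = _step_session()
        tracks = _constant_run_tracks(115, 160)
        for i in range(4):  # post-step turners sharing one bin
            tracks.append(make_track("R" * 100 + "T" * 60, f"p{i}"))
        tracks.append(make_track("R" * 10 + "T" * 150, "pre"))  # baseline event
        sr = step_transition_probability(tracks, stim, RT, cfg)
        assert sr.peak_probability == pytest.approx(4 / 120)
        assert np.isfinite(sr.z_stat)
        assert not sr.valid

    def test_probability_mass_conserves_event_count(self, config):
        spec = SimulationSpec(stimulus_kind="step", n_animals=60, duration_s=60.0,
                              step_onset_s=30.0, seed=3)
        stim, tracks, _ = simulate_session(LNPModelParams.aversive(), spec, config)
        sr = step_transition_probability(tracks, stim, RT, config)
        n_events = sum(e.kind == RT for t in tracks for e in detect_transitions(t))
        assert np.sum(sr.probability * sr.n_at_risk) == pytest.approx(n_events)

    def test_lost_animals_reduce_denominator(self):
        stim, cfg = _step_session(n_animals=3)
        tracks = _constant_run_tracks(2, 160)
        lost = make_track("R" * 160, "lost")
        lost = type(lost)(animal_id="lost", state=lost.state,
                          valid=np.arange(160) < 80, frame_start=0)
        tracks.append(lost)
        sr = step_transition_probability(tracks, stim, RT, cfg)
        assert sr.n_at_risk[0] == 3
        assert sr.n_at_risk[-1] == 2

    def test_onset_at_zero_has_no_baseline(self):
        stim, cfg = _step_session(onset_s=0.0)
        with pytest.raises(ConfigurationError):
            step_transition_probability(_constant_run_tracks(5, 160), stim, RT, cfg)

    def test_no_animals_rejected(self):
        stim, cfg = _step_session()
        with pytest.raises(ParameterError):
            step_transition_probability([], stim, RT, cfg)

    def test_mismatched_track_length_rejected(self):
        stim, cfg = _step_session()
        with pytest.raises(IntegrityError):
            step_transition_probability([make_track("RRRR")], stim, RT, cfg)

    def test_non_step_stimulus_rejected(self):
        flicker = StimulusTrace(np.array([0, 1, 0, 1] * 40, dtype=np.uint8))
        with pytest.raises(ParameterError):
            step_transition_probability(_constant_run_tracks(5, 160), flicker, RT)


class TestRevcorrReport:
    def test_single_animal_report_is_produced(self, config):
        spec = SimulationSpec(n_animals=1, duration_s=200.0, seed=2)
        stim, tracks, _ = simulate_session(LNPModelParams.aversive(), spec, config)
        report = revcorr_report(tracks, stim, config)
        assert report.n_animals == 1
        assert set(report.n_events) == {RT.value, TR.value}

    def test_report_is_deterministic(self, config):
        spec = SimulationSpec(n_animals=8, duration_s=120.0, seed=6)
        stim, tracks, _ = simulate_session(LNPModelParams.aversive(), spec, config)
        r1 = revcorr_report(tracks, stim, config)
        r2 = revcorr_report(tracks, stim, config)
        assert np.array_equal(r1.ta_run_to_turn.mean, r2.ta_run_to_turn.mean)
        assert np.array_equal(r1.ta_run_to_turn.sem, r2.ta_run_to_turn.sem)

    def test_aversive_kernel_ta_rises_toward_lag_zero(self, config):
        """End-to-end sign check: with an aversive filter the run->turn TA
        climbs toward the initiation frame."""
        spec = SimulationSpec(n_animals=60, duration_s=300.0, seed=9)
        stim, tracks, _ = simulate_session(LNPModelParams.aversive(), spec, config)
        ta = revcorr_report(tracks, stim, config).ta_run_to_turn
        early = ta.mean[: ta.mean.size // 2].mean()
        assert ta.mean[-1] > 0.1
        assert ta.mean[-1] > early
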