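"""Fitting condition: windowed response extraction and end-to-end rule calibration."""

import numpy as np
import pytest

from stressloop.characteristics import Adjustment, CharacteristicSpec
from stressloop.errors import FittingError, LogIntegrityError, ProtocolError
from stressloop.fitting import FittingProtocol, build_protocol, extract_responses, run_fitting
from stressloop.session_io import Marker, MarkerLog
from stressloop.signal_model import BaselineStats
from stressloop.subject_sim import SubjectSimulator, default_characteristics, make_subject

from .conftest import step_log


def _adj_marker(t, char="sound", x=5.0):
    return Marker(t, "adjustment", char, repr(float(x)))


def _baseline(channels, mu=50.0, sigma=2.0):
    n = len(channels)
    return BaselineStats(channels, np.full(n, mu), np.full(n, sigma), np.full(n, 100), 60.0)


class TestProtocolValidation:
    def test_empty_protocol_rejected(self):
        with pytest.raises(ProtocolError):
            FittingProtocol([]).validate()

    def test_overlapping_windows_rejected(self):
        adj = Adjustment("sound", value=1.0)
        proto = FittingProtocol([(adj, 30.0), (adj, 45.0)], pre_window_s=10.0, post_window_s=10.0)
        with pytest.raises(ProtocolError, match="overlap"):
            proto.validate()

    def test_non_increasing_onsets_rejected(self):
        adj = Adjustment("sound", value=1.0)
        with pytest.raises(ProtocolError):
            FittingProtocol([(adj, 50.0), (adj, 50.0)]).validate()

    def test_built_protocol_is_valid_and_covers_everything(self, specs):
        proto = build_protocol(specs, x_levels=4, repetitions=2, seed=0)
        proto.validate()
        chars = {adj.characteristic for adj, _ in proto.sequence}
        assert chars == set(specs)
        # every ordered realism transition appears `repetitions` times
        realism = [adj.transition for adj, _ in proto.sequence if adj.characteristic == "realism"]
        assert sorted(realism) == sorted(specs["realism"].transitions() * 2)


class TestExtractResponses:
    def test_clean_step_measured_in_g_units(self, channels):
        # +2 sigma step (sigma=2 -> height 4) with mild noise on every channel
        log = step_log(channels, t_step=30.0, base=50.0, height=4.0,
                       noise_sd=0.05 * 2.0, seed=1, t1=60.0)
        markers = MarkerLog([_adj_marker(30.0)])
        obs, dropped = extract_responses(log, markers, channels, pre_s=10.0, post_s=10.0,
                                         sigma_source="global",
                                         global_baseline=_baseline(channels))
        assert not dropped and len(obs) == 1
        assert np.allclose(obs[0].delta_g, 2.0, atol=0.1)
        assert obs[0].x == 5.0

    def test_marker_at_log_edge_dropped_and_reported(self, channels):
        # first marker's pre-window starts before the log does -> trial dropped
        log = step_log(channels, t_step=30.0, base=50.0, height=4.0, t1=60.0)
        markers = MarkerLog([_adj_marker(5.0), _adj_marker(30.0)])
        obs, dropped = extract_responses(log, markers, channels, pre_s=10.0, post_s=10.0,
                                         sigma_source="global",
                                         global_baseline=_baseline(channels))
        assert len(obs) == 1 and len(dropped) == 1
        assert "t=5" in dropped[0]

    def test_unknown_characteristic_is_integrity_error(self, channels):
        log = step_log(channels, t_step=30.0, base=50.0, height=0.0, t1=60.0)
        markers = MarkerLog([_adj_marker(30.0, char="mystery")])
        with pytest.raises(LogIntegrityError):
            extract_responses(log, markers, channels, known_specs={"sound"},
                              sigma_source="global", global_baseline=_baseline(channels))

    def test_identical_trials_give_identical_deltas(self, channels):
        """Response-consistency: zero noise, two identical steps -> equal delta_g."""
        from stressloop.signal_model import SignalLog
        a = step_log(channels, t_step=30.0, base=50.0, height=4.0, t0=0.0, t1=45.0)
        series = {}
        for ch in channels:
            t1, v1 = a.channel(ch.name)
            series[ch.name] = (np.concatenate([t1, t1 + 60.0]),
                               np.concatenate([v1, v1]))
        log = SignalLog(series)
        markers = MarkerLog([_adj_marker(30.0), _adj_marker(90.0)])
        obs, _ = extract_responses(log, markers, channels, sigma_source="global",
                                   global_baseline=_baseline(channels))
        assert np.array_equal(obs[0].delta_g, obs[1].delta_g)

    def test_pre_sigma_flooring_needs_global_baseline(self, channels):
        log = step_log(channels, t_step=30.0, base=50.0, height=4.0, t1=60.0)  # zero noise
        markers = MarkerLog([_adj_marker(30.0)])
        from stressloop.errors import DegenerateBaselineError
        with pytest.raises(DegenerateBaselineError):
            extract_responses(log, markers, channels, sigma_source="pre", global_baseline=None)
        obs, _ = extract_responses(log, markers, channels, sigma_source="pre",
                                   global_baseline=_baseline(channels))
        # constant pre-window floored at 1e-6 * global sigma -> huge g, but finite
        assert np.all(np.isfinite(obs[0].delta_g))


class TestRunFitting:
    def test_discrete_ground_truth_recovered_from_two_trials(self):
        """Zero-noise subject, two realism trials -> fitted column matches truth."""
        subject = make_subject("easy", 11)
        subject.noise_sd[:] = 0.0
        specs = {"realism": default_characteristics(11)["realism"]}
        seq = [(Adjustment("realism", from_level="first_person", to_level="third_person"), 75.0),
               (Adjustment("realism", from_level="third_person", to_level="first_person"), 110.0),
               (Adjustment("realism", from_level="first_person", to_level="third_person"), 145.0),
               (Adjustment("realism", from_level="third_person", to_level="first_person"), 180.0)]
        proto = FittingProtocol(seq, post_settle_s=2.5)
        res = run_fitting(proto, SubjectSimulator(subject), subject.channels, specs,
                          global_baseline=subject.nominal_baseline(), sigma_source="global")
        rule = res.model.rules["realism"]
        truth = subject.transition_shift("realism", "first_person", "third_person")
        expected = truth / subject.baseline_sigma
        assert np.allclose(rule.D[:, 0], expected, atol=0.05)
        assert np.allclose(rule.D[:, 1], -expected, atol=0.05)

    def test_noiseless_continuous_recovery_is_near_exact(self):
        """With zero noise and settled windows, OLS recovers the true affine response."""
        subject = make_subject("easy", 4)
        subject.noise_sd[:] = 0.0
        subject.latency_s, subject.decay_tau_s = 0.2, 0.2
        specs = {"soundscape": default_characteristics(4)["soundscape"]}
        proto = build_protocol(specs, x_levels=5, repetitions=2, seed=4, post_settle_s=5.0)
        res = run_fitting(proto, SubjectSimulator(subject), subject.channels, specs,
                          global_baseline=subject.nominal_baseline(), sigma_source="global")
        rule = res.model.rules["soundscape"]
        g0, g1 = subject.continuous_truth["soundscape"]
        assert np.allclose(rule.beta1, g1 / subject.baseline_sigma, atol=1e-6)
        assert np.allclose(rule.beta0, g0 / subject.baseline_sigma, atol=1e-6)

    def test_empty_protocol_is_an_error(self, easy_subject, specs):
        with pytest.raises(ProtocolError):
            run_fitting(FittingProtocol([]), SubjectSimulator(easy_subject),
                        easy_subject.channels, specs)

    def test_overlap_detected_before_presentation(self, easy_subject, specs):
        adj = Adjustment("soundscape", value=5.0)
        proto = FittingProtocol([(adj, 70.0), (adj, 75.0)])
        sim = SubjectSimulator(easy_subject)
        with pytest.raises(ProtocolError):
            run_fitting(proto, sim, easy_subject.channels, specs)
        assert sim.adjustments_applied == 0

    def test_file_source_must_cover_protocol(self, channels):
        log = step_log(channels, t_step=30.0, base=50.0, height=1.0, t1=50.0)
        markers = MarkerLog([_adj_marker(30.0)])
        spec = CharacteristicSpec("sound", "continuous", scale_range=(0.0, 10.0))
        proto = FittingProtocol([(Adjustment("sound", value=5.0), 30.0),
                                 (Adjustment("sound", value=2.0), 120.0)])
        with pytest.raises(ProtocolError):
            run_fitting(proto, (log, markers), channels, {"sound": spec},
                        global_baseline=_baseline(channels))

    def test_repetitions_do_not_hurt_discrete_accuracy(self):
        """Median |error| of fitted D entries with 4 reps <= with 2 reps (across seeds)."""
        errs = {2: [], 4: []}
        for seed in range(6):
            for reps in (2, 4):
                subject = make_subject("easy", 100 + seed)
                specs = {"realism": default_characteristics(100 + seed)["realism"]}
                proto = build_protocol(specs, repetitions=reps, seed=seed, post_settle_s=2.5)
                res = run_fitting(proto, SubjectSimulator(subject), subject.channels, specs,
                                  global_baseline=subject.nominal_baseline(),
                                  sigma_source="global")
                truth = (subject.transition_shift("realism", "first_person", "third_person")
                         / subject.baseline_sigma)
                err = np.abs(res.model.rules["realism"].D - np.column_stack([truth, -truth]))
                errs[reps].append(np.median(err))
        assert np.median(errs[4]) <= np.median(errs[2]) + 1e-12
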