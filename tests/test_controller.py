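"""Closed-loop behavior: candidate generation, argmin selection, tracking."""

import numpy as np
import pytest

from stressloop.characteristics import CharacteristicSpec
from stressloop.controller import (
    CandidatePrediction,
    baseline_measurement,
    candidate_set,
    control_loop,
    select_rule,
)
from stressloop.errors import ControllerError, ProtocolError
from stressloop.rules import ContinuousRule, DiscreteRule, FeedbackModel
from stressloop.signal_model import Channel, ChannelSet
from stressloop.subject_sim import SubjectSimulator, default_characteristics, make_subject


def brute_force_select(candidates, s_c, s_d, g, tol=1e-9):
    """Independent exhaustive oracle for the selection rule."""
    best = min(abs(s_d - (s_c + c.delta_hat)) for c in candidates)
    tied = [c for c in candidates if abs(s_d - (s_c + c.delta_hat)) <= best + tol]
    k = int(np.argmax(np.abs(s_d - np.asarray(g))))
    return min(tied, key=lambda c: (-abs(c.delta_g_hat[k]), c.characteristic,
                                    c.adjustment.payload_str()))


def _candidate(name, delta, dg, payload_x=None):
    from stressloop.characteristics import Adjustment
    adj = Adjustment(name, value=0.0 if payload_x is None else payload_x)
    return CandidatePrediction(name, adj, delta, delta, np.asarray(dg, float))


@pytest.fixture
def two_level_model(channels):
    rule = DiscreteRule("realism", [("first", "third"), ("third", "first")],
                        np.tile([[0.5], [-0.5]], (2, 1)).reshape(4, 1).repeat(2, axis=1) * [1, -1])
    return FeedbackModel(channels, np.ones(4), {"realism": rule})


class TestCandidateSet:
    def test_discrete_candidates_leave_current_level_only(self, channels, two_level_model):
        spec = CharacteristicSpec("realism", "discrete", levels=("first", "third"),
                                  current_level="first")
        cands = candidate_set(two_level_model, {"realism": spec}, s_c=0.0, s_d=1.0)
        assert len(cands) == 1
        assert cands[0].adjustment.transition == ("first", "third")

    def test_three_level_rule_yields_two_candidates_from_middle(self, channels):
        levels = ("A", "B", "C")
        from stressloop.characteristics import enumerate_transitions
        transitions = enumerate_transitions(levels)
        rule = DiscreteRule("c", transitions, np.ones((4, 6)))
        model = FeedbackModel(channels, np.ones(4), {"c": rule})
        spec = CharacteristicSpec("c", "discrete", levels=levels, current_level="B")
        cands = candidate_set(model, {"c": spec}, 0.0, 1.0)
        assert sorted(c.adjustment.transition for c in cands) == [("B", "A"), ("B", "C")]

    def test_continuous_candidate_inverts_exactly_when_reachable(self, channels):
        rule = ContinuousRule("sound", np.zeros(4), np.full(4, 0.1), (0.0, 10.0))
        model = FeedbackModel(channels, np.ones(4), {"sound": rule})
        spec = CharacteristicSpec("sound", "continuous", scale_range=(0.0, 10.0))
        cands = candidate_set(model, {"sound": spec}, s_c=0.2, s_d=0.8)
        assert len(cands) == 1
        assert cands[0].delta_hat == pytest.approx(0.6, abs=1e-12)
        assert cands[0].predicted_state == pytest.approx(0.8)
        assert cands[0].adjustment.value == pytest.approx(6.0)

    def test_offset_aware_inversion_accounts_for_active_value(self, channels):
        rule = ContinuousRule("sound", np.zeros(4), np.full(4, 0.1), (0.0, 10.0))
        model = FeedbackModel(channels, np.ones(4), {"sound": rule})
        spec = CharacteristicSpec("sound", "continuous", scale_range=(0.0, 10.0))
        # already at x=6 contributing 0.6; state on target -> keep the same value
        cands = candidate_set(model, {"sound": spec}, s_c=0.8, s_d=0.8,
                              current_x={"sound": 6.0})
        assert cands[0].adjustment.value == pytest.approx(6.0)
        assert cands[0].delta_hat == pytest.approx(0.0, abs=1e-12)
        # literal mode reproduces the plain inversion of s_d - s_c
        literal = candidate_set(model, {"sound": spec}, s_c=0.8, s_d=0.8,
                                current_x={"sound": 6.0}, account_current=False)
        assert literal[0].adjustment.value == pytest.approx(0.0)

    def test_non_invertible_rule_contributes_best_endpoint(self, channels):
        rule = ContinuousRule("sound", np.full(4, 0.3), np.zeros(4), (0.0, 10.0))
        model = FeedbackModel(channels, np.ones(4), {"sound": rule})
        spec = CharacteristicSpec("sound", "continuous", scale_range=(0.0, 10.0))
        cands = candidate_set(model, {"sound": spec}, 0.0, 1.0)
        assert len(cands) == 1 and cands[0].adjustment.value in (0.0, 10.0)

    def test_catalog_backed_candidate_snaps_to_stimulus(self, channels, catalog):
        rule = ContinuousRule("img", np.zeros(4), np.full(4, 0.1), catalog.scale_range)
        model = FeedbackModel(channels, np.ones(4), {"img": rule})
        spec = CharacteristicSpec("img", "continuous", catalog=catalog,
                                  presentation="transient", transient_duration_s=5.0)
        cands = candidate_set(model, {"img": spec}, 0.0, 1.0)
        assert cands[0].adjustment.stimulus_id in set(catalog.table["stimulus_id"])

    def test_empty_model_is_a_controller_error(self, channels):
        model = FeedbackModel(channels, np.ones(4), {})
        with pytest.raises(ControllerError):
            candidate_set(model, {}, 0.0, 1.0)


class TestSelectRule:
    def test_exact_match_wins(self):
        cands = [_candidate("a", 0.5, [0.5] * 4), _candidate("b", 1.0, [1.0] * 4),
                 _candidate("c", 2.0, [2.0] * 4)]
        assert select_rule(cands, 0.0, 1.0, np.zeros(4)).characteristic == "b"

    def test_tie_break_prefers_effect_on_farthest_channel(self):
        # both candidates predict s=1.2; channel 0 sits farthest from target
        # (|1.2 - 0.2| = 1.0 vs |1.2 - 1.8| = 0.6)
        g = np.array([0.2, 1.8])
        a = _candidate("a", 1.2, [1.0, 0.1])
        b = _candidate("b", 1.2, [0.1, 1.0])
        chosen = select_rule([a, b], 0.0, 1.2, g)
        assert chosen.characteristic == "a"  # larger |delta_g| on channel 0

    def test_residual_tie_breaks_by_name_then_payload(self):
        g = np.zeros(2)
        a = _candidate("zeta", 1.0, [1.0, 1.0])
        b = _candidate("alpha", 1.0, [1.0, 1.0])
        assert select_rule([a, b], 0.0, 1.0, g).characteristic == "alpha"
        c = _candidate("alpha", 1.0, [1.0, 1.0], payload_x=2.0)
        d = _candidate("alpha", 1.0, [1.0, 1.0], payload_x=9.0)
        assert select_rule([d, c], 0.0, 1.0, g).adjustment.value == 2.0

    def test_empty_candidates_signal_no_action(self):
        assert select_rule([], 0.0, 1.0, np.zeros(2)) is None

    def test_equivalent_to_brute_force_oracle_on_random_sets(self):
        """200 seeded random candidate sets: identical choice to exhaustive argmin."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(1, 9))
            n_ch = int(rng.integers(2, 5))
            g = rng.normal(size=n_ch)
            s_c, s_d = rng.normal(), rng.normal()
            cands = []
            deltas = rng.choice([0.0, 0.4, 1.0], size=n) + rng.choice([0.0, 1e-12], size=n)
            for i in range(n):
                c = _candidate(f"ch{rng.integers(0, 4)}", float(deltas[i]),
                               rng.normal(size=n_ch), payload_x=float(rng.integers(0, 5)))
                c.predicted_state = s_c + c.delta_hat
                cands.append(c)
            assert select_rule(cands, s_c, s_d, g) is brute_force_select(cands, s_c, s_d, g)


class TestBaselineMeasurement:
    def test_sigma_estimate_within_sampling_tolerance(self, easy_subject):
        easy_subject.noise_sd[:] = 2.0
        sim = SubjectSimulator(easy_subject)
        stats = baseline_measurement(sim, 75.0)  # 600 samples at 8 Hz
        assert np.allclose(stats.sigma, 2.0, rtol=0.15)
        assert np.allclose(stats.mu, easy_subject.baseline_mu, atol=0.5)

    def test_short_baseline_rejected(self, easy_subject):
        with pytest.raises(ProtocolError):
            baseline_measurement(SubjectSimulator(easy_subject), 10.0)

    def test_active_adjustment_rejected(self, easy_subject):
        from stressloop.characteristics import Adjustment
        sim = SubjectSimulator(easy_subject)
        sim.apply(Adjustment("soundscape", value=8.0), 0.0)
        with pytest.raises(ProtocolError):
            baseline_measurement(sim, 60.0)

    def test_zero_noise_sigma_floored(self, easy_subject):
        easy_subject.noise_sd[:] = 0.0
        stats = baseline_measurement(SubjectSimulator(easy_subject), 60.0)
        assert np.all(stats.sigma > 0)
        assert np.allclose(stats.mu, easy_subject.baseline_mu)


def _perfect_model(subject, scale_range=(0.0, 10.0)):
    g0, g1 = subject.continuous_truth["soundscape"]
    sigma = subject.baseline_sigma
    rule = ContinuousRule("soundscape", g0 / sigma, g1 / sigma, scale_range)
    return FeedbackModel(subject.channels, np.ones(len(subject.channels)), {"soundscape": rule})


class TestControlLoop:
    def test_reaches_reachable_target_within_three_periods(self, specs):
        subject = make_subject("easy", 5)
        subject.noise_sd[:] = 0.0
        sess, _, _ = control_loop(_perfect_model(subject), SubjectSimulator(subject),
                                  specs, 0.8, 60.0, baseline=subject.nominal_baseline())
        err = (sess.frame["s_d"] - sess.frame["s_c"]).abs().to_numpy()
        assert np.all(err[2:] <= 0.05)

    def test_error_non_increasing_until_within_granule(self, specs):
        subject = make_subject("easy", 6)
        subject.noise_sd[:] = 0.0
        sess, _, _ = control_loop(_perfect_model(subject), SubjectSimulator(subject),
                                  specs, 0.8, 100.0, baseline=subject.nominal_baseline())
        err = (sess.frame["s_d"] - sess.frame["s_c"]).abs().to_numpy()
        settled = err <= 0.05
        first = int(np.argmax(settled))
        assert np.all(np.diff(err[: first + 1]) <= 1e-9)

    def test_null_rules_yield_no_action_every_step(self, channels, specs):
        subject = make_subject("easy", 7)
        rule = ContinuousRule("soundscape", np.zeros(4), np.zeros(4), (0.0, 10.0))
        model = FeedbackModel(subject.channels, np.ones(4), {"soundscape": rule})
        # target = current state (0) and a null rule: no candidate predicts any
        # change, so the loop records an explicit no-action at every step and
        # the state stays within the noise band
        sim = SubjectSimulator(subject)
        sess, _, _ = control_loop(model, sim, specs, 0.0, 60.0,
                                  baseline=subject.nominal_baseline())
        assert (sess.frame["action"] == "none").all()
        assert sim.adjustments_applied == 0
        assert sess.frame["s_c"].abs().max() < 0.3

    def test_exactly_one_action_or_explicit_no_action_per_iteration(self, specs):
        subject = make_subject("easy", 8)
        sim = SubjectSimulator(subject)
        sess, _, markers = control_loop(_perfect_model(subject), sim, specs, 0.8, 120.0,
                                        baseline=subject.nominal_baseline())
        n_iter = len(sess.frame)
        n_applied = sim.adjustments_applied
        n_no_action = int((sess.frame["action"] == "none").sum())
        assert n_applied + n_no_action == n_iter
        assert len(markers.adjustments()) == n_applied

    def test_control_beats_matched_uncontrolled_run_under_drift(self):
        subject = make_subject("drifting", 12)
        specs = default_characteristics(12)
        model = _perfect_model(subject)
        base = subject.nominal_baseline()
        ctrl, _, _ = control_loop(model, SubjectSimulator(subject), specs, 1.0, 300.0,
                                  baseline=base)
        unc, _, _ = control_loop(model, SubjectSimulator(subject), specs, 1.0, 300.0,
                                 baseline=base, enabled=False)
        e_c = (ctrl.frame["s_d"] - ctrl.frame["s_c"]).abs().to_numpy()[-20:].mean()
        e_u = (unc.frame["s_d"] - unc.frame["s_c"]).abs().to_numpy()[-20:].mean()
        assert e_c < e_u

    def test_piecewise_constant_target_trajectory(self, specs):
        subject = make_subject("easy", 13)
        subject.noise_sd[:] = 0.0
        traj = [(0.0, 0.4), (60.0, 0.9)]
        sess, _, _ = control_loop(_perfect_model(subject), SubjectSimulator(subject),
                                  specs, traj, 120.0, baseline=subject.nominal_baseline())
        frame = sess.frame
        assert frame.loc[frame["t"] < 60.0, "s_d"].unique().tolist() == [0.4]
        assert frame.loc[frame["t"] >= 65.0, "s_d"].unique().tolist() == [0.9]
        late = frame[frame["t"] > 80.0]
        assert (late["s_d"] - late["s_c"]).abs().max() < 0.05

    def test_period_must_cover_state_window(self, specs, easy_subject):
        model = _perfect_model(easy_subject)
        with pytest.raises(ControllerError):
            control_loop(model, SubjectSimulator(easy_subject), specs, 1.0, 60.0,
                         period_s=1.0, state_window_s=2.5)
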