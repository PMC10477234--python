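"""Q-learning updates, drift linkage, session likelihood and simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from rlddm.data_model import behavioral_summary
from rlddm.model import (
    LearningRates,
    QState,
    SubjectParams,
    rate_transform,
    simulate_subject,
    subject_loglik,
    trial_drift,
    update_q,
)
from rlddm.synthetic_data import make_schedule
from rlddm.wfpt import DDMParams, wfpt_logpdf

from conftest import make_session


class TestRateTransform:
    def test_probit_values(self):
        assert rate_transform(0.0) == 0.5
        assert rate_transform(-6.0) < 1e-8
        assert rate_transform(6.0) > 1 - 1e-8

    @given(a=st.floats(-6, 6), b=st.floats(-6, 6))
    @settings(max_examples=50, deadline=None)
    def test_monotone_increasing(self, a, b):
        if a < b:
            assert rate_transform(a) <= rate_transform(b)
            if b - a > 1e-6:  # strict away from float-precision ties
                assert rate_transform(a) < rate_transform(b)


class TestUpdateQ:
    def test_positive_prediction_error(self):
        q = update_q(QState(), 1, True, 1, LearningRates(norm.ppf(0.3), 0.0))
        assert q.q_optimal[0] == pytest.approx(0.5 + 0.3 * 0.5)

    def test_negative_prediction_error(self):
        q = update_q(QState(), 1, True, 0, LearningRates(0.0, norm.ppf(0.2)))
        assert q.q_optimal[0] == pytest.approx(0.5 - 0.2 * 0.5)

    def test_unchosen_values_unchanged(self):
        before = QState()
        after = update_q(before, 1, True, 1, LearningRates(0.0, 0.0))
        assert after.q_suboptimal[0] == before.q_suboptimal[0]
        assert after.q_optimal[1] == before.q_optimal[1]

    @given(rewards=st.lists(st.integers(0, 1), min_size=1, max_size=50),
           ep=st.floats(-3, 3), em=st.floats(-3, 3))
    @settings(max_examples=50, deadline=None)
    def test_q_values_stay_in_unit_interval(self, rewards, ep, em):
        q = QState()
        for r in rewards:
            q = update_q(q, 1, True, r, LearningRates(ep, em))
        assert 0.0 <= q.q_optimal[0] <= 1.0


class TestTrialDrift:
    def test_linear_linkage(self):
        p = SubjectParams(alpha=1.0, tau=0.2, v_coeff=2.0, variant="RLDDM2")
        assert trial_drift(0.3, p) == pytest.approx(0.6)
        assert trial_drift(0.0, p) == 0.0

    def test_null_model_is_constant(self):
        p = SubjectParams(alpha=1.0, tau=0.2, v_const=1.0, variant="DDM0")
        for qd in (-0.5, 0.0, 0.9):
            assert trial_drift(qd, p) == 1.0


class TestSubjectLoglik:
    def _session3(self):
        return make_session(rts=[0.8, 1.1, 0.7], choices=[True, False, True],
                            rewards=[1, 0, 1], pairs=[1, 1, 1])

    def test_manual_three_trial_chain(self):
        """Composes update_q, trial_drift and wfpt_logpdf by hand."""
        sess = self._session3()
        rates = LearningRates(norm.ppf(0.3), norm.ppf(0.2))
        p = SubjectParams(alpha=1.5, tau=0.3, v_coeff=3.0, rates=rates,
                          variant="RLDDM2")
        q = QState()
        expected = []
        for t in sess.trials:
            v = trial_drift(q.qdiff(t.pair_id), p)
            boundary = "upper" if t.chose_optimal else "lower"
            expected.append(wfpt_logpdf(
                t.rt - p.tau, boundary, DDMParams(alpha=p.alpha, tau=p.tau, v=v)))
            q = update_q(q, t.pair_id, t.chose_optimal, t.reward, rates)
        res = subject_loglik(p, sess)
        np.testing.assert_allclose(res.pointwise, expected, rtol=1e-12)
        assert res.total == pytest.approx(sum(expected))

    def test_null_model_decomposes(self):
        sess = self._session3()
        p = SubjectParams(alpha=1.5, tau=0.3, v_const=1.0, variant="DDM0")
        res = subject_loglik(p, sess)
        dp = DDMParams(alpha=1.5, tau=0.3, v=1.0)
        expected = [wfpt_logpdf(t.rt - 0.3, "upper" if t.chose_optimal else "lower", dp)
                    for t in sess.trials]
        np.testing.assert_allclose(res.pointwise, expected, rtol=1e-12)

    def test_total_equals_pointwise_sum(self, session60):
        p = SubjectParams(alpha=1.5, tau=0.25, v_coeff=3.0,
                          rates=LearningRates(-0.5, -1.0), variant="RLDDM2")
        res = subject_loglik(p, session60)
        assert res.total == np.sum(res.pointwise)

    def test_dual_rate_nests_single_rate(self, session60):
        raw = -0.7
        p1 = SubjectParams(alpha=1.4, tau=0.25, v_coeff=2.5,
                           rates=LearningRates(raw, raw), variant="RLDDM1")
        p2 = SubjectParams(alpha=1.4, tau=0.25, v_coeff=2.5,
                           rates=LearningRates(raw, raw), variant="RLDDM2")
        r1 = subject_loglik(p1, session60)
        r2 = subject_loglik(p2, session60)
        np.testing.assert_allclose(r1.pointwise, r2.pointwise, atol=1e-10, rtol=0)

    def test_rt_below_tau_flags_and_returns_neg_inf(self):
        sess = make_session(rts=[0.1, 0.8], pairs=[1, 1])
        p = SubjectParams(alpha=1.0, tau=0.5, v_coeff=1.0, variant="RLDDM2")
        res = subject_loglik(p, sess)
        assert res.total == -np.inf
        assert res.tau_violation

    def test_pure_function_of_inputs(self, session60):
        p = SubjectParams(alpha=1.5, tau=0.25, v_coeff=3.0,
                          rates=LearningRates(-0.5, -1.0), variant="RLDDM2")
        a = subject_loglik(p, session60)
        b = subject_loglik(p, session60)
        assert a.total == b.total
        assert np.array_equal(a.pointwise, b.pointwise)


class TestSimulateSubject:
    def test_reproducible(self):
        sched = make_schedule(seed=3)
        p = SubjectParams(alpha=1.8, tau=0.3, v_coeff=4.0,
                          rates=LearningRates(-0.8, -1.3), variant="RLDDM2")
        a = simulate_subject(p, sched, seed=5)
        b = simulate_subject(p, sched, seed=5)
        assert a.trials == b.trials

    def test_zero_coefficient_gives_chance_accuracy(self):
        p = SubjectParams(alpha=1.5, tau=0.3, v_coeff=0.0,
                          rates=LearningRates(0.0, 0.0), variant="RLDDM2")
        n_opt = n_tot = 0
        for seed in range(30):
            sess = simulate_subject(p, make_schedule(seed=seed), seed=seed + 100)
            for t in sess.non_miss():
                n_opt += t.chose_optimal
                n_tot += 1
        frac = n_opt / n_tot
        assert abs(frac - 0.5) <= 3 * math.sqrt(0.25 / n_tot)

    def test_strong_learner_improves_over_session(self):
        p = SubjectParams(alpha=1.5, tau=0.3, v_coeff=10.0,
                          rates=LearningRates(0.0, 0.0), variant="RLDDM2")
        first = last = 0
        wins = 0
        for seed in range(200):
            sess = simulate_subject(p, make_schedule(seed=seed), seed=seed + 7)
            third = len(sess.trials) // 3
            head = [t for t in sess.trials[:third] if not t.miss]
            tail = [t for t in sess.trials[-third:] if not t.miss]
            first += sum(t.chose_optimal for t in head) / max(len(head), 1)
            last += sum(t.chose_optimal for t in tail) / max(len(tail), 1)
        assert last / 200 > first / 200

    def test_learning_curve_rises_and_rt_falls(self):
        """High-drift learner: accuracy up, RTs down across 10 bins."""
        from rlddm.ppc import bin_learning_curves

        p = SubjectParams(alpha=1.8, tau=0.3, v_coeff=6.0,
                          rates=LearningRates(-0.5, -1.0), variant="RLDDM2")
        sims = [simulate_subject(p, make_schedule(seed=s), seed=s + 1)
                for s in range(60)]
        acc, rt = bin_learning_curves(sims, n_bins=10)
        assert np.mean(acc[-3:]) > np.mean(acc[:3])
        assert np.mean(rt[-3:]) < np.mean(rt[:3])

    def test_rts_respect_deadline_and_tau(self):
        p = SubjectParams(alpha=2.5, tau=0.4, v_coeff=1.0,
                          rates=LearningRates(0.0, 0.0), variant="RLDDM2")
        sess = simulate_subject(p, make_schedule(seed=2), seed=3)
        for t in sess.non_miss():
            assert 0.4 <= t.rt <= 3.0 + 1e-9
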