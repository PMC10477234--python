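"""PSIS-LOO elpd, ranking, HDI, effect summaries and recovery reports."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from rlddm.errors import DomainError, RLDDMError
from rlddm.evaluation import (
    ModelScore,
    effect_summary,
    effects_table,
    hdi,
    pointwise_loglik,
    psis_loo,
    rank_models,
    recovery_report,
    subject_recovery_correlation,
)


class TestPointwiseLoglik:
    def test_column_sums_match_stored_totals(self, fit_rlddm2_placebo8):
        ll = pointwise_loglik(fit_rlddm2_placebo8)
        totals = fit_rlddm2_placebo8.stacked("loglik_total")
        np.testing.assert_allclose(ll.sum(axis=1), totals, rtol=1e-10)

    def test_matrix_shape(self, fit_rlddm2_placebo8):
        ll = pointwise_loglik(fit_rlddm2_placebo8)
        model = fit_rlddm2_placebo8.model
        assert ll.shape == (1500, model.n_trials_included)

    def test_single_draw_matches_subject_loglik(self, fit_rlddm2_placebo8, placebo8):
        from rlddm.data_model import fast_trial_mask
        from rlddm.model import subject_loglik
        from rlddm.ppc import params_from_draw

        model = fit_rlddm2_placebo8.model
        ll = pointwise_loglik(fit_rlddm2_placebo8)
        pars = params_from_draw(fit_rlddm2_placebo8, 0)
        sess = placebo8[0]
        key = (sess.subject_id, sess.condition)
        k = model.session_keys.index(key)
        a = sum(int(model.include[model.offsets[i]:model.offsets[i + 1]].sum())
                for i in range(k))
        n = int(model.include[model.offsets[k]:model.offsets[k + 1]].sum())
        res = subject_loglik(pars[key], sess,
                             include_mask=fast_trial_mask(sess, 0.05))
        np.testing.assert_allclose(ll[0, a:a + n], res.pointwise, rtol=1e-10)


class TestPsisLoo:
    @staticmethod
    def _normal_case(n=40, n_draws=4000, seed=0):
        """iid Normal(mu, 1) with conjugate prior mu ~ N(0, 10^2); exact
        posterior draws and the analytic leave-one-out predictive density."""
        rng = np.random.default_rng(seed)
        y = rng.normal(0.7, 1.0, size=n)
        tau2 = 100.0
        post_var = 1.0 / (n + 1.0 / tau2)
        post_mean = post_var * y.sum()
        mu_draws = rng.normal(post_mean, math.sqrt(post_var), size=n_draws)
        ll = norm.logpdf(y[None, :], loc=mu_draws[:, None], scale=1.0)
        analytic = 0.0
        for i in range(n):
            v_i = 1.0 / (n - 1 + 1.0 / tau2)
            m_i = v_i * (y.sum() - y[i])
            analytic += norm.logpdf(y[i], loc=m_i, scale=math.sqrt(v_i + 1.0))
        return ll, analytic

    def test_matches_analytic_loo_for_normal_model(self):
        ll, analytic = self._normal_case()
        score = psis_loo(ll, label="normal")
        assert -score.neg_elpd == pytest.approx(analytic, abs=3 * score.se)

    def test_trial_permutation_invariant(self):
        ll, _ = self._normal_case()
        perm = np.random.default_rng(1).permutation(ll.shape[1])
        a = psis_loo(ll)
        b = psis_loo(ll[:, perm])
        assert a.neg_elpd == pytest.approx(b.neg_elpd, rel=1e-12)

    def test_requires_enough_draws(self):
        with pytest.raises(RLDDMError, match="100 draws"):
            psis_loo(np.zeros((50, 10)))

    def test_degenerate_draws_rejected(self):
        with pytest.raises(RLDDMError, match="degenerate"):
            psis_loo(np.ones((200, 10)))

    def test_noise_parameter_does_not_improve_elpd(self):
        """Adding a pure-noise parameter cannot beat the base model by more
        than estimation error."""
        ll, _ = self._normal_case()
        rng = np.random.default_rng(5)
        noisy = ll + 0.5 * rng.standard_normal(ll.shape)  # extra stochasticity
        base = psis_loo(ll)
        noise = psis_loo(noisy)
        assert noise.neg_elpd >= base.neg_elpd - 2 * base.se


class TestRankModels:
    @staticmethod
    def _score(label, v):
        return ModelScore(label=label, neg_elpd=v, se=1.0, pareto_k_max=0.1,
                          n_high_k=0, n_trials=100)

    def test_rank_by_neg_elpd(self):
        df = rank_models([self._score("a", 300), self._score("b", 100),
                          self._score("c", 200)])
        assert list(df.model) == ["b", "c", "a"]
        assert list(df["rank"]) == [1, 2, 3]

    def test_tie_flagged(self):
        df = rank_models([self._score("a", 100.0), self._score("b", 100.0)])
        assert df.tie.all()
        assert list(df.model) == ["a", "b"]  # label order breaks the tie

    def test_mismatched_trial_counts_error(self):
        a = self._score("a", 1.0)
        b = ModelScore("b", 2.0, 1.0, 0.1, 0, 99)
        with pytest.raises(RLDDMError, match="trial counts"):
            rank_models([a, b])


class TestHdi:
    def test_uniform_width(self):
        rng = np.random.default_rng(0)
        lo, hi = hdi(rng.random(100_000), 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.02)

    def test_point_mass(self):
        lo, hi = hdi(np.full(1000, 2.5), 0.9)
        assert lo == hi == 2.5

    def test_nesting(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(20_000)
        lo85, hi85 = hdi(x, 0.85)
        lo95, hi95 = hdi(x, 0.95)
        assert lo95 <= lo85 and hi85 <= hi95

    def test_contract_errors(self):
        with pytest.raises(DomainError):
            hdi(np.arange(100), 1.5)
        with pytest.raises(DomainError):
            hdi(np.arange(5), 0.9)


class TestEffectSummary:
    def test_all_negative_caps_dbf(self):
        sd = np.full(2000, 0.3)
        es = effect_summary(-np.abs(np.random.default_rng(0).standard_normal(2000)) - 0.01, sd)
        assert es.p_lt_0 == 1.0
        assert es.dbf_capped

    def test_symmetric_draws(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(20_000)
        es = effect_summary(x, np.full(1000, 1.0))
        assert es.p_lt_0 == pytest.approx(0.5, abs=0.02)
        assert es.dbf == pytest.approx(1.0, abs=0.1)

    def test_exact_odds_arithmetic(self):
        x = np.concatenate([-np.linspace(0.01, 1, 800), np.linspace(0.01, 1, 200)])
        es = effect_summary(x, np.full(1000, 1.0))
        assert es.p_lt_0 == 0.8
        assert es.dbf == pytest.approx(4.0)

    def test_probability_identity(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(5000)
        es = effect_summary(x, np.full(1000, 1.0))
        n_neg = int(np.sum(x < 0)); n_pos = int(np.sum(x > 0)); n_zero = int(np.sum(x == 0))
        assert n_neg + n_pos + n_zero == x.size
        assert es.dbf * (n_pos / n_neg) == pytest.approx(1.0, rel=1e-12)

    def test_rope_uses_placebo_sd(self):
        x = np.random.default_rng(3).standard_normal(2000)
        es = effect_summary(x, np.full(100, 0.5))
        assert es.rope == (-0.05, 0.05)

    def test_hdi85_nested_in_hdi95(self):
        x = np.random.default_rng(4).standard_normal(5000)
        es = effect_summary(x, np.full(1000, 1.0))
        assert es.hdi95[0] <= es.hdi85[0] and es.hdi85[1] <= es.hdi95[1]


class TestRecovery:
    def test_report_covers_injected_point_mass(self, truth8, fit_rlddm2_placebo8):
        """Posterior collapsed onto the truth gives zero bias, full coverage."""
        import copy

        draws = copy.copy(fit_rlddm2_placebo8)
        post = fit_rlddm2_placebo8.idata.posterior.copy(deep=True)
        model = fit_rlddm2_placebo8.model
        target = np.array([truth8.means[p] for p in model.param_names])
        vals = np.broadcast_to(target, post["mu"].values.shape).copy()
        post["mu"] = (post["mu"].dims, vals)
        import arviz as az

        draws.idata = az.InferenceData(posterior=post)
        rep = recovery_report(truth8, draws)
        mu_rows = rep[rep.parameter.str.startswith("mu[")]
        assert (mu_rows.bias.abs() < 1e-9).all()
        assert mu_rows.covered.all()

    def test_subject_correlation_positive_and_shuffle_null(self, dataset8,
                                                           fit_rlddm2_placebo8):
        pop = dataset8["population"]
        r = subject_recovery_correlation(pop, fit_rlddm2_placebo8, "alpha")
        assert r > 0.5
        # negative control: shuffling the truth kills the correlation
        rng = np.random.default_rng(0)
        model = fit_rlddm2_placebo8.model
        ids = list(model.subjects)
        shuffled = {}
        perm = rng.permutation(len(ids))
        for i, sid in enumerate(ids):
            for cond in ("placebo", "ldopa", "haloperidol"):
                shuffled[(sid, cond)] = pop[(ids[perm[i]], cond)]
        r0 = subject_recovery_correlation(shuffled, fit_rlddm2_placebo8, "alpha")
        assert abs(r0) < r
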