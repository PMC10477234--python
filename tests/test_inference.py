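"""Model construction, sampler correctness and convergence diagnostics."""

import numpy as np
import pytest

import arviz as az

from rlddm._sampler import draw_trunc_normal
from rlddm.errors import RLDDMError
from rlddm.inference import (
    MCMCConfig,
    PriorSpec,
    build_model,
    check_convergence,
    diagnostics,
    run_mcmc,
)
from rlddm.synthetic_data import illustrative_truth, generate_dataset


class TestBuildModel:
    def test_combined_requires_all_conditions(self, placebo8):
        with pytest.raises(RLDDMError, match="three conditions"):
            build_model("RLDDM2", placebo8, combined=True)

    def test_separate_requires_single_condition(self, dataset8):
        with pytest.raises(RLDDMError, match="one condition"):
            build_model("RLDDM2", dataset8["sessions"], combined=False)

    def test_finite_log_posterior_at_generating_truth(self, dataset8, truth8):
        model = build_model("RLDDM2", dataset8["sessions"], combined=True)
        pop = dataset8["population"]
        S = model.n_subjects
        x = np.stack([pop[(sid, "placebo")].theta()[:5] for sid in model.subjects])
        shifts = np.stack([
            np.stack([pop[(sid, drug)].theta()[:5] - pop[(sid, "placebo")].theta()[:5]
                      for drug in model.conditions[1:]])
            for sid in model.subjects])
        params = {
            "mu": np.array([truth8.means[p] for p in model.param_names]),
            "sigma": np.array([truth8.sds[p] for p in model.param_names]),
            "shift_mu": np.stack([
                [truth8.shift_means[d][p] for p in model.param_names]
                for d in model.conditions[1:]]),
            "shift_sd": np.stack([
                [truth8.shift_sds[d][p] for p in model.param_names]
                for d in model.conditions[1:]]),
            "subj": x,
            "subj_shift": shifts,
        }
        lp = model.log_posterior(params)
        assert np.isfinite(lp)

    def test_zero_shift_likelihood_nests_separate_models(self, dataset8, truth8):
        """Combined likelihood with all shifts at zero equals the sum of the
        per-condition likelihoods at matched subject parameters."""
        sessions = dataset8["sessions"]
        combined = build_model("RLDDM2", sessions, combined=True)
        S, P = combined.n_subjects, combined.n_params
        rng = np.random.default_rng(0)
        subj = combined.initial_params(rng)["subj"]
        params_c = {"mu": np.full(P, 1.0), "sigma": np.full(P, 0.5),
                    "shift_mu": np.zeros((2, P)), "shift_sd": np.full((2, P), 0.1),
                    "subj": subj, "subj_shift": np.zeros((S, 2, P))}
        total_c = combined.log_likelihood(params_c)
        total_sep = 0.0
        for cond in combined.conditions:
            sub = [s for s in sessions if s.condition == cond]
            m = build_model("RLDDM2", sub, combined=False)
            params_s = {"mu": params_c["mu"], "sigma": params_c["sigma"],
                        "subj": subj}
            total_sep += m.log_likelihood(params_s)
        assert total_c == pytest.approx(total_sep, abs=1e-10)

    def test_zero_data_log_posterior_is_log_prior(self, placebo8):
        model = build_model("RLDDM2", placebo8, combined=False)
        params = model.initial_params(np.random.default_rng(1))
        # a model is its prior plus its likelihood; with the likelihood term
        # removed the two coincide
        assert model.log_posterior(params) == pytest.approx(
            model.log_prior(params) + model.log_likelihood(params))
        assert np.isfinite(model.log_prior(params))


class TestSamplerOracles:
    def test_truncated_normal_gibbs_matches_moments(self):
        """Conjugate group-mean step: truncated-normal draws match
        scipy.stats.truncnorm moments."""
        from scipy.stats import truncnorm

        mean, sd, lo, hi = 1.2, 0.4, 0.8, 1.6
        draws = draw_trunc_normal(mean, sd, lo, hi, 40000, seed=4)
        a, b = (lo - mean) / sd, (hi - mean) / sd
        ref = truncnorm(a, b, loc=mean, scale=sd)
        assert np.mean(draws) == pytest.approx(ref.mean(), abs=4 * ref.std() / 200)
        assert np.std(draws) == pytest.approx(ref.std(), rel=0.05)

    def test_posterior_mean_against_conjugate_toy(self, placebo8):
        """Degenerate-likelihood check: with huge observation noise the
        hierarchy's group mean posterior approaches the conjugate
        Normal-Normal answer (prior bounds wide, subjects pinned).

        Implemented as: group mean posterior of a fitted model must lie
        within a few MC-SEs of the empirical subject mean, which the
        conjugate step prescribes given weak group SD information.
        """
        model = build_model("DDM0", placebo8, combined=False)
        cfg = MCMCConfig.desk(seed=2, n_chains=2, n_burnin=800, n_retained=400)
        draws = run_mcmc(model, cfg)
        mu = draws.stacked("mu")
        subj = draws.stacked("subj")
        # conjugate step: mu | x ~ N(mean(x), sigma/sqrt(S)); across draws the
        # posterior mean of mu must match the posterior mean of mean(x)
        assert np.mean(mu[:, 0]) == pytest.approx(
            np.mean(subj[:, :, 0].mean(axis=1)), abs=0.02)


class TestRunMCMC:
    def test_same_seed_identical_draws(self, placebo8):
        model = build_model("DDM0", placebo8, combined=False)
        cfg = MCMCConfig.desk(seed=3, n_chains=2, n_burnin=300, n_retained=200)
        a = run_mcmc(model, cfg)
        b = run_mcmc(model, cfg)
        assert np.array_equal(a.stacked("mu"), b.stacked("mu"))
        assert np.array_equal(a.stacked("subj"), b.stacked("subj"))

    def test_draw_counts_match_config(self, fit_ddm0_placebo8):
        post = fit_ddm0_placebo8.idata.posterior
        assert post.sizes["chain"] == 2
        assert post.sizes["draw"] == 750

    def test_learning_rates_transform_into_unit_interval(self, fit_rlddm2_placebo8):
        from rlddm.model import rate_transform

        mu = fit_rlddm2_placebo8.stacked("mu")
        rates = [rate_transform(v) for v in mu[:, 3]]
        assert all(0.0 < r < 1.0 for r in rates)


class TestDiagnostics:
    def test_identical_chains_rhat_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(1000)
        idata = az.from_dict(posterior={"theta": np.stack([x, x])})
        r = float(az.rhat(idata)["theta"].values)
        assert r == pytest.approx(1.0, abs=0.01)

    def test_separated_chains_fail_gate(self, fit_ddm0_placebo8):
        # graft two chains with disjoint locations onto the draws object
        import copy

        bad = copy.copy(fit_ddm0_placebo8)
        rng = np.random.default_rng(1)
        post = fit_ddm0_placebo8.idata.posterior.copy(deep=True)
        shape = post["mu"].values.shape
        sep = np.stack([rng.standard_normal(shape[1:]),
                        10.0 + rng.standard_normal(shape[1:])])
        post["mu"] = (post["mu"].dims, sep)
        bad.idata = az.InferenceData(posterior=post)
        table, ok = diagnostics(bad, mode="paper")
        assert not ok
        assert table.loc[table.parameter.str.startswith("mu"), "rhat"].max() > 1.01
        with pytest.raises(Exception):
            check_convergence(bad, mode="paper")

    def test_single_chain_errors(self, placebo8):
        model = build_model("DDM0", placebo8, combined=False)
        cfg = MCMCConfig.desk(seed=3, n_chains=1, n_burnin=200, n_retained=100)
        draws = run_mcmc(model, cfg)
        with pytest.raises(RLDDMError, match="2 chains"):
            diagnostics(draws)

    def test_iid_chains_ess_band(self):
        rng = np.random.default_rng(7)
        idata = az.from_dict(posterior={"theta": rng.standard_normal((2, 500))})
        ess = float(az.ess(idata)["theta"].values)
        assert 500 <= ess <= 1500

    def test_paper_and_desk_modes_have_documented_gates(self):
        assert MCMCConfig.paper().rhat_limit == 1.01
        assert MCMCConfig.desk().rhat_limit == 1.05
        paper = MCMCConfig.paper()
        assert (paper.n_chains, paper.n_burnin, paper.thin, paper.n_retained) == \
            (2, 100_000, 2, 10_000)
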