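"""Hierarchical Bayesian model construction, MCMC sampling and diagnostics.

Two model layouts are supported:

* **separate** — an independent hierarchy (group mean + SD per parameter,
  subject-level Gaussians) fitted to one drug condition at a time;
* **combined** — placebo is the baseline; each drug condition adds
  subject-level additive shift parameters drawn from group-level shift
  Gaussians (mean prior centred at zero), so the group shift means are the
  drug effects of interest.

Subject non-decision times are constrained by the likelihood itself: any
included trial with rt <= tau makes the session log-likelihood -inf, which
the sampler rejects, effectively truncating tau below each subject-session's
minimum retained |RT|.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import arviz as az
import numpy as np
import pandas as pd

from ._sampler import _run_chain
from .data_model import CONDITIONS, SessionData, fast_trial_mask
from .errors import ConvergenceError, DomainError, RLDDMError
from .model import N_PARAMS, PARAM_NAMES, _VARIANT_CODE, VARIANTS

# uniform prior bounds for group means, per parameter (estimation space)
_DEFAULT_MU_BOUNDS = {
    "alpha": (0.05, 5.0),
    "tau": (0.05, 1.0),
    "v_coeff": (0.0, 20.0),
    "v_const": (-10.0, 10.0),
    "eta_raw": (-6.0, 6.0),
    "eta_plus_raw": (-6.0, 6.0),
    "eta_minus_raw": (-6.0, 6.0),
}
_DEFAULT_SD_BOUNDS = {"default": (0.001, 3.0), "eta": (0.001, 4.0)}


@dataclass
class PriorSpec:
    """Prior configuration: uniform group-mean and group-SD bounds, a
    zero-centred Gaussian prior for drug-shift means, uniform shift-SD
    bounds. Defaults cover numerically plausible parameter ranges."""

    mu_bounds: dict = field(default_factory=lambda: dict(_DEFAULT_MU_BOUNDS))
    sd_bounds: dict = field(default_factory=dict)
    shift_mean_sd: dict = field(default_factory=dict)  # Gaussian prior scale per param
    shift_sd_bounds: tuple = (0.001, 2.0)

    def sd_bound(self, pname: str) -> tuple:
        if pname in self.sd_bounds:
            return self.sd_bounds[pname]
        if "eta" in pname:
            return _DEFAULT_SD_BOUNDS["eta"]
        return _DEFAULT_SD_BOUNDS["default"]

    def shift_scale(self, pname: str) -> float:
        return self.shift_mean_sd.get(pname, 1.0)


@dataclass
class MCMCConfig:
    """Sampler configuration. ``paper`` mode mirrors the published settings
    (2 chains, 100k burn-in, thinning 2, 10k retained, R-hat gate 1.01);
    ``desk`` mode is a reduced configuration for interactive use and
    testing (R-hat gate 1.05)."""

    n_chains: int = 4
    n_burnin: int = 2000
    thin: int = 1
    n_retained: int = 2000
    seed: int = 0
    mode: str = "desk"

    @classmethod
    def paper(cls, seed: int = 0) -> "MCMCConfig":
        return cls(n_chains=2, n_burnin=100_000, thin=2, n_retained=10_000,
                   seed=seed, mode="paper")

    @classmethod
    def desk(cls, seed: int = 0, n_chains: int = 4, n_burnin: int = 2000,
             n_retained: int = 2000, thin: int = 1) -> "MCMCConfig":
        return cls(n_chains=n_chains, n_burnin=n_burnin, thin=thin,
                   n_retained=n_retained, seed=seed, mode="desk")

    @property
    def rhat_limit(self) -> float:
        return 1.01 if self.mode == "paper" else 1.05


class Model:
    """Packed dataset + priors with a log-posterior over named parameters.

    Parameters are passed as a dict of arrays: ``mu`` (P,), ``sigma`` (P,),
    ``subj`` (S, P) and, for combined models, ``shift_mu`` (D, P),
    ``shift_sd`` (D, P), ``subj_shift`` (S, D, P); D = number of drug
    conditions, in the order of :attr:`conditions` after placebo.
    """

    def __init__(self, variant: str, sessions: Sequence[SessionData],
                 priors: PriorSpec, combined: bool,
                 fast_quantile: float = 0.05, q_update_filtered: bool = True,
                 min_usable_trials: int = 10):
        if variant not in VARIANTS:
            raise DomainError(f"unknown variant {variant!r}")
        self.variant = variant
        self.priors = priors
        self.combined = combined
        self.q_update_filtered = q_update_filtered
        self.param_names = PARAM_NAMES[variant]
        self.n_params = N_PARAMS[variant]

        conds = [c for c in CONDITIONS if any(s.condition == c for s in sessions)]
        if combined:
            if set(conds) != set(CONDITIONS):
                raise RLDDMError(
                    "combined model requires all three conditions, got "
                    f"{conds}"
                )
            self.conditions = list(CONDITIONS)
        else:
            if len(conds) != 1:
                raise RLDDMError(
                    "separate-mode model fits one condition at a time; got "
                    f"{conds}. Split the dataset (or use fit_separate)."
                )
            self.conditions = conds
        self.subjects = sorted({s.subject_id for s in sessions})
        self.n_subjects = len(self.subjects)
        self.n_conditions = len(self.conditions)

        # pack sessions (CSR over non-miss trials, include = survived filter)
        from .model import pack_session

        subj_idx = {s: i for i, s in enumerate(self.subjects)}
        cond_idx = {c: i for i, c in enumerate(self.conditions)}
        self.sess_index = -np.ones((self.n_subjects, self.n_conditions), dtype=np.int64)
        rts, chs, rws, prs, incs = [], [], [], [], []
        offsets = [0]
        self.session_keys: list[tuple[str, str]] = []
        self.min_rt = np.full(self.n_subjects, np.inf)
        n = 0
        for sess in sessions:
            mask = fast_trial_mask(sess, fast_quantile)
            rt, ch, rw, pr, inc = pack_session(sess, include_mask=mask)
            if int(inc.sum()) < min_usable_trials:
                import warnings

                warnings.warn(
                    f"subject {sess.subject_id} ({sess.condition}) has only "
                    f"{int(inc.sum())} usable trials"
                )
            i, j = subj_idx[sess.subject_id], cond_idx[sess.condition]
            if self.sess_index[i, j] >= 0:
                raise RLDDMError(f"duplicate session ({sess.subject_id}, {sess.condition})")
            self.sess_index[i, j] = n
            self.session_keys.append((sess.subject_id, sess.condition))
            rts.append(rt); chs.append(ch); rws.append(rw); prs.append(pr); incs.append(inc)
            offsets.append(offsets[-1] + len(rt))
            if inc.any():
                self.min_rt[i] = min(self.min_rt[i], float(rt[inc].min()))
            n += 1
        self.rt = np.concatenate(rts) if rts else np.empty(0)
        self.choice = np.concatenate(chs) if chs else np.empty(0, dtype=np.int8)
        self.reward = np.concatenate(rws) if rws else np.empty(0)
        self.pair = np.concatenate(prs) if prs else np.empty(0, dtype=np.int8)
        self.include = (np.concatenate(incs) if incs else np.empty(0, dtype=np.bool_))
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.n_trials_included = int(self.include.sum())

        # prior bound arrays in internal parameter order
        P = self.n_params
        self.mu_lo = np.empty(P); self.mu_hi = np.empty(P)
        self.sig_lo = np.empty(P); self.sig_hi = np.empty(P)
        self.shift_prior_sd = np.empty(P)
        self.s_lo = np.empty(P); self.s_hi = np.empty(P)
        for p, name in enumerate(self.param_names):
            self.mu_lo[p], self.mu_hi[p] = priors.mu_bounds[name]
            self.sig_lo[p], self.sig_hi[p] = priors.sd_bound(name)
            self.shift_prior_sd[p] = priors.shift_scale(name)
            self.s_lo[p], self.s_hi[p] = priors.shift_sd_bounds

    @property
    def n_drugs(self) -> int:
        return self.n_conditions - 1

    # -- densities ---------------------------------------------------------

    def _theta(self, params: dict, s: int, c: int) -> np.ndarray:
        th = np.zeros(5)
        for p in range(self.n_params):
            v = params["subj"][s, p]
            if c > 0:
                v += params["subj_shift"][s, c - 1, p]
            th[p] = v
        return th

    def log_likelihood(self, params: dict) -> float:
        """Sum of session log-likelihoods at the given parameter values."""
        from .model import _session_loglik

        total = 0.0
        empty = np.empty(0)
        code = _VARIANT_CODE[self.variant]
        for s in range(self.n_subjects):
            for c in range(self.n_conditions):
                idx = self.sess_index[s, c]
                if idx < 0:
                    continue
                a, b = self.offsets[idx], self.offsets[idx + 1]
                total += _session_loglik(
                    self._theta(params, s, c), code, self.rt[a:b],
                    self.choice[a:b], self.reward[a:b], self.pair[a:b],
                    self.include[a:b], self.q_update_filtered, empty)
        return float(total)

    def log_prior(self, params: dict) -> float:
        from scipy.stats import norm

        lp = 0.0
        P = self.n_params
        for p in range(P):
            mu, sg = params["mu"][p], params["sigma"][p]
            if not (self.mu_lo[p] <= mu <= self.mu_hi[p]):
                return -np.inf
            if not (self.sig_lo[p] <= sg <= self.sig_hi[p]):
                return -np.inf
            lp -= np.log(self.mu_hi[p] - self.mu_lo[p])
            lp -= np.log(self.sig_hi[p] - self.sig_lo[p])
            lp += float(np.sum(norm.logpdf(params["subj"][:, p], mu, sg)))
        for dd in range(self.n_drugs):
            for p in range(P):
                M, Sg = params["shift_mu"][dd, p], params["shift_sd"][dd, p]
                if not (self.s_lo[p] <= Sg <= self.s_hi[p]):
                    return -np.inf
                lp += float(norm.logpdf(M, 0.0, self.shift_prior_sd[p]))
                lp -= np.log(self.s_hi[p] - self.s_lo[p])
                lp += float(np.sum(norm.logpdf(params["subj_shift"][:, dd, p], M, Sg)))
        return float(lp)

    def log_posterior(self, params: dict) -> float:
        lp = self.log_prior(params)
        if not np.isfinite(lp):
            return -np.inf
        return lp + self.log_likelihood(params)

    # -- initialization ----------------------------------------------------

    def initial_params(self, rng: np.random.Generator) -> dict:
        P = self.n_params
        S = self.n_subjects
        D = self.n_drugs
        base = {"alpha": 1.5, "tau": 0.3, "v_coeff": 3.0, "v_const": 0.5,
                "eta_raw": -1.0, "eta_plus_raw": -1.0, "eta_minus_raw": -1.0}
        x = np.empty((S, P))
        for p, name in enumerate(self.param_names):
            x[:, p] = base[name] + 0.05 * rng.standard_normal(S)
            if name == "tau":
                cap = np.where(np.isfinite(self.min_rt), 0.6 * self.min_rt, 0.3)
                x[:, p] = np.minimum(cap, 0.3 + 0.02 * rng.standard_normal(S))
                x[:, p] = np.maximum(x[:, p], 0.02)
        mu = np.clip(x.mean(axis=0), self.mu_lo + 1e-6, self.mu_hi - 1e-6)
        sig = np.clip(0.5 * np.abs(mu) + 0.05, self.sig_lo + 1e-6, self.sig_hi - 1e-6)
        return {
            "mu": mu, "sigma": sig,
            "shift_mu": np.zeros((D, P)),
            "shift_sd": np.full((D, P), 0.1),
            "subj": x,
            "subj_shift": 0.01 * rng.standard_normal((S, D, P)),
        }


def build_model(variant: str, sessions: Sequence[SessionData], priors: PriorSpec | None = None,
                combined: bool = False, **kwargs) -> Model:
    """Construct a hierarchical model over a filtered dataset.

    ``combined=True`` requires all three conditions and parameterizes drug
    conditions as placebo + additive subject-level shifts; ``combined=False``
    fits an independent hierarchy and expects a single-condition dataset.
    """
    return Model(variant, sessions, priors or PriorSpec(), combined, **kwargs)


class PosteriorDraws:
    """Labelled MCMC draws (chain, draw, parameter tree) with diagnostics.

    Wraps an :class:`arviz.InferenceData` whose posterior holds ``mu``,
    ``sigma``, ``subj`` and, for combined models, ``shift_mu``, ``shift_sd``,
    ``subj_shift``, all with named coordinates.
    """

    def __init__(self, idata: az.InferenceData, model: Model, config: MCMCConfig,
                 accept_rate: float):
        self.idata = idata
        self.model = model
        self.config = config
        self.accept_rate = accept_rate

    @property
    def posterior(self):
        return self.idata.posterior

    def stacked(self, var: str) -> np.ndarray:
        """Draws of ``var`` with chain/draw flattened into the first axis."""
        da = self.idata.posterior[var]
        return da.stack(sample=("chain", "draw")).transpose("sample", ...).values

    def group_mean_draws(self, pname: str) -> np.ndarray:
        return self.stacked("mu")[:, list(self.model.param_names).index(pname)]

    def group_sd_draws(self, pname: str) -> np.ndarray:
        return self.stacked("sigma")[:, list(self.model.param_names).index(pname)]

    def shift_mean_draws(self, drug: str, pname: str) -> np.ndarray:
        dd = self.model.conditions.index(drug) - 1
        if dd < 0:
            raise DomainError(f"{drug!r} is not a drug condition of this model")
        return self.stacked("shift_mu")[:, dd, list(self.model.param_names).index(pname)]

    def save(self, out_dir: str | Path) -> None:
        """Persist draws as .npz + JSON labels (self-describing)."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        arrays = {v: self.idata.posterior[v].values for v in self.idata.posterior.data_vars}
        np.savez(out_dir / "draws.npz", **arrays)
        meta = {
            "variant": self.model.variant,
            "combined": self.model.combined,
            "conditions": self.model.conditions,
            "subjects": self.model.subjects,
            "param_names": list(self.model.param_names),
            "config": asdict(self.config),
            "accept_rate": self.accept_rate,
            "dims": {v: list(self.idata.posterior[v].dims) for v in arrays},
        }
        with open(out_dir / "meta.json", "w") as fh:
            json.dump(meta, fh, indent=1)


def _make_idata(model: Model, chains: list[dict]) -> az.InferenceData:
    pnames = list(model.param_names)
    drugs = model.conditions[1:]
    coords = {"param": pnames, "subject": model.subjects}
    data = {
        "mu": np.stack([c["mu"] for c in chains]),
        "sigma": np.stack([c["sigma"] for c in chains]),
        "subj": np.stack([c["subj"] for c in chains]),
    }
    dims = {"mu": ["param"], "sigma": ["param"], "subj": ["subject", "param"]}
    if model.n_drugs > 0:
        coords["drug"] = drugs
        data["shift_mu"] = np.stack([c["shift_mu"] for c in chains])
        data["shift_sd"] = np.stack([c["shift_sd"] for c in chains])
        data["subj_shift"] = np.stack([c["subj_shift"] for c in chains])
        dims.update({"shift_mu": ["drug", "param"], "shift_sd": ["drug", "param"],
                     "subj_shift": ["subject", "drug", "param"]})
    idata = az.from_dict(posterior=data, coords=coords, dims=dims)
    idata.posterior["loglik_total"] = (("chain", "draw"),
                                       np.stack([c["ll"] for c in chains]))
    return idata


def run_mcmc(model: Model, config: MCMCConfig) -> PosteriorDraws:
    """Sample the model posterior with the adaptive within-Gibbs kernel.

    Chains are run sequentially with per-chain jittered initial values;
    reproducible given ``config.seed``. Raises on a non-finite initial
    log-posterior (parameter snapshot in the message).
    """
    P, S, C, D = model.n_params, model.n_subjects, model.n_conditions, model.n_drugs
    variant = _VARIANT_CODE[model.variant]
    chains = []
    accs = []
    ss = np.random.SeedSequence(config.seed)
    for chain, child in enumerate(ss.spawn(config.n_chains)):
        rng = np.random.default_rng(child)
        init = model.initial_params(rng)
        lp0 = model.log_posterior(init)
        if not np.isfinite(lp0):
            raise RLDDMError(
                f"non-finite log-posterior at initial values (chain {chain}): "
                f"{ {k: np.asarray(v).tolist() for k, v in init.items()} }"
            )
        n_keep = config.n_retained
        omu = np.empty((n_keep, P)); osig = np.empty((n_keep, P))
        oM = np.empty((n_keep, max(D, 1), P)); oS = np.empty((n_keep, max(D, 1), P))
        ox = np.empty((n_keep, S, P)); od = np.empty((n_keep, S, max(D, 1), P))
        oll = np.empty(n_keep)
        acc = np.zeros(1)
        M0 = np.zeros((max(D, 1), P)); S0 = np.full((max(D, 1), P), 0.1)
        d0 = np.zeros((S, max(D, 1), P))
        if D:
            M0[:D] = init["shift_mu"]
            S0[:D] = init["shift_sd"]
            d0[:, :D, :] = init["subj_shift"]
        _run_chain(variant, P, S, C, model.q_update_filtered,
                   model.rt, model.choice, model.reward, model.pair,
                   model.include, model.offsets, model.sess_index,
                   model.mu_lo, model.mu_hi, model.sig_lo, model.sig_hi,
                   model.shift_prior_sd, model.s_lo, model.s_hi,
                   init["mu"].copy(), init["sigma"].copy(), M0, S0,
                   init["subj"].copy(), d0,
                   config.n_burnin, n_keep, config.thin,
                   int(child.generate_state(1)[0]) % (2**31),
                   omu, osig, oM, oS, ox, od, oll, acc)
        if not np.all(np.isfinite(oll)):
            raise RLDDMError("divergent (non-finite) log-likelihood in retained draws")
        chains.append({"mu": omu, "sigma": osig, "shift_mu": oM[:, :D, :],
                       "shift_sd": oS[:, :D, :], "subj": ox,
                       "subj_shift": od[:, :, :D, :], "ll": oll})
        accs.append(acc[0])
    return PosteriorDraws(_make_idata(model, chains), model, config,
                          accept_rate=float(np.mean(accs)))


def fit_separate(variant: str, sessions: Sequence[SessionData], config: MCMCConfig,
                 priors: PriorSpec | None = None, **kwargs) -> dict[str, PosteriorDraws]:
    """Fit an independent hierarchy to each condition present in the data."""
    out = {}
    for cond in CONDITIONS:
        sub = [s for s in sessions if s.condition == cond]
        if not sub:
            continue
        model = build_model(variant, sub, priors, combined=False, **kwargs)
        out[cond] = run_mcmc(model, config)
    return out


def diagnostics(draws: PosteriorDraws, mode: str | None = None) -> tuple[pd.DataFrame, bool]:
    """Split rank-normalized R-hat and ESS per retained parameter.

    Returns ``(table, passed)`` with the gate 1 <= R-hat <= 1.01 in paper
    mode and <= 1.05 in desk mode. Requires >= 2 chains.
    """
    if draws.idata.posterior.sizes["chain"] < 2:
        raise RLDDMError("R-hat requires at least 2 chains")
    mode = mode or draws.config.mode
    limit = 1.01 if mode == "paper" else 1.05
    post = draws.idata.posterior.drop_vars("loglik_total")
    rhat = az.rhat(post)
    ess = az.ess(post)
    rows = []
    for var in post.data_vars:
        r = rhat[var].values.ravel()
        e = ess[var].values.ravel()
        labels = [f"{var}[{i}]" for i in range(r.size)]
        for lbl, rv, ev in zip(labels, r, e):
            rows.append({"parameter": lbl, "rhat": float(rv), "ess": float(ev)})
    table = pd.DataFrame(rows)
    passed = bool(np.all(np.nan_to_num(table["rhat"].values, nan=np.inf) <= limit))
    return table, passed


def check_convergence(draws: PosteriorDraws, mode: str | None = None) -> pd.DataFrame:
    """As :func:`diagnostics` but raises :class:`ConvergenceError` on failure."""
    table, ok = diagnostics(draws, mode)
    if not ok:
        worst = table.loc[table["rhat"].idxmax()]
        raise ConvergenceError(
            f"R-hat gate failed: {worst['parameter']} has R-hat {worst['rhat']:.4f}"
        )
    return table
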