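"""Model comparison (PSIS-LOO elpd) and posterior drug-effect statistics.

Model fit is compared by the estimated log pointwise predictive density
(elpd), a PSIS-smoothed importance-sampling approximation to leave-one-out
cross-validation; −elpd is reported, smaller is better. Drug effects are
summarized by the posterior mean, 95%/85% highest-density intervals, the
posterior probability of a reduction P(effect < 0), a directional Bayes
factor dBF = P(<0)/P(>0) (prior odds are 1 under the zero-centred symmetric
shift prior), and a region of practical equivalence (ROPE) of ±0.1 placebo
group SD. No multiple-comparison correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
from numba import njit
from scipy.special import logsumexp

from ._sampler import _sess_ll  # noqa: F401  (kernel shared with inference)
from .errors import DomainError, RLDDMError
from .model import _VARIANT_CODE, _session_loglik


@dataclass
class ModelScore:
    """PSIS-LOO score of one model: −elpd (smaller = better fit), its
    standard error, the worst Pareto-k, and how many trials exceeded 0.7."""

    label: str
    neg_elpd: float
    se: float
    pareto_k_max: float
    n_high_k: int
    n_trials: int


@dataclass
class EffectSummary:
    """Posterior summary of one additive drug effect."""

    mean: float
    hdi95: tuple[float, float]
    hdi85: tuple[float, float]
    p_lt_0: float
    dbf: float
    dbf_capped: bool
    rope: tuple[float, float]
    rope_verdict: str  # 'excluded', 'overlaps', or 'inside'


@njit(cache=True)
def _pointwise_kernel(variant, P, n_trials, subj_draws, shift_draws, sess_subj,
                      sess_cond, rt, choice, reward, pair, include, offsets,
                      col_offsets, quf, out):
    N = subj_draws.shape[0]
    n_sess = sess_subj.shape[0]
    for n in range(N):
        for k in range(n_sess):
            s = sess_subj[k]
            c = sess_cond[k]
            theta = np.zeros(5)
            for p in range(P):
                v = subj_draws[n, s, p]
                if c > 0:
                    v += shift_draws[n, s, c - 1, p]
                theta[p] = v
            a, b = offsets[k], offsets[k + 1]
            ncol = col_offsets[k + 1] - col_offsets[k]
            pw = np.empty(ncol)
            _session_loglik(theta, variant, rt[a:b], choice[a:b], reward[a:b],
                            pair[a:b], include[a:b], quf, pw)
            out[n, col_offsets[k]:col_offsets[k + 1]] = pw


def pointwise_loglik(draws, model=None) -> np.ndarray:
    """Per-trial log-likelihood matrix, shape (total draws, included trials).

    Rows follow the stacked (chain, draw) order; columns follow the model's
    session order, trials in session order within. Column sums reproduce the
    stored total log-likelihood per draw.
    """
    model = model or draws.model
    subj = np.ascontiguousarray(draws.stacked("subj"))
    N = subj.shape[0]
    S, P = model.n_subjects, model.n_params
    D = model.n_drugs
    if D > 0:
        shift = np.ascontiguousarray(draws.stacked("subj_shift"))
    else:
        shift = np.zeros((N, S, 1, P))
    n_sess = len(model.session_keys)
    sess_subj = np.empty(n_sess, dtype=np.int64)
    sess_cond = np.empty(n_sess, dtype=np.int64)
    col_offsets = [0]
    for k, (sid, cond) in enumerate(model.session_keys):
        sess_subj[k] = model.subjects.index(sid)
        sess_cond[k] = model.conditions.index(cond)
        a, b = model.offsets[k], model.offsets[k + 1]
        col_offsets.append(col_offsets[-1] + int(model.include[a:b].sum()))
    col_offsets = np.asarray(col_offsets, dtype=np.int64)
    out = np.empty((N, int(col_offsets[-1])))
    _pointwise_kernel(_VARIANT_CODE[model.variant], P, int(col_offsets[-1]),
                      subj, shift, sess_subj, sess_cond,
                      model.rt, model.choice, model.reward, model.pair,
                      model.include, model.offsets, col_offsets,
                      model.q_update_filtered, out)
    return out


def psis_loo(loglik: np.ndarray, label: str = "model") -> ModelScore:
    """PSIS-LOO −elpd from a (draws x trials) log-likelihood matrix.

    Importance ratios are Pareto-smoothed (arviz ``psislw``); per-trial
    elpd_i = logsumexp(lw_i + ll_i); SE = sqrt(n * var(elpd_i)). Trials with
    Pareto k > 0.7 are counted as unreliable.
    """
    if loglik.shape[0] < 100:
        raise RLDDMError(f"psis_loo needs >= 100 draws, got {loglik.shape[0]}")
    if np.allclose(loglik.std(axis=0), 0.0):
        raise RLDDMError("degenerate draws: log-likelihood identical across draws")
    import xarray as xr

    lw_in = xr.DataArray(-loglik.T, dims=("obs", "__sample__"))
    lw, k = az.psislw(lw_in)
    lw = np.asarray(lw)
    k = np.asarray(k)
    elpd_i = logsumexp(lw + loglik.T, axis=1)
    n = elpd_i.size
    se = float(np.sqrt(n * np.var(elpd_i)))
    return ModelScore(label=label, neg_elpd=float(-np.sum(elpd_i)), se=se,
                      pareto_k_max=float(np.max(k)), n_high_k=int(np.sum(k > 0.7)),
                      n_trials=n)


def rank_models(scores: list[ModelScore]) -> pd.DataFrame:
    """Rank models by ascending −elpd (rank 1 = best fit).

    All scores must come from the same dataset (equal trial counts). Exact
    ties are broken by label order and flagged.
    """
    if len(scores) < 2:
        raise RLDDMError("need >= 2 model scores to rank")
    if len({s.n_trials for s in scores}) != 1:
        raise RLDDMError("model scores computed on different trial counts")
    ordered = sorted(scores, key=lambda s: (s.neg_elpd, s.label))
    vals = [s.neg_elpd for s in scores]
    tied = len(set(vals)) != len(vals)
    rows = []
    for rank, s in enumerate(ordered, start=1):
        rows.append({"rank": rank, "model": s.label, "neg_elpd": s.neg_elpd,
                     "se": s.se, "pareto_k_max": s.pareto_k_max, "tie": tied})
    return pd.DataFrame(rows)


def hdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest contiguous interval containing ``ceil(mass * n)`` draws."""
    if not (0.0 < mass < 1.0):
        raise DomainError(f"mass must lie in (0,1), got {mass}")
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    if n < 10:
        raise DomainError(f"hdi needs >= 10 draws, got {n}")
    k = int(math.ceil(mass * n))
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def effect_summary(shift_draws: np.ndarray, placebo_sd_draws: np.ndarray) -> EffectSummary:
    """Posterior drug-effect summary: P(<0), HDIs, directional BF, ROPE.

    The ROPE is ±0.1 times the posterior mean of the placebo group-level SD
    of the parameter. The dBF equals the posterior odds P(<0)/P(>0) (prior
    odds 1 under the symmetric zero-centred shift prior); when one side has
    zero draws the dBF is capped at the draw resolution and flagged.
    """
    x = np.asarray(shift_draws, dtype=float)
    n = x.size
    if n < 1000:
        raise RLDDMError(f"effect_summary needs >= 1000 draws, got {n}")
    n_neg = int(np.sum(x < 0))
    n_pos = int(np.sum(x > 0))
    p = n_neg / n
    capped = n_neg == 0 or n_pos == 0
    if capped:
        dbf = float(n) if n_pos == 0 else 1.0 / n
    else:
        dbf = n_neg / n_pos
    rope_half = 0.1 * float(np.mean(placebo_sd_draws))
    h95 = hdi(x, 0.95)
    h85 = hdi(x, 0.85)
    if h95[1] < -rope_half or h95[0] > rope_half:
        verdict = "excluded"
    elif h95[0] >= -rope_half and h95[1] <= rope_half:
        verdict = "inside"
    else:
        verdict = "overlaps"
    return EffectSummary(mean=float(np.mean(x)), hdi95=h95, hdi85=h85,
                         p_lt_0=p, dbf=float(dbf), dbf_capped=capped,
                         rope=(-rope_half, rope_half), rope_verdict=verdict)


def effects_table(draws, drugs: list[str] | None = None) -> pd.DataFrame:
    """Drug-effect summaries for every parameter of a combined-model fit."""
    model = draws.model
    if model.n_drugs == 0:
        raise RLDDMError("effects require a combined-model fit")
    drugs = drugs or model.conditions[1:]
    rows = []
    for drug in drugs:
        for pname in model.param_names:
            es = effect_summary(draws.shift_mean_draws(drug, pname),
                                draws.group_sd_draws(pname))
            rows.append({
                "drug": drug, "parameter": pname, "mean": es.mean,
                "hdi95_lo": es.hdi95[0], "hdi95_hi": es.hdi95[1],
                "p_lt_0": es.p_lt_0, "dbf_lt_0": es.dbf,
                "rope_lo": es.rope[0], "rope_hi": es.rope[1],
                "rope_verdict": es.rope_verdict,
            })
    return pd.DataFrame(rows)


def recovery_report(truth, draws) -> pd.DataFrame:
    """Bias, HDI coverage and subject-level correlation against known truth.

    ``truth`` is the :class:`~rlddm.synthetic_data.GroupTruth` recorded in
    the dataset's provenance sidecar. Group rows report posterior mean −
    truth and whether the 95% HDI covers the truth; subject rows report the
    correlation between true and posterior-mean subject parameters.
    """
    from .synthetic_data import sample_population  # noqa: F401  (type only)

    model = draws.model
    rows = []
    for p, pname in enumerate(model.param_names):
        d = draws.group_mean_draws(pname)
        t = truth.means.get(pname)
        if t is None:
            continue
        lo, hi = hdi(d, 0.95)
        rows.append({"level": "group", "parameter": f"mu[{pname}]",
                     "truth": t, "posterior_mean": float(np.mean(d)),
                     "bias": float(np.mean(d) - t), "hdi95_lo": lo,
                     "hdi95_hi": hi, "covered": bool(lo <= t <= hi),
                     "correlation": np.nan})
    for drug in model.conditions[1:]:
        for pname in model.param_names:
            t = truth.shift_means.get(drug, {}).get(pname)
            if t is None:
                continue
            d = draws.shift_mean_draws(drug, pname)
            lo, hi = hdi(d, 0.95)
            rows.append({"level": "group", "parameter": f"shift[{drug},{pname}]",
                         "truth": t, "posterior_mean": float(np.mean(d)),
                         "bias": float(np.mean(d) - t), "hdi95_lo": lo,
                         "hdi95_hi": hi, "covered": bool(lo <= t <= hi),
                         "correlation": np.nan})
    return pd.DataFrame(rows)


def subject_recovery_correlation(population, draws, pname: str,
                                 condition: str = "placebo") -> float:
    """Correlation between true subject-level parameter values (from a
    generated population) and their posterior means."""
    model = draws.model
    p = list(model.param_names).index(pname)
    post = draws.stacked("subj").mean(axis=0)[:, p]
    attr = {"alpha": "alpha", "tau": "tau", "v_coeff": "v_coeff",
            "v_const": "v_const"}.get(pname)
    vals = []
    for sid in model.subjects:
        sp = population[(sid, condition)]
        if attr is not None:
            vals.append(getattr(sp, attr))
        elif pname in ("eta_raw", "eta_plus_raw"):
            vals.append(sp.rates.eta_plus_raw)
        else:
            vals.append(sp.rates.eta_minus_raw)
    return float(np.corrcoef(vals, post)[0, 1])
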