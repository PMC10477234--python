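"""Adaptive Metropolis-within-Gibbs kernel for the hierarchical RLDDM.

One compiled function runs a full chain over the model's natural-space
parameterization:

* group placebo means  — conjugate Gibbs (truncated to uniform prior bounds);
* group and shift SDs  — conjugate Gibbs (inverse-gamma in sigma^2 under the
  uniform-on-sigma prior, rejection-truncated to bounds);
* drug-shift means     — exact Normal-Normal conjugate Gibbs;
* subject placebo parameters and subject drug shifts — random-walk MH with
  per-scalar scales adapted in batches of 50 during warmup only (frozen
  afterwards, so the retained chain targets the exact posterior);
* interweaving moves along the posterior's stiff directions: baseline/shift
  transfer per subject, per-drug group translation, and group-scale moves
  (the hierarchical funnel fix).

Session log-likelihoods are cached per (subject, condition) and only the
affected entries are recomputed on each proposal.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .model import _session_loglik

_BATCH = 50
_ADAPT_STEP = 0.1


@njit(cache=True)
def _sess_ll(s, c, P, variant, x, d, rt, choice, reward, pair, include,
             offsets, sess_index, quf):
    idx = sess_index[s, c]
    if idx < 0:
        return 0.0
    theta = np.zeros(5)
    for p in range(P):
        val = x[s, p]
        if c > 0:
            val += d[s, c - 1, p]
        theta[p] = val
    a, b = offsets[idx], offsets[idx + 1]
    empty = np.empty(0)
    return _session_loglik(theta, variant, rt[a:b], choice[a:b], reward[a:b],
                           pair[a:b], include[a:b], quf, empty)


@njit(cache=True)
def _logn(val, mu, sd):
    z = (val - mu) / sd
    return -0.5 * z * z - math.log(sd)


@njit(cache=True)
def _trunc_normal(mean, sd, lo, hi):
    """Rejection draw from N(mean, sd) truncated to [lo, hi]; returns NaN
    after 100 failed tries (caller keeps the current value)."""
    for _ in range(100):
        z = mean + sd * np.random.normal()
        if lo <= z <= hi:
            return z
    return np.nan


@njit(cache=True)
def _run_chain(variant, P, S, C, quf,
               rt, choice, reward, pair, include, offsets, sess_index,
               mu_lo, mu_hi, sig_lo, sig_hi, shift_prior_sd, s_lo, s_hi,
               mu, sig, M, Sg, x, d,
               n_warmup, n_keep, thin, seed,
               omu, osig, oM, oS, ox, od, oll, acc_out):
    np.random.seed(seed)
    D = C - 1
    # session log-likelihood cache
    ll = np.zeros((S, C))
    for s in range(S):
        for c in range(C):
            ll[s, c] = _sess_ll(s, c, P, variant, x, d, rt, choice, reward,
                                pair, include, offsets, sess_index, quf)
    # adaptive proposal scales
    sc_x = np.full((S, P), 0.1)
    sc_d = np.full((S, max(D, 1), P), 0.1)
    acc_x = np.zeros((S, P)); try_x = np.zeros((S, P))
    sc_j = np.full((S, P), 0.1)
    acc_j = np.zeros((S, P)); try_j = np.zeros((S, P))
    sc_t = np.full((max(D, 1), P), 0.05)
    acc_t = np.zeros((max(D, 1), P)); try_t = np.zeros((max(D, 1), P))
    acc_d = np.zeros((S, max(D, 1), P)); try_d = np.zeros((S, max(D, 1), P))
    tot_acc = 0.0
    tot_try = 0.0

    n_iter = n_warmup + n_keep * thin
    rec = 0
    for it in range(n_iter):
        # ---- group placebo means: conjugate Gibbs, truncated to bounds ----
        for p in range(P):
            m = 0.0
            for s in range(S):
                m += x[s, p]
            m /= S
            z = _trunc_normal(m, sig[p] / math.sqrt(S), mu_lo[p], mu_hi[p])
            if not math.isnan(z):
                mu[p] = z
        # ---- group placebo SDs: conjugate Gibbs ----
        # uniform prior on sigma => sigma^2 | x is Inv-Gamma((S-1)/2, SSE/2),
        # rejection-truncated to the prior bounds
        for p in range(P):
            sse = 0.0
            for s in range(S):
                dev = x[s, p] - mu[p]
                sse += dev * dev
            for _ in range(100):
                g = np.random.gamma((S - 1.0) / 2.0, 1.0)
                if g <= 0.0:
                    continue
                prop = math.sqrt(sse / (2.0 * g))
                if sig_lo[p] <= prop <= sig_hi[p]:
                    sig[p] = prop
                    break
        # ---- shift means: exact conjugate Gibbs ----
        for dd in range(D):
            for p in range(P):
                prec = S / (Sg[dd, p] * Sg[dd, p]) + 1.0 / (shift_prior_sd[p] * shift_prior_sd[p])
                tot = 0.0
                for s in range(S):
                    tot += d[s, dd, p]
                mean = (tot / (Sg[dd, p] * Sg[dd, p])) / prec
                M[dd, p] = mean + np.random.normal() / math.sqrt(prec)
        # ---- shift SDs: conjugate Gibbs (as the placebo SDs) ----
        for dd in range(D):
            for p in range(P):
                sse = 0.0
                for s in range(S):
                    dev = d[s, dd, p] - M[dd, p]
                    sse += dev * dev
                for _ in range(100):
                    g = np.random.gamma((S - 1.0) / 2.0, 1.0)
                    if g <= 0.0:
                        continue
                    prop = math.sqrt(sse / (2.0 * g))
                    if s_lo[p] <= prop <= s_hi[p]:
                        Sg[dd, p] = prop
                        break
        # ---- subject placebo parameters: random-walk MH ----
        for s in range(S):
            for p in range(P):
                try_x[s, p] += 1.0
                tot_try += 1.0
                old = x[s, p]
                prop = old + sc_x[s, p] * np.random.normal()
                delta = _logn(prop, mu[p], sig[p]) - _logn(old, mu[p], sig[p])
                x[s, p] = prop
                new_ll = np.empty(C)
                ok = True
                for c in range(C):
                    new_ll[c] = _sess_ll(s, c, P, variant, x, d, rt, choice,
                                         reward, pair, include, offsets,
                                         sess_index, quf)
                    if math.isinf(new_ll[c]) and new_ll[c] < 0 and math.isinf(ll[s, c]):
                        ok = False  # -inf -> -inf: reject outright
                for c in range(C):
                    delta += new_ll[c] - ll[s, c]
                if ok and not math.isnan(delta) and \
                        (delta >= 0.0 or np.random.random() < math.exp(delta)):
                    for c in range(C):
                        ll[s, c] = new_ll[c]
                    acc_x[s, p] += 1.0
                    tot_acc += 1.0
                else:
                    x[s, p] = old
        # ---- subject drug shifts: random-walk MH ----
        for s in range(S):
            for dd in range(D):
                c = dd + 1
                for p in range(P):
                    try_d[s, dd, p] += 1.0
                    tot_try += 1.0
                    old = d[s, dd, p]
                    prop = old + sc_d[s, dd, p] * np.random.normal()
                    delta = _logn(prop, M[dd, p], Sg[dd, p]) \
                        - _logn(old, M[dd, p], Sg[dd, p])
                    d[s, dd, p] = prop
                    new_ll = _sess_ll(s, c, P, variant, x, d, rt, choice,
                                      reward, pair, include, offsets,
                                      sess_index, quf)
                    bad = math.isinf(new_ll) and math.isinf(ll[s, c])
                    delta += new_ll - ll[s, c]
                    if (not bad) and not math.isnan(delta) and \
                            (delta >= 0.0 or np.random.random() < math.exp(delta)):
                        ll[s, c] = new_ll
                        acc_d[s, dd, p] += 1.0
                        tot_acc += 1.0
                    else:
                        d[s, dd, p] = old
        # ---- baseline/shift transfer move ----
        # x[s,p] and its drug shifts are anticorrelated (drug sessions only
        # constrain their sum); move e into the baseline and -e into every
        # shift so drug-session parameters stay fixed and only the placebo
        # likelihood and the Gaussian priors change.
        if D > 0:
            for s in range(S):
                for p in range(P):
                    try_j[s, p] += 1.0
                    e = sc_j[s, p] * np.random.normal()
                    old_x = x[s, p]
                    prop_x = old_x + e
                    delta = _logn(prop_x, mu[p], sig[p]) - _logn(old_x, mu[p], sig[p])
                    for dd in range(D):
                        delta += _logn(d[s, dd, p] - e, M[dd, p], Sg[dd, p]) \
                            - _logn(d[s, dd, p], M[dd, p], Sg[dd, p])
                    x[s, p] = prop_x
                    new_ll0 = _sess_ll(s, 0, P, variant, x, d, rt, choice,
                                       reward, pair, include, offsets,
                                       sess_index, quf)
                    bad = math.isinf(new_ll0) and math.isinf(ll[s, 0])
                    delta += new_ll0 - ll[s, 0]
                    if (not bad) and not math.isnan(delta) and \
                            (delta >= 0.0 or np.random.random() < math.exp(delta)):
                        for dd in range(D):
                            d[s, dd, p] -= e
                        ll[s, 0] = new_ll0
                        acc_j[s, p] += 1.0
                    else:
                        x[s, p] = old_x
        # ---- drug-condition translation move ----
        # jointly translate the group shift mean and every subject shift of
        # one (drug, parameter) block; d - M stays invariant so only the
        # drug-session likelihoods and the N(0, prior_sd) prior on M change.
        # Moves the drug-condition group location, which the conjugate M
        # step (conditional on d) cannot reach.
        for dd in range(D):
            cc = dd + 1
            for p in range(P):
                try_t[dd, p] += 1.0
                e = sc_t[dd, p] * np.random.normal()
                prop_M = M[dd, p] + e
                delta = _logn(prop_M, 0.0, shift_prior_sd[p]) \
                    - _logn(M[dd, p], 0.0, shift_prior_sd[p])
                old_d = d[:, dd, p].copy()
                for s in range(S):
                    d[s, dd, p] += e
                new_llt = np.empty(S)
                bad = False
                for s in range(S):
                    new_llt[s] = _sess_ll(s, cc, P, variant, x, d, rt, choice,
                                          reward, pair, include, offsets,
                                          sess_index, quf)
                    if math.isinf(new_llt[s]) and math.isinf(ll[s, cc]):
                        bad = True
                    delta += new_llt[s] - ll[s, cc]
                if (not bad) and not math.isnan(delta) and \
                        (delta >= 0.0 or np.random.random() < math.exp(delta)):
                    M[dd, p] = prop_M
                    for s in range(S):
                        ll[s, cc] = new_llt[s]
                    acc_t[dd, p] += 1.0
                else:
                    for s in range(S):
                        d[s, dd, p] = old_d[s]
        # ---- group-scale interweaving move per parameter ----
        # jointly rescale subject deviations and the group SD:
        # x' = mu + c (x - mu), sigma' = c sigma with c lognormal-proposed.
        # The Gaussian exponents are invariant; the MH log-ratio reduces to
        # delta_loglik + log c (normalization -S log c + Jacobian (S+1) log c).
        # Breaks the funnel coupling between group SDs and subject values.
        for p in range(P):
            logc = 0.15 * np.random.normal()
            c = math.exp(logc)
            prop_sig = sig[p] * c
            if not (sig_lo[p] <= prop_sig <= sig_hi[p]):
                continue
            old_x = x[:, p].copy()
            for s in range(S):
                x[s, p] = mu[p] + c * (x[s, p] - mu[p])
            delta = logc
            new_ll = np.empty((S, C))
            bad = False
            for s in range(S):
                for c_ in range(C):
                    new_ll[s, c_] = _sess_ll(s, c_, P, variant, x, d, rt, choice,
                                             reward, pair, include, offsets,
                                             sess_index, quf)
                    if math.isinf(new_ll[s, c_]) and math.isinf(ll[s, c_]):
                        bad = True
                    delta += new_ll[s, c_] - ll[s, c_]
            if (not bad) and not math.isnan(delta) and \
                    (delta >= 0.0 or np.random.random() < math.exp(delta)):
                sig[p] = prop_sig
                for s in range(S):
                    for c_ in range(C):
                        ll[s, c_] = new_ll[s, c_]
            else:
                for s in range(S):
                    x[s, p] = old_x[s]
        # same interweaving move for each drug-shift block
        for dd in range(D):
            for p in range(P):
                logc = 0.15 * np.random.normal()
                c = math.exp(logc)
                prop_S = Sg[dd, p] * c
                if not (s_lo[p] <= prop_S <= s_hi[p]):
                    continue
                old_d = d[:, dd, p].copy()
                for s in range(S):
                    d[s, dd, p] = M[dd, p] + c * (d[s, dd, p] - M[dd, p])
                delta = logc
                cc = dd + 1
                new_ll1 = np.empty(S)
                bad = False
                for s in range(S):
                    new_ll1[s] = _sess_ll(s, cc, P, variant, x, d, rt, choice,
                                          reward, pair, include, offsets,
                                          sess_index, quf)
                    if math.isinf(new_ll1[s]) and math.isinf(ll[s, cc]):
                        bad = True
                    delta += new_ll1[s] - ll[s, cc]
                if (not bad) and not math.isnan(delta) and \
                        (delta >= 0.0 or np.random.random() < math.exp(delta)):
                    Sg[dd, p] = prop_S
                    for s in range(S):
                        ll[s, cc] = new_ll1[s]
                else:
                    for s in range(S):
                        d[s, dd, p] = old_d[s]
        # ---- batch adaptation during warmup ----
        if it < n_warmup and (it + 1) % _BATCH == 0:
            for s in range(S):
                for p in range(P):
                    rate = acc_x[s, p] / max(try_x[s, p], 1.0)
                    sc_x[s, p] *= math.exp(_ADAPT_STEP if rate > 0.44 else -_ADAPT_STEP)
                    sc_x[s, p] = min(max(sc_x[s, p], 1e-5), 10.0)
                    acc_x[s, p] = 0.0; try_x[s, p] = 0.0
                    rate = acc_j[s, p] / max(try_j[s, p], 1.0)
                    sc_j[s, p] *= math.exp(_ADAPT_STEP if rate > 0.44 else -_ADAPT_STEP)
                    sc_j[s, p] = min(max(sc_j[s, p], 1e-5), 10.0)
                    acc_j[s, p] = 0.0; try_j[s, p] = 0.0
                for dd in range(D):
                    for p in range(P):
                        rate = acc_d[s, dd, p] / max(try_d[s, dd, p], 1.0)
                        sc_d[s, dd, p] *= math.exp(_ADAPT_STEP if rate > 0.44 else -_ADAPT_STEP)
                        sc_d[s, dd, p] = min(max(sc_d[s, dd, p], 1e-5), 10.0)
                        acc_d[s, dd, p] = 0.0; try_d[s, dd, p] = 0.0
            for dd in range(D):
                for p in range(P):
                    rate = acc_t[dd, p] / max(try_t[dd, p], 1.0)
                    sc_t[dd, p] *= math.exp(_ADAPT_STEP if rate > 0.44 else -_ADAPT_STEP)
                    sc_t[dd, p] = min(max(sc_t[dd, p], 1e-5), 10.0)
                    acc_t[dd, p] = 0.0; try_t[dd, p] = 0.0
        # ---- record ----
        if it >= n_warmup and (it - n_warmup) % thin == 0 and rec < n_keep:
            for p in range(P):
                omu[rec, p] = mu[p]
                osig[rec, p] = sig[p]
            for dd in range(D):
                for p in range(P):
                    oM[rec, dd, p] = M[dd, p]
                    oS[rec, dd, p] = Sg[dd, p]
            tot = 0.0
            for s in range(S):
                for p in range(P):
                    ox[rec, s, p] = x[s, p]
                for dd in range(D):
                    for p in range(P):
                        od[rec, s, dd, p] = d[s, dd, p]
                for c in range(C):
                    tot += ll[s, c]
            oll[rec] = tot
            rec += 1
    acc_out[0] = tot_acc / max(tot_try, 1.0)


@njit(cache=True)
def draw_trunc_normal(mean, sd, lo, hi, n, seed):
    """Standalone truncated-normal Gibbs draw used by the conjugate-step
    oracle tests."""
    np.random.seed(seed)
    out = np.empty(n)
    for i in range(n):
        z = _trunc_normal(mean, sd, lo, hi)
        out[i] = mean if math.isnan(z) else z
    return out
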