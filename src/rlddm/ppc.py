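"""Posterior predictive checks against learning curves and RT distributions.

Observed and simulated data go through the identical binning code path:
trials are ordered by position within session (both stimulus pairs pooled),
split into equal-count time bins, and per-bin means of accuracy and RT are
averaged over subjects. Bands are 2.5%/97.5% percentiles over simulated
datasets of the per-bin group mean. Misses are excluded from bin means in
observed and simulated data alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import SessionData
from .errors import DomainError, RLDDMError
from .model import SubjectParams, LearningRates, simulate_subject
from .synthetic_data import TaskSchedule


@dataclass
class PPCSummary:
    """Binned observed vs. simulated accuracy/RT with percentile bands."""

    level: str  # 'group' or 'individual'
    n_bins: int
    obs_acc: np.ndarray
    obs_rt: np.ndarray
    sim_acc_mean: np.ndarray
    sim_acc_lo: np.ndarray
    sim_acc_hi: np.ndarray
    sim_rt_mean: np.ndarray
    sim_rt_lo: np.ndarray
    sim_rt_hi: np.ndarray
    coverage_acc: float = np.nan
    coverage_rt: float = np.nan
    subject_id: str | None = None
    flagged: bool = False


def _session_bins(session: SessionData, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin mean accuracy and RT for one session (NaN for all-miss bins)."""
    if n_bins > session.n_trials:
        raise DomainError(
            f"n_bins={n_bins} exceeds {session.n_trials} trials in "
            f"({session.subject_id}, {session.condition})"
        )
    acc = np.full(n_bins, np.nan)
    rt = np.full(n_bins, np.nan)
    for b, chunk in enumerate(np.array_split(session.trials, n_bins)):
        oks = [t for t in chunk if not t.miss]
        if oks:
            acc[b] = np.mean([t.chose_optimal for t in oks])
            rt[b] = np.mean([t.rt for t in oks])
    return acc, rt


def bin_learning_curves(sessions: list[SessionData], n_bins: int = 10):
    """Group learning curves: mean over subjects of per-session bin means.

    Returns ``(acc_curve, rt_curve)`` arrays of length ``n_bins``.
    """
    accs, rts = zip(*(_session_bins(s, n_bins) for s in sessions))
    return (np.nanmean(np.vstack(accs), axis=0), np.nanmean(np.vstack(rts), axis=0))


def params_from_draw(draws, draw_index: int) -> dict[tuple[str, str], SubjectParams]:
    """Subject-level parameters per (subject, condition) at one posterior draw."""
    model = draws.model
    subj = draws.stacked("subj")[draw_index]
    shift = draws.stacked("subj_shift")[draw_index] if model.n_drugs else None
    out = {}
    for s, sid in enumerate(model.subjects):
        for c, cond in enumerate(model.conditions):
            if model.sess_index[s, c] < 0:
                continue
            th = subj[s].copy()
            if c > 0:
                th = th + shift[s, c - 1]
            v = model.variant
            if v == "DDM0":
                sp = SubjectParams(alpha=th[0], tau=th[1], v_const=th[2], variant=v)
            elif v == "RLDDM1":
                sp = SubjectParams(alpha=th[0], tau=th[1], v_coeff=th[2],
                                   rates=LearningRates(th[3], th[3]), variant=v)
            else:
                sp = SubjectParams(alpha=th[0], tau=th[1], v_coeff=th[2],
                                   rates=LearningRates(th[3], th[4]), variant=v)
            out[(sid, cond)] = sp
    return out


def schedules_from_sessions(sessions: list[SessionData], seed: int = 0,
                            p_optimal: float = 0.8, p_suboptimal: float = 0.2
                            ) -> dict[tuple[str, str], TaskSchedule]:
    """Reconstruct task schedules from observed sessions.

    Pair order is taken from the data; the chosen option's predrawn reward
    equals the observed outcome, the unchosen option's outcome is redrawn at
    the task rates (it was never revealed to the participant).
    """
    rng = np.random.default_rng(seed)
    out = {}
    for sess in sessions:
        n = sess.n_trials
        pair = np.array([t.pair_id - 1 for t in sess.trials], dtype=np.int8)
        rew_opt = (rng.random(n) < p_optimal).astype(np.int8)
        rew_sub = (rng.random(n) < p_suboptimal).astype(np.int8)
        for i, t in enumerate(sess.trials):
            if t.miss:
                continue
            if t.chose_optimal:
                rew_opt[i] = t.reward
            else:
                rew_sub[i] = t.reward
        out[(sess.subject_id, sess.condition)] = TaskSchedule(
            pair=pair, reward_optimal=rew_opt, reward_suboptimal=rew_sub,
            subject_id=sess.subject_id, condition=sess.condition)
    return out


def simulate_ppc(draws, schedules: dict[tuple[str, str], TaskSchedule],
                 n_sims: int, n_keep: int | None = None, seed: int = 0,
                 dt: float = 1e-3) -> list[list[SessionData]]:
    """Simulate datasets from random posterior draws.

    Each simulated dataset uses one draw's subject-level parameters and
    regenerates every session on its observed schedule; a random ``n_keep``
    subset is retained for analysis.
    """
    n_keep = n_sims if n_keep is None else n_keep
    if n_keep > n_sims:
        raise RLDDMError(f"n_keep={n_keep} exceeds n_sims={n_sims}")
    rng = np.random.default_rng(seed)
    n_draws = draws.stacked("subj").shape[0]
    idx = rng.integers(0, n_draws, size=n_sims)
    sims = []
    for i in idx:
        pars = params_from_draw(draws, int(i))
        ds = [simulate_subject(pars[key], sched, seed=int(rng.integers(2**31)), dt=dt)
              for key, sched in schedules.items() if key in pars]
        sims.append(ds)
    keep = rng.choice(n_sims, size=n_keep, replace=False)
    return [sims[i] for i in sorted(keep)]


def _band_coverage(obs, lo, hi):
    ok = ~np.isnan(obs)
    return float(np.mean((obs[ok] >= lo[ok]) & (obs[ok] <= hi[ok])))


def ppc_group(sims: list[list[SessionData]], sessions: list[SessionData],
              n_bins: int = 10) -> PPCSummary:
    """Group-level check: observed 10-bin curves against simulated mean and
    2.5/97.5% percentile bands, with the share of observed bins inside."""
    obs_acc, obs_rt = bin_learning_curves(sessions, n_bins)
    sim_acc = np.vstack([bin_learning_curves(ds, n_bins)[0] for ds in sims])
    sim_rt = np.vstack([bin_learning_curves(ds, n_bins)[1] for ds in sims])
    acc_lo, acc_hi = np.nanpercentile(sim_acc, [2.5, 97.5], axis=0)
    rt_lo, rt_hi = np.nanpercentile(sim_rt, [2.5, 97.5], axis=0)
    return PPCSummary(
        level="group", n_bins=n_bins, obs_acc=obs_acc, obs_rt=obs_rt,
        sim_acc_mean=np.nanmean(sim_acc, axis=0), sim_acc_lo=acc_lo, sim_acc_hi=acc_hi,
        sim_rt_mean=np.nanmean(sim_rt, axis=0), sim_rt_lo=rt_lo, sim_rt_hi=rt_hi,
        coverage_acc=_band_coverage(obs_acc, acc_lo, acc_hi),
        coverage_rt=_band_coverage(obs_rt, rt_lo, rt_hi),
    )


def rt_percentile_check(sims: list[list[SessionData]], sessions: list[SessionData],
                        percentiles=(17, 50, 83)):
    """Observed RT percentiles vs. simulated 2.5/97.5% percentile bands.

    Percentiles are computed over the pooled non-miss RTs of the dataset.
    Returns a list of dict rows (percentile, observed, band, inside).
    """
    for q in percentiles:
        if not (0 < q < 100):
            raise DomainError(f"percentile must lie in (0, 100), got {q}")

    def pooled_rts(ds):
        return np.array([t.rt for s in ds for t in s.trials if not t.miss])

    obs = np.percentile(pooled_rts(sessions), percentiles)
    sim = np.vstack([np.percentile(pooled_rts(ds), percentiles) for ds in sims])
    lo, hi = np.percentile(sim, [2.5, 97.5], axis=0)
    return [
        {"percentile": q, "observed": float(o), "sim_lo": float(l),
         "sim_hi": float(h), "inside": bool(l <= o <= h)}
        for q, o, l, h in zip(percentiles, obs, lo, hi)
    ]


def ppc_individual(sims: list[list[SessionData]], sessions: list[SessionData],
                   n_bins: int = 5) -> list[PPCSummary]:
    """Per-subject binned RT checks with 2.5/97.5% bands.

    Flags a subject when any observed bin-mean RT leaves the 95% prediction
    interval of the simulated datasets.
    """
    out = []
    sim_index: dict[tuple[str, str], list] = {}
    for ds in sims:
        for s in ds:
            sim_index.setdefault((s.subject_id, s.condition), []).append(s)
    for sess in sessions:
        key = (sess.subject_id, sess.condition)
        sim_sessions = sim_index.get(key, [])
        if not sim_sessions:
            continue
        obs_acc, obs_rt = _session_bins(sess, n_bins)
        accs, rts = zip(*(_session_bins(s, n_bins) for s in sim_sessions))
        accs = np.vstack(accs); rts = np.vstack(rts)
        acc_lo, acc_hi = np.nanpercentile(accs, [2.5, 97.5], axis=0)
        rt_lo, rt_hi = np.nanpercentile(rts, [2.5, 97.5], axis=0)
        cov_rt = _band_coverage(obs_rt, rt_lo, rt_hi)
        out.append(PPCSummary(
            level="individual", n_bins=n_bins, obs_acc=obs_acc, obs_rt=obs_rt,
            sim_acc_mean=np.nanmean(accs, axis=0), sim_acc_lo=acc_lo, sim_acc_hi=acc_hi,
            sim_rt_mean=np.nanmean(rts, axis=0), sim_rt_lo=rt_lo, sim_rt_hi=rt_hi,
            coverage_acc=_band_coverage(obs_acc, acc_lo, acc_hi),
            coverage_rt=cov_rt,
            subject_id=f"{sess.subject_id}/{sess.condition}",
            flagged=cov_rt < 1.0,
        ))
    return out
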