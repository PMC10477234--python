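"""Q-learning value updates, drift linkage, RLDDM likelihoods and simulation.

Three model variants are supported:

* ``DDM0`` — null diffusion model with a constant drift rate (no learning);
* ``RLDDM1`` — Q-learning with a single learning rate feeding trial-wise
  drift rates ``v_t = v_coeff * (Q_optimal - Q_suboptimal)``;
* ``RLDDM2`` — dual learning rates for positive vs. negative prediction
  errors (learning from reward delivery vs. reward omission).

Learning rates are estimated in probit space ([-6, 6]) and mapped to (0, 1)
through the standard normal CDF. The upper diffusion boundary corresponds to
choosing the optimal (80%-reinforced) option; suboptimal choices carry
negative signed RTs. Q-values start at 0.5 (the expected value of a 1-euro
coin under a flat prior) and only the chosen option's value is updated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from numba import njit
from scipy.stats import norm

from .data_model import DEADLINE, SessionData, TrialRecord
from .errors import DomainError
from .wfpt import DENSITY_EPS, _logf_signed, _sample_kernel

VARIANTS = ("DDM0", "RLDDM1", "RLDDM2")
_VARIANT_CODE = {"DDM0": 0, "RLDDM1": 1, "RLDDM2": 2}
# parameter count per variant: (alpha, tau, v) / (+eta) / (+eta_minus)
N_PARAMS = {"DDM0": 3, "RLDDM1": 4, "RLDDM2": 5}
PARAM_NAMES = {
    "DDM0": ("alpha", "tau", "v_const"),
    "RLDDM1": ("alpha", "tau", "v_coeff", "eta_raw"),
    "RLDDM2": ("alpha", "tau", "v_coeff", "eta_plus_raw", "eta_minus_raw"),
}


def rate_transform(raw: float) -> float:
    """Map a probit-space learning rate to (0, 1) via the standard normal CDF."""
    return float(norm.cdf(raw))


def rate_untransform(rate: float) -> float:
    """Inverse of :func:`rate_transform` (probit)."""
    return float(norm.ppf(rate))


@dataclass(frozen=True)
class LearningRates:
    """Learning rates in probit (estimation) space."""

    eta_plus_raw: float
    eta_minus_raw: float

    @property
    def eta_plus(self) -> float:
        return rate_transform(self.eta_plus_raw)

    @property
    def eta_minus(self) -> float:
        return rate_transform(self.eta_minus_raw)


@dataclass
class QState:
    """Expected reward (euros) of the optimal/suboptimal option per pair."""

    q_optimal: np.ndarray = field(default_factory=lambda: np.full(2, 0.5))
    q_suboptimal: np.ndarray = field(default_factory=lambda: np.full(2, 0.5))

    def qdiff(self, pair_id: int) -> float:
        return float(self.q_optimal[pair_id - 1] - self.q_suboptimal[pair_id - 1])

    def copy(self) -> "QState":
        return QState(self.q_optimal.copy(), self.q_suboptimal.copy())


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject (per-condition) diffusion + learning parameters."""

    alpha: float
    tau: float
    v_coeff: float = 0.0
    rates: LearningRates = LearningRates(0.0, 0.0)
    variant: str = "RLDDM2"
    v_const: float = 0.0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise DomainError(f"unknown variant {self.variant!r}")

    def theta(self) -> np.ndarray:
        """Flat parameter vector in the internal (alpha, tau, v, eta+, eta-) layout."""
        if self.variant == "DDM0":
            return np.array([self.alpha, self.tau, self.v_const, 0.0, 0.0])
        em = self.rates.eta_plus_raw if self.variant == "RLDDM1" else self.rates.eta_minus_raw
        return np.array([self.alpha, self.tau, self.v_coeff,
                         self.rates.eta_plus_raw, em])


def update_q(state: QState, pair_id: int, chose_optimal: bool, reward: int,
             rates: LearningRates, single_rate: bool = False) -> QState:
    """One prediction-error update of the chosen option's Q-value.

    delta = r - Q_chosen; Q_chosen += eta * delta with eta = eta_plus when
    delta > 0 and eta_minus otherwise (ties delta == 0 use eta_minus, which
    leaves the value unchanged anyway). Unchosen values are untouched; with
    rewards in {0, 1} and eta in (0, 1), values stay inside [0, 1].
    """
    new = state.copy()
    arr = new.q_optimal if chose_optimal else new.q_suboptimal
    q = arr[pair_id - 1]
    delta = reward - q
    if single_rate:
        eta = rates.eta_plus
    else:
        eta = rates.eta_plus if delta > 0 else rates.eta_minus
    arr[pair_id - 1] = q + eta * delta
    return new


def trial_drift(qdiff: float, params: SubjectParams) -> float:
    """Trial-wise drift rate: ``v_coeff * qdiff`` (constant for DDM0)."""
    if params.variant == "DDM0":
        return params.v_const
    return params.v_coeff * qdiff


@njit(cache=True)
def _phi(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


@njit(cache=True)
def _session_loglik(theta: np.ndarray, variant: int,
                    rt: np.ndarray, choice: np.ndarray, reward: np.ndarray,
                    pair: np.ndarray, include: np.ndarray,
                    q_update_filtered: bool, pointwise: np.ndarray) -> float:
    """Replay one session's observed choices/rewards, accumulating the WFPT
    log-likelihood of included trials. ``pointwise`` must have one slot per
    included trial (pass an empty array to skip). Returns -inf when any
    included rt <= tau or alpha/tau leave their domain."""
    alpha = theta[0]
    tau = theta[1]
    if alpha <= 1e-3 or tau < 0.0:
        return -np.inf
    q = np.full(4, 0.5)  # [opt p1, opt p2, sub p1, sub p2]
    if variant == 0:
        etap = 0.0
        etam = 0.0
    elif variant == 1:
        etap = _phi(theta[3])
        etam = etap
    else:
        etap = _phi(theta[3])
        etam = _phi(theta[4])
    total = 0.0
    j = 0
    bad = False
    for i in range(rt.shape[0]):
        p = pair[i]
        qd = q[p] - q[2 + p]
        v = theta[2] if variant == 0 else theta[2] * qd
        if include[i]:
            t_dec = rt[i] - tau
            if t_dec <= 0.0:
                ll = -np.inf
                bad = True
            else:
                ll = _logf_signed(t_dec, choice[i] > 0, v, alpha, 0.5, DENSITY_EPS)
            if pointwise.shape[0] > 0:
                pointwise[j] = ll
            j += 1
            total += ll
        if variant > 0 and (include[i] or q_update_filtered):
            k = p if choice[i] > 0 else 2 + p
            delta = reward[i] - q[k]
            eta = etap if delta > 0.0 else etam
            q[k] = q[k] + eta * delta
    if bad:
        return -np.inf
    return total


class SubjectLogLik(NamedTuple):
    total: float
    pointwise: np.ndarray
    tau_violation: bool


def pack_session(session: SessionData, include_mask=None):
    """Convert a session to the flat arrays consumed by the numba kernels.

    Miss trials are dropped entirely (no feedback was shown, so no Q update
    and no likelihood contribution). ``include_mask``, aligned with
    ``session.trials``, marks trials contributing to the likelihood; trials
    excluded by the fast-RT filter still drive Q updates by default.
    """
    keep = [(i, t) for i, t in enumerate(session.trials) if not t.miss]
    rt = np.array([t.rt for _, t in keep])
    choice = np.array([1 if t.chose_optimal else -1 for _, t in keep], dtype=np.int8)
    reward = np.array([t.reward for _, t in keep], dtype=np.float64)
    pair = np.array([t.pair_id - 1 for _, t in keep], dtype=np.int8)
    if include_mask is None:
        include = np.ones(len(keep), dtype=np.bool_)
    else:
        include = np.array([include_mask[i] for i, _ in keep], dtype=np.bool_)
    return rt, choice, reward, pair, include


def subject_loglik(params: SubjectParams, session: SessionData,
                   include_mask=None, q_update_filtered: bool = True) -> SubjectLogLik:
    """Total and per-trial WFPT log-likelihood of a session under ``params``.

    The session is replayed in trial order, updating Q-values from the
    *observed* choices and rewards; each included trial contributes the log
    WFPT density of its signed RT at the current trial-wise drift. Any
    included rt <= tau yields ``total = -inf`` with ``tau_violation=True``
    (rejectable by a sampler) rather than an exception.
    """
    rt, choice, reward, pair, include = pack_session(session, include_mask)
    pointwise = np.empty(int(include.sum()))
    total = _session_loglik(params.theta(), _VARIANT_CODE[params.variant],
                            rt, choice, reward, pair, include,
                            q_update_filtered, pointwise)
    violation = bool(np.any(rt[include] <= params.tau))
    return SubjectLogLik(float(total), pointwise, violation)


@njit(cache=True)
def _simulate_session(theta: np.ndarray, variant: int, pair: np.ndarray,
                      rew_opt: np.ndarray, rew_sub: np.ndarray,
                      deadline: float, dt: float, seed: int):
    """Generate choices/RTs/rewards for one session. choice: +1 optimal,
    -1 suboptimal, 0 miss (first passage later than the deadline)."""
    np.random.seed(seed)
    n = pair.shape[0]
    alpha = theta[0]
    tau = theta[1]
    if variant == 1:
        etap = _phi(theta[3]); etam = etap
    else:
        etap = _phi(theta[3]); etam = _phi(theta[4])
    q = np.full(4, 0.5)
    choice = np.zeros(n, dtype=np.int8)
    rt = np.full(n, np.nan)
    reward = np.full(n, -1.0)
    sqdt = math.sqrt(dt)
    max_steps = int(max(deadline - tau, dt) / dt) + 1
    for i in range(n):
        p = pair[i]
        qd = q[p] - q[2 + p]
        v = theta[2] if variant == 0 else theta[2] * qd
        # single-stream Euler-Maruyama with bridge crossing correction
        x = 0.5 * alpha
        srt = np.nan
        for step in range(1, max_steps + 1):
            x_new = x + v * dt + sqdt * np.random.normal()
            if x_new >= alpha:
                srt = tau + step * dt
                break
            if x_new <= 0.0:
                srt = -(tau + step * dt)
                break
            p_up = math.exp(-2.0 * (alpha - x) * (alpha - x_new) / dt)
            if np.random.random() < p_up:
                srt = tau + step * dt
                break
            p_lo = math.exp(-2.0 * x * x_new / dt)
            if np.random.random() < p_lo:
                srt = -(tau + step * dt)
                break
            x = x_new
        if math.isnan(srt) or abs(srt) > deadline:
            continue  # miss: no feedback, no update
        c = 1 if srt > 0.0 else -1
        choice[i] = c
        rt[i] = abs(srt)
        r = rew_opt[i] if c > 0 else rew_sub[i]
        reward[i] = r
        if variant > 0:
            k = p if c > 0 else 2 + p
            delta = r - q[k]
            eta = etap if delta > 0.0 else etam
            q[k] = q[k] + eta * delta
    return choice, rt, reward


def simulate_subject(params: SubjectParams, schedule, seed: int,
                     dt: float = 1e-3) -> SessionData:
    """Simulate one session of the task under ``params``.

    Each trial draws a signed first-passage RT at the current trial-wise
    drift; the sign maps to the chosen option, the reward comes from the
    schedule's predrawn outcome for that option, and the chosen Q-value is
    updated. First passages beyond the 3-s deadline become misses with no
    feedback and no update. Bit-reproducible under ``seed``.
    """
    pair = np.asarray(schedule.pair, dtype=np.int8)
    choice, rt, reward = _simulate_session(
        params.theta(), _VARIANT_CODE[params.variant], pair,
        np.asarray(schedule.reward_optimal, dtype=np.float64),
        np.asarray(schedule.reward_suboptimal, dtype=np.float64),
        schedule.deadline, dt, int(seed) % (2**31),
    )
    trials = []
    for i in range(len(pair)):
        if choice[i] == 0:
            trials.append(TrialRecord(schedule.subject_id, schedule.condition,
                                      int(pair[i]) + 1, i + 1, None, None, None, miss=True))
        else:
            trials.append(TrialRecord(schedule.subject_id, schedule.condition,
                                      int(pair[i]) + 1, i + 1, choice[i] > 0,
                                      float(rt[i]), int(reward[i])))
    return SessionData(subject_id=schedule.subject_id,
                       condition=schedule.condition, trials=trials)
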