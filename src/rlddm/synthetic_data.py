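"""Task schedules and hierarchical ground-truth populations.

Emulates the study conditions of the probabilistic reward task: 31 subjects
x 3 within-subject drug conditions (placebo, L-dopa, haloperidol) x 60
trials, two stimulus pairs of 30 trials each with 80%/20% reinforcement, a
3-s response deadline, and subject-level RLDDM parameters drawn from group
Gaussians plus additive per-drug shifts (applied in probit space for the
learning rates).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .data_model import CONDITIONS, DEADLINE, SessionData, save_trials
from .errors import DomainError
from .model import LearningRates, SubjectParams, simulate_subject

DRUGS = ("ldopa", "haloperidol")
PARAMS_RLDDM2 = ("alpha", "tau", "v_coeff", "eta_plus_raw", "eta_minus_raw")
# domain floors used when truncating subject-level draws
_ALPHA_MIN = 0.1
_TAU_MIN = 0.05


@dataclass
class TaskSchedule:
    """One session's trial schedule: randomized pair order (30 trials per
    pair) and predrawn Bernoulli reward outcomes for both options."""

    pair: np.ndarray  # 0/1 per trial
    reward_optimal: np.ndarray  # predrawn outcome of the 80% option, per trial
    reward_suboptimal: np.ndarray  # predrawn outcome of the 20% option
    deadline: float = DEADLINE
    subject_id: str = "sim"
    condition: str = "placebo"

    @property
    def n_trials(self) -> int:
        return len(self.pair)


def make_schedule(seed: int, n_trials: int = 60,
                  p_optimal: float = 0.8, p_suboptimal: float = 0.2,
                  subject_id: str = "sim", condition: str = "placebo") -> TaskSchedule:
    """Random pair interleaving (n_trials/2 per pair) with independently
    predrawn reward outcomes for both options at the stated rates."""
    rng = np.random.default_rng(seed)
    pair = np.repeat(np.array([0, 1], dtype=np.int8), n_trials // 2)
    rng.shuffle(pair)
    return TaskSchedule(
        pair=pair,
        reward_optimal=(rng.random(n_trials) < p_optimal).astype(np.int8),
        reward_suboptimal=(rng.random(n_trials) < p_suboptimal).astype(np.int8),
        subject_id=subject_id,
        condition=condition,
    )


@dataclass
class GroupTruth:
    """Ground-truth group-level parameters for the generative population.

    Placebo is the baseline; drug conditions add subject-level Gaussian
    shifts (mean ``shift_means[drug][param]``, SD ``shift_sds[drug][param]``)
    to the placebo value of each parameter. Learning-rate shifts act in
    probit (raw) space.
    """

    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)
    shift_means: dict = field(default_factory=dict)
    shift_sds: dict = field(default_factory=dict)
    n_subjects: int = 31
    variant: str = "RLDDM2"

    def __post_init__(self):
        for p, s in self.sds.items():
            if s <= 0:
                raise DomainError(f"group SD for {p} must be > 0, got {s}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroupTruth":
        return cls(**d)


def illustrative_truth(n_subjects: int = 31) -> GroupTruth:
    """Illustrative generating truth on the scale of the reported placebo
    posteriors, with drug-shift means on the scale of the reported drug
    effects. Illustrative only — not the study's ground truth."""
    return GroupTruth(
        means={"alpha": 2.0, "tau": 0.35, "v_coeff": 4.0,
               "eta_plus_raw": -0.8, "eta_minus_raw": -1.3},
        sds={"alpha": 0.35, "tau": 0.08, "v_coeff": 1.2,
             "eta_plus_raw": 0.5, "eta_minus_raw": 0.6},
        shift_means={
            "ldopa": {"alpha": -0.114, "tau": 0.000, "v_coeff": -0.0104,
                      "eta_plus_raw": -0.076, "eta_minus_raw": -0.655},
            "haloperidol": {"alpha": -0.125, "tau": -0.013, "v_coeff": -0.255,
                            "eta_plus_raw": -0.046, "eta_minus_raw": -1.69},
        },
        shift_sds={
            "ldopa": {"alpha": 0.08, "tau": 0.03, "v_coeff": 0.4,
                      "eta_plus_raw": 0.25, "eta_minus_raw": 0.5},
            "haloperidol": {"alpha": 0.08, "tau": 0.03, "v_coeff": 0.4,
                            "eta_plus_raw": 0.25, "eta_minus_raw": 0.5},
        },
        n_subjects=n_subjects,
    )


def _params_from_theta(values: dict, variant: str) -> SubjectParams:
    if variant == "DDM0":
        return SubjectParams(alpha=values["alpha"], tau=values["tau"],
                             v_const=values["v_const"], variant=variant)
    if variant == "RLDDM1":
        rates = LearningRates(values["eta_raw"], values["eta_raw"])
    else:
        rates = LearningRates(values["eta_plus_raw"], values["eta_minus_raw"])
    return SubjectParams(alpha=values["alpha"], tau=values["tau"],
                         v_coeff=values["v_coeff"], rates=rates, variant=variant)


def sample_population(truth: GroupTruth, seed: int,
                      max_tries: int = 1000) -> dict[tuple[str, str], SubjectParams]:
    """Draw subject-level parameters for every subject x condition.

    Placebo parameters are Normal(mean, SD) per parameter, rejection-sampled
    so that alpha and tau stay in their domains in *every* condition after
    adding the subject's drug shifts. Zero shift means and a degenerate-small
    shift SD therefore give (numerically) identical conditions per subject.
    """
    rng = np.random.default_rng(seed)
    drugs = [d for d in truth.shift_means]
    out: dict[tuple[str, str], SubjectParams] = {}
    pnames = list(truth.means)
    for s in range(truth.n_subjects):
        sid = f"S{s + 1:02d}"
        for _ in range(max_tries):
            base = {p: rng.normal(truth.means[p], truth.sds[p]) for p in pnames}
            shifts = {
                d: {p: rng.normal(truth.shift_means[d][p], truth.shift_sds[d][p])
                    for p in pnames}
                for d in drugs
            }
            cond_vals = {"placebo": base}
            for d in drugs:
                cond_vals[d] = {p: base[p] + shifts[d][p] for p in pnames}
            ok = all(v["alpha"] > _ALPHA_MIN and v["tau"] >= _TAU_MIN
                     for v in cond_vals.values())
            if ok:
                break
        else:
            raise DomainError(
                f"could not satisfy parameter truncation for subject {sid}; "
                "truth places too much mass outside the valid domain"
            )
        for cond, vals in cond_vals.items():
            out[(sid, cond)] = _params_from_theta(vals, truth.variant)
    return out


def generate_dataset(truth: GroupTruth, seed: int, out_dir: str | Path | None = None,
                     n_trials: int = 60, dt: float = 1e-3):
    """Simulate a full trial table (all subjects, all conditions).

    The master seed is split hierarchically (population draw, per-session
    schedule, per-session diffusion noise) so each component is
    independently reproducible. When ``out_dir`` is given, writes the
    canonical CSV plus a YAML provenance sidecar recording truth and seed.

    Returns ``(sessions, schedules, population, provenance)``.
    """
    ss = np.random.SeedSequence(seed)
    pop_seed, sched_seed, sim_seed = (int(s.generate_state(1)[0]) % (2**31)
                                      for s in ss.spawn(3))
    population = sample_population(truth, pop_seed)
    conditions = ["placebo"] + list(truth.shift_means)
    sessions, schedules = [], {}
    rng_sched = np.random.default_rng(sched_seed)
    rng_sim = np.random.default_rng(sim_seed)
    for s in range(truth.n_subjects):
        sid = f"S{s + 1:02d}"
        for cond in conditions:
            sched = make_schedule(int(rng_sched.integers(2**31)), n_trials=n_trials,
                                  subject_id=sid, condition=cond)
            schedules[(sid, cond)] = sched
            sessions.append(simulate_subject(population[(sid, cond)], sched,
                                             seed=int(rng_sim.integers(2**31)), dt=dt))
    provenance = {"seed": int(seed), "truth": truth.to_dict(), "n_trials": n_trials,
                  "generator": "rlddm.synthetic_data.generate_dataset"}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_trials(sessions, out_dir / "trials.csv")
        with open(out_dir / "provenance.yaml", "w") as fh:
            yaml.safe_dump(provenance, fh, sort_keys=False)
    return sessions, schedules, population, provenance


def load_provenance(path: str | Path) -> dict:
    """Read a provenance sidecar written by :func:`generate_dataset`."""
    with open(path) as fh:
        return yaml.safe_load(fh)
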