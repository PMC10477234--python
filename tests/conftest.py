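"""Shared fixtures: hand-written trial tables and cached desk-scale fits."""

import warnings

import numpy as np
import pytest

from rlddm.data_model import SessionData, TrialRecord
from rlddm.inference import MCMCConfig, build_model, run_mcmc
from rlddm.synthetic_data import generate_dataset, illustrative_truth

warnings.filterwarnings("ignore", category=FutureWarning)


def make_session(subject="S1", condition="placebo", rts=None, choices=None,
                 rewards=None, pairs=None, misses=None):
    """Build a session from parallel lists (misses override the rest)."""
    n = len(rts)
    choices = choices if choices is not None else [True] * n
    rewards = rewards if rewards is not None else [1] * n
    pairs = pairs if pairs is not None else [1 + (i % 2) for i in range(n)]
    misses = misses if misses is not None else [False] * n
    trials = []
    for i in range(n):
        if misses[i]:
            trials.append(TrialRecord(subject, condition, pairs[i], i + 1,
                                      None, None, None, miss=True))
        else:
            trials.append(TrialRecord(subject, condition, pairs[i], i + 1,
                                      choices[i], rts[i], rewards[i]))
    return SessionData(subject_id=subject, condition=condition, trials=trials)


@pytest.fixture
def session60():
    """60 trials, RTs equally spaced 0.3..3.0, alternating choices."""
    rts = np.linspace(0.3, 3.0, 60)
    choices = [i % 2 == 0 for i in range(60)]
    rewards = [1 if c else 0 for c in choices]
    return make_session(rts=list(rts), choices=choices, rewards=rewards)


@pytest.fixture
def tiny_csv(tmp_path):
    """Hand-written 6-row table: 2 subjects x 3 trials."""
    p = tmp_path / "tiny.csv"
    p.write_text(
        "subject,condition,pair,trial,choice,rt,reward\n"
        "S1,placebo,1,1,optimal,0.8,1\n"
        "S1,placebo,2,2,suboptimal,1.1,0\n"
        "S1,placebo,1,3,miss,,\n"
        "S2,placebo,2,1,optimal,0.55,1\n"
        "S2,placebo,1,2,optimal,0.9,0\n"
        "S2,placebo,2,3,suboptimal,2.95,1\n"
    )
    return p


@pytest.fixture(scope="session")
def truth8():
    return illustrative_truth(n_subjects=8)


@pytest.fixture(scope="session")
def dataset8(truth8):
    """Small synthetic dataset: 8 subjects x 3 conditions x 60 trials."""
    sessions, schedules, population, provenance = generate_dataset(truth8, seed=11)
    return {"sessions": sessions, "schedules": schedules,
            "population": population, "provenance": provenance}


@pytest.fixture(scope="session")
def placebo8(dataset8):
    return [s for s in dataset8["sessions"] if s.condition == "placebo"]


@pytest.fixture(scope="session")
def fit_rlddm2_placebo8(placebo8):
    """Desk-scale dual-learning-rate fit reused across evaluation/ppc tests."""
    model = build_model("RLDDM2", placebo8, combined=False)
    cfg = MCMCConfig.desk(seed=5, n_chains=2, n_burnin=1500, n_retained=750, thin=2)
    return run_mcmc(model, cfg)


@pytest.fixture(scope="session")
def fit_ddm0_placebo8(placebo8):
    """Desk-scale null-model fit (constant drift) reused across tests."""
    model = build_model("DDM0", placebo8, combined=False)
    cfg = MCMCConfig.desk(seed=5, n_chains=2, n_burnin=1500, n_retained=750, thin=2)
    return run_mcmc(model, cfg)
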