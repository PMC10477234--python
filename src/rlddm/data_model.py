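"""Domain types, trial-table IO, trial filtering, and model-agnostic summaries.

The canonical on-disk format is a long-format CSV/TSV with one row per trial
and columns ``subject, condition, pair, trial, choice, rt, reward``:

* ``condition`` — one of ``placebo``, ``ldopa``, ``haloperidol``;
* ``pair`` — stimulus pair, 1 or 2 (30 trials each per session);
* ``choice`` — ``optimal``, ``suboptimal`` or ``miss`` (no response within
  the 3-s deadline);
* ``rt`` — response time in seconds (empty for misses);
* ``reward`` — 0/1 euros (empty for misses).

Choices of the suboptimal option are coded as negative response times for
model estimation (see :func:`signed_rt`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptySessionError, SchemaError, ValidationError

CONDITIONS = ("placebo", "ldopa", "haloperidol")
DEADLINE = 3.0  # response deadline in seconds
REQUIRED_COLUMNS = ("subject", "condition", "pair", "trial", "choice", "rt", "reward")


@dataclass(frozen=True)
class TrialRecord:
    """One trial of the probabilistic reward task.

    ``chose_optimal``, ``rt`` and ``reward`` are ``None`` for miss trials
    (no response within the deadline).
    """

    subject_id: str
    condition: str
    pair_id: int
    trial_index: int
    chose_optimal: bool | None
    rt: float | None
    reward: int | None
    miss: bool = False

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.pair_id not in (1, 2):
            raise ValidationError(f"pair_id must be 1 or 2, got {self.pair_id}")
        if self.miss:
            if self.rt is not None or self.reward is not None:
                raise ValidationError("miss trials carry no rt or reward")
        else:
            if self.rt is None or self.rt <= 0:
                raise ValidationError(f"non-miss trial requires rt > 0, got {self.rt}")
            if self.reward not in (0, 1):
                raise ValidationError(f"reward must be 0 or 1, got {self.reward}")


@dataclass
class SessionData:
    """Ordered trials for one subject in one drug condition."""

    subject_id: str
    condition: str
    trials: list[TrialRecord] = field(default_factory=list)

    def __post_init__(self):
        self.trials = sorted(self.trials, key=lambda t: t.trial_index)
        seen = set()
        for t in self.trials:
            if t.trial_index in seen:
                raise ValidationError(
                    f"duplicate trial_index {t.trial_index} in "
                    f"({self.subject_id}, {self.condition})"
                )
            seen.add(t.trial_index)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def non_miss(self) -> list[TrialRecord]:
        return [t for t in self.trials if not t.miss]

    def __iter__(self):
        return iter(self.trials)

    def __len__(self):
        return len(self.trials)


@dataclass(frozen=True)
class BehavioralSummary:
    """Model-agnostic performance measures for one session."""

    accuracy: float
    total_rewards: int
    median_rt: float
    n_misses: int


def _parse_row(row, idx: int) -> TrialRecord:
    choice = str(row["choice"]).strip().lower()
    if choice not in ("optimal", "suboptimal", "miss"):
        raise ValidationError(f"row {idx}: unknown choice {choice!r}")
    miss = choice == "miss"
    if miss:
        rt, reward, chose = None, None, None
    else:
        rt = float(row["rt"])
        if not math.isfinite(rt) or rt <= 0:
            raise ValidationError(f"row {idx}: rt must be > 0 on non-miss rows, got {rt}")
        if rt > DEADLINE:
            raise ValidationError(
                f"row {idx}: rt {rt} exceeds the {DEADLINE}-s response deadline")
        reward = int(row["reward"])
        chose = choice == "optimal"
    return TrialRecord(
        subject_id=str(row["subject"]),
        condition=str(row["condition"]).strip().lower(),
        pair_id=int(row["pair"]),
        trial_index=int(row["trial"]),
        chose_optimal=chose,
        rt=rt,
        reward=reward,
        miss=miss,
    )


def load_trials(path: str | Path, sep: str | None = None) -> list[SessionData]:
    """Load a long-format trial table into per-(subject, condition) sessions.

    Sessions are returned sorted by (subject, condition order placebo →
    ldopa → haloperidol), trials sorted by ``trial`` within each.

    Raises
    ------
    SchemaError
        If a required column is missing.
    ValidationError
        If a row violates a domain invariant (rt <= 0, unknown choice, ...).
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"trial table {path} is missing required column {col!r}")
    records = [_parse_row(row, idx) for idx, row in df.iterrows()]
    sessions: dict[tuple[str, str], list[TrialRecord]] = {}
    for rec in records:
        sessions.setdefault((rec.subject_id, rec.condition), []).append(rec)
    cond_order = {c: i for i, c in enumerate(CONDITIONS)}
    keys = sorted(sessions, key=lambda k: (k[0], cond_order.get(k[1], 99)))
    return [SessionData(subject_id=s, condition=c, trials=sessions[(s, c)]) for s, c in keys]


def to_frame(sessions: Iterable[SessionData]) -> pd.DataFrame:
    """Flatten sessions back into the canonical long-format table."""
    rows = []
    for sess in sessions:
        for t in sess.trials:
            if t.miss:
                choice, rt, reward = "miss", "", ""
            else:
                choice = "optimal" if t.chose_optimal else "suboptimal"
                rt, reward = repr(t.rt), t.reward
            rows.append(
                {
                    "subject": t.subject_id,
                    "condition": t.condition,
                    "pair": t.pair_id,
                    "trial": t.trial_index,
                    "choice": choice,
                    "rt": rt,
                    "reward": reward,
                }
            )
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def save_trials(sessions: Iterable[SessionData], path: str | Path) -> None:
    """Write sessions to CSV/TSV; full-precision RTs (``repr``) so that a
    load/save round trip is bit-exact."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    to_frame(sessions).to_csv(path, sep=sep, index=False)


def fast_trial_mask(session: SessionData, fast_quantile: float = 0.05) -> list[bool]:
    """Per-trial keep-mask over ``session.trials``: ``False`` for misses and
    for the fastest ``ceil(q * n_non_miss)`` non-miss trials.

    Ties on rt are broken by trial_index (earlier trials removed first).
    """
    if session.n_trials == 0:
        raise EmptySessionError(f"empty session ({session.subject_id}, {session.condition})")
    non_miss = [(t.rt, t.trial_index, i) for i, t in enumerate(session.trials) if not t.miss]
    if not non_miss:
        raise EmptySessionError(
            f"all trials are misses in ({session.subject_id}, {session.condition})"
        )
    n_remove = math.ceil(fast_quantile * len(non_miss)) if fast_quantile > 0 else 0
    removed = {i for _, _, i in sorted(non_miss)[:n_remove]}
    return [
        (not t.miss) and (i not in removed) for i, t in enumerate(session.trials)
    ]


def filter_trials(session: SessionData, fast_quantile: float = 0.05) -> SessionData:
    """Drop misses and the fastest ``ceil(q*n)`` non-miss trials of a session.

    Implausibly fast responses would otherwise dominate the diffusion-model
    RT likelihood. Original trial indices are preserved on survivors; the
    operation is *not* idempotent (re-filtering removes a further
    ``ceil(q*n')`` trials from the survivors).
    """
    mask = fast_trial_mask(session, fast_quantile)
    return SessionData(
        subject_id=session.subject_id,
        condition=session.condition,
        trials=[t for t, keep in zip(session.trials, mask) if keep],
    )


def signed_rt(trial: TrialRecord) -> float:
    """Signed response time: +rt for optimal choices, −rt for suboptimal."""
    if trial.miss:
        raise ValidationError("signed_rt is undefined for miss trials")
    return trial.rt if trial.chose_optimal else -trial.rt


def behavioral_summary(session: SessionData) -> BehavioralSummary:
    """Accuracy, total rewards, median RT and miss count for one session.

    Accuracy and median RT are computed over non-miss trials only.
    """
    non_miss = session.non_miss()
    if not non_miss:
        raise EmptySessionError(
            f"no non-miss trials in ({session.subject_id}, {session.condition})"
        )
    acc = sum(t.chose_optimal for t in non_miss) / len(non_miss)
    rewards = sum(t.reward for t in non_miss)
    med = float(np.median([t.rt for t in non_miss]))
    return BehavioralSummary(
        accuracy=acc,
        total_rewards=int(rewards),
        median_rt=med,
        n_misses=session.n_trials - len(non_miss),
    )


def _slowest_third(session: SessionData) -> list[TrialRecord]:
    non_miss = sorted(session.non_miss(), key=lambda t: (t.rt, t.trial_index))
    n = len(non_miss)
    k = n // 3
    if k == 0:
        raise EmptySessionError(
            f"slowest-third subset empty in ({session.subject_id}, {session.condition})"
        )
    return non_miss[n - k:]


def slowest_third_diffs(placebo: SessionData, drug: SessionData) -> tuple[float, float]:
    """Placebo-minus-drug differences on the slowest third of trials.

    Returns ``(ΔRT, Δacc)`` where ΔRT is the difference in mean RT and Δacc
    the difference in arcsine-square-root transformed accuracy, each computed
    on the slowest third (by rt) of each session's non-miss trials. These are
    the behavioral covariates used to relate drug-induced decision-threshold
    changes back to raw performance.
    """
    sub_p = _slowest_third(placebo)
    sub_d = _slowest_third(drug)
    d_rt = float(np.mean([t.rt for t in sub_p]) - np.mean([t.rt for t in sub_d]))
    acc_p = sum(t.chose_optimal for t in sub_p) / len(sub_p)
    acc_d = sum(t.chose_optimal for t in sub_d) / len(sub_d)
    d_acc = math.asin(math.sqrt(acc_p)) - math.asin(math.sqrt(acc_d))
    return d_rt, d_acc
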