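"""Adaptive probabilistic reversal-learning task engine.

Two stimuli carry complementary win probabilities (by default 70/30 for the
currently "good" stimulus and 40/60 for the "bad" one).  Each trial the agent
picks a stimulus and receives a monetary win or loss.  After four consecutive
choices of the good stimulus the contingencies reverse with 25% probability,
re-drawn on every subsequent qualifying trial, so better learners face more
reversals — the task adapts its difficulty to performance.

Random draws consume a single per-session generator in a fixed order
(feedback first, then the hazard draw if the streak qualifies), so sessions
are bit-reproducible from ``seed``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TaskConfig",
    "TaskState",
    "TrialRecord",
    "SessionData",
    "step",
    "run_policy",
    "count_reversals",
    "sessions_to_frame",
    "write_sessions_csv",
    "read_sessions_csv",
]


class InvalidChoiceError(ValueError):
    """Raised when a policy returns something other than stimulus 0 or 1."""


class SessionExhaustedError(RuntimeError):
    """Raised when ``step`` is called on a finished session."""


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the reversal task.

    Defaults are the study task: 120 trials, 70%/40% win probability for the
    good/bad stimulus, reversal hazard 0.25 once the agent has chosen the
    good stimulus on >= 4 consecutive trials, and +/- 0.20 EUR feedback.
    """

    n_trials: int = 120
    p_win_good: float = 0.70
    p_win_bad: float = 0.40
    reversal_criterion: int = 4
    reversal_hazard: float = 0.25
    win_amount: float = 0.20
    loss_amount: float = -0.20

    def __post_init__(self) -> None:
        for name in ("p_win_good", "p_win_bad", "reversal_hazard"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} is not a probability")
        if self.p_win_good <= self.p_win_bad:
            raise ValueError("p_win_good must exceed p_win_bad")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.reversal_criterion < 1:
            raise ValueError("reversal_criterion must be >= 1")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "TaskConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in mapping.items() if k in known})

    @classmethod
    def from_file(cls, path: str | Path) -> "TaskConfig":
        """Read a config from a YAML or JSON file (top-level ``task`` block
        or flat mapping)."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        if isinstance(data, dict) and "task" in data and isinstance(data["task"], dict):
            data = data["task"]
        return cls.from_mapping(data)


@dataclass
class TaskState:
    """Mutable state of a running session."""

    config: TaskConfig
    rng: np.random.Generator
    trial_index: int = 0
    good_stimulus: int = 0
    streak: int = 0
    cumulative_reward: float = 0.0

    @classmethod
    def new(cls, config: TaskConfig, seed: int | np.random.SeedSequence) -> "TaskState":
        return cls(config=config, rng=np.random.default_rng(seed))

    @property
    def finished(self) -> bool:
        return self.trial_index >= self.config.n_trials


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int  # 0-based internally; serialized 1-based
    choice: int | None
    correct: bool | None
    feedback_sign: int | None  # +1 win, -1 loss, None missing
    feedback_value: float | None
    reversal_after: bool
    good_stimulus: int


@dataclass
class SessionData:
    """One subject-wave's ordered trial records plus task config."""

    subject: str
    wave: int
    config: TaskConfig
    trials: list[TrialRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def choices(self) -> np.ndarray:
        """Choices as int8, -1 for missing trials."""
        return np.array(
            [-1 if t.choice is None else t.choice for t in self.trials], dtype=np.int8
        )

    @property
    def outcomes(self) -> np.ndarray:
        """Feedback signs as int8 (+1 win, -1 loss), 0 for missing trials."""
        return np.array(
            [0 if t.feedback_sign is None else t.feedback_sign for t in self.trials],
            dtype=np.int8,
        )

    @property
    def n_responded(self) -> int:
        return int(np.sum(self.choices >= 0))


def step(state: TaskState, choice: int) -> TrialRecord:
    """Advance the task by one trial given the agent's ``choice``.

    Feedback is Bernoulli(p_win_good) if the good stimulus was chosen, else
    Bernoulli(p_win_bad).  The correct-streak counter increments on a correct
    choice and resets on an incorrect one; if the post-update streak reaches
    the criterion, a hazard draw below ``reversal_hazard`` flips the good
    stimulus and zeroes the streak before the next trial.
    """
    config = state.config
    if state.finished:
        raise SessionExhaustedError(
            f"session already has {config.n_trials} trials"
        )
    if choice not in (0, 1):
        raise InvalidChoiceError(f"choice must be 0 or 1, got {choice!r}")

    correct = choice == state.good_stimulus
    p_win = config.p_win_good if correct else config.p_win_bad
    win = state.rng.random() < p_win
    value = config.win_amount if win else config.loss_amount
    state.cumulative_reward += value

    state.streak = state.streak + 1 if correct else 0
    reversal = False
    if state.streak >= config.reversal_criterion:
        if state.rng.random() < config.reversal_hazard:
            reversal = True

    record = TrialRecord(
        trial_index=state.trial_index,
        choice=choice,
        correct=correct,
        feedback_sign=1 if win else -1,
        feedback_value=value,
        reversal_after=reversal,
        good_stimulus=state.good_stimulus,
    )
    if reversal:
        state.good_stimulus = 1 - state.good_stimulus
        state.streak = 0
    state.trial_index += 1
    return record


def run_policy(
    config: TaskConfig,
    policy: Callable[[TaskState], int],
    seed: int | np.random.SeedSequence,
    subject: str = "sim",
    wave: int = 1,
) -> SessionData:
    """Run ``policy`` (a callable state -> stimulus id) through a full session.

    Identical seed + config + policy yields a bit-identical session.
    """
    state = TaskState.new(config, seed)
    session = SessionData(subject=subject, wave=wave, config=config)
    while not state.finished:
        session.trials.append(step(state, policy(state)))
    return session


def count_reversals(session: SessionData) -> int:
    """Number of contingency changes in the session."""
    return sum(t.reversal_after for t in session.trials)


# ---------------------------------------------------------------------------
# tidy CSV serialization


def sessions_to_frame(sessions: Iterable[SessionData]) -> pd.DataFrame:
    rows = []
    for s in sessions:
        for t in s.trials:
            rows.append(
                {
                    "subject": s.subject,
                    "wave": s.wave,
                    "trial": t.trial_index + 1,  # 1-based in the tidy table
                    "choice": t.choice,
                    "correct": t.correct,
                    "feedback_sign": t.feedback_sign,
                    "feedback_value": t.feedback_value,
                    "reversal_after": t.reversal_after,
                    "good_stimulus": t.good_stimulus,
                }
            )
    return pd.DataFrame(rows)


def write_sessions_csv(sessions: Iterable[SessionData], path: str | Path) -> None:
    sessions_to_frame(sessions).to_csv(path, index=False)


def read_sessions_csv(
    path: str | Path, config: TaskConfig | None = None
) -> list[SessionData]:
    """Read sessions back from the tidy CSV written by ``write_sessions_csv``."""
    df = pd.read_csv(path)
    config = config or TaskConfig()
    sessions = []
    for (subject, wave), grp in df.groupby(["subject", "wave"], sort=False):
        grp = grp.sort_values("trial")
        trials = []
        for _, r in grp.iterrows():
            missing = pd.isna(r["choice"])
            trials.append(
                TrialRecord(
                    trial_index=int(r["trial"]) - 1,
                    choice=None if missing else int(r["choice"]),
                    correct=None if missing else bool(r["correct"]),
                    feedback_sign=None if missing else int(r["feedback_sign"]),
                    feedback_value=None if missing else float(r["feedback_value"]),
                    reversal_after=bool(r["reversal_after"]),
                    good_stimulus=int(r["good_stimulus"]),
                )
            )
        sessions.append(
            SessionData(subject=str(subject), wave=int(wave), config=config, trials=trials)
        )
    return sessions
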