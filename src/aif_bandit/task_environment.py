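"""The contextual two-armed bandit environment (the true generative process).

Each trial has two sequential choices. The first choice is between ``Stay``
(free, uninformative) and ``Cue`` (pay one apple, learn the trial's context).
The second choice is between a ``Safe`` path paying a fixed reward and a
``Risky`` path whose payout distribution depends on a per-trial latent
context. On some trials the first choice is forced to ``Stay`` ("you can't
ask" trials).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Protocol, Sequence
import json

import numpy as np
import pandas as pd

CONTEXT1 = "Context1"
CONTEXT2 = "Context2"
STAY = "Stay"
CUE = "Cue"
SAFE = "Safe"
RISKY = "Risky"
NULL_OBS = "Null"
CUE1_OBS = "Cue1"
CUE2_OBS = "Cue2"

FIRST_ACTIONS = (STAY, CUE)
SECOND_ACTIONS = (SAFE, RISKY)
CONTEXTS = (CONTEXT1, CONTEXT2)


class InvalidActionError(ValueError):
    """Raised when an actor emits an action label the stage does not accept."""


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the generative process.

    Reward distributions follow the administered task: the risky path pays
    [12, 9, 6, 3, 0] apples with probabilities (.55, .25, .10, .05, .05)
    in the high-reward context and the mirrored probabilities in the
    low-reward context.
    """

    n_trials: int = 120
    reward_values: tuple = (0, 3, 6, 9, 12)
    ctx1_probs: tuple = (0.05, 0.05, 0.10, 0.25, 0.55)
    ctx2_probs: tuple = (0.55, 0.25, 0.10, 0.05, 0.05)
    safe_reward: float = 6.0
    cue_cost: float = -1.0
    initial_reward: float = 5.0
    p_context1: float = 0.5
    p_can_ask: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ctx1_probs", "ctx2_probs"):
            p = np.asarray(getattr(self, name), dtype=float)
            if len(p) != len(self.reward_values):
                raise ValueError(f"{name} must match reward_values in length")
            if np.any(p < 0) or np.any(p > 1):
                raise ValueError(f"{name} entries must lie in [0, 1]")
            if abs(p.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name} must sum to 1 within 1e-12")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if np.any(np.diff(self.reward_values) <= 0):
            raise ValueError("reward_values must be strictly increasing")
        for name in ("p_context1", "p_can_ask"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def context_probs(self, context: str) -> np.ndarray:
        if context == CONTEXT1:
            return np.asarray(self.ctx1_probs, dtype=float)
        if context == CONTEXT2:
            return np.asarray(self.ctx2_probs, dtype=float)
        raise ValueError(f"unknown context {context!r}")

    def expected_risky_reward(self, context: str) -> float:
        return float(np.dot(self.context_probs(context), self.reward_values))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TaskConfig":
        d = json.loads(text)
        for key in ("reward_values", "ctx1_probs", "ctx2_probs"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int  # 1-based
    can_ask: bool
    context: str
    first_action: str
    first_observation: str
    second_action: str
    reward: float
    net_trial_reward: float


@dataclass
class BehavioralDataset:
    participant_id: str
    records: list
    cumulative_reward: float = 0.0
    config: TaskConfig = field(default_factory=TaskConfig)

    def __len__(self) -> int:
        return len(self.records)


class Actor(Protocol):
    """Decision callback protocol for :func:`run_session`."""

    def begin_trial(self, trial_index: int, can_ask: bool) -> None: ...

    def first_action(self) -> str: ...

    def observe_first(self, action: str, observation: str, reward: float) -> None: ...

    def second_action(self) -> str: ...

    def observe_second(self, action: str, reward: float) -> None: ...


def sample_context(config: TaskConfig, rng: np.random.Generator) -> str:
    """Draw the trial's latent context (independent across trials)."""
    return CONTEXT1 if rng.random() < config.p_context1 else CONTEXT2


def can_ask_schedule(config: TaskConfig, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli(p_can_ask) flags for each trial; False forces Stay."""
    return rng.random(config.n_trials) < config.p_can_ask


def step_first_choice(context: str, action: str, config: TaskConfig):
    """Resolve the first choice: Cue reveals the context at a cost."""
    if action == CUE:
        obs = CUE1_OBS if context == CONTEXT1 else CUE2_OBS
        return obs, config.cue_cost
    if action == STAY:
        return NULL_OBS, 0.0
    raise InvalidActionError(f"unknown first-stage action {action!r}")


def step_second_choice(
    context: str, action: str, config: TaskConfig, rng: np.random.Generator
) -> float:
    """Resolve the second choice: Safe is deterministic, Risky is a draw."""
    if action == SAFE:
        return float(config.safe_reward)
    if action == RISKY:
        probs = config.context_probs(context)
        idx = rng.choice(len(config.reward_values), p=probs)
        return float(config.reward_values[idx])
    raise InvalidActionError(f"unknown second-stage action {action!r}")


def run_session(
    config: TaskConfig,
    actor: Actor,
    seed: int,
    participant_id: str = "sim",
) -> BehavioralDataset:
    """Run one full session of ``config.n_trials`` trials.

    The environment draws contexts, can-ask flags, and risky outcomes from a
    generator seeded with ``seed``; any stochasticity inside the actor is the
    actor's own responsibility, so identical (seed, actor) pairs give
    identical datasets.
    """
    rng = np.random.default_rng(seed)
    schedule = can_ask_schedule(config, rng)
    records: list[TrialRecord] = []
    total = float(config.initial_reward)
    for t in range(config.n_trials):
        can_ask = bool(schedule[t])
        context = sample_context(config, rng)
        actor.begin_trial(t + 1, can_ask)
        if can_ask:
            a1 = actor.first_action()
            if a1 not in FIRST_ACTIONS:
                raise InvalidActionError(f"unknown first-stage action {a1!r}")
        else:
            a1 = STAY
        obs1, cost = step_first_choice(context, a1, config)
        actor.observe_first(a1, obs1, cost)
        a2 = actor.second_action()
        if a2 not in SECOND_ACTIONS:
            raise InvalidActionError(f"unknown second-stage action {a2!r}")
        reward = step_second_choice(context, a2, config, rng)
        actor.observe_second(a2, reward)
        net = reward + (config.cue_cost if a1 == CUE else 0.0)
        total += net
        records.append(
            TrialRecord(
                trial_index=t + 1,
                can_ask=can_ask,
                context=context,
                first_action=a1,
                first_observation=obs1,
                second_action=a2,
                reward=reward,
                net_trial_reward=net,
            )
        )
    return BehavioralDataset(
        participant_id=participant_id,
        records=records,
        cumulative_reward=total,
        config=config,
    )


class CallableActor:
    """Adapter turning plain functions into the Actor protocol.

    ``first`` and ``second`` receive (trial_index, can_ask, first_observation)
    with ``first_observation`` None at stage 1.
    """

    def __init__(self, first: Callable, second: Callable):
        self._first = first
        self._second = second
        self._trial = 0
        self._can_ask = True
        self._obs1: str | None = None

    def begin_trial(self, trial_index: int, can_ask: bool) -> None:
        self._trial, self._can_ask, self._obs1 = trial_index, can_ask, None

    def first_action(self) -> str:
        return self._first(self._trial, self._can_ask, None)

    def observe_first(self, action: str, observation: str, reward: float) -> None:
        self._obs1 = observation

    def second_action(self) -> str:
        return self._second(self._trial, self._can_ask, self._obs1)

    def observe_second(self, action: str, reward: float) -> None:
        pass


# ---------------------------------------------------------------------------
# Behavioural log I/O
# ---------------------------------------------------------------------------

LOG_COLUMNS = [
    "participant_id",
    "trial",
    "can_ask",
    "context",
    "first_action",
    "first_observation",
    "second_action",
    "reward",
    "net_reward",
]


def dataset_to_frame(dataset: BehavioralDataset) -> pd.DataFrame:
    rows = [
        {
            "participant_id": dataset.participant_id,
            "trial": r.trial_index,
            "can_ask": int(r.can_ask),
            "context": 1 if r.context == CONTEXT1 else 2,
            "first_action": r.first_action,
            "first_observation": r.first_observation,
            "second_action": r.second_action,
            "reward": r.reward,
            "net_reward": r.net_trial_reward,
        }
        for r in dataset.records
    ]
    return pd.DataFrame(rows, columns=LOG_COLUMNS)


def write_log(dataset: BehavioralDataset, path) -> None:
    dataset_to_frame(dataset).to_csv(path, index=False)


def frame_to_dataset(
    frame: pd.DataFrame, config: TaskConfig | None = None
) -> BehavioralDataset:
    config = config or TaskConfig()
    records = []
    for _, row in frame.iterrows():
        records.append(
            TrialRecord(
                trial_index=int(row["trial"]),
                can_ask=bool(int(row["can_ask"])),
                context=CONTEXT1 if int(row["context"]) == 1 else CONTEXT2,
                first_action=str(row["first_action"]),
                first_observation=str(row["first_observation"]),
                second_action=str(row["second_action"]),
                reward=float(row["reward"]),
                net_trial_reward=float(row["net_reward"]),
            )
        )
    total = config.initial_reward + sum(r.net_trial_reward for r in records)
    return BehavioralDataset(
        participant_id=str(frame["participant_id"].iloc[0]),
        records=records,
        cumulative_reward=total,
        config=config,
    )


def read_log(path, config: TaskConfig | None = None) -> list:
    """Read a behavioural CSV, returning one dataset per participant."""
    frame = pd.read_csv(path)
    return [
        frame_to_dataset(g, config)
        for _, g in frame.groupby("participant_id", sort=True)
    ]
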