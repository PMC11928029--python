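"""Model-free and model-based reinforcement learning baselines.

Both models expose the same trial protocol as the active inference process
(begin_trial / first_action_probs / observe_first / second_action_probs /
observe_second), so they are interchangeable in simulation, fitting, and
model comparison.

The model-free learner is delta-rule Q-learning with a softmax choice rule;
its stage-2 values are conditioned on the information shown at the first
result (Cue1, Cue2, or none), since an unconditioned learner could not
express context-dependent behaviour at all. The model-based learner keeps a
running mean-reward estimate of the risky arm per context (initialised at a
free ``prior`` parameter) plus a context-marginal estimate, and plans the
value of asking as the expected best-arm value given the revealed context
minus the cue fee.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .task_environment import (
    CUE,
    CUE1_OBS,
    CUE2_OBS,
    NULL_OBS,
    RISKY,
    SAFE,
    STAY,
    TaskConfig,
)

INFO_CONDITIONS = (CUE1_OBS, CUE2_OBS, NULL_OBS)


@dataclass(frozen=True)
class MFParams:
    alpha_mf: float
    gamma_mf: float

    def __post_init__(self):
        if not 0.0 <= self.alpha_mf <= 1.0:
            raise ValueError("alpha_mf must lie in [0, 1]")
        if self.gamma_mf <= 0:
            raise ValueError("gamma_mf must be > 0")


@dataclass(frozen=True)
class MBParams:
    alpha_mb: float
    gamma_mb: float
    prior_mb: float

    def __post_init__(self):
        if not 0.0 <= self.alpha_mb <= 1.0:
            raise ValueError("alpha_mb must lie in [0, 1]")
        if self.gamma_mb <= 0:
            raise ValueError("gamma_mb must be > 0")


def mf_update(q: float, reward: float, alpha_mf: float) -> float:
    """Delta rule: move the value estimate toward the received reward."""
    if not 0.0 <= alpha_mf <= 1.0:
        raise ValueError("alpha_mf must lie in [0, 1]")
    return q + alpha_mf * (reward - q)


def softmax_choice(values, gamma: float) -> np.ndarray:
    """P(a) proportional to exp(gamma * value_a)."""
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    v = gamma * np.asarray(values, dtype=float)
    v = v - v.max()
    w = np.exp(v)
    return w / w.sum()


class ModelFreeProcess:
    """Q-learning over the two stages of the bandit trial."""

    def __init__(self, params: MFParams, config: TaskConfig | None = None):
        self.params = params
        self.config = config or TaskConfig()
        init = float(self.config.safe_reward)
        self.q1 = {STAY: init, CUE: init}
        self.q2 = {cond: {SAFE: init, RISKY: init} for cond in INFO_CONDITIONS}
        self._a1 = STAY
        self._cond = NULL_OBS

    def begin_trial(self, trial_index: int, can_ask: bool) -> None:
        self._a1 = STAY
        self._cond = NULL_OBS

    def first_action_probs(self) -> dict:
        p = softmax_choice([self.q1[STAY], self.q1[CUE]], self.params.gamma_mf)
        return {STAY: float(p[0]), CUE: float(p[1])}

    def observe_first(self, action: str, observation: str, reward: float) -> None:
        self._a1 = action
        self._cond = observation

    def second_action_probs(self) -> dict:
        q = self.q2[self._cond]
        p = softmax_choice([q[SAFE], q[RISKY]], self.params.gamma_mf)
        return {SAFE: float(p[0]), RISKY: float(p[1])}

    def observe_second(self, action: str, reward: float) -> None:
        a = self.params.alpha_mf
        self.q2[self._cond][action] = mf_update(self.q2[self._cond][action], reward, a)
        net = reward + (self.config.cue_cost if self._a1 == CUE else 0.0)
        self.q1[self._a1] = mf_update(self.q1[self._a1], net, a)


def mb_update(estimate: float, reward: float, alpha_mb: float) -> float:
    """Move a per-context mean-reward estimate toward the received reward."""
    if not 0.0 <= alpha_mb <= 1.0:
        raise ValueError("alpha_mb must lie in [0, 1]")
    return estimate + alpha_mb * (reward - estimate)


def mb_plan(
    estimates: dict, params: MBParams, config: TaskConfig
) -> tuple[dict, dict]:
    """Choice probabilities of the mean-estimate planner.

    Stage-2 values are (safe_reward, risky estimate) given the information
    condition; the stage-1 value of Cue is the expected best-arm value over
    contexts plus the cue fee, and of Stay the best-arm value under the
    context-marginal estimate.
    """
    safe = float(config.safe_reward)
    p1 = config.p_context1
    v_cue = (
        p1 * max(safe, estimates[CUE1_OBS])
        + (1.0 - p1) * max(safe, estimates[CUE2_OBS])
        + config.cue_cost
    )
    v_stay = max(safe, estimates[NULL_OBS])
    p_first = softmax_choice([v_stay, v_cue], params.gamma_mb)
    first = {STAY: float(p_first[0]), CUE: float(p_first[1])}
    second = {}
    for cond in INFO_CONDITIONS:
        p = softmax_choice([safe, estimates[cond]], params.gamma_mb)
        second[cond] = {SAFE: float(p[0]), RISKY: float(p[1])}
    return first, second


class ModelBasedProcess:
    """Planner over per-context risky-arm mean estimates."""

    def __init__(self, params: MBParams, config: TaskConfig | None = None):
        self.params = params
        self.config = config or TaskConfig()
        self.estimates = {cond: float(params.prior_mb) for cond in INFO_CONDITIONS}
        self._cond = NULL_OBS

    def begin_trial(self, trial_index: int, can_ask: bool) -> None:
        self._cond = NULL_OBS

    def first_action_probs(self) -> dict:
        first, _ = mb_plan(self.estimates, self.params, self.config)
        return first

    def observe_first(self, action: str, observation: str, reward: float) -> None:
        self._cond = observation

    def second_action_probs(self) -> dict:
        _, second = mb_plan(self.estimates, self.params, self.config)
        return second[self._cond]

    def observe_second(self, action: str, reward: float) -> None:
        if action == RISKY:
            self.estimates[self._cond] = mb_update(
                self.estimates[self._cond], reward, self.params.alpha_mb
            )


class ProcessActor:
    """Actor adapter sampling from any choice process's probabilities."""

    def __init__(self, process, rng: np.random.Generator):
        self.process = process
        self.rng = rng

    def begin_trial(self, trial_index: int, can_ask: bool) -> None:
        self.process.begin_trial(trial_index, can_ask)

    def first_action(self) -> str:
        probs = self.process.first_action_probs()
        return CUE if self.rng.random() < probs[CUE] else STAY

    def observe_first(self, action: str, observation: str, reward: float) -> None:
        self.process.observe_first(action, observation, reward)

    def second_action(self) -> str:
        probs = self.process.second_action_probs()
        return RISKY if self.rng.random() < probs[RISKY] else SAFE

    def observe_second(self, action: str, reward: float) -> None:
        self.process.observe_second(action, reward)
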