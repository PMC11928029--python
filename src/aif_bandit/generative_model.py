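"""The agent's internal POMDP model of the bandit task.

Hidden states factorise as {stage} x {context}: the within-trial stage is one
of Start, Cued, ChoseSafe, ChoseRisky, and the context is Context1 or
Context2, giving 8 hidden states. Observations are Null, the two cues, and
the five reward levels (8 in total). The likelihood is parameterised by
Dirichlet concentrations: deterministic stage/cue/safe mappings carry a unit
concentration on the true cell, while the two ChoseRisky columns start with a
flat concentration ``prior`` over the five reward rows and are learned from
experience by adding learning-rate-scaled outcome/state outer products.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import json

import numpy as np

from .task_environment import (
    CONTEXT1,
    CONTEXT2,
    CUE,
    RISKY,
    SAFE,
    STAY,
    TaskConfig,
)

LOG_FLOOR = 1e-16

HIDDEN_STATES = (
    "Start-Context1",
    "Start-Context2",
    "Cued-Context1",
    "Cued-Context2",
    "ChoseSafe-Context1",
    "ChoseSafe-Context2",
    "ChoseRisky-Context1",
    "ChoseRisky-Context2",
)
OBSERVATIONS = ("Null", "Cue1", "Cue2", "R0", "R3", "R6", "R9", "R12")
ACTIONS = (STAY, CUE, SAFE, RISKY)
# Policy order: (Cue,Safe), (Cue,Risky), (Stay,Safe), (Stay,Risky)
POLICIES = ((CUE, SAFE), (CUE, RISKY), (STAY, SAFE), (STAY, RISKY))

N_STATES = len(HIDDEN_STATES)
N_OBS = len(OBSERVATIONS)

_CONTEXT_OF_STATE = (0, 1, 0, 1, 0, 1, 0, 1)
START_STATES = (0, 1)
CUED_STATES = (2, 3)
SAFE_STATES = (4, 5)
RISKY_STATES = (6, 7)
REWARD_OBS = (3, 4, 5, 6, 7)  # R0, R3, R6, R9, R12
OBS_INDEX = {name: i for i, name in enumerate(OBSERVATIONS)}


class InvalidParameterError(ValueError):
    pass


class DegenerateColumnError(ValueError):
    pass


@dataclass
class GenerativeModel:
    """Container for the agent's model parameters and coefficients.

    ``AL``, ``AI`` and ``EX`` scale the value of reducing novelty, the value
    of reducing variability, and extrinsic value inside expected free energy;
    ``alpha`` is the Dirichlet learning rate; ``gamma`` the policy precision.
    ``logC`` holds the log prior preference per observation, set to
    ``preference_scale`` nats per apple of each observation's monetary value.
    """

    a: np.ndarray
    B: dict
    logC: np.ndarray
    d: np.ndarray
    AL: float = 1.0
    AI: float = 1.0
    EX: float = 1.0
    alpha: float = 1.0
    gamma: float = 1.0
    beta: float = 1.0
    preference_scale: float = 0.25
    learnable: np.ndarray = field(default=None)
    reward_values: tuple = (0, 3, 6, 9, 12)

    @property
    def A(self) -> np.ndarray:
        """Current likelihood: the Dirichlet mean of the concentrations."""
        return normalize_likelihood(self.a)

    def copy(self) -> "GenerativeModel":
        return replace(
            self,
            a=self.a.copy(),
            B={k: v for k, v in self.B.items()},
            logC=self.logC.copy(),
            d=self.d.copy(),
            learnable=None if self.learnable is None else self.learnable.copy(),
        )

    def context_belief(self, qs: np.ndarray) -> np.ndarray:
        """Marginalize a state distribution onto the two contexts."""
        ctx = np.asarray(_CONTEXT_OF_STATE)
        return np.array([qs[ctx == 0].sum(), qs[ctx == 1].sum()])

    def to_json(self) -> str:
        payload = {
            "hidden_states": HIDDEN_STATES,
            "observations": OBSERVATIONS,
            "a": self.a.tolist(),
            "B": {k: v.tolist() for k, v in self.B.items()},
            "logC": self.logC.tolist(),
            "d": self.d.tolist(),
            "AL": self.AL,
            "AI": self.AI,
            "EX": self.EX,
            "alpha": self.alpha,
            "gamma": self.gamma,
            "beta": self.beta,
            "preference_scale": self.preference_scale,
            "reward_values": list(self.reward_values),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GenerativeModel":
        p = json.loads(text)
        model = cls(
            a=np.asarray(p["a"], dtype=float),
            B={k: np.asarray(v, dtype=float) for k, v in p["B"].items()},
            logC=np.asarray(p["logC"], dtype=float),
            d=np.asarray(p["d"], dtype=float),
            AL=p["AL"],
            AI=p["AI"],
            EX=p["EX"],
            alpha=p["alpha"],
            gamma=p["gamma"],
            beta=p.get("beta", 1.0),
            preference_scale=p.get("preference_scale", 0.25),
            reward_values=tuple(p.get("reward_values", (0, 3, 6, 9, 12))),
        )
        model.learnable = _learnable_mask()
        return model


def _transition_matrices() -> dict:
    """Per-action column-stochastic transitions; context always persists."""
    eye = np.eye(N_STATES)
    B = {STAY: eye.copy()}
    b_cue = eye.copy()
    for c in (0, 1):
        b_cue[:, START_STATES[c]] = 0.0
        b_cue[CUED_STATES[c], START_STATES[c]] = 1.0
    B[CUE] = b_cue
    b_safe = eye.copy()
    b_risky = eye.copy()
    for c in (0, 1):
        for src in (START_STATES[c], CUED_STATES[c]):
            b_safe[:, src] = 0.0
            b_safe[SAFE_STATES[c], src] = 1.0
            b_risky[:, src] = 0.0
            b_risky[RISKY_STATES[c], src] = 1.0
    B[SAFE] = b_safe
    B[RISKY] = b_risky
    return B


def _learnable_mask() -> np.ndarray:
    mask = np.zeros((N_OBS, N_STATES), dtype=bool)
    for s in RISKY_STATES:
        for o in REWARD_OBS:
            mask[o, s] = True
    return mask


def init_model(
    prior: float = 0.25,
    AL: float = 1.0,
    AI: float = 1.0,
    EX: float = 1.0,
    alpha: float = 1.0,
    gamma: float = 1.0,
    config: TaskConfig | None = None,
    preference_scale: float = 0.25,
    merge_null_observation: bool = False,
) -> GenerativeModel:
    """Build the task model with flat concentration ``prior`` on risky cells.

    The default ``prior`` of 0.25 is a sparse Dirichlet prior over the five
    reward levels: the whole risky column carries 1.25 pseudo-counts, about
    one observation's worth of prior mass, so the initial risky estimate sits
    at the grid midpoint (6 apples) but yields quickly to evidence.

    ``merge_null_observation`` folds the Null row into the zero-reward row,
    reproducing a 7-observation variant of the likelihood; the default keeps
    Null as its own row so every stage is observable.
    """
    if prior <= 0:
        raise InvalidParameterError("prior must be > 0")
    if alpha < 0:
        raise InvalidParameterError("alpha must be >= 0")
    if gamma <= 0:
        raise InvalidParameterError("gamma must be > 0")
    for name, v in (("AL", AL), ("AI", AI), ("EX", EX)):
        if v < 0:
            raise InvalidParameterError(f"{name} must be >= 0")
    config = config or TaskConfig()

    a = np.full((N_OBS, N_STATES), LOG_FLOOR)
    null_row = OBS_INDEX["R0"] if merge_null_observation else OBS_INDEX["Null"]
    a[null_row, START_STATES[0]] = 1.0
    a[null_row, START_STATES[1]] = 1.0
    a[OBS_INDEX["Cue1"], CUED_STATES[0]] = 1.0
    a[OBS_INDEX["Cue2"], CUED_STATES[1]] = 1.0
    safe_obs = OBS_INDEX[f"R{int(config.safe_reward)}"]
    a[safe_obs, SAFE_STATES[0]] = 1.0
    a[safe_obs, SAFE_STATES[1]] = 1.0
    for s in RISKY_STATES:
        a[REWARD_OBS, s] = prior

    logC = np.zeros(N_OBS)
    logC[OBS_INDEX["Cue1"]] = config.cue_cost
    logC[OBS_INDEX["Cue2"]] = config.cue_cost
    for o, r in zip(REWARD_OBS, config.reward_values):
        logC[o] += r  # += so a merged Null/R0 row keeps the R0 value
    logC = logC * preference_scale

    d = np.zeros(N_STATES)
    d[START_STATES[0]] = config.p_context1
    d[START_STATES[1]] = 1.0 - config.p_context1

    model = GenerativeModel(
        a=a,
        B=_transition_matrices(),
        logC=logC,
        d=d,
        AL=AL,
        AI=AI,
        EX=EX,
        alpha=alpha,
        gamma=gamma,
        preference_scale=preference_scale,
        reward_values=tuple(config.reward_values),
    )
    model.learnable = _learnable_mask()
    return model


def normalize_likelihood(a: np.ndarray) -> np.ndarray:
    """Column-wise Dirichlet mean of a concentration array."""
    a = np.asarray(a, dtype=float)
    sums = a.sum(axis=0)
    if np.any(sums <= 0):
        raise DegenerateColumnError("every column must have positive total")
    return a / sums


def update_concentrations(
    a: np.ndarray,
    observation: np.ndarray,
    state_posterior: np.ndarray,
    alpha: float,
) -> np.ndarray:
    """Dirichlet learning step: a' = a + alpha * (o outer q(s))."""
    if alpha < 0:
        raise InvalidParameterError("alpha must be >= 0")
    observation = np.asarray(observation, dtype=float)
    state_posterior = np.asarray(state_posterior, dtype=float)
    return a + alpha * np.outer(observation, state_posterior)


def expected_risky_reward(model: GenerativeModel, context: str) -> float:
    """Mean payout the agent currently attributes to the risky arm."""
    if context not in (CONTEXT1, CONTEXT2):
        raise ValueError(f"unknown context {context!r}")
    col = RISKY_STATES[0] if context == CONTEXT1 else RISKY_STATES[1]
    probs = model.A[REWARD_OBS, col]
    probs = probs / probs.sum()
    return float(np.dot(probs, model.reward_values))
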