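"""Running the active inference agent through task sessions.

The :class:`ActiveInferenceProcess` steps a generative model through one
trial at a time and exposes the stage-wise action probabilities. It is driven
in two ways: sampling its own actions inside :func:`run_agent` (simulation),
or replaying a recorded dataset (teacher forcing) during model fitting. Both
paths share the same belief updates, expected-free-energy evaluations, and
Dirichlet learning, so fitted parameters mean the same thing as simulated
ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import generative_model as gm
from .generative_model import (
    GenerativeModel,
    OBS_INDEX,
    POLICIES,
    expected_risky_reward,
    init_model,
    update_concentrations,
)
from .inference_engine import (
    EFEDecomposition,
    _dirichlet_unit_kl,
    action_marginal,
    efe_step,
    policy_efe,
    policy_posterior,
)
from .task_environment import (
    CONTEXT1,
    CONTEXT2,
    CUE,
    CUE1_OBS,
    CUE2_OBS,
    NULL_OBS,
    RISKY,
    SAFE,
    STAY,
    BehavioralDataset,
    TaskConfig,
    run_session,
)


def _reward_obs_label(reward: float) -> str:
    return f"R{int(round(reward))}"


def prediction_error(
    reward: float,
    model: GenerativeModel,
    chosen_action: str,
    context_belief: np.ndarray,
) -> float:
    """|reward - E[reward | action, beliefs]| under the current likelihood."""
    return abs(signed_prediction_error(reward, model, chosen_action, context_belief))


def signed_prediction_error(
    reward: float,
    model: GenerativeModel,
    chosen_action: str,
    context_belief: np.ndarray,
) -> float:
    if chosen_action == SAFE:
        col = gm.SAFE_STATES[0]
        probs = model.A[gm.REWARD_OBS, col]
        expected = float(np.dot(probs / probs.sum(), model.reward_values))
    elif chosen_action == RISKY:
        expected = context_belief[0] * expected_risky_reward(
            model, CONTEXT1
        ) + context_belief[1] * expected_risky_reward(model, CONTEXT2)
    else:
        raise ValueError(f"no reward expectation for action {chosen_action!r}")
    return float(reward - expected)


def _combine(decomps, weights) -> EFEDecomposition:
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    return EFEDecomposition(
        raw_novelty=float(sum(wi * d.raw_novelty for wi, d in zip(w, decomps))),
        raw_salience=float(sum(wi * d.raw_salience for wi, d in zip(w, decomps))),
        raw_extrinsic=float(sum(wi * d.raw_extrinsic for wi, d in zip(w, decomps))),
        AL=decomps[0].AL,
        AI=decomps[0].AI,
        EX=decomps[0].EX,
    )


@dataclass
class TrialComputation:
    """Model quantities recorded for one trial (regressor source material)."""

    trial_index: int
    can_ask: bool
    first_action: str = STAY
    first_observation: str = NULL_OBS
    second_action: str = SAFE
    reward: float = 0.0
    p_first: dict = field(default_factory=dict)
    p_second: dict = field(default_factory=dict)
    q_policy: np.ndarray | None = None
    G_per_policy: np.ndarray | None = None
    choice1: EFEDecomposition | None = None
    choice2: EFEDecomposition | None = None
    reducing_variability_raw: float = 0.0  # realised state info gain, negated
    reducing_novelty_raw: float = 0.0  # realised parameter info gain, negated
    prediction_error: float = 0.0
    signed_prediction_error: float = 0.0
    est_risky_ctx1: float = 0.0
    est_risky_ctx2: float = 0.0
    policy_entropy: float = 0.0


class ActiveInferenceProcess:
    """One agent's trial-by-trial belief updating and action evaluation."""

    def __init__(self, model: GenerativeModel, exact_novelty: bool = True):
        self.model = model.copy()
        self.exact_novelty = exact_novelty
        self.qs = model.d.copy()
        self._a_version = 0
        self._stage1_cache: tuple | None = None
        self._stage2_cache: dict = {}
        self.current: TrialComputation | None = None

    # -- caching helpers ---------------------------------------------------

    def _belief_key(self):
        b = self.model.context_belief(self.qs)
        if abs(b[0] - 1.0) < 1e-12:
            return "c1"
        if abs(b[1] - 1.0) < 1e-12:
            return "c2"
        d0 = self.model.d[gm.START_STATES[0]]
        if abs(b[0] - d0) < 1e-12:
            return "d"
        return None

    def _stage1(self):
        if self._stage1_cache is None or self._stage1_cache[0] != self._a_version:
            decomps = policy_efe(self.model, self.model.d, self.exact_novelty)
            G = np.array([d.total_G for d in decomps])
            q_pi = policy_posterior(G, self.model.gamma)
            self._stage1_cache = (self._a_version, decomps, G, q_pi)
        return self._stage1_cache[1:]

    def _stage2_efe(self, action: str) -> EFEDecomposition:
        key = self._belief_key()
        if key is not None:
            cached = self._stage2_cache.get((self._a_version, key, action))
            if cached is not None:
                return cached
        dec = efe_step(self.model, self.qs, action, exact_novelty=self.exact_novelty)
        if key is not None:
            self._stage2_cache[(self._a_version, key, action)] = dec
        return dec

    # -- trial protocol ----------------------------------------------------

    def begin_trial(self, trial_index: int, can_ask: bool) -> None:
        self.qs = self.model.d.copy()
        self.current = TrialComputation(trial_index=trial_index, can_ask=can_ask)

    def first_action_probs(self) -> dict:
        decomps, G, q_pi = self._stage1()
        self.current.q_policy = q_pi
        self.current.G_per_policy = G
        self.current.policy_entropy = float(
            -np.sum(q_pi * np.log(np.maximum(q_pi, gm.LOG_FLOOR)))
        )
        return action_marginal(q_pi, stage=1)

    def observe_first(self, action: str, observation: str, reward: float) -> None:
        cur = self.current
        cur.first_action = action
        cur.first_observation = observation
        decomps, G, q_pi = self._stage1()
        cur.q_policy = q_pi
        cur.G_per_policy = G
        idx = [i for i, pol in enumerate(POLICIES) if pol[0] == action]
        cur.choice1 = _combine([decomps[i] for i in idx], q_pi[idx])
        # belief update with the realised first observation
        q_pred = self.model.B[action] @ self.qs
        like = self.model.A[OBS_INDEX[observation], :]
        q_post = like * q_pred
        q_post = q_post / q_post.sum()
        # realised state information gain (negated), the trial's
        # "reducing variability" quantity at the first result
        mask = q_post > 0
        ig = float(
            np.sum(
                q_post[mask]
                * (
                    np.log(q_post[mask])
                    - np.log(np.maximum(q_pred[mask], gm.LOG_FLOOR))
                )
            )
        )
        cur.reducing_variability_raw = -ig
        self.qs = q_post

    def second_action_probs(self) -> dict:
        g2 = np.array([self._stage2_efe(a).total_G for a in (SAFE, RISKY)])
        p = policy_posterior(g2, self.model.gamma)
        return {SAFE: float(p[0]), RISKY: float(p[1])}

    def observe_second(self, action: str, reward: float) -> None:
        cur = self.current
        cur.second_action = action
        cur.reward = reward
        cur.choice2 = self._stage2_efe(action)
        belief = self.model.context_belief(self.qs)
        cur.signed_prediction_error = signed_prediction_error(
            reward, self.model, action, belief
        )
        cur.prediction_error = abs(cur.signed_prediction_error)
        obs_label = _reward_obs_label(reward)
        o_idx = OBS_INDEX[obs_label]
        q_pred = self.model.B[action] @ self.qs
        like = self.model.A[o_idx, :]
        q_post = like * q_pred
        q_post = q_post / q_post.sum()
        # realised parameter information gain (negated): expected Dirichlet
        # KL of the unit update actually received, under the state posterior
        kl = _dirichlet_unit_kl(self.model.a)[o_idx, :]
        cur.reducing_novelty_raw = -float(np.dot(q_post, kl))
        # Dirichlet learning
        obs_onehot = np.zeros(gm.N_OBS)
        obs_onehot[o_idx] = 1.0
        self.model.a = update_concentrations(
            self.model.a, obs_onehot, q_post, self.model.alpha
        )
        if self.model.alpha > 0:
            self._a_version += 1
        self.qs = q_post
        cur.est_risky_ctx1 = expected_risky_reward(self.model, CONTEXT1)
        cur.est_risky_ctx2 = expected_risky_reward(self.model, CONTEXT2)


class AIFActor:
    """Actor adapter: samples actions from the process's marginals."""

    def __init__(self, process: ActiveInferenceProcess, rng: np.random.Generator):
        self.process = process
        self.rng = rng
        self.trace: list[TrialComputation] = []

    def begin_trial(self, trial_index: int, can_ask: bool) -> None:
        self.process.begin_trial(trial_index, can_ask)

    def first_action(self) -> str:
        probs = self.process.first_action_probs()
        self.process.current.p_first = probs
        return CUE if self.rng.random() < probs[CUE] else STAY

    def observe_first(self, action: str, observation: str, reward: float) -> None:
        self.process.observe_first(action, observation, reward)

    def second_action(self) -> str:
        probs = self.process.second_action_probs()
        self.process.current.p_second = probs
        return RISKY if self.rng.random() < probs[RISKY] else SAFE

    def observe_second(self, action: str, reward: float) -> None:
        self.process.observe_second(action, reward)
        self.trace.append(self.process.current)


@dataclass
class SimulationTrace:
    """Per-trial record of the agent's beliefs, values, and outcomes."""

    dataset: BehavioralDataset
    computations: list
    model: GenerativeModel

    def __len__(self) -> int:
        return len(self.computations)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.computations:
            rows.append(
                {
                    "trial": c.trial_index,
                    "can_ask": int(c.can_ask),
                    "first_action": c.first_action,
                    "first_observation": c.first_observation,
                    "second_action": c.second_action,
                    "reward": c.reward,
                    "p_cue": c.p_first.get(CUE, np.nan),
                    "p_risky": c.p_second.get(RISKY, np.nan),
                    "G_choice1": c.choice1.total_G,
                    "G_choice2": c.choice2.total_G,
                    "novelty_value_choice2": c.choice2.novelty_value,
                    "variability_value_choice1": c.choice1.variability_value,
                    "extrinsic_value_choice1": c.choice1.extrinsic_value,
                    "extrinsic_value_choice2": c.choice2.extrinsic_value,
                    "reducing_variability": c.reducing_variability_raw,
                    "reducing_novelty": c.reducing_novelty_raw,
                    "prediction_error": c.prediction_error,
                    "signed_prediction_error": c.signed_prediction_error,
                    "est_risky_ctx1": c.est_risky_ctx1,
                    "est_risky_ctx2": c.est_risky_ctx2,
                    "policy_entropy": c.policy_entropy,
                }
            )
        return pd.DataFrame(rows)


def build_model(params: dict, config: TaskConfig | None = None) -> GenerativeModel:
    """Instantiate the generative model from a free-parameter dict."""
    return init_model(
        prior=params.get("prior", 0.25),
        AL=params.get("AL", 1.0),
        AI=params.get("AI", 1.0),
        EX=params.get("EX", 1.0),
        alpha=params.get("alpha", 1.0),
        gamma=params.get("gamma", 1.0),
        config=config,
        preference_scale=params.get("preference_scale", 0.25),
    )


def run_agent(
    model_params: dict | GenerativeModel,
    config: TaskConfig | None = None,
    seed: int = 0,
    participant_id: str = "aif-sim",
    exact_novelty: bool = True,
) -> SimulationTrace:
    """Simulate an active inference agent through one session.

    Per trial: beliefs reset to the context prior, expected free energy is
    evaluated for all four policies, the first action is sampled from the
    policy-posterior marginal (forced to Stay on no-ask trials), beliefs are
    updated with the outcome, the second stage is re-evaluated and sampled,
    and the reward drives Dirichlet learning of the risky columns.
    """
    config = config or TaskConfig()
    model = (
        model_params.copy()
        if isinstance(model_params, GenerativeModel)
        else build_model(model_params, config)
    )
    process = ActiveInferenceProcess(model, exact_novelty=exact_novelty)
    actor_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    actor = AIFActor(process, actor_rng)
    dataset = run_session(config, actor, seed=seed, participant_id=participant_id)
    return SimulationTrace(dataset=dataset, computations=actor.trace, model=process.model)


def summarize_policy_blocks(trace: SimulationTrace, block: int) -> pd.DataFrame:
    """Per-block action frequencies (Cue among free trials; Risky by context
    information shown at the second choice)."""
    comps = trace.computations
    rows = []
    for start in range(0, len(comps), block):
        chunk = comps[start : start + block]
        free = [c for c in chunk if c.can_ask]
        cue_freq = (
            float(np.mean([c.first_action == CUE for c in free])) if free else np.nan
        )

        def _risky_freq(obs_label):
            sel = [c for c in chunk if c.first_observation == obs_label]
            if not sel:
                return np.nan
            return float(np.mean([c.second_action == RISKY for c in sel]))

        rows.append(
            {
                "block_start": start + 1,
                "n_trials": len(chunk),
                "cue_freq": cue_freq,
                "risky_given_cue1": _risky_freq(CUE1_OBS),
                "risky_given_cue2": _risky_freq(CUE2_OBS),
                "risky_given_no_cue": _risky_freq(NULL_OBS),
            }
        )
    return pd.DataFrame(rows)
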