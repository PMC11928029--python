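"""Belief updating and policy evaluation.

State inference is exact Bayes on the 8-state space (the variational minimum
for this model family); the variational free energy functional is kept as a
verifiable quantity. Expected free energy is decomposed into the value of
reducing novelty (expected information gain about the likelihood Dirichlet
parameters), the value of reducing variability (expected information gain
about hidden states, a.k.a. salience), and extrinsic value (expected log
prior preference):

    G = AL * (-IG_parameters) + AI * (-IG_states) - EX * E[logC(o)]

so lower G marks more valuable policies and both raw epistemic terms are
non-positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln, xlogy

from .generative_model import (
    LOG_FLOOR,
    N_STATES,
    POLICIES,
    GenerativeModel,
    OBS_INDEX,
)
from .task_environment import CUE, RISKY, SAFE, STAY

_EVIDENCE_TINY = 1e-13


class ImpossibleObservationError(ValueError):
    pass


class DegeneratePolicyError(ValueError):
    pass


@dataclass
class EFEDecomposition:
    """Per-policy, per-step expected free energy and its three components."""

    raw_novelty: float
    raw_salience: float
    raw_extrinsic: float
    AL: float
    AI: float
    EX: float

    @property
    def novelty_value(self) -> float:
        return self.AL * self.raw_novelty

    @property
    def variability_value(self) -> float:
        return self.AI * self.raw_salience

    @property
    def extrinsic_value(self) -> float:
        return self.EX * self.raw_extrinsic

    @property
    def total_G(self) -> float:
        return self.novelty_value + self.variability_value - self.extrinsic_value

    def __add__(self, other: "EFEDecomposition") -> "EFEDecomposition":
        if (self.AL, self.AI, self.EX) != (other.AL, other.AI, other.EX):
            raise ValueError("cannot add decompositions with different coefficients")
        return EFEDecomposition(
            raw_novelty=self.raw_novelty + other.raw_novelty,
            raw_salience=self.raw_salience + other.raw_salience,
            raw_extrinsic=self.raw_extrinsic + other.raw_extrinsic,
            AL=self.AL,
            AI=self.AI,
            EX=self.EX,
        )


@dataclass
class BeliefState:
    """Posterior beliefs carried across a trial."""

    qs: np.ndarray
    q_policy: np.ndarray = field(default_factory=lambda: np.full(len(POLICIES), 0.25))
    gamma: float = 1.0


def _safe_log(x: np.ndarray) -> np.ndarray:
    return np.log(np.maximum(x, LOG_FLOOR))


def infer_states(
    model: GenerativeModel,
    observations,
    actions=(),
) -> np.ndarray:
    """Exact posterior over hidden states given an observation history.

    ``observations`` are observation labels, the first received in the
    initial (Start) state and each later one after the corresponding entry of
    ``actions``; ``len(observations) == len(actions) + 1``.
    """
    if len(observations) != len(actions) + 1:
        raise ValueError("need exactly one more observation than actions")
    A = model.A
    p = model.d.copy()
    for k, obs in enumerate(observations):
        if k > 0:
            p = model.B[actions[k - 1]] @ p
        like = A[OBS_INDEX[obs], :]
        p = like * p
        z = p.sum()
        if z < _EVIDENCE_TINY:
            raise ImpossibleObservationError(
                f"observation {obs!r} has (near-)zero likelihood under every state"
            )
        p = p / z
    return p


def variational_free_energy(
    q: np.ndarray, prior: np.ndarray, likelihood: np.ndarray
) -> float:
    """F = KL(q || prior) - E_q[ln P(o | s)] for one observed outcome.

    ``likelihood`` is the vector P(o|s) of the observed outcome across
    states. At the exact posterior this equals the negative log evidence
    -ln P(o); for any other q it upper-bounds it.
    """
    q = np.asarray(q, dtype=float)
    if abs(q.sum() - 1.0) > 1e-8:
        raise ValueError("q must sum to 1")
    kl = float(np.sum(xlogy(q, np.maximum(q, LOG_FLOOR)) - q * _safe_log(prior)))
    accuracy = float(np.sum(q * _safe_log(likelihood)))
    return kl - accuracy


def _dirichlet_unit_kl(a: np.ndarray) -> np.ndarray:
    """KL( Dir(a + e_o) || Dir(a) ) for every cell (o, s) of ``a``.

    Closed form for a unit count added to entry o of column s:
    ln a0 - ln a_os + psi(a_os + 1) - psi(a0 + 1), with a0 the column total.
    """
    a0 = a.sum(axis=0, keepdims=True)
    return np.log(a0) - np.log(a) + digamma(a + 1.0) - digamma(a0 + 1.0)


def _dirichlet_kl_general(a_new: np.ndarray, a_old: np.ndarray) -> float:
    """KL between two Dirichlet distributions over one column (oracle use)."""
    s_new, s_old = a_new.sum(), a_old.sum()
    return float(
        gammaln(s_new)
        - gammaln(s_old)
        - np.sum(gammaln(a_new) - gammaln(a_old))
        + np.sum((a_new - a_old) * (digamma(a_new) - digamma(s_new)))
    )


def efe_step(
    model: GenerativeModel,
    qs: np.ndarray,
    action: str,
    exact_novelty: bool = True,
) -> EFEDecomposition:
    """One-step-ahead expected free energy after taking ``action`` from ``qs``.

    The predictive state distribution is the transition applied to the
    current belief; epistemic terms are evaluated exactly by enumerating the
    8 possible observations. ``exact_novelty=False`` switches to the common
    linearised Dirichlet information-gain approximation (for cross-checks).
    """
    qs_next = model.B[action] @ qs
    A = model.A
    qo = A @ qs_next  # predictive observation distribution

    # salience: negated mutual information between next states and outcomes
    joint = A * qs_next[np.newaxis, :]  # P(o, s)
    # MI = sum_{o,s} P(o,s) ln( P(o,s) / (P(o) P(s)) )
    denom = qo[:, np.newaxis] * qs_next[np.newaxis, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(joint > 0, joint / np.maximum(denom, LOG_FLOOR), 1.0)
    mi = float(np.sum(xlogy(joint, ratio)))
    raw_salience = -max(mi, 0.0)

    # novelty: negated expected KL from posterior to prior Dirichlet over a
    if exact_novelty:
        kl = _dirichlet_unit_kl(model.a)
    else:
        # linearised form, restricted to learnable cells to avoid the
        # floor concentrations blowing up the 1/a term
        a0 = model.a.sum(axis=0, keepdims=True)
        kl = 0.5 * (1.0 / model.a - 1.0 / a0)
        if model.learnable is not None:
            kl = np.where(model.learnable, kl, 0.0)
    raw_novelty = -float(np.sum(joint * kl))

    raw_extrinsic = float(qo @ model.logC)
    return EFEDecomposition(
        raw_novelty=raw_novelty,
        raw_salience=raw_salience,
        raw_extrinsic=raw_extrinsic,
        AL=model.AL,
        AI=model.AI,
        EX=model.EX,
    )


def expected_free_energy(
    model: GenerativeModel,
    belief: BeliefState | np.ndarray,
    policy,
    tau: int | None = None,
    exact_novelty: bool = True,
) -> EFEDecomposition:
    """Expected free energy of a policy from the current belief.

    With ``tau`` given (1 or 2), returns the single-step decomposition at
    that within-trial step; otherwise the sum over both steps,
    G(pi) = sum_tau G(pi, tau).
    """
    qs = belief.qs if isinstance(belief, BeliefState) else np.asarray(belief)
    steps = []
    q = qs
    for step_idx, action in enumerate(policy, start=1):
        dec = efe_step(model, q, action, exact_novelty=exact_novelty)
        steps.append(dec)
        q = model.B[action] @ q
    if tau is not None:
        return steps[tau - 1]
    total = steps[0]
    for dec in steps[1:]:
        total = total + dec
    return total


def policy_efe(
    model: GenerativeModel, qs: np.ndarray, exact_novelty: bool = True
) -> list:
    """Two-step EFE decomposition for each of the four policies."""
    return [
        expected_free_energy(model, qs, pol, exact_novelty=exact_novelty)
        for pol in POLICIES
    ]


def policy_posterior(G, gamma: float) -> np.ndarray:
    """Q(pi) = softmax(-gamma * G): lower expected free energy, higher mass."""
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    g = np.asarray(G, dtype=float)
    z = -gamma * g
    z = z - z.max()
    w = np.exp(z)
    return w / w.sum()


def action_marginal(
    q_policy: np.ndarray,
    stage: int,
    realized_first: str | None = None,
) -> dict:
    """Marginal action probabilities implied by a policy posterior.

    At stage 1 the marginal sums policy mass by first action; at stage 2,
    policies inconsistent with the realised first action are zeroed and the
    remainder renormalised.
    """
    q = np.asarray(q_policy, dtype=float)
    if stage == 1:
        return {
            a1: float(sum(q[i] for i, pol in enumerate(POLICIES) if pol[0] == a1))
            for a1 in (STAY, CUE)
        }
    if stage == 2:
        if realized_first is None:
            raise ValueError("stage 2 marginal requires the realised first action")
        mask = np.array([pol[0] == realized_first for pol in POLICIES])
        z = float(q[mask].sum())
        if z <= 0:
            raise DegeneratePolicyError(
                "no posterior mass on policies consistent with the first action"
            )
        return {
            a2: float(
                sum(
                    q[i]
                    for i, pol in enumerate(POLICIES)
                    if mask[i] and pol[1] == a2
                )
            )
            / z
            for a2 in (SAFE, RISKY)
        }
    raise ValueError("stage must be 1 or 2")
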