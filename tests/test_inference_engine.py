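"""Unit tests for belief updating and expected free energy."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from aif_bandit.generative_model import (
    N_OBS,
    N_STATES,
    OBS_INDEX,
    POLICIES,
    REWARD_OBS,
    RISKY_STATES,
    init_model,
)
from aif_bandit.inference_engine import (
    DegeneratePolicyError,
    EFEDecomposition,
    ImpossibleObservationError,
    _dirichlet_kl_general,
    _dirichlet_unit_kl,
    action_marginal,
    efe_step,
    expected_free_energy,
    infer_states,
    policy_efe,
    policy_posterior,
    variational_free_energy,
)
from aif_bandit.task_environment import CUE, RISKY, SAFE, STAY


def brute_force_posterior(model, observations, actions):
    """Oracle: enumerate every hidden-state path and marginalise."""
    T = len(observations)
    A = model.A
    post = np.zeros(N_STATES)
    evidence = 0.0
    for path in itertools.product(range(N_STATES), repeat=T):
        p = model.d[path[0]] * A[OBS_INDEX[observations[0]], path[0]]
        for k in range(1, T):
            p *= model.B[actions[k - 1]][path[k], path[k - 1]]
            p *= A[OBS_INDEX[observations[k]], path[k]]
        post[path[-1]] += p
        evidence += p
    return post / evidence, evidence


def reachable_histories():
    """All observation/action histories the task can generate in one trial."""
    histories = [(("Null",), ())]
    for a1, o1 in ((STAY, "Null"), (CUE, "Cue1"), (CUE, "Cue2")):
        histories.append((("Null", o1), (a1,)))
        for a2 in (SAFE, RISKY):
            rewards = ("R6",) if a2 == SAFE else ("R0", "R3", "R6", "R9", "R12")
            for r in rewards:
                histories.append((("Null", o1, r), (a1, a2)))
    return histories


def random_learned_model(seed, **kwargs):
    rng = np.random.default_rng(seed)
    model = init_model(
        AL=float(rng.random() * 3),
        AI=float(rng.random() * 3),
        EX=float(rng.random() * 3),
        prior=float(rng.random() * 2 + 0.05),
        **kwargs,
    )
    a = model.a.copy()
    for s in RISKY_STATES:
        a[REWARD_OBS, s] = rng.random(5) * 4 + 0.05
    model.a = a
    return model


class TestInferStates:
    def test_matches_brute_force_on_all_reachable_histories(self, model):
        for obs, acts in reachable_histories():
            fast = infer_states(model, obs, acts)
            oracle, _ = brute_force_posterior(model, obs, acts)
            np.testing.assert_allclose(fast, oracle, atol=1e-12)

    def test_matches_brute_force_with_learned_likelihood(self):
        model = random_learned_model(7)
        for obs, acts in reachable_histories():
            fast = infer_states(model, obs, acts)
            oracle, _ = brute_force_posterior(model, obs, acts)
            np.testing.assert_allclose(fast, oracle, atol=1e-12)

    def test_cue_identifies_context(self, model):
        post = infer_states(model, ("Null", "Cue1"), (CUE,))
        assert model.context_belief(post)[0] == pytest.approx(1.0)

    def test_history_length_mismatch(self, model):
        with pytest.raises(ValueError):
            infer_states(model, ("Null", "Cue1"), ())

    def test_impossible_observation(self, model):
        with pytest.raises(ImpossibleObservationError):
            infer_states(model, ("Cue1",), ())  # no cue from the start state


class TestVariationalFreeEnergy:
    def test_bounds_negative_log_evidence(self, model, rng):
        obs, acts = ("Null", "Cue1", "R12"), (CUE, RISKY)
        posterior, _ = brute_force_posterior(model, obs, acts)
        prior = model.B[RISKY] @ (
            infer_states(model, obs[:2], acts[:1])
        )
        like = model.A[OBS_INDEX["R12"], :]
        evidence = float(like @ prior)
        bound = -np.log(evidence)
        f_star = variational_free_energy(posterior, prior, like)
        assert f_star == pytest.approx(bound, abs=1e-10)
        for _ in range(200):
            q = rng.dirichlet(np.ones(N_STATES))
            assert variational_free_energy(q, prior, like) >= bound - 1e-10

    def test_rejects_unnormalized_q(self, model):
        with pytest.raises(ValueError):
            variational_free_energy(
                np.full(N_STATES, 0.2), model.d, model.A[0, :]
            )


class TestDirichletKL:
    def test_unit_kl_matches_general_formula(self, rng):
        a = rng.random((5, 3)) * 3 + 0.1
        unit = _dirichlet_unit_kl(a)
        for s in range(3):
            for o in range(5):
                a_new = a[:, s].copy()
                a_new[o] += 1.0
                oracle = _dirichlet_kl_general(a_new, a[:, s])
                assert unit[o, s] == pytest.approx(oracle, abs=1e-10)


class TestEFE:
    def test_decomposition_identity(self):
        for seed in range(50):
            model = random_learned_model(seed)
            rng = np.random.default_rng(seed + 10_000)
            qs = rng.dirichlet(np.ones(N_STATES))
            for action in (STAY, CUE, SAFE, RISKY):
                dec = efe_step(model, qs, action)
                expected = (
                    model.AL * dec.raw_novelty
                    + model.AI * dec.raw_salience
                    - model.EX * dec.raw_extrinsic
                )
                assert dec.total_G == pytest.approx(expected, abs=1e-10)

    def test_policy_efe_sums_over_steps(self):
        model = random_learned_model(3)
        qs = model.d
        for policy in POLICIES:
            total = expected_free_energy(model, qs, policy)
            step1 = expected_free_energy(model, qs, policy, tau=1)
            step2 = expected_free_energy(model, qs, policy, tau=2)
            assert total.total_G == pytest.approx(
                step1.total_G + step2.total_G, abs=1e-10
            )

    @given(st.integers(min_value=0, max_value=10_000))
    def test_epistemic_terms_nonpositive(self, seed):
        model = random_learned_model(seed)
        rng = np.random.default_rng(seed + 1)
        qs = rng.dirichlet(np.ones(N_STATES))
        for action in (STAY, CUE, SAFE, RISKY):
            dec = efe_step(model, qs, action)
            assert dec.raw_novelty <= 1e-12
            assert dec.raw_salience <= 1e-12

    def test_cue_salience_is_one_bit(self, model):
        dec = efe_step(model, model.d, CUE)
        assert dec.raw_salience == pytest.approx(-np.log(2), abs=1e-10)

    def test_known_likelihood_has_no_novelty(self, model):
        model = model.copy()
        model.a = model.a * 1e6
        dec = efe_step(model, model.d, RISKY)
        assert abs(dec.raw_novelty) < 1e-3

    def test_extrinsic_is_expected_log_preference(self, model):
        dec = efe_step(model, model.d, SAFE)
        assert dec.raw_extrinsic == pytest.approx(
            model.preference_scale * 6.0, abs=1e-10
        )

    def test_linearized_novelty_close_to_exact(self):
        model = random_learned_model(11)
        exact = efe_step(model, model.d, RISKY, exact_novelty=True)
        approx = efe_step(model, model.d, RISKY, exact_novelty=False)
        assert approx.raw_salience == pytest.approx(exact.raw_salience)
        assert np.sign(approx.raw_novelty) == np.sign(exact.raw_novelty)
        assert abs(approx.raw_novelty - exact.raw_novelty) < 0.5 * abs(
            exact.raw_novelty
        )

    def test_addition_requires_matching_coefficients(self):
        a = EFEDecomposition(-1, -1, 1, 1, 1, 1)
        b = EFEDecomposition(-1, -1, 1, 2, 1, 1)
        with pytest.raises(ValueError):
            a + b


class TestPolicyPosterior:
    def test_uniform_under_equal_G(self):
        np.testing.assert_allclose(policy_posterior(np.zeros(4), 1.0), 0.25)

    def test_two_policy_example(self):
        q = policy_posterior(np.array([-2.0, -1.0]), 1.0)
        np.testing.assert_allclose(q, [0.73105858, 0.26894142], atol=1e-8)

    def test_large_gamma_selects_argmin(self):
        q = policy_posterior(np.array([-2.0, -1.0, 0.0]), 200.0)
        assert q[0] == pytest.approx(1.0, abs=1e-10)

    def test_gamma_must_be_positive(self):
        with pytest.raises(ValueError):
            policy_posterior(np.zeros(4), 0.0)


class TestActionMarginal:
    def test_stage1_marginal_sums_policy_mass(self):
        q = np.array([0.1, 0.2, 0.3, 0.4])
        marg = action_marginal(q, stage=1)
        assert marg[CUE] == pytest.approx(0.3)
        assert marg[STAY] == pytest.approx(0.7)

    def test_stage2_conditions_on_first_action(self):
        q = np.array([0.1, 0.2, 0.3, 0.4])
        marg = action_marginal(q, stage=2, realized_first=CUE)
        assert marg[SAFE] == pytest.approx(0.1 / 0.3)
        assert marg[RISKY] == pytest.approx(0.2 / 0.3)

    def test_degenerate_mass_raises(self):
        q = np.array([0.0, 0.0, 0.5, 0.5])
        with pytest.raises(DegeneratePolicyError):
            action_marginal(q, stage=2, realized_first=CUE)

    def test_stage2_requires_realized_action(self):
        with pytest.raises(ValueError):
            action_marginal(np.full(4, 0.25), stage=2)


class TestPolicyEFEWiring:
    def test_four_policies_evaluated(self, model):
        decomps = policy_efe(model, model.d)
        assert len(decomps) == 4

    def test_cue_preferred_at_unit_coefficients(self, model):
        decomps = policy_efe(model, model.d)
        G = np.array([d.total_G for d in decomps])
        marg = action_marginal(policy_posterior(G, model.gamma), stage=1)
        assert marg[CUE] > 0.5
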