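"""Unit tests for the agent's generative model."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from aif_bandit.generative_model import (
    DegenerateColumnError,
    GenerativeModel,
    HIDDEN_STATES,
    InvalidParameterError,
    N_OBS,
    N_STATES,
    OBS_INDEX,
    OBSERVATIONS,
    POLICIES,
    REWARD_OBS,
    RISKY_STATES,
    SAFE_STATES,
    expected_risky_reward,
    init_model,
    normalize_likelihood,
    update_concentrations,
)
from aif_bandit.task_environment import CONTEXT1, CONTEXT2, TaskConfig


class TestStateSpace:
    def test_counts(self):
        assert len(HIDDEN_STATES) == 8
        assert len(OBSERVATIONS) == 8
        assert len(POLICIES) == 4


class TestInitModel:
    def test_risky_column_uniform_at_half_prior(self):
        model = init_model(prior=0.5)
        col = model.A[:, RISKY_STATES[0]]
        np.testing.assert_allclose(col[list(REWARD_OBS)], 0.2, atol=1e-12)

    def test_safe_column_one_hot_on_r6(self, model):
        col = model.A[:, SAFE_STATES[0]]
        assert col[OBS_INDEX["R6"]] == pytest.approx(1.0)
        assert col.sum() == pytest.approx(1.0)

    def test_learnable_cells_equal_prior(self):
        model = init_model(prior=0.7)
        assert np.all(model.a[model.learnable] == 0.7)

    def test_columns_stochastic(self, model):
        np.testing.assert_allclose(model.A.sum(axis=0), 1.0, atol=1e-12)
        for B in model.B.values():
            np.testing.assert_allclose(B.sum(axis=0), 1.0, atol=1e-12)

    def test_d_is_context_prior_on_start_states(self):
        model = init_model(config=TaskConfig(p_context1=0.3))
        assert model.d[0] == pytest.approx(0.3)
        assert model.d[1] == pytest.approx(0.7)
        assert model.d.sum() == pytest.approx(1.0)

    def test_logC_encodes_preferences(self, model, config):
        scale = model.preference_scale
        assert model.logC[OBS_INDEX["Cue1"]] == pytest.approx(scale * config.cue_cost)
        assert model.logC[OBS_INDEX["R12"]] == pytest.approx(scale * 12)
        assert model.logC[OBS_INDEX["Null"]] == 0.0

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            init_model(prior=0.0)
        with pytest.raises(InvalidParameterError):
            init_model(alpha=-0.1)
        with pytest.raises(InvalidParameterError):
            init_model(gamma=0.0)
        with pytest.raises(InvalidParameterError):
            init_model(AL=-1.0)

    def test_merge_null_observation_variant(self):
        model = init_model(merge_null_observation=True)
        null_row = model.a[OBS_INDEX["Null"], :]
        assert np.all(null_row <= 1e-15)
        # Start states observe the merged zero-reward row instead
        assert model.a[OBS_INDEX["R0"], 0] == pytest.approx(1.0)


class TestNormalizeLikelihood:
    def test_uniform_column(self):
        out = normalize_likelihood(np.ones((5, 1)))
        np.testing.assert_allclose(out[:, 0], 0.2)

    def test_three_one_column(self):
        out = normalize_likelihood(np.array([[3.0], [1.0]]))
        np.testing.assert_allclose(out[:, 0], [0.75, 0.25])

    def test_degenerate_column_raises(self):
        with pytest.raises(DegenerateColumnError):
            normalize_likelihood(np.zeros((3, 2)))

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_columns_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((6, 4)) + 1e-3
        np.testing.assert_allclose(
            normalize_likelihood(a).sum(axis=0), 1.0, atol=1e-12
        )


class TestUpdateConcentrations:
    def test_alpha_zero_is_identity(self, model):
        obs = np.eye(N_OBS)[OBS_INDEX["R12"]]
        qs = np.eye(N_STATES)[RISKY_STATES[0]]
        np.testing.assert_array_equal(
            update_concentrations(model.a, obs, qs, 0.0), model.a
        )

    def test_one_hot_increments_single_cell(self, model):
        obs = np.eye(N_OBS)[OBS_INDEX["R12"]]
        qs = np.eye(N_STATES)[RISKY_STATES[0]]
        new = update_concentrations(model.a, obs, qs, 1.0)
        diff = new - model.a
        assert diff[OBS_INDEX["R12"], RISKY_STATES[0]] == pytest.approx(1.0)
        assert diff.sum() == pytest.approx(1.0)

    def test_added_mass_equals_alpha(self, model, rng):
        obs = np.eye(N_OBS)[OBS_INDEX["R3"]]
        qs = rng.dirichlet(np.ones(N_STATES))
        new = update_concentrations(model.a, obs, qs, 0.37)
        assert (new - model.a).sum() == pytest.approx(0.37)

    def test_negative_alpha_raises(self, model):
        with pytest.raises(InvalidParameterError):
            update_concentrations(
                model.a, np.eye(N_OBS)[3], np.eye(N_STATES)[6], -1.0
            )

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_likelihood_remains_stochastic_after_updates(self, seed):
        rng = np.random.default_rng(seed)
        model = init_model()
        a = model.a
        for _ in range(5):
            obs = np.eye(N_OBS)[rng.integers(0, N_OBS)]
            qs = rng.dirichlet(np.ones(N_STATES))
            a = update_concentrations(a, obs, qs, float(rng.random()))
        np.testing.assert_allclose(
            normalize_likelihood(a).sum(axis=0), 1.0, atol=1e-12
        )

    def test_deterministic_columns_untouched_without_posterior_mass(self, model):
        qs = np.zeros(N_STATES)
        qs[RISKY_STATES[0]] = 1.0
        obs = np.eye(N_OBS)[OBS_INDEX["R9"]]
        new = update_concentrations(model.a, obs, qs, 1.0)
        np.testing.assert_array_equal(
            new[:, SAFE_STATES[0]], model.a[:, SAFE_STATES[0]]
        )


class TestExpectedRiskyReward:
    def test_uniform_gives_grid_mean(self, model):
        assert expected_risky_reward(model, CONTEXT1) == pytest.approx(6.0)

    def test_true_distributions_give_oracles(self, model, config):
        a = model.a.copy()
        a[REWARD_OBS, RISKY_STATES[0]] = config.ctx1_probs
        a[REWARD_OBS, RISKY_STATES[1]] = config.ctx2_probs
        model.a = a
        assert expected_risky_reward(model, CONTEXT1) == pytest.approx(9.6)
        assert expected_risky_reward(model, CONTEXT2) == pytest.approx(2.4)

    def test_unknown_context_raises(self, model):
        with pytest.raises(ValueError):
            expected_risky_reward(model, "Context3")

    def test_convergence_to_true_distribution(self, config):
        model = init_model(alpha=1.0, config=config)
        rng = np.random.default_rng(0)
        obs_labels = [f"R{r}" for r in config.reward_values]
        qs = np.zeros(N_STATES)
        qs[RISKY_STATES[0]] = 1.0
        a = model.a
        probs = np.asarray(config.ctx1_probs)
        for _ in range(10_000):
            idx = rng.choice(5, p=probs)
            obs = np.eye(N_OBS)[OBS_INDEX[obs_labels[idx]]]
            a = update_concentrations(a, obs, qs, 1.0)
        model.a = a
        assert abs(expected_risky_reward(model, CONTEXT1) - 9.6) < 0.1


class TestSerialization:
    def test_json_round_trip(self, model):
        back = GenerativeModel.from_json(model.to_json())
        np.testing.assert_allclose(back.a, model.a)
        np.testing.assert_allclose(back.logC, model.logC)
        np.testing.assert_allclose(back.d, model.d)
        for key in model.B:
            np.testing.assert_allclose(back.B[key], model.B[key])
        assert back.AL == model.AL
        assert back.preference_scale == model.preference_scale

    def test_copy_is_deep_for_arrays(self, model):
        clone = model.copy()
        clone.a[REWARD_OBS[0], RISKY_STATES[0]] += 5.0
        assert model.a[REWARD_OBS[0], RISKY_STATES[0]] != pytest.approx(
            clone.a[REWARD_OBS[0], RISKY_STATES[0]]
        )

    def test_context_belief_marginalization(self, model):
        qs = np.zeros(N_STATES)
        qs[RISKY_STATES[0]] = 0.25
        qs[RISKY_STATES[1]] = 0.75
        np.testing.assert_allclose(model.context_belief(qs), [0.25, 0.75])
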