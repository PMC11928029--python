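"""Synthetic cohorts and neural epochs with planted regressor effects.

The behavioural generator simulates cohorts of participants from a known
model (active inference, model-free RL, or model-based RL) with parameters
drawn from configurable ranges, recording the ground truth so parameter- and
model-recovery pipelines can run without any external data. The neural
generator produces trials x regions x timepoints arrays of Gaussian (or
AR(1)) noise with a standardized regressor effect planted in one region's
time window, for exercising the mass-univariate regression stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agent_loop import run_agent
from .rl_baselines import MBParams, MFParams, ModelBasedProcess, ModelFreeProcess, ProcessActor
from .task_environment import BehavioralDataset, TaskConfig, run_session

# parameter sampling ranges per generator model: the cohort's "population"
DEFAULT_RANGES: dict = {
    "aif": {
        "AL": (0.25, 2.0),
        "AI": (0.25, 2.0),
        "EX": (0.25, 3.0),
        "prior": (0.25, 2.0),
        "alpha": (0.1, 1.0),
    },
    "mf": {
        "alpha_mf": (0.1, 0.9),
        "gamma_mf": (0.5, 3.0),
    },
    "mb": {
        "alpha_mb": (0.1, 0.9),
        "gamma_mb": (0.5, 3.0),
        "prior_mb": (3.0, 9.0),
    },
}


@dataclass
class CohortSpec:
    n_participants: int = 25
    generator_model: str = "aif"
    parameter_ranges: dict = None
    task: TaskConfig = field(default_factory=TaskConfig)
    master_seed: int = 0

    def __post_init__(self):
        if self.generator_model not in DEFAULT_RANGES:
            raise ValueError(f"unknown generator model {self.generator_model!r}")
        if self.parameter_ranges is None:
            self.parameter_ranges = dict(DEFAULT_RANGES[self.generator_model])


@dataclass
class Cohort:
    datasets: list
    ground_truth: pd.DataFrame
    spec: CohortSpec


def _simulate_participant(
    model_name: str, params: dict, config: TaskConfig, seed: int, pid: str
) -> BehavioralDataset:
    if model_name == "aif":
        return run_agent(params, config, seed=seed, participant_id=pid).dataset
    if model_name == "mf":
        process = ModelFreeProcess(MFParams(**params), config)
    elif model_name == "mb":
        process = ModelBasedProcess(MBParams(**params), config)
    else:
        raise ValueError(f"unknown generator model {model_name!r}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    actor = ProcessActor(process, rng)
    return run_session(config, actor, seed=seed, participant_id=pid)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate a cohort and record each participant's true parameters."""
    rng = np.random.default_rng(spec.master_seed)
    datasets, truth_rows = [], []
    for i in range(spec.n_participants):
        params = {
            name: lo + rng.random() * (hi - lo)
            for name, (lo, hi) in spec.parameter_ranges.items()
        }
        pid = f"{spec.generator_model}-{i:03d}"
        seed = int(rng.integers(0, 2**31 - 1))
        dataset = _simulate_participant(
            spec.generator_model, params, spec.task, seed, pid
        )
        datasets.append(dataset)
        truth_rows.append(
            {"participant_id": pid, "model": spec.generator_model, "seed": seed, **params}
        )
    return Cohort(
        datasets=datasets,
        ground_truth=pd.DataFrame(truth_rows),
        spec=spec,
    )


@dataclass
class NeuralEpochs:
    """trials x regions x timepoints activity with generation metadata."""

    activity: np.ndarray
    sampling_rate: float = 250.0
    region_labels: list = None
    stage: str = "second_choice"
    ground_truth: dict = None

    def __post_init__(self):
        if self.region_labels is None:
            self.region_labels = [
                f"region_{i}" for i in range(self.activity.shape[1])
            ]

    def save(self, path) -> None:
        np.savez(
            path,
            activity=self.activity,
            sampling_rate=self.sampling_rate,
            region_labels=np.array(self.region_labels),
        )


def generate_neural_epochs(
    regressor: np.ndarray,
    beta_true: float = 0.5,
    noise_sd: float = 1.0,
    n_regions: int = 8,
    n_timepoints: int = 100,
    effect_region: int = 0,
    effect_window: tuple = (40, 60),
    seed: int = 0,
    ar1: float = 0.0,
    sampling_rate: float = 250.0,
) -> NeuralEpochs:
    """Plant a linear effect of a z-scored regressor in one region/window.

    Outside the effect window (and in all other regions) the signal is pure
    noise; inside it, ``beta_true`` times the standardized regressor is
    added, so a regression on the window recovers ``beta_true`` exactly when
    ``noise_sd`` is 0. ``ar1`` > 0 makes the noise temporally correlated.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    regressor = np.asarray(regressor, dtype=float)
    n_trials = len(regressor)
    sd = regressor.std()
    z = (regressor - regressor.mean()) / sd if sd > 0 else np.zeros(n_trials)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, 1.0, size=(n_trials, n_regions, n_timepoints))
    if ar1 > 0.0:
        for t in range(1, n_timepoints):
            noise[:, :, t] = ar1 * noise[:, :, t - 1] + np.sqrt(1 - ar1**2) * noise[:, :, t]
    activity = noise_sd * noise
    lo, hi = effect_window
    activity[:, effect_region, lo:hi] += beta_true * z[:, np.newaxis]
    return NeuralEpochs(
        activity=activity,
        sampling_rate=sampling_rate,
        stage="second_choice",
        ground_truth={
            "beta_true": beta_true,
            "noise_sd": noise_sd,
            "effect_region": effect_region,
            "effect_window": tuple(effect_window),
            "ar1": ar1,
            "seed": seed,
        },
    )
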