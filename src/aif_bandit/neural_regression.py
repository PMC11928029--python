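"""Trial-wise model regressors and mass-univariate regression with FDR.

Regressors are the agent's expected-free-energy quantities per trial and
stage: the choice stages carry the chosen action's policy-evaluated values
(expected free energy and its three components), and the result stages carry
the realised belief-update quantities (state information gain at the first
result, parameter information gain at the second result) plus reward and
prediction error. Each region x timepoint series is regressed on one
z-scored regressor with an intercept (Activity ~ Regressor + Intercept) and
p-values are corrected with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .agent_loop import ActiveInferenceProcess, SimulationTrace, build_model
from .synthetic_data import NeuralEpochs
from .task_environment import BehavioralDataset, CUE

STAGES = ("first_choice", "first_result", "second_choice", "second_result")


class IncompleteTraceError(ValueError):
    pass


class DegenerateDesignError(ValueError):
    pass


def replay(dataset: BehavioralDataset, params: dict) -> SimulationTrace:
    """Step a fitted model through a recorded dataset (teacher forcing),
    collecting the same per-trial quantities as a simulation."""
    config = dataset.config
    process = ActiveInferenceProcess(build_model(params, config))
    computations = []
    for rec in dataset.records:
        process.begin_trial(rec.trial_index, rec.can_ask)
        if rec.can_ask:
            process.current.p_first = process.first_action_probs()
        process.observe_first(
            rec.first_action,
            rec.first_observation,
            config.cue_cost if rec.first_action == CUE else 0.0,
        )
        process.current.p_second = process.second_action_probs()
        process.observe_second(rec.second_action, rec.reward)
        computations.append(process.current)
    return SimulationTrace(
        dataset=dataset, computations=computations, model=process.model
    )


def compute_regressors(
    trace: SimulationTrace | BehavioralDataset,
    params: dict | None = None,
) -> pd.DataFrame:
    """Long-format regressor table: one row per trial per stage.

    Pass either a :class:`SimulationTrace` from :func:`run_agent`, or a
    recorded dataset together with (fitted) parameters to replay it.
    Choice-stage rows carry the chosen action's expected free energy and its
    components; result-stage rows carry the realised reducing-variability and
    reducing-novelty quantities, the reward, and the prediction error.
    """
    if isinstance(trace, BehavioralDataset):
        if params is None:
            raise IncompleteTraceError(
                "replaying a dataset requires model parameters"
            )
        trace = replay(trace, params)
    rows = []
    for c in trace.computations:
        if c.choice1 is None or c.choice2 is None:
            raise IncompleteTraceError("trial is missing belief snapshots")
        AL, AI, EX = c.choice1.AL, c.choice1.AI, c.choice1.EX
        base = {"trial": c.trial_index, "can_ask": int(c.can_ask)}
        for stage, dec in (("first_choice", c.choice1), ("second_choice", c.choice2)):
            rows.append(
                {
                    **base,
                    "stage": stage,
                    "expected_free_energy": dec.total_G,
                    "value_of_reducing_novelty": dec.novelty_value,
                    "value_of_reducing_variability": dec.variability_value,
                    "extrinsic_value": dec.extrinsic_value,
                    "novelty": dec.raw_novelty,
                    "salience": dec.raw_salience,
                    "reducing_variability": 0.0,
                    "reducing_novelty": 0.0,
                    "reward": 0.0,
                    "prediction_error": 0.0,
                }
            )
        rows.append(
            {
                **base,
                "stage": "first_result",
                "expected_free_energy": 0.0,
                "value_of_reducing_novelty": 0.0,
                "value_of_reducing_variability": 0.0,
                "extrinsic_value": 0.0,
                "novelty": 0.0,
                "salience": 0.0,
                "reducing_variability": AI * c.reducing_variability_raw,
                "reducing_novelty": 0.0,
                "reward": 0.0,
                "prediction_error": 0.0,
            }
        )
        rows.append(
            {
                **base,
                "stage": "second_result",
                "expected_free_energy": 0.0,
                "value_of_reducing_novelty": 0.0,
                "value_of_reducing_variability": 0.0,
                "extrinsic_value": 0.0,
                "novelty": 0.0,
                "salience": 0.0,
                "reducing_variability": 0.0,
                "reducing_novelty": c.reducing_novelty_raw,
                "reward": c.reward,
                "prediction_error": c.signed_prediction_error,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RegressionResult:
    beta: np.ndarray  # regions x timepoints
    t: np.ndarray
    p: np.ndarray
    fdr_mask: np.ndarray
    q_level: float
    intercept: np.ndarray | None = None

    def to_frame(self, region_labels=None) -> pd.DataFrame:
        n_regions, n_time = self.beta.shape
        labels = region_labels or [f"region_{i}" for i in range(n_regions)]
        rows = []
        for r in range(n_regions):
            for t_idx in range(n_time):
                rows.append(
                    {
                        "region": labels[r],
                        "timepoint": t_idx,
                        "beta": self.beta[r, t_idx],
                        "t": self.t[r, t_idx],
                        "p": self.p[r, t_idx],
                        "significant": bool(self.fdr_mask[r, t_idx]),
                    }
                )
        return pd.DataFrame(rows)


def mass_univariate_regression(
    epochs: NeuralEpochs | np.ndarray,
    regressor: np.ndarray,
    q_level: float = 0.05,
    standardize: bool = True,
) -> RegressionResult:
    """OLS of every region x timepoint series on one regressor + intercept.

    The regressor is z-scored by default so betas are in standardized units;
    t statistics use n - 2 degrees of freedom with two-sided p-values, and
    the FDR mask applies Benjamini-Hochberg at ``q_level`` over the whole
    region x timepoint grid.
    """
    activity = epochs.activity if isinstance(epochs, NeuralEpochs) else np.asarray(epochs)
    x = np.asarray(regressor, dtype=float)
    n = activity.shape[0]
    if len(x) != n:
        raise ValueError("regressor length must match the number of trials")
    sx = x.std(ddof=0)
    if sx == 0:
        raise DegenerateDesignError("regressor has zero variance")
    if standardize:
        x = (x - x.mean()) / sx
    xc = x - x.mean()
    ssx = float(np.sum(xc**2))
    y = activity.reshape(n, -1)
    ymean = y.mean(axis=0)
    beta = (xc @ (y - ymean)) / ssx
    intercept = ymean - beta * x.mean()
    resid = y - ymean - np.outer(xc, beta)
    df = n - 2
    sigma2 = np.sum(resid**2, axis=0) / df
    se = np.sqrt(sigma2 / ssx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_val = np.where(se > 0, beta / se, 0.0)
    p_val = 2.0 * stats.t.sf(np.abs(t_val), df)
    mask = fdr_correct(p_val, q=q_level)
    shape = activity.shape[1:]
    return RegressionResult(
        beta=beta.reshape(shape),
        t=t_val.reshape(shape),
        p=p_val.reshape(shape),
        fdr_mask=mask.reshape(shape),
        q_level=q_level,
        intercept=intercept.reshape(shape),
    )


def fdr_correct(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up over the flattened array at level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(p.shape, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(p.shape)
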