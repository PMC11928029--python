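# Methods

This document describes the generative model, the parameterisation and its
defaults, the fitting and comparison procedures, the synthetic-data
pipeline, the numerical choices, and the known limitations.

## Task environment

`TaskConfig` fixes the generative process of the task:

| Field | Default | Units | Meaning |
|---|---|---|---|
| `n_trials` | 120 | trials | session length |
| `reward_values` | (0, 3, 6, 9, 12) | apples | risky payout grid |
| `ctx1_probs` | (.05, .05, .10, .25, .55) | probability | risky payout distribution in Context 1 (mean 9.6) |
| `ctx2_probs` | (.55, .25, .10, .05, .05) | probability | mirrored distribution in Context 2 (mean 2.4) |
| `safe_reward` | 6 | apples | deterministic safe payout |
| `cue_cost` | −1 | apples | fee for asking the context |
| `initial_reward` | 5 | apples | starting endowment |
| `p_context1` | 0.5 | probability | per-trial context redraw |
| `p_can_ask` | 0.5 | probability | fraction of trials where the cue is offered |

Each trial has two stages: Stay/Cue (the cue reveals the context and costs
one apple; on forced trials only Stay is available), then Safe/Risky.

## Generative model (active inference agent)

Hidden states are the product of a four-level trial phase
{Start, Cued, ChoseSafe, ChoseRisky} and the two contexts (8 states).
Observations are {Null, Cue1, Cue2, R0, R3, R6, R9, R12}. Policies are the
four two-step sequences (Stay/Cue × Safe/Risky).

- **Likelihood** `A = normalize(a)`. The Dirichlet concentration matrix `a`
  is deterministic everywhere except the two risky-state reward columns,
  which start at `prior` per cell and are learned.
- **Transitions** `B[action]` are deterministic given the action; the
  context persists within a trial.
- **Preferences** `logC = preference_scale × monetary value` of each
  observation (so R12 is preferred to R6, and the cue's fee enters as a
  small negative preference).
- **State inference** is exact: the state space is small enough that the
  posterior over the 8 states given any within-trial history is computed by
  direct enumeration (verified in the tests against a brute-force oracle).
- **Expected free energy** of a policy sums over its two steps:
  `G = AL·novelty + AI·salience − EX·extrinsic`, where novelty is the
  (negative) expected KL between the posterior and prior Dirichlet
  distributions over `a`, salience is the (negative) expected information
  gain about the hidden state, and extrinsic value is the expected
  log-preference. Policies are chosen with `softmax(−γ G)`; the precision γ
  is fixed at 1 (the epistemic and extrinsic weights already set the
  effective temperature per stream, so a free γ would be redundant with
  them at fitting time).
- **Learning**: after each observation, `a ← a + α · (o ⊗ q(s))`,
  i.e. learning rate `alpha` scales the Dirichlet count added to cells
  consistent with the posterior state belief.

### Parameter defaults and rationale

| Parameter | Default | Rationale |
|---|---|---|
| `AL`, `AI`, `EX` | 1.0 | unit weighting of the three value streams; the qualitative behavioural signatures (cue buying, context-conditional gambling, estimate convergence, declining prediction errors) emerge at this neutral setting |
| `alpha` | 1.0 | one observation adds one Dirichlet count; the simulated regime is a fast, ideal-observer learner |
| `prior` | 0.25 | sparse prior: the whole 5-cell risky column carries 1.25 pseudo-counts, about one observation's worth. The initial payout estimate sits at the grid midpoint (6 apples) but yields quickly to data. Heavier priors (≥ 0.5/cell) anchor the estimates near 6 for tens of trials, which both prevents convergence to the true means within a 60-trial session and suppresses the early-vs-late decline in prediction errors |
| `preference_scale` | 0.25 | converts apples to log-preference units; keeps extrinsic value on a scale commensurate with the information-gain terms at unit weights |
| `gamma` | 1.0 (fixed) | see above: redundant with the stream weights |

### Prediction error

The reward prediction error on a stage-2 outcome is
`|reward − E[reward | chosen action, current beliefs]|`, where the
expectation marginalises the learned likelihood over the current context
belief. A signed variant is also provided and used as the neural regressor.

## Baseline models

- **Model-free (`mf`)**: delta-rule values for the two stage-1 actions and,
  separately for each information condition (Cue1 / Cue2 / no cue), the two
  stage-2 actions; softmax choice with inverse temperature `gamma_mf`;
  learning rate `alpha_mf`. Stage-1 values learn the net trial outcome
  (reward minus cue fee). Conditioning the stage-2 values on the cue
  content gives this baseline the same information access as the other
  models — it is deliberately not handicapped.
- **Model-based (`mb`)**: point estimates of the risky payout per
  information condition (initialised at `prior_mb`, updated by delta rule
  only when the risky door is taken), combined with the known task
  structure to plan: the value of asking is the expected value of acting
  optimally per context, minus the fee.

## Model fitting

Fitting maximises the penalised choice log-likelihood (MAP). The likelihood
is teacher-forced: the model is stepped through the recorded trial sequence
and scored on every free choice (the stage-1 choice on can-ask trials and
every stage-2 choice). Weakly informative priors regularise parameters that
the likelihood constrains only weakly at 120 trials:

| Parameter | Prior | Mode |
|---|---|---|
| `AL`, `AI`, `prior` | Gamma(shape 3, scale 0.375) | 0.75 |
| `EX` | Gamma(shape 4, scale 0.4) | 1.2 |
| `alpha_mf`, `alpha_mb`, `alpha` | Beta(1.5, 1.5) | 0.5 |
| `gamma_mf`, `gamma_mb` | Gamma(shape 2, scale 1) | 1.0 |
| `prior_mb` | Gamma(shape 3, scale 2) | 4.0 |

The search is a fixed budget of uniform random draws inside the parameter
bounds followed by a Nelder–Mead polish from the incumbent, with the
function-evaluation count capped by the second budget component. The
reported `log_likelihood` and BIC use the *pure* likelihood (no prior) at
the returned parameters, so model comparison is not distorted by the
regulariser: `BIC = k ln n − 2 lnL`, with `n` the number of scored choices
and `k` the number of free parameters (5 for `aif`, 2 for `mf`, 3 for
`mb`).

## Synthetic data

`generate_cohort` simulates participants from a chosen generator model with
parameters drawn uniformly from configurable ranges, recording the ground
truth. This supports two validation exercises:

- **Parameter recovery** — fit the generating model and compare estimates
  to the truth. What the synthetic data shows: the learning rate `alpha`
  and the extrinsic weight `EX` carry recoverable signal at 120 trials,
  though both are noisy (see Limitations). It does not show that all five
  parameters are jointly identifiable — they are not at this session
  length.
- **Model recovery** — fit all three models to each cohort and pick the
  winner by lowest mean BIC. The `mf` and `mb` generators are reliably
  recovered. The `aif` generator is frequently misattributed to `mf`: with
  only ~180 scored binary choices, the aif likelihood advantage over an
  information-matched model-free account is usually smaller than the BIC
  penalty for its three extra parameters.

`generate_neural_epochs` produces trials × regions × timepoints Gaussian
(optionally AR(1)) noise with `beta_true` times a z-scored regressor added
in one region/time window. With `noise_sd = 0` the regression recovers
`beta_true` exactly; under the null the uncorrected false-positive rate is
the nominal 5% and Benjamini–Hochberg FDR controls the corrected rate.
These are machinery checks, not simulations of physiological signals.

## Numerical choices

- Dirichlet concentrations are floored at 1e-16 so deterministic likelihood
  columns never produce log(0); observations declared impossible below
  1e-13 evidence raise an error rather than returning junk posteriors.
- The novelty term uses the closed-form KL between Dirichlet distributions
  differing by a unit count, `ln a₀ − ln a_os + ψ(a_os+1) − ψ(a₀+1)`; an
  exact (non-linearised) variant is available for verification.
- Choice probabilities entering the likelihood are floored at 1e-16.
- All stochastic components take explicit seeds; simulations, cohorts, and
  fits are bit-reproducible given the seed.

## Limitations

- **Weak identifiability at 120 trials.** With ~180 binary choices, the
  likelihood surface over the five agent parameters is nearly flat along
  several directions; in particular `EX` trades off against
  `preference_scale`-like rescalings and `AL`/`prior` against each other.
  Profile-likelihood checks with an oracle optimiser put the rank
  correlation between true and best-achievable `EX` estimates near 0.56 —
  an information ceiling of the data, not an optimiser deficiency. Recovery
  of `alpha` is similarly at the edge of usefulness (median absolute error
  ≈ 0.2 over the default cohort ranges).
- **BIC penalty asymmetry.** Because the model-free baseline is given the
  same information access as the agent (stage-2 values conditioned on the
  cue content) and has 3 fewer parameters, BIC favours it even on data
  generated by the active inference agent whenever the epistemic dynamics
  leave too small a likelihood footprint. Model recovery for the `aif`
  generator therefore fails more often than not at this session length;
  distinguishing the accounts empirically needs longer sessions, stronger
  epistemic parameter settings, or design features that decouple
  information seeking from reward seeking.
- The neural pipeline is a mass-univariate OLS sanity harness; it does not
  model hemodynamics/electrophysiology, spatial correlation, or
  participant-level random effects.
- The task model assumes the printed reward grid and context distributions;
  no misspecification robustness is claimed.
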