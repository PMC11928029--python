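# aif-bandit

Active inference modelling of a contextual two-armed bandit task, with
reinforcement-learning baselines, model fitting and comparison, and a
synthetic-data pipeline for parameter recovery, model recovery, and
mass-univariate neural regression.

## The task

On each of 120 trials a gambler faces two doors. Behind the risky door the
payout is one of {0, 3, 6, 9, 12} apples; behind the safe door it is always
6 apples. Which payout distribution governs the risky door depends on a
hidden context, redrawn every trial with probability 0.5:

| Context | P(0) | P(3) | P(6) | P(9) | P(12) | expected payout |
|---|---|---|---|---|---|---|
| Context 1 | .05 | .05 | .10 | .25 | .55 | **9.6** |
| Context 2 | .55 | .25 | .10 | .05 | .05 | **2.4** |

Before choosing a door the player may, on roughly half of the trials, pay
1 apple to ask which context is active ("Cue") or decide directly ("Stay").
Paying for the cue is never worth it for its immediate monetary consequences
alone — its value is informational: knowing the context lets the player take
the risky door only when it pays 9.6 on average.

## The agent

The agent is a discrete partially observed Markov decision process doing
active inference. It holds Dirichlet beliefs about the risky payout
distribution in each context and evaluates the four two-step policies
(Cue/Stay × Safe/Risky) by expected free energy **G**, which splits into
three additive streams, each with its own weight:

- **novelty** (weight `AL`) — expected information gain about the payout
  *distributions* (Dirichlet parameter learning),
- **salience** (weight `AI`) — expected information gain about the hidden
  *context* (state estimation; this is what makes the cue attractive),
- **extrinsic value** (weight `EX`) — expected log-preference of outcomes,
  proportional to apples won.

Policies are selected by a softmax over −G, and after each outcome the
Dirichlet counts are updated at learning rate `alpha`. Two baselines — a
model-free delta-rule learner and a model-based planner over point estimates
of the payouts — provide the comparison set for model recovery.

## Worked example

```python
from aif_bandit import TaskConfig, run_agent, summarize_policy_blocks

config = TaskConfig(n_trials=60, p_can_ask=1.0)
trace = run_agent({"AL": 1.0, "AI": 1.0, "EX": 1.0, "prior": 0.25, "alpha": 1.0},
                  config, seed=0)
frame = trace.to_frame()
print(summarize_policy_blocks(trace, block=20).round(2).to_string(index=False))
print("final risky estimates:",
      round(frame["est_risky_ctx1"].iloc[-1], 2),
      round(frame["est_risky_ctx2"].iloc[-1], 2))
print("mean |PE| trials 1-10 :", round(frame[frame.trial <= 10]["prediction_error"].mean(), 2))
print("mean |PE| trials 51-60:", round(frame[frame.trial > 50]["prediction_error"].mean(), 2))
```

Output:

```
 block_start  n_trials  cue_freq  risky_given_cue1  risky_given_cue2  risky_given_no_cue
           1        20      0.65              0.75              0.44                0.71
          21        20      0.55              0.50              0.20                0.67
          41        20      0.55              0.50              0.33                0.44
final risky estimates: 8.54 2.97
mean |PE| trials 1-10 : 2.52
mean |PE| trials 51-60: 0.65
```

The agent keeps buying the cue, gambles more after Cue 1 than after Cue 2,
its payout estimates approach the true means 9.6 and 2.4, and its absolute
reward prediction errors shrink as learning proceeds.

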