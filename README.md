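# gonogo

A neurocomputational model of the basal ganglia for probabilistic
stimulus–action association and reversal learning.

The package is aimed at computational neuroscientists studying how the
direct (Go) and indirect (NoGo) striatal pathways, under dopaminergic
modulation, learn *hetero-associative* tasks: every action is correct in
some context, so the agent must associate each stimulus with a different
action from probabilistic rewards and punishments, and re-associate them
when the contingencies reverse.

## The model

Each neural unit follows first-order membrane dynamics with a sigmoidal
static nonlinearity,

```
τ du_i/dt = −u_i + net_i(y),     y_i = 1 / (1 + exp(−a (u_i − c))),
```

wired into segregated action channels: sensory cortex S → striatal
Go/NoGo populations (plastic arrays `W^GS`, `W^NS`, fully connected) and
motor cortex C → Go/NoGo (plastic diagonal arrays `W^GC`, `W^NC`);
Go ⊣ GPi (direct pathway), NoGo ⊣ GPe ⊣ GPi (indirect pathway),
GPi ⊣ thalamus, a thalamo-cortical self-excitation loop that closes a
winner-takes-all competition in the motor cortex, and a shared STN unit
on the hyperdirect route that brakes the GPi under cortical conflict.

A scalar dopaminergic input `D = D_tonic + ΔD_phasic` modulates the
striatum: on Go (D1) neurons it acts as a contrast enhancer, exciting
strongly driven neurons and inhibiting weakly driven ones; on NoGo (D2)
neurons it is inhibitory. Rewards raise `D` to twice the tonic level
(`ΔD_reward = D_tonic`), punishments drop it by a factor
`ΔD_punishment = −D_drop · D_tonic` (the total may transiently go
negative). At the post-feedback steady state one of five dopamine-gated
Hebbian rules updates the four plastic arrays — pre-gated, post-gated,
mixed, ex-or covariance, or Oja — with every synapse clipped to
`[0, w_max = 0.8]`.

The distinctive ingredient is an expectancy-driven phasic-dopamine
controller: the winner-channel Go activity at the instant of feedback is
read as the expected reward probability `r = go_w(t_response)`, and

```
ΔD_reward     = [2 (1 − r)]^m · D_tonic
ΔD_punishment = −0.5 · [2 r]^m · D_tonic
```

so expected rewards evoke vanishing dopamine peaks while punishments of
confidently expected rewards evoke amplified dips — exactly the
adjustment that reversal learning needs, without manual tuning of
`D_drop`.

## Worked example

Train one agent on the two-choice task (stimuli `S1=[1,0.3]`,
`S2=[0.3,1]`, reward probabilities 0.8/0.3) and test it with frozen
weights and no phasic dopamine:

```python
import dataclasses
import numpy as np
from gonogo import (BGNetwork, DopamineConfig, LearningConfig,
                    calibrate, make_two_choice_task, run_agent)

params = calibrate(n_channels=2)          # tune basal drives + naive weights
net = BGNetwork(params, n_channels=2)
task = dataclasses.replace(make_two_choice_task(), n_epochs=100,
                           test_schedule=(1, 50, 100))
agent = run_agent(seed=42, network=net, task=task,
                  learn_cfg=LearningConfig(rule="post_post"),
                  dopa_cfg=DopamineConfig(mode="fixed", d_drop=0.5))
for epoch, report in agent.tests.items():
    t = report.totals
    print(f"epoch {epoch:>3}: first={t['first']:>2}  second={t['second']:>2}  "
          f"no-response={t['no_response']:>2}  (of {report.battery_size})")
print("final sensory->Go weights:")
print(np.round(agent.weights.w_gs, 2))
```

Output:

```
epoch   1: first=52  second=37  no-response=11  (of 100)
epoch  50: first=81  second= 3  no-response=16  (of 100)
epoch 100: first=74  second= 4  no-response=22  (of 100)
final sensory->Go weights:
[[0.48 0.15]
 [0.17 0.41]]
```

At epoch 1 the naive agent responds near chance (52 vs 37 of 100 test
trials). After training, the more frequently rewarded action dominates
(~three quarters of trials; the remainder are mostly no-responses, in
which no motor neuron reaches the 0.9 winner criterion). The sensory→Go
weight matrix shows the learned association: the principal diagonal
(stimulus element *i* → action *i*) has strengthened while the
off-diagonal entries have decayed.

Cohort-level experiments (rule comparison, punishment-drop sweeps,
dopamine-depletion sweeps, adaptive-controller suites) live in
`gonogo.experiments` and behind the `gonogo` command-line tool:

```bash
gonogo calibrate --channels 2 --out params.yaml
gonogo ddrop-sweep --out-dir results/
gonogo tonic-sweep --out-dir results/
```

Each command writes CSV summaries plus a `manifest.json` with the
configuration hash and master seed, so every cohort is reproducible.

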