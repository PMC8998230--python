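# Model and methods

## Circuit

The network models action selection in the basal ganglia with `N_c`
segregated channels (2 or 4), one per candidate action. Layers: sensory
cortex S (an input vector, length `N_s = N_c` here), motor cortex C,
striatal Go and NoGo populations (one unit per channel), GPe, GPi,
thalamus, and a single shared STN unit. Every unit obeys

    τ du/dt = −u + net(y),      y = 1 / (1 + exp(−a (u − c))),

integrated with explicit Euler steps (`dt = τ/10`). Activities are
normalized firing rates in (0, 1); `τ` and `dt` share one arbitrary
time unit, chosen so that a trial settles within ~100 τ. The sigmoid
slope is 4 for cortex, pallidum, thalamus and STN and 2 for the striatal
populations (a shallower striatal response keeps the Hebbian threshold
region wide); the common center is c = 1.

Net inputs per channel `i` (ν are fixed gains, `W` plastic weights):

    C_i   : ν_TC·Th_i − λ·Σ_{j≠i} C_j + η_i
    Go_i  : drive_i + D1 modulation,  drive_i = ν_GS·(W^GS s)_i + ν_GC·W^GC_ii·C_i
    NoGo_i: ν_NS·(W^NS s)_i + ν_NC·W^NC_ii·C_i − k_D2·max(D, 0)
    GPe_i : b_GPe − ν_EN·NoGo_i
    GPi_i : b_GPi − ν_IG·Go_i − ν_IE·GPe_i + ν_IS·STN
    Th_i  : b_Th − ν_TI·GPi_i + ν_CT·C_i − ν_CT·Σ_{j≠i} C_j
    STN   : ν_STN·Σ_j C_j

Selection works by disinhibition. At rest the GPi sits near saturation
and holds the thalamus silent; a stimulus drives the striatum through
`W^GS`, the Go population suppresses its GPi channel, the thalamus
disinhibits and closes a self-excitatory loop with its motor-cortex
channel. Cortical lateral inhibition (λ) plus a cross-channel cortical
inhibition of the thalamus (the `−ν_CT·Σ_{j≠i} C_j` term, a
reticular-style competition we found necessary for a clean single
winner) force winner-takes-all: the winning C unit exceeds 0.9 while the
losers fall near zero. Trial-frozen Gaussian noise on the motor cortex
(SD 0.2, one draw per neuron per trial) makes the naive choice a fair
coin; freezing it within the trial guarantees a well-defined steady
state. The STN sums cortical activity and diffusely excites the GPi, a
global brake that delays disinhibition while several cortical channels
are active.

## Dopamine

A scalar drive `D = D_tonic + ΔD_phasic` (basal `D_tonic = 1`)
modulates the striatum:

* **Go (D1), contrast enhancement.** Each Go unit carries a smooth
  "active" gate `g = σ(8·(drive − 0.7))` on its synaptic drive. Its
  dopamine term is `(D−1)·k_act·g − (max(D, 0.5)−1)·k_in·(1−g)`:
  above-basal dopamine excites strongly driven neurons and inhibits
  weakly driven ones; dips do the reverse. The cholinergic push–pull is
  folded into the two coefficients rather than modelled as a separate
  unit. The inactive-side term saturates at `D = 0.5`: without that
  saturation, deep dips disinhibit *unrelated* channels enough that
  their Go units cross the learning threshold during a punishment and
  bind spurious associations (ruinous with four channels).
* **NoGo (D2), uniform inhibition.** `−k_D2·max(D, 0)`: dopamine
  inhibits all NoGo units; a dip excites them by withdrawal of that
  inhibition, most strongly in the winning channel (which also receives
  cortical support). The effect saturates at `D = 0`, reading `D` as a
  receptor-mediated drive that cannot invert sign once dopamine is
  absent. Consequently NoGo activity is non-increasing in `D`, strictly
  decreasing for `D > 0`.

Phasic events: in **fixed** mode a reward sets `ΔD = +D_tonic` (the
input doubles) and a punishment `ΔD = −D_drop·D_tonic` (`D_drop` = 0.5
in basal training; 1.0 and 1.5 in the reversal sweeps; the total may go
negative). In **adaptive** mode the winner-channel Go activity at the
moment feedback is delivered is read as the expected reward probability
`r`, and

    ΔD_reward     = [2(1−r)]^m · D_tonic
    ΔD_punishment = −0.5·[2r]^m · D_tonic

with exponent `m ≥ 1` (default 2). Both reduce to the fixed basal values
at `r = 0.5` for every `m`. The bracket placement is forced by those
anchors: the alternative reading `2(1−r)^m` would give a peak of 0.5 at
`r = 0.5, m = 2`, contradicting the required equivalence with the fixed
regime. The phasic change is applied as a step at the feedback instant,
held until the network reaches its post-feedback steady state, and then
cleared.

## Plasticity

Four arrays are plastic: `W^GS`, `W^NS` (sensory → striatum, fully
connected) and `W^GC`, `W^NC` (motor cortex → striatum, strictly
diagonal; off-diagonal entries are identically zero and never trained).
One update fires per feedback event, using the post-feedback steady
state activities (striatal units post-synaptically, stimulus elements
and motor-cortex units pre-synaptically); no-response trials trigger no
dopamine transient and no plasticity. Five rule variants share the
learning factor σ and thresholds θ_PRE = θ_POST = 0.5:

| rule        | Δw = σ ·                                   | gate |
|-------------|--------------------------------------------|------|
| `pre_pre`   | (pre−θ)⁺ (post−θ)                          | pre-synaptic neuron active |
| `post_post` | (pre−θ) (post−θ)⁺                          | post-synaptic neuron active |
| `post_pre`  | pre-gated for motor afferents, post-gated for sensory | mixed |
| `exor`      | (pre−θ)(post−θ) unless both below θ        | not both silent |
| `oja`       | post (pre − post·w)                        | none (multiplicative forgetting) |

After every update each entry is clipped to `[0, w_max]` with
`w_max = 0.8`. σ = 0.02 per feedback event, calibrated once so that
two-choice post-post training reaches about three quarters correct near
epoch 100, and frozen for all experiments. NoGo populations use the same
rule and thresholds as Go.

## Tasks and protocol

An epoch presents every stimulus exactly once in random order. The
default two-choice task uses `S1 = [1, 0.3]` with reward probabilities
`[0.8, 0.3]` and `S2 = [0.3, 1]` with `[0.3, 0.8]` (variants: simple
0.9/0.2, hard 0.7/0.4); 200 training epochs. The four-choice task uses
four stimuli, each with a 1.0 in its own channel and 0.3 in its paired
channel, with probabilities 0.8/0.3/0.1/0.1 patterned the same way, for
300 epochs. (The fourth stimulus is `[0.1, 0.1, 0.3, 1.0]`; a printed
source lists its last element as 0.1, which is inconsistent with the
pattern and with rewarding action 4 at 0.8, so the patterned value is
used.) Reversal swaps the per-stimulus probability vectors (pairwise
between stimuli 1↔2 and 3↔4 in the four-choice case); applying it twice
restores the task.

A trial: integrate to steady state at tonic dopamine; detect a response
(exactly one motor unit above 0.9, all others below 0.1 — anything else
is a no-response and ends the trial); draw Bernoulli feedback with the
stimulus-action reward probability; apply the phasic dopamine step;
integrate to the new steady state; apply the Hebb rule and clip.

Test batteries run 50 trials per stimulus with frozen weights and no
phasic dopamine, with Gaussian noise (SD 0.2) on both the motor cortex
and the stimulus elements (stimuli stay clipped to [0, 1]); they count
first-choice (more frequently rewarded), second-choice, other and
no-response trials. Batteries fork from weight snapshots on independent
random substreams, so testing never perturbs training. Cohorts are 10
independently seeded agents; one master seed spawns per-agent,
per-phase integer seeds, making every suite bit-reproducible.

## Calibration

The micro-parameters are fixed by requiring the stated operating points
on the full simulator: with zero stimulus the GPe rests at half
activation and the GPi near saturation (the basal drives `b_GPe`,
`b_GPi` are solved by fixed-point iteration); on a naive trial the
winner-channel Go and NoGo settle at 0.5 before feedback (the naive
diagonal weights `W^GC_0`, `W^NC_0` are solved by secant iteration);
naive choices are 50/50 with a high response rate. Naive sensory weights
are normalized by the stimulus sum so the per-neuron drive is the same
for 2- and 4-channel topologies. Calibration is deterministic, takes a
few seconds, and is cached per topology; `gonogo calibrate` writes the
tuned parameter set to YAML for reuse.

The remaining fixed gains were tuned once, by hand, against the
qualitative behavioral repertoire: naive punishments (drop 0.5) push the
winner Go well below the 0.5 learning threshold, while after training
the same drop leaves it above threshold and only stronger drops (1.0,
1.5) depotentiate — the mechanism that makes reversal demand stronger
punishments after longer training. During a punishment the winning
cortical channel stays latched (so NoGo suppression learning remains
channel-specific) and the learned NoGo can veto the old action at choice
time through the indirect pathway, which is what ultimately produces the
behavioral switch.

## Numerical choices

Steady state is declared when every activity changes by less than 1e-4
for 10 consecutive Euler steps; trials are capped at 1200 steps (~120 τ)
and scored from the final state if the cap is hit (non-convergence is
flagged, not fatal). The stopping rule leaves ~1e-2 slack in membrane
units relative to the exact algebraic fixed point; the test suite
verifies agreement with an independent root solve at that tolerance.
The integration kernel is JIT-compiled (numba) with a pure-numpy
reference path tested for exact agreement; a full 10-agent, 600-epoch
cohort runs in seconds, so all experiments use the published problem
sizes (10 agents; the four-choice suites in the test suite use 5).

## What the protocol does and does not emulate

The synthetic tasks reproduce the probabilistic hetero-associative
structure — every action correct under some stimulus, feedback as
Bernoulli draws, reversal as contingency swaps — and the two noise
sources (cortical and test-stimulus). They do not emulate reaction
times, trial-to-trial carry-over (the network is reset between trials),
stimulus generalization beyond the two/four fixed vectors, or any
fitting to behavioral data; passing tests therefore constrain the
circuit mechanism, not quantitative human performance.

## Known limitations

* The thresholded Hebb rules can only *grow* NoGo weights (rewards gate
  their updates off), so NoGo strength is a ratchet. On long reversal
  horizons the newly correct action slowly accumulates self-suppression
  from its residual punishments, and the old action — whose Go drive is
  saturated and cannot be fully vetoed by the bounded indirect pathway —
  partially re-emerges. Prolonged two-choice reversal therefore peaks
  near 200 reversal epochs and declines afterwards, and the four-choice
  reversal relapses rather than stabilizing at a high correct rate.
* Reversal in this calibration is carried mainly by learned NoGo
  suppression plus re-binding of the newly rewarded action; the
  previously potentiated sensory→Go diagonal decays only weakly rather
  than unwinding to baseline.
* The pre-gated and ex-or rules remain competitive with the post-gated
  rules on the two-choice task at this calibration (the Oja rule fails
  clearly, and the pre-gated rule shows much larger between-agent
  variability); the circuit's response machinery is robust enough that
  their characteristic failure — depression of useful synapses early in
  learning — does not depress overt performance much.
* Dopamine depletion during training (tonic 0.6) yields near-chance
  discrimination as intended, but with a somewhat lower overall response
  rate than the model should show when tested at the restored tonic
  level.
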