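"""Probabilistic hetero-associative task protocols.

An *epoch* presents every stimulus exactly once in random order.  On
each trial the network runs to its pre-feedback steady state; if it
commits to a single action the choice is rewarded with the
stimulus-specific probability (otherwise punished), the phasic dopamine
transient is applied, the network settles again, and one Hebbian update
fires.  No-response trials receive no feedback and no plasticity.

Test batteries run with frozen weights and no phasic dopamine, with
Gaussian noise on both the motor cortex and the stimulus elements, and
count first-choice (more frequently rewarded), second-choice and
no-response trials.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dopamine import phasic_delta
from .network import NO_RESPONSE, BGNetwork
from .params import DopamineConfig, LearningConfig
from .plasticity import PlasticWeights, apply_learning_step

__all__ = [
    "TaskSpec",
    "TrialResult",
    "TestReport",
    "AgentResult",
    "default_stimulus",
    "make_two_choice_task",
    "make_four_choice_task",
    "reverse_task",
    "sample_feedback",
    "run_training_trial",
    "run_test_battery",
    "run_agent",
]

TWO_CHOICE_VARIANTS = {
    "standard": (0.8, 0.3),
    "simple": (0.9, 0.2),
    "hard": (0.7, 0.4),
}

#: default epochs at which test batteries are run during two-choice training
TWO_CHOICE_SCHEDULE = (1, 25, 50, 75, 100, 150, 200)
FOUR_CHOICE_SCHEDULE = (1, 50, 100, 150, 200, 250, 300)


def default_stimulus(n_channels: int) -> np.ndarray:
    """The first stimulus of the standard task with ``n_channels`` actions."""
    if n_channels == 2:
        return np.array([1.0, 0.3])
    if n_channels == 4:
        return np.array([1.0, 0.3, 0.1, 0.1])
    raise ValueError("supported channel counts are 2 and 4")


@dataclass
class TaskSpec:
    """Stimuli, per-stimulus reward probabilities and protocol sizes."""

    stimuli: np.ndarray        # (n_stimuli, N_s)
    reward_probs: np.ndarray   # (n_stimuli, N_c)
    n_epochs: int
    test_schedule: tuple = ()
    input_noise_sd: float = 0.2   # test-phase stimulus noise
    name: str = "task"

    def __post_init__(self) -> None:
        self.stimuli = np.atleast_2d(np.asarray(self.stimuli, float))
        self.reward_probs = np.atleast_2d(np.asarray(self.reward_probs,
                                                     float))
        if self.stimuli.shape[0] != self.reward_probs.shape[0]:
            raise ValueError("stimuli / reward_probs count mismatch")
        if ((self.reward_probs < 0) | (self.reward_probs > 1)).any():
            raise ValueError("reward probabilities must lie in [0, 1]")

    @property
    def n_stimuli(self) -> int:
        return self.stimuli.shape[0]

    @property
    def n_channels(self) -> int:
        return self.reward_probs.shape[1]

    def first_choice(self, stim_idx: int) -> int:
        """Action most frequently rewarded for this stimulus."""
        return int(self.reward_probs[stim_idx].argmax())

    def second_choice(self, stim_idx: int) -> int:
        """Second most frequently rewarded action."""
        order = np.argsort(-self.reward_probs[stim_idx], kind="stable")
        return int(order[1])


def make_two_choice_task(variant: str = "standard") -> TaskSpec:
    """Two stimuli, two actions; S1=[1,0.3] with P=[p_hi,p_lo], mirrored."""
    p_hi, p_lo = TWO_CHOICE_VARIANTS[variant]
    return TaskSpec(
        stimuli=np.array([[1.0, 0.3], [0.3, 1.0]]),
        reward_probs=np.array([[p_hi, p_lo], [p_lo, p_hi]]),
        n_epochs=200,
        test_schedule=TWO_CHOICE_SCHEDULE,
        name=f"two_choice_{variant}",
    )


def make_four_choice_task() -> TaskSpec:
    """Four stimuli, four actions, 300 training epochs, 50 tests/stimulus."""
    return TaskSpec(
        stimuli=np.array([
            [1.0, 0.3, 0.1, 0.1],
            [0.3, 1.0, 0.1, 0.1],
            [0.1, 0.1, 1.0, 0.3],
            [0.1, 0.1, 0.3, 1.0],
        ]),
        reward_probs=np.array([
            [0.8, 0.3, 0.1, 0.1],
            [0.3, 0.8, 0.1, 0.1],
            [0.1, 0.1, 0.8, 0.3],
            [0.1, 0.1, 0.3, 0.8],
        ]),
        n_epochs=300,
        test_schedule=FOUR_CHOICE_SCHEDULE,
        name="four_choice",
    )


def reverse_task(task: TaskSpec) -> TaskSpec:
    """Swap reward contingencies; applying it twice restores the task.

    Two-choice: the per-stimulus probability vectors are swapped across
    actions.  Four-choice: P1 and P2 are exchanged between S1 and S2,
    and P3 and P4 between S3 and S4.
    """
    probs = task.reward_probs.copy()
    if task.n_channels == 2:
        probs = probs[:, ::-1]
    elif task.n_channels == 4:
        probs = probs[[1, 0, 3, 2]]
    else:
        raise ValueError("supported channel counts are 2 and 4")
    return replace(task, reward_probs=probs,
                   name=task.name.removesuffix("_reversed")
                   if task.name.endswith("_reversed")
                   else task.name + "_reversed")


def sample_feedback(action: int, stim_idx: int, task: TaskSpec,
                    rng: np.random.Generator) -> bool:
    """Bernoulli feedback: True = reward, False = punishment."""
    p = task.reward_probs[stim_idx, action]
    return bool(rng.random() < p)


@dataclass
class TrialResult:
    stim_idx: int
    action: int                  # NO_RESPONSE when no single winner
    r_expected: float = np.nan   # winner Go activity at feedback time
    feedback: str = "none"       # "reward" | "punishment" | "none"
    applied_delta_d: float = 0.0
    converged: bool = True

    @property
    def responded(self) -> bool:
        return self.action != NO_RESPONSE


@dataclass
class TestReport:
    """Counts per stimulus over one test battery."""

    first: np.ndarray        # first-choice responses per stimulus
    second: np.ndarray
    other: np.ndarray        # remaining actions (four-choice case)
    no_response: np.ndarray
    n_per_stimulus: int

    @property
    def battery_size(self) -> int:
        return self.n_per_stimulus * self.first.shape[0]

    @property
    def totals(self) -> dict:
        return {
            "first": int(self.first.sum()),
            "second": int(self.second.sum()),
            "other": int(self.other.sum()),
            "no_response": int(self.no_response.sum()),
        }


def run_training_trial(network: BGNetwork, weights: PlasticWeights,
                       task: TaskSpec, stim_idx: int,
                       learn_cfg: LearningConfig, dopa_cfg: DopamineConfig,
                       rng: np.random.Generator) -> TrialResult:
    """One training trial; mutates ``weights`` when feedback is delivered."""
    p = network.params
    s = task.stimuli[stim_idx]
    noise_c = rng.normal(0.0, p.noise_sd, network.n_channels)

    state, u, conv = network.run_to_steady_state(
        s, weights, D=dopa_cfg.d_tonic, noise_c=noise_c)
    action = network.detect_response(state.cortex)
    if action == NO_RESPONSE:
        return TrialResult(stim_idx, NO_RESPONSE, converged=conv)

    r_expected = float(state.go[action])
    rewarded = sample_feedback(action, stim_idx, task, rng)
    delta_d = phasic_delta(dopa_cfg, rewarded, r_expected)

    state2, _, conv2 = network.run_to_steady_state(
        s, weights, D=dopa_cfg.d_tonic + delta_d, noise_c=noise_c, u0=u)
    apply_learning_step(weights, state2, s, learn_cfg)
    return TrialResult(stim_idx, action, r_expected,
                       "reward" if rewarded else "punishment",
                       delta_d, conv and conv2)


def run_test_battery(network: BGNetwork, weights: PlasticWeights,
                     task: TaskSpec, rng: np.random.Generator,
                     n_per_stimulus: int = 50,
                     d_tonic: float = 1.0) -> TestReport:
    """Noisy test battery with frozen weights and no phasic dopamine.

    Gaussian noise (SD ``noise_sd``) is applied to the motor cortex and
    (SD ``input_noise_sd``) to the stimulus elements, which stay clipped
    to the [0, 1] activity range.
    """
    p = network.params
    n_stim = task.n_stimuli
    first = np.zeros(n_stim, dtype=int)
    second = np.zeros(n_stim, dtype=int)
    other = np.zeros(n_stim, dtype=int)
    noresp = np.zeros(n_stim, dtype=int)

    for stim_idx in range(n_stim):
        fc = task.first_choice(stim_idx)
        sc = task.second_choice(stim_idx)
        for _ in range(n_per_stimulus):
            s = task.stimuli[stim_idx] + rng.normal(
                0.0, task.input_noise_sd, task.stimuli.shape[1])
            np.clip(s, 0.0, 1.0, out=s)
            noise_c = rng.normal(0.0, p.noise_sd, network.n_channels)
            state, _, _ = network.run_to_steady_state(
                s, weights, D=d_tonic, noise_c=noise_c)
            action = network.detect_response(state.cortex)
            if action == NO_RESPONSE:
                noresp[stim_idx] += 1
            elif action == fc:
                first[stim_idx] += 1
            elif action == sc:
                second[stim_idx] += 1
            else:
                other[stim_idx] += 1
    return TestReport(first, second, other, noresp, n_per_stimulus)


@dataclass
class AgentResult:
    """Outcome of one independently seeded training phase."""

    tests: dict                      # epoch -> TestReport
    snapshots: dict                  # epoch -> PlasticWeights
    weights: PlasticWeights          # final weights
    w_gs_trajectory: np.ndarray | None = None   # (n_epochs, N_c, N_s)
    trials: list = field(default_factory=list)


def _rng(seed_key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed_key))


def run_agent(seed: int, network: BGNetwork, task: TaskSpec,
              learn_cfg: LearningConfig, dopa_cfg: DopamineConfig,
              initial_weights: PlasticWeights | None = None,
              snapshot_epochs: tuple = (),
              n_test_per_stimulus: int = 50,
              d_tonic_test: float | None = None,
              record_weights: bool = False,
              record_trials: bool = False) -> AgentResult:
    """Run one training phase of ``task.n_epochs`` epochs from a seed.

    Deterministic given (seed, configs, initial weights).  The training
    noise stream and each scheduled test battery use independent
    sub-streams of the seed, so test batteries fork from weight
    snapshots without perturbing training.  ``d_tonic_test`` overrides
    the tonic level during test batteries only (defaults to the training
    tonic level).
    """
    params = network.params
    if initial_weights is None:
        weights = PlasticWeights.naive(
            network.n_channels, task.stimuli.shape[1], params)
    else:
        weights = initial_weights.copy()
    train_rng = _rng([seed, 0])
    d_test = dopa_cfg.d_tonic if d_tonic_test is None else d_tonic_test

    tests: dict = {}
    snaps: dict = {}
    traj = (np.empty((task.n_epochs,) + weights.w_gs.shape)
            if record_weights else None)
    trials: list = []

    for epoch in range(1, task.n_epochs + 1):
        for stim_idx in train_rng.permutation(task.n_stimuli):
            res = run_training_trial(network, weights, task, int(stim_idx),
                                     learn_cfg, dopa_cfg, train_rng)
            if record_trials:
                trials.append((epoch, res))
        if traj is not None:
            traj[epoch - 1] = weights.w_gs
        if epoch in snapshot_epochs:
            snaps[epoch] = weights.copy()
        if epoch in task.test_schedule:
            tests[epoch] = run_test_battery(
                network, weights, task, _rng([seed, 1, epoch]),
                n_test_per_stimulus, d_tonic=d_test)
    return AgentResult(tests, snaps, weights, traj, trials)
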