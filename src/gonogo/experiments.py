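"""Cohort-level experiment drivers.

Every suite runs a cohort of independently seeded agents (default 10,
as the cohort statistics require) and reports mean and standard
deviation over agents of the first-choice, second-choice and
no-response counts at each scheduled test epoch.

Reversal phases always start from per-agent weight snapshots of the
basal phase, with the reward contingencies swapped and (in fixed mode)
a configurable punishment drop factor.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import BGNetwork, calibrate
from .params import DopamineConfig, LearningConfig, NetworkParams
from .tasks import (AgentResult, TaskSpec, make_four_choice_task,
                    make_two_choice_task, reverse_task, run_agent,
                    run_test_battery)

__all__ = [
    "CohortSummary",
    "export_weight_trajectory",
    "agent_seeds",
    "run_cohort",
    "summarize",
    "compare_rules",
    "basal_cohort",
    "reversal_cohort",
    "ddrop_sweep",
    "tonic_sensitivity",
    "adaptive_control_suite",
    "calibrated_network",
]

_CAL_CACHE: dict = {}


def calibrated_network(n_channels: int,
                       params: NetworkParams | None = None) -> BGNetwork:
    """Network with basal drives / naive weights tuned for this topology.

    Calibration is deterministic, so results are cached per channel
    count (and per explicit parameter set).
    """
    key = (n_channels, None if params is None else tuple(
        dataclasses.astuple(params)))
    if key not in _CAL_CACHE:
        _CAL_CACHE[key] = BGNetwork(calibrate(params, n_channels), n_channels)
    return _CAL_CACHE[key]


def export_weight_trajectory(result: AgentResult) -> pd.DataFrame:
    """Tabular per-epoch series of the sensory-Go synapses.

    Requires the agent to have been run with ``record_weights=True``.
    Columns: epoch, array, i, j, value.
    """
    if result.w_gs_trajectory is None:
        raise ValueError("agent was run without record_weights=True")
    tr = result.w_gs_trajectory
    n_ep, nc, ns = tr.shape
    epochs, ii, jj = np.meshgrid(np.arange(1, n_ep + 1), np.arange(nc),
                                 np.arange(ns), indexing="ij")
    return pd.DataFrame({
        "epoch": epochs.ravel(), "array": "w_gs",
        "i": ii.ravel(), "j": jj.ravel(), "value": tr.ravel(),
    })


def agent_seeds(master_seed: int, phase: int, n_agents: int) -> np.ndarray:
    """Per-agent integer seeds for one experiment phase."""
    ss = np.random.SeedSequence([int(master_seed), int(phase)])
    return (ss.generate_state(n_agents) & 0x7FFFFFFF).astype(np.int64)


@dataclass
class CohortSummary:
    """Mean/SD over agents of the test-battery counts per epoch."""

    table: pd.DataFrame   # columns: epoch, first_mean, first_sd, ...
    battery_size: int

    def at_epoch(self, epoch: int) -> pd.Series:
        row = self.table[self.table.epoch == epoch]
        if row.empty:
            raise KeyError(f"no test battery at epoch {epoch}")
        return row.iloc[0]


def summarize(results: list[AgentResult]) -> CohortSummary:
    epochs = sorted(results[0].tests)
    rows = []
    size = results[0].tests[epochs[0]].battery_size if epochs else 0
    for e in epochs:
        counts = {k: np.array([r.tests[e].totals[k] for r in results])
                  for k in ("first", "second", "other", "no_response")}
        row = {"epoch": e}
        for k, v in counts.items():
            row[f"{k}_mean"] = v.mean()
            row[f"{k}_sd"] = v.std(ddof=1) if len(v) > 1 else 0.0
        rows.append(row)
    return CohortSummary(pd.DataFrame(rows), size)


def run_cohort(network: BGNetwork, task: TaskSpec,
               learn_cfg: LearningConfig, dopa_cfg: DopamineConfig,
               n_agents: int = 10, master_seed: int = 1, phase: int = 0,
               initial_weights: list | None = None,
               snapshot_epochs: tuple = (),
               d_tonic_test: float | None = None,
               record_weights: bool = False) -> list[AgentResult]:
    seeds = agent_seeds(master_seed, phase, n_agents)
    out = []
    for i, seed in enumerate(seeds):
        w0 = None if initial_weights is None else initial_weights[i]
        out.append(run_agent(int(seed), network, task, learn_cfg, dopa_cfg,
                             initial_weights=w0,
                             snapshot_epochs=snapshot_epochs,
                             d_tonic_test=d_tonic_test,
                             record_weights=record_weights))
    return out


def basal_cohort(n_agents: int = 10, master_seed: int = 1,
                 n_epochs: int = 200, rule: str = "post_post",
                 variant: str = "standard", d_tonic: float = 1.0,
                 snapshot_epochs: tuple = (50, 75),
                 test_schedule: tuple | None = None,
                 d_tonic_test: float | None = None,
                 params: NetworkParams | None = None,
                 record_weights: bool = False):
    """Two-choice basal training cohort; returns (results, summary)."""
    task = make_two_choice_task(variant)
    schedule = (tuple(e for e in task.test_schedule if e <= n_epochs)
                if test_schedule is None else test_schedule)
    task = dataclasses.replace(task, n_epochs=n_epochs,
                               test_schedule=schedule)
    net = calibrated_network(2, params)
    learn = LearningConfig(rule=rule)
    dopa = DopamineConfig(mode="fixed", d_tonic=d_tonic, d_drop=0.5)
    res = run_cohort(net, task, learn, dopa, n_agents, master_seed, phase=0,
                     snapshot_epochs=snapshot_epochs,
                     d_tonic_test=d_tonic_test,
                     record_weights=record_weights)
    return res, summarize(res)


def reversal_cohort(basal_results: list[AgentResult], snapshot_epoch: int,
                    d_drop: float, n_epochs: int = 200,
                    master_seed: int = 1, phase: int = 1,
                    rule: str = "post_post", variant: str = "standard",
                    mode: str = "fixed", m: float = 2.0,
                    test_schedule: tuple | None = None,
                    params: NetworkParams | None = None,
                    record_weights: bool = False):
    """Two-choice reversal from per-agent basal snapshots.

    In the returned reports "first choice" refers to the *new*
    contingencies, i.e. the now-correct action; the perseverative
    (previously rewarded) action is counted as "second".
    """
    task = reverse_task(make_two_choice_task(variant))
    schedule = (tuple(e for e in (25, 50, 75, 100, 125, 150, 175, 200, 250,
                                  300, 325, 350, 400) if e <= n_epochs)
                if test_schedule is None else test_schedule)
    task = dataclasses.replace(task, n_epochs=n_epochs,
                               test_schedule=schedule)
    net = calibrated_network(2, params)
    learn = LearningConfig(rule=rule)
    dopa = DopamineConfig(mode=mode, d_drop=d_drop, m=m)
    w0 = [r.snapshots[snapshot_epoch] for r in basal_results]
    res = run_cohort(net, task, learn, dopa,
                     n_agents=len(basal_results), master_seed=master_seed,
                     phase=phase, initial_weights=w0,
                     record_weights=record_weights)
    return res, summarize(res)


def compare_rules(n_agents: int = 10, n_epochs: int = 100,
                  master_seed: int = 1, rules: tuple = LearningConfig.VALID_RULES,
                  variant: str = "standard",
                  params: NetworkParams | None = None) -> dict:
    """Five-rule comparison on identical seed sets (two-choice task)."""
    out = {}
    for rule in rules:
        _, summary = basal_cohort(n_agents, master_seed, n_epochs, rule,
                                  variant, snapshot_epochs=(),
                                  test_schedule=(1, 50, 75, n_epochs),
                                  params=params)
        out[rule] = summary
    return out


def ddrop_sweep(n_agents: int = 10, master_seed: int = 1,
                reversal_epochs: tuple = (50, 75),
                drops: tuple = (0.5, 1.0, 1.5),
                reversal_length: int = 200,
                params: NetworkParams | None = None) -> pd.DataFrame:
    """Reversal performance grid over (basal length, punishment drop).

    "correct" is the newly rewarded action after the contingency swap.
    Returns one row per configuration with the terminal battery means.
    """
    basal, _ = basal_cohort(n_agents, master_seed,
                            n_epochs=max(reversal_epochs),
                            snapshot_epochs=tuple(reversal_epochs),
                            test_schedule=(), params=params)
    rows = []
    phase = 10
    for rev_epoch in reversal_epochs:
        for drop in drops:
            phase += 1
            _, summary = reversal_cohort(
                basal, rev_epoch, drop, reversal_length, master_seed,
                phase=phase, test_schedule=(reversal_length,),
                params=params)
            row = summary.at_epoch(reversal_length)
            rows.append({"reversal_after": rev_epoch, "d_drop": drop,
                         "correct_mean": row.first_mean,
                         "correct_sd": row.first_sd,
                         "perseverative_mean": row.second_mean,
                         "no_response_mean": row.no_response_mean})
    return pd.DataFrame(rows)


def tonic_sensitivity(d_values: tuple = (1.0, 0.9, 0.8, 0.7, 0.6),
                      n_agents: int = 10, master_seed: int = 1,
                      n_epochs: int = 100,
                      params: NetworkParams | None = None) -> pd.DataFrame:
    """Dopamine-depletion sweep on two-choice training.

    Two scenarios per tonic level: depleted training with the normal
    level restored at test (medication analogue), and depletion in both
    phases.  Phasic feedback always scales with the training tonic
    level (peak = +D_tonic, dip = 0.5 D_tonic).
    """
    net = calibrated_network(2, params)
    rows = []
    for i, d in enumerate(d_values):
        res, _ = basal_cohort(n_agents, master_seed, n_epochs,
                              d_tonic=d, snapshot_epochs=(n_epochs,),
                              test_schedule=(), params=params)
        for mode, d_test in (("train_only_depleted", 1.0),
                             ("train_and_test_depleted", d)):
            firsts, seconds, nrs = [], [], []
            for j, r in enumerate(res):
                seed = int(agent_seeds(master_seed, 0, n_agents)[j])
                rng = np.random.default_rng(
                    np.random.SeedSequence([seed, 3, i]))
                rep = run_test_battery(net, r.snapshots[n_epochs],
                                       make_two_choice_task(), rng,
                                       d_tonic=d_test)
                firsts.append(rep.totals["first"])
                seconds.append(rep.totals["second"])
                nrs.append(rep.totals["no_response"])
            rows.append({"d_tonic": d, "mode": mode,
                         "first_mean": np.mean(firsts),
                         "first_sd": np.std(firsts, ddof=1),
                         "second_mean": np.mean(seconds),
                         "no_response_mean": np.mean(nrs)})
    return pd.DataFrame(rows)


def adaptive_control_suite(m: float = 2.0, n_agents: int = 10,
                           master_seed: int = 1,
                           tasks: tuple = ("two_choice",),
                           reversal_after: int = 50,
                           reversal_length: int = 200,
                           params: NetworkParams | None = None) -> dict:
    """Basal + reversal runs with the expectancy-driven dopamine controller.

    Replaces the manually tuned drop factor with the adaptive phasic
    rule (exponent ``m``) in both phases; report format matches the
    fixed-mode suites.
    """
    out = {}
    for name in tasks:
        if name == "two_choice":
            task = make_two_choice_task()
            net = calibrated_network(2, params)
        elif name == "four_choice":
            task = make_four_choice_task()
            net = calibrated_network(4, params)
        else:
            raise ValueError(f"unknown task {name!r}")
        learn = LearningConfig(rule="post_post")
        dopa = DopamineConfig(mode="adaptive", m=m)
        basal_task = dataclasses.replace(
            task, n_epochs=reversal_after,
            test_schedule=(1, reversal_after))
        basal = run_cohort(net, basal_task, learn, dopa, n_agents,
                           master_seed, phase=40,
                           snapshot_epochs=(reversal_after,))
        rev_task = dataclasses.replace(
            reverse_task(task), n_epochs=reversal_length,
            test_schedule=tuple(e for e in (50, 100, 150, 200, 300, 400)
                                if e <= reversal_length))
        rev = run_cohort(net, rev_task, learn, dopa, n_agents,
                         master_seed, phase=41,
                         initial_weights=[r.snapshots[reversal_after]
                                          for r in basal])
        out[name] = {"basal": summarize(basal), "reversal": summarize(rev)}
    return out
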