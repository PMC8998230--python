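"""Phasic dopamine control: fixed peaks/dips and the expectancy-driven
adaptive controller.

The dopaminergic input is ``D = D_tonic + dD_phasic`` at all times; it
may transiently go negative during a strong dip (D is an effective
receptor-mediated drive, not a concentration).

In fixed mode a reward doubles the input (``dD = +D_tonic``) and a
punishment subtracts ``D_drop * D_tonic``.  In adaptive mode the phasic
change is computed from the *reward expectancy* — the winner-channel Go
activity read out at the instant feedback is delivered, interpreted as
the agent's running estimate of the reward probability:

    dD_reward     = [2 (1 - r)]^m * D_tonic
    dD_punishment = -0.5 * [2 r]^m * D_tonic

Both reduce exactly to the fixed basal values at r = 0.5 for any
exponent m, so the controller is a strict generalization of the fixed
regime: expected rewards evoke vanishing peaks, expected-reward
punishments evoke amplified dips — which is precisely what flexible
reversal learning needs.
"""
from __future__ import annotations

from .params import DopamineConfig

__all__ = [
    "phasic_fixed_reward",
    "phasic_fixed_punishment",
    "expected_reward",
    "phasic_adaptive_reward",
    "phasic_adaptive_punishment",
    "phasic_delta",
]


def phasic_fixed_reward(d_tonic: float) -> float:
    """Fixed reward peak: the input is raised to twice the tonic level."""
    return float(d_tonic)


def phasic_fixed_punishment(d_tonic: float, d_drop: float) -> float:
    """Fixed punishment dip, scaled by the drop factor (may exceed 1)."""
    if d_drop < 0:
        raise ValueError("d_drop must be non-negative")
    return -float(d_drop) * float(d_tonic)


def expected_reward(winner_go_activity: float) -> float:
    """Reward expectancy carried by the winner Go neuron at feedback time.

    The activity is already normalized to [0, 1] so it is read directly
    as a probability estimate.
    """
    r = float(winner_go_activity)
    if not 0.0 <= r <= 1.0:
        raise ValueError("winner Go activity must lie in [0, 1]")
    return r


def phasic_adaptive_reward(r_expected: float, m: float,
                           d_tonic: float) -> float:
    """Expectancy-modulated reward peak, strictly decreasing in r."""
    r = expected_reward(r_expected)
    if m < 1:
        raise ValueError("exponent m must be >= 1")
    return (2.0 * (1.0 - r)) ** m * float(d_tonic)


def phasic_adaptive_punishment(r_expected: float, m: float,
                               d_tonic: float) -> float:
    """Expectancy-modulated dip, magnitude strictly increasing in r."""
    r = expected_reward(r_expected)
    if m < 1:
        raise ValueError("exponent m must be >= 1")
    return -0.5 * (2.0 * r) ** m * float(d_tonic)


def phasic_delta(cfg: DopamineConfig, rewarded: bool,
                 r_expected: float) -> float:
    """Phasic change for one feedback event under the configured regime."""
    if cfg.mode == "fixed":
        if rewarded:
            return phasic_fixed_reward(cfg.d_tonic)
        return phasic_fixed_punishment(cfg.d_tonic, cfg.d_drop)
    if rewarded:
        return phasic_adaptive_reward(r_expected, cfg.m, cfg.d_tonic)
    return phasic_adaptive_punishment(r_expected, cfg.m, cfg.d_tonic)
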