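"""Model parameters and plain-text (YAML) configuration handling.

All quantities are dimensionless except the membrane time constant ``tau``
and the integration step ``dt``, which share one arbitrary time unit.
Neuron activities are normalized firing rates in [0, 1].
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "NetworkParams",
    "DopamineConfig",
    "LearningConfig",
    "load_params",
    "save_params",
]


@dataclass
class NetworkParams:
    """Fixed (non-plastic) parameters of the firing-rate network.

    The defaults are calibrated so that, with two channels and naive
    plastic weights:

    * at rest (zero stimulus, basal dopamine) cortex, thalamus and
      striatum are silent, GPe sits near half activation and GPi near
      its upper saturation;
    * a single suprathreshold stimulus drives exactly one motor-cortex
      channel above 0.9 through the thalamo-cortical loop, and the
      winner-channel Go and NoGo neurons settle near 0.5 before any
      feedback.
    """

    # integration
    tau: float = 10.0          # membrane time constant (time units)
    dt: float = 1.0            # Euler step; dt = tau / 10
    max_steps: int = 1200      # trial cap, ~120 tau
    ss_tol: float = 1e-4       # per-neuron steady-state tolerance
    ss_window: int = 10        # consecutive sub-tolerance steps required

    # sigmoid static nonlinearity, y = 1 / (1 + exp(-a (u - c)))
    a_fast: float = 4.0        # slope: cortex, pallidum, thalamus, STN
    a_striatum: float = 2.0    # slope: Go / NoGo populations
    center: float = 1.0        # common sigmoid center

    # fixed connection gains (dimensionless)
    nu_gs: float = 2.1         # sensory cortex -> Go (scales W^GS)
    nu_ns: float = 4.0         # sensory cortex -> NoGo (scales W^NS)
    nu_gc: float = 0.8         # motor cortex -> Go (scales W^GC)
    nu_nc: float = 1.6         # motor cortex -> NoGo (scales W^NC)
    nu_en: float = 0.8         # NoGo -| GPe
    nu_ig: float = 6.5         # Go -| GPi
    nu_ie: float = 6.5         # GPe -| GPi
    nu_is: float = 0.5         # STN -> GPi (hyperdirect)
    nu_stn: float = 1.0        # summed cortex -> STN
    nu_ti: float = 5.0         # GPi -| thalamus
    nu_ct: float = 4.2         # cortex -> thalamus
    nu_tc: float = 1.7         # thalamus -> cortex (self-excitation loop)
    lateral: float = 1.0       # cortical lateral inhibition strength
    lateral_thal: float = 4.2  # cross-channel cortical inhibition of thalamus

    # basal drives (calibrated; GPe/GPi/thalamic operating points)
    b_gpe: float = 1.04        # GPe basal drive -> resting GPe ~ 0.5
    b_gpi: float = 2.77        # GPi basal drive -> resting GPi ~ 0.95
    b_thal: float = 3.2        # thalamic drive; sets loop-closing threshold

    # dopaminergic modulation (D1 contrast enhancement, D2 inhibition)
    k_d1_act: float = 0.75     # D1 gain on strongly driven Go neurons
    k_d1_inact: float = 1.0    # D1 gain (inhibitory) on weakly driven Go
    k_d2: float = 1.2          # D2 inhibitory gain on all NoGo neurons
    gate_slope: float = 8.0    # steepness of the Go "active" gate
    gate_center: float = 0.7   # synaptic-drive level separating active/inactive

    # naive plastic-weight initialization (channel- and stimulus-symmetric)
    w_gs0: float = 0.235
    w_ns0: float = 0.20
    w_gc0: float = 0.60
    w_nc0: float = 0.60

    # trial noise and response criterion
    noise_sd: float = 0.2      # motor-cortex (and test-stimulus) Gaussian SD
    response_hi: float = 0.9   # winner criterion on motor cortex
    response_lo: float = 0.1   # "close to zero" criterion for losers

    def validate(self) -> None:
        if not self.dt < self.tau:
            raise ValueError("dt must be smaller than tau")
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and not np.isfinite(v):
                raise ValueError(f"non-finite parameter {f.name}")


@dataclass
class DopamineConfig:
    """Dopaminergic regime for one experiment phase.

    mode "fixed": reward peak = +d_tonic, punishment dip = -d_drop * d_tonic.
    mode "adaptive": peak and dip are computed from the reward expectancy
    (winner-Go activity at feedback time) with exponent ``m``.
    """

    mode: str = "fixed"        # "fixed" | "adaptive"
    d_tonic: float = 1.0
    d_drop: float = 0.5
    m: float = 2.0

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "adaptive"):
            raise ValueError(f"unknown dopamine mode {self.mode!r}")
        if self.d_drop < 0:
            raise ValueError("d_drop must be non-negative")
        if self.mode == "adaptive" and self.m < 1:
            raise ValueError("expectancy exponent m must be >= 1")


@dataclass
class LearningConfig:
    """Hebbian rule selection and learning constants."""

    rule: str = "post_post"    # pre_pre | post_post | post_pre | exor | oja
    sigma: float = 0.02        # slow learning factor, per feedback event
    theta_pre: float = 0.5
    theta_post: float = 0.5
    w_max: float = 0.8         # synaptic saturation

    VALID_RULES = ("pre_pre", "post_post", "post_pre", "exor", "oja")

    def __post_init__(self) -> None:
        if self.rule not in self.VALID_RULES:
            raise ValueError(f"unknown learning rule {self.rule!r}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (0 < self.theta_pre < 1 and 0 < self.theta_post < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if not (0 < self.w_max <= 1):
            raise ValueError("w_max must lie in (0, 1]")


def save_params(path: str | Path, params: NetworkParams) -> None:
    """Serialize a (possibly calibrated) parameter set to YAML."""
    data = {k: (int(v) if isinstance(v, (int, np.integer)) and
                not isinstance(v, bool) else float(v))
            for k, v in dataclasses.asdict(params).items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_params(path: str | Path) -> NetworkParams:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    known = {f.name for f in dataclasses.fields(NetworkParams)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    p = NetworkParams(**data)
    p.validate()
    return p
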