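"""Dopamine-gated Hebbian plasticity of the corticostriatal synapses.

Four arrays are trainable: W^GS and W^NS (sensory cortex to Go/NoGo,
fully connected) and W^GC and W^NC (motor cortex to Go/NoGo, diagonal —
channels are segregated).  A weight update fires only on trials that
received feedback, at the post-feedback steady state, and every entry is
clipped to [0, w_max] afterwards.

Five rule variants are provided.  All the thresholded rules multiply the
threshold-subtracted pre- and post-synaptic activities; they differ in
where the "positive part" gate sits, i.e. in which neuron must be active
for the update to fire at all:

================  ====================================================
pre_pre           gate on the pre-synaptic term
post_post         gate on the post-synaptic (striatal) term
post_pre          gate on pre for motor-cortex afferents, on post for
                  sensory afferents
exor              plain covariance unless both neurons are silent
oja               threshold-free Hebb with multiplicative forgetting
================  ====================================================
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import LearningConfig, NetworkParams

__all__ = [
    "PlasticWeights",
    "hebb_pre_pre",
    "hebb_post_post",
    "hebb_post_pre",
    "hebb_exor",
    "hebb_oja",
    "clip_weights",
    "apply_learning_step",
]


@dataclass
class PlasticWeights:
    """The four trainable synapse arrays.

    ``w_gs``/``w_ns`` have shape (N_c, N_s); ``w_gc``/``w_nc`` are
    (N_c, N_c) and strictly diagonal — their off-diagonal entries are
    identically zero and never trained.
    """

    w_gs: np.ndarray
    w_ns: np.ndarray
    w_gc: np.ndarray
    w_nc: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.w_gs.shape[0]

    @classmethod
    def naive(cls, n_channels: int, n_sensory: int,
              params: NetworkParams) -> "PlasticWeights":
        """Channel- and stimulus-symmetric initialization.

        Every sensory synapse starts at the same value, so no action is
        preferentially selected and the stimulus elements are initially
        interchangeable.
        """
        p = params
        return cls(
            w_gs=np.full((n_channels, n_sensory), p.w_gs0),
            w_ns=np.full((n_channels, n_sensory), p.w_ns0),
            w_gc=np.eye(n_channels) * p.w_gc0,
            w_nc=np.eye(n_channels) * p.w_nc0,
        )

    def copy(self) -> "PlasticWeights":
        return PlasticWeights(self.w_gs.copy(), self.w_ns.copy(),
                              self.w_gc.copy(), self.w_nc.copy())


def _pos(x):
    return np.maximum(x, 0.0)


def hebb_pre_pre(pre, post, cfg: LearningConfig):
    """dW = sigma * (pre - theta_PRE)^+ * (post - theta_POST)."""
    pre, post = np.asarray(pre, float), np.asarray(post, float)
    return cfg.sigma * _pos(pre - cfg.theta_pre) * (post - cfg.theta_post)


def hebb_post_post(pre, post, cfg: LearningConfig):
    """dW = sigma * (pre - theta_PRE) * (post - theta_POST)^+.

    The update fires only when the post-synaptic striatal neuron is
    active (above threshold).
    """
    pre, post = np.asarray(pre, float), np.asarray(post, float)
    return cfg.sigma * (pre - cfg.theta_pre) * _pos(post - cfg.theta_post)


def hebb_post_pre(pre, post, upstream: str, cfg: LearningConfig):
    """Mixed rule: pre-gated for motor-cortex afferents, post-gated for
    sensory afferents."""
    if upstream == "motor":
        return hebb_pre_pre(pre, post, cfg)
    if upstream == "sensory":
        return hebb_post_post(pre, post, cfg)
    raise ValueError(f"unknown upstream layer {upstream!r}")


def hebb_exor(pre, post, cfg: LearningConfig):
    """Covariance rule, zeroed only when both neurons are below threshold."""
    pre, post = np.asarray(pre, float), np.asarray(post, float)
    dw = cfg.sigma * (pre - cfg.theta_pre) * (post - cfg.theta_post)
    gate = (pre >= cfg.theta_pre) | (post >= cfg.theta_post)
    return np.where(gate, dw, 0.0)


def hebb_oja(pre, post, w, cfg: LearningConfig):
    """Threshold-free Hebb with a forgetting term: sigma*post*(pre - post*w)."""
    pre, post, w = (np.asarray(pre, float), np.asarray(post, float),
                    np.asarray(w, float))
    return cfg.sigma * post * (pre - post * w)


def clip_weights(w: PlasticWeights, w_max: float) -> PlasticWeights:
    """Clamp every synapse to [0, w_max] in place; returns the same object."""
    for arr in (w.w_gs, w.w_ns, w.w_gc, w.w_nc):
        np.clip(arr, 0.0, w_max, out=arr)
    return w


def _delta(rule: str, pre: np.ndarray, post: np.ndarray, w: np.ndarray,
           upstream: str, cfg: LearningConfig) -> np.ndarray:
    """Update matrix for one array: dW[i, j] = rule(pre_j, post_i)."""
    pj, pi = pre[None, :], post[:, None]
    if rule == "pre_pre":
        return hebb_pre_pre(pj, pi, cfg)
    if rule == "post_post":
        return hebb_post_post(pj, pi, cfg)
    if rule == "post_pre":
        return hebb_post_pre(pj, pi, upstream, cfg)
    if rule == "exor":
        return hebb_exor(pj, pi, cfg)
    if rule == "oja":
        return hebb_oja(pj, pi, w, cfg)
    raise ValueError(f"unknown learning rule {rule!r}")


def apply_learning_step(weights: PlasticWeights, state, stimulus,
                        cfg: LearningConfig) -> PlasticWeights:
    """One Hebbian update of all four arrays, then saturation clipping.

    ``state`` is the post-feedback steady state: the striatal Go/NoGo
    activities act post-synaptically, the stimulus elements and motor
    cortex pre-synaptically.  The diagonal structure of W^GC/W^NC is
    preserved by masking.  Updates the arrays in place and returns the
    object.  Callers must not invoke this on no-response trials (no
    feedback means no dopamine transient, hence no plasticity).
    """
    s = np.asarray(stimulus, float)
    n = weights.n_channels
    eye = np.eye(n, dtype=bool)
    rule = cfg.rule

    weights.w_gs += _delta(rule, s, state.go, weights.w_gs, "sensory", cfg)
    weights.w_ns += _delta(rule, s, state.nogo, weights.w_ns, "sensory", cfg)
    dgc = _delta(rule, state.cortex, state.go, weights.w_gc, "motor", cfg)
    dnc = _delta(rule, state.cortex, state.nogo, weights.w_nc, "motor", cfg)
    weights.w_gc[eye] += dgc[eye]
    weights.w_nc[eye] += dnc[eye]
    return clip_weights(weights, cfg.w_max)
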