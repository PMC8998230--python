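"""Firing-rate dynamics of the basal-ganglia action-selection circuit.

The circuit implements segregated action channels through sensory cortex
(S), motor cortex (C), striatal Go/NoGo populations, GPe, GPi and
thalamus, plus a single shared subthalamic (STN) unit fed by summed
cortical activity (the hyperdirect conflict brake).  Every unit obeys a
first-order membrane equation integrated with explicit Euler steps and a
sigmoidal static nonlinearity, so all activities live in (0, 1).

Action selection works by disinhibition: an active Go population
suppresses its GPi channel, which releases the thalamus; the thalamic
unit then closes a self-excitatory loop with its motor-cortex channel.
Combined with cortical lateral inhibition this yields winner-takes-all
competition, with trial-frozen Gaussian noise on the motor cortex
breaking symmetry.

Dopamine enters as a scalar drive ``D``: on Go (D1) neurons it acts as a
contrast enhancer — excitatory above basal level on strongly driven
neurons, inhibitory on weakly driven ones (the cholinergic push-pull is
folded into the gains); on NoGo (D2) neurons it is uniformly inhibitory.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from numba import njit

from .params import NetworkParams
from .plasticity import PlasticWeights

__all__ = [
    "LayerActivity",
    "BGNetwork",
    "sigmoid_activation",
    "calibrate",
]

NO_RESPONSE = -1


def sigmoid_activation(u, slope: float = 4.0, center: float = 1.0):
    """Static sigmoid mapping membrane state to activity in (0, 1).

    Value 0.5 at ``center``; saturates to 0 and 1 at the extremes.
    """
    z = slope * (np.asarray(u, dtype=float) - center)
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500.0, 500.0)))


@dataclass
class LayerActivity:
    """Per-layer activity vectors (normalized firing rates in [0, 1])."""

    s: np.ndarray        # sensory input actually applied (length N_s)
    cortex: np.ndarray   # motor cortex, length N_c
    go: np.ndarray
    nogo: np.ndarray
    gpe: np.ndarray
    gpi: np.ndarray
    thalamus: np.ndarray
    stn: float

    @property
    def n_channels(self) -> int:
        return self.cortex.shape[0]


# ---------------------------------------------------------------------------
# fast Euler integration (numba)
# ---------------------------------------------------------------------------

# packed fixed-parameter vector layout for the jitted kernel
_P_FIELDS = (
    "tau", "dt", "a_fast", "a_striatum", "center",
    "nu_en", "nu_ig", "nu_ie", "nu_is", "nu_stn",
    "nu_ti", "nu_ct", "nu_tc", "lateral", "lateral_thal",
    "b_gpe", "b_gpi", "b_thal",
    "k_d1_act", "k_d1_inact", "k_d2", "gate_slope", "gate_center",
    "ss_tol",
)


def _pack(p: NetworkParams) -> np.ndarray:
    return np.array([getattr(p, f) for f in _P_FIELDS], dtype=np.float64)


@njit(cache=True)
def _integrate(u, sens_g, sens_n, wgc, wnc, noise_c, D, pv, max_steps,
               ss_window):  # pragma: no cover - exercised via wrapper
    (tau, dt, a_fast, a_str, center,
     nu_en, nu_ig, nu_ie, nu_is, nu_stn,
     nu_ti, nu_ct, nu_tc, lateral, lat_t,
     b_gpe, b_gpi, b_thal,
     k_act, k_in, k_d2, g_slope, g_center,
     tol) = (pv[0], pv[1], pv[2], pv[3], pv[4], pv[5], pv[6], pv[7], pv[8],
             pv[9], pv[10], pv[11], pv[12], pv[13], pv[14], pv[15], pv[16],
             pv[17], pv[18], pv[19], pv[20], pv[21], pv[22], pv[23])
    n = wgc.shape[0]
    m = 6 * n + 1
    y = np.empty(m)
    y_prev = np.empty(m)
    net = np.empty(m)
    k = dt / tau
    dD = D - 1.0
    d_pos = D if D > 0.0 else 0.0   # D2 inhibition saturates at zero dopamine
    dD_in = (D if D > 0.5 else 0.5) - 1.0   # inactive-D1 term saturates in dips

    for i in range(m):
        a = a_str if n <= i < 3 * n else a_fast
        y[i] = 1.0 / (1.0 + np.exp(-a * (u[i] - center)))

    ok = 0
    steps = 0
    for step in range(max_steps):
        sum_c = 0.0
        for i in range(n):
            sum_c += y[i]
        y_stn = y[6 * n]
        for i in range(n):
            yc = y[i]
            drive_g = sens_g[i] + wgc[i] * yc
            gate = 1.0 / (1.0 + np.exp(-g_slope * (drive_g - g_center)))
            net[i] = nu_tc * y[5 * n + i] - lateral * (sum_c - yc) + noise_c[i]
            net[n + i] = (drive_g + dD * k_act * gate
                          - dD_in * k_in * (1.0 - gate))
            net[2 * n + i] = sens_n[i] + wnc[i] * yc - k_d2 * d_pos
            net[3 * n + i] = b_gpe - nu_en * y[2 * n + i]
            net[4 * n + i] = (b_gpi - nu_ig * y[n + i] - nu_ie * y[3 * n + i]
                              + nu_is * y_stn)
            net[5 * n + i] = (b_thal - nu_ti * y[4 * n + i]
                              + nu_ct * yc - lat_t * (sum_c - yc))
        net[6 * n] = nu_stn * sum_c

        dmax = 0.0
        for i in range(m):
            u[i] += k * (net[i] - u[i])
            a = a_str if n <= i < 3 * n else a_fast
            y_prev[i] = y[i]
            y[i] = 1.0 / (1.0 + np.exp(-a * (u[i] - center)))
            d = abs(y[i] - y_prev[i])
            if d > dmax:
                dmax = d
        steps = step + 1
        if dmax < tol:
            ok += 1
            if ok >= ss_window:
                return u, y, steps, True
        else:
            ok = 0
    return u, y, steps, False


class BGNetwork:
    """Simulator for one basal-ganglia circuit with ``n_channels`` actions.

    The plastic corticostriatal weights are supplied per call, so a
    single network object can serve an entire training run.
    """

    def __init__(self, params: NetworkParams | None = None,
                 n_channels: int = 2):
        self.params = params or NetworkParams()
        self.params.validate()
        self.n_channels = int(n_channels)
        self._pv = _pack(self.params)

    # -- state helpers ------------------------------------------------------

    def zero_state(self) -> np.ndarray:
        """Membrane vector before any input (deep rest)."""
        return np.zeros(6 * self.n_channels + 1)

    def _slope_vec(self) -> np.ndarray:
        n = self.n_channels
        a = np.full(6 * n + 1, self.params.a_fast)
        a[n:3 * n] = self.params.a_striatum
        return a

    def _unpack(self, y: np.ndarray, s: np.ndarray) -> LayerActivity:
        n = self.n_channels
        return LayerActivity(
            s=np.asarray(s, dtype=float).copy(),
            cortex=y[0:n].copy(), go=y[n:2 * n].copy(),
            nogo=y[2 * n:3 * n].copy(), gpe=y[3 * n:4 * n].copy(),
            gpi=y[4 * n:5 * n].copy(), thalamus=y[5 * n:6 * n].copy(),
            stn=float(y[6 * n]),
        )

    def _drives(self, s: np.ndarray, w: PlasticWeights):
        p = self.params
        s = np.asarray(s, dtype=float)
        if s.shape[0] != w.w_gs.shape[1]:
            raise ValueError("stimulus length does not match sensory weights")
        if w.n_channels != self.n_channels:
            raise ValueError("weight arrays do not match the channel count")
        sens_g = p.nu_gs * (w.w_gs @ s)
        sens_n = p.nu_ns * (w.w_ns @ s)
        wgc = p.nu_gc * np.diag(w.w_gc).copy()
        wnc = p.nu_nc * np.diag(w.w_nc).copy()
        return sens_g, sens_n, wgc, wnc

    # -- public dynamics ----------------------------------------------------

    def net_inputs(self, y: np.ndarray, s: np.ndarray, w: PlasticWeights,
                   D: float, noise_c: np.ndarray) -> np.ndarray:
        """Instantaneous net input to every unit (reference implementation).

        Pure-numpy mirror of the jitted kernel; used by the slow stepping
        path and by equivalence tests against it.
        """
        p = self.params
        n = self.n_channels
        sens_g, sens_n, wgc, wnc = self._drives(s, w)
        yc, yg, yn = y[0:n], y[n:2 * n], y[2 * n:3 * n]
        ye, yi, yt = y[3 * n:4 * n], y[4 * n:5 * n], y[5 * n:6 * n]
        y_stn = y[6 * n]
        drive_g = sens_g + wgc * yc
        gate = 1.0 / (1.0 + np.exp(-p.gate_slope * (drive_g - p.gate_center)))
        net = np.empty_like(y)
        net[0:n] = (p.nu_tc * yt - p.lateral * (yc.sum() - yc) + noise_c)
        net[n:2 * n] = (drive_g + (D - 1.0) * p.k_d1_act * gate
                        + (max(D, 0.5) - 1.0) * -p.k_d1_inact * (1.0 - gate))
        net[2 * n:3 * n] = sens_n + wnc * yc - p.k_d2 * max(D, 0.0)
        net[3 * n:4 * n] = p.b_gpe - p.nu_en * yn
        net[4 * n:5 * n] = (p.b_gpi - p.nu_ig * yg - p.nu_ie * ye
                            + p.nu_is * y_stn)
        net[5 * n:6 * n] = (p.b_thal - p.nu_ti * yi + p.nu_ct * yc
                            - p.lateral_thal * (yc.sum() - yc))
        net[6 * n] = p.nu_stn * yc.sum()
        return net

    def step(self, u: np.ndarray, s: np.ndarray, w: PlasticWeights,
             D: float, noise_c: np.ndarray, dt: float | None = None
             ) -> np.ndarray:
        """One explicit Euler step of the membrane equations.

        Returns the new membrane vector; with ``dt == 0`` the state is
        unchanged.  Activities derived from it stay within (0, 1) by
        construction of the sigmoid.
        """
        p = self.params
        dt = p.dt if dt is None else dt
        a = self._slope_vec()
        y = 1.0 / (1.0 + np.exp(-a * (u - p.center)))
        net = self.net_inputs(y, s, w, D, noise_c)
        return u + (dt / p.tau) * (net - u)

    def activity(self, u: np.ndarray, s: np.ndarray) -> LayerActivity:
        a = self._slope_vec()
        y = 1.0 / (1.0 + np.exp(-a * (u - self.params.center)))
        return self._unpack(y, s)

    def run_to_steady_state(self, s: np.ndarray, w: PlasticWeights,
                            D: float, noise_c: np.ndarray | None = None,
                            u0: np.ndarray | None = None):
        """Integrate until the activity pattern stops changing.

        Convergence requires every per-neuron activity change to stay
        below ``ss_tol`` for ``ss_window`` consecutive steps; if the cap
        ``max_steps`` is hit first the final state is still returned with
        ``converged = False`` (the trial is then scored from it).

        Returns ``(state, u, converged)``.
        """
        p = self.params
        n = self.n_channels
        if noise_c is None:
            noise_c = np.zeros(n)
        noise_c = np.asarray(noise_c, dtype=float)
        if noise_c.shape[0] != n:
            raise ValueError("noise vector length must equal n_channels")
        u = self.zero_state() if u0 is None else u0.astype(float).copy()
        sens_g, sens_n, wgc, wnc = self._drives(s, w)
        u, y, _, converged = _integrate(
            u, sens_g, sens_n, wgc, wnc, noise_c, float(D), self._pv,
            p.max_steps, p.ss_window)
        return self._unpack(y, s), u, bool(converged)

    def resting_state(self, w: PlasticWeights, D: float = 1.0
                      ) -> LayerActivity:
        """Steady state with zero stimulus and no noise."""
        s = np.zeros(w.w_gs.shape[1])
        state, _, _ = self.run_to_steady_state(s, w, D)
        return state

    def detect_response(self, cortex: np.ndarray) -> int:
        """Single-winner response criterion on the motor cortex.

        Returns the winner index when exactly one neuron exceeds
        ``response_hi`` and every other one is below ``response_lo``
        ("close to zero"); otherwise ``NO_RESPONSE`` — covering both the
        absence of a response and multiple simultaneous responses.
        """
        p = self.params
        cortex = np.asarray(cortex, dtype=float)
        above = np.flatnonzero(cortex > p.response_hi)
        if above.size != 1:
            return NO_RESPONSE
        wnr = int(above[0])
        losers = np.delete(cortex, wnr)
        if losers.size and losers.max() >= p.response_lo:
            return NO_RESPONSE
        return wnr


# ---------------------------------------------------------------------------
# calibration to the stated operating points
# ---------------------------------------------------------------------------

def _naive_trial(net: BGNetwork, w: PlasticWeights, stimulus: np.ndarray,
                 eps: float = 0.05):
    """Deterministic naive trial with a tiny symmetry-breaking offset."""
    noise = np.zeros(net.n_channels)
    noise[0] = eps
    state, _, _ = net.run_to_steady_state(stimulus, w, D=1.0, noise_c=noise)
    return state


def calibrate(params: NetworkParams | None = None, n_channels: int = 2,
              gpi_target: float = 0.95, naive_level: float = 0.5,
              n_iter: int = 6) -> NetworkParams:
    """Tune basal drives and naive weights to the network's operating points.

    Solves, by fixed-point/secant iteration on the full simulator:

    * ``b_gpe`` so the resting GPe sits at half activation,
    * ``b_gpi`` so the resting GPi sits near saturation (``gpi_target``),
    * naive ``w_gc0`` / ``w_nc0`` so the winner-channel Go and NoGo
      activities settle at ``naive_level`` on a naive noiseless trial.

    Returns a new :class:`NetworkParams`; the input is not modified.
    """
    from .tasks import default_stimulus  # local import, avoids cycle

    p = dataclasses.replace(params or NetworkParams())
    stimulus = default_stimulus(n_channels)
    # keep the naive sensory drive per striatal neuron independent of the
    # stimulus dimensionality (defaults are referenced to the two-channel
    # stimulus, which sums to 1.3)
    scale = 1.3 / float(stimulus.sum())
    p = dataclasses.replace(p, w_gs0=float(p.w_gs0 * scale),
                            w_ns0=float(p.w_ns0 * scale))
    logit = lambda q: np.log(q / (1.0 - q))

    for _ in range(n_iter):
        net = BGNetwork(p, n_channels)
        w = PlasticWeights.naive(n_channels, stimulus.shape[0], p)
        rest = net.resting_state(w)
        b_gpe = p.center + p.nu_en * rest.nogo.mean()
        b_gpi = (p.center + logit(gpi_target) / p.a_fast
                 + p.nu_ig * rest.go.mean() + p.nu_ie * rest.gpe.mean()
                 - p.nu_is * rest.stn)

        # winner Go/NoGo at naive_level: secant on the cortical weights
        def winner_go(wgc0, wnc0):
            q = dataclasses.replace(p, b_gpe=b_gpe, b_gpi=b_gpi,
                                    w_gc0=wgc0, w_nc0=wnc0)
            st = _naive_trial(BGNetwork(q, n_channels),
                              PlasticWeights.naive(n_channels,
                                                   stimulus.shape[0], q),
                              stimulus)
            wnr = int(st.cortex.argmax())
            return st.go[wnr], st.nogo[wnr]

        wgc0, wnc0 = p.w_gc0, p.w_nc0
        for _ in range(3):
            g0, _n0 = winner_go(wgc0, wnc0)
            g1, _ = winner_go(wgc0 + 0.02, wnc0)
            slope = (g1 - g0) / 0.02
            if abs(slope) > 1e-6:
                wgc0 = float(np.clip(wgc0 + (naive_level - g0) / slope,
                                     0.02, 0.8))
            _g, n0 = winner_go(wgc0, wnc0)
            _g, n1 = winner_go(wgc0, wnc0 + 0.02)
            slope = (n1 - n0) / 0.02
            if abs(slope) > 1e-6:
                wnc0 = float(np.clip(wnc0 + (naive_level - n0) / slope,
                                     0.02, 0.8))
        p = dataclasses.replace(p, b_gpe=float(b_gpe), b_gpi=float(b_gpi),
                                w_gc0=wgc0, w_nc0=wnc0)
    return p
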