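"""Conductance-based LIF neurons, triplet STDP, and the plastic synapse bank.

The neuron model is a leaky integrate-and-fire unit with excitatory and
inhibitory conductance channels,

    tau_m dv/dt = (v_r - v) - g_e (v - E_exc) - g_i (v - E_inh),

where the conductances decay first-order (tau_ge, tau_gi) and jump by the
synaptic weight on each presynaptic spike.  A neuron spikes when v reaches
v_th + theta, resets to v_r, and its adaptive threshold offset theta grows
by a small constant and slowly decays — the homeostasis that keeps
winner-take-all competition fair.

Plasticity is the triplet STDP rule: one presynaptic trace x_j and two
postsynaptic traces y1_i (fast) and y2_i (slow), each reset to 1 at its
owner's spike and decaying exponentially otherwise.  A presynaptic spike
depresses the synapse by mu_pre * y1_i; a postsynaptic spike potentiates it
by mu_post * x_j * y2_i (with y2_i taken just before its own reset).

Integration is clock-driven: explicit Euler for the membrane potential,
exact exponential factors for conductances, traces, and theta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ACTIVE",
    "REMOVED",
    "FROZEN",
    "NeuronParams",
    "NeuronState",
    "PlasticityParams",
    "TraceState",
    "SynapseBank",
    "step_neurons",
    "decay_traces",
    "stdp_on_pre",
    "stdp_on_post",
]

# Synapse status codes.  Removed synapses contribute nothing and never change;
# frozen synapses still conduct but are excluded from plasticity.
ACTIVE: int = 0
REMOVED: int = 1
FROZEN: int = 2


@dataclass(frozen=True)
class NeuronParams:
    """LIF membrane and conductance constants.

    Units are ms for time constants and mV for potentials; conductances are
    dimensionless multiples of the leak conductance.
    """

    tau_m: float = 100.0
    v_r: float = -60.0
    v_th: float = -50.0
    E_exc: float = 0.0
    E_inh: float = -100.0
    tau_ge: float = 1.0
    tau_gi: float = 2.0
    theta_plus: float = 0.01
    tau_theta: float = 1e5
    t_refrac: float = 0.0

    def __post_init__(self) -> None:
        for name in ("tau_m", "tau_ge", "tau_gi", "tau_theta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not self.v_r < self.v_th:
            raise ValueError("require v_r < v_th")
        if not self.E_inh < self.v_r:
            raise ValueError("require E_inh < v_r")
        if not self.E_exc > self.v_th:
            raise ValueError("require E_exc > v_th")
        if self.t_refrac < 0:
            raise ValueError("t_refrac must be >= 0")


@dataclass
class NeuronState:
    """Per-neuron state vectors: membrane, conductances, threshold offset."""

    v: np.ndarray
    g_e: np.ndarray
    g_i: np.ndarray
    theta: np.ndarray
    refrac_left: np.ndarray

    @classmethod
    def resting(cls, n: int, params: NeuronParams) -> "NeuronState":
        return cls(
            v=np.full(n, params.v_r, dtype=np.float64),
            g_e=np.zeros(n, dtype=np.float64),
            g_i=np.zeros(n, dtype=np.float64),
            theta=np.zeros(n, dtype=np.float64),
            refrac_left=np.zeros(n, dtype=np.float64),
        )

    def copy(self) -> "NeuronState":
        return NeuronState(
            self.v.copy(),
            self.g_e.copy(),
            self.g_i.copy(),
            self.theta.copy(),
            self.refrac_left.copy(),
        )


@dataclass(frozen=True)
class PlasticityParams:
    """Triplet STDP constants: trace time constants, learning rates, bounds."""

    tau_x: float = 8.0
    tau_y1: float = 16.0
    tau_y2: float = 32.0
    mu_pre: float = 0.0001
    mu_post: float = 0.01
    w_max: float = 1.0
    w_min: float = 0.0

    def __post_init__(self) -> None:
        if not (self.tau_x > 0 and self.tau_y1 > 0 and self.tau_y2 > 0):
            raise ValueError("trace time constants must be > 0")
        if self.mu_pre < 0 or self.mu_post < 0:
            raise ValueError("learning rates must be >= 0")
        if self.w_min != 0.0 or self.w_max <= self.w_min:
            raise ValueError("require w_max > w_min = 0")


@dataclass
class TraceState:
    """STDP trace vectors: x per presynaptic unit, y1/y2 per postsynaptic."""

    x: np.ndarray
    y1: np.ndarray
    y2: np.ndarray

    @classmethod
    def zeros(cls, n_pre: int, n_post: int) -> "TraceState":
        return cls(
            x=np.zeros(n_pre, dtype=np.float64),
            y1=np.zeros(n_post, dtype=np.float64),
            y2=np.zeros(n_post, dtype=np.float64),
        )

    def copy(self) -> "TraceState":
        return TraceState(self.x.copy(), self.y1.copy(), self.y2.copy())


@dataclass
class SynapseBank:
    """Plastic weight matrix with per-synapse status flags.

    ``w`` has shape (n_pre, n_post).  ``status`` holds ACTIVE / REMOVED /
    FROZEN codes; removed synapses neither conduct nor learn, frozen ones
    conduct at their frozen weight but never learn.
    """

    w: np.ndarray
    status: np.ndarray

    def __post_init__(self) -> None:
        if self.w.shape != self.status.shape:
            raise ValueError("w and status must have the same shape")

    @classmethod
    def init_random(
        cls,
        n_pre: int,
        n_post: int,
        rng: np.random.Generator,
        w_max: float = 1.0,
        init_scale: float = 0.3,
    ) -> "SynapseBank":
        """Weights uniform on [0, init_scale * w_max], all synapses active."""
        w = rng.uniform(0.0, init_scale * w_max, size=(n_pre, n_post))
        return cls(w=w, status=np.zeros((n_pre, n_post), dtype=np.int8))

    @property
    def n_total(self) -> int:
        return self.w.size

    @property
    def active_mask(self) -> np.ndarray:
        return self.status == ACTIVE

    @property
    def conducting_mask(self) -> np.ndarray:
        """Synapses that contribute conductance (active or frozen)."""
        return self.status != REMOVED

    def conducting_w(self) -> np.ndarray:
        """Effective weight matrix with removed synapses zeroed."""
        return np.where(self.status != REMOVED, self.w, 0.0)

    def copy(self) -> "SynapseBank":
        return SynapseBank(self.w.copy(), self.status.copy())


def step_neurons(
    state: NeuronState,
    params: NeuronParams,
    exc_input: np.ndarray | float,
    inh_input: np.ndarray | float,
    dt: float,
    adapt_theta: bool = True,
) -> np.ndarray:
    """Advance a neuron population by one time step; return the spike mask.

    Conductances decay by their exact exponential factor and are then
    incremented by the summed weight of spikes arriving this step.  The
    membrane potential takes one explicit-Euler step.  A neuron spikes when
    it is out of its refractory period and v >= v_th + theta; on a spike the
    membrane resets to v_r, theta jumps by theta_plus, and the refractory
    timer restarts.  With ``adapt_theta=False`` the threshold offset is held
    fixed (used during inference).

    ``dt`` must satisfy 0 < dt <= tau_ge for stability of the Euler step.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if dt > params.tau_ge:
        raise ValueError("dt must not exceed tau_ge (stability)")
    if np.any(np.asarray(exc_input) < 0) or np.any(np.asarray(inh_input) < 0):
        raise ValueError("synaptic inputs must be non-negative")
    if not (np.all(np.isfinite(state.v)) and np.all(np.isfinite(state.g_e))):
        raise FloatingPointError("non-finite neuron state")

    state.g_e *= np.exp(-dt / params.tau_ge)
    state.g_i *= np.exp(-dt / params.tau_gi)
    state.g_e += exc_input
    state.g_i += inh_input

    refractory = state.refrac_left > 0
    dv = (
        (params.v_r - state.v)
        - state.g_e * (state.v - params.E_exc)
        - state.g_i * (state.v - params.E_inh)
    ) * (dt / params.tau_m)
    # Membrane is clamped during the refractory period.
    state.v = np.where(refractory, state.v, state.v + dv)

    spiked = (~refractory) & (state.v >= params.v_th + state.theta)
    state.v[spiked] = params.v_r
    if adapt_theta:
        state.theta[spiked] += params.theta_plus
        state.theta *= np.exp(-dt / params.tau_theta)
    state.refrac_left[spiked] = params.t_refrac
    state.refrac_left = np.maximum(state.refrac_left - dt, 0.0)
    return spiked


def decay_traces(traces: TraceState, dt: float, params: PlasticityParams) -> None:
    """Decay all STDP traces in place by their exact exponential factors.

    Reset-to-1 at the owner's spike is applied by the spike handlers
    (:func:`stdp_on_pre` / :func:`stdp_on_post`), not here.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    traces.x *= np.exp(-dt / params.tau_x)
    traces.y1 *= np.exp(-dt / params.tau_y1)
    traces.y2 *= np.exp(-dt / params.tau_y2)


def stdp_on_pre(
    bank: SynapseBank,
    traces: TraceState,
    j: int | np.ndarray,
    params: PlasticityParams,
) -> None:
    """Depression triggered by presynaptic spike(s) at unit(s) ``j``.

    Every ACTIVE synapse (j, i) is depressed by mu_pre * y1_i and clipped to
    [0, w_max]; removed and frozen synapses are untouched.  The presynaptic
    trace x_j is then reset to 1.
    """
    rows = np.atleast_1d(np.asarray(j, dtype=np.intp))
    if rows.size:
        active = bank.status[rows] == ACTIVE
        w = bank.w[rows]
        updated = np.clip(w - params.mu_pre * traces.y1[None, :], 0.0, params.w_max)
        bank.w[rows] = np.where(active, updated, w)
        traces.x[rows] = 1.0


def stdp_on_post(
    bank: SynapseBank,
    traces: TraceState,
    i: int | np.ndarray,
    params: PlasticityParams,
) -> None:
    """Potentiation triggered by postsynaptic spike(s) at neuron(s) ``i``.

    Every ACTIVE synapse (j, i) is potentiated by mu_post * x_j * y2_i using
    y2_i as it stood immediately before its own reset, then y1_i and y2_i
    are reset to 1.
    """
    cols = np.atleast_1d(np.asarray(i, dtype=np.intp))
    if cols.size:
        active = bank.status[:, cols] == ACTIVE
        w = bank.w[:, cols]
        dw = params.mu_post * traces.x[:, None] * traces.y2[None, cols]
        updated = np.clip(w + dw, 0.0, params.w_max)
        bank.w[:, cols] = np.where(active, updated, w)
        traces.y1[cols] = 1.0
        traces.y2[cols] = 1.0
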