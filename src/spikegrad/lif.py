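"""Event-driven leaky integrate-and-fire primitives.

The membrane potential of a LIF neuron decays exponentially with time
constant ``tau_mp`` and jumps by ``w * w_dyn`` on each input spike, where
``w_dyn`` is a dynamic weight in [0, 1] implementing a quadratically
recovering refractory period.  On crossing the threshold ``V_th`` the
neuron emits a spike and the potential is reset by subtraction of
``V_th``; it is clipped from below at ``-V_th``.

Alongside the potential, each neuron maintains exponentially low-pass
filtered spike traces: the input trace ``x_k`` accumulates the (unit)
contribution of every input spike at synapse k, and the output trace
``a_i`` accumulates the neuron's own output spikes.  Both decay with the
shared membrane time constant and are the differentiable surrogate signals
through which training gradients flow.

All functions here are scalar, single-neuron operations with lazy
(event-time) state updates; the vectorized network engine in
:mod:`spikegrad.network` implements the same dynamics layer-wise and is
tested for exact agreement against a clock-driven simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "NeuronParams",
    "NeuronState",
    "SynapseTrace",
    "decay",
    "refractory_weight",
    "receive_spike",
    "update_trace",
]

#: sentinel for "the neuron has never spiked"
NEVER = -math.inf


@dataclass(frozen=True)
class NeuronParams:
    """Static LIF parameters.

    v_th
        firing threshold (> 0), same units as synaptic weights.
    tau_mp
        membrane (and trace) time constant in seconds.  Defaults to the
        20 ms used for Poisson-coded images; DVS-style inputs with slow
        saccade dynamics use 200 ms.
    t_ref
        maximum refractory duration in seconds (0 disables refractoriness).
    """

    v_th: float = 1.0
    tau_mp: float = 0.020
    t_ref: float = 0.001

    def __post_init__(self):
        if self.v_th <= 0:
            raise ValueError("v_th must be positive")
        if self.tau_mp <= 0:
            raise ValueError("tau_mp must be positive")
        if self.t_ref < 0:
            raise ValueError("t_ref must be non-negative")


@dataclass(frozen=True)
class NeuronState:
    """Lazily-updated neuron state, valid at time ``t_last``."""

    v_mp: float = 0.0
    t_last: float = 0.0
    w_dyn: float = 1.0
    t_out: float = NEVER
    a: float = 0.0


@dataclass(frozen=True)
class SynapseTrace:
    """Low-pass-filtered input spike train of one synapse at ``t_last``."""

    x: float = 0.0
    t_last: float = 0.0


def decay(value: float, t_from: float, t_to: float, tau: float) -> float:
    """Exponential decay of a trace or potential from ``t_from`` to ``t_to``."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    if t_to < t_from:
        raise ValueError(f"t_to={t_to} earlier than t_from={t_from}")
    return value * math.exp((t_from - t_to) / tau)


def refractory_weight(t_out: float, t: float, t_ref: float,
                      w_dyn_prev: float = 0.0) -> float:
    """Dynamic weight at time ``t`` given the latest refractory trigger.

    Returns ``(dt/t_ref)**2`` while ``dt = t - t_out < t_ref`` and the
    neuron has not yet recovered (``w_dyn_prev < 1``), else 1.  A trigger
    (own output spike or lateral inhibition) restarts the recovery by
    setting ``t_out = t`` and the stored previous value to 0.  Returns 1
    if the neuron never spiked or ``t_ref`` is 0.
    """
    if t_out == NEVER or t_ref <= 0:
        return 1.0
    dt = t - t_out
    if dt < 0:
        raise ValueError(f"evaluation time {t} precedes trigger time {t_out}")
    if dt < t_ref and w_dyn_prev < 1.0:
        return (dt / t_ref) ** 2
    return 1.0


def receive_spike(state: NeuronState, params: NeuronParams, w: float,
                  t: float) -> tuple[NeuronState, int]:
    """Process one input spike of weight ``w`` arriving at time ``t``.

    Returns the new state and the number of output spikes emitted (usually
    0 or 1; a single input with ``w >= 2*v_th`` triggers repeated
    threshold subtraction and multiple spikes, preserving the input-output
    rate proportionality of the rate transfer function).
    """
    if t < state.t_last:
        raise ValueError(f"out-of-order event at t={t} (state at {state.t_last})")
    v = decay(state.v_mp, state.t_last, t, params.tau_mp)
    a = decay(state.a, state.t_last, t, params.tau_mp)
    w_dyn = refractory_weight(state.t_out, t, params.t_ref, state.w_dyn)
    v += w * w_dyn
    n_spikes = 0
    t_out = state.t_out
    while v >= params.v_th:
        v -= params.v_th
        a += 1.0
        n_spikes += 1
        t_out = t
        w_dyn = 0.0 if params.t_ref > 0 else 1.0
    if v < -params.v_th:
        v = -params.v_th
    return (
        replace(state, v_mp=v, t_last=t, w_dyn=w_dyn, t_out=t_out, a=a),
        n_spikes,
    )


def update_trace(trace: SynapseTrace, t: float, tau: float,
                 jump: float = 1.0) -> SynapseTrace:
    """Decay a filtered spike trace to time ``t`` and add ``jump``.

    Incrementally equivalent to evaluating the full sum
    ``x(t) = sum_p exp((t_p - t)/tau)`` over all past spike times.
    """
    x = decay(trace.x, trace.t_last, t, tau)
    return SynapseTrace(x=x + jump, t_last=t)
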