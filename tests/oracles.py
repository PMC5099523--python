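"""Independent reference implementations used as test oracles.

Everything here is deliberately written the slow, obvious way (explicit
sums, time-stepped simulation, damped fixed-point iteration) and shares no
code path with the package implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np

from spikegrad.network import ForwardRecord, LayerRecord, SpikingNetwork


def decode_nmnist_record(record: bytes) -> tuple[int, int, int, int]:
    """Bit-level decode of one 5-byte AER record: (x, y, polarity, t_us)."""
    assert len(record) == 5
    bits = "".join(f"{b:08b}" for b in record)
    x = int(bits[0:8], 2)
    y = int(bits[8:16], 2)
    pol = int(bits[16], 2)
    t_us = int(bits[17:40], 2)
    return x, y, pol, t_us


def trace_direct_sum(spike_times, t: float, tau: float) -> float:
    """Explicit evaluation of the filtered trace sum_p exp((t_p - t)/tau)."""
    return sum(math.exp((tp - t) / tau) for tp in spike_times if tp <= t)


def clock_driven_dense(W, vth, tau_mp: float, t_ref: float, events,
                       T_us: int):
    """1 us time-stepped simulation of one dense LIF layer (no WTA).

    ``events`` is a sequence of (t_us, source) pairs.  Returns the spike
    list [(t_us, neuron)] and the final membrane potentials.  Within a
    time step, events are processed sequentially in source order with full
    threshold resolution after each event, mirroring the event-driven
    contract.
    """
    W = np.asarray(W, dtype=np.float64)
    vth = np.asarray(vth, dtype=np.float64)
    N = W.shape[0]
    v = np.zeros(N)
    t_out_us = np.zeros(N, dtype=np.int64)
    has_spiked = np.zeros(N, dtype=bool)
    d = math.exp(-1e-6 / tau_mp)
    spikes = []
    events = sorted(events, key=lambda e: (e[0], e[1]))
    ev_idx = 0
    for step in range(T_us + 1):
        if step > 0:
            v *= d
        while ev_idx < len(events) and events[ev_idx][0] == step:
            k = events[ev_idx][1]
            ev_idx += 1
            if t_ref > 0:
                dt = (step - t_out_us) * 1e-6
                wd = np.where(has_spiked & (dt < t_ref), (dt / t_ref) ** 2, 1.0)
            else:
                wd = np.ones(N)
            v = v + W[:, k] * wd
            np.maximum(v, -vth, out=v)
            for i in range(N):
                while v[i] >= vth[i]:
                    v[i] -= vth[i]
                    spikes.append((step, i))
                    t_out_us[i] = step
                    has_spiked[i] = True
    return spikes, v


def damped_fixed_point(s, vth, K, sigma: float, gamma: float = 0.3,
                       iters: int = 20000) -> np.ndarray:
    """Rectified WTA fixed point by damped projected iteration."""
    s = np.asarray(s, dtype=np.float64)
    a = np.maximum(s / vth, 0.0)
    for _ in range(iters):
        a_new = np.maximum(s / vth + sigma * (K @ a), 0.0)
        a = (1 - gamma) * a + gamma * a_new
    return a


def full_activity_record(net: SpikingNetwork, duration: float = 1.0,
                         ) -> ForwardRecord:
    """Synthetic record in which every synapse and neuron is active.

    Used to exercise the backprop normalization in isolation from the
    simulator (unit traces, unit counts).
    """
    recs = [
        LayerRecord(
            counts=np.ones(sp.n_out, dtype=np.int64),
            x=np.ones(sp.n_in),
            a=np.ones(sp.n_out),
            active_in=np.ones(sp.n_in, dtype=bool),
            active_out=np.ones(sp.n_out, dtype=bool),
        )
        for sp in net.layers
    ]
    return ForwardRecord(recs, duration)
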