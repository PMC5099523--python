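"""Layered event-driven forward propagation.

A network is a feed-forward stack of layers (dense, convolutional with
weight sharing, or fixed spiking sum-pooling).  Events are propagated in
time order; spikes emitted by layer ``l`` become input events of layer
``l+1`` at the same timestamp (zero propagation delay).  Within one
timestamp the engine canonically orders events by source index and
processes them sequentially, which makes the simulation deterministic and
insensitive to permutations of equal-time input events.

During a presentation the engine also maintains the low-pass-filtered
traces ``x_k`` (per input synapse) and ``a_i`` (per neuron) that the
training module reads out at the end of the presentation, plus the active
synapse/neuron sets (a synapse or neuron is active iff it carried at
least one spike, equivalently its trace is nonzero at the end time).

Flattening of 3-D shapes (H, W, C) is row-major with the channel/map axis
slowest: ``index = c*H*W + y*W + x``, matching the polarity-channel
convention of :mod:`spikegrad.events`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .events import EventStream, StreamValidationError
from .wta import WTAConfig

__all__ = [
    "LayerSpec",
    "LayerRecord",
    "ForwardRecord",
    "dense_layer",
    "unroll_convolution",
    "make_pool_layer",
    "SpikingNetwork",
    "forward_sample",
    "net_from_config",
    "save_checkpoint",
    "load_checkpoint",
]

POOL_WEIGHT = 1.0
POOL_VTH = 0.8


@dataclass
class LayerSpec:
    """Static description of one layer's topology and parameters.

    Weights live in a flat slot vector; dense layers use the implicit slot
    ``i*n_in + k`` for neuron i and input k, conv/pool layers enumerate
    explicit (pre, post, slot) edges so that all spatial positions of a
    feature map share one slot per kernel element.  ``thr_index`` maps each
    neuron to its threshold parameter (identity for dense, the map index
    for conv, a single shared fixed value for pool).
    """

    kind: str                      # dense | conv | pool
    n_in: int
    n_out: int
    in_shape: tuple
    out_shape: tuple
    n_slots: int
    n_thr: int
    thr_index: np.ndarray
    edges_pre: np.ndarray | None = None
    edges_post: np.ndarray | None = None
    edges_slot: np.ndarray | None = None
    trainable: bool = True
    wta: WTAConfig | None = None
    alpha: float = 3.0
    # CSR over sources, built lazily
    _indptr: np.ndarray | None = field(default=None, repr=False)
    _csr_post: np.ndarray | None = field(default=None, repr=False)
    _csr_slot: np.ndarray | None = field(default=None, repr=False)

    @property
    def fan_in(self) -> int:
        """Number of synapses per neuron (M)."""
        if self.kind == "dense":
            return self.n_in
        return int(len(self.edges_pre) // self.n_out)

    def _build_csr(self) -> None:
        order = np.argsort(self.edges_pre, kind="stable")
        pre = self.edges_pre[order]
        self._csr_post = self.edges_post[order]
        self._csr_slot = self.edges_slot[order]
        self._indptr = np.searchsorted(pre, np.arange(self.n_in + 1))

    def targets_of(self, k: int):
        """(neuron indices, weight slot indices) reached from source ``k``."""
        if self._indptr is None:
            self._build_csr()
        a, b = self._indptr[k], self._indptr[k + 1]
        return self._csr_post[a:b], self._csr_slot[a:b]


def dense_layer(n_in: int, n_out: int, alpha: float = 3.0,
                wta: WTAConfig | None = None) -> LayerSpec:
    """Fully connected spiking layer with per-neuron thresholds."""
    return LayerSpec(
        kind="dense", n_in=n_in, n_out=n_out,
        in_shape=(n_in,), out_shape=(n_out,),
        n_slots=n_in * n_out, n_thr=n_out,
        thr_index=np.arange(n_out), wta=wta, alpha=alpha,
    )


def unroll_convolution(input_shape: tuple, n_maps: int, kernel: int,
                       mode: str = "valid", alpha: float = 3.0) -> LayerSpec:
    """Convolutional layer: weight-shared kernels over a (H, W, C) input.

    All spatial positions of a feature map share the same ``kernel**2 * C``
    weight slots and one per-map threshold.  Only 'valid' convolution is
    supported; the output shape is (H-k+1, W-k+1, n_maps).
    """
    if mode != "valid":
        raise ValueError("only 'valid' convolution is supported")
    H, W, C = (input_shape if len(input_shape) == 3 else (*input_shape, 1))
    k = int(kernel)
    if k > H or k > W:
        raise ValueError(f"kernel {k} larger than input {H}x{W}")
    Ho, Wo = H - k + 1, W - k + 1
    # enumerate edges: out neuron (m, oy, ox) x kernel element (c, dy, dx)
    m_, oy, ox, c_, dy, dx = np.meshgrid(
        np.arange(n_maps), np.arange(Ho), np.arange(Wo),
        np.arange(C), np.arange(k), np.arange(k), indexing="ij",
    )
    post = (m_ * Ho + oy) * Wo + ox
    pre = c_ * H * W + (oy + dy) * W + (ox + dx)
    slot = ((m_ * C + c_) * k + dy) * k + dx
    out_neurons = n_maps * Ho * Wo
    return LayerSpec(
        kind="conv", n_in=H * W * C, n_out=out_neurons,
        in_shape=(H, W, C), out_shape=(Ho, Wo, n_maps),
        n_slots=n_maps * C * k * k, n_thr=n_maps,
        thr_index=np.repeat(np.arange(n_maps), Ho * Wo),
        edges_pre=pre.ravel(), edges_post=post.ravel(), edges_slot=slot.ravel(),
        alpha=alpha,
    )


def make_pool_layer(input_shape: tuple, window: int = 2) -> LayerSpec:
    """Spiking sum-pooling: fixed weights of 1 and threshold 0.8.

    Each pool neuron integrates its window; not exactly sum pooling because
    refractoriness can swallow near-coincident input spikes.  Weights and
    thresholds are frozen (not trained).
    """
    H, W, C = (input_shape if len(input_shape) == 3 else (*input_shape, 1))
    w = int(window)
    if H % w or W % w:
        raise ValueError(f"input {H}x{W} not divisible by {w}x{w} window")
    Ho, Wo = H // w, W // w
    c_, oy, ox, dy, dx = np.meshgrid(
        np.arange(C), np.arange(Ho), np.arange(Wo),
        np.arange(w), np.arange(w), indexing="ij",
    )
    post = (c_ * Ho + oy) * Wo + ox
    pre = c_ * H * W + (oy * w + dy) * W + (ox * w + dx)
    n_out = C * Ho * Wo
    return LayerSpec(
        kind="pool", n_in=H * W * C, n_out=n_out,
        in_shape=(H, W, C), out_shape=(Ho, Wo, C),
        n_slots=1, n_thr=1,
        thr_index=np.zeros(n_out, dtype=np.int64),
        edges_pre=pre.ravel(), edges_post=post.ravel(),
        edges_slot=np.zeros(pre.size, dtype=np.int64),
        trainable=False,
    )


@dataclass
class LayerRecord:
    """End-of-presentation summary of one layer used by backprop."""

    counts: np.ndarray        # output spikes per neuron
    x: np.ndarray             # input traces x_k(T)
    a: np.ndarray             # output traces a_i(T)
    active_in: np.ndarray     # bool, x > 0
    active_out: np.ndarray    # bool, a > 0

    @property
    def m(self) -> int:
        """Number of active synapses (active input sources)."""
        return int(self.active_in.sum())

    @property
    def n(self) -> int:
        """Number of active neurons."""
        return int(self.active_out.sum())


@dataclass
class ForwardRecord:
    layers: list[LayerRecord]
    duration: float

    @property
    def output_counts(self) -> np.ndarray:
        return self.layers[-1].counts


class _LayerState:
    __slots__ = ("v", "t_last", "t_out", "x", "x_t", "a", "a_t", "counts")

    def __init__(self, n_in: int, n_out: int):
        self.v = np.zeros(n_out)
        self.t_last = np.zeros(n_out)
        self.t_out = np.full(n_out, -np.inf)
        self.x = np.zeros(n_in)
        self.x_t = np.zeros(n_in)
        self.a = np.zeros(n_out)
        self.a_t = np.zeros(n_out)
        self.counts = np.zeros(n_out, dtype=np.int64)


class SpikingNetwork:
    """A stack of event-driven LIF layers with shared membrane time constant.

    Parameters are held as a flat weight-slot vector and a threshold vector
    per layer.  ``initialize`` draws weights uniform in [-sqrt(3/M),
    sqrt(3/M)] (unit expected squared fan-in sum) and sets thresholds to
    ``alpha * sqrt(3/M)``, the scheme that keeps backpropagated error
    energy constant across layers.
    """

    def __init__(self, layers: list[LayerSpec], tau_mp: float = 0.020,
                 t_ref: float = 0.001):
        for a, b in zip(layers, layers[1:]):
            if a.n_out != b.n_in:
                raise ValueError(
                    f"layer size mismatch: {a.n_out} outputs feed {b.n_in} inputs"
                )
        if tau_mp <= 0:
            raise ValueError("tau_mp must be positive")
        self.layers = layers
        self.tau_mp = float(tau_mp)
        self.t_ref = float(t_ref)
        self.weights: list[np.ndarray] = []
        self.vth: list[np.ndarray] = []
        self.vth_floor: list[np.ndarray] = []
        for sp in layers:
            if sp.kind == "pool":
                self.weights.append(np.array([POOL_WEIGHT]))
                self.vth.append(np.array([POOL_VTH]))
            else:
                bound = math.sqrt(3.0 / sp.fan_in)
                self.weights.append(np.zeros(sp.n_slots))
                self.vth.append(np.full(sp.n_thr, sp.alpha * bound))
            self.vth_floor.append(0.01 * self.vth[-1].copy())

    @property
    def n_in(self) -> int:
        return self.layers[0].n_in

    def W(self, l: int) -> np.ndarray:
        """Dense weight matrix view (n_out, n_in) of layer ``l``."""
        sp = self.layers[l]
        if sp.kind != "dense":
            raise ValueError("matrix view only defined for dense layers")
        return self.weights[l].reshape(sp.n_out, sp.n_in)

    def neuron_vth(self, l: int) -> np.ndarray:
        """Per-neuron thresholds of layer ``l`` (expands shared thresholds)."""
        return self.vth[l][self.layers[l].thr_index]

    def initialize(self, seed: int | np.random.Generator) -> "SpikingNetwork":
        from .train import init_layer  # local import avoids a module cycle

        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        for l, sp in enumerate(self.layers):
            if sp.kind == "pool":
                continue
            if sp.kind == "dense":
                W, vth = init_layer(sp.n_in, sp.n_out, sp.alpha, rng)
                self.weights[l] = W.ravel()
                self.vth[l] = vth
            else:  # conv: fan-in is C*k*k, one threshold per map
                M = sp.fan_in
                w, vth = init_layer(M, sp.n_thr, sp.alpha, rng)
                self.weights[l] = w.ravel()
                self.vth[l] = vth
            self.vth_floor[l] = 0.01 * self.vth[l].copy()
        return self

    # ------------------------------------------------------------------
    # forward simulation
    # ------------------------------------------------------------------

    def forward(self, stream: EventStream, duration: float | None = None,
                train: bool = False, rho: float = 0.0) -> ForwardRecord:
        """Propagate one presentation through the network.

        In training mode (``train=True`` with ``rho > 0``) the per-event
        threshold-regularization rule runs during forward propagation on
        every trainable layer with per-neuron thresholds.
        """
        if stream.n_sources != self.n_in:
            raise StreamValidationError(
                f"stream has {stream.n_sources} sources, network expects {self.n_in}"
            )
        T = float(stream.duration if duration is None else duration)
        states = [_LayerState(sp.n_in, sp.n_out) for sp in self.layers]
        times, sources = stream.times, stream.sources
        i, n_ev = 0, len(times)
        while i < n_ev:
            t = times[i]
            j = i
            while j < n_ev and times[j] == t:
                j += 1
            batch = np.sort(sources[i:j])
            self._inject(states, float(t), batch, train, rho)
            i = j
        # roll all traces forward to the common end time T
        for st in states:
            np.multiply(st.x, np.exp((st.x_t - T) / self.tau_mp), out=st.x)
            st.x_t.fill(T)
            np.multiply(st.a, np.exp((st.a_t - T) / self.tau_mp), out=st.a)
            st.a_t.fill(T)
        recs = [
            LayerRecord(
                counts=st.counts, x=st.x, a=st.a,
                active_in=st.x > 0, active_out=st.a > 0,
            )
            for st in states
        ]
        return ForwardRecord(recs, T)

    def _inject(self, states, t: float, batch: np.ndarray,
                train: bool, rho: float) -> None:
        current = batch
        for l in range(len(self.layers)):
            if len(current) == 0:
                break
            out: list[int] = []
            for k in current:
                out.extend(self._process(states[l], l, t, int(k), train, rho))
            current = np.sort(np.asarray(out, dtype=np.int64))

    def _process(self, st: _LayerState, l: int, t: float, k: int,
                 train: bool, rho: float) -> list[int]:
        sp = self.layers[l]
        tau = self.tau_mp
        t_ref = self.t_ref
        # input trace of source k
        st.x[k] = st.x[k] * math.exp((st.x_t[k] - t) / tau) + 1.0
        st.x_t[k] = t
        vth_n = self.vth[l][sp.thr_index]
        if sp.kind == "dense":
            wcol = self.weights[l].reshape(sp.n_out, sp.n_in)[:, k]
            # decay all neurons to t
            np.multiply(st.v, np.exp((st.t_last - t) / tau), out=st.v)
            st.t_last.fill(t)
            if t_ref > 0:
                dt = t - st.t_out
                w_dyn = np.where(dt >= t_ref, 1.0, (dt / t_ref) ** 2)
                st.v += wcol * w_dyn
            else:
                st.v += wcol
            np.maximum(st.v, -vth_n, out=st.v)
            cand = np.flatnonzero(st.v >= vth_n)
        else:
            tg, slots = sp.targets_of(k)
            w = self.weights[l][slots]
            v = st.v[tg] * np.exp((st.t_last[tg] - t) / tau)
            if t_ref > 0:
                dt = t - st.t_out[tg]
                w_dyn = np.where(dt >= t_ref, 1.0, (dt / t_ref) ** 2)
                v = v + w * w_dyn
            else:
                v = v + w
            np.maximum(v, -vth_n[tg], out=v)
            st.v[tg] = v
            st.t_last[tg] = t
            cand = tg[v >= vth_n[tg]]
            cand = np.unique(cand)
        spikes: list[int] = []
        for i in cand:
            i = int(i)
            # the neuron may have been inhibited by an earlier winner
            while st.v[i] >= vth_n[i]:
                st.v[i] -= vth_n[i]
                st.counts[i] += 1
                st.a[i] = st.a[i] * math.exp((st.a_t[i] - t) / tau) + 1.0
                st.a_t[i] = t
                st.t_out[i] = t
                spikes.append(i)
                if sp.wta is not None and sp.wta.kappa < 0:
                    self._inhibit(st, sp, vth_n, t, i)
        if train and rho > 0 and spikes and sp.trainable and sp.kind == "dense":
            self._threshold_regularize(st, l, sp, spikes, rho)
        return spikes

    def _inhibit(self, st: _LayerState, sp: LayerSpec, vth_n: np.ndarray,
                 t: float, winner: int) -> None:
        cfg = sp.wta
        if cfg.members is None:
            members = np.arange(sp.n_out)
        else:
            members = np.asarray(cfg.members)
        others = members[members != winner]
        v = st.v[others] * np.exp((st.t_last[others] - t) / self.tau_mp)
        v += cfg.kappa * vth_n[others]
        np.maximum(v, -vth_n[others], out=v)
        st.v[others] = v
        st.t_last[others] = t
        st.t_out[others] = t  # refractory trigger through lateral inhibition

    def _threshold_regularize(self, st: _LayerState, l: int, sp: LayerSpec,
                              spikes: list[int], rho: float) -> None:
        """Homeostatic per-event rule: +rho*N to firing neurons, -rho*N_w to all.

        Conserves the threshold sum exactly while no neuron sits at the
        floor; a neuron at the floor keeps its threshold and instead has
        all its weights raised by the pending decrement.
        """
        fired = np.unique(np.asarray(spikes, dtype=np.int64))
        N = sp.n_out
        N_w = len(fired)
        vth = self.vth[l]
        vth[fired] += rho * N
        dec = rho * N_w
        floored = vth - dec < self.vth_floor[l]
        vth[~floored] -= dec
        if np.any(floored):
            W = self.weights[l].reshape(sp.n_out, sp.n_in)
            W[np.flatnonzero(floored), :] += dec


def forward_sample(net: SpikingNetwork, stream: EventStream,
                   duration: float | None = None, train: bool = False,
                   rho: float = 0.0) -> ForwardRecord:
    """Functional wrapper around :meth:`SpikingNetwork.forward`."""
    return net.forward(stream, duration=duration, train=train, rho=rho)


# ---------------------------------------------------------------------------
# configuration and checkpoints
# ---------------------------------------------------------------------------

def _wta_from_cfg(cfg) -> WTAConfig | None:
    if not cfg:
        return None
    return WTAConfig(kappa=float(cfg.get("kappa", -0.4)),
                     sigma=float(cfg.get("sigma", 0.5)))


def net_from_config(cfg: dict) -> SpikingNetwork:
    """Build a network from a plain dict (parsed YAML/JSON).

    Expected keys: ``input`` (flat size or [H, W, C] shape), ``layers``
    (list of {kind, ...}), optional ``tau_mp`` and ``t_ref`` in seconds.
    """
    inp = cfg["input"]
    shape = tuple(inp) if isinstance(inp, (list, tuple)) else (int(inp),)
    specs: list[LayerSpec] = []
    for lc in cfg["layers"]:
        kind = lc["kind"]
        if kind == "dense":
            n_in = int(np.prod(shape))
            spec = dense_layer(n_in, int(lc["n"]), alpha=float(lc.get("alpha", 3.0)),
                               wta=_wta_from_cfg(lc.get("wta")))
        elif kind == "conv":
            if len(shape) == 1:
                raise ValueError("conv layer needs a (H, W, C) input shape")
            spec = unroll_convolution(shape, int(lc["maps"]), int(lc["kernel"]),
                                      alpha=float(lc.get("alpha", 3.0)))
        elif kind == "pool":
            if len(shape) == 1:
                raise ValueError("pool layer needs a (H, W, C) input shape")
            spec = make_pool_layer(shape, int(lc.get("window", 2)))
        else:
            raise ValueError(f"unknown layer kind {kind!r}")
        specs.append(spec)
        shape = spec.out_shape
    return SpikingNetwork(specs, tau_mp=float(cfg.get("tau_mp", 0.020)),
                          t_ref=float(cfg.get("t_ref", 0.001)))


def _spec_to_dict(sp: LayerSpec) -> dict:
    d = {"kind": sp.kind, "alpha": sp.alpha,
         "in_shape": list(sp.in_shape), "out_shape": list(sp.out_shape)}
    if sp.kind == "dense":
        d["n"] = sp.n_out
    elif sp.kind == "conv":
        d["maps"] = sp.n_thr
        k = round(math.sqrt(sp.n_slots // (sp.n_thr * sp.in_shape[2])))
        d["kernel"] = k
    elif sp.kind == "pool":
        d["window"] = sp.in_shape[0] // sp.out_shape[0]
    if sp.wta is not None:
        d["wta"] = {"kappa": sp.wta.kappa, "sigma": sp.wta.sigma}
    return d


def save_checkpoint(net: SpikingNetwork, path) -> None:
    import h5py

    arch = {
        "input": list(net.layers[0].in_shape),
        "tau_mp": net.tau_mp,
        "t_ref": net.t_ref,
        "layers": [_spec_to_dict(sp) for sp in net.layers],
    }
    with h5py.File(path, "w") as f:
        f.attrs["arch"] = json.dumps(arch)
        for l in range(len(net.layers)):
            g = f.create_group(f"layer{l}")
            g.create_dataset("w", data=net.weights[l])
            g.create_dataset("vth", data=net.vth[l])
            g.create_dataset("vth_floor", data=net.vth_floor[l])


def load_checkpoint(path) -> SpikingNetwork:
    import h5py

    with h5py.File(path, "r") as f:
        arch = json.loads(f.attrs["arch"])
        net = net_from_config(arch)
        for l in range(len(net.layers)):
            g = f[f"layer{l}"]
            net.weights[l] = np.asarray(g["w"])
            net.vth[l] = np.asarray(g["vth"])
            net.vth_floor[l] = np.asarray(g["vth_floor"])
    return net
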