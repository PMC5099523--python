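"""Backpropagation on spike traces: transfer function, gradients, updates.

The trainable surrogate of a spiking layer is the rate-domain transfer
function obtained by zeroing the residual membrane potential: with
``s_i = sum_k w_ik x_k`` the filtered input drive, the activities of a
WTA-coupled layer satisfy the linear fixed point

    a_i = s_i / V_th,i + sigma * sum_{j != i} kappa_ij a_j .

Its derivatives with respect to weights, thresholds and lateral strengths
(first-order in the lateral connections) and with respect to the inputs
(exact, via the coupled linear system) give the backpropagation rule.
Errors are normalized layer-wise so that, at the scaled-uniform
initialization used here, the expected squared error sum is constant
across depth — the ingredient that lets multi-hidden-layer spiking
networks train without exploding gradients.

Conventions
-----------
* Gradients returned by :func:`backpropagate` are *descent* gradients: the
  parameter update is ``theta <- theta - eta * g`` (possibly through ADAM).
* The threshold update direction follows the chain rule through
  ``da/dV_th = -(a - sigma*sum kappa a)/V_th``, so thresholds decrease when
  a neuron under-responds to its target drive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .network import ForwardRecord, SpikingNetwork
from .regularize import exp_weight_decay

__all__ = [
    "TrainHyper",
    "LayerGradients",
    "EffectiveActivities",
    "AdamState",
    "init_layer",
    "transfer_function",
    "grads_params",
    "grad_input",
    "output_error",
    "effective_activities",
    "backpropagate",
    "apply_updates",
    "adam_step",
    "epoch_decay",
    "Trainer",
    "evaluate",
]


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def init_layer(M: int, N: int, alpha: float,
               seed: int | np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Initialize one layer: weights (N, M) and thresholds (N,).

    Weights are i.i.d. uniform on [-sqrt(3/M), sqrt(3/M)], which gives
    ``E[sum_k w_ik^2] = 1`` per neuron; thresholds are ``alpha*sqrt(3/M)``
    with ``alpha > 1`` (large enough to keep firing stable, small enough
    that activity survives through depth; 3-10 in practice).
    """
    if M < 1:
        raise ValueError("fan-in M must be >= 1")
    if alpha <= 1:
        raise ValueError("alpha must exceed 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bound = math.sqrt(3.0 / M)
    W = rng.uniform(-bound, bound, size=(N, M))
    vth = np.full(N, alpha * bound)
    return W, vth


# ---------------------------------------------------------------------------
# transfer function and derivatives
# ---------------------------------------------------------------------------

def _kappa_matrix(kappa, n: int) -> np.ndarray:
    """Expand a scalar lateral strength to an (n, n) zero-diagonal matrix."""
    K = np.asarray(kappa, dtype=np.float64)
    if K.ndim == 0:
        K = float(K) * (np.ones((n, n)) - np.eye(n))
    if K.shape != (n, n):
        raise ValueError(f"kappa matrix must be ({n}, {n})")
    return K


def transfer_function(s, v_th, kappa=0.0, sigma: float = 0.5) -> np.ndarray:
    """Steady-state rate vector of a (possibly WTA-coupled) LIF layer.

    Solves the rectified fixed point of ``a = s/V_th + sigma*K a`` with
    ``a >= 0``: units whose rate would be negative are clamped at zero and
    removed from the coupled system (a silent unit does not inhibit its
    peers), iterating until the remaining support is self-consistent.
    With ``kappa = 0`` this is simply ``a = max(s / V_th, 0)``.
    """
    s = np.atleast_1d(np.asarray(s, dtype=np.float64))
    v_th = np.broadcast_to(np.asarray(v_th, dtype=np.float64), s.shape)
    if np.any(v_th <= 0):
        raise ValueError("thresholds must be positive")
    n = s.size
    K = _kappa_matrix(kappa, n)
    active = np.ones(n, dtype=bool)
    while True:
        idx = np.flatnonzero(active)
        A = np.eye(idx.size) - sigma * K[np.ix_(idx, idx)]
        try:
            a_sub = np.linalg.solve(A, s[idx] / v_th[idx])
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"singular WTA system (support {idx.size}/{n}, sigma={sigma}, "
                f"kappa range [{K.min():g}, {K.max():g}]): {err}"
            ) from err
        neg = a_sub < 0
        if not np.any(neg) or idx.size == 1:
            a = np.zeros(n)
            a[idx] = np.maximum(a_sub, 0.0)
            return a
        active[idx[neg]] = False


def grads_params(a, s, x, v_th, kappa=0.0, sigma: float = 0.5):
    """First-order derivatives of the layer activities w.r.t. parameters.

    Differentiates the per-neuron fixed-point relation (other activities
    held fixed — lateral feedback of a parameter through its peers is a
    higher-order effect that is neglected):

    * ``da_i/dw_ik = x_k / V_th,i``
    * ``da_i/dV_th,i = (-a_i + sigma*sum_j kappa_ij a_j) / V_th,i``
    * ``da_i/dkappa_ih = sigma * a_h``

    Returns (da_dw (n, m), da_dvth (n,), da_dkappa (n, n, zero diagonal)).
    """
    a = np.atleast_1d(np.asarray(a, dtype=np.float64))
    x = np.atleast_1d(np.asarray(x, dtype=np.float64))
    v_th = np.broadcast_to(np.asarray(v_th, dtype=np.float64), a.shape)
    n = a.size
    K = _kappa_matrix(kappa, n)
    g = 1.0 / v_th
    da_dw = np.outer(g, x)
    lateral = sigma * (K @ a)
    da_dvth = g * (-a + lateral)
    da_dkappa = sigma * np.tile(a, (n, 1))
    np.fill_diagonal(da_dkappa, 0.0)
    return da_dw, da_dvth, da_dkappa


def grad_input(W, v_th, mu=None, sigma: float = 0.5,
               n: int | None = None, kappa=None) -> np.ndarray:
    """Exact input gradient matrix ``d a_i / d x_k`` of the coupled layer.

    For a uniform lateral strength ``mu`` the closed form is used::

        da_i/dx_k = 1/(1+mu*sigma) * ( w_ik/V_i
                    + mu*sigma/(1 - mu*sigma*(n-1)) * sum_j w_jk/V_j )

    which reduces to ``w_ik/V_i`` for ``mu = 0``; for a general ``kappa``
    matrix the linear system ``(I - sigma*K)`` is solved directly.  Both
    routes agree to machine precision for uniform circuits.
    """
    W = np.atleast_2d(np.asarray(W, dtype=np.float64))
    n_neurons = n if n is not None else W.shape[0]
    v_th = np.broadcast_to(np.asarray(v_th, dtype=np.float64), (n_neurons,))
    V = W[:n_neurons] / v_th[:, None]
    if kappa is not None:
        K = _kappa_matrix(kappa, n_neurons)
        return np.linalg.solve(np.eye(n_neurons) - sigma * K, V)
    mu = 0.0 if mu is None else float(mu)
    c = mu * sigma
    if abs(1.0 + c) < 1e-12:
        raise np.linalg.LinAlgError(
            f"singular uniform WTA gradient: mu*sigma = {c:g} (needs != -1)"
        )
    corr = c / (1.0 - c * (n_neurons - 1))
    return (V + corr * V.sum(axis=0, keepdims=True)) / (1.0 + c)


# ---------------------------------------------------------------------------
# output error and error backpropagation
# ---------------------------------------------------------------------------

def output_error(spike_counts, y) -> np.ndarray:
    """Normalized output error ``(o - y) / N_nze``.

    ``o_i = count_i / max_j count_j`` (the zero vector if no output neuron
    spiked) and ``N_nze`` is the number of nonzero entries of ``o - y``.
    A perfectly classified sample yields the zero vector.
    """
    counts = np.asarray(spike_counts, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if np.any(counts < 0):
        raise ValueError("spike counts must be non-negative")
    peak = counts.max() if counts.size else 0.0
    o = counts / peak if peak > 0 else np.zeros_like(counts)
    diff = o - y
    n_nze = int(np.count_nonzero(diff))
    if n_nze == 0:
        return np.zeros_like(diff)
    return diff / n_nze


@dataclass
class EffectiveActivities:
    """Per-layer quantities entering the normalized updates."""

    x_hat: np.ndarray   # effective inputs (= x)
    a_hat: np.ndarray   # effective outputs gamma*a - sigma*sum_{j!=i} kappa*a_j
    g: np.ndarray       # per-neuron 1/V_th
    g_bar: float        # RMS of g over active neurons


def effective_activities(net: SpikingNetwork, record: ForwardRecord, l: int,
                         gamma: float = 1.0) -> EffectiveActivities:
    rec = record.layers[l]
    sp = net.layers[l]
    g = 1.0 / net.neuron_vth(l)
    act = rec.active_out
    g_bar = float(np.sqrt(np.mean(g[act] ** 2))) if act.any() else float(
        np.sqrt(np.mean(g ** 2)))
    a_hat = gamma * rec.a
    if sp.wta is not None and sp.wta.kappa != 0.0:
        mu, sig = sp.wta.kappa, sp.wta.sigma
        a_hat = gamma * rec.a - sig * mu * (rec.a.sum() - rec.a)
    return EffectiveActivities(x_hat=rec.x, a_hat=a_hat, g=g, g_bar=g_bar)


@dataclass
class LayerGradients:
    """Normalized error and descent gradients of one layer."""

    delta: np.ndarray
    dW: np.ndarray | None     # per weight slot
    dVth: np.ndarray | None   # per threshold parameter


def _backprop_matrix(net: SpikingNetwork, record: ForwardRecord, l: int) -> np.ndarray:
    """Effective backprop weights B_ji = V_th,j * (d a_j / d x_i) of layer l.

    Without WTA this is the plain weight matrix; with a uniform WTA it
    carries the first-order lateral correction of the exact input
    gradient.  Only dense layers support WTA circuits.
    """
    sp = net.layers[l]
    W = net.W(l)
    if sp.wta is None or sp.wta.kappa == 0.0:
        return W
    n_act = record.layers[l].n
    if n_act == 0:
        return W
    mu, sig = sp.wta.kappa, sp.wta.sigma
    c = mu * sig
    vth = net.neuron_vth(l)
    act = record.layers[l].active_out
    u = (W[act] / vth[act, None]).sum(axis=0)
    corr = c / (1.0 - c * (n_act - 1))
    return (W + np.outer(vth, corr * u)) / (1.0 + c)


def backpropagate(record: ForwardRecord, e: np.ndarray, net: SpikingNetwork,
                  hyper: "TrainHyper | None" = None) -> list[LayerGradients]:
    """Propagate the output error down the stack and form descent gradients.

    The output layer's delta is the error vector itself (not gated by
    activity, so a silent target neuron still receives weight updates).
    For every lower layer

        delta_i^(l) = (g_i / g_rms) * sqrt(M^(l+1) / m^(l+1))
                      * sum_j B_ji^(l+1) delta_j^(l+1)

    restricted to active neurons, with B the (lateral-corrected) backprop
    matrix.  Descent gradients use the square-root scalings

        gW_ij  = +sqrt(N/m) * delta_i * x_j        (weights)
        gVth_i = -sqrt(N/(m M)) * delta_i * a_hat_i  (thresholds)

    so that the magnitude of per-parameter updates is balanced across
    layers at initialization.
    """
    hyper = hyper or TrainHyper()
    L = len(net.layers)
    e = np.asarray(e, dtype=np.float64)
    if e.shape != (net.layers[-1].n_out,):
        raise ValueError(
            f"error vector shape {e.shape} does not match output size "
            f"{net.layers[-1].n_out}"
        )
    deltas: list[np.ndarray] = [np.zeros(sp.n_out) for sp in net.layers]
    deltas[-1] = e.copy()
    for l in range(L - 2, -1, -1):
        sp_next = net.layers[l + 1]
        d_next = deltas[l + 1]
        if not np.any(d_next):
            continue
        if sp_next.kind == "dense":
            B = _backprop_matrix(net, record, l + 1)
            d_pre = B.T @ d_next
        else:
            d_pre = np.zeros(sp_next.n_in)
            np.add.at(
                d_pre, sp_next.edges_pre,
                net.weights[l + 1][sp_next.edges_slot] * d_next[sp_next.edges_post],
            )
        rec_l = record.layers[l]
        act = rec_l.active_out
        if not act.any():
            continue
        g = 1.0 / net.neuron_vth(l)
        g_rms = np.sqrt(np.mean(g[act] ** 2))
        M_next = sp_next.fan_in
        m_next = _active_fan_in(net, record, l + 1)
        d = (g / g_rms) * math.sqrt(M_next / m_next) * d_pre
        d[~act] = 0.0
        deltas[l] = d

    grads: list[LayerGradients] = []
    for l, sp in enumerate(net.layers):
        if not sp.trainable:
            grads.append(LayerGradients(deltas[l], None, None))
            continue
        rec = record.layers[l]
        m_l = max(1.0, _active_fan_in(net, record, l))
        N_l = sp.n_out
        M_l = sp.fan_in
        eff = effective_activities(net, record, l, gamma=hyper.gamma)
        d = deltas[l]
        sw = math.sqrt(N_l / m_l)
        sv = math.sqrt(N_l / (m_l * M_l))
        if sp.kind == "dense":
            dW = sw * np.outer(d, eff.x_hat)
            dVth = -sv * d * eff.a_hat
        else:
            dW = np.zeros(sp.n_slots)
            np.add.at(
                dW, sp.edges_slot,
                sw * d[sp.edges_post] * eff.x_hat[sp.edges_pre],
            )
            dVth = np.zeros(sp.n_thr)
            np.add.at(dVth, sp.thr_index, -sv * d * eff.a_hat)
        grads.append(LayerGradients(d, dW.ravel() if dW.ndim > 1 else dW, dVth))
    return grads


def _active_fan_in(net: SpikingNetwork, record: ForwardRecord, l: int) -> float:
    """m^(l): active synapses per neuron (for conv: average over neurons)."""
    sp = net.layers[l]
    rec = record.layers[l]
    if sp.kind == "dense":
        return float(max(1, rec.m))
    frac = rec.m / sp.n_in if sp.n_in else 0.0
    return float(max(1.0, sp.fan_in * frac))


# ---------------------------------------------------------------------------
# optimizers and schedules
# ---------------------------------------------------------------------------

@dataclass
class AdamState:
    m: np.ndarray
    v: np.ndarray

    @classmethod
    def like(cls, arr: np.ndarray) -> "AdamState":
        return cls(np.zeros_like(arr, dtype=np.float64),
                   np.zeros_like(arr, dtype=np.float64))


def adam_step(g: np.ndarray, state: AdamState, t: int,
              beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
              eta: float = 1e-3) -> tuple[np.ndarray, AdamState]:
    """One ADAM step with bias correction; returns (parameter delta, state).

    The delta already carries the minus sign: ``theta <- theta + delta``.
    """
    if t < 1:
        raise ValueError("ADAM step index starts at 1")
    g = np.asarray(g, dtype=np.float64)
    m = beta1 * state.m + (1.0 - beta1) * g
    v = beta2 * state.v + (1.0 - beta2) * g * g
    m_hat = m / (1.0 - beta1 ** t)
    v_hat = v / (1.0 - beta2 ** t)
    delta = -eta * m_hat / (np.sqrt(v_hat) + eps)
    return delta, AdamState(m, v)


def epoch_decay(value: float, epochs: int = 1, tau_epochs: float = 35.0) -> float:
    """Multiplicative schedule ``value * exp(-epochs/tau)``.

    Applied once per epoch (identically) to the learning rates and the
    threshold-regularization step.
    """
    if epochs < 0:
        raise ValueError("epochs must be non-negative")
    return value * math.exp(-epochs / tau_epochs)


@dataclass
class TrainHyper:
    """Training hyper-parameters.

    eta_w : weight learning rate (0.002-0.004 typical).
    eta_th : threshold learning rate; if None, resolves to 0.1*eta_w under
        SGD and eta_w under ADAM.
    optimizer : "sgd" or "adam" (beta1=0.9, beta2=0.999, eps=1e-8).
    lam, beta : exponential weight-regularization coefficients (hidden
        layers only; the max-normalized output error makes output-layer
        weight decay unnecessary).
    rho : threshold-regularization step per input event.
    gamma : coefficient of a_i in the effective output activity a_hat.
    decay_tau : epoch constant of the exp(-1/tau) schedule for eta_w,
        eta_th and rho.
    """

    eta_w: float = 0.002
    eta_th: float | None = None
    optimizer: str = "adam"
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    lam: float = 0.002
    beta: float = 10.0
    rho: float = 1e-4
    gamma: float = 1.0
    decay_tau: float = 35.0

    def __post_init__(self):
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError("optimizer must be 'sgd' or 'adam'")
        for name in ("eta_w", "beta1", "beta2", "eps", "decay_tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("beta1, beta2 must lie in (0, 1)")

    def resolved_eta_th(self, eta_w: float | None = None) -> float:
        base = self.eta_w if eta_w is None else eta_w
        if self.eta_th is not None:
            # keep the user-set ratio when the schedule decays eta_w
            return self.eta_th * (base / self.eta_w)
        return base if self.optimizer == "adam" else 0.1 * base


def apply_updates(net: SpikingNetwork, grads: list[LayerGradients],
                  hyper: TrainHyper, eta_w: float | None = None,
                  opt_state: dict | None = None, step: int = 1,
                  ) -> list[tuple[np.ndarray | None, np.ndarray | None]]:
    """Apply per-layer parameter updates in place; returns the deltas.

    Under SGD the update is ``-eta * g``; under ADAM the gradient feeds the
    per-parameter moment estimates in ``opt_state``.  Thresholds are kept
    above the layer floor: a threshold that would cross it is held and the
    neuron's weights are raised by the pending decrement instead.
    """
    eta_w = hyper.eta_w if eta_w is None else eta_w
    eta_th = hyper.resolved_eta_th(eta_w)
    deltas: list[tuple[np.ndarray | None, np.ndarray | None]] = []
    for l, (sp, gr) in enumerate(zip(net.layers, grads)):
        if not sp.trainable or gr.dW is None:
            deltas.append((None, None))
            continue
        if hyper.optimizer == "adam":
            if opt_state is None:
                raise ValueError("ADAM requires an optimizer state dict")
            key_w, key_v = ("w", l), ("vth", l)
            if key_w not in opt_state:
                opt_state[key_w] = AdamState.like(net.weights[l])
                opt_state[key_v] = AdamState.like(net.vth[l])
            dw, opt_state[key_w] = adam_step(
                gr.dW, opt_state[key_w], step, hyper.beta1, hyper.beta2,
                hyper.eps, eta_w)
            dv, opt_state[key_v] = adam_step(
                gr.dVth, opt_state[key_v], step, hyper.beta1, hyper.beta2,
                hyper.eps, eta_th)
        else:
            dw = -eta_w * gr.dW
            dv = -eta_th * gr.dVth
        net.weights[l] += dw
        new_vth = net.vth[l] + dv
        below = new_vth < net.vth_floor[l]
        if np.any(below):
            idx = np.flatnonzero(below)
            lift = net.vth[l][idx] - new_vth[idx]  # withheld decrease
            new_vth[idx] = net.vth[l][idx]
            if sp.kind == "dense":
                W = net.weights[l].reshape(sp.n_out, sp.n_in)
                W[idx, :] += lift[:, None]
            else:  # per-map thresholds: lift that map's kernel weights
                per_map = sp.n_slots // sp.n_thr
                Wm = net.weights[l].reshape(sp.n_thr, per_map)
                Wm[idx, :] += lift[:, None]
            dv = new_vth - net.vth[l]
        net.vth[l] = new_vth
        deltas.append((dw, dv))
    return deltas


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _one_hot(label: int, n: int) -> np.ndarray:
    y = np.zeros(n)
    y[label] = 1.0
    return y


def regularization_loss(net: SpikingNetwork, hyper: TrainHyper) -> float:
    """Sum of the exponential weight-regularizer cost over hidden layers."""
    total = 0.0
    for sp, w in zip(net.layers[:-1], net.weights[:-1]):
        if not sp.trainable:
            continue
        rows = w.reshape(-1, sp.fan_in) if sp.kind == "dense" else \
            w.reshape(sp.n_thr, -1)
        sq = np.sum(rows * rows, axis=1)
        total += 0.5 * hyper.lam * float(np.sum(np.exp(
            np.minimum(hyper.beta * (sq - 1.0), 50.0))))
    return total


class Trainer:
    """Per-sample (batch size 1) spike-based backpropagation.

    For each presentation: events are propagated forward in training mode
    (threshold regularization active), the output spike counts give the
    normalized error, one backward pass forms the gradients, and the
    parameters are updated.  Learning rates and the threshold-
    regularization step decay by ``exp(-1/decay_tau)`` after every epoch.
    """

    def __init__(self, net: SpikingNetwork, hyper: TrainHyper | None = None):
        self.net = net
        self.hyper = hyper or TrainHyper()
        self.eta_w = self.hyper.eta_w
        self.rho = self.hyper.rho
        self.opt_state: dict = {}
        self.step = 0
        self.history: list[dict] = []
        n_hidden = sum(
            1 for sp in net.layers[:-1] if sp.trainable and sp.kind != "pool"
        )
        self.n_hidden = n_hidden

    @property
    def n_out(self) -> int:
        return self.net.layers[-1].n_out

    def train_sample(self, stream, label: int,
                     duration: float | None = None) -> tuple[float, bool]:
        """One forward/backward/update cycle; returns (loss, correct)."""
        record = self.net.forward(stream, duration=duration, train=True,
                                  rho=self.rho)
        counts = record.output_counts
        y = _one_hot(label, self.n_out)
        e = output_error(counts, y)
        pred = int(np.argmax(counts))
        correct = pred == label and counts[pred] > 0
        peak = counts.max()
        o = counts / peak if peak > 0 else np.zeros_like(y)
        loss = 0.5 * float(np.sum((o - y) ** 2)) + regularization_loss(
            self.net, self.hyper)
        if record.layers[0].m == 0:
            warnings.warn("sample skipped: no active input synapses")
            return loss, correct
        grads = backpropagate(record, e, self.net, self.hyper)
        self._add_weight_regularization(grads)
        self.step += 1
        apply_updates(self.net, grads, self.hyper, eta_w=self.eta_w,
                      opt_state=self.opt_state, step=self.step)
        self._check_finite()
        return loss, correct

    def _add_weight_regularization(self, grads: list[LayerGradients]) -> None:
        # hidden layers only; Eq-16's max-normalized output needs no decay
        for l, sp in enumerate(self.net.layers[:-1]):
            if not sp.trainable or grads[l].dW is None:
                continue
            rows = (self.net.weights[l].reshape(sp.n_out, sp.n_in)
                    if sp.kind == "dense"
                    else self.net.weights[l].reshape(sp.n_thr, -1))
            grads[l].dW += exp_weight_decay(
                rows, self.hyper.beta, self.hyper.lam).ravel()

    def _check_finite(self) -> None:
        for l, (w, v) in enumerate(zip(self.net.weights, self.net.vth)):
            if not (np.all(np.isfinite(w)) and np.all(np.isfinite(v))):
                raise FloatingPointError(
                    f"training diverged: non-finite parameters in layer {l} "
                    f"({self.net.layers[l].kind})"
                )

    def end_epoch(self) -> None:
        """Decay learning rates and threshold regularization."""
        self.eta_w = epoch_decay(self.eta_w, 1, self.hyper.decay_tau)
        self.rho = epoch_decay(self.rho, 1, self.hyper.decay_tau)

    def fit(self, dataset, epochs: int, train_duration: float = 0.050,
            rng: np.random.Generator | None = None,
            first_epoch_duration: float | None = None,
            stop_at_accuracy: float | None = None) -> list[dict]:
        """Train for ``epochs`` epochs over ``dataset``.

        ``dataset`` provides ``n_train`` and ``train_sample(i, duration,
        rng) -> (stream, label)``; events are regenerated per presentation
        when the dataset is stochastic.  Deep stacks (two or more hidden
        layers) use a longer first-epoch presentation (200 ms by default)
        so that early activity survives the initially large thresholds.
        """
        rng = rng or np.random.default_rng(0)
        if first_epoch_duration is None and self.n_hidden >= 2:
            first_epoch_duration = 0.200
        for epoch in range(1, epochs + 1):
            dur = (first_epoch_duration
                   if (epoch == 1 and first_epoch_duration) else train_duration)
            losses, hits = [], 0
            for i in range(dataset.n_train):
                stream, label = dataset.train_sample(i, dur, rng)
                loss, ok = self.train_sample(stream, label, duration=dur)
                losses.append(loss)
                hits += ok
            acc = hits / dataset.n_train
            self.history.append(
                {"epoch": epoch, "loss": float(np.mean(losses)),
                 "train_accuracy": acc, "eta_w": self.eta_w, "rho": self.rho}
            )
            self.end_epoch()
            if stop_at_accuracy is not None and acc >= stop_at_accuracy:
                break
        return self.history


def evaluate(net: SpikingNetwork, dataset, duration: float = 1.0,
             rng: np.random.Generator | None = None,
             split: str = "test") -> dict:
    """Classification accuracy with long read-out presentations.

    Predicted class is the output neuron with the most spikes (ties
    resolved toward the lowest index and counted in the report).
    """
    rng = rng or np.random.default_rng(0)
    n = dataset.n_test if split == "test" else dataset.n_train
    sample = dataset.test_sample if split == "test" else dataset.train_sample
    n_out = net.layers[-1].n_out
    hits, ties = 0, 0
    confusion = np.zeros((n_out, n_out), dtype=np.int64)
    for i in range(n):
        stream, label = sample(i, duration, rng)
        counts = net.forward(stream, duration=duration).output_counts
        pred = int(np.argmax(counts))
        if (counts == counts[pred]).sum() > 1:
            ties += 1
        confusion[label, pred] += 1
        hits += pred == label
    return {
        "accuracy": hits / n if n else float("nan"),
        "n": n,
        "ties": ties,
        "confusion": confusion,
    }
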