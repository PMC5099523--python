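"""Weight and threshold regularization.

Two mechanisms keep training of spiking networks stable:

* **Exponential weight regularization** — a decay whose rate grows
  exponentially with the squared weight sum of a neuron,
  ``L_w = (lambda/2) * exp(beta * (sum_j w_ij^2 - 1))``.  It strongly
  prohibits weight growth (like max-norm) while always decaying a little
  (like L2), holding each neuron's squared fan-in sum near the value 1
  established at initialization.

* **Threshold regularization** — a homeostatic per-event rule that
  balances activity across the N neurons of a layer: neurons that fire on
  an input spike have their threshold raised by ``rho*N``, then all N
  thresholds are lowered by ``rho*N_w`` (N_w = number that fired).  The
  threshold sum is conserved exactly; rarely active neurons become more
  excitable, preventing dead neurons, which matters most under WTA
  competition.  A lower bound (floor) protects against runaway firing: a
  neuron at the floor keeps its threshold and instead has all its weights
  raised by the pending decrement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["RegState", "exp_weight_decay", "threshold_regularize"]

_EXP_CLAMP = 50.0


@dataclass
class RegState:
    """Regularization parameters.

    lam, beta : exponential weight-decay coefficients (typical: lambda in
        [0.002, 0.04], beta = 10).
    rho : threshold-regularization step per input event (typical:
        [4e-5, 2e-4]); decayed together with the learning rates.
    vth_floor : lower bound on thresholds (default 1% of the initial
        threshold, set by the network at initialization).
    """

    lam: float = 0.002
    beta: float = 10.0
    rho: float = 1e-4
    vth_floor: float = 0.0

    def __post_init__(self):
        if min(self.lam, self.beta, self.rho, self.vth_floor) < 0:
            raise ValueError("regularization parameters must be non-negative")


def exp_weight_decay(w: np.ndarray, beta: float, lam: float) -> np.ndarray:
    """Gradient of the exponential regularizer, row-wise per neuron.

    For a weight matrix (neurons x synapses) or a single weight row,
    returns ``beta*lam * w_ij * exp(beta*(sum_j w_ij^2 - 1))``; this is
    added to the weight gradient of hidden layers on every update.  The
    exponent is clamped (with a warning) to avoid overflow for weight rows
    far outside the stability corridor.
    """
    w = np.asarray(w, dtype=np.float64)
    row_sq = np.sum(w * w, axis=-1, keepdims=True)
    expo = beta * (row_sq - 1.0)
    if np.any(expo > _EXP_CLAMP):
        warnings.warn(
            "exponential weight regularizer: clamping exponent "
            f"(max {float(expo.max()):.1f} > {_EXP_CLAMP})",
            RuntimeWarning,
        )
        expo = np.minimum(expo, _EXP_CLAMP)
    return beta * lam * w * np.exp(expo)


def threshold_regularize(
    vth: np.ndarray,
    fired: np.ndarray,
    rho: float,
    n_layer: int | None = None,
    vth_floor: float | np.ndarray = 0.0,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Apply one step of the homeostatic threshold rule.

    ``fired`` holds the indices of neurons that spiked on the current
    input event.  Returns the updated threshold vector (a copy).  If
    ``weights`` (neurons x synapses, modified in place) is given, neurons
    whose threshold would cross ``vth_floor`` keep their threshold and
    have all their weights raised by the pending decrement instead.
    """
    vth = np.array(vth, dtype=np.float64, copy=True)
    fired = np.unique(np.asarray(fired, dtype=np.int64))
    if fired.size == 0:
        return vth
    N = int(n_layer if n_layer is not None else vth.size)
    N_w = int(fired.size)
    vth[fired] += rho * N
    dec = rho * N_w
    floored = vth - dec < vth_floor
    vth[~floored] -= dec
    if np.any(floored) and weights is not None:
        weights[np.flatnonzero(floored), :] += dec
    return vth
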