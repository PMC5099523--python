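"""Winner-take-all lateral inhibition.

A WTA circuit groups neurons with all-to-all inhibitory lateral
connections of one shared strength ``kappa`` in [-1, 0].  When any member
spikes, every other member's membrane potential is reduced by
``|kappa| * V_th`` of the *inhibited* neuron (threshold-proportional
inhibition) and clipped at its lower bound ``-V_th``, and the member is
put into the refractory state so that the winner gets another chance to
win the next competition.

``sigma`` is the expected efficacy of inhibition: because the potential is
clipped at -V_th, the average realized inhibition is a fraction of the
full ``kappa * V_th``.  It enters only the rate-domain transfer function
and its gradients (sigma ~ 0.5 works well in practice); the forward
dynamics always apply the full inhibition with clipping.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .lif import NeuronParams, NeuronState, decay

__all__ = ["WTAConfig", "apply_inhibition"]


@dataclass(frozen=True)
class WTAConfig:
    """Shared-strength WTA circuit configuration.

    kappa : lateral strength, -1 <= kappa <= 0 (0 disables competition).
    sigma : expected inhibition efficacy in (0, 1].
    members : indices of participating neurons, or None for "all in layer".
    """

    kappa: float = -0.4
    sigma: float = 0.5
    members: Sequence[int] | None = None

    def __post_init__(self):
        if not -1.0 <= self.kappa <= 0.0:
            raise ValueError("kappa must lie in [-1, 0]")
        if not 0.0 < self.sigma <= 1.0:
            raise ValueError("sigma must lie in (0, 1]")


def apply_inhibition(
    states: list[NeuronState],
    params: list[NeuronParams],
    winner: int,
    cfg: WTAConfig,
    t: float,
) -> list[NeuronState]:
    """Inhibit all WTA members except ``winner`` at the winner's spike time.

    For every other member: the potential is decayed to ``t``, shifted by
    ``kappa * V_th`` (clipped at ``-V_th``), and the neuron enters the
    refractory state (``t_out = t``, dynamic weight restarting from 0).
    The winner's state is left untouched by this call (its own reset is
    handled by the spike that triggered the inhibition).
    """
    members = range(len(states)) if cfg.members is None else cfg.members
    if winner not in members:
        raise IndexError(f"winner {winner} not a member of the WTA circuit")
    out = list(states)
    for i in members:
        if i == winner:
            continue
        st, p = states[i], params[i]
        v = decay(st.v_mp, st.t_last, t, p.tau_mp)
        a = decay(st.a, st.t_last, t, p.tau_mp)
        v = max(-p.v_th, v + cfg.kappa * p.v_th)
        w_dyn = 0.0 if p.t_ref > 0 else 1.0
        out[i] = replace(st, v_mp=v, t_last=t, t_out=t, w_dyn=w_dyn, a=a)
    return out
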