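"""Event-driven LIF dynamics of a single neuron.

Drives one leaky integrate-and-fire neuron with a constant-rate Poisson
train and compares the measured output rate with the rate-domain
prediction s/V_th (weighted input drive over threshold), the surrogate
through which gradients flow during training.
"""

import numpy as np

from spikegrad import NeuronParams, NeuronState, poisson_stream, receive_spike

params = NeuronParams(v_th=0.5, tau_mp=0.2, t_ref=0.0)
w = 0.05
rate_in = 1500.0
duration = 5.0

stream = poisson_stream([rate_in], duration, np.random.default_rng(0))
state = NeuronState()
n_out = 0
for t in stream.times:
    state, fired = receive_spike(state, params, w, float(t))
    n_out += fired

predicted = w * rate_in / params.v_th
measured = n_out / duration
print(f"input rate {rate_in:.0f} eps, weight {w}, threshold {params.v_th}")
print(f"predicted output rate s/V_th = {predicted:.1f} eps")
print(f"measured  output rate        = {measured:.1f} eps "
      f"({100 * abs(measured - predicted) / predicted:.1f}% off)")
print("The agreement is what lets filtered spike traces act as a "
      "differentiable stand-in for the spiking nonlinearity.")
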