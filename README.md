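# spikegrad

Event-driven spiking neural networks trained by backpropagation on
low-pass-filtered spike traces.

Spiking neural networks (SNNs) communicate through discrete, asynchronously
timed events rather than continuous activations, which makes them natural
consumers of data from event-based sensors (dynamic vision sensors emitting
per-pixel on/off brightness events) and attractive for low-latency,
low-power inference. Training them is hard because spike generation is not
differentiable. `spikegrad` implements a supervised training framework that
works directly on spike signals: the simulator is purely event-driven (no
time stepping), and the exponentially filtered spike traces that spikes
leave on the membrane potential are treated as differentiable signals, with
the discontinuities at spike times regarded as noise. The package is aimed
at researchers in neuromorphic computing and computational neuroscience who
want a compact, fully tested reference implementation of this training
scheme that runs at desk scale on synthetic event streams or DVS-style
recordings.

## Model

**Neuron.** A leaky integrate-and-fire (LIF) neuron is updated per input
event:

    V_mp(t_p) = V_mp(t_{p-1}) · exp((t_{p-1} − t_p)/τ_mp) + w_i · w_dyn

On crossing the threshold `V_th` the neuron spikes and `V_th` is
subtracted; the potential is clipped from below at `−V_th`. The dynamic
weight `w_dyn ∈ [0, 1]` implements the refractory period: after an output
spike (or an inhibition trigger) at `t_out`, `w_dyn = (Δt/T_ref)²` until it
recovers to 1 at `Δt = T_ref`.

**Winner-take-all (WTA) circuits.** Within a layer configured as a WTA
group, any spike inhibits all other members by `κ·V_th,i` (threshold-
proportional, `−1 ≤ κ ≤ 0`) and puts them into the refractory state.

**Surrogate gradients.** Each input synapse and each neuron maintain
filtered traces `x_k(t) = Σ_p exp((t_p−t)/τ_mp)` and
`a_i(t) = Σ_q exp((t_q−t)/τ_mp)`. Setting the residual membrane potential
to zero gives the rate-domain transfer function of a WTA layer,

    a_i = s_i / V_th,i + σ Σ_{j≠i} κ_ij a_j ,   s_i = Σ_k w_ik x_k ,

where `σ ≈ 0.5` is the expected efficacy of lateral inhibition (inhibition
is partly absorbed by the `−V_th` lower bound). First-order derivatives of
this relation with respect to weights, thresholds, and inputs give the
backpropagation rule, with errors normalized layer-wise,

    δ_i^(l) = (g_i/ḡ) · √(M^(l+1)/m^(l+1)) · Σ_j w_ji^(l+1) δ_j^(l+1) ,

(`g_i = 1/V_th,i`, `ḡ` its RMS over active neurons, `M`/`m` total/active
fan-in) so that the expected squared error sum stays constant across
layers — the ingredient that lets deep stacks train without exploding
gradients. Weights are initialized uniform on `±√(3/M)` (unit expected
squared row sum) with thresholds `α·√(3/M)`, `α > 1`; exponential weight
regularization and a homeostatic per-event threshold rule (+ρN to firing
neurons, −ρN_w to all) keep the network in this operating regime.

## Worked example

`examples/04_train_synthetic.py` trains a 100→20(WTA)→4 network on a
4-class Poisson rate-pattern task (5 keps total input rate, 50 ms training
presentations, ADAM):

```
epoch  1: loss 0.2097 train accuracy 0.74
epoch  2: loss 0.0423 train accuracy 0.94
...
epoch 10: loss 0.0148 train accuracy 0.97
test accuracy with 1 s read-out: 1.00 (40 samples)
```

The per-epoch accuracy is measured on the 50 ms training presentations;
the final line evaluates with 1 s presentations, which integrate more
output spikes per decision. The remaining examples demonstrate Poisson
encoding (`01`), single-neuron rate consistency (`02`), WTA sparsification
(`03`), and AER file round trips with 300-event window sampling (`05`).

A thin CLI wraps the same library calls:

```bash
spikegrad synth --kind rate --out ds/          # generate a dataset
spikegrad encode image.png --out stream.h5     # Poisson-encode an image
spikegrad train run.yaml --out run/            # train from a YAML config
spikegrad eval run/checkpoint.h5 run.yaml      # evaluate a checkpoint
```

## Scope

Benchmark-scale experiments (MNIST / N-MNIST downloads, hours of training)
are outside the desk-scale test surface; the synthetic task generator in
`spikegrad.synth` produces event streams with the statistical structure
the trainer assumes, at sizes that run in seconds. See `docs/methods.md`
for modeling assumptions, parameter defaults, and known limitations.
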