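# Methods

This note records the model, the numerical choices, and the places where
the design was genuinely open, in the package's own terms.

## Event-driven simulation

The simulator is purely event-driven: neuron state is stored lazily at the
time of its last update and rolled forward analytically
(`V ← V·exp(−Δt/τ_mp)`) when the next event touches it. The test suite
verifies spike-for-spike equivalence against a 1 µs time-stepped oracle,
so the event-driven formulation loses nothing relative to fine-grained
clocked simulation.

**Equal-time events.** Zero-delay propagation means inter-layer spikes and
multi-source inputs can share a timestamp. The engine canonically orders
every equal-time batch by source index and processes it sequentially, with
full threshold resolution after each event. This makes runs deterministic
and spike counts invariant under permutations of simultaneous input
events, while preserving the sequential semantics of refractory
suppression (the second of two simultaneous spikes into a fresh pooling
neuron is absorbed by the refractory state the first one triggered).

**Refractory mechanism.** Every trigger — an own output spike or a lateral
inhibition — sets `t_out = t` and restarts the quadratic recovery
`w_dyn = (Δt/T_ref)²` from zero; once recovered, `w_dyn` latches at 1
until the next trigger. `w_dyn` scales synaptic input only; lateral
inhibition itself is applied at full strength (with clipping at `−V_th`).

**Reset.** Threshold crossing subtracts `V_th` once per spike; if a single
synaptic weight exceeds `2·V_th` the subtraction repeats and multiple
spikes are emitted at the same timestamp. This preserves the
proportionality between input drive and output rate that the rate-domain
transfer function assumes.

**WTA resolution.** Within one event, candidate neurons are examined in
ascending index; each winner's spike immediately inhibits its group
(threshold-proportional, clipped), which can silence later candidates.
Ties at identical membrane trajectories therefore resolve toward the
lowest index, deterministically.

## Rate-domain surrogate and gradients

The transfer function solves the *rectified* fixed point of
`a = s/V_th + σ K a`: units whose rate would be negative are clamped at
zero and removed from the coupled system, since a silent unit cannot
inhibit its peers. The parameter derivatives are first-order — they
differentiate the per-neuron relation with peer activities frozen; lateral
feedback of a parameter through other neurons' rates is a higher-order
effect of the (inhibitory, hence rapidly decaying) lateral chains and is
neglected. The input gradient, by contrast, is the exact derivative of the
coupled linear system; for uniform lateral strength µ it has the closed
form

    ∂a_i/∂x_k = 1/(1+µσ) · ( w_ik/V_i + µσ/(1−µσ(n−1)) · Σ_j w_jk/V_j ) ,

which the tests verify against the dense matrix-inverse form to 1e−10 and
against central finite differences of the solve. The form is singular only
at `µσ = −1` (full-strength inhibition with unit efficacy), which is
guarded.

**How well does the rate model describe the simulator?** Without WTA,
under positive drive with negligible refractoriness, measured per-neuron
rates track `s_i/V_th` within a few percent once the leak residual is
small — the relative bias is about `⟨V⟩/(τ_mp·V_th·rate)`, so
consistency checks use a long τ (0.2–1 s) or rates ≫ 1/τ. With WTA the
constant-efficacy model is an *ensemble* statement: in any single
balanced-drive network the realized efficacy is close to 1 (clipping at
`−V_th` rarely binds), while strongly suppressed units fire from membrane-
fluctuation rectification that no linear rate model captures. Averaged
over random networks at moderate rates the total output rate matches the
σ = 0.5 rectified fixed point within ~10%, which is the level at which the
acceptance suite checks it; per-neuron, per-instance deviations of 15–40%
are expected and normal.

## Error normalization and updates

Backpropagated errors are rescaled per layer by `(g_i/ḡ)·√(M/m)` with
`ḡ = sqrt(mean g² over active neurons)` (an RMS, so the factor is
dimensionless and exactly 1 for the uniform thresholds produced by
initialization). Under the unit-row-energy initialization this keeps
`E[Σ δ²]` constant across depth, which the acceptance suite verifies at 5%
on a 200-100-50 stack. Updates use the square-root scalings
`Δw = −η_w·√(N/m)·δ·x̂` and `ΔV_th = +η_th·√(N/(mM))·δ·â` with
`â_i = γ·a_i − σ Σ_{j≠i} κ a_j` (γ = 1 by default; the coefficient is
exposed in `TrainHyper` since nothing pins it). The threshold update
direction follows the chain rule through `∂a/∂V_th = −â/V_th`: thresholds
*decrease* when a neuron under-responds to its target, the homeostatically
sensible direction; smaller default threshold learning rates (0.1·η_w
under SGD) keep thresholds from collapsing.

Gradients flow only through active neurons and synapses (nonzero trace at
the end of the presentation). The output layer's δ is the normalized error
itself, not gated by activity: a silent target neuron must still receive
weight updates, otherwise an initially quiet network could never begin to
learn (and the all-silent error convention `e = −y` would be dead code).

The backward pass runs once per presentation (batch size 1), reading all
traces at the common end time T — the only instant at which every layer's
information is complete.

**Convolutional layers** share `k²·C` weights and one threshold per
feature map. The active fan-in `m` of a conv layer is taken as the mean
number of active synapses per neuron (fan-in × active-input fraction);
per-neuron active counts would differ only in the √-scaling of updates.
Pooling layers are fixed routing (weights 1, threshold 0.8, untrained)
and pass gradients through scaled by `1/V_th` like any layer; threshold
regularization applies only to layers with per-neuron thresholds, since
the per-event ±ρ bookkeeping is ill-defined for a threshold shared across
spatial positions.

## Regularization

Exponential weight decay `βλ·w·exp(β(Σw²−1))` is added to the weight
gradient of hidden layers each update (the max-normalized output error
makes output-layer decay unnecessary). The exponent is clamped at 50 with
a warning; in normal operation `Σw²` stays within roughly [0.5, 2] of the
initialization condition. Threshold regularization runs during forward
propagation in training mode, per input event: firing neurons gain `ρN`,
then all `N` neurons lose `ρN_w`, conserving `Σ V_th` exactly. A floor at
1% of the initial threshold (the value is a package choice; nothing pins
it) stops runaway excitability: a neuron at the floor keeps its threshold
and has all its weights raised by the pending decrement instead, for both
the regularizer and gradient updates.

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| τ_mp | 20 ms (200 ms for slow spatio-temporal streams) | membrane/trace time constant |
| T_ref | 1 ms | maximum refractory duration |
| α | 3–10 per layer | threshold scale at initialization |
| η_w | 0.002–0.004 | weight learning rate |
| η_th | 0.1·η_w (SGD), η_w (ADAM) | threshold learning rate |
| β, λ | 10, 0.002–0.04 | exponential weight decay |
| ρ | 4e−5–2e−4 | threshold-regularization step |
| σ | 0.5 | expected lateral-inhibition efficacy |
| κ | −0.4 (hidden), −1.0 (output) | lateral strength |
| decay | exp(−1/35) per epoch | schedule for η_w, η_th, ρ |

Training presentations default to 50 ms; evaluation uses 1 s read-outs
(accuracy improves with integration time and is stable at 1 s). Networks
with two or more hidden layers use a 200 ms first epoch so that activity
survives the initially large thresholds.

## Synthetic tasks

The generator produces the statistical structure the trainer assumes, at
desk scale. The rate task gives each class an elevated Poisson rate on a
disjoint random subset of inputs, total rate normalized to 5 keps, with a
5% background floor so that losing neurons and the threshold-
regularization paths are exercised. The moving task translates a small
per-class pattern across a 2-channel (on/off polarity) grid in 3 timed
phases, emulating saccade-style sensor streams; it shares the AER
flattening convention and round-trips through the binary event-file
writer. What these tasks do *not* model: sensor noise and pixel mismatch,
realistic saccade kinematics, or the heavy class overlap of natural data —
so passing tests demonstrate the correctness and stability of the
training machinery, not benchmark-level generalization.

## Problem sizes

The acceptance suite uses a 200-100-50 stack with 1000 Monte-Carlo draws
for the energy measurement, 10⁴ neurons per fan-in for the initialization
condition, 100 encodings for the encoder check, 50 random trains against
the 1 µs clocked oracle, 10 random 30→8 networks for the WTA rate
comparison, and a 100→20→4 network (80 presentations/epoch, up to 30
epochs, 3 seeds) for end-to-end learning — sizes chosen so the whole suite
runs in a few minutes on one CPU while keeping Monte-Carlo error well
inside the asserted tolerances.

## Known limitations

* No axonal/synaptic delays, conductance-based synapses, or adaptive
  thresholds; no recurrent topologies; no max pooling.
* Lateral strengths κ are fixed, not learned (the derivative `σ·a_h` is
  provided but unused by the trainer).
* The rate-domain surrogate ignores refractoriness; training regimes where
  refractory periods dominate (per-neuron rates approaching 1/T_ref) break
  the gradient model's assumptions.
* Mini-batching is intentionally absent (batch size 1 per presentation);
  ADAM provides the variance damping instead.
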