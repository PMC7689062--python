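# Methods

## Model

Neurons are conductance-based leaky integrate-and-fire units. The membrane
potential obeys

    tau_m dv/dt = (v_r - v) - g_e (v - E_exc) - g_i (v - E_inh)

with tau_m = 100 ms, resting potential v_r = -60 mV, base threshold
v_th = -50 mV, excitatory reversal E_exc = 0 mV, inhibitory reversal
E_inh = -100 mV. Conductances are dimensionless multiples of the leak
conductance; each decays first-order (tau_ge = 1 ms, tau_gi = 2 ms) and
jumps by the synaptic weight whenever a presynaptic spike arrives. A neuron
spikes when v reaches v_th + theta, resets to v_r, and its adaptive offset
theta jumps by theta_plus and decays exponentially with tau_theta — the
homeostatic mechanism that keeps winner-take-all competition fair. Default
theta_plus = 0.01 mV; tau_theta is not constrained by the model source and
defaults to 1e5 ms (slow relative to one presentation). The refractory
period defaults to 0 ms; during a nonzero refractory window the membrane is
clamped at v_r.

Plasticity is the triplet STDP rule. Each presynaptic unit carries a trace
x_j (tau_x = 8 ms), each postsynaptic neuron a fast trace y1_i
(tau_y1 = 16 ms) and a slow trace y2_i (tau_y2 = 32 ms); every trace decays
exponentially and is reset to 1 at its owner's spike. A presynaptic spike
at j depresses every active synapse (j, i) by mu_pre * y1_i
(mu_pre = 1e-4); a postsynaptic spike at i potentiates every active synapse
by mu_post * x_j * y2_i (mu_post = 0.01), using y2_i as it stood just
before its own reset. Weights are clipped to [0, w_max]; w_max is not
fixed by the model source and defaults to 1. As printed, the source rule
attaches depression to the postsynaptic spike and potentiation to the
presynaptic one, which transposes the standard triplet rule and would make
x_j identically 1 inside its own update; we implement the standard
semantics and provide no literal mode.

Within one time step the event order is: deliver spikes (conductance
increments), integrate membranes, detect spikes, decay traces, apply
depression for presynaptic spikes, apply potentiation for postsynaptic
spikes, then reset traces. Simultaneous pre/post spikes therefore both
fire their updates.

## Architecture

The input layer has one Poisson unit per pixel; unit j fires each step
with probability (I_j / 255) * max_rate * dt (rate coding). The plastic
projection fully connects the input to n_exc excitatory neurons; weights
are initialized uniformly on [0, 0.3 * w_max]. Each excitatory neuron
drives one dedicated inhibitory neuron (fixed weight w_exc_inh = 10.4
conductance units) and each inhibitory neuron suppresses every excitatory
neuron except its source (w_inh_exc = 17.0) — lateral inhibition
implementing the winner-take-all competition. Recurrent spikes are
delivered with a one-step synaptic delay. Presentation timing and input
scaling follow the conventions of the classic unsupervised-WTA digit
architecture: 350 ms presentation, 150 ms rest, 63.75 Hz at full
intensity; all configurable.

After training, a dedicated pass with plasticity and threshold adaptation
frozen labels each excitatory neuron with the class for which it fired the
most spikes (ties to the lowest class; neurons silent for every class get
label 0 and are flagged). An image is classified as the class whose neuron
group has the highest mean spike count; empty groups are skipped, a fully
silent response falls back to class 0 with a no-signal flag.

## Pruning

Pruning acts only on the plastic input -> excitatory projection, at batch
boundaries (default 5,000 images) after a pre-pruning phase (default
30,000 images). An active synapse strictly below its neuron's threshold is
removed permanently: it stops conducting, stops learning, and is never
resurrected. A weight exactly at threshold survives.

The global threshold follows one of three families in the pruning-step
index k (time acts at batch granularity, since pruning only happens at
batch boundaries): f1(k) = wth0 * a^k, f2(k) = w_max - (w_max - wth0) *
b^(-k), f3(k) = wth0 + c * k, each capped at w_max so the network is never
pruned entirely. Optimized full-scale factors: a = 1.3 (100 neurons) or
1.2 (800 neurons), b = 1.1, c = 0.01 for adaptation over time; a = 1.15
for adaptation over neurons; spike-count interval SI = 30.

For adaptation over neurons, per-neuron average spike counts over the last
batch are grouped greedily from the weakest neuron upward: take the
minimum count S among ungrouped neurons and group everything within
[S, S + SI], ends inclusive. Group 0 receives the current global threshold
exactly; group n receives the adaptation family evaluated at index n.
SI = infinity gives one group and disables the neuron adaptation; neutral
factors (a = 1, b = 1, c = 0) disable the time adaptation; with both
neutral every method reduces bit-for-bit to constant pruning.

Baselines: constant threshold; soft pruning, which freezes sub-threshold
weights at their current value (they keep conducting, stop learning, and
connectivity — the active fraction — still falls, but no synapse is
removed from the conducting set); and post-training pruning, a single
uniform threshold applied after the full pass, leaving training costs
untouched.

If a neuron loses its last conducting synapse a warning is emitted; no
survivor floor is enforced.

## Cost accounting

One accumulation SOP per presynaptic spike delivered across each
non-removed synapse; one STDP SOP per performed weight update on an active
synapse (counted even when the trace product is zero — hardware executes
the update regardless), pre- and post-triggered tallied separately. Frozen
synapses accumulate but never learn; removed synapses cost nothing.
Events on the fixed recurrent projections are tallied separately and
excluded from reduction percentages, since pruning cannot affect them.
Reductions are SOPs/image of a pruned run over its same-seed unpruned
baseline; FOM = accuracy loss (percentage points) x normalized total
(training + inference) SOPs/image.

The hardware-overhead estimator assumes a synchronous digital design with
one weight memory accessed one word per cycle and no parallelism (an
upper limit): the weight-pruning phase costs n_input * n_exc cycles and
2 * n_input * n_exc operations (one access plus one comparison per
synapse); grouping and adapting phases use per-batch constants (120/400
and 2,000/1,100 cycles/ops, assuming at most 20 groups and 16.8
fixed-point weights). Energy: 23.6 pJ per SOP (the minimum reported for a
current digital neuromorphic chip), 0.5 pJ per SRAM access, every pruning
operation costed as an access (worst case). Per-image averages are
reported as per-batch sums divided by the batch size.

## Numerical scheme

Clock-driven integration with dt = 0.5 ms — half the smallest time
constant (tau_ge = 1 ms); the membrane uses explicit Euler, while
conductances, traces, and theta use exact exponential decay factors, so
inter-spike trace decay is exact to machine precision. The production
presentation loop is a numba-compiled kernel; the public step functions
(`step_neurons`, `decay_traces`, `stdp_on_pre`, `stdp_on_post`) form an
independent reference path, and the suite asserts bit-level agreement
between the two routes. All randomness flows from one seed through
per-component streams (data, initialization, training/assignment/
evaluation encoding), so a rerun from a saved config is bit-identical and
runs differing only in the pruning method consume identical random
numbers.

## Synthetic data

The generator emulates the structure the WTA network exploits in digit
data: each class owns a fixed sparse prototype of bright square blobs
(default 3 blobs of 3 x 3 pixels at intensity 255 on a 16 x 16 grid),
blobs disjoint across classes, and each sample adds independent Gaussian
pixel noise (sigma = 16 intensity units, clipped to [0, 255]). Intensity
maps to Poisson rate, so class separation in pixel space becomes
separable input spike statistics. It does not emulate stroke-like
correlated structure, within-class shape variation, overlapping class
supports, or intensity gradients — so passing desk-scale tests shows the
mechanisms work (receptive fields form, pruning preserves them, costs
scale with connectivity), not that full-scale benchmark accuracy would be
reached.

## Desk-scale study configuration

`desk_scale_config` scales the full protocol to minutes on one core:
3 classes, 30 excitatory neurons, 3,000 training images, 150 ms
presentations with 50 ms rest, 600 assignment and 300 test images. Three
parameters are deliberately rescaled rather than inherited:

* max_rate = 127.5 Hz and theta_plus = 0.05 mV — with a 20x shorter
  training pass and a sparser 256-pixel input, the homeostatic pressure
  per image must be larger or a few early winners monopolize the
  competition and most neurons never differentiate;
* pruning starts at t_m = 1,500 images — the point where the firing-rate
  monitor stabilizes in this configuration, mirroring the
  start-at-stabilization protocol of the full-scale study (and the same
  halfway fraction of training), with 500-image batches;
* SI = 0.5 — desk-scale batch-average counts sit below ~2 spikes/image,
  so the full-scale SI = 30 would put every neuron in one group and
  silently disable the neuron-adaptation mechanism.

Matching constant pruning to a target final connectivity does not require
bisection over training runs: under a constant threshold w a synapse is
removed the first time its weight sits below w at a batch boundary, so the
unpruned baseline's weight snapshots at those boundaries predict final
connectivity as the fraction of synapses whose minimum-over-boundaries
weight is at least w. The matching threshold is the corresponding
quantile; because removal frees STDP updates for the survivors the first
run can overshoot slightly, and one corrective re-run retargets the
quantile.

## Limitations

Single plastic layer only; no axonal delays or multi-compartment neurons;
no neuron pruning, structured pruning, or prune-retrain cycles; the
overhead model counts operations rather than simulating hardware, and
neural-state update energy is acknowledged but not modeled. Full-scale
MNIST/Fashion-MNIST reproduction requires the external IDX downloads and
hours of single-core simulation; the shipped tests and the acceptance
script operate at desk scale.
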