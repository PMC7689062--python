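# snnprune

Online adaptive weight pruning for unsupervised spiking neural networks,
with synaptic-operation energy accounting.

## The problem

Event-driven neuromorphic hardware spends its energy on synaptic operations
(SOPs): every spike delivered across a synapse costs one weight
accumulation, and every plasticity update costs one more. A fully connected
spiking network therefore pays for all of its synapses on every input, even
though most weights end up near zero after unsupervised learning. Pruning
those weights *while training* — not merely afterwards — cuts both training
and inference cost, but a fixed magnitude threshold is a blunt instrument:
too high early in training and still-learning weights are destroyed, too
low and little is removed; and a threshold that suits strongly driven
neurons strips weakly driven ones of their last useful synapses.

`snnprune` implements the adaptive alternative for the classic two-layer
winner-take-all (WTA) digit-recognition architecture: conductance-based
leaky integrate-and-fire neurons,

```
tau_m dv/dt = (v_r - v) - g_e (v - E_exc) - g_i (v - E_inh),
```

Poisson rate coding of pixel intensities, triplet spike-timing-dependent
plasticity (one presynaptic trace `x_j`, fast/slow postsynaptic traces
`y1_i`, `y2_i`; depression `-mu_pre * y1_i` on a presynaptic spike,
potentiation `+mu_post * x_j * y2_i` on a postsynaptic one), and adaptive
firing thresholds for homeostasis. On top of it sit the pruning
controllers:

* **APT** — the global threshold grows with the pruning step `k`:
  `f1(k) = wth0 * a^k`, `f2(k) = w_max - (w_max - wth0) * b^(-k)`, or
  `f3(k) = wth0 + c*k`, confined to `[wth0, w_max]`;
* **APN** — neurons are grouped by batch-average spike count (within-group
  spread at most `SI`); weakly firing groups keep the low base threshold,
  strongly firing groups get it scaled up by the same function families;
* **APTN** — both at once (the full method);
* baselines: constant threshold, soft pruning (freeze instead of remove),
  and post-training pruning.

A `SOPLedger` counts accumulations and STDP updates per phase, and the
cost model turns them into normalized reductions, a figure of merit
`FOM = accuracy_loss x normalized total SOPs/image`, and digital-hardware
overhead estimates (clock cycles, operations, energy, NAND-gate counts)
for the pruning unit itself.

## Worked example

The package ships a desk-scale synthetic study: three sparse blob classes
on a 16 x 16 grid, 30 excitatory neurons, 3,000 training images — the same
shape as the full MNIST study, small enough to train in seconds.

```python
from snnprune import desk_scale_config, run_train

baseline = run_train(desk_scale_config(seed=1, method="none"))
aptn     = run_train(desk_scale_config(seed=1, method="APTN", wth0=0.13))
report   = aptn.fom_report(baseline)
print(f"baseline accuracy {baseline.accuracy:.3f}")
print(f"APTN accuracy {aptn.accuracy:.3f} at connectivity {aptn.connectivity:.3f}")
print(f"train SOP reduction {100 * (1 - report.norm_train):.1f}%  "
      f"inference SOP reduction {100 * (1 - report.norm_infer):.1f}%")
```

prints

```
baseline accuracy 1.000
APTN accuracy 1.000 at connectivity 0.111
train SOP reduction 28.7%  inference SOP reduction 89.6%
```

— adaptive pruning removed 89% of the plastic synapses with no accuracy
loss, cutting training SOPs by 29% and inference SOPs by 90% (inference
cost tracks connectivity almost linearly, since every surviving synapse is
paid for on every input spike).

The same workflow is available from the shell:

```
snnprune train --synthetic --seed 1 --out runs/demo
snnprune prune-sweep --synthetic --seed 1 --wth0 0.01 --wth0 0.04 --wth0 0.08 --out runs/sweep
snnprune overhead --synthetic --out runs/overhead
```

Full-scale runs use MNIST/Fashion-MNIST in IDX format via a YAML config
(`snnprune train --config cfg.yaml`); see `snnprune.data.read_idx` and
`snnprune.experiments.ExperimentConfig`. No dataset is downloaded
automatically.

## Hardware-overhead estimates

```python
from snnprune import estimate_pruning_overhead, estimate_energy, gate_ratio

estimate_pruning_overhead(784, 100)   # weight-pruning phase: 78,400 cycles, 156,800 ops
estimate_energy(96099, 0.0)           # 96,099 SOPs/image -> 2.27 uJ/image
gate_ratio()                          # pruning unit / SNN NAND gates ~ 0.28%
```

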