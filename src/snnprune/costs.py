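"""Synaptic-operation accounting, figure of merit, and hardware overhead.

On event-driven neuromorphic hardware the energy of a network run is
dominated by synaptic operations (SOPs): one weight accumulation per spike
delivered across a synapse, and one STDP update per weight change performed.
Pruning removes synapses and therefore SOPs; this module counts them, turns
the counts into normalized reductions against an unpruned baseline, combines
accuracy loss and cost into a figure of merit

    FOM = accuracy_loss (pct points) x normalized total SOPs/image,

and estimates the clock-cycle / operation / energy / gate-count overhead of
running the pruning algorithm itself on a synchronous digital system.

Counting contract: a presynaptic spike delivered across each non-removed
synapse costs one accumulation SOP; each performed STDP update on an active
synapse costs one STDP SOP (pre- and post-triggered tallied separately, and
counted even when the trace product makes the update zero — the hardware
still executes it); frozen synapses accumulate but never learn; removed
synapses cost nothing.  Only the plastic input -> excitatory projection
enters the reduction percentages, since pruning cannot touch the fixed
recurrent weights; recurrent events are tallied separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SOPLedger",
    "FomReport",
    "OverheadModel",
    "normalized_reduction",
    "compute_fom",
    "select_best_connectivity",
    "estimate_pruning_overhead",
    "estimate_energy",
    "gate_ratio",
]


@dataclass
class SOPLedger:
    """Monotone counters of synaptic operations, split by phase and kind."""

    train_accum: int = 0
    train_stdp_pre: int = 0
    train_stdp_post: int = 0
    infer_accum: int = 0
    images_train: int = 0
    images_infer: int = 0
    # Recurrent (fixed-weight) projections, excluded from reductions.
    train_exc_inh: int = 0
    train_inh_exc: int = 0
    infer_exc_inh: int = 0
    infer_inh_exc: int = 0

    def record_accum(self, phase: str, count: int) -> None:
        if count < 0:
            raise ValueError("SOP counts must be non-negative")
        if phase == "train":
            self.train_accum += count
        elif phase == "infer":
            self.infer_accum += count
        else:
            raise ValueError(f"unknown phase {phase!r}")

    def record_stdp(self, trigger: str, count: int) -> None:
        """STDP updates occur only during training."""
        if count < 0:
            raise ValueError("SOP counts must be non-negative")
        if trigger == "pre":
            self.train_stdp_pre += count
        elif trigger == "post":
            self.train_stdp_post += count
        else:
            raise ValueError(f"unknown trigger {trigger!r}")

    def record_recurrent(self, phase: str, exc_inh: int = 0, inh_exc: int = 0) -> None:
        if phase == "train":
            self.train_exc_inh += exc_inh
            self.train_inh_exc += inh_exc
        else:
            self.infer_exc_inh += exc_inh
            self.infer_inh_exc += inh_exc

    def record_image(self, phase: str) -> None:
        if phase == "train":
            self.images_train += 1
        else:
            self.images_infer += 1

    @property
    def train_stdp(self) -> int:
        return self.train_stdp_pre + self.train_stdp_post

    @property
    def train_total(self) -> int:
        return self.train_accum + self.train_stdp

    def sops_per_image(self, phase: str) -> float:
        if phase == "train":
            if self.images_train == 0:
                raise ZeroDivisionError("no training images recorded")
            return self.train_total / self.images_train
        if self.images_infer == 0:
            raise ZeroDivisionError("no inference images recorded")
        return self.infer_accum / self.images_infer


def normalized_reduction(pruned: SOPLedger, baseline: SOPLedger) -> dict[str, float]:
    """Percent reduction in SOPs/image of a pruned run against its baseline.

    Returns train / infer reductions in percent, plus the normalized (pruned
    over baseline) per-phase and total ratios used by the figure of merit.
    """
    norm_train = pruned.sops_per_image("train") / baseline.sops_per_image("train")
    norm_infer = pruned.sops_per_image("infer") / baseline.sops_per_image("infer")
    total_base = baseline.sops_per_image("train") + baseline.sops_per_image("infer")
    total_pruned = pruned.sops_per_image("train") + pruned.sops_per_image("infer")
    return {
        "train_reduction_pct": 100.0 * (1.0 - norm_train),
        "infer_reduction_pct": 100.0 * (1.0 - norm_infer),
        "norm_train": norm_train,
        "norm_infer": norm_infer,
        "norm_total": total_pruned / total_base,
    }


@dataclass(frozen=True)
class FomReport:
    """Accuracy-vs-cost summary for one pruned run."""

    connectivity: float
    accuracy: float
    accuracy_loss: float  # percentage points vs the unpruned baseline
    norm_train: float
    norm_infer: float
    norm_total: float
    fom: float


def compute_fom(accuracy_loss: float, norm_total: float) -> float:
    """Figure of merit: accuracy loss (pct points) x normalized total SOPs."""
    return accuracy_loss * norm_total


def select_best_connectivity(reports: list[FomReport]) -> FomReport:
    """The sweep point minimizing the figure of merit (first on ties)."""
    if not reports:
        raise ValueError("empty sweep")
    return min(reports, key=lambda r: r.fom)


@dataclass(frozen=True)
class OverheadModel:
    """Constants for the digital-hardware overhead estimate.

    Per-batch grouping/adapting costs assume at most ``n_groups`` neuron
    groups, fixed-point weights with ``int_bits``/``frac_bits``, a single
    weight memory accessed one word per cycle, and no parallelism — an
    upper-limit estimate.  Energy constants: 23.6 pJ per SOP (the minimum
    reported for a current digital neuromorphic chip) and 0.5 pJ per SRAM
    access, with every pruning operation costed as a memory access (worst
    case).
    """

    n_groups: int = 20
    int_bits: int = 16
    frac_bits: int = 8
    grouping_cycles: int = 120
    grouping_ops: int = 400
    adapting_cycles: int = 2000
    adapting_ops: int = 1100
    energy_per_sop_pj: float = 23.6
    energy_per_access_pj: float = 0.5
    gates_prune: int = 8284
    brams_prune: int = 2
    gates_snn: float = 3.0e6
    brams_snn: int = 50

    def __post_init__(self) -> None:
        for name in ("n_groups", "grouping_cycles", "grouping_ops",
                     "adapting_cycles", "adapting_ops", "energy_per_sop_pj",
                     "energy_per_access_pj", "gates_prune", "gates_snn"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def estimate_pruning_overhead(
    n_input: int,
    n_exc: int,
    model: OverheadModel = OverheadModel(),
    batch_size: int | None = None,
) -> dict:
    """Per-batch clock cycles and basic operations of the pruning algorithm.

    The weight-pruning phase scans every synapse once: one cycle per weight
    (single-port memory) and two operations per weight (one access plus one
    threshold comparison), so n_input * n_exc cycles and twice that in ops.
    Grouping and adapting use the model's per-batch constants.  If a batch
    size is given, per-image averages (per-batch sums divided by the batch
    size) are included.
    """
    if n_input < 1 or n_exc < 1:
        raise ValueError("layer sizes must be >= 1")
    wp_cycles = n_input * n_exc
    wp_ops = 2 * n_input * n_exc
    out = {
        "grouping_cycles": model.grouping_cycles,
        "grouping_ops": model.grouping_ops,
        "adapting_cycles": model.adapting_cycles,
        "adapting_ops": model.adapting_ops,
        "weight_pruning_cycles": wp_cycles,
        "weight_pruning_ops": wp_ops,
        "total_cycles": model.grouping_cycles + model.adapting_cycles + wp_cycles,
        "total_ops": model.grouping_ops + model.adapting_ops + wp_ops,
    }
    if batch_size is not None:
        if batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        out["cycles_per_image"] = out["total_cycles"] / batch_size
        out["ops_per_image"] = out["total_ops"] / batch_size
    return out


def estimate_energy(
    sops_per_image: float,
    pruning_ops_per_image: float,
    model: OverheadModel = OverheadModel(),
) -> dict:
    """Energy per image of synaptic operations vs the pruning algorithm.

    SOP energy = SOPs/image x energy/SOP; pruning energy costs every
    operation as one memory access (the dominant term).  Values in
    picojoules, with the ratio pruning/SOP.
    """
    sop_pj = sops_per_image * model.energy_per_sop_pj
    prune_pj = pruning_ops_per_image * model.energy_per_access_pj
    return {
        "sop_energy_pj": sop_pj,
        "sop_energy_uj": sop_pj * 1e-6,
        "pruning_energy_pj": prune_pj,
        "ratio": prune_pj / sop_pj if sop_pj > 0 else float("inf"),
    }


def gate_ratio(model: OverheadModel = OverheadModel()) -> float:
    """Pruning-unit NAND-gate count as a fraction of the SNN's."""
    return model.gates_prune / model.gates_snn
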