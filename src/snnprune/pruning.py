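"""Online adaptive weight pruning: threshold schedules, grouping, controller.

Magnitude pruning during training removes synapses whose weight falls below
a threshold w_th.  A constant threshold treats every training stage and
every neuron alike; the adaptive schemes here raise the threshold

* over time (APT): at pruning step k (one step per batch of images after a
  pre-pruning phase of t_m images), the global threshold follows one of

      f1(k) = wth0 * a**k              (slow start, fast finish)
      f2(k) = w_max - (w_max - wth0) * b**(-k)   (fast start, saturating)
      f3(k) = wth0 + c * k             (linear)

  each confined to [wth0, w_max) — the threshold must stay below w_max or
  the whole network would be pruned;

* over neurons (APN): neurons are ranked by their average spike count over
  the last batch and greedily grouped so that counts within a group span at
  most SI; group 0 (weakest) gets the global threshold, group n gets the
  same family evaluated at index n — weakly driven neurons keep more of
  their synapses;

* over both (APTN): grouping and per-group adaptation at every step, then
  the global threshold advances along the time schedule.

Removal is permanent.  The soft variant freezes sub-threshold weights at
their current value instead (they keep conducting but stop learning), and
the post-training variant applies a single uniform threshold after the
full training pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .neuro import ACTIVE, FROZEN, REMOVED, SynapseBank

__all__ = [
    "TimeSchedule",
    "GroupPartition",
    "PruneMethodConfig",
    "eval_time_threshold",
    "eval_adaptation",
    "compute_batch_spike_counts",
    "group_neurons",
    "assign_group_thresholds",
    "prune_batch",
    "PruneController",
    "post_training_prune",
    "connectivity",
    "calibrate_constant_threshold",
]

_KINDS = ("f1_exponential", "f2_saturating", "f3_linear", "constant")


def eval_adaptation(kind: str, base: float, factor: float, k: int,
                    w_max: float) -> float:
    """Evaluate one adaptation family at index k, capped at w_max."""
    if k < 0:
        raise ValueError("index must be >= 0")
    if factor < 0:
        raise ValueError("adaptation factors must be >= 0")
    if kind == "f1_exponential":
        val = base * factor**k
    elif kind == "f2_saturating":
        val = w_max - (w_max - base) * factor ** (-k)
    elif kind == "f3_linear":
        val = base + factor * k
    elif kind == "constant":
        val = base
    else:
        raise ValueError(f"unknown adaptation kind {kind!r}")
    return min(val, w_max)


@dataclass
class TimeSchedule:
    """Threshold-over-time schedule, advanced once per pruning batch."""

    kind: str = "f1_exponential"
    wth0: float = 0.02
    factor: float = 1.3
    w_max: float = 1.0
    t_m: int = 30000  # pre-pruning phase, in images
    batch: int = 5000  # images per pruning step

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")
        if self.wth0 < 0 or self.factor < 0:
            raise ValueError("wth0 and factor must be >= 0")
        if self.batch < 1 or self.t_m < 0:
            raise ValueError("batch >= 1 and t_m >= 0 required")

    def threshold(self, k: int) -> float:
        return eval_time_threshold(self, k)

    @property
    def is_neutral(self) -> bool:
        """True when the schedule collapses to constant pruning."""
        return (
            self.kind == "constant"
            or (self.kind == "f1_exponential" and self.factor == 1.0)
            or (self.kind == "f2_saturating" and self.factor == 1.0)
            or (self.kind == "f3_linear" and self.factor == 0.0)
        )


def eval_time_threshold(schedule: TimeSchedule, k: int) -> float:
    """The global pruning threshold at pruning-step index k."""
    return eval_adaptation(
        schedule.kind, schedule.wth0, schedule.factor, k, schedule.w_max
    )


@dataclass
class GroupPartition:
    """Neurons grouped by ascending batch spike count, span <= SI per group."""

    groups: list[np.ndarray]  # member indices, ordered by ascending minimum
    minima: np.ndarray  # minimum spike count per group, strictly increasing
    si: float

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def sizes(self) -> list[int]:
        return [g.size for g in self.groups]


def compute_batch_spike_counts(
    spike_log: np.ndarray, window: slice | None = None
) -> np.ndarray:
    """Average spikes per image per excitatory neuron over one batch.

    ``spike_log`` is (n_images, n_exc); ``window`` selects the batch rows
    (default: all rows).
    """
    log = np.asarray(spike_log, dtype=np.float64)
    if window is not None:
        log = log[window]
    if log.shape[0] == 0:
        raise ValueError("empty batch window")
    return log.mean(axis=0)


def group_neurons(counts: np.ndarray, si: float) -> GroupPartition:
    """Greedy grouping from the weakest neuron upward.

    Repeatedly take S = the minimum count among ungrouped neurons and group
    every ungrouped neuron with count in [S, S + SI] (both ends inclusive).
    SI = inf yields a single group.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if not (si > 0):
        raise ValueError("SI must be > 0 (inf allowed)")
    order = np.argsort(counts, kind="stable")
    groups: list[np.ndarray] = []
    minima: list[float] = []
    i = 0
    n = counts.size
    while i < n:
        s = counts[order[i]]
        j = i
        while j < n and counts[order[j]] <= s + si:
            j += 1
        groups.append(np.sort(order[i:j]))
        minima.append(s)
        i = j
    return GroupPartition(groups=groups, minima=np.asarray(minima), si=si)


def assign_group_thresholds(
    partition: GroupPartition,
    base: float,
    fn_kind: str,
    factor: float,
    w_max: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-group thresholds from the global base, broadcast per neuron.

    Group 0 receives exactly ``base``; group n receives the adaptation
    family evaluated at index n, capped at w_max.  Returns (per-group
    thresholds, per-neuron thresholds).
    """
    n_neurons = sum(g.size for g in partition.groups)
    group_th = np.array([
        eval_adaptation(fn_kind, base, factor, n, w_max)
        for n in range(partition.n_groups)
    ])
    per_neuron = np.empty(n_neurons)
    for th, members in zip(group_th, partition.groups):
        per_neuron[members] = th
    return group_th, per_neuron


def prune_batch(
    bank: SynapseBank,
    thresholds: np.ndarray | float,
    method: str = "APTN",
) -> int:
    """Prune every active synapse strictly below its neuron's threshold.

    Hard methods mark the synapse REMOVED; the soft method marks it FROZEN,
    retaining the current weight.  Both are permanent.  Returns the number
    of synapses newly pruned.  Warns if any neuron loses its last synapse.
    """
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if np.any(thresholds < 0):
        raise ValueError("thresholds must be >= 0")
    new_status = FROZEN if method == "soft" else REMOVED
    hit = (bank.status == ACTIVE) & (bank.w < thresholds)
    n_new = int(hit.sum())
    if n_new:
        bank.status[hit] = new_status
        dead = ~bank.conducting_mask.any(axis=0)
        if dead.any():
            warnings.warn(
                f"{int(dead.sum())} neuron(s) lost all synapses after pruning",
                stacklevel=2,
            )
    return n_new


def connectivity(bank: SynapseBank) -> float:
    """Fraction of active (unpruned, unfrozen) synapses in the projection."""
    return float(bank.active_mask.sum()) / bank.n_total


@dataclass
class PruneMethodConfig:
    """Which pruning method to run and with which adaptation settings.

    ``method``: none | constant | APT | APN | APTN | soft | post_training.
    APT adapts over time only (one group); APN over neurons only (time
    schedule frozen at wth0); APTN over both.  ``soft`` freezes instead of
    removing, with the same time/neuron adaptation machinery available;
    ``constant`` is a fixed threshold for all neurons at every step.
    """

    method: str = "APTN"
    schedule: TimeSchedule = field(default_factory=TimeSchedule)
    fn_kind: str = "f1_exponential"
    fn_factor: float = 1.15
    si: float = 30.0

    def __post_init__(self) -> None:
        allowed = ("none", "constant", "APT", "APN", "APTN", "soft",
                   "post_training")
        if self.method not in allowed:
            raise ValueError(f"method must be one of {allowed}")
        if self.fn_kind not in _KINDS:
            raise ValueError(f"fn_kind must be one of {_KINDS}")

    @property
    def groups_neurons(self) -> bool:
        return self.method in ("APN", "APTN") or (
            self.method == "soft" and np.isfinite(self.si)
        )

    @property
    def advances_time(self) -> bool:
        return self.method in ("APT", "APTN", "soft")


@dataclass
class _BatchLogRow:
    k: int
    images_seen: int
    global_threshold: float
    n_groups: int
    group_thresholds: list[float]
    newly_pruned: int
    connectivity: float


class PruneController:
    """Batch hook driving online pruning during training.

    Fed one per-image excitatory spike-count vector at a time; at each batch
    boundary past the pre-pruning phase it computes batch-average counts,
    groups neurons (unless the method is time-only), assigns per-group
    thresholds from the current global threshold, prunes, and advances the
    time schedule.  With neutral adaptation factors and a single group every
    method reduces exactly to constant pruning.
    """

    def __init__(self, config: PruneMethodConfig) -> None:
        self.config = config
        self.k = 0
        self.current_global = config.schedule.threshold(0)
        self._buffer: list[np.ndarray] = []
        self.log: list[_BatchLogRow] = []

    def on_image(self, net, counts: np.ndarray) -> None:
        cfg = self.config
        if cfg.method in ("none", "post_training"):
            return
        sched = cfg.schedule
        self._buffer.append(np.asarray(counts))
        if len(self._buffer) > sched.batch:
            self._buffer.pop(0)
        seen = net.images_seen
        if seen < sched.t_m or (seen - sched.t_m) % sched.batch != 0:
            return
        batch_counts = compute_batch_spike_counts(np.stack(self._buffer))
        self.prune_step(net.bank, batch_counts, images_seen=seen)

    def prune_step(
        self, bank: SynapseBank, batch_counts: np.ndarray, images_seen: int = -1
    ) -> _BatchLogRow:
        """One pruning step: group -> adapt -> prune -> advance schedule."""
        cfg = self.config
        base = self.current_global
        if cfg.groups_neurons:
            partition = group_neurons(batch_counts, cfg.si)
            group_th, per_neuron = assign_group_thresholds(
                partition, base, cfg.fn_kind, cfg.fn_factor,
                cfg.schedule.w_max,
            )
        else:
            group_th = np.array([base])
            per_neuron = np.full(batch_counts.size, base)
        n_new = prune_batch(
            bank, per_neuron, "soft" if cfg.method == "soft" else cfg.method
        )
        row = _BatchLogRow(
            k=self.k,
            images_seen=images_seen,
            global_threshold=base,
            n_groups=len(group_th),
            group_thresholds=[float(t) for t in group_th],
            newly_pruned=n_new,
            connectivity=connectivity(bank),
        )
        self.log.append(row)
        self.k += 1
        if cfg.advances_time:
            self.current_global = cfg.schedule.threshold(self.k)
        return row

    def log_frame(self):
        """The per-batch log as a pandas DataFrame (CSV-ready)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "k": [r.k for r in self.log],
                "images_seen": [r.images_seen for r in self.log],
                "global_threshold": [r.global_threshold for r in self.log],
                "n_groups": [r.n_groups for r in self.log],
                "group_thresholds": [
                    ";".join(f"{t:.6g}" for t in r.group_thresholds)
                    for r in self.log
                ],
                "newly_pruned": [r.newly_pruned for r in self.log],
                "connectivity": [r.connectivity for r in self.log],
            }
        )


def post_training_prune(bank: SynapseBank, wth: float) -> int:
    """Single uniform-threshold prune applied after the full training pass.

    Training costs are untouched by construction (nothing is removed while
    training runs); only inference benefits.
    """
    return prune_batch(bank, np.full(bank.w.shape[1], wth), "post_training")


def calibrate_constant_threshold(
    weight_snapshots: list[np.ndarray],
    target_connectivity: float,
) -> float:
    """Threshold for constant pruning expected to hit a target connectivity.

    Under constant pruning a synapse is removed the first time its weight
    sits below the threshold at any batch boundary, so (ignoring feedback of
    pruning on the weight trajectory) final connectivity at threshold w
    equals the fraction of synapses whose minimum-over-boundaries weight is
    >= w.  Given weight snapshots of an unpruned run at the batch
    boundaries, the matching threshold is the (1 - target) quantile of those
    minima.
    """
    if not weight_snapshots:
        raise ValueError("need at least one weight snapshot")
    if not 0.0 < target_connectivity <= 1.0:
        raise ValueError("target connectivity must be in (0, 1]")
    minima = np.minimum.reduce([np.asarray(w) for w in weight_snapshots]).ravel()
    return float(np.quantile(minima, 1.0 - target_connectivity))
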