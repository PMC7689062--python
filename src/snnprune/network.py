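"""Two-layer winner-take-all spiking network: rate coding, training, readout.

The architecture is the classic unsupervised digit-recognition circuit: an
input layer of Poisson units (one per pixel, rate proportional to intensity)
fully connected through plastic synapses to a layer of excitatory LIF
neurons.  Each excitatory neuron drives one dedicated inhibitory neuron,
and each inhibitory neuron suppresses every excitatory neuron except its
source — lateral inhibition that makes the excitatory neurons compete for
input features.  Adaptive firing thresholds keep the competition fair.

Only the input -> excitatory projection is plastic (triplet STDP) and only
it is subject to pruning.  After training, each excitatory neuron is
labelled with the class for which it fired the most spikes, and an image is
classified as the class whose neuron group shows the highest mean spike
count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .costs import SOPLedger
from .neuro import (
    NeuronParams,
    NeuronState,
    PlasticityParams,
    SynapseBank,
    TraceState,
    decay_traces,
    stdp_on_pre,
    stdp_on_post,
    step_neurons,
)

__all__ = [
    "ArchitectureConfig",
    "SpikeRecord",
    "TrainingDynamics",
    "LabelAssignment",
    "Prediction",
    "WTANetwork",
    "encode_poisson",
    "present_image",
    "train",
    "compute_training_dynamics",
    "dw_moments_from_values",
    "assign_labels",
    "classify",
    "evaluate_accuracy",
]


@dataclass(frozen=True)
class ArchitectureConfig:
    """Network wiring, timing, and input-scaling constants.

    ``w_exc_inh`` is the fixed one-to-one excitatory -> inhibitory weight and
    ``w_inh_exc`` the fixed all-but-self inhibitory -> excitatory weight, both
    in conductance units.  ``max_rate_hz`` is the Poisson rate assigned to a
    pixel at full intensity 255.
    """

    grid_h: int = 28
    grid_w: int = 28
    n_exc: int = 100
    w_exc_inh: float = 10.4
    w_inh_exc: float = 17.0
    present_ms: float = 350.0
    rest_ms: float = 150.0
    max_rate_hz: float = 63.75
    dt_ms: float = 0.5

    def __post_init__(self) -> None:
        if self.present_ms <= 0:
            raise ValueError("present_ms must be > 0")
        if self.w_exc_inh < 0 or self.w_inh_exc < 0:
            raise ValueError("fixed WTA weights must be >= 0")
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be > 0")

    @property
    def n_input(self) -> int:
        return self.grid_h * self.grid_w

    @property
    def n_inh(self) -> int:
        # One inhibitory partner per excitatory neuron.
        return self.n_exc


@dataclass
class SpikeRecord:
    """Excitatory spike counts for one image presentation."""

    counts: np.ndarray  # (n_exc,) non-negative integers

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class TrainingDynamics:
    """Per-window training monitor: firing activity and weight-update stats.

    One row per monitoring window (default 5,000 images): the mean excitatory
    spike count per image, and the mean and variance of all STDP weight
    updates performed in the window.  Windows with no updates carry NaN
    moments and are flagged.
    """

    window: int
    mean_spike_count: np.ndarray
    mean_dw: np.ndarray
    var_dw: np.ndarray
    n_updates: np.ndarray


@dataclass
class LabelAssignment:
    """Class label per excitatory neuron plus per-class neuron groups."""

    labels: np.ndarray  # (n_exc,) int
    groups: dict[int, np.ndarray]
    silent: np.ndarray  # neurons that never fired during assignment

    @property
    def n_classes(self) -> int:
        return len(self.groups)


@dataclass(frozen=True)
class Prediction:
    label: int
    no_signal: bool = False


class WTANetwork:
    """Simulation state for the two-layer WTA network."""

    def __init__(
        self,
        arch: ArchitectureConfig,
        neuron_params: NeuronParams | None = None,
        plasticity: PlasticityParams | None = None,
        rng: np.random.Generator | None = None,
    ) -> None:
        self.arch = arch
        self.neuron_params = neuron_params or NeuronParams()
        self.plasticity = plasticity or PlasticityParams()
        rng = rng or np.random.default_rng()
        self.bank = SynapseBank.init_random(
            arch.n_input, arch.n_exc, rng, w_max=self.plasticity.w_max
        )
        self.exc = NeuronState.resting(arch.n_exc, self.neuron_params)
        self.inh = NeuronState.resting(arch.n_inh, self.neuron_params)
        self.traces = TraceState.zeros(arch.n_input, arch.n_exc)
        # Recurrent spikes are delivered with a one-step synaptic delay.
        self._pending_exc = np.zeros(arch.n_exc, dtype=bool)
        self._pending_inh = np.zeros(arch.n_inh, dtype=bool)
        self.images_seen = 0

    def reset_transient(self) -> None:
        """Clear membrane, conductance, trace, and pending-spike state.

        Weights, statuses, and adaptive thresholds persist across images;
        this is called between presentations only if a hard reset is wanted
        (the default training loop does not — the inter-image rest period
        lets the state relax naturally).
        """
        p = self.neuron_params
        for state in (self.exc, self.inh):
            state.v[:] = p.v_r
            state.g_e[:] = 0.0
            state.g_i[:] = 0.0
            state.refrac_left[:] = 0.0
        self.traces.x[:] = 0.0
        self.traces.y1[:] = 0.0
        self.traces.y2[:] = 0.0
        self._pending_exc[:] = False
        self._pending_inh[:] = False


def encode_poisson(
    image: np.ndarray,
    duration_ms: float,
    dt_ms: float,
    max_rate_hz: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rate-code an intensity image into Bernoulli spike trains.

    Pixel j with intensity I_j in [0, 255] fires on each step independently
    with probability (I_j / 255) * max_rate_hz * dt, the discrete-time
    approximation of a Poisson process.  Returns a (n_steps, n_pixels)
    boolean array.
    """
    flat = np.asarray(image, dtype=np.float64).ravel()
    if flat.min() < 0 or flat.max() > 255:
        raise ValueError("pixel intensities must lie in [0, 255]")
    n_steps = int(round(duration_ms / dt_ms))
    p = (flat / 255.0) * max_rate_hz * (dt_ms / 1000.0)
    return rng.random((n_steps, flat.size)) < p


@dataclass
class _DwStats:
    """Streaming moments of STDP weight updates within a presentation."""

    count: int = 0
    total: float = 0.0
    total_sq: float = 0.0

    def add(self, dw: np.ndarray) -> None:
        self.count += dw.size
        self.total += float(dw.sum())
        self.total_sq += float(np.square(dw).sum())


def present_image(
    net: WTANetwork,
    image: np.ndarray,
    plastic: bool,
    rng: np.random.Generator,
    ledger: SOPLedger | None = None,
    phase: str = "train",
    dw_stats: _DwStats | None = None,
    use_kernel: bool = True,
) -> SpikeRecord:
    """Present one image for present_ms followed by rest_ms of silence.

    With ``plastic=False`` the weights, statuses, STDP traces, and adaptive
    thresholds are left untouched (inference mode).  If a ledger is given,
    weight-accumulation and STDP synaptic operations on the plastic
    projection are recorded, plus the recurrent WTA events separately.

    ``use_kernel=False`` runs the step-by-step reference path built from the
    public neuron/plasticity primitives instead of the compiled loop; both
    routes implement the same dynamics.
    """
    arch = net.arch
    if use_kernel:
        return _present_compiled(net, image, plastic, rng, ledger, phase, dw_stats)
    dt = arch.dt_ms
    n_present = int(round(arch.present_ms / dt))
    n_rest = int(round(arch.rest_ms / dt))
    input_spikes = encode_poisson(image, arch.present_ms, dt, arch.max_rate_hz, rng)

    plast = net.plasticity
    bank = net.bank
    conducting = bank.conducting_mask
    active = bank.active_mask
    w_inh_row = np.full(arch.n_exc, arch.w_inh_exc)
    counts = np.zeros(arch.n_exc, dtype=np.int64)

    n_accum = 0
    n_stdp_pre = 0
    n_stdp_post = 0
    n_exc_inh = 0
    n_inh_exc = 0

    for step in range(n_present + n_rest):
        if step < n_present:
            rows = np.nonzero(input_spikes[step])[0]
        else:
            rows = _EMPTY_ROWS

        # --- spike delivery -------------------------------------------------
        if rows.size:
            exc_drive = (bank.w[rows] * conducting[rows]).sum(axis=0)
            if ledger is not None:
                n_accum += int(conducting[rows].sum())
        else:
            exc_drive = 0.0
        prev_inh = net._pending_inh
        if prev_inh.any():
            k = int(prev_inh.sum())
            inh_drive = arch.w_inh_exc * (k - prev_inh.astype(np.float64))
            if ledger is not None:
                n_inh_exc += k * (arch.n_exc - 1)
        else:
            inh_drive = 0.0
        prev_exc = net._pending_exc
        if prev_exc.any():
            inh_exc_drive = arch.w_exc_inh * prev_exc.astype(np.float64)
            if ledger is not None:
                n_exc_inh += int(prev_exc.sum())
        else:
            inh_exc_drive = 0.0

        exc_spiked = step_neurons(
            net.exc, net.neuron_params, exc_drive, inh_drive, dt, adapt_theta=plastic
        )
        inh_spiked = step_neurons(
            net.inh, net.neuron_params, inh_exc_drive, 0.0, dt, adapt_theta=False
        )
        counts += exc_spiked

        # --- plasticity -----------------------------------------------------
        if plastic:
            decay_traces(net.traces, dt, plast)
            if rows.size:
                if ledger is not None or dw_stats is not None:
                    before = bank.w[rows].copy()
                stdp_on_pre(bank, net.traces, rows, plast)
                if ledger is not None:
                    n_stdp_pre += int(active[rows].sum())
                if dw_stats is not None:
                    dw_stats.add((bank.w[rows] - before)[active[rows]])
            if exc_spiked.any():
                cols = np.nonzero(exc_spiked)[0]
                if ledger is not None or dw_stats is not None:
                    before = bank.w[:, cols].copy()
                stdp_on_post(bank, net.traces, cols, plast)
                if ledger is not None:
                    n_stdp_post += int(active[:, cols].sum())
                if dw_stats is not None:
                    dw_stats.add((bank.w[:, cols] - before)[active[:, cols]])

        net._pending_exc = exc_spiked
        net._pending_inh = inh_spiked

    if ledger is not None:
        ledger.record_accum(phase, n_accum)
        if plastic:
            ledger.record_stdp("pre", n_stdp_pre)
            ledger.record_stdp("post", n_stdp_post)
        ledger.record_recurrent(phase, exc_inh=n_exc_inh, inh_exc=n_inh_exc)
        ledger.record_image(phase)

    return SpikeRecord(counts=counts)


_EMPTY_ROWS = np.empty(0, dtype=np.intp)


def _present_compiled(
    net: WTANetwork,
    image: np.ndarray,
    plastic: bool,
    rng: np.random.Generator,
    ledger: SOPLedger | None,
    phase: str,
    dw_stats: _DwStats | None,
) -> SpikeRecord:
    """Compiled fast path; dynamics identical to the reference loop."""
    from ._kernel import present_kernel

    arch = net.arch
    p = net.neuron_params
    pl = net.plasticity
    dt = arch.dt_ms
    n_rest = int(round(arch.rest_ms / dt))
    input_spikes = encode_poisson(image, arch.present_ms, dt, arch.max_rate_hz, rng)
    counts, sops, dw_count, dw_total, dw_total_sq = present_kernel(
        net.bank.w, net.bank.status,
        net.exc.v, net.exc.g_e, net.exc.g_i, net.exc.theta, net.exc.refrac_left,
        net.inh.v, net.inh.g_e, net.inh.g_i, net.inh.refrac_left,
        net.traces.x, net.traces.y1, net.traces.y2,
        net._pending_exc, net._pending_inh,
        input_spikes, n_rest, dt,
        p.tau_m, p.v_r, p.v_th, p.E_exc, p.E_inh,
        np.exp(-dt / p.tau_ge), np.exp(-dt / p.tau_gi),
        p.theta_plus, np.exp(-dt / p.tau_theta), p.t_refrac,
        np.exp(-dt / pl.tau_x), np.exp(-dt / pl.tau_y1), np.exp(-dt / pl.tau_y2),
        pl.mu_pre, pl.mu_post, pl.w_max,
        arch.w_exc_inh, arch.w_inh_exc,
        plastic, dw_stats is not None,
    )
    if ledger is not None:
        ledger.record_accum(phase, int(sops[0]))
        if plastic:
            ledger.record_stdp("pre", int(sops[1]))
            ledger.record_stdp("post", int(sops[2]))
        ledger.record_recurrent(phase, exc_inh=int(sops[3]), inh_exc=int(sops[4]))
        ledger.record_image(phase)
    if dw_stats is not None:
        dw_stats.count += dw_count
        dw_stats.total += dw_total
        dw_stats.total_sq += dw_total_sq
    return SpikeRecord(counts=counts)


def train(
    net: WTANetwork,
    images: np.ndarray,
    labels: np.ndarray | None,
    rng: np.random.Generator,
    prune_controller=None,
    ledger: SOPLedger | None = None,
    monitor_window: int = 5000,
) -> TrainingDynamics:
    """One pass of unsupervised STDP training over an image stream.

    The pruning controller (if any) is consulted after every image with the
    per-image excitatory spike counts; it acts only at its own batch
    boundaries.  Firing activity and weight-update statistics are aggregated
    in windows of ``monitor_window`` images.
    """
    if len(images) < 1:
        raise ValueError("training stream must contain at least one image")
    n = len(images)
    n_windows = (n + monitor_window - 1) // monitor_window
    mean_counts = np.zeros(n_windows)
    mean_dw = np.full(n_windows, np.nan)
    var_dw = np.full(n_windows, np.nan)
    n_updates = np.zeros(n_windows, dtype=np.int64)
    win_stats = _DwStats()
    win_spikes = 0.0

    for idx in range(n):
        record = present_image(
            net, images[idx], plastic=True, rng=rng, ledger=ledger, phase="train",
            dw_stats=win_stats,
        )
        net.images_seen += 1
        win_spikes += record.counts.mean()
        if prune_controller is not None:
            prune_controller.on_image(net, record.counts)
        if (idx + 1) % monitor_window == 0 or idx == n - 1:
            w = idx // monitor_window
            span = idx % monitor_window + 1
            mean_counts[w] = win_spikes / span
            if win_stats.count:
                m = win_stats.total / win_stats.count
                mean_dw[w] = m
                var_dw[w] = max(win_stats.total_sq / win_stats.count - m * m, 0.0)
            n_updates[w] = win_stats.count
            win_stats = _DwStats()
            win_spikes = 0.0

    return TrainingDynamics(
        window=monitor_window,
        mean_spike_count=mean_counts,
        mean_dw=mean_dw,
        var_dw=var_dw,
        n_updates=n_updates,
    )


def dw_moments_from_values(values_per_image: list[np.ndarray]) -> list[_DwStats]:
    """Package raw per-image weight-update values into streaming moments."""
    out = []
    for vals in values_per_image:
        s = _DwStats()
        s.add(np.asarray(vals, dtype=np.float64))
        out.append(s)
    return out


def compute_training_dynamics(
    spike_counts: np.ndarray,
    dw_moments: list[_DwStats],
    window: int = 5000,
) -> TrainingDynamics:
    """Aggregate per-image logs into per-window training dynamics.

    ``spike_counts`` is (n_images, n_exc); ``dw_moments`` one streaming-moment
    record per image.  Variance is the population variance of all update
    values in the window; windows with zero updates are flagged with NaN.
    """
    spike_counts = np.asarray(spike_counts, dtype=np.float64)
    n = spike_counts.shape[0]
    if len(dw_moments) != n:
        raise ValueError("spike log and weight-update log must align per image")
    n_windows = (n + window - 1) // window
    mean_counts = np.zeros(n_windows)
    mean_dw = np.full(n_windows, np.nan)
    var_dw = np.full(n_windows, np.nan)
    n_updates = np.zeros(n_windows, dtype=np.int64)
    for w in range(n_windows):
        lo, hi = w * window, min((w + 1) * window, n)
        mean_counts[w] = spike_counts[lo:hi].mean(axis=1).mean()
        cnt = sum(m.count for m in dw_moments[lo:hi])
        n_updates[w] = cnt
        if cnt:
            tot = sum(m.total for m in dw_moments[lo:hi])
            tot_sq = sum(m.total_sq for m in dw_moments[lo:hi])
            mu = tot / cnt
            mean_dw[w] = mu
            var_dw[w] = max(tot_sq / cnt - mu * mu, 0.0)
    return TrainingDynamics(window, mean_counts, mean_dw, var_dw, n_updates)


def assign_labels(
    net: WTANetwork,
    images: np.ndarray,
    labels: np.ndarray,
    rng: np.random.Generator,
    n_classes: int | None = None,
) -> LabelAssignment:
    """Label each excitatory neuron by the class it fires most spikes for.

    Runs a dedicated pass with plasticity off.  Ties break toward the lowest
    class index; neurons silent for every class get label 0 and are flagged.
    """
    labels = np.asarray(labels)
    if n_classes is None:
        n_classes = int(labels.max()) + 1
    totals = np.zeros((n_classes, net.arch.n_exc), dtype=np.int64)
    for img, lab in zip(images, labels):
        rec = present_image(net, img, plastic=False, rng=rng)
        totals[int(lab)] += rec.counts
    return assignment_from_counts(totals)


def assignment_from_counts(totals: np.ndarray) -> LabelAssignment:
    """Build a label assignment from a (n_classes, n_exc) spike-count table."""
    totals = np.asarray(totals)
    neuron_labels = totals.argmax(axis=0)  # argmax -> lowest index on ties
    silent = totals.sum(axis=0) == 0
    neuron_labels = np.where(silent, 0, neuron_labels)
    groups = {
        c: np.nonzero(neuron_labels == c)[0] for c in range(totals.shape[0])
    }
    return LabelAssignment(labels=neuron_labels, groups=groups, silent=silent)


def classify(record: SpikeRecord, assignment: LabelAssignment) -> Prediction:
    """Predict the class whose neuron group has the highest mean spike count.

    Empty groups are excluded; ties break toward the lowest class index.
    If every group is silent the prediction falls back to class 0 with the
    ``no_signal`` flag set.
    """
    if not assignment.groups:
        raise ValueError("assignment has no groups")
    best_class, best_mean = None, -1.0
    for c in sorted(assignment.groups):
        members = assignment.groups[c]
        if members.size == 0:
            continue
        mean = float(record.counts[members].mean())
        if mean > best_mean:
            best_class, best_mean = c, mean
    if best_class is None or best_mean <= 0.0:
        return Prediction(label=0, no_signal=True)
    return Prediction(label=best_class)


def evaluate_accuracy(
    net: WTANetwork,
    assignment: LabelAssignment,
    images: np.ndarray,
    labels: np.ndarray,
    rng: np.random.Generator,
    ledger: SOPLedger | None = None,
) -> float:
    """Fraction of test images classified correctly (plasticity frozen)."""
    correct = 0
    for img, lab in zip(images, labels):
        rec = present_image(net, img, plastic=False, rng=rng, ledger=ledger,
                            phase="infer")
        if classify(rec, assignment).label == int(lab):
            correct += 1
    return correct / len(images)
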