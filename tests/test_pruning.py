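"""Pruning schedules, neuron grouping, threshold adaptation, and removal."""

import dataclasses
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snnprune.neuro import ACTIVE, FROZEN, REMOVED, SynapseBank
from snnprune.pruning import (
    PruneController,
    PruneMethodConfig,
    TimeSchedule,
    assign_group_thresholds,
    calibrate_constant_threshold,
    compute_batch_spike_counts,
    connectivity,
    eval_time_threshold,
    group_neurons,
    post_training_prune,
    prune_batch,
)


def bank_from(w, status=None):
    w = np.asarray(w, dtype=np.float64)
    s = np.zeros(w.shape, dtype=np.int8) if status is None else status
    return SynapseBank(w, s)


class TestTimeSchedules:
    def test_unit_base_is_constant(self):
        s = TimeSchedule(kind="f1_exponential", wth0=0.05, factor=1.0)
        assert all(s.threshold(k) == 0.05 for k in range(20))
        assert s.is_neutral

    def test_linear_starts_at_wth0(self):
        s = TimeSchedule(kind="f3_linear", wth0=0.03, factor=0.01)
        assert s.threshold(0) == 0.03

    def test_exponential_growth_value(self):
        """f1 with wth0=0.036, a=1.3 at k=2 gives 0.036*1.3^2 = 0.06084."""
        s = TimeSchedule(kind="f1_exponential", wth0=0.036, factor=1.3)
        assert s.threshold(2) == pytest.approx(0.06084, rel=1e-12)

    def test_saturating_approaches_w_max(self):
        s = TimeSchedule(kind="f2_saturating", wth0=0.1, factor=1.5, w_max=1.0)
        vals = [s.threshold(k) for k in range(40)]
        assert vals[0] == pytest.approx(0.1)
        assert all(np.diff(vals) >= 0)
        assert vals[-1] == pytest.approx(1.0, abs=1e-4)

    def test_cap_at_w_max(self):
        s = TimeSchedule(kind="f1_exponential", wth0=0.5, factor=2.0, w_max=1.0)
        assert s.threshold(10) == 1.0

    def test_negative_factor_rejected(self):
        with pytest.raises(ValueError):
            TimeSchedule(factor=-0.1)

    @settings(derandomize=True, max_examples=60)
    @given(
        st.sampled_from(["f1_exponential", "f2_saturating", "f3_linear"]),
        st.floats(0.001, 0.5),
        st.floats(1.0, 2.0),
        st.integers(0, 100),
    )
    def test_confined_to_range(self, kind, wth0, factor, k):
        """Growing schedules stay within [wth0, w_max] for any step index."""
        factor = factor if kind != "f3_linear" else factor - 1.0
        s = TimeSchedule(kind=kind, wth0=wth0, factor=factor, w_max=1.0)
        val = s.threshold(k)
        assert wth0 - 1e-12 <= val <= 1.0


class TestGrouping:
    def test_all_equal_counts_one_group(self):
        p = group_neurons(np.full(7, 3.0), si=1.0)
        assert p.n_groups == 1 and p.groups[0].size == 7

    def test_infinite_interval_one_group(self):
        p = group_neurons(np.array([0.0, 10.0, 1e6]), si=np.inf)
        assert p.n_groups == 1

    def test_worked_partition(self):
        """Counts {0,10,40,100} at SI=30 partition as {0,10},{40},{100}."""
        p = group_neurons(np.array([0.0, 10.0, 40.0, 100.0]), si=30.0)
        assert [list(g) for g in p.groups] == [[0, 1], [2], [3]]
        np.testing.assert_array_equal(p.minima, [0.0, 40.0, 100.0])

    def test_boundary_inclusive(self):
        """A count exactly at S + SI joins the current group."""
        p = group_neurons(np.array([0.0, 30.0, 30.000001]), si=30.0)
        assert list(p.groups[0]) == [0, 1]

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 2**31 - 1), st.floats(0.5, 50.0))
    def test_partition_properties(self, seed, si):
        """Groups partition all neurons, spans <= SI, minima increasing."""
        counts = np.random.default_rng(seed).uniform(0, 100, size=25)
        p = group_neurons(counts, si)
        members = np.concatenate(p.groups)
        assert sorted(members) == list(range(25))
        for g in p.groups:
            assert counts[g].max() - counts[g].min() <= si + 1e-9
        assert (np.diff(p.minima) > 0).all()


class TestGroupThresholds:
    def test_group_zero_gets_base_exactly(self):
        p = group_neurons(np.array([0.0, 50.0, 100.0]), si=10.0)
        group_th, _ = assign_group_thresholds(p, 0.04, "f1_exponential", 1.15, 1.0)
        assert group_th[0] == 0.04

    def test_neutral_factor_all_base(self):
        p = group_neurons(np.array([0.0, 50.0, 100.0]), si=10.0)
        group_th, per_neuron = assign_group_thresholds(
            p, 0.04, "f1_exponential", 1.0, 1.0
        )
        assert (group_th == 0.04).all() and (per_neuron == 0.04).all()

    def test_exponential_ladder(self):
        """f1 base 0.02, a=1.15 over 3 groups: 0.02, 0.023, 0.02645."""
        p = group_neurons(np.array([0.0, 50.0, 100.0]), si=10.0)
        group_th, per_neuron = assign_group_thresholds(
            p, 0.02, "f1_exponential", 1.15, 1.0
        )
        np.testing.assert_allclose(group_th, [0.02, 0.023, 0.02645], rtol=1e-12)
        # weakest neuron (index 0) carries the lowest threshold
        assert per_neuron[0] == 0.02 and per_neuron[2] == pytest.approx(0.02645)

    def test_monotone_in_group_index_for_growing_factor(self):
        counts = np.arange(0.0, 100.0, 7.0)
        p = group_neurons(counts, si=5.0)
        for kind, factor in [("f1_exponential", 1.2), ("f3_linear", 0.05)]:
            group_th, _ = assign_group_thresholds(p, 0.03, kind, factor, 1.0)
            assert (np.diff(group_th) >= 0).all()


class TestPruneBatch:
    def test_zero_threshold_prunes_nothing(self):
        b = bank_from([[0.0, 0.5], [0.2, 0.0]])
        assert prune_batch(b, np.zeros(2)) == 0
        assert (b.status == ACTIVE).all()

    def test_toy_matrix_brute_force(self):
        """3x2 weights against per-neuron thresholds (0.2, 0.2)."""
        w = np.array([[0.1, 0.5], [0.3, 0.02], [0.0, 0.9]])
        b = bank_from(w)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            n = prune_batch(b, np.array([0.2, 0.2]))
        removed = {(j, i) for j in range(3) for i in range(2)
                   if b.status[j, i] == REMOVED}
        assert removed == {(0, 0), (1, 1), (2, 0)} and n == 3

    def test_repeat_call_prunes_nothing_new(self):
        b = bank_from([[0.1, 0.5], [0.3, 0.02]])
        prune_batch(b, np.array([0.2, 0.2]))
        assert prune_batch(b, np.array([0.2, 0.2])) == 0

    def test_exactly_at_threshold_survives(self):
        b = bank_from([[0.2]])
        assert prune_batch(b, np.array([0.2])) == 0

    def test_soft_freezes_with_weight_retained(self):
        b = bank_from([[0.1, 0.5]])
        prune_batch(b, np.array([0.2, 0.2]), method="soft")
        assert b.status[0, 0] == FROZEN and b.w[0, 0] == 0.1
        assert connectivity(b) == 0.5  # frozen no longer counts as active

    def test_dead_neuron_warning(self):
        b = bank_from([[0.1, 0.5]])
        with pytest.warns(UserWarning, match="lost all synapses"):
            prune_batch(b, np.array([0.9, 0.0]))


class TestConnectivity:
    def test_fresh_full_and_all_removed(self):
        b = bank_from(np.full((3, 2), 0.5))
        assert connectivity(b) == 1.0
        b.status[:] = REMOVED
        assert connectivity(b) == 0.0

    def test_partial(self):
        b = bank_from(np.full((3, 2), 0.5))
        b.status[0, 0] = REMOVED
        b.status[1, 1] = REMOVED
        assert connectivity(b) == pytest.approx(4 / 6)


class TestBatchCounts:
    def test_all_silent_zero(self):
        counts = compute_batch_spike_counts(np.zeros((10, 4)))
        np.testing.assert_array_equal(counts, np.zeros(4))

    def test_one_spike_per_image_is_one(self):
        log = np.zeros((8, 3))
        log[:, 1] = 1
        np.testing.assert_array_equal(compute_batch_spike_counts(log),
                                      [0.0, 1.0, 0.0])

    def test_matches_brute_force_mean(self):
        log = np.random.default_rng(4).integers(0, 6, size=(12, 5))
        np.testing.assert_allclose(compute_batch_spike_counts(log),
                                   log.mean(axis=0))


class TestController:
    def cfg(self, **kw):
        sched = TimeSchedule(kind=kw.pop("kind", "f1_exponential"),
                             wth0=kw.pop("wth0", 0.1),
                             factor=kw.pop("factor", 1.3),
                             t_m=0, batch=1)
        return PruneMethodConfig(schedule=sched, **kw)

    def test_aptn_step_sequence(self):
        """Counts -> groups -> thresholds -> prune -> advance schedule."""
        ctrl = PruneController(self.cfg(method="APTN", si=30.0, fn_factor=1.15))
        bank = bank_from(np.linspace(0.0, 0.9, 12).reshape(4, 3))
        counts = np.array([0.0, 40.0, 100.0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            row = ctrl.prune_step(bank, counts)
        assert row.n_groups == 3
        np.testing.assert_allclose(
            row.group_thresholds, [0.1, 0.1 * 1.15, 0.1 * 1.15**2]
        )
        assert ctrl.current_global == pytest.approx(0.13)  # f1 advanced to k=1

    def test_apn_freezes_time_schedule(self):
        ctrl = PruneController(self.cfg(method="APN"))
        bank = bank_from(np.full((4, 3), 0.5))
        ctrl.prune_step(bank, np.zeros(3))
        ctrl.prune_step(bank, np.zeros(3))
        assert ctrl.current_global == 0.1

    def test_apt_single_group(self):
        ctrl = PruneController(self.cfg(method="APT"))
        bank = bank_from(np.full((4, 3), 0.5))
        row = ctrl.prune_step(bank, np.array([0.0, 40.0, 100.0]))
        assert row.n_groups == 1

    def test_si_infinite_reduces_apn_to_apt(self):
        """With SI = inf the grouped method performs exactly the ungrouped
        prune at every step."""
        w = np.random.default_rng(0).uniform(0, 0.4, size=(6, 4))
        banks = [bank_from(w.copy()), bank_from(w.copy())]
        ctrls = [
            PruneController(self.cfg(method="APN", si=np.inf)),
            PruneController(self.cfg(method="APT")),
        ]
        counts = np.array([1.0, 5.0, 80.0, 200.0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for bank, ctrl in zip(banks, ctrls):
                ctrl.prune_step(bank, counts)
        np.testing.assert_array_equal(banks[0].status, banks[1].status)


class TestPostTrainingAndCalibration:
    def test_post_training_uniform_prune(self):
        b = bank_from([[0.1, 0.5], [0.3, 0.02]])
        n = post_training_prune(b, 0.25)
        assert n == 2
        assert b.status[0, 0] == REMOVED and b.status[1, 1] == REMOVED

    def test_calibration_quantile_on_known_trajectory(self):
        """Synapses whose minimum-over-snapshots weight falls below the
        calibrated threshold are exactly the targeted fraction."""
        rng = np.random.default_rng(8)
        snaps = [rng.uniform(0, 1, size=(20, 10)) for _ in range(4)]
        wth = calibrate_constant_threshold(snaps, target_connectivity=0.3)
        minima = np.minimum.reduce(snaps).ravel()
        surviving = (minima >= wth).mean()
        assert surviving == pytest.approx(0.3, abs=0.02)
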