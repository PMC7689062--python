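"""Shared fixtures.

The heavy desk-scale simulations (multi-seed training runs and the
threshold sweep) are computed once per session and shared by every test
that needs them.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from snnprune.experiments import (
    desk_scale_config,
    run_matched_constant,
    run_prune_sweep,
    run_train,
)

SEEDS = (0, 1, 2, 3, 4)
APTN_WTH0 = 0.13  # drives the desk-scale network to ~10-15% connectivity
SWEEP_WTH0 = [0.005, 0.01, 0.02, 0.04, 0.08]


@pytest.fixture(scope="session")
def five_seed_runs():
    """Per-seed unpruned baseline, APTN run, and matched constant run."""
    out = {}
    for seed in SEEDS:
        base = run_train(
            desk_scale_config(seed=seed, method="none"), snapshot_weights=True
        )
        aptn_cfg = desk_scale_config(seed=seed, method="APTN", wth0=APTN_WTH0)
        aptn = run_train(aptn_cfg)
        const = run_matched_constant(aptn_cfg, base, aptn.connectivity)
        out[seed] = {"base": base, "aptn": aptn, "const": const}
    return out


@pytest.fixture(scope="session")
def wth0_sweep(five_seed_runs):
    """Five-point initial-threshold sweep at seed 0, sharing its baseline."""
    cfg = desk_scale_config(seed=0, method="APTN")
    frame, results = run_prune_sweep(
        cfg, SWEEP_WTH0, baseline=five_seed_runs[0]["base"]
    )
    return frame, results


def tiny_config(seed: int = 0, method: str = "none", **kwargs):
    """A very small synthetic run (seconds) for equivalence-style tests."""
    cfg = desk_scale_config(
        seed=seed,
        method=method,
        n_exc=kwargs.pop("n_exc", 12),
        n_train=kwargs.pop("n_train", 400),
        t_m=kwargs.pop("t_m", 200),
        batch=kwargs.pop("batch", 100),
        **kwargs,
    )
    return dataclasses.replace(cfg, n_assign=150, n_test=90)
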