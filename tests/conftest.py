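"""Shared fixtures: a small fast study and the full default study.

The full default synthetic time course (200 compartment bins, 2,500 TAD-layer
bins, a 2,000-bin loop window, 4 time points x 2 replicates) is generated
once per session and shared by the recovery and end-to-end tests.
"""

import numpy as np
import pytest

from hicdyn import (
    ContactMatrix,
    BinsTable,
    SimulationConfig,
    generate_expression,
    generate_timecourse,
    ice_balance,
    pool_replicates,
)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(master_seed=1)


@pytest.fixture(scope="session")
def study(default_config):
    """Full default synthetic study: (matrices, truth)."""
    return generate_timecourse(default_config)


@pytest.fixture(scope="session")
def study_expression(study, default_config):
    _, truth = study
    return generate_expression(truth, default_config)


@pytest.fixture(scope="session")
def pooled_balanced(study):
    """Replicate-pooled, ICE-balanced matrix per (timepoint, layer)."""
    matrices, truth = study
    cfg = truth.config
    out = {}
    for layer in ("compartment", "tad", "loop"):
        for tp in range(cfg.n_timepoints):
            pooled = pool_replicates(
                matrices[(tp, 0, layer)], matrices[(tp, 1, layer)]
            )
            out[(tp, layer)] = ice_balance(pooled)
    return out


@pytest.fixture(scope="session")
def small_config():
    """Cheap 20-Mb study used by pipeline and module tests."""
    return SimulationConfig(
        chrom_length=20_000_000,
        loop_window=(4_000_000, 12_000_000),
        depth_compartment=6e5,
        depth_strat=8e5,
        depth_tad=3e6,
        depth_loop=4e6,
        loop_counts=(4, 6, 8, 10),
        tad_mean_bp=800_000,
        segment_mean_bp=2_000_000,
        n_background_degs=10,
        master_seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_timecourse(small_config)


def random_contact_matrix(rng, n, binsize=100_000, density=0.8):
    """Random symmetric non-negative matrix with a mild decay, for oracles."""
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    base = 50.0 / (d + 1.0)
    counts = rng.poisson(base * rng.uniform(0.5, 1.5, size=(n, n)))
    counts = np.triu(counts)
    counts = counts + np.triu(counts, 1).T
    bins = BinsTable.from_chrom_length("chrT", n * binsize, binsize)
    return ContactMatrix(bins, counts.astype(float))
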