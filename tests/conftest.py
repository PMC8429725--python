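"""Shared fixtures.

The expensive Monte-Carlo computations (bootstrap-LRT null calibration,
model-selection recovery, FISH test calibration) are session-scoped so the
calibration tests and the property tests share a single run.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from raexi.fish import burst_gof_test
from raexi.mixture import bootstrap_lrt, select_model
from raexi.simulate import (
    FishSimSpec,
    preset_rme_three_state,
    simulate_fish_population,
    simulate_gene_clones,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lrt_null_pvalues() -> np.ndarray:
    """Bootstrap-LRT p-values for 200 single-Gaussian null datasets.

    n=100 values per dataset, B=199 replications, K=1 vs K=2.
    """
    ss = np.random.SeedSequence(186283)
    pvals = []
    for child in ss.spawn(200):
        rng = np.random.default_rng(child)
        x = rng.normal(0.5, 0.05, 100)
        res = bootstrap_lrt(x, k_null=1, b=199, seed=child.spawn(1)[0])
        pvals.append(res.p_value)
    return np.asarray(pvals)


@pytest.fixture(scope="session")
def three_state_recovery() -> list:
    """200 seeded simulations of the three-state RME preset, model-selected.

    Each entry is (selected fit, generating spec); n=150 clones per run.
    """
    spec = preset_rme_three_state()
    out = []
    ss = np.random.SeedSequence(424243)
    for child in ss.spawn(200):
        sim_seed, fit_seed = child.spawn(2)
        counts, _ = simulate_gene_clones(spec, n_clones=150, seed=sim_seed)
        total = counts["cast_count"] + counts["ref_count"]
        ratios = (counts["cast_count"] / total).to_numpy()
        out.append((select_model(ratios, k_max=5, seed=fit_seed), spec))
    return out


@pytest.fixture(scope="session")
def fish_null_rejection_rate() -> float:
    """Rejection rate of the burst test over 1000 purely-bursty populations.

    N=300 cells, P_detect=0.6, alpha=0.05.
    """
    spec = FishSimSpec(n_cells=300, stable_fraction=0.0, p_on=0.75, p_sense=0.8)
    ss = np.random.SeedSequence(271828)
    rejections = 0
    for child in ss.spawn(1000):
        counts, _ = simulate_fish_population(spec, seed=child)
        if burst_gof_test(counts).p_value < 0.05:
            rejections += 1
    return rejections / 1000
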