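"""Gaussian mixture fitting, BIC model selection and bootstrap inference."""

import numpy as np
import pytest
from scipy.stats import kstest

from raexi.mixture import (
    EQUAL,
    UNEQUAL,
    VARIANCE_FLOOR,
    assign_clones,
    bic_score,
    bootstrap_lrt,
    bootstrap_param_ci,
    em_fit,
    mixture_log_lik,
    n_free_params,
    select_model,
)


def _two_component_sample(seed=0, n=60, means=(0.2, 0.8), sd=0.05, w=0.5):
    rng = np.random.default_rng(seed)
    comps = rng.random(n) < w
    return np.where(comps, rng.normal(means[0], sd, n), rng.normal(means[1], sd, n))


# ---------------------------------------------------------------------------
# EM correctness


@pytest.mark.parametrize("family", [EQUAL, UNEQUAL])
def test_k1_em_equals_closed_form_gaussian_mle(family):
    """K=1 must reproduce the sample mean and biased variance exactly."""
    x = np.random.default_rng(1).normal(0.5, 0.03, 200)
    fit = em_fit(x, k=1, variance_family=family)
    assert fit.means[0] == pytest.approx(x.mean(), abs=1e-9)
    assert fit.variances[0] == pytest.approx(x.var(), abs=1e-9)
    expected_ll = mixture_log_lik(x, [1.0], [x.mean()], [x.var()])
    assert fit.log_lik == pytest.approx(expected_ll, abs=1e-9)


def test_point_mass_hits_variance_floor():
    x = np.full(20, 0.5)
    fit = em_fit(x, k=1)
    assert fit.means[0] == pytest.approx(0.5)
    assert fit.variances[0] == VARIANCE_FLOOR
    assert np.isfinite(fit.log_lik)


def test_em_rejects_bad_input():
    with pytest.raises(ValueError):
        em_fit([0.1, 0.2, 0.3], k=2)  # n < 2K
    with pytest.raises(ValueError):
        em_fit([0.1, np.nan, 0.3, 0.4], k=1)


@pytest.mark.parametrize("k,family", [(2, UNEQUAL), (2, EQUAL), (3, UNEQUAL)])
def test_em_loglik_trace_is_nondecreasing(k, family):
    """EM monotonicity, up to 1e-8 relative tolerance at the variance floor."""
    x = _two_component_sample(seed=k)
    fit = em_fit(x, k=k, variance_family=family, seed=0)
    trace = fit.loglik_trace
    drops = np.diff(trace)
    assert np.all(drops >= -1e-8 * np.maximum(1.0, np.abs(trace[:-1])))


def test_k2_em_beats_dense_grid_oracle():
    """EM log-likelihood must dominate a brute-force grid search with the
    variance fixed at its generating value."""
    sd = 0.05
    x = _two_component_sample(seed=42, n=60, sd=sd)
    fit = em_fit(x, k=2, seed=3)
    best_grid = -np.inf
    for w in np.linspace(0.1, 0.9, 17):
        for m1 in np.linspace(0.05, 0.5, 19):
            for m2 in np.linspace(0.5, 0.95, 19):
                ll = mixture_log_lik(x, [w, 1 - w], [m1, m2], [sd**2, sd**2])
                best_grid = max(best_grid, ll)
    assert fit.log_lik >= best_grid - 1e-9


def test_em_is_deterministic_given_seed():
    x = _two_component_sample(seed=5)
    a = em_fit(x, k=2, seed=99)
    b = em_fit(x, k=2, seed=99)
    assert np.array_equal(a.means, b.means)
    assert a.log_lik == b.log_lik


# ---------------------------------------------------------------------------
# BIC and model selection


@pytest.mark.parametrize("family,k_free", [(UNEQUAL, 2), (EQUAL, 2)])
def test_bic_convention_for_single_gaussian(family, k_free):
    """BIC = 2 logL - k_free log n, with k_free = 2 for one component."""
    x = np.random.default_rng(2).normal(0.4, 0.05, 80)
    fit = em_fit(x, k=1, variance_family=family)
    ll = mixture_log_lik(x, [1.0], [x.mean()], [x.var()])
    assert n_free_params(1, family) == k_free
    assert fit.bic == pytest.approx(2 * ll - k_free * np.log(x.size), abs=1e-9)
    assert bic_score(ll, 1, family, x.size) == pytest.approx(fit.bic)


def test_single_tight_population_selects_one_component():
    """A unimodal gene (83 clones around 0.5) is one allelic state."""
    x = np.random.default_rng(4).normal(0.5, 0.03, 83)
    fit = select_model(x, k_max=5, seed=8)
    assert fit.k == 1


def test_constant_values_select_one_component_at_floor():
    fit = select_model(np.full(5, 0.5), k_max=5, seed=0)
    assert fit.k == 1
    assert fit.variances[0] == VARIANCE_FLOOR


def test_three_state_mixture_recovered_on_single_draw():
    rng = np.random.default_rng(10)
    comps = rng.choice(3, size=150, p=[0.25, 0.5, 0.25])
    x = rng.normal(np.array([0.05, 0.5, 0.95])[comps],
                   np.array([0.03, 0.05, 0.03])[comps])
    fit = select_model(np.clip(x, 0, 1), k_max=5, seed=11)
    assert fit.k == 3
    assert np.allclose(fit.means, [0.05, 0.5, 0.95], atol=0.03)


def test_model_selection_consistency_well_separated():
    """Separation >= 6 sigma, balanced weights, n=100: true K recovered
    in at least 90% of seeded runs."""
    hits = 0
    runs = 100
    ss = np.random.SeedSequence(987)
    for child in ss.spawn(runs):
        rng = np.random.default_rng(child)
        x = _two_component_sample(seed=rng.integers(2**31), n=100,
                                  means=(0.3, 0.7), sd=0.05)
        fit = select_model(x, k_max=3, seed=child.spawn(1)[0])
        hits += fit.k == 2
    assert hits / runs >= 0.90


# ---------------------------------------------------------------------------
# Bootstrap LRT


def test_lrt_on_well_separated_mixture_rejects_at_resolution_limit():
    """10-sigma separation: the observed LRT exceeds every bootstrap stat."""
    x = _two_component_sample(seed=21, n=80, means=(0.2, 0.8), sd=0.03)
    res = bootstrap_lrt(x, k_null=1, b=99, seed=5)
    assert res.p_value == pytest.approx(1.0 / (99 + 1.0))
    assert res.lrt_obs > res.bootstrap_stats.max()


def test_lrt_null_pvalues_approximately_uniform(lrt_null_pvalues):
    """Under a single-Gaussian truth the bootstrap p-values are ~U(0,1)."""
    d = kstest(lrt_null_pvalues, "uniform").statistic
    assert d < 0.15


def test_lrt_requires_enough_data_and_replicates():
    with pytest.raises(ValueError):
        bootstrap_lrt([0.1, 0.2, 0.3], k_null=1, b=199)
    with pytest.raises(ValueError):
        bootstrap_lrt(np.linspace(0, 1, 50), k_null=1, b=50)


# ---------------------------------------------------------------------------
# Bootstrap parameter CIs


def test_point_mass_gives_zero_width_mean_interval():
    x = np.full(30, 0.4)
    fit = em_fit(x, k=1)
    ci = bootstrap_param_ci(x, fit, b=99, seed=1)
    assert ci.means_lower[0] == pytest.approx(0.4, abs=1e-12)
    assert ci.means_upper[0] == pytest.approx(0.4, abs=1e-12)


def test_mean_ci_coverage_for_single_gaussian():
    """95% percentile intervals cover the true mean in ~95% of runs
    (accept 88-99% over 200 seeded runs)."""
    covered = 0
    runs = 200
    true_mean = 0.5
    ss = np.random.SeedSequence(321)
    for child in ss.spawn(runs):
        rng = np.random.default_rng(child)
        x = rng.normal(true_mean, 0.05, 200)
        fit = em_fit(x, k=1)
        ci = bootstrap_param_ci(x, fit, b=199, seed=child.spawn(1)[0])
        covered += ci.means_lower[0] <= true_mean <= ci.means_upper[0]
    assert 0.88 <= covered / runs <= 0.99


# ---------------------------------------------------------------------------
# Clone assignment


def test_assignment_trivial_for_one_component():
    x = np.random.default_rng(3).normal(0.5, 0.02, 40)
    fit = em_fit(x, k=1)
    labels, post, shares = assign_clones(fit, x)
    assert np.all(labels == 0)
    assert shares == pytest.approx([1.0])


def test_assignment_forced_by_separation():
    x = _two_component_sample(seed=9, n=100, means=(0.05, 0.95), sd=0.02)
    fit = em_fit(x, k=2, seed=1)
    labels, post, shares = assign_clones(fit, np.array([0.05]))
    assert labels[0] == 0
    assert post[0, 0] > 0.999


def test_assignment_shares_match_generating_weights():
    rng = np.random.default_rng(14)
    comps = rng.random(150) < 0.3
    x = np.where(comps, rng.normal(0.1, 0.04, 150), rng.normal(0.7, 0.06, 150))
    fit = em_fit(x, k=2, seed=2)
    _, _, shares = assign_clones(fit, x)
    assert shares[0] == pytest.approx(0.3, abs=0.1)
    assert shares.sum() == pytest.approx(1.0, abs=1e-9)
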