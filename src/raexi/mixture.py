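"""Univariate Gaussian mixture decomposition of clonal allelic-ratio distributions.

A gene's distribution of allelic ratios across clonal cell lines is modelled
as a mixture of K Gaussian components, each component being one stable
allelic state (e.g. 129-monoallelic, biased, biallelic).  The number of
states is chosen by maximising the Bayesian Information Criterion

    BIC = 2*logL - k_free * log(n)

over K = 1..K_max and over two variance families (all components sharing one
variance, or component-specific variances; k_free = 2K and 3K-1 free
parameters respectively).  Uncertainty is quantified by a parametric
bootstrap likelihood-ratio test for K vs K+1 and by nonparametric bootstrap
percentile confidence intervals for the component parameters.

Plain (untruncated) Gaussians are fitted even though ratios live on [0, 1];
densities are not renormalised.  This keeps the model identical to standard
univariate mixture practice and is a mild, documented misspecification for
components near the boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

_LOG_2PI = float(np.log(2.0 * np.pi))

#: Lower bound on component variances (ratio^2 units); prevents singular
#: components when values are replicated.
VARIANCE_FLOOR = 1e-6

EQUAL = "equal"
UNEQUAL = "unequal"
VARIANCE_FAMILIES = (EQUAL, UNEQUAL)


@dataclass
class MixtureFit:
    """Fitted K-component univariate Gaussian mixture.

    Components are sorted by ascending mean.  ``loglik_trace`` is the
    log-likelihood after each EM expectation step of the winning restart
    (non-decreasing up to the variance-floor tolerance).
    """

    k: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    variance_family: str
    log_lik: float
    bic: float
    n: int
    converged: bool
    n_iter: int
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class LrtResult:
    """Parametric-bootstrap likelihood-ratio test of K vs K+1 components."""

    k_null: int
    k_alt: int
    lrt_obs: float
    b: int
    p_value: float
    bootstrap_stats: np.ndarray
    n_failed: int = 0


@dataclass
class ParamCI:
    """Bootstrap percentile confidence intervals for mixture parameters.

    Arrays are (K,) per component, matched across replicates by sorting on
    component means.  ``label_switching_flag`` is set when some replicate
    had tied sorted means; intervals are then widened to the across-component
    union.
    """

    level: float
    b: int
    weights_lower: np.ndarray
    weights_upper: np.ndarray
    means_lower: np.ndarray
    means_upper: np.ndarray
    variances_lower: np.ndarray
    variances_upper: np.ndarray
    label_switching_flag: bool = False


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def n_free_params(k: int, variance_family: str) -> int:
    """Free parameters: K-1 weights + K means + K (or 1) variances."""
    if variance_family == UNEQUAL:
        return 3 * k - 1
    if variance_family == EQUAL:
        return 2 * k
    raise ValueError(f"unknown variance family {variance_family!r}")


def bic_score(log_lik: float, k: int, variance_family: str, n: int) -> float:
    return 2.0 * log_lik - n_free_params(k, variance_family) * np.log(n)


def _log_component_densities(x, weights, means, variances):
    """(n, K) matrix of log(pi_k * N(x | mu_k, var_k))."""
    return (
        np.log(weights)[None, :]
        - 0.5 * (_LOG_2PI + np.log(variances))[None, :]
        - 0.5 * (x[:, None] - means[None, :]) ** 2 / variances[None, :]
    )


def mixture_log_lik(x, weights, means, variances) -> float:
    logp = _log_component_densities(
        np.asarray(x, float), np.asarray(weights, float),
        np.asarray(means, float), np.asarray(variances, float),
    )
    return float(logsumexp(logp, axis=1).sum())


def _fit_k1(x: np.ndarray, variance_family: str, var_floor: float) -> MixtureFit:
    """K=1 maximum likelihood is closed form (sample mean, biased variance)."""
    n = x.size
    mu = float(x.mean())
    var = max(float(x.var()), var_floor)
    ll = -0.5 * n * (_LOG_2PI + np.log(var)) - 0.5 * ((x - mu) ** 2).sum() / var
    ll = float(ll)
    return MixtureFit(
        k=1,
        weights=np.array([1.0]),
        means=np.array([mu]),
        variances=np.array([var]),
        variance_family=variance_family,
        log_lik=ll,
        bic=bic_score(ll, 1, variance_family, n),
        n=n,
        converged=True,
        n_iter=0,
        loglik_trace=np.array([ll]),
    )


def _quantile_init(x_sorted: np.ndarray, k: int, var_floor: float):
    """Cut the sorted sample into K contiguous blocks; block moments as init."""
    blocks = np.array_split(x_sorted, k)
    weights = np.array([len(b) for b in blocks], float)
    weights /= weights.sum()
    means = np.array([b.mean() for b in blocks])
    variances = np.array([max(float(b.var()), var_floor) for b in blocks])
    return weights, means, variances


def _run_em(x, weights, means, variances, variance_family, max_iter, tol, var_floor):
    """One EM run from a given initialisation; returns params + trace.

    The E-step log-sum-exp is inlined (K is tiny, n modest) — this loop
    dominates the bootstrap LRT and model-selection runtimes.
    """
    n = x.size
    k = means.size
    xcol = x[:, None]
    trace = []
    ll_prev = -np.inf
    converged = False
    for _ in range(max_iter):
        diff = xcol - means[None, :]
        logp = (np.log(weights) - 0.5 * (_LOG_2PI + np.log(variances)))[None, :] \
            - 0.5 * diff * diff / variances[None, :]
        top = logp.max(axis=1)
        p = np.exp(logp - top[:, None])
        s = p.sum(axis=1)
        ll = float((top + np.log(s)).sum())
        trace.append(ll)
        if ll - ll_prev <= tol * max(1.0, abs(ll)) and len(trace) > 1:
            converged = True
            break
        ll_prev = ll
        resp = p / s[:, None]
        nk = np.maximum(resp.sum(axis=0), 1e-300)
        weights = nk / n
        means = (resp.T @ x) / nk
        diff2 = (xcol - means[None, :]) ** 2
        if variance_family == EQUAL:
            shared = max(float((resp * diff2).sum() / n), var_floor)
            variances = np.full(k, shared)
        else:
            variances = np.maximum((resp * diff2).sum(axis=0) / nk, var_floor)
    else:
        # Hit max_iter with a trailing M-step: score the final parameters.
        logp = _log_component_densities(x, weights, means, variances)
        ll = float(logsumexp(logp, axis=1).sum())
        trace.append(ll)
    return weights, means, variances, trace[-1], np.array(trace), converged


def em_fit(
    values,
    k: int,
    variance_family: str = UNEQUAL,
    n_restarts: int = 10,
    seed=None,
    max_iter: int = 1000,
    tol: float = 1e-8,
    var_floor: float = VARIANCE_FLOOR,
    init=None,
) -> MixtureFit:
    """Fit a K-component Gaussian mixture by EM; best of ``n_restarts``.

    The first restart is deterministic (quantile cut of the sorted sample
    into K blocks); later restarts perturb that initialisation with the
    seeded generator, so the result is deterministic given ``seed``.  An
    explicit ``init`` (weights, means, variances) replaces the quantile
    start, e.g. to warm-start bootstrap refits.

    Raises ``ValueError`` for non-finite input or n < 2K.
    """
    if variance_family not in VARIANCE_FAMILIES:
        raise ValueError(f"unknown variance family {variance_family!r}")
    x = np.asarray(values, float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    n = x.size
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < 2 * k:
        raise ValueError(f"insufficient data: need n >= {2 * k} for k={k}, got {n}")
    if k == 1:
        return _fit_k1(x, variance_family, var_floor)

    rng = np.random.default_rng(seed)
    x_sorted = np.sort(x)
    scale = max(float(x.std()), 1e-3)
    best = None
    for r in range(max(1, n_restarts)):
        if r == 0 and init is not None:
            w0 = np.asarray(init[0], float).copy()
            mu0 = np.asarray(init[1], float).copy()
            v0 = np.maximum(np.asarray(init[2], float), var_floor)
        else:
            w0, mu0, v0 = _quantile_init(x_sorted, k, var_floor)
            if r > 0:
                mu0 = mu0 + rng.normal(0.0, 0.5 * scale, size=k)
                v0 = v0 * np.exp(rng.normal(0.0, 0.5, size=k))
                v0 = np.maximum(v0, var_floor)
                w0 = rng.dirichlet(np.full(k, 5.0))
        if variance_family == EQUAL:
            v0 = np.full(k, max(float(v0.mean()), var_floor))
        w, mu, v, ll, trace, conv = _run_em(
            x, w0, mu0, v0, variance_family, max_iter, tol, var_floor
        )
        if best is None or ll > best[3]:
            best = (w, mu, v, ll, trace, conv)
    w, mu, v, ll, trace, conv = best
    order = np.argsort(mu)
    return MixtureFit(
        k=k,
        weights=w[order],
        means=mu[order],
        variances=v[order],
        variance_family=variance_family,
        log_lik=ll,
        bic=bic_score(ll, k, variance_family, n),
        n=n,
        converged=conv,
        n_iter=len(trace) - 1,
        loglik_trace=trace,
    )


def select_model(
    values,
    k_max: int = 5,
    seed=None,
    n_restarts: int = 10,
    variance_families=VARIANCE_FAMILIES,
    full: bool = False,
    **em_kwargs,
) -> MixtureFit | tuple[MixtureFit, list[MixtureFit]]:
    """Choose the number of allelic states by maximising the BIC.

    Fits K = 1..min(k_max, n//2) for each variance family and returns the
    fit with the highest BIC; ties are broken toward smaller K, then the
    equal-variance family.  With ``full=True`` also returns all candidates.
    """
    x = np.asarray(values, float).ravel()
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    k_cap = max(1, min(k_max, x.size // 2))
    families = list(variance_families)
    ss = _as_seedseq(seed)
    children = ss.spawn(k_cap * len(families))
    candidates: list[MixtureFit] = []
    i = 0
    for k in range(1, k_cap + 1):
        for fam in families:
            candidates.append(
                em_fit(
                    x, k, variance_family=fam, n_restarts=n_restarts,
                    seed=children[i], **em_kwargs,
                )
            )
            i += 1
    def _rank(fit: MixtureFit):
        return (-fit.bic, fit.k, 0 if fit.variance_family == EQUAL else 1)
    best = min(candidates, key=_rank)
    return (best, candidates) if full else best


def sample_from_fit(fit: MixtureFit, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n values from a fitted mixture (parametric bootstrap)."""
    comps = rng.choice(fit.k, size=n, p=fit.weights / fit.weights.sum())
    return rng.normal(fit.means[comps], np.sqrt(fit.variances[comps]))


def bootstrap_lrt(
    values,
    k_null: int,
    b: int = 1000,
    seed=None,
    variance_family: str = UNEQUAL,
    n_restarts: int = 2,
    max_iter: int = 200,
    tol: float = 1e-6,
    max_fail_frac: float = 0.1,
) -> LrtResult:
    """Parametric-bootstrap LRT of K_null vs K_null+1 components.

    The observed statistic is 2*(logL_alt - logL_null) (clipped at 0 against
    EM sub-optimality).  B datasets of size n are simulated from the fitted
    null model and refitted under both hypotheses with the same EM settings
    as the observed fits, keeping the statistic exchangeable;
    p = (1 + #{boot >= obs}) / (B + 1).  Replicates whose refits return a
    non-finite likelihood are retried with fresh seeds and dropped after 3
    attempts; more than ``max_fail_frac`` dropped replicates is an error.
    """
    if b < 99:
        raise ValueError("b must be >= 99")
    x = np.asarray(values, float).ravel()
    n = x.size
    k_alt = k_null + 1
    if n < 2 * k_alt:
        raise ValueError(f"insufficient data for the K={k_alt} alternative")
    ss = _as_seedseq(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    def _stat(data, s0, s1):
        f0 = em_fit(data, k_null, variance_family, n_restarts, seed=s0,
                    max_iter=max_iter, tol=tol)
        f1 = em_fit(data, k_alt, variance_family, n_restarts, seed=s1,
                    max_iter=max_iter, tol=tol)
        return max(0.0, 2.0 * (f1.log_lik - f0.log_lik)), f0

    seeds = ss.spawn(2)
    lrt_obs, fit_null = _stat(x, seeds[0], seeds[1])

    stats = []
    n_failed = 0
    boot_seeds = ss.spawn(3 * b * 2)
    for i in range(b):
        ok = False
        for attempt in range(3):
            j = 2 * (3 * i + attempt)
            sim = sample_from_fit(fit_null, n, rng)
            try:
                s, _ = _stat(sim, boot_seeds[j], boot_seeds[j + 1])
            except ValueError:
                continue
            if np.isfinite(s):
                stats.append(s)
                ok = True
                break
        if not ok:
            n_failed += 1
    if n_failed > max_fail_frac * b:
        raise RuntimeError(f"{n_failed}/{b} bootstrap refits failed")
    stats = np.asarray(stats)
    p = (1.0 + float((stats >= lrt_obs).sum())) / (stats.size + 1.0)
    return LrtResult(
        k_null=k_null, k_alt=k_alt, lrt_obs=lrt_obs,
        b=stats.size, p_value=p, bootstrap_stats=stats, n_failed=n_failed,
    )


def sequential_lrt(
    values, k_max: int = 5, b: int = 1000, alpha: float = 0.05, seed=None, **kwargs
) -> tuple[int, list[LrtResult]]:
    """Test K vs K+1 starting at K=1, stopping at the first p > alpha.

    Returns the selected K (the first null not rejected) and all results.
    """
    ss = _as_seedseq(seed)
    results: list[LrtResult] = []
    n = np.asarray(values).size
    k = 1
    while k < k_max and n >= 2 * (k + 1):
        res = bootstrap_lrt(values, k, b=b, seed=ss.spawn(1)[0], **kwargs)
        results.append(res)
        if res.p_value > alpha:
            return k, results
        k += 1
    return k, results


def bootstrap_param_ci(
    values,
    fit: MixtureFit,
    b: int = 1000,
    level: float = 0.95,
    seed=None,
    n_restarts: int = 2,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> ParamCI:
    """Nonparametric bootstrap percentile CIs for mixture parameters.

    Resamples the data with replacement, refits at fixed K and variance
    family (warm-started from the original fit), matches components across
    replicates by sorting on means, and takes percentile intervals.
    """
    if not fit.converged:
        raise ValueError("fit must have converged before bootstrapping CIs")
    if b < 99:
        raise ValueError("b must be >= 99")
    if not 0.5 < level < 1.0:
        raise ValueError("level must be in (0.5, 1)")
    x = np.asarray(values, float).ravel()
    n = x.size
    ss = _as_seedseq(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    seeds = ss.spawn(b)
    ws = np.empty((b, fit.k))
    mus = np.empty((b, fit.k))
    vs = np.empty((b, fit.k))
    switching = False
    init = (fit.weights, fit.means, fit.variances)
    for i in range(b):
        idx = rng.integers(0, n, size=n)
        fb = em_fit(
            x[idx], fit.k, fit.variance_family, n_restarts, seed=seeds[i],
            max_iter=max_iter, tol=tol, init=init,
        )
        if fb.k > 1 and np.any(np.diff(fb.means) == 0.0):
            switching = True
        ws[i], mus[i], vs[i] = fb.weights, fb.means, fb.variances
    lo = 100 * (1 - level) / 2
    hi = 100 - lo
    def _ci(a):
        return np.percentile(a, lo, axis=0), np.percentile(a, hi, axis=0)
    wl, wu = _ci(ws)
    ml, mu_ = _ci(mus)
    vl, vu = _ci(vs)
    if switching:
        # Component identity is ambiguous: widen every interval to the
        # union across components.
        wl, wu = np.full(fit.k, wl.min()), np.full(fit.k, wu.max())
        ml, mu_ = np.full(fit.k, ml.min()), np.full(fit.k, mu_.max())
        vl, vu = np.full(fit.k, vl.min()), np.full(fit.k, vu.max())
    return ParamCI(
        level=level, b=b,
        weights_lower=wl, weights_upper=wu,
        means_lower=ml, means_upper=mu_,
        variances_lower=vl, variances_upper=vu,
        label_switching_flag=switching,
    )


def assign_clones(fit: MixtureFit, values):
    """Posterior component assignment of each clone under a fitted mixture.

    Returns (labels, posterior, shares): hard labels by maximum posterior
    responsibility (0-based, components sorted by mean), the (n, K)
    posterior matrix, and per-component soft clone shares (mean
    responsibility; sums to 1).
    """
    if not fit.converged:
        raise ValueError("fit must have converged")
    x = np.asarray(values, float).ravel()
    logp = _log_component_densities(x, fit.weights, fit.means, fit.variances)
    post = np.exp(logp - logsumexp(logp, axis=1)[:, None])
    labels = post.argmax(axis=1)
    shares = post.mean(axis=0)
    return labels, post, shares


def component_density(fit: MixtureFit, grid) -> np.ndarray:
    """Mixture density on a grid (for histogram-overlay reports)."""
    g = np.asarray(grid, float)
    return np.sum(
        fit.weights[None, :]
        * norm.pdf(g[:, None], fit.means[None, :], np.sqrt(fit.variances)[None, :]),
        axis=1,
    )
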