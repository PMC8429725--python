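"""Downstream statistics: stability, dosage, epidrug screen, dose-response.

Covers the quantitative procedures that sit after the modality analysis:

* Kolmogorov-Smirnov comparison of allelic-ratio distributions between cell
  states (e.g. embryonic stem cells vs neural progenitors).
* Per-clone Pearson stability correlation of allelic ratios across two
  timepoints (e.g. progenitors vs derived astrocytes), with the standard
  20-read filter on both measurements.
* Gene-dosage analysis: split clones into high/low expressors, then compare
  mRNA levels of monoallelic vs biallelic high-expressing clones with an
  equal-variance two-tailed t-test.  Under purely cis-acting silencing the
  monoallelic/biallelic mean ratio approaches one half.
* Protein ~ mRNA simple regression (F with (1, n-2) df).
* Epidrug screen hit calling: a compound is a hit when its allelic-ratio
  shift toward the silent allele exceeds the control mean + 3 SD threshold
  in BOTH reporter clones.
* Four-parameter logistic (4PL) dose-response fitting on log10 dose, with
  the EC50 reported in micromolar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._regression import SimpleOls, simple_ols
from .ratios import AllelicCategory, classify_ratio

DEFAULT_MIN_READS = 20


def ks_compare(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov D and asymptotic p-value."""
    a = np.asarray(sample_a, float).ravel()
    b = np.asarray(sample_b, float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class StabilityResult:
    r: float
    n_genes: int
    status: str  # "ok" | "undefined"


def stability_correlation(
    ratios_t1: pd.DataFrame,
    ratios_t2: pd.DataFrame,
    min_reads: int = DEFAULT_MIN_READS,
) -> StabilityResult:
    """Pearson correlation of per-gene allelic ratios between two timepoints.

    Inputs are per-clone tables indexed by gene with columns ``ratio`` and
    (optionally) ``n_reads``; genes with fewer than ``min_reads`` informative
    reads at either timepoint are dropped.  Fewer than 3 shared genes leaves
    the correlation undefined.
    """
    joined = ratios_t1.join(
        ratios_t2, how="inner", lsuffix="_t1", rsuffix="_t2"
    ).dropna(subset=["ratio_t1", "ratio_t2"])
    for col in ("n_reads_t1", "n_reads_t2"):
        if col in joined.columns:
            joined = joined[joined[col].isna() | (joined[col] >= min_reads)]
    if len(joined) < 3:
        return StabilityResult(r=np.nan, n_genes=len(joined), status="undefined")
    r, _ = stats.pearsonr(joined["ratio_t1"], joined["ratio_t2"])
    return StabilityResult(r=float(r), n_genes=len(joined), status="ok")


def split_expression_groups(levels, threshold: float) -> np.ndarray:
    """Label clones 'high' (level >= threshold) or 'low'.

    The threshold is a required analysis input (it is a per-gene judgement
    call); :func:`propose_expression_threshold` can suggest one from a
    two-component mixture on log levels.
    """
    x = np.asarray(levels, float).ravel()
    labels = np.where(x >= threshold, "high", "low")
    if len(set(labels)) == 1:
        warnings.warn(
            "all clones fall in one expression group; the dosage test is undefined",
            stacklevel=2,
        )
    return labels


def propose_expression_threshold(levels, seed=None) -> float:
    """Antimode of a 2-component Gaussian mixture on log10 levels.

    Returns the point between the two component means where the posterior
    responsibilities cross (equal-posterior boundary).
    """
    from .mixture import assign_clones, em_fit

    x = np.log10(np.maximum(np.asarray(levels, float).ravel(), 1e-12))
    fit = em_fit(x, k=2, seed=seed)
    grid = np.linspace(fit.means[0], fit.means[1], 2001)
    _, post, _ = assign_clones(fit, grid)
    crossing = grid[np.argmin(np.abs(post[:, 0] - post[:, 1]))]
    return float(10 ** crossing)


@dataclass(frozen=True)
class DosageTestResult:
    t: float
    df: int
    p_value: float
    mean_monoallelic: float
    mean_biallelic: float
    ratio_of_means: float
    n_monoallelic: int
    n_biallelic: int


_MONO = {AllelicCategory.MONOALLELIC_129, AllelicCategory.MONOALLELIC_CAST}


def dosage_ttest(levels, categories) -> DosageTestResult:
    """mRNA levels of monoallelic vs biallelic clones (two-tailed, equal variance).

    ``categories`` holds an :class:`AllelicCategory` (or its string value)
    per clone; biased clones are excluded from the test.  Callers should
    restrict to high-expressing clones first (see
    :func:`split_expression_groups`).  df = n1 + n2 - 2.
    """
    x = np.asarray(levels, float).ravel()
    cats = [
        c if isinstance(c, AllelicCategory) else AllelicCategory(c)
        for c in categories
    ]
    if x.size != len(cats):
        raise ValueError("levels and categories must be paired")
    mono = x[[c in _MONO for c in cats]]
    bi = x[[c is AllelicCategory.BIALLELIC for c in cats]]
    if mono.size < 2 or bi.size < 2:
        raise ValueError(
            f"need >=2 monoallelic and >=2 biallelic clones, got {mono.size}/{bi.size}"
        )
    t, p = stats.ttest_ind(mono, bi, equal_var=True)
    return DosageTestResult(
        t=float(t),
        df=mono.size + bi.size - 2,
        p_value=float(p),
        mean_monoallelic=float(mono.mean()),
        mean_biallelic=float(bi.mean()),
        ratio_of_means=float(mono.mean() / bi.mean()),
        n_monoallelic=int(mono.size),
        n_biallelic=int(bi.size),
    )


def protein_rna_regression(protein, rna) -> SimpleOls:
    """OLS of normalised protein level on relative mRNA abundance."""
    return simple_ols(rna, protein)


@dataclass
class ScreenPlate:
    """Post-treatment allelic ratios for an epidrug screen on two clones.

    ``ratios``: compounds x clones DataFrame of post-treatment allelic
    ratios (NaN = no data).  ``controls``: per clone, the vehicle-control
    ratios (>= 2 wells; the reference screen used 11).  ``silent_allele``:
    per clone, which allele is silenced ("cast" or "ref"), fixing the
    direction in which a ratio shift counts as reactivation.
    """

    ratios: pd.DataFrame
    controls: Mapping[str, Sequence[float]]
    silent_allele: Mapping[str, str]

    def __post_init__(self):
        for clone in self.ratios.columns:
            ctl = np.asarray(self.controls[clone], float)
            if ctl.size < 2:
                raise ValueError(f"clone {clone}: need >=2 control wells")
            if self.silent_allele[clone] not in ("cast", "ref"):
                raise ValueError("silent_allele entries must be 'cast' or 'ref'")


def call_screen_hits(plate: ScreenPlate, sigma_multiplier: float = 3.0) -> pd.DataFrame:
    """Hit calling: effect > mean + 3 SD of controls in BOTH clones.

    The effect is the shift of the allelic ratio toward the silent allele
    relative to the clone's own control mean (the two clones silence
    opposite alleles, so the sign convention is per clone).  The SD is the
    sample standard deviation (n-1) of the control wells.  Compounds with a
    missing measurement in either clone are marked ND and are never hits.

    Returns one row per compound with per-clone effects, thresholds, a
    ``hit`` flag and a ``status`` (ok / ND).
    """
    clones = list(plate.ratios.columns)
    out = pd.DataFrame(index=plate.ratios.index)
    exceeds = []
    for clone in clones:
        ctl = np.asarray(plate.controls[clone], float)
        mean, sd = float(ctl.mean()), float(ctl.std(ddof=1))
        direction = 1.0 if plate.silent_allele[clone] == "cast" else -1.0
        effect = direction * (plate.ratios[clone] - mean)
        out[f"effect_{clone}"] = effect
        out[f"threshold_{clone}"] = sigma_multiplier * sd
        exceeds.append(effect > sigma_multiplier * sd)
    nd = plate.ratios[clones].isna().any(axis=1)
    out["status"] = np.where(nd, "ND", "ok")
    out["hit"] = np.logical_and.reduce(exceeds) & ~nd
    return out


@dataclass
class DoseResponse:
    bottom: float
    top: float
    ec50: float
    hill: float
    sse: float
    status: str  # "ok" | "no_fit"
    n_points: int


def _four_pl(log_dose, bottom, top, log_ec50, hill):
    return bottom + (top - bottom) / (1.0 + 10 ** (hill * (log_ec50 - log_dose)))


def fit_dose_response(
    doses,
    responses,
    seed=None,
    n_starts: int = 20,
    zero_dose_decades: float = 2.0,
) -> DoseResponse:
    """Least-squares 4-parameter logistic fit on log10(dose).

    Doses are in micromolar; zero doses (vehicle wells) anchor the bottom
    asymptote and are placed ``zero_dose_decades`` decades below the lowest
    nonzero dose.  Multi-start (seeded) least squares avoids local minima;
    the orientation is normalised afterwards so bottom <= top, with the Hill
    slope sign flipped accordingly.  EC50 is reported in micromolar.
    """
    d = np.asarray(doses, float).ravel()
    y = np.asarray(responses, float).ravel()
    if d.size != y.size:
        raise ValueError("doses and responses must be paired")
    if np.unique(d).size < 4:
        raise ValueError("need at least 4 distinct dose levels")
    nonzero = d[d > 0]
    if nonzero.size == 0:
        raise ValueError("need at least one nonzero dose")
    floor = nonzero.min() * 10 ** (-zero_dose_decades)
    log_d = np.log10(np.where(d > 0, d, floor))

    rng = np.random.default_rng(seed)
    lo, hi = float(y.min()), float(y.max())
    span = max(hi - lo, 1e-6)
    base = np.array([lo, hi, float(np.median(log_d)), 1.0])
    bounds = (
        [lo - 2 * span, lo - 2 * span, log_d.min() - 3.0, -10.0],
        [hi + 2 * span, hi + 2 * span, log_d.max() + 3.0, 10.0],
    )

    def residuals(theta):
        return _four_pl(log_d, *theta) - y

    best = None
    for s in range(n_starts):
        theta0 = base.copy()
        if s > 0:
            theta0[0] += rng.normal(0, 0.1 * span)
            theta0[1] += rng.normal(0, 0.1 * span)
            theta0[2] = rng.uniform(log_d.min(), log_d.max())
            theta0[3] = rng.choice([-1.0, 1.0]) * 10 ** rng.uniform(-0.5, 0.7)
        theta0 = np.clip(theta0, bounds[0], bounds[1])
        try:
            res = optimize.least_squares(residuals, theta0, bounds=bounds)
        except Exception:
            continue
        sse = float(2 * res.cost)
        if res.success and (best is None or sse < best[1]):
            best = (res.x, sse)
    if best is None:
        return DoseResponse(np.nan, np.nan, np.nan, np.nan, np.nan, "no_fit", d.size)
    (bottom, top, log_ec50, hill), sse = best
    if bottom > top:
        bottom, top, hill = top, bottom, -hill
    return DoseResponse(
        bottom=float(bottom),
        top=float(top),
        ec50=float(10 ** log_ec50),
        hill=float(hill),
        sse=sse,
        status="ok",
        n_points=int(d.size),
    )


def categorize_ratios(ratios) -> list[AllelicCategory]:
    """Convenience: classify an iterable of ratios (used by dosage drivers)."""
    return [classify_ratio(r) for r in np.asarray(ratios, float).ravel()]
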