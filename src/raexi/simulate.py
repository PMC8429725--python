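"""Ground-truth-labelled synthetic data for every pipeline stage.

The generators emulate the statistical structure the analysis stages
assume, so the whole pipeline is testable without any external download:

* gene x clone allele-specific counts whose clonal ratio distribution is a
  gene-specific mixture of allelic states (with per-differentiation-
  experiment weight variability and binomial read sampling at finite depth);
* RNA-FISH cell tallies mixing bursty biallelic cells with a stably
  monoallelic subpopulation;
* a peak landscape in which exactly one TSS peak's allelic accessibility is
  coupled to the gene's allelic expression across clones;
* epidrug screen plates with known true hits, and per-allele expression
  levels for the dosage analysis.

All generators are deterministic given their seed and return the generating
truth alongside the observable data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .downstream import ScreenPlate
from .fish import FishCellCounts
from .ratios import AllelicCategory
from .scan import Peak


# ---------------------------------------------------------------------------
# Gene modality mixtures


@dataclass
class GeneModalitySpec:
    """Generating mixture of allelic states for one gene.

    ``components`` is a list of (weight, mean, sd) on the ratio scale;
    weights must sum to 1 and means lie in [0, 1].  ``read_depth`` is the
    mean total allele-specific reads per clone (Poisson);
    ``measurement_sd`` adds technical noise on the ratio itself;
    ``experiment_weight_concentration`` is the Dirichlet concentration
    governing how much the state proportions vary between independent
    differentiation experiments (infinity = identical proportions).
    """

    components: Sequence[tuple[float, float, float]]
    read_depth: float = 1000.0
    measurement_sd: float = 0.01
    experiment_weight_concentration: float = 50.0

    def __post_init__(self):
        w = np.array([c[0] for c in self.components], float)
        m = np.array([c[1] for c in self.components], float)
        s = np.array([c[2] for c in self.components], float)
        if w.size == 0 or not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ValueError("component weights must sum to 1")
        if np.any(w <= 0) or np.any((m < 0) | (m > 1)) or np.any(s <= 0):
            raise ValueError("invalid component parameters")

    @property
    def weights(self) -> np.ndarray:
        return np.array([c[0] for c in self.components], float)

    @property
    def means(self) -> np.ndarray:
        return np.array([c[1] for c in self.components], float)

    @property
    def sds(self) -> np.ndarray:
        return np.array([c[2] for c in self.components], float)


def preset_unimodal_biallelic() -> GeneModalitySpec:
    """One tight biallelic state with a slight 129 bias (mean 41% Cast)."""
    return GeneModalitySpec(components=[(1.0, 0.41, 0.03)])


def preset_two_state_biased() -> GeneModalitySpec:
    """Two reciprocally biased states without full monoallelism."""
    return GeneModalitySpec(components=[(0.5, 0.30, 0.05), (0.5, 0.70, 0.05)])


def preset_rme_three_state() -> GeneModalitySpec:
    """Random monoallelic expression: both monoallelic states plus biallelic."""
    return GeneModalitySpec(
        components=[(0.25, 0.05, 0.03), (0.50, 0.50, 0.03), (0.25, 0.95, 0.03)]
    )


def _truncated_normal(rng, mean, sd, size):
    a = (0.0 - mean) / sd
    b = (1.0 - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_gene_clones(
    spec: GeneModalitySpec,
    n_clones: int,
    n_experiments: int = 6,
    seed=None,
    gene_id: str = "gene",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Allele-specific counts for ``n_clones`` clonal lines of one gene.

    Each clone is assigned to a differentiation experiment; the experiment's
    state proportions are a Dirichlet perturbation of the spec weights.  The
    clone's true ratio is drawn from its state's truncated-to-[0,1] Gaussian
    plus technical noise; reads are Binomial(Poisson depth, true ratio).

    Returns (counts, truth): counts has columns gene_id, clone_id,
    cast_count, ref_count; truth has clone_id, experiment, component,
    true_ratio.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    rng = np.random.default_rng(seed)
    k = len(spec.components)
    conc = spec.experiment_weight_concentration
    if np.isinf(conc):
        exp_weights = np.tile(spec.weights, (n_experiments, 1))
    else:
        exp_weights = rng.dirichlet(conc * spec.weights, size=n_experiments)
    experiment = rng.integers(0, n_experiments, size=n_clones)
    component = np.empty(n_clones, dtype=int)
    for e in range(n_experiments):
        mask = experiment == e
        component[mask] = rng.choice(k, size=int(mask.sum()), p=exp_weights[e])
    true_ratio = np.empty(n_clones)
    for c in range(k):
        mask = component == c
        if mask.any():
            true_ratio[mask] = _truncated_normal(
                rng, spec.means[c], spec.sds[c], int(mask.sum())
            )
    observed = np.clip(
        true_ratio + rng.normal(0.0, spec.measurement_sd, size=n_clones), 0.0, 1.0
    )
    depth = rng.poisson(spec.read_depth, size=n_clones)
    cast = rng.binomial(depth, observed)
    counts = pd.DataFrame(
        {
            "gene_id": gene_id,
            "clone_id": [f"clone_{i:03d}" for i in range(n_clones)],
            "cast_count": cast,
            "ref_count": depth - cast,
        }
    )
    truth = pd.DataFrame(
        {
            "clone_id": counts["clone_id"],
            "experiment": experiment,
            "component": component,
            "true_ratio": true_ratio,
        }
    )
    return counts, truth


# ---------------------------------------------------------------------------
# RNA-FISH populations


@dataclass
class FishSimSpec:
    """Cell population for the burst test.

    ``stable_fraction`` of cells carry one permanently silent allele (the
    silent allele is the reference with probability ``allele_bias``); the
    rest are bursty biallelic.  Any active allele is detected with
    P_detect = P_ON * P_sense.
    """

    n_cells: int
    stable_fraction: float = 0.0
    allele_bias: float = 0.5
    p_on: float = 1.0
    p_sense: float = 1.0

    def __post_init__(self):
        for name in ("stable_fraction", "allele_bias", "p_on", "p_sense"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    @property
    def p_detect(self) -> float:
        return self.p_on * self.p_sense


def simulate_fish_population(
    spec: FishSimSpec, seed=None, region_id: str = "region", animal_id=None
) -> tuple[FishCellCounts, pd.DataFrame]:
    """Simulate per-cell signal counts; returns tallies plus per-cell truth.

    Expected class fractions: E[n2]/N = (1-f) p^2,
    E[n1]/N = f p + (1-f) 2 p (1-p), with p = P_ON * P_sense.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_cells
    p = spec.p_detect
    stable = rng.random(n) < spec.stable_fraction
    silent_is_ref = rng.random(n) < spec.allele_bias
    signals = np.where(
        stable,
        (rng.random(n) < p).astype(int),
        rng.binomial(2, p, size=n),
    )
    counts = FishCellCounts(
        n0=int((signals == 0).sum()),
        n1=int((signals == 1).sum()),
        n2=int((signals == 2).sum()),
        region_id=region_id,
        animal_id=animal_id,
    )
    truth = pd.DataFrame(
        {
            "stable_monoallelic": stable,
            "silent_allele": np.where(
                stable, np.where(silent_is_ref, "ref", "cast"), "none"
            ),
            "n_signals": signals,
        }
    )
    return counts, truth


# ---------------------------------------------------------------------------
# Regulatory peak landscapes


@dataclass
class LandscapeSpec:
    """Accessible-chromatin landscape with one expression-coupled peak.

    Peaks are placed in the +/-``window_bp`` window around the TSS; the
    coupled peak sits at the TSS itself and its per-clone allelic
    accessibility tracks the clone's RNA allelic ratio up to
    ``coupling_noise_sd``.  Uncoupled peaks fluctuate around balanced
    accessibility (0.5) with ``baseline_ratio_sd``.  Allele-specific reads
    are Binomial at a Poisson depth per peak x clone.
    """

    n_peaks: int = 150
    window_bp: int = 3_000_000
    tss: int = 5_000_000
    chrom: str = "chr1"
    coupled_peak_index: int = 0
    coupling_noise_sd: float = 0.05
    baseline_ratio_sd: float = 0.10
    peak_read_depth: float = 100.0
    peak_width: int = 400

    def __post_init__(self):
        if not 0 <= self.coupled_peak_index < self.n_peaks:
            raise ValueError("coupled_peak_index out of range")


def default_clone_rna_ratios(n_clones: int = 13) -> np.ndarray:
    """Clone RNA allelic ratios spanning the full imbalance range."""
    return np.linspace(0.05, 0.95, n_clones)


def simulate_peak_landscape(
    spec: LandscapeSpec,
    clone_rna_ratios,
    seed=None,
) -> tuple[list[Peak], pd.DataFrame, dict]:
    """Peak set plus allele-specific ATAC count table for each clone.

    Returns (peaks, atac_counts, truth) where truth holds the coupled
    peak_id and the underlying true per-peak, per-clone accessibility
    ratios (before read sampling).
    """
    rng = np.random.default_rng(seed)
    rna = np.asarray(clone_rna_ratios, float).ravel()
    n_clones = rna.size
    clone_ids = [f"clone_{i:02d}" for i in range(n_clones)]
    half_w = spec.peak_width // 2
    mids = rng.integers(
        spec.tss - spec.window_bp, spec.tss + spec.window_bp + 1, size=spec.n_peaks
    )
    mids[spec.coupled_peak_index] = spec.tss
    peaks = [
        Peak(
            chrom=spec.chrom,
            start=int(m - half_w),
            end=int(m + half_w),
            peak_id=f"peak_{i:04d}",
            has_snp=True,
        )
        for i, m in enumerate(mids)
    ]
    true_ratio = np.clip(
        rng.normal(0.5, spec.baseline_ratio_sd, size=(spec.n_peaks, n_clones)),
        0.0, 1.0,
    )
    true_ratio[spec.coupled_peak_index] = np.clip(
        rna + rng.normal(0.0, spec.coupling_noise_sd, size=n_clones), 0.0, 1.0
    )
    depth = rng.poisson(spec.peak_read_depth, size=(spec.n_peaks, n_clones))
    cast = rng.binomial(depth, true_ratio)
    records = []
    for i, peak in enumerate(peaks):
        for j, clone in enumerate(clone_ids):
            records.append(
                (peak.peak_id, clone, int(cast[i, j]), int(depth[i, j] - cast[i, j]))
            )
    atac_counts = pd.DataFrame(
        records, columns=["peak_id", "clone_id", "cast_count", "ref_count"]
    )
    truth = {
        "coupled_peak_id": peaks[spec.coupled_peak_index].peak_id,
        "true_ratios": pd.DataFrame(
            true_ratio, index=[p.peak_id for p in peaks], columns=clone_ids
        ),
        "clone_rna_ratios": pd.Series(rna, index=clone_ids),
    }
    return peaks, atac_counts, truth


# ---------------------------------------------------------------------------
# Epidrug screen plates


def simulate_screen_plate(
    n_compounds: int = 181,
    n_hits: int = 5,
    control_mean_per_clone: Mapping[str, float] | None = None,
    control_sd: float = 0.01,
    hit_effect: float = 0.15,
    n_controls: int = 11,
    seed=None,
) -> tuple[ScreenPlate, pd.DataFrame]:
    """Screen plate with known true hits on two reporter clones.

    The two clones silence opposite alleles (control ratios near 0 and
    near 1), as when one clone expresses only the 129 allele and the other
    only the Cast allele.  Null compounds are drawn from each clone's
    control distribution; true hits are shifted by ``hit_effect`` toward
    the silent allele in both clones.
    """
    if n_hits > n_compounds:
        raise ValueError("n_hits cannot exceed n_compounds")
    if control_mean_per_clone is None:
        control_mean_per_clone = {"clone_31": 0.03, "clone_84": 0.97}
    rng = np.random.default_rng(seed)
    clones = list(control_mean_per_clone)
    silent = {
        c: ("cast" if control_mean_per_clone[c] < 0.5 else "ref") for c in clones
    }
    controls = {
        c: np.clip(
            rng.normal(control_mean_per_clone[c], control_sd, size=n_controls), 0, 1
        )
        for c in clones
    }
    compound_ids = [f"compound_{i:03d}" for i in range(n_compounds)]
    is_hit = np.zeros(n_compounds, dtype=bool)
    if n_hits:
        is_hit[rng.choice(n_compounds, size=n_hits, replace=False)] = True
    ratios = pd.DataFrame(index=compound_ids, columns=clones, dtype=float)
    for c in clones:
        base = rng.normal(control_mean_per_clone[c], control_sd, size=n_compounds)
        direction = 1.0 if silent[c] == "cast" else -1.0
        base[is_hit] += direction * hit_effect
        ratios[c] = np.clip(base, 0.0, 1.0)
    plate = ScreenPlate(ratios=ratios, controls=controls, silent_allele=silent)
    truth = pd.DataFrame({"compound_id": compound_ids, "is_hit": is_hit}).set_index(
        "compound_id"
    )
    return plate, truth


# ---------------------------------------------------------------------------
# Per-allele expression levels (dosage analysis)


def simulate_dosage_clones(
    n_monoallelic: int = 30,
    n_biallelic: int = 30,
    allele_mean: float = 1.0,
    allele_sd: float = 0.1,
    seed=None,
) -> pd.DataFrame:
    """Expression levels under a per-allele model.

    Each active allele contributes an independent Normal(allele_mean,
    allele_sd) amount of mRNA: monoallelic clones express one allele,
    biallelic clones two, so the expected monoallelic/biallelic mean level
    ratio is one half.  Returns clone_id, level, category.
    """
    rng = np.random.default_rng(seed)
    mono = rng.normal(allele_mean, allele_sd, size=n_monoallelic)
    bi = (
        rng.normal(allele_mean, allele_sd, size=n_biallelic)
        + rng.normal(allele_mean, allele_sd, size=n_biallelic)
    )
    cats = [
        (
            AllelicCategory.MONOALLELIC_CAST
            if i % 2
            else AllelicCategory.MONOALLELIC_129
        ).value
        for i in range(n_monoallelic)
    ] + [AllelicCategory.BIALLELIC.value] * n_biallelic
    return pd.DataFrame(
        {
            "clone_id": [f"clone_{i:03d}" for i in range(n_monoallelic + n_biallelic)],
            "level": np.concatenate([mono, bi]),
            "category": cats,
        }
    )
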