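"""Stability, dosage, screen hit-calling and dose-response statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import linregress

from raexi.downstream import (
    ScreenPlate,
    call_screen_hits,
    dosage_ttest,
    fit_dose_response,
    ks_compare,
    propose_expression_threshold,
    protein_rna_regression,
    split_expression_groups,
    stability_correlation,
)
from raexi.ratios import AllelicCategory
from raexi.simulate import simulate_dosage_clones


# ---------------------------------------------------------------------------
# KS comparison


def test_ks_identical_samples():
    x = np.linspace(0.1, 0.9, 20)
    d, p = ks_compare(x, x)
    assert d == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_ks_disjoint_supports():
    d, _ = ks_compare(np.linspace(0.0, 0.2, 15), np.linspace(0.8, 1.0, 15))
    assert d == pytest.approx(1.0)


def _ecdf_max_gap(a, b):
    """Brute-force oracle: maximum |ECDF_a - ECDF_b| over all data points."""
    grid = np.concatenate([a, b])
    fa = np.array([(a <= g).mean() for g in grid])
    fb = np.array([(b <= g).mean() for g in grid])
    return np.abs(fa - fb).max()


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_ks_matches_brute_force_ecdf_gap(seed):
    """Tight unimodal sample vs a trimodal one, like stem cells vs
    progenitors; D must equal the explicit ECDF maximum gap."""
    rng = np.random.default_rng(seed)
    esc = rng.normal(0.5, 0.02, 18)
    comps = rng.choice(3, 150, p=[0.25, 0.5, 0.25])
    npc = rng.normal(np.array([0.05, 0.5, 0.95])[comps], 0.04)
    d, _ = ks_compare(esc, npc)
    assert d == pytest.approx(_ecdf_max_gap(esc, npc), abs=1e-12)


def test_ks_rejects_empty_sample():
    with pytest.raises(ValueError):
        ks_compare([], [0.5])


# ---------------------------------------------------------------------------
# Stability correlation


def _tp(genes, ratios, reads):
    return pd.DataFrame({"ratio": ratios, "n_reads": reads}, index=genes)


def test_stability_perfectly_stable_and_antistable():
    genes = list("abcdefgh")
    ratios = np.linspace(0.1, 0.9, 8)
    t1 = _tp(genes, ratios, [50] * 8)
    assert stability_correlation(t1, t1).r == pytest.approx(1.0)
    t2 = _tp(genes, 1 - ratios, [50] * 8)
    assert stability_correlation(t1, t2).r == pytest.approx(-1.0)


def test_stability_read_filter_drops_gene():
    genes = list("abcd")
    t1 = _tp(genes, [0.1, 0.5, 0.9, 0.3], [50, 50, 50, 50])
    t2 = _tp(genes, [0.1, 0.5, 0.9, 0.99], [50, 50, 50, 19])
    res = stability_correlation(t1, t2, min_reads=20)
    assert res.n_genes == 3
    assert res.r == pytest.approx(1.0)


def test_stability_undefined_below_three_genes():
    t1 = _tp(["a", "b"], [0.1, 0.9], [50, 50])
    res = stability_correlation(t1, t1)
    assert res.status == "undefined"
    assert np.isnan(res.r)


# ---------------------------------------------------------------------------
# Expression groups & dosage


def test_split_expression_groups_thresholding():
    labels = split_expression_groups([0.2, 0.9], threshold=0.5)
    assert list(labels) == ["low", "high"]
    with pytest.warns(UserWarning):
        split_expression_groups([0.1, 0.2], threshold=0.5)


def test_proposed_threshold_separates_bimodal_levels():
    rng = np.random.default_rng(8)
    low = 10 ** rng.normal(-1.0, 0.15, 60)
    high = 10 ** rng.normal(0.5, 0.15, 60)
    levels = np.concatenate([low, high])
    thr = propose_expression_threshold(levels, seed=3)
    labels = split_expression_groups(levels, thr)
    truth = np.array(["low"] * 60 + ["high"] * 60)
    assert (labels == truth).mean() >= 0.95


def test_dosage_equal_groups_give_null_t():
    levels = [1.0, 2.0, 1.0, 2.0]
    cats = [
        AllelicCategory.MONOALLELIC_CAST,
        AllelicCategory.MONOALLELIC_129,
        AllelicCategory.BIALLELIC,
        AllelicCategory.BIALLELIC,
    ]
    res = dosage_ttest(levels, cats)
    assert res.t == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)
    assert res.df == 2


def test_dosage_matches_pooled_variance_formula_on_toy_input():
    mono = np.array([0.9, 1.0, 1.1, 1.0])
    bi = np.array([1.9, 2.1, 2.0, 2.0])
    levels = np.concatenate([mono, bi])
    cats = [AllelicCategory.MONOALLELIC_129] * 4 + [AllelicCategory.BIALLELIC] * 4
    res = dosage_ttest(levels, cats)
    # hand-evaluated pooled-variance Student t
    sp2 = (mono.var(ddof=1) * 3 + bi.var(ddof=1) * 3) / 6
    t_hand = (mono.mean() - bi.mean()) / np.sqrt(sp2 * (1 / 4 + 1 / 4))
    assert res.t == pytest.approx(t_hand, abs=1e-12)
    assert res.df == 6


def test_dosage_excludes_biased_clones_and_requires_groups():
    levels = [1.0, 1.1, 2.0, 2.1, 5.0]
    cats = [
        AllelicCategory.MONOALLELIC_129,
        AllelicCategory.MONOALLELIC_CAST,
        AllelicCategory.BIALLELIC,
        AllelicCategory.BIALLELIC,
        AllelicCategory.BIASED_CAST,  # must not enter either group
    ]
    res = dosage_ttest(levels, cats)
    assert res.n_monoallelic == 2 and res.n_biallelic == 2
    with pytest.raises(ValueError):
        dosage_ttest([1.0, 2.0], [AllelicCategory.MONOALLELIC_129,
                                  AllelicCategory.BIALLELIC])


def test_dosage_halving_under_per_allele_model():
    """One active allele produces half the mRNA of two: the mono/bi mean
    ratio estimator concentrates near 0.5."""
    df = simulate_dosage_clones(n_monoallelic=30, n_biallelic=30, seed=5)
    res = dosage_ttest(df["level"], df["category"])
    assert 0.45 <= res.ratio_of_means <= 0.55
    assert res.p_value < 0.01


# ---------------------------------------------------------------------------
# Protein ~ mRNA regression


def test_protein_regression_recovers_exact_slope():
    rna = np.linspace(0.5, 2.0, 11)
    res = protein_rna_regression(0.8 * rna, rna)
    assert res.slope == pytest.approx(0.8)
    assert res.r_squared == pytest.approx(1.0)
    assert res.df == (1, 9)  # 11 clones -> F(1, 9)


def test_protein_regression_matches_independent_fit():
    rng = np.random.default_rng(12)
    rna = np.linspace(0.5, 2.0, 11)
    protein = 0.8 * rna + rng.normal(0, 0.05, 11)
    res = protein_rna_regression(protein, rna)
    ref = linregress(rna, protein)
    assert res.slope == pytest.approx(ref.slope, abs=1e-12)
    assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)
    assert res.f_stat == pytest.approx((ref.slope / ref.stderr) ** 2, abs=1e-9)


# ---------------------------------------------------------------------------
# Screen hit calling


def _plate(effects_31, effects_84, sd=0.01, n_controls=11):
    # control wells constructed with exact mean and exact sample SD
    base = np.linspace(-1, 1, n_controls)
    base = base / base.std(ddof=1)
    controls = {
        "clone_31": 0.02 + sd * base,
        "clone_84": 0.98 - sd * base,
    }
    ratios = pd.DataFrame(
        {
            "clone_31": 0.02 + np.asarray(effects_31, float),
            "clone_84": 0.98 - np.asarray(effects_84, float),
        },
        index=[f"cmp_{i}" for i in range(len(effects_31))],
    )
    return ScreenPlate(
        ratios=ratios,
        controls=controls,
        silent_allele={"clone_31": "cast", "clone_84": "ref"},
    )


def test_hand_evaluated_three_sigma_rule():
    """Controls with SD 0.01 -> threshold 0.03 above the mean; effects of
    0.08/0.09 in the two clones are a hit."""
    plate = _plate([0.08, 0.0, 0.05], [0.09, 0.0, 0.0])
    hits = call_screen_hits(plate)
    assert list(hits["hit"]) == [True, False, False]
    assert hits["threshold_clone_31"].iloc[0] == pytest.approx(0.03)


def test_effect_in_one_clone_only_is_never_a_hit():
    plate = _plate([0.2, 0.0], [0.0, 0.2])
    hits = call_screen_hits(plate)
    assert not hits["hit"].any()


def test_missing_measurement_marks_nd_not_hit():
    plate = _plate([0.2, 0.2], [0.2, 0.2])
    plate.ratios.iloc[1, 1] = np.nan
    hits = call_screen_hits(plate)
    assert hits["status"].iloc[1] == "ND"
    assert bool(hits["hit"].iloc[0]) and not bool(hits["hit"].iloc[1])


def test_plate_requires_two_controls():
    with pytest.raises(ValueError):
        ScreenPlate(
            ratios=pd.DataFrame({"c": [0.5]}),
            controls={"c": [0.5]},
            silent_allele={"c": "cast"},
        )


# ---------------------------------------------------------------------------
# Dose-response (4PL)


def _four_pl(dose, bottom, top, ec50, hill, floor=1e-4):
    log_d = np.log10(np.where(dose > 0, dose, floor))
    return bottom + (top - bottom) / (1 + 10 ** (hill * (np.log10(ec50) - log_d)))


def test_noiseless_four_pl_recovered_exactly():
    doses = np.repeat([0.01, 0.03, 0.1, 0.3, 1, 3, 10, 30], 2)
    y = _four_pl(doses, 0.0, 1.0, 1.0, 1.0)
    fit = fit_dose_response(doses, y, seed=1)
    assert fit.status == "ok"
    assert fit.bottom == pytest.approx(0.0, abs=1e-6)
    assert fit.top == pytest.approx(1.0, abs=1e-6)
    assert fit.ec50 == pytest.approx(1.0, abs=1e-6)
    assert fit.hill == pytest.approx(1.0, abs=1e-6)


def test_zero_doses_anchor_bottom_asymptote():
    doses = np.repeat([0, 0.1, 0.5, 1, 5, 10], 3)
    y = _four_pl(doses, 0.05, 0.6, 0.9, 1.2, floor=0.001)
    fit = fit_dose_response(doses, y, seed=2)
    assert fit.bottom == pytest.approx(0.05, abs=0.01)


def test_noisy_ec50_recovery_within_ten_percent():
    """3 replicates/dose with ratio noise SD 0.02: EC50 recovered within
    +/-10% in at least 90% of seeded runs (and nearly always close)."""
    doses = np.repeat([0, 0.01, 0.1, 0.3, 1, 3, 10, 30], 3)
    clean = _four_pl(doses, 0.0, 1.0, 1.0, 1.0)
    ok = 0
    runs = 100
    ss = np.random.SeedSequence(55)
    for child in ss.spawn(runs):
        rng = np.random.default_rng(child)
        y = clean + rng.normal(0, 0.02, doses.size)
        fit = fit_dose_response(doses, y, seed=child.spawn(1)[0])
        ok += fit.status == "ok" and abs(fit.ec50 - 1.0) <= 0.10
    assert ok / runs >= 0.90


def test_dose_response_requires_four_dose_levels():
    with pytest.raises(ValueError):
        fit_dose_response([1, 1, 10, 10], [0.1, 0.1, 0.9, 0.9], seed=0)
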