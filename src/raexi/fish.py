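"""Binomial goodness-of-fit test separating stable monoallelic expression
from transcriptional bursting in nascent RNA-FISH cell tallies.

Each cell of a homogeneous population carries two genetically identical
alleles.  An active allele's nascent RNA is seen with probability
P_detect = P_ON * P_sense (probability of being in the ON phase of bursty
transcription, times the detection sensitivity of the FISH assay).  If the
gene is biallelic in every cell and the two alleles burst independently,
the number of detected signals per cell follows Binomial(2, P_detect), with
P_detect estimated as n_tot / (2 * N_cells) from the total pinpoint count.
A chi-squared goodness-of-fit test with one degree of freedom (three count
classes, one estimated parameter) asks whether the observed excess of
one-signal cells can be explained by bursting/detection alone; rejection
indicates a stably silent allele in part of the population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2


@dataclass(frozen=True)
class FishCellCounts:
    """Tally of cells with 0, 1 or 2 detected nascent signals."""

    n0: int
    n1: int
    n2: int
    region_id: str = "region"
    animal_id: str | None = None

    def __post_init__(self):
        if min(self.n0, self.n1, self.n2) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.n0 + self.n1 + self.n2

    @property
    def n_tot(self) -> int:
        """Total pinpoints detected over all cells (each cell has 2 alleles)."""
        return self.n1 + 2 * self.n2


@dataclass(frozen=True)
class BurstTestResult:
    p_detect: float
    expected: tuple[float, float, float]
    chi2: float
    df: int
    p_value: float
    low_expected_warning: bool
    infinite_statistic: bool = False


def estimate_p_detect(counts: FishCellCounts) -> float:
    """P_detect = n_tot / (2 * N_cells)."""
    if counts.n_cells < 1:
        raise ValueError("need at least one cell")
    return counts.n_tot / (2.0 * counts.n_cells)


def expected_allele_counts(p: float, n: int) -> tuple[float, float, float]:
    """Expected (0, 1, 2)-signal cell counts under Binomial(2, p)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    q = 1.0 - p
    return (n * q * q, 2.0 * n * p * q, n * p * p)


def burst_gof_test(counts: FishCellCounts) -> BurstTestResult:
    """Chi-squared test of the observed signal classes against Binomial(2, p_detect).

    Classes with zero expectation and zero observation are skipped; a class
    with zero expectation but a positive observation makes the statistic
    infinite (p = 0).  The degrees of freedom are always 1 (three classes,
    one estimated parameter).  A warning flag is set when any expected class
    is below 5, where the chi-squared approximation degrades; no continuity
    correction is applied.
    """
    p = estimate_p_detect(counts)
    expected = expected_allele_counts(p, counts.n_cells)
    observed = (counts.n0, counts.n1, counts.n2)
    stat = 0.0
    infinite = False
    for obs, exp in zip(observed, expected):
        if exp == 0.0:
            if obs > 0:
                infinite = True
            continue
        stat += (obs - exp) ** 2 / exp
    low = any(e < 5.0 for e in expected)
    if infinite:
        return BurstTestResult(
            p_detect=p, expected=expected, chi2=np.inf, df=1, p_value=0.0,
            low_expected_warning=True, infinite_statistic=True,
        )
    return BurstTestResult(
        p_detect=p, expected=expected, chi2=stat, df=1,
        p_value=float(chi2.sf(stat, df=1)), low_expected_warning=low,
    )


def pool_regions(
    counts: Sequence[FishCellCounts],
    by: str = "region",
    allow_mixed: bool = False,
) -> FishCellCounts:
    """Element-wise sum of cell tallies sharing a pooling key.

    ``by="region"`` pools animals within one region (the default analysis);
    ``by="animal"`` pools records of one animal.  Mixing different key
    values is an error unless ``allow_mixed`` is set explicitly.
    """
    items = list(counts)
    if not items:
        raise ValueError("nothing to pool")
    if by not in ("region", "animal"):
        raise ValueError("by must be 'region' or 'animal'")
    key = lambda c: c.region_id if by == "region" else (c.region_id, c.animal_id)
    keys = {key(c) for c in items}
    if len(keys) > 1 and not allow_mixed:
        raise ValueError(f"refusing to pool across mixed {by} keys: {sorted(map(str, keys))}")
    return FishCellCounts(
        n0=sum(c.n0 for c in items),
        n1=sum(c.n1 for c in items),
        n2=sum(c.n2 for c in items),
        region_id=items[0].region_id if len({c.region_id for c in items}) == 1 else "pooled",
        animal_id=items[0].animal_id if len({c.animal_id for c in items}) == 1 else None,
    )


def burst_test_table(counts: Iterable[FishCellCounts]) -> pd.DataFrame:
    """Per-animal tests plus a pooled test per region, as one tidy table."""
    rows = []
    items = list(counts)
    regions: dict[str, list[FishCellCounts]] = {}
    for c in items:
        regions.setdefault(c.region_id, []).append(c)
    for region, group in regions.items():
        for c in group:
            res = burst_gof_test(c)
            rows.append(_row(region, c.animal_id, c, res))
        if len(group) > 1:
            pooled = pool_regions(group, by="region")
            rows.append(_row(region, "pooled", pooled, burst_gof_test(pooled)))
    return pd.DataFrame(rows)


def _row(region, animal, c: FishCellCounts, res: BurstTestResult) -> dict:
    return {
        "region_id": region,
        "animal_id": animal,
        "n0": c.n0, "n1": c.n1, "n2": c.n2,
        "n_cells": c.n_cells, "n_tot": c.n_tot,
        "p_detect": res.p_detect,
        "e0": res.expected[0], "e1": res.expected[1], "e2": res.expected[2],
        "chi2": res.chi2, "df": res.df, "p_value": res.p_value,
        "low_expected_warning": res.low_expected_warning,
    }
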