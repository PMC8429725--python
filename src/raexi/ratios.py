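"""Allelic ratio computation, filtering and categorisation.

The allelic expression (or chromatin accessibility) ratio of a gene in a
clonal cell line is the fraction of allele-specific signal assigned to the
Castaneus (Cast) allele over the total Cast + 129/Sv signal.  A ratio of 0
means exclusive expression from the 129 allele, 1 exclusive expression from
the Cast allele, and 0.5 balanced biallelic expression.  Ratios are stored
as fractions in [0, 1] throughout; they are rendered as percentages only in
reports.

Gene x clone ratios with too few informative (allele-specific) reads are
excluded rather than reported as noisy values; the default thresholds are
20 reads for RNA-seq gene ratios and 10 for ATAC-seq peaks.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

DEFAULT_MIN_READS_RNA = 20
DEFAULT_MIN_READS_ATAC = 10

STATUS_OK = "ok"
STATUS_EXCLUDED = "excluded_low_reads"


class AllelicCategory(Enum):
    """Five-way categorisation of an allelic ratio.

    monoallelic: ratio < 0.15 or > 0.85; biased: 0.15 <= ratio <= 0.35 or
    0.65 <= ratio <= 0.85; biallelic: 0.35 < ratio < 0.65.  The categories
    partition [0, 1] and are ordered from 129-monoallelic to Cast-monoallelic.
    """

    MONOALLELIC_129 = "monoallelic_129"
    BIASED_129 = "biased_129"
    BIALLELIC = "biallelic"
    BIASED_CAST = "biased_cast"
    MONOALLELIC_CAST = "monoallelic_cast"


#: Categories in increasing order of the Cast fraction.
CATEGORY_ORDER = (
    AllelicCategory.MONOALLELIC_129,
    AllelicCategory.BIASED_129,
    AllelicCategory.BIALLELIC,
    AllelicCategory.BIASED_CAST,
    AllelicCategory.MONOALLELIC_CAST,
)


@dataclass(frozen=True)
class AllelicRatio:
    """A single gene x clone allelic ratio.

    ``value`` is the Cast fraction (None when excluded), ``n_informative``
    the total allele-specific reads behind it (None for assays such as
    pyrosequencing that report percentages without read counts).
    """

    value: float | None
    n_informative: int | None
    status: str

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK


def compute_allelic_ratio(
    cast: int, ref: int, min_reads: int = DEFAULT_MIN_READS_RNA
) -> AllelicRatio:
    """Cast / (Cast + 129) ratio, excluded when coverage is below ``min_reads``.

    Parameters
    ----------
    cast, ref:
        Non-negative allele-specific read (or pyrosequencing signal) counts
        for the Castaneus and 129/Sv alleles.
    min_reads:
        Minimum total informative reads for the ratio to be reported.

    Raises
    ------
    ValueError
        If counts are negative, or if ``min_reads`` is 0 and the total count
        is 0 (the ratio is undefined and no filter would catch it).
    """
    if cast < 0 or ref < 0:
        raise ValueError(f"allele counts must be non-negative, got ({cast}, {ref})")
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    total = cast + ref
    if total == 0 and min_reads == 0:
        raise ValueError("ratio undefined: zero total reads and no read filter")
    if total < min_reads:
        return AllelicRatio(value=None, n_informative=total, status=STATUS_EXCLUDED)
    return AllelicRatio(value=cast / total, n_informative=total, status=STATUS_OK)


def classify_ratio(r: float) -> AllelicCategory:
    """Map a ratio in [0, 1] to its allelic category (deterministic, total)."""
    if not np.isfinite(r) or r < 0.0 or r > 1.0:
        raise ValueError(f"ratio must be in [0, 1], got {r!r}")
    if r < 0.15:
        return AllelicCategory.MONOALLELIC_129
    if r <= 0.35:
        return AllelicCategory.BIASED_129
    if r < 0.65:
        return AllelicCategory.BIALLELIC
    if r <= 0.85:
        return AllelicCategory.BIASED_CAST
    return AllelicCategory.MONOALLELIC_CAST


def category_proportions(ratios: Iterable[float]) -> dict[str, float]:
    """Proportion of values in each allelic category.

    Returns a dict keyed by the five category names plus a combined
    ``"monoallelic"`` entry (both directions pooled).  The five category
    proportions sum to 1.
    """
    values = list(ratios)
    if not values:
        raise ValueError("category_proportions requires a non-empty collection")
    counts = Counter(classify_ratio(r) for r in values)
    n = len(values)
    out = {cat.value: counts.get(cat, 0) / n for cat in CATEGORY_ORDER}
    out["monoallelic"] = (
        out[AllelicCategory.MONOALLELIC_129.value]
        + out[AllelicCategory.MONOALLELIC_CAST.value]
    )
    return out


@dataclass
class RatioMatrix:
    """Genes x clones grid of allelic ratios with provenance.

    ``ratios`` holds the Cast fraction (NaN for missing or excluded entries),
    ``reads`` the informative read totals (NaN when the assay reports none),
    and ``n_excluded_low_reads`` how many entries failed the read filter.
    """

    ratios: pd.DataFrame
    reads: pd.DataFrame
    provenance: str = "RNA-seq"
    n_excluded_low_reads: int = 0

    def category_table(self) -> pd.DataFrame:
        """Per-entry allelic category names (NaN propagated)."""
        return self.ratios.map(
            lambda r: classify_ratio(r).value if np.isfinite(r) else np.nan
        )


def build_ratio_matrix(
    counts: pd.DataFrame,
    min_reads: int = DEFAULT_MIN_READS_RNA,
    provenance: str = "RNA-seq",
) -> RatioMatrix:
    """Turn a long allele-count table into a gene x clone ratio matrix.

    ``counts`` must have columns gene_id, clone_id, cast_count, ref_count
    with at most one row per (gene, clone) pair.
    """
    required = ["gene_id", "clone_id", "cast_count", "ref_count"]
    missing = [c for c in required if c not in counts.columns]
    if missing:
        raise ValueError(f"missing column {missing[0]}")
    if counts.empty:
        empty = pd.DataFrame(dtype=float)
        return RatioMatrix(ratios=empty, reads=empty.copy(), provenance=provenance)
    dup = counts.duplicated(subset=["gene_id", "clone_id"])
    if dup.any():
        row = counts.loc[dup.idxmax()]
        raise ValueError(
            f"duplicate (gene, clone) pair: ({row['gene_id']}, {row['clone_id']})"
        )
    n_excluded = 0
    records = []
    for rec in counts.itertuples(index=False):
        ratio = compute_allelic_ratio(
            int(rec.cast_count), int(rec.ref_count), min_reads=min_reads
        )
        if not ratio.ok:
            n_excluded += 1
        records.append(
            (rec.gene_id, rec.clone_id, ratio.value, ratio.n_informative)
        )
    long = pd.DataFrame(records, columns=["gene_id", "clone_id", "ratio", "reads"])
    ratios = long.pivot(index="gene_id", columns="clone_id", values="ratio")
    reads = long.pivot(index="gene_id", columns="clone_id", values="reads")
    return RatioMatrix(
        ratios=ratios.astype(float),
        reads=reads.astype(float),
        provenance=provenance,
        n_excluded_low_reads=n_excluded,
    )


def ratio_matrix_from_percentages(
    percent: pd.DataFrame, provenance: str = "pyrosequencing"
) -> RatioMatrix:
    """Accept a wide gene x clone percentage matrix (no read counts).

    Pyrosequencing reports allelic percentages without per-assay read
    totals, so no read filter applies and ``reads`` is all-NaN.
    """
    ratios = percent.astype(float) / 100.0
    finite = ratios.to_numpy()[np.isfinite(ratios.to_numpy())]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("percentages must lie in [0, 100]")
    reads = pd.DataFrame(np.nan, index=ratios.index, columns=ratios.columns)
    return RatioMatrix(ratios=ratios, reads=reads, provenance=provenance)
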