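"""Allelic ATAC-RNA regulatory-region scan around a gene's TSS.

For a gene showing random allelic expression imbalance, the scan asks which
accessible-chromatin peak within +/-3 Mb of the transcription start site has
allele-specific accessibility that predicts the gene's allele-specific
expression across clonal cell lines.  Per peak, clones' ATAC allelic ratios
(Cast / total allele-specific reads) are regressed against the gene's RNA
allelic ratios by ordinary least squares; p-values are Bonferroni-adjusted
over the peaks actually tested for that gene, and the best peak is the one
with the smallest adjusted p (ties broken toward the TSS).

Filters before regression (defaults from the analysis this reproduces):
clone values with fewer than 10 allele-specific ATAC reads are dropped; a
peak needs at least 4 remaining values and at least 2 clones whose RNA ratio
is biased (< 1/3 or > 2/3) to be tested.  Peaks without a strain-
discriminating SNP carry no allelic information and are dropped up front.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._regression import simple_ols

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 3_000_000

STATUS_TESTED = "tested"
STATUS_FEW_VALUES = "excluded_few_values"
STATUS_NO_BIAS = "excluded_no_bias"
STATUS_DEGENERATE = "degenerate_predictor"
STATUS_NO_DATA = "no_data"


@dataclass(frozen=True)
class Peak:
    """BED-style peak: 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    peak_id: str
    has_snp: bool = True

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"peak {self.peak_id}: start must be < end")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class ScanConfig:
    window_bp: int = DEFAULT_WINDOW_BP
    min_reads: int = 10
    min_values: int = 4
    bias_lo: float = 1.0 / 3.0
    bias_hi: float = 2.0 / 3.0
    min_biased_clones: int = 2


@dataclass
class PeakRegression:
    peak_id: str
    status: str
    n_clones_used: int = 0
    slope: float = np.nan
    intercept: float = np.nan
    r_squared: float = np.nan
    f_stat: float = np.nan
    df: tuple[int, int] | None = None
    p_raw: float = np.nan
    p_adjusted: float = np.nan
    distance_to_tss: float = np.nan


@dataclass
class ScanResult:
    gene_id: str
    tss: int
    window_bp: int
    m_tested: int
    regressions: list[PeakRegression] = field(default_factory=list)
    best_peak: str | None = None
    n_peaks_in_window: int = 0
    n_dropped_no_snp: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "peak_id": r.peak_id,
                "status": r.status,
                "n_clones_used": r.n_clones_used,
                "slope": r.slope,
                "intercept": r.intercept,
                "r_squared": r.r_squared,
                "f_stat": r.f_stat,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "distance_to_tss": r.distance_to_tss,
            }
            for r in self.regressions
        ]
        df = pd.DataFrame(rows)
        if not df.empty:
            df = df.sort_values(
                ["p_adjusted", "distance_to_tss"], na_position="last"
            ).reset_index(drop=True)
        return df


def select_window_peaks(
    peaks: Iterable[Peak],
    tss: int,
    window_bp: int = DEFAULT_WINDOW_BP,
    chrom: str | None = None,
) -> list[Peak]:
    """Peaks whose midpoint lies within [tss - window, tss + window].

    Peaks without a SNP are dropped (their count is logged); peaks on a
    different chromosome are ignored when ``chrom`` is given.
    """
    if tss is None:
        raise ValueError("missing TSS")
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    candidates = [
        p for p in peaks
        if (chrom is None or p.chrom == chrom)
        and abs(p.midpoint - tss) <= window_bp
    ]
    kept = [p for p in candidates if p.has_snp]
    n_dropped = len(candidates) - len(kept)
    if n_dropped:
        logger.info("dropped %d peaks without strain SNPs", n_dropped)
    return kept


def bonferroni(p_raw: float, m: int) -> float:
    """Family-wise adjustment p_adjusted = min(1, m * p_raw)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p_raw)


def apply_scan_filters(
    series: pd.DataFrame, config: ScanConfig | None = None
) -> tuple[pd.DataFrame, str]:
    """Read and bias filters for one peak's clone series.

    ``series`` has one row per clone with columns atac_ratio, atac_reads and
    rna_ratio (atac_reads may be NaN for assays without read counts, which
    then pass the read filter).  Returns the retained rows and a status:
    tested, excluded_few_values, or excluded_no_bias.  The bias criterion is
    applied to the gene's RNA ratio of exactly the clones entering the
    regression.
    """
    cfg = config or ScanConfig()
    kept = series.dropna(subset=["atac_ratio", "rna_ratio"])
    if "atac_reads" in kept.columns:
        reads = kept["atac_reads"]
        kept = kept[reads.isna() | (reads >= cfg.min_reads)]
    if len(kept) < cfg.min_values:
        return kept, STATUS_FEW_VALUES
    rna = kept["rna_ratio"]
    n_biased = int(((rna < cfg.bias_lo) | (rna > cfg.bias_hi)).sum())
    if n_biased < cfg.min_biased_clones:
        return kept, STATUS_NO_BIAS
    return kept, STATUS_TESTED


def regress_peak(atac, rna, peak_id: str = "") -> PeakRegression:
    """OLS of RNA allelic ratio on ATAC allelic ratio for one peak.

    The direction (RNA ~ ATAC) affects only the reported slope; F, R^2 and
    the p-value are identical for the reversed simple regression.
    """
    atac = np.asarray(atac, float).ravel()
    rna = np.asarray(rna, float).ravel()
    try:
        ols = simple_ols(atac, rna)
    except ValueError as err:
        if "constant predictor" in str(err):
            return PeakRegression(
                peak_id=peak_id, status=STATUS_DEGENERATE, n_clones_used=atac.size
            )
        raise
    return PeakRegression(
        peak_id=peak_id,
        status=STATUS_TESTED,
        n_clones_used=ols.n,
        slope=ols.slope,
        intercept=ols.intercept,
        r_squared=ols.r_squared,
        f_stat=ols.f_stat,
        df=ols.df,
        p_raw=ols.p_value,
    )


def build_peak_series(
    atac_counts: pd.DataFrame,
    rna_ratios: Mapping[str, float] | pd.Series,
) -> dict[str, pd.DataFrame]:
    """Pair per-clone ATAC allelic ratios with the gene's RNA ratios.

    ``atac_counts`` is a long table peak_id, clone_id, cast_count, ref_count;
    ``rna_ratios`` maps clone_id to the gene's RNA allelic ratio.  Clones
    without both measurements are absent from the series.
    """
    rna = pd.Series(rna_ratios, dtype=float)
    out: dict[str, pd.DataFrame] = {}
    for peak_id, grp in atac_counts.groupby("peak_id", sort=False):
        total = grp["cast_count"].to_numpy(float) + grp["ref_count"].to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(total > 0, grp["cast_count"].to_numpy(float) / total, np.nan)
        df = pd.DataFrame(
            {
                "clone_id": grp["clone_id"].to_numpy(),
                "atac_ratio": ratio,
                "atac_reads": total,
            }
        )
        df["rna_ratio"] = df["clone_id"].map(rna)
        out[str(peak_id)] = df.dropna(subset=["rna_ratio"]).reset_index(drop=True)
    return out


def scan_gene(
    gene_id: str,
    tss: int,
    peaks: Sequence[Peak],
    series_by_peak: Mapping[str, pd.DataFrame],
    config: ScanConfig | None = None,
    chrom: str | None = None,
) -> ScanResult:
    """Full scan: window selection, filters, per-peak OLS, Bonferroni.

    The Bonferroni family size m is the number of peaks actually tested for
    this gene.  The best peak minimises the adjusted p; ties are broken by
    distance to the TSS.  Zero tested peaks yields an empty result with a
    logged warning, not an error.
    """
    cfg = config or ScanConfig()
    peaks = list(peaks)
    in_window = select_window_peaks(peaks, tss, cfg.window_bp, chrom=chrom)
    n_no_snp = sum(
        1 for p in peaks
        if (chrom is None or p.chrom == chrom)
        and abs(p.midpoint - tss) <= cfg.window_bp and not p.has_snp
    )
    regressions: list[PeakRegression] = []
    for peak in in_window:
        series = series_by_peak.get(peak.peak_id)
        if series is None or series.empty:
            reg = PeakRegression(peak_id=peak.peak_id, status=STATUS_NO_DATA)
        else:
            kept, status = apply_scan_filters(series, cfg)
            if status != STATUS_TESTED:
                reg = PeakRegression(
                    peak_id=peak.peak_id, status=status, n_clones_used=len(kept)
                )
            else:
                reg = regress_peak(
                    kept["atac_ratio"], kept["rna_ratio"], peak_id=peak.peak_id
                )
        reg.distance_to_tss = abs(peak.midpoint - tss)
        regressions.append(reg)
    tested = [r for r in regressions if r.status == STATUS_TESTED]
    m = len(tested)
    for r in tested:
        r.p_adjusted = bonferroni(r.p_raw, m)
    best = None
    if m:
        best = min(tested, key=lambda r: (r.p_adjusted, r.distance_to_tss)).peak_id
    else:
        logger.warning("gene %s: no peaks passed the scan filters", gene_id)
    return ScanResult(
        gene_id=gene_id,
        tss=tss,
        window_bp=cfg.window_bp,
        m_tested=m,
        regressions=regressions,
        best_peak=best,
        n_peaks_in_window=len(in_window),
        n_dropped_no_snp=n_no_snp,
    )
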