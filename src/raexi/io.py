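"""Readers, writers, run configuration and the run manifest.

All tables are tab-delimited UTF-8 with a header row; peak coordinates use
the BED convention (0-based half-open).  Data tables are written at full
double precision (so a written ratio matrix reads back identically);
summary reports use 6 significant digits.  A run manifest (YAML) records
the configuration, seed,
package versions and per-stage exclusion counts, so any run can be
re-executed identically.
"""

from __future__ import annotations

import dataclasses
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fish import FishCellCounts
from .scan import Peak

#: Data tables keep full double precision so written matrices round-trip;
#: human-facing reports are rendered separately at 6 significant digits.
FLOAT_FORMAT = "%.12g"
REPORT_FLOAT_FORMAT = "%.6g"


@dataclass
class RunConfig:
    """Thresholds and paths for a pipeline run (defaults as documented
    per stage: 20-read RNA filter, 10-read ATAC filter, 15/35/65/85%
    category boundaries, 1/3-2/3 bias bounds, +/-3 Mb scan window,
    1000 bootstrap replications, 95% CIs, 3-sigma screen rule)."""

    min_reads_rna: int = 20
    min_reads_atac: int = 10
    category_boundaries: tuple[float, float, float, float] = (0.15, 0.35, 0.65, 0.85)
    bias_lo: float = 1.0 / 3.0
    bias_hi: float = 2.0 / 3.0
    window_bp: int = 3_000_000
    k_max: int = 5
    bootstrap_b: int = 1000
    ci_level: float = 0.95
    alpha: float = 0.05
    screen_sigma_multiplier: float = 3.0
    seed: int | None = None
    out_dir: str = "results"
    inputs: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["category_boundaries"] = list(self.category_boundaries)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "category_boundaries" in d:
            d["category_boundaries"] = tuple(d["category_boundaries"])
        return cls(**d)


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t")


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    for col in columns:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")


def _check_counts(df: pd.DataFrame, columns, path) -> None:
    for col in columns:
        series = pd.to_numeric(df[col], errors="coerce")
        bad = series.isna() | (series != series.round())
        if bad.any():
            row = int(np.argmax(bad.to_numpy())) + 2  # header is line 1
            raise ValueError(f"{path}: non-integer {col} at line {row}")
        neg = series < 0
        if neg.any():
            row = int(np.argmax(neg.to_numpy())) + 2
            raise ValueError(f"{path}: negative {col} at line {row}")
        df[col] = series.astype(int)


def read_count_table(path) -> pd.DataFrame:
    """Long allele-count table: gene_id, clone_id, cast_count, ref_count."""
    df = _read_table(path)
    _require_columns(df, ["gene_id", "clone_id", "cast_count", "ref_count"], path)
    _check_counts(df, ["cast_count", "ref_count"], path)
    return df


def read_peak_count_table(path) -> pd.DataFrame:
    """Long peak-count table: peak_id, clone_id, cast_count, ref_count."""
    df = _read_table(path)
    _require_columns(df, ["peak_id", "clone_id", "cast_count", "ref_count"], path)
    _check_counts(df, ["cast_count", "ref_count"], path)
    return df


def read_fish_table(path) -> list[FishCellCounts]:
    """Cell tallies: region_id, animal_id, n0, n1, n2."""
    df = _read_table(path)
    _require_columns(df, ["region_id", "n0", "n1", "n2"], path)
    _check_counts(df, ["n0", "n1", "n2"], path)
    out = []
    for rec in df.itertuples(index=False):
        animal = getattr(rec, "animal_id", None)
        out.append(
            FishCellCounts(
                n0=int(rec.n0), n1=int(rec.n1), n2=int(rec.n2),
                region_id=str(rec.region_id),
                animal_id=None if animal is None or pd.isna(animal) else str(animal),
            )
        )
    return out


def read_peak_bed(path) -> list[Peak]:
    """BED-like peak table: chrom, start, end, peak_id [, has_snp]."""
    df = pd.read_csv(path, sep="\t")
    if "chrom" not in df.columns:  # headerless BED
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "peak_id", "has_snp"][: len(df.columns) + 1],
        )
    _require_columns(df, ["chrom", "start", "end", "peak_id"], path)
    has_snp = df["has_snp"].astype(bool) if "has_snp" in df.columns else True
    return [
        Peak(
            chrom=str(r.chrom), start=int(r.start), end=int(r.end),
            peak_id=str(r.peak_id),
            has_snp=bool(has_snp if has_snp is True else has_snp.iloc[i]),
        )
        for i, r in enumerate(df.itertuples(index=False))
    ]


def read_tss_table(path) -> pd.DataFrame:
    """Gene TSS coordinates: gene_id, chrom, tss [, strand]."""
    df = _read_table(path)
    _require_columns(df, ["gene_id", "chrom", "tss"], path)
    _check_counts(df, ["tss"], path)
    return df.set_index("gene_id")


def read_ratio_table(path) -> pd.DataFrame:
    """Wide gene x clone ratio matrix (first column = gene_id)."""
    df = _read_table(path)
    return df.set_index(df.columns[0])


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def write_manifest(path, config: RunConfig, counts: dict | None = None) -> None:
    """Run manifest: config + seed + versions + per-stage exclusion counts."""
    import raexi

    manifest = {
        "config": {
            **dataclasses.asdict(config),
            "category_boundaries": list(config.category_boundaries),
        },
        "seed": config.seed,
        "versions": {
            "python": sys.version.split()[0],
            "raexi": raexi.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "counts": counts or {},
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=True))


def mixture_report(fit, ci=None) -> pd.DataFrame:
    """One row per mixture component: weight, mean, variance (+ CI bounds)."""
    rows = []
    for i in range(fit.k):
        row = {
            "component": i + 1,
            "weight": fit.weights[i],
            "mean": fit.means[i],
            "variance": fit.variances[i],
        }
        if ci is not None:
            row.update(
                {
                    "weight_lo": ci.weights_lower[i],
                    "weight_hi": ci.weights_upper[i],
                    "mean_lo": ci.means_lower[i],
                    "mean_hi": ci.means_upper[i],
                    "variance_lo": ci.variances_lower[i],
                    "variance_hi": ci.variances_upper[i],
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def selection_report(candidates) -> pd.DataFrame:
    """Model-selection table: one row per (K, variance family) candidate."""
    return pd.DataFrame(
        {
            "k": [f.k for f in candidates],
            "variance_family": [f.variance_family for f in candidates],
            "log_lik": [f.log_lik for f in candidates],
            "bic": [f.bic for f in candidates],
            "converged": [f.converged for f in candidates],
        }
    ).sort_values("bic", ascending=False, ignore_index=True)
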