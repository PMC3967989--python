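"""qPCR validation: standard curves, splicing indices, Welch comparison.

Candidate splice switches are validated with isoform-specific qPCR
assays quantified absolutely against serial ten-fold dilution standard
curves.  Per sample, the splicing index is the short-isoform copy
number divided by the total (short plus pooled long) copy number, a
proportion in [0, 1].  The per-sample reference-gene (18S) factor is a
scalar on both channels and cancels in the index; it matters only when
absolute expression levels are reported.  Tumor and normal index
distributions are compared with the unequal-variance (Welch) two-sample
t test using Welch-Satterthwaite degrees of freedom.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

QUANT_COLUMNS = [
    "sample_id",
    "group",
    "gene",
    "short_copies",
    "long_copies",
    "reference_copies",
]


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of Ct against log10(input copies) for a dilution series.

    ``slope`` is in Ct per log10(copies) and is negative for a working
    assay (about -3.32 for perfect doubling chemistry); ``efficiency``
    is ``10**(-1/slope) - 1``, 1.0 meaning exact doubling per cycle.
    """

    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    valid: bool


@dataclass(frozen=True)
class SplicingIndexResult:
    """Welch comparison of per-sample splicing indices between cohorts."""

    gene: str
    tumor_indices: tuple[float, ...]
    normal_indices: tuple[float, ...]
    tumor_mean: float
    normal_mean: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    n_excluded: int


def fit_standard_curve(copies, ct) -> StandardCurve:
    """Fit a standard curve by ordinary least squares of Ct on log10(copies).

    Requires at least three strictly positive standards.  A
    non-negative slope yields a curve flagged invalid (with a warning)
    rather than an exception, so a failed assay can still be inspected.
    """
    copies = np.asarray(copies, dtype=float)
    ct = np.asarray(ct, dtype=float)
    if copies.shape != ct.shape or copies.ndim != 1:
        raise ValueError("copies and ct must be 1-D arrays of equal length")
    if copies.size < 3:
        raise ValueError("a standard curve needs at least 3 points")
    if (copies <= 0).any():
        raise ValueError("standard copies must be strictly positive")
    if not np.isfinite(ct).all():
        raise ValueError("non-finite Ct in standard series")
    res = stats.linregress(np.log10(copies), ct)
    slope = float(res.slope)
    valid = slope < 0
    if not valid:
        logger.warning("standard curve has non-negative slope %.4f", slope)
        efficiency = float("nan")
    else:
        efficiency = 10.0 ** (-1.0 / slope) - 1.0
    return StandardCurve(
        slope=slope,
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        efficiency=efficiency,
        valid=valid,
    )


def predict_ct(copies: float, curve: StandardCurve) -> float:
    """Ct the fitted curve predicts for a given input copy number."""
    if copies <= 0:
        raise ValueError("copies must be positive")
    return curve.intercept + curve.slope * math.log10(copies)


def ct_to_copies(ct: float, curve: StandardCurve) -> float:
    """Invert the fitted curve: absolute copies from an observed Ct."""
    if not curve.valid:
        raise ValueError("cannot invert a curve with non-negative slope")
    if not np.isfinite(ct):
        raise ValueError("non-finite Ct")
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def splicing_index(short_copies, long_copies):
    """Short-isoform proportion: short / (short + long), in [0, 1].

    Accepts scalars or arrays.  When both channels are zero the index
    is undefined and returned as NaN; callers exclude such samples with
    a logged count.  Negative copy numbers are a hard error.
    """
    short = np.asarray(short_copies, dtype=float)
    long = np.asarray(long_copies, dtype=float)
    if (short < 0).any() or (long < 0).any():
        raise ValueError("copy numbers must be non-negative")
    total = short + long
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = np.where(total > 0, short / np.where(total > 0, total, 1.0), np.nan)
    if idx.ndim == 0:
        return float(idx)
    return idx


def compare_groups(table: pd.DataFrame, gene: str | None = None) -> SplicingIndexResult:
    """Welch two-sample test of splicing indices, tumor versus normal.

    ``table`` follows the quant-table layout (one row per sample and
    gene).  Undefined indices (zero total copies) are excluded; each
    group must retain at least two usable samples.
    """
    sub = table if gene is None else table[table["gene"] == gene]
    if sub.empty:
        raise ValueError(f"no rows for gene {gene!r}")
    gene_name = str(sub["gene"].iloc[0]) if "gene" in sub.columns else ""
    idx = splicing_index(
        sub["short_copies"].to_numpy(), sub["long_copies"].to_numpy()
    )
    idx = np.atleast_1d(idx)
    defined = np.isfinite(idx)
    n_excluded = int((~defined).sum())
    if n_excluded:
        logger.info(
            "compare_groups[%s]: excluded %d samples with zero total copies",
            gene_name,
            n_excluded,
        )
    groups = sub["group"].to_numpy()
    tumor = idx[(groups == "tumor") & defined]
    normal = idx[(groups == "normal") & defined]
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError(
            f"need >= 2 usable samples per group, got {len(tumor)} tumor / "
            f"{len(normal)} normal"
        )
    res = stats.ttest_ind(tumor, normal, equal_var=False)
    return SplicingIndexResult(
        gene=gene_name,
        tumor_indices=tuple(float(x) for x in tumor),
        normal_indices=tuple(float(x) for x in normal),
        tumor_mean=float(tumor.mean()),
        normal_mean=float(normal.mean()),
        t_statistic=float(res.statistic),
        degrees_of_freedom=float(res.df),
        p_value=float(res.pvalue),
        n_excluded=n_excluded,
    )


def compare_all_genes(table: pd.DataFrame) -> pd.DataFrame:
    """Run :func:`compare_groups` per gene; one result row per gene."""
    rows = []
    for gene in sorted(table["gene"].unique()):
        r = compare_groups(table, gene=gene)
        rows.append(
            {
                "gene": r.gene,
                "n_tumor": len(r.tumor_indices),
                "n_normal": len(r.normal_indices),
                "tumor_mean_index": r.tumor_mean,
                "normal_mean_index": r.normal_mean,
                "t_statistic": r.t_statistic,
                "degrees_of_freedom": r.degrees_of_freedom,
                "p_value": r.p_value,
            }
        )
    return pd.DataFrame(rows)


def read_quant_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str, "gene": str})
    missing = [c for c in QUANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: quant table is missing column(s) {missing}")
    if not df["group"].isin(["tumor", "normal"]).all():
        bad = df.loc[~df["group"].isin(["tumor", "normal"]), "group"].iloc[0]
        raise ValueError(f"{path}: invalid group label {bad!r}")
    if (df["reference_copies"] <= 0).any():
        raise ValueError(f"{path}: reference_copies must be positive")
    return df


def write_quant_table(df: pd.DataFrame, path: str | Path) -> None:
    df[QUANT_COLUMNS].to_csv(path, sep="\t", index=False)
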