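"""Visual-screening plot data and rendering.

High-scoring genes are screened graphically before validation.  Two
views are built per gene: a cohort plot (mean tumor-minus-normal signal
per probeset, with per-probeset counts of tumors deviating beyond one
normal-cohort standard deviation, drawn as a signed histogram) and a
per-tumor plot (one tumor's normal-relative probeset values).  Both lay
probesets out 5' (left) to 3' (right) under the gene's exon track.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from mmes.expression import ExpressionMatrix


@dataclass(frozen=True)
class CohortPlotData:
    """Cohort-level screening data for one gene.

    ``tracing`` is the per-probeset difference of tumor and normal
    means (log2).  ``baseline`` is the grand mean of the raw log2
    signal over the gene's probesets and all samples, rounded down to
    the nearest whole number; it is a cosmetic horizontal reference
    only.  ``count_above``/``count_below`` count tumors strictly beyond
    the normal mean plus/minus one normal-cohort SD per probeset.
    """

    gene_id: str
    probeset_ids: tuple[str, ...]
    exon_ids: tuple[str, ...]
    tracing: tuple[float, ...]
    baseline: int
    count_above: tuple[int, ...]
    count_below: tuple[int, ...]
    n_tumors: int


@dataclass(frozen=True)
class TumorPlotData:
    """One tumor's normal-relative probeset values for one gene."""

    gene_id: str
    tumor_id: str
    probeset_ids: tuple[str, ...]
    exon_ids: tuple[str, ...]
    values: tuple[float, ...]


def _gene_probesets(annotation: pd.DataFrame, gene_id: str) -> pd.DataFrame:
    sub = annotation[annotation["gene_id"] == gene_id]
    if sub.empty:
        raise KeyError(f"gene {gene_id!r} not found in annotation")
    return sub.sort_values("order_index")


def build_cohort_plot(
    matrix: ExpressionMatrix, annotation: pd.DataFrame, gene_id: str
) -> CohortPlotData:
    """Assemble the cohort-level screening data for one gene.

    The deviation thresholds use the normal cohort's per-probeset
    sample standard deviation (n-1 denominator), so at least two normal
    samples are required.
    """
    sub = _gene_probesets(annotation, gene_id)
    probesets = [p for p in sub["probeset_id"] if p in matrix.values.index]
    if not probesets:
        raise KeyError(f"gene {gene_id!r} has no probesets in the matrix")
    if len(matrix.normal_ids) < 2:
        raise ValueError(
            "cohort plot needs >= 2 normal samples to estimate the SD"
        )
    exon_of = dict(zip(sub["probeset_id"], sub["exon_id"]))
    vals = matrix.values.loc[probesets]
    tumors = vals[matrix.tumor_ids]
    normals = vals[matrix.normal_ids]
    normal_mean = normals.mean(axis=1)
    normal_sd = normals.std(axis=1, ddof=1)
    tracing = tumors.mean(axis=1) - normal_mean
    above = tumors.gt(normal_mean + normal_sd, axis=0).sum(axis=1)
    below = tumors.lt(normal_mean - normal_sd, axis=0).sum(axis=1)
    baseline = math.floor(float(vals.to_numpy().mean()))
    return CohortPlotData(
        gene_id=gene_id,
        probeset_ids=tuple(probesets),
        exon_ids=tuple(exon_of[p] for p in probesets),
        tracing=tuple(float(x) for x in tracing),
        baseline=baseline,
        count_above=tuple(int(x) for x in above),
        count_below=tuple(int(x) for x in below),
        n_tumors=len(matrix.tumor_ids),
    )


def build_tumor_plot(
    norm: pd.DataFrame, annotation: pd.DataFrame, gene_id: str, tumor_id: str
) -> TumorPlotData:
    """Assemble one tumor's normal-relative probeset trace for one gene."""
    if tumor_id not in norm.columns:
        raise KeyError(f"unknown tumor {tumor_id!r}")
    sub = _gene_probesets(annotation, gene_id)
    probesets = [p for p in sub["probeset_id"] if p in norm.index]
    if not probesets:
        raise KeyError(f"gene {gene_id!r} has no probesets in the matrix")
    exon_of = dict(zip(sub["probeset_id"], sub["exon_id"]))
    values = norm.loc[probesets, tumor_id]
    return TumorPlotData(
        gene_id=gene_id,
        tumor_id=tumor_id,
        probeset_ids=tuple(probesets),
        exon_ids=tuple(exon_of[p] for p in probesets),
        values=tuple(float(x) for x in values),
    )


def _draw_exon_track(ax, exon_ids: tuple[str, ...]) -> None:
    """Alternate shaded blocks marking exon boundaries along the probeset axis."""
    boundaries: list[tuple[int, int, str]] = []
    start = 0
    for i in range(1, len(exon_ids) + 1):
        if i == len(exon_ids) or exon_ids[i] != exon_ids[start]:
            boundaries.append((start, i, exon_ids[start]))
            start = i
    for k, (lo, hi, exon) in enumerate(boundaries):
        ax.axvspan(lo - 0.5, hi - 0.5, color=("0.75", "0.9")[k % 2])
        ax.text((lo + hi - 1) / 2, 0.5, exon, ha="center", va="center", fontsize=6)
    ax.set_xlim(-0.5, len(exon_ids) - 0.5)
    ax.set_yticks([])
    ax.set_xticks([])


def render_gene_plot(
    data: CohortPlotData | TumorPlotData,
    out_path: str | Path,
    format: str = "png",
) -> Path:
    """Render a screening plot to PNG or PDF and return the written path.

    Output is deterministic for fixed input: PDF metadata that would
    embed a timestamp is stripped.
    """
    if format not in ("png", "pdf"):
        raise ValueError(f"unsupported format {format!r}")
    out_path = Path(out_path)
    x = np.arange(len(data.probeset_ids))

    if isinstance(data, CohortPlotData):
        fig, (ax_track, ax_sig, ax_hist) = plt.subplots(
            3,
            1,
            figsize=(max(4.0, 0.35 * len(x) + 1.5), 5.0),
            height_ratios=[1, 4, 2],
            sharex=True,
        )
        _draw_exon_track(ax_track, data.exon_ids)
        ax_sig.axhline(0.0, color="black", lw=0.8)
        ax_sig.plot(x, data.tracing, marker="o", ms=3, lw=1, color="tab:red")
        ax_sig.set_ylabel("tumor − normal mean (log2)")
        ax_sig.set_title(f"{data.gene_id} — cohort (baseline {data.baseline})")
        ax_hist.bar(x, data.count_above, color="tab:red", width=0.8)
        ax_hist.bar(x, [-c for c in data.count_below], color="tab:blue", width=0.8)
        ax_hist.axhline(0.0, color="black", lw=0.8)
        ax_hist.set_ylim(-data.n_tumors, data.n_tumors)
        ax_hist.set_ylabel("tumors beyond ±1 SD")
        ax_hist.set_xlabel("probesets, 5′ → 3′")
    else:
        fig, (ax_track, ax_sig) = plt.subplots(
            2,
            1,
            figsize=(max(4.0, 0.35 * len(x) + 1.5), 3.8),
            height_ratios=[1, 5],
            sharex=True,
        )
        _draw_exon_track(ax_track, data.exon_ids)
        ax_sig.axhline(0.0, color="black", lw=0.8)
        ax_sig.plot(x, data.values, marker="o", ms=3, lw=1, color="tab:purple")
        ax_sig.set_ylabel("signal relative to normal (log2)")
        ax_sig.set_xlabel("probesets, 5′ → 3′")
        ax_sig.set_title(f"{data.gene_id} — tumor {data.tumor_id}")

    ax_sig.set_xticks(x)
    ax_sig.set_xticklabels(data.probeset_ids, rotation=90, fontsize=5)
    fig.tight_layout()
    metadata = {"CreationDate": None} if format == "pdf" else None
    fig.savefig(out_path, format=format, dpi=100, metadata=metadata)
    plt.close(fig)
    return out_path
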