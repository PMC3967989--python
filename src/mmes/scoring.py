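"""Max-min exon scoring, ranking and candidate selection.

For each gene and tumor, the score is the spread of the gene's
exon-level normal-relative values: max over exons minus min over exons,
in log2 units.  A gene whose exons all move together — including any
whole-gene expression change — scores 0; a gene in which an exon subset
departs from the rest scores the size of that departure.  Genes are
ranked by the arithmetic mean of their per-tumor scores.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from mmes.annotation import GeneModel

logger = logging.getLogger(__name__)


def mmes_per_tumor(
    exon_signals: pd.DataFrame, model: GeneModel, tumor_id: str
) -> float:
    """Max-min spread of one gene's exon values in one tumor (>= 0).

    ``exon_signals`` is the exon-by-tumor matrix from
    :func:`mmes.expression.aggregate_exons`.  A single-exon gene scores
    exactly 0.  A gene none of whose exons appear in the matrix is a
    hard error.
    """
    exons = [e for e in model.exons if e in exon_signals.index]
    if not exons:
        raise KeyError(f"gene {model.gene_id!r} has no exons in the signal matrix")
    col = exon_signals.loc[exons, tumor_id].to_numpy()
    return float(col.max() - col.min())


def score_all(
    exon_signals: pd.DataFrame, models: dict[str, GeneModel] | list[GeneModel]
) -> pd.DataFrame:
    """Score every gene in every tumor and rank genes by mean score.

    Returns a DataFrame indexed by ``gene_id`` with columns ``rank``,
    ``mean_mmes`` and one column per tumor.  Rank 1 is the highest mean
    score; ties are broken by ascending gene id so output is
    deterministic.  Genes with no exon present in the matrix are
    excluded with a logged reason rather than scored 0.
    """
    if isinstance(models, dict):
        model_list = list(models.values())
    else:
        model_list = list(models)
    if not model_list:
        raise ValueError("no gene models to score")
    if exon_signals.shape[1] == 0:
        raise ValueError("no tumor columns in exon signal matrix")

    values = exon_signals.to_numpy()
    row_of = {e: i for i, e in enumerate(exon_signals.index)}
    gene_ids: list[str] = []
    score_rows: list[np.ndarray] = []
    skipped: list[str] = []
    for model in model_list:
        idx = [row_of[e] for e in model.exons if e in row_of]
        if not idx:
            skipped.append(model.gene_id)
            continue
        sub = values[idx]
        score_rows.append(sub.max(axis=0) - sub.min(axis=0))
        gene_ids.append(model.gene_id)
    if skipped:
        logger.info(
            "score_all: excluded %d genes with no exon signal: %s",
            len(skipped),
            skipped[:20],
        )
    if not gene_ids:
        raise ValueError("no gene has exon signal; nothing to score")

    table = pd.DataFrame(
        np.vstack(score_rows), index=pd.Index(gene_ids, name="gene_id"),
        columns=exon_signals.columns,
    )
    table.insert(0, "mean_mmes", table.mean(axis=1))
    order = table.sort_values(
        ["mean_mmes", "gene_id"], ascending=[False, True], kind="mergesort"
    ).index
    rank = pd.Series(np.arange(1, len(order) + 1), index=order)
    table.insert(0, "rank", rank)
    return table.loc[order]


def select_top(table: pd.DataFrame, n: int = 900) -> list[str]:
    """The top ``n`` gene ids in rank order (all genes if fewer)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ordered = table.sort_values("rank").index
    return list(ordered[: min(n, len(ordered))])


def write_rank_list(table: pd.DataFrame, path: str | Path) -> None:
    """Write the rank list TSV: rank, gene_id, mean_mmes, one column per tumor."""
    out = table.sort_values("rank").reset_index()
    cols = ["rank", "gene_id", "mean_mmes"] + [
        c for c in out.columns if c not in ("rank", "gene_id", "mean_mmes")
    ]
    out[cols].to_csv(path, sep="\t", index=False)


def read_rank_list(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return df.set_index("gene_id")
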