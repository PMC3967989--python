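"""Log2 expression matrices and the first two scoring steps.

The input is a probeset-by-sample matrix of log2 intensities as
produced by a summarization method such as RMA, together with a
tumor/normal label per sample.  Step one expresses every probeset in
every tumor relative to the mean of the normal cohort for that probeset
(a log2 fold change, since subtraction on the log2 scale is a ratio on
the linear scale).  Step two averages those normal-relative values over
the probesets of each exon, yielding one exon-level value per exon per
tumor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mmes.annotation import GeneModel

logger = logging.getLogger(__name__)

GROUPS = ("tumor", "normal")


@dataclass
class ExpressionMatrix:
    """A finite log2 probeset-by-sample matrix with cohort labels.

    ``values`` has probesets as rows and samples as columns; ``groups``
    maps each sample id to ``"tumor"`` or ``"normal"``.  At least one
    sample of each group is required and all values must be finite.
    """

    values: pd.DataFrame
    groups: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = self.groups[self.groups.isna()].index.tolist()
            raise ValueError(f"samples without a group label: {missing}")
        bad = self.groups[~self.groups.isin(GROUPS)]
        if not bad.empty:
            raise ValueError(
                f"sample {bad.index[0]!r} has invalid group {bad.iloc[0]!r}"
            )
        if self.values.index.duplicated().any():
            raise ValueError("duplicate probeset ids in expression matrix")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids in expression matrix")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                "non-finite value at probeset "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )
        if not self.tumor_ids or not self.normal_ids:
            raise ValueError("need at least one tumor and one normal sample")

    @property
    def tumor_ids(self) -> list[str]:
        return list(self.groups[self.groups == "tumor"].index)

    @property
    def normal_ids(self) -> list[str]:
        return list(self.groups[self.groups == "normal"].index)

    @property
    def probeset_ids(self) -> list[str]:
        return list(self.values.index)


def read_matrix(
    path: str | Path, labels: str | Path | dict[str, str] | pd.Series
) -> ExpressionMatrix:
    """Read an expression TSV plus sample labels into an :class:`ExpressionMatrix`.

    The matrix TSV has ``probeset_id`` in the first column and one
    column per sample.  ``labels`` is either a mapping of sample id to
    group or the path to a two-column TSV (``sample_id``, ``group``).
    Missing or non-finite cells are a hard error naming the cell.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    non_numeric = df.columns[
        [not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]
    ]
    for col in non_numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = coerced.index[coerced.isna()][0]
            raise ValueError(
                f"{path}: non-numeric value at probeset {row!r}, sample {col!r}"
            )
        df[col] = coerced
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        row = df.index[df[col].isna()][0]
        raise ValueError(f"{path}: missing value at probeset {row!r}, sample {col!r}")
    if isinstance(labels, (str, Path)):
        lab = pd.read_csv(labels, sep="\t", dtype=str)
        groups = pd.Series(
            lab["group"].values, index=lab["sample_id"].astype(str), name="group"
        )
    else:
        groups = pd.Series(dict(labels), name="group")
    return ExpressionMatrix(values=df.astype(float), groups=groups)


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="probeset_id")


def write_labels(matrix: ExpressionMatrix, path: str | Path) -> None:
    lab = matrix.groups.rename_axis("sample_id").rename("group").reset_index()
    lab.to_csv(path, sep="\t", index=False)


def normalize_to_normal_mean(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Express each tumor's probeset signal relative to the normal-cohort mean.

    Returns the probeset-by-tumor matrix of log2 differences (tumor
    signal minus the arithmetic mean of the normal samples for the same
    probeset).  A tumor equal to the normal mean maps to exactly 0.
    """
    normals = matrix.normal_ids
    if not normals:
        raise ValueError("cannot normalize: no normal samples")
    normal_mean = matrix.values[normals].mean(axis=1)
    return matrix.values[matrix.tumor_ids].sub(normal_mean, axis=0)


def aggregate_exons(
    norm: pd.DataFrame, models: dict[str, GeneModel] | list[GeneModel]
) -> pd.DataFrame:
    """Average normal-relative probeset values within each exon, per tumor.

    ``norm`` is the probeset-by-tumor output of
    :func:`normalize_to_normal_mean`.  The result is an exon-by-tumor
    matrix, exons ordered gene by gene in 5'-to-3' order.  Each exon's
    value is the unweighted mean of its probesets, however many there
    are.  Probesets in ``norm`` not covered by any model are dropped
    with a logged count; an exon none of whose probesets are present is
    dropped with a warning.
    """
    if isinstance(models, dict):
        model_list = list(models.values())
    else:
        model_list = list(models)
    covered: set[str] = set()
    exon_rows: list[np.ndarray] = []
    exon_ids: list[str] = []
    values = norm.to_numpy()
    row_of = {p: i for i, p in enumerate(norm.index)}
    for model in model_list:
        for exon in model.exons:
            idx = [row_of[p] for p in model.probesets_by_exon[exon] if p in row_of]
            covered.update(
                p for p in model.probesets_by_exon[exon] if p in row_of
            )
            if not idx:
                logger.warning(
                    "aggregate_exons: exon %r of gene %r has no probesets in "
                    "the matrix; dropped",
                    exon,
                    model.gene_id,
                )
                continue
            exon_ids.append(exon)
            exon_rows.append(values[idx].mean(axis=0))
    n_uncovered = len(norm.index) - len(covered)
    if n_uncovered:
        logger.info(
            "aggregate_exons: %d probesets in the matrix are absent from the "
            "annotation and were ignored",
            n_uncovered,
        )
    if not exon_ids:
        return pd.DataFrame(
            np.empty((0, norm.shape[1])), index=[], columns=norm.columns
        )
    return pd.DataFrame(np.vstack(exon_rows), index=exon_ids, columns=norm.columns)
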