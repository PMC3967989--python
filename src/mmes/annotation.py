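"""Probeset-to-exon-to-gene annotation: loading, validation, gene models.

The annotation table maps each exon-array probeset to the exon and gene
it interrogates, with genomic coordinates (0-based, half-open, BED
convention) and an ``order_index`` giving the probeset's position along
the transcript from 5' to 3'.  Probesets target non-overlapping exonic
sequence, so a probeset belongs to exactly one exon and one gene; that
uniqueness is enforced at load time rather than resolved heuristically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = [
    "probeset_id",
    "gene_id",
    "exon_id",
    "chrom",
    "start",
    "end",
    "strand",
    "order_index",
]

_INT_COLUMNS = ("start", "end", "order_index")


class AnnotationError(ValueError):
    """Raised when an annotation table violates its contract."""


@dataclass(frozen=True)
class GeneModel:
    """A gene as an ordered list of exons, each carrying its probesets.

    ``exons`` runs 5' to 3' (genomic order on the '+' strand, reversed
    on the '-' strand); ``probesets_by_exon`` keeps each exon's
    probesets in transcript order.
    """

    gene_id: str
    exons: tuple[str, ...]
    probesets_by_exon: dict[str, tuple[str, ...]]

    @property
    def probesets(self) -> tuple[str, ...]:
        return tuple(p for e in self.exons for p in self.probesets_by_exon[e])

    @property
    def n_probesets(self) -> int:
        return sum(len(v) for v in self.probesets_by_exon.values())


def load_annotation(path: str | Path) -> pd.DataFrame:
    """Read and validate a probeset annotation TSV.

    The file has a header naming the seven annotation fields plus
    ``order_index``; ``#``-prefixed comment lines are ignored.  Returns
    a validated :class:`pandas.DataFrame` with one row per probeset.

    Raises
    ------
    AnnotationError
        On a duplicated probeset id, an exon mapped to two genes, or
        malformed coordinates (reported with the offending line number).
    """
    path = Path(path)
    rows: list[list[str]] = []
    line_numbers: list[int] = []
    header: list[str] | None = None
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                missing = [c for c in ANNOTATION_COLUMNS if c not in header]
                if missing:
                    raise AnnotationError(
                        f"{path}: header is missing required column(s) {missing}"
                    )
                continue
            if len(fields) != len(header):
                raise AnnotationError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            rows.append(fields)
            line_numbers.append(lineno)
    if header is None or not rows:
        raise AnnotationError(f"{path}: no annotation records found")

    df = pd.DataFrame(rows, columns=header)[ANNOTATION_COLUMNS].copy()
    for col in _INT_COLUMNS:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() | (converted != converted.round())
        if bad.any():
            i = int(bad.idxmax())
            raise AnnotationError(
                f"{path}:{line_numbers[i]}: malformed integer in column "
                f"'{col}': {df[col].iloc[i]!r}"
            )
        df[col] = converted.astype(int)
    df.index = pd.RangeIndex(len(df))
    validate_annotation(df, source=str(path))
    return df


def validate_annotation(df: pd.DataFrame, source: str = "annotation") -> None:
    """Check all annotation invariants; raise :class:`AnnotationError`."""
    dup = df["probeset_id"][df["probeset_id"].duplicated()]
    if not dup.empty:
        raise AnnotationError(
            f"{source}: duplicate probeset_id {dup.iloc[0]!r}"
        )
    genes_per_exon = df.groupby("exon_id")["gene_id"].nunique()
    multi = genes_per_exon[genes_per_exon > 1]
    if not multi.empty:
        raise AnnotationError(
            f"{source}: exon {multi.index[0]!r} is mapped to "
            f"{multi.iloc[0]} genes"
        )
    bad_coord = df[df["start"] >= df["end"]]
    if not bad_coord.empty:
        row = bad_coord.iloc[0]
        raise AnnotationError(
            f"{source}: probeset {row['probeset_id']!r} has start "
            f"{row['start']} >= end {row['end']}"
        )
    bad_strand = df[~df["strand"].isin(["+", "-"])]
    if not bad_strand.empty:
        row = bad_strand.iloc[0]
        raise AnnotationError(
            f"{source}: probeset {row['probeset_id']!r} has invalid strand "
            f"{row['strand']!r}"
        )
    if (df["order_index"] < 0).any():
        row = df[df["order_index"] < 0].iloc[0]
        raise AnnotationError(
            f"{source}: probeset {row['probeset_id']!r} has negative "
            f"order_index {row['order_index']}"
        )
    for gene_id, sub in df.groupby("gene_id"):
        if sub["order_index"].duplicated().any():
            raise AnnotationError(
                f"{source}: gene {gene_id!r} has duplicated order_index values"
            )


def write_annotation(df: pd.DataFrame, path: str | Path) -> None:
    """Write an annotation table in the TSV dialect read by :func:`load_annotation`."""
    df[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def filter_min_probesets(df: pd.DataFrame, min_probesets: int = 3) -> pd.DataFrame:
    """Keep genes with at least ``min_probesets`` probesets (whole-gene count).

    Genes with too few probesets cannot contrast exon subsets against
    the rest of the gene, so they are excluded from scoring.  Removed
    genes are logged with their probeset counts; an empty result is a
    warning, not an error.
    """
    if min_probesets < 1:
        raise ValueError("min_probesets must be >= 1")
    counts = df.groupby("gene_id")["probeset_id"].size()
    dropped = counts[counts < min_probesets]
    if not dropped.empty:
        logger.info(
            "filter_min_probesets: removed %d/%d genes below %d probesets: %s",
            len(dropped),
            len(counts),
            min_probesets,
            dict(dropped.head(20)),
        )
    kept = counts[counts >= min_probesets].index
    out = df[df["gene_id"].isin(kept)].copy()
    out.index = pd.RangeIndex(len(out))
    if out.empty:
        logger.warning(
            "filter_min_probesets: no gene has >= %d probesets", min_probesets
        )
    return out


def build_gene_models(df: pd.DataFrame) -> dict[str, GeneModel]:
    """Group a validated annotation into per-gene models, exons 5' to 3'.

    Exons are ordered by genomic start, reversed on the '-' strand so
    that the order follows transcription; probesets within an exon are
    ordered by ``order_index``.
    """
    models: dict[str, GeneModel] = {}
    for gene_id, sub in df.groupby("gene_id", sort=True):
        strand = sub["strand"].iloc[0]
        exon_starts = sub.groupby("exon_id")["start"].min()
        exon_order = exon_starts.sort_values(ascending=(strand == "+")).index
        probesets_by_exon = {
            exon: tuple(
                sub[sub["exon_id"] == exon].sort_values("order_index")["probeset_id"]
            )
            for exon in exon_order
        }
        models[str(gene_id)] = GeneModel(
            gene_id=str(gene_id),
            exons=tuple(exon_order),
            probesets_by_exon=probesets_by_exon,
        )
    return models
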