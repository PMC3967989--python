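"""Synthetic exon-array cohorts with known splice-switch ground truth.

The generator emulates the discovery design the scoring pipeline
assumes: a 44-tumor / 25-normal cohort of log2 probeset intensities.
Each probeset has its own baseline level (probesets differ in affinity),
per-measurement Gaussian noise is added on the log2 scale, a set of
confounder genes carries a whole-gene expression shift in tumors, and a
disjoint set of splice genes carries a shift confined to a contiguous
5' or 3' exon block — the shape of an alternative first/last-exon
switch — in a random subset of tumors.  The spiked genes, their exon
blocks, affected tumors and effect sizes are recorded as ground truth,
so ranking performance can be measured exactly.

A companion qPCR generator emulates the validation design (47 tumors /
19 normals): per-sample isoform copy numbers drawn log-normally around
group-specific short-isoform proportions, plus a ten-fold dilution
standard series per assay.

All streams derive from one seed through ``numpy.random.SeedSequence``
spawning, so each stage is independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mmes.annotation import ANNOTATION_COLUMNS, validate_annotation
from mmes.expression import ExpressionMatrix

_CHROMS = tuple(f"chr{i}" for i in range(1, 23))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the discovery design the pipeline targets: 44
    tumors and 25 normals, baseline log2 intensity around 6, Gaussian
    measurement noise of 0.25 log2 units, 50 splice-switch genes (a 1.5
    log2-unit shift on half of the gene's exons in half of the tumors)
    and 50 whole-gene differential-expression confounders of equal
    magnitude.  The qPCR block mirrors the validation design: 47 tumors
    and 19 normals with short-isoform proportions 0.8 (tumor) versus
    0.3 (normal).
    """

    n_genes: int = 1000
    exons_per_gene: tuple[int, int] = (4, 10)
    probesets_per_exon: tuple[int, int] = (1, 3)
    n_tumors: int = 44
    n_normals: int = 25
    baseline_mean: float = 6.0
    baseline_sd_between_probesets: float = 1.0
    noise_sd: float = 0.25
    n_splice_genes: int = 50
    splice_delta: float = 1.5
    splice_exon_fraction: float = 0.5
    splice_tumor_fraction: float = 0.5
    n_de_genes: int = 50
    de_delta: float = 1.5
    seed: int = 0
    # qPCR validation block
    qpcr_n_tumors: int = 47
    qpcr_n_normals: int = 19
    qpcr_n_genes: int = 3
    tumor_short_prop: float = 0.8
    normal_short_prop: float = 0.3
    qpcr_logit_sd: float = 0.5
    qpcr_total_log10_mean: float = 5.0
    qpcr_total_log10_sd: float = 0.5
    qpcr_reference_log10_mean: float = 7.0
    curve_slope: float = -3.3219280948873626
    curve_intercept: float = 40.0
    curve_ct_sd: float = 0.05

    def __post_init__(self) -> None:
        self.exons_per_gene = tuple(self.exons_per_gene)  # type: ignore[assignment]
        self.probesets_per_exon = tuple(self.probesets_per_exon)  # type: ignore[assignment]
        for name in ("n_genes", "n_tumors", "n_normals"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("n_splice_genes", "n_de_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_splice_genes + self.n_de_genes > self.n_genes:
            raise ValueError("spiked gene sets exceed n_genes")
        for name in ("splice_tumor_fraction", "splice_exon_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        lo, hi = self.exons_per_gene
        if lo < 1 or hi < lo:
            raise ValueError("exons_per_gene must be a valid positive range")
        lo, hi = self.probesets_per_exon
        if lo < 1 or hi < lo:
            raise ValueError("probesets_per_exon must be a valid positive range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


@dataclass(frozen=True)
class SpliceEvent:
    """One spiked splice switch: which exons, which tumors, how big."""

    gene_id: str
    exon_ids: tuple[str, ...]
    tumor_ids: tuple[str, ...]
    delta: float


@dataclass
class GroundTruth:
    """Record of every spiked effect in a simulated cohort."""

    splice_events: list[SpliceEvent] = field(default_factory=list)
    de_genes: list[str] = field(default_factory=list)

    @property
    def splice_genes(self) -> list[str]:
        return [e.gene_id for e in self.splice_events]

    def validate(self) -> None:
        if set(self.splice_genes) & set(self.de_genes):
            raise ValueError("splice and DE-only gene sets must be disjoint")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "splice_events": [asdict(e) for e in self.splice_events],
            "de_genes": list(self.de_genes),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        events = [
            SpliceEvent(
                gene_id=e["gene_id"],
                exon_ids=tuple(e["exon_ids"]),
                tumor_ids=tuple(e["tumor_ids"]),
                delta=float(e["delta"]),
            )
            for e in payload["splice_events"]
        ]
        truth = cls(splice_events=events, de_genes=list(payload["de_genes"]))
        truth.validate()
        return truth


def _spawn(seed: int, stream: int) -> np.random.Generator:
    # one root sequence, fixed child per stage, so stages regenerate independently
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stream + 1)[stream])


def simulate_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Generate a non-overlapping probeset annotation for ``n_genes`` genes.

    Genes are laid out on alternating strands across autosomes with
    non-overlapping coordinates; exon counts and probesets-per-exon are
    uniform over the configured ranges.  Deterministic given the seed.
    """
    rng = _spawn(config.seed, 0)
    cursors = {c: 1000 for c in _CHROMS}
    records: list[tuple] = []
    width = len(str(config.n_genes))
    for g in range(config.n_genes):
        gene_id = f"G{g + 1:0{width}d}"
        chrom = _CHROMS[int(rng.integers(len(_CHROMS)))]
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        pos = cursors[chrom]
        # exon genomic intervals, ascending
        exon_spans: list[tuple[int, int, int]] = []  # (start, end, n_probesets)
        for e in range(n_exons):
            n_ps = int(
                rng.integers(config.probesets_per_exon[0], config.probesets_per_exon[1] + 1)
            )
            length = 50 * n_ps
            exon_spans.append((pos, pos + length, n_ps))
            pos += length + int(rng.integers(200, 2000))  # intron gap
        cursors[chrom] = pos + 5000
        # 5'->3' exon order: genomic ascending on '+', descending on '-'
        exon_numbers = range(1, n_exons + 1)
        genomic = list(zip(exon_numbers, exon_spans))
        transcript_order = genomic if strand == "+" else list(reversed(genomic))
        order_index = 0
        for exon_num, (start, end, n_ps) in transcript_order:
            exon_id = f"{gene_id}.E{exon_num:02d}"
            # probesets tile the exon; on '-' the most 5' probeset is the
            # genomically last sub-interval
            sub_starts = [start + 50 * k for k in range(n_ps)]
            if strand == "-":
                sub_starts = sub_starts[::-1]
            for k, ps_start in enumerate(sub_starts):
                records.append(
                    (
                        f"{exon_id}.P{k + 1}",
                        gene_id,
                        exon_id,
                        chrom,
                        ps_start,
                        ps_start + 50,
                        strand,
                        order_index,
                    )
                )
                order_index += 1
    df = pd.DataFrame(records, columns=ANNOTATION_COLUMNS)
    validate_annotation(df, source="simulated annotation")
    return df


def simulate_expression(
    config: SimulationConfig, annotation: pd.DataFrame
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate the log2 cohort matrix and its ground truth.

    Each value is ``probeset baseline + N(0, noise_sd)``, plus
    ``de_delta`` for all probesets of a confounder gene in tumor
    samples, plus ``splice_delta`` for probesets in the affected exon
    block of a splice gene in that gene's affected tumors.
    """
    rng = _spawn(config.seed, 1)
    probesets = list(annotation["probeset_id"])
    n_ps = len(probesets)
    tumor_ids = [f"T{t + 1:03d}" for t in range(config.n_tumors)]
    normal_ids = [f"N{n + 1:03d}" for n in range(config.n_normals)]
    samples = tumor_ids + normal_ids
    baseline = config.baseline_mean + rng.normal(
        0.0, config.baseline_sd_between_probesets, size=n_ps
    )
    # snap baselines to a dyadic grid (2^-16 log2 units, far below noise):
    # noise-free cohorts then propagate bit-exactly through normalization
    # and exon averaging, so spiked effects can be verified exactly
    baseline = np.round(baseline * 65536.0) / 65536.0
    values = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, size=(n_ps, len(samples))
    )
    df = pd.DataFrame(values, index=probesets, columns=samples)

    gene_ids = list(pd.unique(annotation["gene_id"]))
    n_spiked = config.n_splice_genes + config.n_de_genes
    spiked = rng.choice(len(gene_ids), size=n_spiked, replace=False)
    splice_genes = [gene_ids[i] for i in spiked[: config.n_splice_genes]]
    de_genes = [gene_ids[i] for i in spiked[config.n_splice_genes:]]

    row_of = {p: i for i, p in enumerate(probesets)}
    tumor_cols = np.arange(config.n_tumors)
    arr = df.to_numpy()

    for gene in de_genes:
        ps = annotation.loc[annotation["gene_id"] == gene, "probeset_id"]
        rows = [row_of[p] for p in ps]
        arr[np.ix_(rows, tumor_cols)] += config.de_delta

    events: list[SpliceEvent] = []
    for gene in splice_genes:
        sub = annotation[annotation["gene_id"] == gene].sort_values("order_index")
        # exon ids in 5'->3' order
        exon_order = list(pd.unique(sub["exon_id"]))
        n_exons = len(exon_order)
        block = max(1, round(config.splice_exon_fraction * n_exons))
        block = min(block, n_exons - 1) if n_exons > 1 else 1
        from_five_prime = rng.random() < 0.5
        affected_exons = exon_order[:block] if from_five_prime else exon_order[-block:]
        hit = rng.random(config.n_tumors) < config.splice_tumor_fraction
        if not hit.any():
            hit[int(rng.integers(config.n_tumors))] = True
        affected_tumors = [tumor_ids[t] for t in np.flatnonzero(hit)]
        rows = [
            row_of[p]
            for p in sub.loc[sub["exon_id"].isin(affected_exons), "probeset_id"]
        ]
        cols = np.flatnonzero(hit)
        arr[np.ix_(rows, cols)] += config.splice_delta
        events.append(
            SpliceEvent(
                gene_id=str(gene),
                exon_ids=tuple(affected_exons),
                tumor_ids=tuple(affected_tumors),
                delta=float(config.splice_delta),
            )
        )

    df = pd.DataFrame(arr, index=probesets, columns=samples)
    groups = pd.Series(
        ["tumor"] * config.n_tumors + ["normal"] * config.n_normals,
        index=samples,
        name="group",
    )
    truth = GroundTruth(splice_events=events, de_genes=[str(g) for g in de_genes])
    truth.validate()
    return ExpressionMatrix(values=df, groups=groups), truth


def simulate_qpcr(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Generate isoform qPCR copy-number tables and dilution standards.

    Assays are generated for the first ``qpcr_n_genes`` splice genes of
    the ground truth (synthetic assay names are used if the truth holds
    none).  Per sample, total gene copies are log-normal; the short
    fraction is the group proportion jittered on the logit scale; the
    18S reference is a log-normal per-sample scalar.  Each assay also
    gets a six-point ten-fold dilution series with Ct values from the
    configured curve plus small Gaussian jitter.
    """
    rng = _spawn(config.seed, 2)
    genes = truth.splice_genes[: config.qpcr_n_genes]
    if not genes:
        genes = [f"ASSAY{i + 1}" for i in range(config.qpcr_n_genes)]
    sample_ids = [f"VT{t + 1:03d}" for t in range(config.qpcr_n_tumors)] + [
        f"VN{n + 1:03d}" for n in range(config.qpcr_n_normals)
    ]
    groups = ["tumor"] * config.qpcr_n_tumors + ["normal"] * config.qpcr_n_normals
    rows = []
    for gene in genes:
        for sample_id, group in zip(sample_ids, groups):
            total = 10.0 ** rng.normal(
                config.qpcr_total_log10_mean, config.qpcr_total_log10_sd
            )
            p0 = (
                config.tumor_short_prop
                if group == "tumor"
                else config.normal_short_prop
            )
            logit = np.log(p0 / (1.0 - p0)) + rng.normal(0.0, config.qpcr_logit_sd)
            p = 1.0 / (1.0 + np.exp(-logit))
            reference = 10.0 ** rng.normal(config.qpcr_reference_log10_mean, 0.3)
            rows.append(
                {
                    "sample_id": sample_id,
                    "group": group,
                    "gene": gene,
                    "short_copies": total * p,
                    "long_copies": total * (1.0 - p),
                    "reference_copies": reference,
                }
            )
    table = pd.DataFrame(rows)

    standards: dict[str, pd.DataFrame] = {}
    dilution_copies = 10.0 ** np.arange(7, 1, -1)  # 1e7 .. 1e2, ten-fold steps
    for gene in genes:
        ct = (
            config.curve_intercept
            + config.curve_slope * np.log10(dilution_copies)
            + rng.normal(0.0, config.curve_ct_sd, size=dilution_copies.size)
        )
        standards[gene] = pd.DataFrame({"copies": dilution_copies, "ct": ct})
    return table, standards


def enrichment_auc(rank_list: list[str], positives: set[str] | list[str]) -> float:
    """Probability a positive gene outranks a non-positive one (rank AUC).

    1.0 means every positive gene precedes every other gene in the
    list; 0.5 is chance.  Every positive must appear in the list.
    """
    positives = set(positives)
    missing = positives - set(rank_list)
    if missing:
        raise ValueError(f"positive genes absent from rank list: {sorted(missing)[:5]}")
    n = len(rank_list)
    n_pos = len(positives)
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both positive and non-positive genes for an AUC")
    # rank 1 = best; U counts (positive, negative) pairs ordered correctly
    rank_sum = sum(i + 1 for i, g in enumerate(rank_list) if g in positives)
    u = n_pos * n_neg + n_pos * (n_pos + 1) / 2 - rank_sum
    return float(u / (n_pos * n_neg))


def recovery_metrics(
    rank_list: list[str], truth: GroundTruth, k: int
) -> dict[str, float]:
    """Recall@k and enrichment AUC of the spiked splice genes.

    ``rank_list`` is the gene ids in rank order (best first) and must
    contain every spiked gene.
    """
    splice = set(truth.splice_genes)
    missing = splice - set(rank_list)
    if missing:
        raise ValueError(f"truth genes absent from rank list: {sorted(missing)[:5]}")
    if not splice:
        raise ValueError("ground truth has no splice genes")
    top = set(rank_list[:k])
    recall = len(splice & top) / len(splice)
    return {
        "recall_at_k": float(recall),
        "auc": enrichment_auc(rank_list, splice),
    }
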