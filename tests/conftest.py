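import numpy as np
import pandas as pd
import pytest

from mmes import (
    SimulationConfig,
    build_gene_models,
    filter_min_probesets,
    simulate_annotation,
    simulate_expression,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_genes=40,
        exons_per_gene=(3, 6),
        probesets_per_exon=(1, 3),
        n_tumors=8,
        n_normals=6,
        noise_sd=0.25,
        n_splice_genes=4,
        splice_delta=1.5,
        n_de_genes=4,
        de_delta=1.5,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    annotation = simulate_annotation(small_config)
    matrix, truth = simulate_expression(small_config, annotation)
    return annotation, matrix, truth


@pytest.fixture(scope="session")
def small_models(small_dataset):
    annotation, _, _ = small_dataset
    return build_gene_models(filter_min_probesets(annotation))


def make_annotation(rows) -> pd.DataFrame:
    """Build an annotation frame from (probeset, gene, exon, chrom, start, end, strand, order) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "probeset_id",
            "gene_id",
            "exon_id",
            "chrom",
            "start",
            "end",
            "strand",
            "order_index",
        ],
    )


def naive_mmes_table(matrix, annotation, min_probesets=3):
    """Independent reference: the whole scoring chain as explicit loops.

    Every quantity (normal means, normal-relative values, exon means,
    max-min spread, mean over tumors) is recomputed with plain Python
    arithmetic, independent of the package's vectorized path.
    """
    normals = [s for s in matrix.values.columns if matrix.groups[s] == "normal"]
    tumors = [s for s in matrix.values.columns if matrix.groups[s] == "tumor"]
    counts = annotation.groupby("gene_id")["probeset_id"].size()
    genes = sorted(g for g in counts.index if counts[g] >= min_probesets)
    out = {}
    for gene in genes:
        sub = annotation[annotation["gene_id"] == gene]
        exon_probesets = {
            e: list(sub[sub["exon_id"] == e]["probeset_id"])
            for e in sub["exon_id"].unique()
        }
        scores = {}
        for t in tumors:
            exon_vals = []
            for probesets in exon_probesets.values():
                vals = []
                for p in probesets:
                    nmean = sum(matrix.values.at[p, s] for s in normals) / len(normals)
                    vals.append(matrix.values.at[p, t] - nmean)
                exon_vals.append(sum(vals) / len(vals))
            scores[t] = max(exon_vals) - min(exon_vals)
        out[gene] = {"scores": scores, "mean": sum(scores.values()) / len(scores)}
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
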