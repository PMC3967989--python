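# mmes

Exon-level screening for tumor-specific alternative splicing from exon-array
cohorts, built around the **Maximum-Minimum Exon Score (MMES)**, with the
downstream qPCR splicing-index validation statistics and a synthetic-cohort
generator with known ground truth.

## The problem

Exon expression arrays (e.g. the Affymetrix Human Exon 1.0 ST) measure one
log2 signal per *probeset*, where each probeset interrogates part of one
exon. Comparing tumors to normal tissue at this resolution can reveal
*isoform switches* — genes in which tumors preferentially express a splice
variant that includes or excludes a block of exons (ΔNp63 vs TAp63,
LAMA3A vs LAMA3B, DST 1e vs the long isoforms are classic examples in
squamous carcinoma). The difficulty is separating a genuine change in exon
*usage* from ordinary whole-gene differential expression and from probeset
noise.

## The score

Given RMA-style log2 intensities \(P_{is}\) for probeset \(i\) in sample
\(s\), a tumor cohort \(T\) and a normal cohort \(N\):

1. **Normalize to the normal cohort.** For each tumor \(t\):
   \(P_{it}^{N} = P_{it} - \overline{P_{iN}}\), the log2 difference from the
   mean normal signal of the same probeset.
2. **Aggregate to exons.** For exon \(e\) with probesets \(I_e\):
   \(\mathrm{Exon}_{et} = \frac{1}{|I_e|}\sum_{i \in I_e} P_{it}^{N}\).
3. **Score.** For gene \(g\) with exons \(E_g\):
   \(\mathrm{MMES}_{gt} = \max_{e \in E_g}\mathrm{Exon}_{et} -
   \min_{e \in E_g}\mathrm{Exon}_{et}\), one non-negative score per gene per
   tumor, and the gene's summary score is the mean over tumors.
4. **Rank and screen.** Genes with ≥ 3 probesets are ranked by mean score
   (default: the top 900 go to graphical review); the package renders the
   cohort and per-tumor screening plots with exon tracks and ±1-SD
   deviation histograms.

Because the max-min spread is computed *within* a gene after normal-cohort
centering, a uniform shift of all of a gene's exons — whole-gene
differential expression or an array-wide effect — contributes nothing:
only exon subsets that move differently from the rest of the gene score.

Predicted switches are validated by isoform-specific qPCR: absolute copy
numbers from ten-fold serial-dilution standard curves
(slope ≈ −3.32 Ct per decade at 100 % efficiency), a per-sample
**splicing index** \(\mathrm{SI} = \text{short} / (\text{short} +
\text{long})\), and a two-sided Welch *t* test between cohorts.

## Worked example

```python
from mmes import *

config = SimulationConfig(n_genes=200, n_splice_genes=10, n_de_genes=10, seed=42)
annotation = simulate_annotation(config)
matrix, truth = simulate_expression(config, annotation)

models = build_gene_models(filter_min_probesets(annotation, 3))
norm = normalize_to_normal_mean(matrix)
exon_signals = aggregate_exons(norm, models)
table = score_all(exon_signals, models)

print(table[["rank", "mean_mmes"]].head(5))
rank_list = select_top(table, len(table))
print("recall@20:", recovery_metrics(rank_list, truth, k=20)["recall_at_k"])
print("DE-confounder AUC:", round(enrichment_auc(rank_list, truth.de_genes), 3))

quant, standards = simulate_qpcr(config, truth)
gene = truth.splice_genes[0]
curve = fit_standard_curve(standards[gene]["copies"], standards[gene]["ct"])
print(f"standard curve: slope={curve.slope:.4f}, efficiency={curve.efficiency:.3f}")
res = compare_groups(quant, gene=gene)
print(f"{gene}: index {res.tumor_mean:.3f} (tumor) vs {res.normal_mean:.3f} (normal), "
      f"t={res.t_statistic:.2f}, df={res.degrees_of_freedom:.1f}, p={res.p_value:.3g}")
```

prints

```
         rank  mean_mmes
gene_id
G110        1   1.478295
G157        2   1.472963
G176        3   1.369381
G082        4   1.354587
G193        5   1.336192
recall@20: 1.0
DE-confounder AUC: 0.473
standard curve: slope=-3.3116, efficiency=1.004
G082: index 0.797 (tumor) vs 0.293 (normal), t=16.73, df=25.7, p=2.52e-15
```

All ten spiked splice genes land in the top 20 of 200 (`recall@20 = 1.0`),
while the ten whole-gene differential-expression confounders rank no better
than chance (AUC ≈ 0.5). The simulated validation assay recovers the spiked
switch: tumors carry ~80 % short isoform versus ~30 % in normals, and the
Welch test is decisive.

The same workflow is available from the shell:

```bash
mmes simulate --out-dir data --seed 42
mmes score    --annotation data/annotation.tsv --matrix data/expression.tsv \
              --labels data/labels.tsv --out ranks.tsv
mmes plot     --annotation data/annotation.tsv --matrix data/expression.tsv \
              --labels data/labels.tsv --top-n 10 --out-dir plots
mmes validate --quant data/quant.tsv --out results.tsv
```

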