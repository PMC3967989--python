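import numpy as np
import pandas as pd
import pytest

from mmes import (
    GroundTruth,
    SimulationConfig,
    SpliceEvent,
    aggregate_exons,
    build_gene_models,
    compare_groups,
    enrichment_auc,
    filter_min_probesets,
    normalize_to_normal_mean,
    recovery_metrics,
    score_all,
    simulate_annotation,
    simulate_expression,
    simulate_qpcr,
)


def score_genes(annotation, matrix):
    models = build_gene_models(filter_min_probesets(annotation))
    ex = aggregate_exons(normalize_to_normal_mean(matrix), models)
    return score_all(ex, models)


class TestConfig:
    def test_rejects_bad_ranges(self):
        with pytest.raises(ValueError):
            SimulationConfig(exons_per_gene=(5, 3))
        with pytest.raises(ValueError):
            SimulationConfig(splice_tumor_fraction=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=10, n_splice_genes=8, n_de_genes=8)

    def test_from_dict_rejects_unknown_fields(self):
        with pytest.raises(ValueError, match="unknown"):
            SimulationConfig.from_dict({"n_genes": 5, "bogus": 1})

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "c.yaml"
        path.write_text("n_genes: 12\nn_splice_genes: 2\nn_de_genes: 1\nseed: 9\n")
        config = SimulationConfig.from_yaml(path)
        assert config.n_genes == 12
        assert config.seed == 9


class TestSimulateAnnotation:
    def test_deterministic_given_seed(self):
        config = SimulationConfig(n_genes=25, seed=4, n_splice_genes=0, n_de_genes=0)
        a1 = simulate_annotation(config)
        a2 = simulate_annotation(config)
        pd.testing.assert_frame_equal(a1, a2)

    def test_counts_within_configured_ranges(self):
        config = SimulationConfig(
            n_genes=10, exons_per_gene=(3, 5), probesets_per_exon=(1, 2),
            n_splice_genes=0, n_de_genes=0, seed=2,
        )
        df = simulate_annotation(config)
        per_gene = df.groupby("gene_id")["probeset_id"].size()
        assert per_gene.between(3, 10).all()
        exons = df.groupby("gene_id")["exon_id"].nunique()
        assert exons.between(3, 5).all()

    def test_all_genes_pass_filter_by_construction(self):
        config = SimulationConfig(
            n_genes=15, exons_per_gene=(3, 4), probesets_per_exon=(1, 2),
            n_splice_genes=0, n_de_genes=0, seed=2,
        )
        df = simulate_annotation(config)
        assert filter_min_probesets(df, 3)["gene_id"].nunique() == 15

    def test_coordinates_do_not_overlap(self):
        config = SimulationConfig(n_genes=60, n_splice_genes=0, n_de_genes=0, seed=8)
        df = simulate_annotation(config)
        for _, sub in df.groupby("chrom"):
            s = sub.sort_values("start")
            assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()


class TestSimulateExpression:
    def test_deterministic_given_seed(self, small_config):
        annotation = simulate_annotation(small_config)
        m1, t1 = simulate_expression(small_config, annotation)
        m2, t2 = simulate_expression(small_config, annotation)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        assert t1.splice_events == t2.splice_events
        assert t1.de_genes == t2.de_genes

    def test_truth_sets_disjoint_and_tumors_in_cohort(self, small_dataset):
        _, matrix, truth = small_dataset
        truth.validate()
        tumor_set = set(matrix.tumor_ids)
        for event in truth.splice_events:
            assert set(event.tumor_ids) <= tumor_set
            assert len(event.tumor_ids) >= 1

    def test_noise_free_null_chain_scores_zero(self):
        config = SimulationConfig(
            n_genes=12, n_tumors=5, n_normals=4, noise_sd=0.0,
            n_splice_genes=0, n_de_genes=0, seed=1,
        )
        annotation = simulate_annotation(config)
        matrix, _ = simulate_expression(config, annotation)
        table = score_genes(annotation, matrix)
        assert (table[matrix.tumor_ids].to_numpy() == 0.0).all()

    def test_noise_free_effect_propagates_exactly(self):
        config = SimulationConfig(
            n_genes=12, n_tumors=6, n_normals=5, noise_sd=0.0,
            n_splice_genes=1, splice_delta=2.0, splice_exon_fraction=0.5,
            splice_tumor_fraction=1.0, n_de_genes=2, de_delta=4.0, seed=3,
        )
        annotation = simulate_annotation(config)
        matrix, truth = simulate_expression(config, annotation)
        table = score_genes(annotation, matrix)
        spiked = truth.splice_genes[0]
        assert (table.loc[spiked, matrix.tumor_ids].to_numpy() == 2.0).all()
        others = table.drop(index=spiked)[matrix.tumor_ids].to_numpy()
        assert (others == 0.0).all()

    def test_affected_block_is_contiguous_and_terminal(self, small_dataset, small_models):
        annotation, _, truth = small_dataset
        for event in truth.splice_events:
            model = small_models[event.gene_id]
            exon_list = list(model.exons)
            block = [exon_list.index(e) for e in event.exon_ids]
            assert block == list(range(min(block), max(block) + 1))
            assert min(block) == 0 or max(block) == len(exon_list) - 1
            assert len(block) < len(exon_list)

    def test_ground_truth_json_round_trip(self, tmp_path, small_dataset):
        _, _, truth = small_dataset
        truth.to_json(tmp_path / "truth.json")
        back = GroundTruth.from_json(tmp_path / "truth.json")
        assert back.splice_events == truth.splice_events
        assert back.de_genes == truth.de_genes


class TestSimulateQpcr:
    def test_deterministic_given_seed(self, small_config, small_dataset):
        _, _, truth = small_dataset
        q1, s1 = simulate_qpcr(small_config, truth)
        q2, s2 = simulate_qpcr(small_config, truth)
        pd.testing.assert_frame_equal(q1, q2)
        for gene in s1:
            pd.testing.assert_frame_equal(s1[gene], s2[gene])

    def test_cohort_geometry_and_standards(self, small_config, small_dataset):
        _, _, truth = small_dataset
        quant, standards = simulate_qpcr(small_config, truth)
        one = quant[quant["gene"] == quant["gene"].iloc[0]]
        assert (one["group"] == "tumor").sum() == small_config.qpcr_n_tumors
        assert (one["group"] == "normal").sum() == small_config.qpcr_n_normals
        for series in standards.values():
            ratios = series["copies"].to_numpy()[:-1] / series["copies"].to_numpy()[1:]
            assert np.allclose(ratios, 10.0)

    def test_strong_switch_is_detected_in_most_seeds(self, small_dataset):
        _, _, truth = small_dataset
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            config = SimulationConfig(
                seed=seed, qpcr_n_genes=1,
                tumor_short_prop=0.8, normal_short_prop=0.3, qpcr_logit_sd=0.5,
            )
            quant, _ = simulate_qpcr(config, truth)
            res = compare_groups(quant, gene=quant["gene"].iloc[0])
            hits += res.p_value < 0.001
        assert hits >= 0.95 * n_seeds

    def test_equal_proportions_give_unremarkable_p(self, small_dataset):
        _, _, truth = small_dataset
        pvals = []
        for seed in range(40):
            config = SimulationConfig(
                seed=seed, qpcr_n_genes=1,
                tumor_short_prop=0.5, normal_short_prop=0.5,
            )
            quant, _ = simulate_qpcr(config, truth)
            pvals.append(compare_groups(quant, gene=quant["gene"].iloc[0]).p_value)
        # null p-values should not pile up near zero
        assert np.mean(np.array(pvals) < 0.05) < 0.2


class TestRecoveryMetrics:
    truth = GroundTruth(
        splice_events=[
            SpliceEvent("g1", ("e1",), ("t1",), 1.5),
            SpliceEvent("g4", ("e1",), ("t1",), 1.5),
        ],
        de_genes=["g6"],
    )

    def test_perfect_recovery(self):
        ranks = ["g1", "g4", "g2", "g3", "g5", "g6"]
        metrics = recovery_metrics(ranks, self.truth, k=2)
        assert metrics == {"recall_at_k": 1.0, "auc": 1.0}

    def test_hand_counted_partial_recovery(self):
        # spikes at ranks 1 and 4 of 6; top-3 holds one of two -> recall 0.5
        ranks = ["g1", "g2", "g3", "g4", "g5", "g6"]
        metrics = recovery_metrics(ranks, self.truth, k=3)
        assert metrics["recall_at_k"] == 0.5
        # positives occupy ranks 1 and 4: U = 2*4 + 3 - 5 = 6 -> AUC 0.75
        assert metrics["auc"] == 0.75

    def test_random_ranking_auc_near_half(self, rng):
        genes = [f"g{i}" for i in range(200)]
        positives = set(genes[:20])
        aucs = []
        for _ in range(50):
            order = list(rng.permutation(genes))
            aucs.append(enrichment_auc(order, positives))
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_missing_truth_gene_is_hard_error(self):
        with pytest.raises(ValueError, match="absent"):
            recovery_metrics(["g1", "g2"], self.truth, k=1)
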