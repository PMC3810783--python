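"""Generator determinism, planted-truth fidelity and distributional
calibration of the synthetic-data module."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lop import motif, setcompare, synth


class TestSurvivalCohort:
    def test_no_censoring_means_all_events(self):
        spec = synth.CohortSpec(groups=(synth.GroupSpec("A", 50, 0.005, 1e-4, 0.0),),
                                seed=1)
        table = synth.gen_survival_cohort(spec)
        assert (table["event"] == 1).all()

    def test_censoring_fraction_and_flags(self):
        spec = synth.CohortSpec(groups=(synth.GroupSpec("A", 100, 0.005, 1e-4, 0.25),),
                                seed=1)
        table = synth.gen_survival_cohort(spec)
        assert (table["event"] == 0).sum() == 25

    def test_seed_determinism(self):
        spec = synth.CohortSpec(groups=(synth.GroupSpec("A", 40, 0.005, 1e-4, 0.1),),
                                seed=9)
        t1 = synth.gen_survival_cohort(spec)
        t2 = synth.gen_survival_cohort(spec)
        pd.testing.assert_frame_equal(t1, t2)

    def test_identical_specs_are_exchangeable(self):
        """Two groups with identical Gompertz parameters pass a two-sample
        rank test at alpha=0.01 in ~99% of replicates (>=97 of these 100
        fixed-seed draws)."""
        passes = 0
        for rep in range(100):
            spec = synth.CohortSpec(
                groups=(synth.GroupSpec("A", 40, 0.008, 1e-4),
                        synth.GroupSpec("B", 40, 0.008, 1e-4)),
                seed=20_000 + rep)
            table = synth.gen_survival_cohort(spec)
            a = table.loc[table["group"] == "A", "time"]
            b = table.loc[table["group"] == "B", "time"]
            if stats.mannwhitneyu(a, b).pvalue > 0.01:
                passes += 1
        assert passes >= 97

    def test_shape_zero_is_exponential(self):
        rate = 1.0 / 300.0
        spec = synth.CohortSpec(groups=(synth.GroupSpec("A", 5000, 0.0, rate),), seed=2)
        times = synth.gen_survival_cohort(spec)["time"]
        assert stats.kstest(times, "expon", args=(0, 1 / rate)).pvalue > 0.01

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            synth.GroupSpec("A", 10, 0.005, 0.0)
        with pytest.raises(ValueError, match="censor"):
            synth.GroupSpec("A", 10, 0.005, 1e-4, 1.5)
        with pytest.raises(ValueError, match="n_animals"):
            synth.GroupSpec("A", 0, 0.005, 1e-4)


class TestExpressionStudy:
    def test_null_spec_has_empty_truth_and_balanced_means(self):
        spec = synth.ExpressionSpec(n_genes=500, effect_log2fc=0.0, planted_up=50,
                                    residual_sd=0.2, seed=3)
        study, truth = synth.gen_expression_study(spec)
        assert (truth["log2fc"] == 0).all()
        ko = study.matrix[study.samples_in("KO")].to_numpy().mean()
        wt = study.matrix[study.samples_in("WT")].to_numpy().mean()
        se = 0.2 / np.sqrt(study.matrix.size / 2)
        assert abs(ko - wt) < 3 * se

    def test_determinism(self):
        spec = synth.ExpressionSpec(n_genes=300, planted_up=10, planted_down=5,
                                    n_sibling_probes=30, n_unexpressed_probes=20, seed=1)
        s1, t1 = synth.gen_expression_study(spec)
        s2, t2 = synth.gen_expression_study(spec)
        pd.testing.assert_frame_equal(s1.matrix, s2.matrix)
        pd.testing.assert_frame_equal(t1, t2)

    def test_sibling_probes_share_genes(self):
        spec = synth.ExpressionSpec(n_genes=100, n_sibling_probes=40, seed=2)
        study, _ = synth.gen_expression_study(spec)
        genes = pd.Series(study.probe_to_gene)
        assert len(study.matrix) == 140
        assert genes.nunique() == 100
        assert (genes.value_counts() >= 1).all()

    def test_overplanting_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            synth.ExpressionSpec(n_genes=10, planted_up=6, planted_down=6)

    def test_planted_recovery_through_de(self, de_pipeline):
        """Strong planted effects are recovered by the moderated-t pipeline."""
        spec = synth.ExpressionSpec(n_genes=2000, planted_up=50, effect_log2fc=2.0,
                                    residual_sd=0.25, seed=7)
        study, truth = synth.gen_expression_study(spec)
        classified, _ = de_pipeline(study)
        hits = classified.loc[truth["gene"], "q"] < 0.05
        assert hits.mean() >= 0.9


class TestPromoters:
    def _consensus_pwm(self):
        pfm = np.zeros((4, 6))
        for j, b in enumerate("ACGTAC"):
            pfm["ACGT".index(b), j] = 10
        return motif.build_pwm("cons", pfm, pseudocount=0.0)

    def test_fully_masked_background_has_no_eligible_windows(self):
        pwm = self._consensus_pwm()
        spec = synth.PromoterSpec(n_genes=5, region_length=200, masked_fraction=1.0,
                                  n_target=0, seed=1)
        seqs, _ = synth.gen_promoter_set(spec, pwm)
        for seq in seqs.values():
            assert motif.scan_region(seq, pwm).scanned_length == 0

    def test_planted_consensus_always_found(self):
        pwm = self._consensus_pwm()
        spec = synth.PromoterSpec(n_genes=20, region_length=300, masked_fraction=0.2,
                                  n_target=10, instances_per_gene=1, seed=4)
        seqs, truth = synth.gen_promoter_set(spec, pwm)
        for gene, is_target in zip(truth["gene"], truth["is_target"]):
            count = motif.scan_region(seqs[gene], pwm).count
            if is_target:
                assert count >= 1

    def test_count_accounting_matches_planted_instances(self):
        """Mean target count exceeds background count by about the number of
        planted instances (forward strand, so a partially self-reverse-
        complementary consensus cannot double count)."""
        pfm = np.ones((4, 6))
        for j, b in enumerate("ACGTAC"):
            pfm["ACGT".index(b), j] = 50
        pwm = motif.build_pwm("sharp", pfm, pseudocount=0.0)
        spec = synth.PromoterSpec(n_genes=300, region_length=500, masked_fraction=0.0,
                                  n_target=200, instances_per_gene=3, seed=8)
        seqs, truth = synth.gen_promoter_set(spec, pwm)
        counts = {g: motif.scan_region(s, pwm, strands="forward").count
                  for g, s in seqs.items()}
        tgt = truth[truth["is_target"]]["gene"]
        bg = truth[~truth["is_target"]]["gene"]
        diff = np.mean([counts[g] for g in tgt]) - np.mean([counts[g] for g in bg])
        assert diff == pytest.approx(3.0, abs=0.4)

    def test_masked_region_too_small_raises(self):
        pwm = self._consensus_pwm()
        spec = synth.PromoterSpec(n_genes=2, region_length=50, masked_fraction=0.99,
                                  n_target=2, instances_per_gene=5, mask_block=10, seed=1)
        with pytest.raises(ValueError, match="could not place"):
            synth.gen_promoter_set(spec, pwm)


class TestOntologyAndRankedLists:
    def test_dag_determinism_and_acyclicity(self):
        import networkx as nx
        e1, a1, _ = synth.gen_toy_ontology(20, 50, seed=6)
        e2, a2, _ = synth.gen_toy_ontology(20, 50, seed=6)
        assert e1 == e2 and a1 == a2
        g = nx.DiGraph(e1)
        assert nx.is_directed_acyclic_graph(g)
        # every non-root term reaches the root
        for term in g.nodes:
            assert term == "T000" or nx.has_path(g, term, "T000")

    def test_concordance_zero_gives_uniform_enrichment_p(self):
        """Null ranked experiments yield uniform rank-enrichment p-values."""
        genes = {f"s{i}" for i in range(50)}
        gs = setcompare.GeneSet("set", genes, direction=-1)
        pvals = []
        for rep in range(200):
            df = synth.gen_ranked_experiment(0.0, genes, -1, n_genes=400,
                                             seed=30_000 + rep)
            pvals.append(setcompare.rank_enrichment(gs, setcompare.make_ranked_list(df)).p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_concordance_bounds_validated(self):
        with pytest.raises(ValueError, match="concordance"):
            synth.gen_ranked_experiment(1.5, {"a"}, 1)

    def test_qpcr_plate_determinism(self):
        spec = synth.QpcrSpec(genes=("X", "Y"), fold_changes={"X": 4.0}, seed=12)
        pd.testing.assert_frame_equal(synth.gen_qpcr_plate(spec),
                                      synth.gen_qpcr_plate(spec))
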