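"""Detection filtering, empirical-Bayes moderated t, BH adjustment,
sibling-probe collapse and fold-change classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from lop import diffexpr, synth
from lop.diffexpr import ExpressionStudy


def tiny_study(values, genes=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[1] // 2
    probes = [f"p{i}" for i in range(len(values))]
    samples = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
    design = {s: ("A" if s.startswith("a") else "B") for s in samples}
    p2g = dict(zip(probes, genes or probes))
    return ExpressionStudy(pd.DataFrame(values, index=probes, columns=samples),
                           p2g, design)


class TestDetectionFilter:
    def test_minus_inf_floor_retains_everything(self, null_study):
        assert len(diffexpr.detection_filter(null_study, floor=-np.inf)) == \
            len(null_study.matrix)

    def test_impossible_min_samples_retains_nothing(self, null_study):
        n = null_study.matrix.shape[1]
        assert len(diffexpr.detection_filter(null_study, floor=-np.inf,
                                             min_samples=n + 1)) == 0

    def test_generator_bookkeeping(self):
        """A study generated with 19,956 of 45,101 probes below the floor in
        every sample retains exactly 25,145 probes."""
        spec = synth.ExpressionSpec(n_genes=13_201, n_sibling_probes=11_944,
                                    n_unexpressed_probes=19_956, seed=2)
        study, _ = synth.gen_expression_study(spec)
        assert len(study.matrix) == 45_101
        retained = diffexpr.detection_filter(study, floor=spec.detection_floor)
        assert len(retained) == 25_145


class TestModeratedT:
    def test_zero_prior_df_equals_ordinary_t(self, null_study):
        res = diffexpr.moderated_t(null_study, "KO", "WT", prior_df=0.0)
        a = null_study.matrix[null_study.samples_in("KO")].to_numpy()
        b = null_study.matrix[null_study.samples_in("WT")].to_numpy()
        t_ref, p_ref = stats.ttest_ind(a, b, axis=1)
        np.testing.assert_allclose(res["t_mod"], t_ref, atol=1e-10)
        np.testing.assert_allclose(res["p"], p_ref, atol=1e-10)

    def test_infinite_prior_df_pools_one_variance(self, null_study):
        res = diffexpr.moderated_t(null_study, "KO", "WT", prior_df=np.inf)
        assert res["s2_post"].nunique() == 1
        s0 = np.sqrt(res["s02_prior"].iloc[0])
        c = np.sqrt(1 / 3 + 1 / 3)
        np.testing.assert_allclose(res["t_mod"], res["log2fc"] / (s0 * c), rtol=1e-12)

    def test_prior_estimation_recovers_hierarchical_truth(self):
        """Variances drawn as s0^2 * chi2_d0/d0-inverse yield d0, s0 estimates
        near the simulated truth."""
        rng = np.random.default_rng(0)
        d0_true, s0_true, d = 8.0, 0.04, 4
        s2_probe = s0_true * d0_true / rng.chisquare(d0_true, size=5000)
        s2_obs = s2_probe * rng.chisquare(d, size=5000) / d
        d0_hat, s0_hat = diffexpr.fit_f_dist(s2_obs, d)
        assert d0_hat == pytest.approx(d0_true, rel=0.2)
        assert s0_hat == pytest.approx(s0_true, rel=0.1)

    def test_null_p_uniform_and_no_fdr_calls(self, null_study):
        res = diffexpr.moderated_t(null_study, "KO", "WT")
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01
        q = diffexpr.bh_adjust(res["p"].to_numpy())
        assert (q < 0.05).sum() == 0

    def test_group_swap_antisymmetry(self, null_study):
        r1 = diffexpr.moderated_t(null_study, "KO", "WT")
        r2 = diffexpr.moderated_t(null_study, "WT", "KO")
        np.testing.assert_allclose(r1["log2fc"], -r2["log2fc"], atol=1e-12)
        np.testing.assert_allclose(r1["t_mod"], -r2["t_mod"], atol=1e-12)
        np.testing.assert_allclose(r1["p"], r2["p"], atol=1e-12)

    def test_single_sample_group_rejected(self):
        study = tiny_study(np.random.default_rng(0).normal(8, 1, (5, 2)))
        with pytest.raises(ValueError, match="2 samples"):
            diffexpr.moderated_t(study, "A", "B")


class TestBHAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(diffexpr.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(diffexpr.bh_adjust([0.3]), [0.3])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_dominance_and_monotonicity(self, p):
        q = diffexpr.bh_adjust(p)
        assert (q >= np.asarray(p) - 1e-12).all()
        assert (q <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            diffexpr.bh_adjust([0.5, 1.5])


class TestCollapseAndClassify:
    def _results(self, rows):
        return pd.DataFrame(rows, columns=["p", "log2fc"],
                            index=pd.Index([f"pr{i}" for i in range(len(rows))],
                                           name="probe"))

    def test_lowest_p_probe_kept(self):
        res = self._results([(0.01, 1.0), (0.5, 3.0)])
        out = diffexpr.collapse_probes(res, {"pr0": "g1", "pr1": "g1"})
        assert out.loc["g1", "chosen_probe"] == "pr0"

    def test_one_probe_per_gene_is_identity(self):
        res = self._results([(0.2, 1.0), (0.3, -1.0)])
        out = diffexpr.collapse_probes(res, {"pr0": "gA", "pr1": "gB"})
        assert len(out) == 2

    def test_p_tie_broken_by_fold_change_then_probe_id(self):
        res = self._results([(0.05, 1.2), (0.05, -2.0), (0.05, 2.0)])
        out = diffexpr.collapse_probes(res, {p: "g" for p in res.index})
        assert out.loc["g", "chosen_probe"] == "pr1"  # |−2.0| ties |2.0|? no: 2.0 vs -2.0 tie on |fc| -> probe id
        # explicit check of both tie levels
        res2 = self._results([(0.05, 1.2), (0.05, 2.0)])
        out2 = diffexpr.collapse_probes(res2, {p: "g" for p in res2.index})
        assert out2.loc["g", "chosen_probe"] == "pr1"

    def test_unmapped_probe_dropped(self, caplog):
        res = self._results([(0.1, 1.0), (0.2, 1.0)])
        out = diffexpr.collapse_probes(res, {"pr0": "g1"})
        assert list(out.index) == ["g1"]

    @pytest.mark.parametrize("q, fc, expected", [
        (0.04, 1.6, "increased"),
        (0.04, 1.4, "unchanged"),   # inside the dead zone
        (0.04, 0.5, "decreased"),
        (0.2, 3.0, "unchanged"),    # not significant
    ])
    def test_classification_rule(self, q, fc, expected):
        df = pd.DataFrame({"log2fc": [np.log2(fc)], "q": [q]}, index=["g"])
        out = diffexpr.classify(df)
        assert out["class"].iloc[0] == expected

    def test_classes_disjoint_and_consistent(self, de_pipeline):
        spec = synth.ExpressionSpec(n_genes=1000, planted_up=30, planted_down=30,
                                    residual_sd=0.2, seed=4)
        study, _ = synth.gen_expression_study(spec)
        classified, _ = de_pipeline(study)
        inc, dec = diffexpr.gene_sets(classified)
        assert not inc & dec
        outside_dead_zone = ((classified["q"] < 0.05)
                             & ((classified["fold_change"] > 1.5)
                                | (classified["fold_change"] < 0.67)))
        assert len(inc) + len(dec) == int(outside_dead_zone.sum())

    def test_planted_recovery_over_seeds(self, de_pipeline):
        """Recall >= 0.9 at empirical FDR <= 0.1 for strong planted effects."""
        recalls, efdrs = [], []
        for seed in range(20):
            spec = synth.ExpressionSpec(n_genes=2000, planted_up=50,
                                        effect_log2fc=2.0, residual_sd=0.25,
                                        seed=100 + seed)
            study, truth = synth.gen_expression_study(spec)
            classified, _ = de_pipeline(study)
            inc, dec = diffexpr.gene_sets(classified)
            called = inc | dec
            planted = set(truth["gene"])
            recalls.append(len(called & planted) / len(planted))
            efdrs.append(len(called - planted) / max(1, len(called)))
        assert np.mean(recalls) >= 0.9
        assert np.mean(efdrs) <= 0.1
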