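"""Trans-eQTL calling: Bonferroni threshold and the exclusion cascade."""

import numpy as np
import pandas as pd
import pytest

from eqtlmap import simulate
from eqtlmap.association import scan_table
from eqtlmap.cis import call_cis
from eqtlmap.trans import (
    bonferroni_threshold,
    call_trans,
    cis_capture_filter,
    joint_model_check,
    low_expression_cutoff,
    sequential_conditional_prune,
)


class TestBonferroniThreshold:
    def test_study_scale_value(self):
        # 30,395 probes x 1,425,832 SNPs minus 16,986,695 local pairs
        alpha = bonferroni_threshold(30_395, 1_425_832, 16_986_695, 0.05)
        assert alpha == pytest.approx(1.15e-12, rel=5e-3)

    def test_single_test(self):
        assert bonferroni_threshold(1, 1, 0, 0.05) == 0.05

    def test_hand_computed(self):
        assert bonferroni_threshold(10, 10, 50, 0.05) == pytest.approx(0.001)

    def test_zero_distant_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(10, 10, 100)


class TestCisCaptureFilter:
    def test_identical_dosage_fails(self, rng):
        g = rng.binomial(2, 0.3, 300).astype(float)
        y = 0.7 * g + rng.normal(0, 0.5, 300)
        ok, p = cis_capture_filter(g, g, y)
        assert not ok and p > 0.9

    def test_independent_true_effect_passes(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(600 + s)
            g_cis = rng.binomial(2, 0.3, 300).astype(float)
            g_trans = rng.binomial(2, 0.3, 300).astype(float)
            y = 0.5 * g_cis + 0.6 * g_trans + rng.normal(0, 1, 300)
            ok, _ = cis_capture_filter(g_trans, g_cis, y)
            hits += ok
        assert hits >= 19  # >= 95% of seeds


class TestSequentialConditionalPrune:
    def test_perfect_ld_pair_pruned(self, rng):
        g = rng.binomial(2, 0.3, 300).astype(float)
        y = 0.6 * g + rng.normal(0, 0.5, 300)
        cands = pd.DataFrame({"snp": ["a", "b"], "p_value": [1e-20, 1e-19]})
        kept = sequential_conditional_prune(cands, {"a": g, "b": g.copy()}, y)
        assert list(kept["snp"]) == ["a"]

    def test_two_independent_effects_both_kept(self):
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(700 + s)
            g1 = rng.binomial(2, 0.3, 300).astype(float)
            g2 = rng.binomial(2, 0.3, 300).astype(float)
            y = 0.6 * g1 + 0.6 * g2 + rng.normal(0, 1, 300)
            cands = pd.DataFrame({"snp": ["a", "b"], "p_value": [1e-10, 1e-9]})
            kept = sequential_conditional_prune(cands, {"a": g1, "b": g2}, y)
            hits += len(kept) == 2
        assert hits >= 9  # >= 90% of seeds

    def test_single_candidate_kept(self, rng):
        g = rng.binomial(2, 0.3, 300).astype(float)
        y = 0.6 * g + rng.normal(0, 0.5, 300)
        cands = pd.DataFrame({"snp": ["a"], "p_value": [1e-15]})
        kept = sequential_conditional_prune(cands, {"a": g}, y)
        assert list(kept["snp"]) == ["a"]

    def test_processes_in_ascending_p_order(self, rng):
        g = rng.binomial(2, 0.3, 300).astype(float)
        y = 0.6 * g + rng.normal(0, 0.5, 300)
        # rows given out of order: the smaller P must win the tie
        cands = pd.DataFrame({"snp": ["weak", "strong"], "p_value": [1e-9, 1e-20]})
        kept = sequential_conditional_prune(cands, {"weak": g.copy(), "strong": g}, y)
        assert list(kept["snp"]) == ["strong"]


class TestJointModelCheck:
    def test_orthogonal_dosages_all_kept(self, rng):
        g1 = rng.binomial(2, 0.3, 400).astype(float)
        g2 = rng.binomial(2, 0.3, 400).astype(float)
        y = 0.5 * g1 + 0.5 * g2 + rng.normal(0, 0.8, 400)
        retained = pd.DataFrame({"snp": ["a", "b"], "p_value": [1e-8, 1e-8]})
        out = joint_model_check(retained, {"a": g1, "b": g2}, y)
        assert set(out["snp"]) == {"a", "b"}

    def test_correlated_null_term_dropped(self):
        drops = 0
        for s in range(10):
            rng = np.random.default_rng(800 + s)
            n = 300
            h = rng.binomial(1, 0.3, (2, n))
            g_true = h.sum(axis=0).astype(float)
            # r2 = 0.5 proxy of the true SNP with no own effect
            keep = rng.random((2, n)) < np.sqrt(0.5)
            g_null = np.where(keep, h, rng.binomial(1, 0.3, (2, n))).sum(axis=0).astype(float)
            y = 0.6 * g_true + rng.normal(0, 1, n)
            retained = pd.DataFrame({"snp": ["true", "null"], "p_value": [1e-12, 1e-6]})
            out = joint_model_check(retained, {"true": g_true, "null": g_null}, y)
            drops += "null" not in set(out["snp"])
        assert drops >= 6  # dropped in the majority of seeds

    def test_empty_input_empty_output(self):
        out = joint_model_check(pd.DataFrame(columns=["snp", "p_value"]), {}, np.zeros(10))
        assert len(out) == 0

    def test_collinear_term_dropped_with_log(self, rng):
        g = rng.binomial(2, 0.3, 200).astype(float)
        y = 0.6 * g + rng.normal(0, 0.5, 200)
        retained = pd.DataFrame({"snp": ["a", "dup"], "p_value": [1e-9, 1e-9]})
        out = joint_model_check(retained, {"a": g, "dup": g.copy()}, y)
        assert list(out["snp"]) == ["a"]


class TestLowExpressionCutoff:
    def test_degenerate_all_equal(self):
        assert low_expression_cutoff(np.full(20, -2.0)) == -2.0

    def test_linear_interpolation_percentile(self):
        meds = np.linspace(-8, 2, 100)
        expect = np.percentile(meds, 5)
        assert low_expression_cutoff(meds) == pytest.approx(expect)

    def test_fallback_when_no_cis(self):
        assert low_expression_cutoff(np.array([])) == -4.5
        assert low_expression_cutoff(np.array([]), fallback=-3.0) == -3.0


def cascade_world(seed=4):
    """Truth-table fixture exercising every cascade exit.

    chr1 carries gene A (cis-driven by rs_c) and, >500 kb away, rs_ld in
    LD (r2 = 0.9) with rs_c but with no effect of its own: a pure
    cis-capture candidate. chr2 carries rs_xh (trans effect on gene B,
    probe copy planted in its flank -> cross-hybridization exit) and
    rs_t (clean trans effect on gene C, expected to survive).
    """
    genes = [
        simulate.GeneSpec("GA", "GENEA", "mRNA", "1", 100_000, 120_000, "+"),
        simulate.GeneSpec("GB", "GENEB", "mRNA", "1", 3_000_000, 3_020_000, "+"),
        simulate.GeneSpec("GC", "GENEC", "mRNA", "1", 5_000_000, 5_020_000, "+"),
        simulate.GeneSpec("GD", "GENED", "mRNA", "2", 100_000, 120_000, "+"),
    ]
    blocks = [
        simulate.LdBlockSpec(
            "1", "rs_c", 110_000, 0.3,
            partners=(simulate.PartnerSpec("rs_ld", 900_000, 0.9),),
        ),
        simulate.LdBlockSpec("2", "rs_xh", 200_000, 0.3),
        simulate.LdBlockSpec("2", "rs_t", 700_000, 0.3),
    ]
    return simulate.SimulationPlan(
        n_samples=300,
        chromosomes=[("1", 6_000_000), ("2", 1_000_000)],
        ld_blocks=blocks,
        genes=genes,
        cis_effects=[simulate.EffectSpec("rs_c", "GA_p1", 0.8)],
        trans_effects=[
            simulate.EffectSpec("rs_xh", "GB_p1", 0.9),
            simulate.EffectSpec("rs_t", "GC_p1", 0.9),
        ],
        cross_hyb=[simulate.CrossHybSpec("GB_p1", "rs_xh", 0)],
        noise_sd=0.5,
        baseline_sd=0.0,
        seed=seed,
    )


class TestCallTrans:
    def run_cascade(self, seed=4):
        plan = cascade_world(seed)
        g = simulate.generate_genotypes(plan)
        e, _ = simulate.generate_expression(g, plan)
        e = e.with_values(e.values, "adjusted")
        e.normalized_medians = pd.Series(
            np.median(e.values, axis=1), index=e.probes["probe"].to_numpy()
        )
        models = simulate.gene_models_by_probe(plan)
        _, _, probe_seqs, flank_seqs = simulate.generate_annotation_and_sequences(plan)
        cis_calls = call_cis(g, e, models, seed=seed)
        distant = scan_table(g, e, models, mode="distant")
        retained, audit = call_trans(
            distant, g, e, cis_calls,
            probe_sequences=probe_seqs, flank_sequences=flank_seqs,
            n_local_pairs=0,
        )
        return plan, retained, audit

    def test_truth_table_cascade(self):
        _, retained, audit = self.run_cascade()
        by_pair = audit.set_index(["snp", "probe"])
        # pure LD-with-cis candidate removed by the conditional filter
        assert ("rs_ld", "GA_p1") in by_pair.index
        assert by_pair.loc[("rs_ld", "GA_p1"), "pass_cis_capture"] == False
        # cross-hybridizing probe removed by the alignment screen
        assert by_pair.loc[("rs_xh", "GB_p1"), "pass_cross_hyb"] == False
        # the clean planted trans effect survives every step
        kept = set(zip(retained["snp"], retained["probe"]))
        assert ("rs_t", "GC_p1") in kept
        assert ("rs_ld", "GA_p1") not in kept
        assert ("rs_xh", "GB_p1") not in kept

    def test_cascade_non_expanding_and_flags_consistent(self):
        _, retained, audit = self.run_cascade()
        assert len(retained) <= len(audit)
        flag_cols = [c for c in audit.columns if c.startswith("pass_")]
        for _, row in retained.iterrows():
            assert all(row[c] == True for c in flag_cols)

    def test_missing_flank_raises(self):
        plan = cascade_world()
        g = simulate.generate_genotypes(plan)
        e, _ = simulate.generate_expression(g, plan)
        e = e.with_values(e.values, "adjusted")
        models = simulate.gene_models_by_probe(plan)
        _, _, probe_seqs, _ = simulate.generate_annotation_and_sequences(plan)
        cis_calls = call_cis(g, e, models, seed=4)
        distant = scan_table(g, e, models, mode="distant")
        with pytest.raises(ValueError, match="flank"):
            call_trans(
                distant, g, e, cis_calls,
                probe_sequences=probe_seqs, flank_sequences={},
                n_local_pairs=0,
            )

    def test_global_null_rarely_calls(self):
        # no planted effects at all: Bonferroni protects the family
        total_calls = 0
        for s in range(5):
            r = np.random.default_rng(900 + s)
            n = 100
            from conftest import make_expression, make_genotypes, simple_gene

            g = make_genotypes(r.binomial(2, 0.3, size=(30, n)).astype(float),
                               chrom="1", start_pos=10_000, spacing=1_000)
            e = make_expression(r.standard_normal((10, n)), chrom="2")
            models = {
                f"P{i+1}": simple_gene(chrom="2", gene_id=f"G{i+1}") for i in range(10)
            }
            distant = scan_table(g, e, models, mode="distant")
            retained, _ = call_trans(distant, g, e, pd.DataFrame(), n_local_pairs=0)
            total_calls += len(retained)
        assert total_calls <= 1
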