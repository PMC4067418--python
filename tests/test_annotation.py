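"""Gene-structure categories, enrichment folds, trend tests, multi-regulatory eQTLs."""

import itertools

import numpy as np
import pandas as pd
import pytest

from eqtlmap.annotation import (
    assign_category,
    compare_categories,
    distance_profile,
    enrichment,
    enrichment_table,
    find_multi_regulatory,
    jonckheere_terpstra,
    jt_statistic,
)
from eqtlmap.datatypes import GeneModel


def coding_gene(strand="+"):
    """10 kb gene with three exons and a CDS leaving UTRs on both ends."""
    return GeneModel(
        "G1", "GENE1", "1", 10_000, 20_000, strand,
        exons=((10_000, 12_000), (14_000, 16_000), (18_000, 20_000)),
        cds_start=11_000, cds_end=19_000,
    )


class TestAssignCategory:
    def test_upstream_within_1kb(self):
        assert assign_category(9_500, "1", coding_gene()) == "upstream"

    def test_downstream_minus_strand(self):
        # on the - strand the genomic left flank is downstream
        assert assign_category(9_500, "1", coding_gene("-")) == "downstream"

    def test_intergenic_beyond_1kb(self):
        assert assign_category(8_999, "1", coding_gene()) == "intergenic"
        assert assign_category(21_001, "1", coding_gene()) == "intergenic"

    def test_inside_other_gene_is_still_intergenic(self):
        # category is judged against the *target* gene only
        target = coding_gene()
        assert assign_category(40_000, "1", target) == "intergenic"

    def test_utr_assignment_by_strand(self):
        plus = coding_gene("+")
        assert assign_category(10_500, "1", plus) == "5utr"
        assert assign_category(19_500, "1", plus) == "3utr"
        minus = coding_gene("-")
        assert assign_category(10_500, "1", minus) == "3utr"
        assert assign_category(19_500, "1", minus) == "5utr"

    def test_exonic_inside_cds(self):
        assert assign_category(15_000, "1", coding_gene()) == "exonic"

    def test_splicing_two_bp_intron_side(self):
        gene = coding_gene()
        # intron 12,001..13,999: positions within 2 bp of either junction
        assert assign_category(12_001, "1", gene) == "splicing"
        assert assign_category(12_002, "1", gene) == "splicing"
        assert assign_category(12_003, "1", gene) == "intronic"
        assert assign_category(13_998, "1", gene) == "splicing"
        # 2 bp from a junction but inside the exon stays exonic/utr
        assert assign_category(14_001, "1", gene) == "exonic"

    def test_no_exon_structure_gives_na(self):
        bare = GeneModel("G1", "GENE1", "1", 10_000, 20_000, "+")
        assert assign_category(15_000, "1", bare) == "na"

    def test_total_function_over_window(self):
        gene = coding_gene()
        for pos in range(8_900, 21_100, 37):
            cat = assign_category(pos, "1", gene)
            assert cat in {
                "intergenic", "exonic", "splicing", "intronic", "3utr", "5utr",
                "upstream", "downstream", "na",
            }


class TestEnrichment:
    def test_table2_derived_folds(self):
        # recomputed from the published category counts
        assert enrichment(1_370, 2_995, 716_576, 11_028_260) == pytest.approx(7.04, abs=0.005)
        assert enrichment(45, 2_995, 3_965, 11_028_260) == pytest.approx(41.79, abs=0.005)
        assert enrichment(89, 2_995, 11_727, 11_028_260) == pytest.approx(27.95, abs=0.005)
        assert enrichment(2, 109, 52, 25_822) == pytest.approx(9.11, abs=0.005)

    def test_identical_proportions_give_one(self):
        assert enrichment(10, 100, 50, 500) == pytest.approx(1.0)

    def test_absent_category_undefined(self):
        assert np.isnan(enrichment(0, 100, 0, 500))

    def test_table_structure_and_rollup(self):
        eqtl_cats = pd.Series(["intronic"] * 6 + ["upstream"] * 2 + ["intergenic"] * 2)
        local_cats = pd.Series(["intronic"] * 30 + ["upstream"] * 10 + ["intergenic"] * 60)
        effects = pd.DataFrame({"abs_beta": np.full(10, 0.4), "r2": np.full(10, 0.2)})
        table = enrichment_table(eqtl_cats, local_cats, effects)
        by_cat = table.set_index("category")
        assert by_cat.loc["genic", "n_eqtls"] == 8
        assert by_cat.loc["intronic", "enrichment"] == pytest.approx((6 / 10) / (30 / 100))
        # proportions sum to 100% within each column
        rows = by_cat.loc[["intergenic", "genic", "na"]]
        assert rows["eqtl_pct"].sum() == pytest.approx(100.0)
        assert rows["local_pct"].sum() == pytest.approx(100.0)


class TestCompareCategories:
    def test_null_type_one_error(self):
        ps = []
        for s in range(40):
            rng = np.random.default_rng(1000 + s)
            eff = pd.Series(np.exp(rng.standard_normal(200) * 0.3))
            cats = pd.Series(["a"] * 100 + ["b"] * 100)
            res, _ = compare_categories(eff, cats)
            ps.append(res.p_value)
        assert 0.5 * 0.05 * 40 - 2 <= sum(p < 0.05 for p in ps) <= 3 * 0.05 * 40 + 2

    def test_shifted_category_detected(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(2000 + s)
            a = np.exp(rng.standard_normal(100) * 0.3)
            b = np.exp(rng.standard_normal(100) * 0.3 + 0.5)
            res, pairs = compare_categories(
                pd.Series(np.concatenate([a, b])), pd.Series(["a"] * 100 + ["b"] * 100)
            )
            hits += res.p_value < 0.01
        assert hits >= 19

    def test_small_category_dropped(self):
        eff = pd.Series(np.exp(np.linspace(-1, 1, 24)))
        cats = pd.Series(["a"] * 10 + ["b"] * 10 + ["tiny"] * 4)
        res, pairs = compare_categories(eff, cats)
        named = set(pairs["group1"]).union(pairs["group2"])
        assert "tiny" not in named

    def test_fewer_than_two_categories_rejected(self):
        with pytest.raises(ValueError):
            compare_categories(pd.Series([1.0] * 10), pd.Series(["a"] * 10))


def jt_enumeration_oracle(groups):
    """Full enumeration of distinct assignments of the pooled values."""
    sizes = [len(g) for g in groups]
    pooled = list(itertools.chain.from_iterable(groups))
    observed = jt_statistic(np.asarray(pooled, dtype=float), np.asarray(sizes))
    stats = []
    for perm in set(itertools.permutations(pooled)):
        stats.append(jt_statistic(np.asarray(perm, dtype=float), np.asarray(sizes)))
    count_ge = sum(s >= observed - 1e-9 for s in stats)
    return observed, count_ge / len(stats)


class TestJonckheereTerpstra:
    def test_ordered_example_statistic_and_exact_p(self):
        groups = [np.array([1.0, 2.0]), np.array([3.0, 4.0]), np.array([5.0, 6.0])]
        res = jonckheere_terpstra(groups, n_perm=30_000, seed=1)
        assert res.statistic == 12.0
        obs, exact_p = jt_enumeration_oracle([[1, 2], [3, 4], [5, 6]])
        assert obs == 12.0
        assert exact_p == pytest.approx(1 / 90)
        # permutation estimate within Monte-Carlo error of the exact value
        se = np.sqrt(exact_p * (1 - exact_p) / 30_000)
        assert res.p_value == pytest.approx(exact_p, abs=4 * se + 1 / 30_000)

    def test_matches_enumeration_on_random_tiny_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(3):
            groups = [rng.integers(0, 5, rng.integers(2, 4)).astype(float) for _ in range(3)]
            if sum(len(g) for g in groups) > 9:
                continue
            obs, exact_p = jt_enumeration_oracle([list(g) for g in groups])
            res = jonckheere_terpstra(groups, n_perm=20_000, seed=0)
            assert res.statistic == pytest.approx(obs)
            se = np.sqrt(exact_p * (1 - exact_p) / 20_000)
            assert res.p_value == pytest.approx(exact_p, abs=4 * se + 1e-4)

    def test_all_ties(self):
        groups = [np.ones(3), np.ones(3), np.ones(2)]
        res = jonckheere_terpstra(groups, n_perm=2_000, seed=0)
        # every cross-pair is a tie: JT = half the cross-pair count, P ~ 1
        assert res.statistic == pytest.approx((9 + 6 + 6) / 2)
        assert res.p_value == pytest.approx(1.0)

    def test_reversed_ordering_one_sided(self):
        groups = [np.array([5.0, 6.0]), np.array([3.0, 4.0]), np.array([1.0, 2.0])]
        res = jonckheere_terpstra(groups, n_perm=5_000, seed=2)
        assert res.p_value > 0.98

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            jonckheere_terpstra([np.array([1.0, 2.0])])


class TestDistanceProfile:
    def test_all_inside_genes(self):
        out = distance_profile(pd.Series([0.0, 0.0, 0.0]))
        assert out["cumulative_fraction"][0] == 1.0

    def test_hand_counted_fractions(self):
        out = distance_profile(pd.Series([0.0, 10_000.0, -40_000.0, 200_000.0]))
        cum = out["cumulative_fraction"]
        assert cum[0] == pytest.approx(0.25)
        assert cum[17_000] == pytest.approx(0.50)
        assert cum[50_000] == pytest.approx(0.75)
        assert cum[500_000] == pytest.approx(1.0)

    def test_decay_detected_by_spearman(self):
        rng = np.random.default_rng(5)
        d = rng.uniform(2_000, 400_000, 200)
        eff = 1.0 / np.sqrt(d) + rng.normal(0, 0.0005, 200)
        out = distance_profile(pd.Series(d), pd.Series(eff))
        assert out["spearman_rho"] < -0.5
        assert out["spearman_p"] < 0.01


class TestFindMultiRegulatory:
    def eqtls(self):
        return pd.DataFrame(
            {
                "snp": ["rs1"] * 4 + ["rs2"] * 2 + ["rs3"] * 3,
                "probe": [f"P{i}" for i in range(1, 10)],
                "gene_id": [f"G{i}" for i in range(1, 10)],
                "beta": [0.5, 0.4, 0.6, 0.3, 0.5, -0.2, 0.4, 0.3, 0.5],
            }
        )

    def annotation(self, classes=None):
        classes = classes or ["mRNA"] * 9
        return pd.DataFrame(
            {
                "probe": [f"P{i}" for i in range(1, 10)],
                "gene_id": [f"G{i}" for i in range(1, 10)],
                "rna_class": classes,
            }
        )

    def test_four_gene_snp_flagged_two_gene_not(self):
        out = find_multi_regulatory(self.eqtls(), self.annotation())
        assert list(out["snp"]) == ["rs1", "rs3"]
        row = out.set_index("snp").loc["rs1"]
        assert row["n_genes"] == 4
        assert row["direction_consistent"]

    def test_non_coding_probes_not_counted(self):
        ann = self.annotation(["mRNA", "lincRNA", "mRNA", "lincRNA"] + ["mRNA"] * 5)
        out = find_multi_regulatory(self.eqtls(), ann)
        # rs1 drops to two coding genes
        assert "rs1" not in set(out["snp"])

    def test_cross_hybridizing_probe_uncounted(self, rng):
        from test_alignment import rand_seq

        eq = self.eqtls()[lambda f: f["snp"] == "rs3"].reset_index(drop=True)
        seqs = {p: rand_seq(rng, 60) for p in eq["probe"]}
        # P7's sequence is planted inside G8's exons: P7 must not count
        exons = {
            "G8": rand_seq(rng, 200) + seqs["P7"] + rand_seq(rng, 200),
            "G7": rand_seq(rng, 400),
            "G9": rand_seq(rng, 400),
        }
        out = find_multi_regulatory(eq, self.annotation(), seqs, exons)
        assert len(out) == 0  # only 2 countable genes remain

    def test_direction_inconsistency_reported_not_enforced(self):
        eq = self.eqtls()
        eq.loc[0, "beta"] = -0.5  # rs1 now mixes signs
        out = find_multi_regulatory(eq, self.annotation())
        row = out.set_index("snp").loc["rs1"]
        assert row["n_genes"] == 4
        assert not row["direction_consistent"]
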