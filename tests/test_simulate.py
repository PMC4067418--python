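"""Synthetic-data generator: determinism, planned-parameter convergence,
annotation placement, cross-hybridization planting and catalog construction."""

import numpy as np
import pytest

from eqtlmap import simulate
from eqtlmap.alignment import seeded_mapped, smith_waterman
from eqtlmap.association import fit_additive
from eqtlmap.genotype_qc import ld_r2


def one_block_plan(maf=0.3, partners=(), n=1000, seed=0, **kwargs):
    genes = [simulate.GeneSpec("G1", "GENE1", "mRNA", "1", 100_000, 120_000, "+")]
    blocks = [simulate.LdBlockSpec("1", "rs1", 90_000, maf, partners=tuple(partners))]
    defaults = dict(
        n_samples=n,
        chromosomes=[("1", 1_000_000)],
        ld_blocks=blocks,
        genes=genes,
        noise_sd=0.5,
        baseline_sd=0.0,
        seed=seed,
    )
    defaults.update(kwargs)
    return simulate.SimulationPlan(**defaults)


class TestGenerateGenotypes:
    def test_deterministic_given_seed(self):
        plan = one_block_plan(partners=[simulate.PartnerSpec("rs2", 95_000, 0.6)])
        a = simulate.generate_genotypes(plan)
        b = simulate.generate_genotypes(plan)
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_r2_one_same_maf_is_exact_copy(self):
        plan = one_block_plan(partners=[simulate.PartnerSpec("rs2", 95_000, 1.0)])
        g = simulate.generate_genotypes(plan)
        np.testing.assert_array_equal(g.dosage("rs1"), g.dosage("rs2"))
        assert ld_r2(g.dosage("rs1"), g.dosage("rs2")).r2 == pytest.approx(1.0)

    def test_r2_zero_partner_independent(self):
        plan = one_block_plan(partners=[simulate.PartnerSpec("rs2", 95_000, 0.0)], n=1000)
        g = simulate.generate_genotypes(plan)
        # independence oracle: realized r2 within Monte-Carlo error at n=1000
        assert ld_r2(g.dosage("rs1"), g.dosage("rs2")).r2 < 3 / 1000 * 10

    @pytest.mark.parametrize("target", [0.3, 0.6, 0.9])
    def test_r2_target_approached(self, target):
        plan = one_block_plan(partners=[simulate.PartnerSpec("rs2", 95_000, target)], n=5000)
        g = simulate.generate_genotypes(plan)
        realized = ld_r2(g.dosage("rs1"), g.dosage("rs2")).r2
        assert realized == pytest.approx(target, abs=0.06)

    def test_maf_converges(self):
        plan = one_block_plan(maf=0.3, n=10_000)
        g = simulate.generate_genotypes(plan)
        assert np.nanmean(g.dosage("rs1")) / 2 == pytest.approx(0.3, abs=0.02)

    def test_r2_one_with_different_maf_rejected(self):
        with pytest.raises(ValueError, match="unattainable"):
            one_block_plan(partners=[simulate.PartnerSpec("rs2", 95_000, 1.0, maf=0.1)])

    def test_missing_rate_planted(self):
        plan = one_block_plan(n=2000)
        plan.ld_blocks[0] = simulate.LdBlockSpec("1", "rs1", 90_000, 0.3, missing_rate=0.05)
        g = simulate.generate_genotypes(plan)
        assert np.isnan(g.dosage("rs1")).mean() == pytest.approx(0.05, abs=0.02)


class TestGenerateExpression:
    def test_noiseless_recovery_is_exact(self):
        plan = one_block_plan(
            n=200, cis_effects=[simulate.EffectSpec("rs1", "G1_p1", 0.5)], noise_sd=1e-12
        )
        g = simulate.generate_genotypes(plan)
        e, _ = simulate.generate_expression(g, plan)
        fit = fit_additive(g.dosage("rs1"), e.probe_values("G1_p1"))
        assert fit.beta == pytest.approx(0.5, abs=1e-6)

    def test_homozygote_fold_change(self):
        # planted beta = 0.3 -> 2^(2 * 0.3) ~ 1.5-fold between homozygote classes
        plan = one_block_plan(
            n=20_000, cis_effects=[simulate.EffectSpec("rs1", "G1_p1", 0.3)], noise_sd=0.2
        )
        g = simulate.generate_genotypes(plan)
        e, _ = simulate.generate_expression(g, plan)
        d, y = g.dosage("rs1"), e.probe_values("G1_p1")
        fold = 2 ** (y[d == 2].mean() - y[d == 0].mean())
        assert fold == pytest.approx(2 ** 0.6, abs=0.05)
        assert round(fold, 1) == 1.5

    def test_latent_factor_found_by_pca(self):
        genes = [
            simulate.GeneSpec(f"G{i+1}", f"GENE{i+1}", "mRNA", "1", 100_000 + i * 30_000,
                              110_000 + i * 30_000, "+")
            for i in range(100)
        ]
        plan = simulate.SimulationPlan(
            n_samples=200,
            chromosomes=[("1", 5_000_000)],
            ld_blocks=[simulate.LdBlockSpec("1", "rs1", 90_000, 0.3)],
            genes=genes,
            n_latent_factors=1,
            latent_loadings={f"G{i+1}_p1": (1.0,) for i in range(100)},
            noise_sd=0.5,
            baseline_sd=0.0,
            seed=11,
        )
        g = simulate.generate_genotypes(plan)
        e, _ = simulate.generate_expression(g, plan)
        centered = e.values - e.values.mean(axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        # the factor realization is recoverable from the loadings-1 structure:
        # PC1 must align with the per-sample mean across probes
        factor_proxy = centered.mean(axis=0)
        assert abs(np.corrcoef(vt[0], factor_proxy)[0, 1]) > 0.9

    def test_unknown_effect_reference_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            one_block_plan(cis_effects=[simulate.EffectSpec("rsX", "G1_p1", 0.5)])

    def test_covariate_and_raw_export(self):
        plan = one_block_plan(n=300, covariate_effects={"G1_p1": (0.01, 0.2)})
        g = simulate.generate_genotypes(plan)
        raw, cov = simulate.generate_expression(g, plan, raw=True)
        assert raw.stage == "raw"
        assert (raw.values > 0).all()
        assert set(cov.columns) == {"age", "sex"}
        assert cov["age"].between(32, 66).all()
        assert set(cov["sex"].unique()) <= {0, 1}


class TestAnnotationAndSequences:
    def test_upstream_placement(self):
        # SNP 500 bp before a + strand gene TSS -> upstream category
        plan = one_block_plan(cis_effects=[simulate.EffectSpec("rs1", "G1_p1", 0.5)])
        plan.ld_blocks[0] = simulate.LdBlockSpec("1", "rs1", 100_000 - 500, 0.3)
        _, ann, _, _ = simulate.generate_annotation_and_sequences(plan)
        assert ann.set_index("snp").loc["rs1", "category"] == "upstream"

    def test_exact_copy_is_flagged(self):
        plan = one_block_plan(
            trans_effects=[], cross_hyb=[simulate.CrossHybSpec("G1_p1", "rs1", 0)]
        )
        _, _, probes, flanks = simulate.generate_annotation_and_sequences(plan)
        assert seeded_mapped(probes["G1_p1"], flanks["rs1"])

    def test_heavily_mutated_copy_not_flagged(self):
        plan = one_block_plan(cross_hyb=[simulate.CrossHybSpec("G1_p1", "rs1", 45)])
        _, _, probes, flanks = simulate.generate_annotation_and_sequences(plan)
        assert not seeded_mapped(probes["G1_p1"], flanks["rs1"])

    def test_mutated_pair_alignment_scores(self):
        # DP oracle on the generated pair: 45 of 60 mutated leaves ~15 matches
        plan = one_block_plan(cross_hyb=[simulate.CrossHybSpec("G1_p1", "rs1", 45)])
        _, _, probes, flanks = simulate.generate_annotation_and_sequences(plan)
        probe = probes["G1_p1"]
        # locate the planted copy by best window score and check the exact run
        best_run = 0
        flank = flanks["rs1"]
        for i in range(len(flank) - len(probe) + 1):
            window = flank[i : i + len(probe)]
            run = cur = 0
            for a, b in zip(probe, window):
                cur = cur + 1 if a == b else 0
                run = max(run, cur)
            best_run = max(best_run, run)
        assert best_run < 14  # no seed anchor anywhere

    def test_copy_longer_than_flank_rejected(self):
        plan = one_block_plan(
            flank_length=10, cross_hyb=[simulate.CrossHybSpec("G1_p1", "rs1", 0)]
        )
        with pytest.raises(ValueError, match="longer than the flank"):
            simulate.generate_annotation_and_sequences(plan)

    def test_determinism(self):
        plan = one_block_plan(cross_hyb=[simulate.CrossHybSpec("G1_p1", "rs1", 3)])
        out1 = simulate.generate_annotation_and_sequences(plan)
        out2 = simulate.generate_annotation_and_sequences(plan)
        assert out1[2] == out2[2] and out1[3] == out2[3]


class TestLocalityValidation:
    def test_cis_effect_must_be_local(self):
        genes = [simulate.GeneSpec("G1", "GENE1", "mRNA", "2", 100_000, 120_000, "+")]
        blocks = [simulate.LdBlockSpec("1", "rs1", 90_000, 0.3)]
        with pytest.raises(ValueError, match="locality"):
            simulate.SimulationPlan(
                n_samples=100, chromosomes=[("1", 1_000_000), ("2", 1_000_000)],
                ld_blocks=blocks, genes=genes,
                cis_effects=[simulate.EffectSpec("rs1", "G1_p1", 0.5)], seed=0,
            )

    def test_trans_effect_must_be_distant(self):
        with pytest.raises(ValueError, match="locality"):
            one_block_plan(trans_effects=[simulate.EffectSpec("rs1", "G1_p1", 0.5)])


class TestGwasCatalog:
    def test_cases_by_construction(self, trio_world):
        plan = trio_world
        plan.cis_effects = [
            simulate.EffectSpec("rs1", "G1_p1", 0.8),
            simulate.EffectSpec("rs2", "G2_p1", 0.8),
            simulate.EffectSpec("rs3", "G3_p1", -0.6),
        ]
        plan.validate()
        cat = simulate.generate_gwas_catalog(plan)
        by_case = cat.set_index("expected_case")
        # case 2: reported gene equals the regulated gene
        row2 = by_case.loc["case2"]
        assert row2["reported_genes"] == "GENE2"
        # case 1: reported gene differs from the regulated one
        row1 = by_case.loc["case1"]
        assert "GENE1" not in row1["reported_genes"].split(";")
        # case 3: regulated gene among several reported
        row3 = by_case.loc["case3"]
        genes3 = row3["reported_genes"].split(";")
        assert "GENE3" in genes3 and len(genes3) == 2

    def test_case4_only_for_trans_only_snps(self):
        genes = [
            simulate.GeneSpec("G1", "GENE1", "mRNA", "1", 100_000, 120_000, "+"),
            simulate.GeneSpec("G2", "GENE2", "mRNA", "2", 100_000, 120_000, "+"),
        ]
        plan = simulate.SimulationPlan(
            n_samples=100,
            chromosomes=[("1", 1_000_000), ("2", 1_000_000)],
            ld_blocks=[
                simulate.LdBlockSpec("1", "rs1", 90_000, 0.3),
                simulate.LdBlockSpec("1", "rs2", 500_000, 0.3),
            ],
            genes=genes,
            trans_effects=[simulate.EffectSpec("rs1", "G2_p1", 0.7)],
            seed=0,
        )
        cat = simulate.generate_gwas_catalog(plan)
        case4 = cat[cat["expected_case"] == "case4"]
        assert list(case4["snp"]) == ["rs1"]
        # an effect-free SNP yields an uninformative record
        assert (cat["expected_case"] == "uninformative").sum() == 1
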