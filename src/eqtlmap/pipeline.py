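"""End-to-end orchestration of the eQTL discovery pipeline.

``run_all`` composes the stages exactly as the numbered analysis drivers
do: simulate -> genotype QC -> normalize -> adjust (SVA + covariates) ->
cis mapping (permutation FDR) -> trans mapping (Bonferroni + exclusion
cascade) -> enrichment/multi-regulatory statistics -> GWAS record
classification. Every stage is a pure function of its inputs and the
seed, so the composition is reproducible byte-for-byte.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import annotation as annostats
from . import cis as cis_mod
from . import gwas as gwas_mod
from . import preprocess, simulate, trans
from .association import local_snp_indices, scan_table
from .datatypes import ExpressionMatrix, GenotypeMatrix
from .genotype_qc import qc_filter
from .io import PipelineConfig

logger = logging.getLogger(__name__)


def count_local_pairs(genotypes: GenotypeMatrix, expression: ExpressionMatrix, gene_models, window: int) -> int:
    total = 0
    for probe in expression.probes["probe"]:
        gene = gene_models.get(probe)
        if gene is not None:
            total += int(local_snp_indices(genotypes, gene, window).size)
    return total


def run_all(plan: simulate.SimulationPlan, config: PipelineConfig | None = None) -> dict:
    """Run the full pipeline on a simulation plan; returns all artifacts."""
    config = config or PipelineConfig(seed=plan.seed)
    out: dict = {"plan": plan, "config": config}

    # --- simulate ------------------------------------------------------
    genotypes = simulate.generate_genotypes(plan)
    raw, covariates = simulate.generate_expression(genotypes, plan, raw=True)
    models, snp_annotation, probe_seqs, flank_seqs = simulate.generate_annotation_and_sequences(plan)
    truth = simulate.truth_table(plan)
    catalog = simulate.generate_gwas_catalog(plan)
    out.update(
        truth=truth, snp_annotation=snp_annotation, probe_sequences=probe_seqs,
        flank_sequences=flank_seqs, gwas_catalog=catalog, covariates=covariates,
    )

    # --- genotype QC ---------------------------------------------------
    genotypes, qc_report = qc_filter(
        genotypes, maf_min=config.maf_min, missing_max=config.missing_max, hwe_min=config.hwe_min
    )
    out["genotypes"] = genotypes
    out["qc_report"] = qc_report

    # --- normalize & adjust -------------------------------------------
    normalized = preprocess.normalize_75th(raw)
    normalized, probe_report = preprocess.filter_probes(normalized)
    out["probe_report"] = probe_report
    known = covariates[["age", "sex"]]
    svs = preprocess.estimate_surrogate_variables(normalized, known, seed=config.seed)
    design = known.join(svs)
    adjusted = preprocess.adjust_expression(normalized, design)
    out["normalized"] = normalized
    out["adjusted"] = adjusted
    out["surrogate_variables"] = svs

    # --- cis mapping ---------------------------------------------------
    cis_calls = cis_mod.call_cis(
        genotypes, adjusted, models,
        fdr_max=config.cis_fdr, kw_alpha=config.kw_alpha,
        n_perm=config.n_perm_cis, seed=config.seed, window=config.cis_window,
    )
    out["cis_calls"] = cis_calls
    cis_final = cis_calls[cis_calls["kw_pass"]].reset_index(drop=True)
    out["cis_eqtls"] = cis_final

    # --- trans mapping -------------------------------------------------
    distant = scan_table(genotypes, adjusted, models, mode="distant", window=config.cis_window)
    n_local = count_local_pairs(genotypes, adjusted, models, config.cis_window)
    trans_calls, trans_audit = trans.call_trans(
        distant, genotypes, adjusted, cis_calls,
        probe_sequences=probe_seqs, flank_sequences=flank_seqs,
        family_alpha=config.trans_fwer, n_local_pairs=n_local,
        conditional_alpha=config.conditional_alpha, kw_alpha=config.kw_alpha,
        low_expr_percentile=config.low_expr_percentile,
    )
    out["trans_eqtls"] = trans_calls
    out["trans_audit"] = trans_audit

    # --- annotation statistics ----------------------------------------
    ann = snp_annotation.set_index("snp")
    mrna_probes = set(adjusted.probes.loc[adjusted.probes["rna_class"] == "mRNA", "probe"])
    cis_mrna = cis_final[cis_final["probe"].isin(mrna_probes)]
    if len(cis_mrna):
        eqtl_cats = ann.reindex(cis_mrna["snp"])["category"].reset_index(drop=True)
        local_cats = ann["category"].reset_index(drop=True)
        effects = pd.DataFrame(
            {"abs_beta": cis_mrna["beta"].abs().to_numpy(), "r2": cis_mrna["r2"].to_numpy()}
        )
        out["enrichment"] = annostats.enrichment_table(eqtl_cats, local_cats, effects)
        out["distance_profile"] = annostats.distance_profile(
            cis_mrna["distance"], cis_mrna["beta"].abs(), eqtl_cats
        )
    multireg_input = pd.concat([cis_final, trans_calls], ignore_index=True) if len(trans_calls) else cis_final
    out["multi_regulatory"] = annostats.find_multi_regulatory(
        multireg_input.merge(adjusted.probes[["probe", "gene_id", "rna_class"]], on="probe", how="left", suffixes=("", "_ann")),
        adjusted.probes, probe_seqs, exon_sequences=None,
        min_genes=config.multi_reg_min_genes,
    )

    # --- GWAS integration ---------------------------------------------
    eqtl_map = _combined_eqtl_table(cis_final, trans_calls, adjusted.probes)
    records = [
        gwas_mod.GwasRecord(r["record_id"], r["snp"], r["trait"], tuple(str(r["reported_genes"]).split(";")), r["p"])
        for _, r in catalog.iterrows()
    ]
    classifications = gwas_mod.classify_records(
        records, eqtl_map, genotypes, adjusted,
        r2_min=config.ld_match_r2, conditional_alpha=config.conditional_alpha,
    )
    out["gwas_classifications"] = classifications
    out["gwas_summary"] = gwas_mod.summarize_cases(classifications, n_records=len(catalog))
    return out


def _combined_eqtl_table(cis_final: pd.DataFrame, trans_calls: pd.DataFrame, probes: pd.DataFrame) -> pd.DataFrame:
    cols = ["snp", "probe", "gene_id", "symbol", "beta", "p_value", "kind"]
    parts = []
    if len(cis_final):
        c = cis_final.copy()
        c["kind"] = "cis"
        parts.append(c[cols])
    if len(trans_calls):
        t = trans_calls.merge(
            probes[["probe", "gene_id", "symbol"]], on="probe", how="left"
        )
        t["kind"] = "trans"
        parts.append(t[cols])
    if not parts:
        return pd.DataFrame(columns=cols)
    return pd.concat(parts, ignore_index=True)
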