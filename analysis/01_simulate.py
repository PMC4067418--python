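"""Generate the synthetic cohort: genotypes, expression, annotations, sequences.

Writes every pipeline input under results/data/: genotypes as VCF and
dosage TSV, raw probe intensities, probe/gene annotation, probe and flank
FASTA, the engineered GWAS catalog, the covariate table, and the planted
truth table that later stages are benchmarked against.
"""

import argparse
from pathlib import Path

import pandas as pd

from eqtlmap import io, simulate


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-samples", type=int, default=298)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    plan = simulate.example_plan(seed=args.seed, n_samples=args.n_samples)
    genotypes = simulate.generate_genotypes(plan)
    raw, covariates = simulate.generate_expression(genotypes, plan, raw=True)
    models, snp_annotation, probe_seqs, flank_seqs = simulate.generate_annotation_and_sequences(plan)
    truth = simulate.truth_table(plan)
    catalog = simulate.generate_gwas_catalog(plan)

    io.write_genotypes_vcf(genotypes, args.out / "genotypes.vcf")
    io.write_genotypes_tsv(genotypes, args.out / "genotypes.tsv")
    io.write_expression(raw, args.out / "expression_raw.tsv")
    simulate.annotation_table(plan).to_csv(args.out / "probe_annotation.tsv", sep="\t", index=False)
    io.write_gene_models(models, args.out / "gene_models.tsv")
    io.write_fasta(probe_seqs, args.out / "probes.fasta")
    io.write_fasta(flank_seqs, args.out / "flanks.fasta")
    snp_annotation.to_csv(args.out / "snp_annotation.tsv", sep="\t", index=False)
    covariates.to_csv(args.out / "covariates.tsv", sep="\t", index_label="sample")
    truth.to_csv(args.out / "truth.tsv", sep="\t", index=False)
    catalog.to_csv(args.out / "gwas_catalog.tsv", sep="\t", index=False)

    print(f"cohort: {plan.n_samples} samples, {genotypes.n_snps} SNPs, {raw.n_probes} probes")
    print(f"planted effects: {len(plan.cis_effects)} cis, {len(plan.trans_effects)} trans")
    print(f"inputs written to {args.out}")


if __name__ == "__main__":
    main()
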