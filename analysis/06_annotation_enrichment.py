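"""Functional interpretation of the cis-eQTL map.

Builds the gene-structure enrichment table (fold change of each category's
share among cis-eQTLs vs among all local SNPs), compares effect sizes
across categories by ANOVA with Tukey HSD on log effects, tests the trend
of effects over RegulomeDB classes with a one-sided Jonckheere-Terpstra
permutation test, profiles effect size against distance from the target
gene, and lists multi-regulatory eQTLs (SNPs regulating >= 3 coding genes
after cross-hybridization exclusion).
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from eqtlmap import io
from eqtlmap.annotation import (
    compare_categories,
    distance_profile,
    enrichment_table,
    find_multi_regulatory,
    jonckheere_terpstra,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--jt-permutations", type=int, default=100_000)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    annotation = io.read_annotation(args.data / "probe_annotation.tsv")
    snp_ann = pd.read_csv(args.data / "snp_annotation.tsv", sep="\t", dtype={"chrom": str}).set_index("snp")
    cis = io.read_results(args.out / "cis_eqtls.tsv")
    trans = io.read_results(args.out / "trans_eqtls.tsv")
    probe_seqs = io.read_fasta(args.data / "probes.fasta")

    mrna = set(annotation.loc[annotation["rna_class"] == "mRNA", "probe"])
    cis_mrna = cis[cis["probe"].isin(mrna)].reset_index(drop=True)
    print(f"{len(cis)} cis-eQTLs, {len(cis_mrna)} on mRNA transcripts")

    # enrichment of gene-structure categories
    eqtl_cats = snp_ann.reindex(cis_mrna["snp"])["category"].reset_index(drop=True)
    local_cats = snp_ann["category"].reset_index(drop=True)
    effects = pd.DataFrame({"abs_beta": cis_mrna["beta"].abs(), "r2": cis_mrna["r2"]})
    table = enrichment_table(eqtl_cats, local_cats, effects)
    io.write_results(table, args.out / "enrichment.tsv")
    genic = table.set_index("category").loc["genic"]
    print(f"genic enrichment {genic['enrichment']:.2f} "
          f"({genic['eqtl_pct']:.1f}% of cis-eQTLs vs {genic['local_pct']:.1f}% of local SNPs)")

    # effect-size comparison across categories (log scale)
    try:
        anova, tukey = compare_categories(effects["abs_beta"], eqtl_cats)
        tukey.to_csv(args.out / "tukey_abs_beta.tsv", sep="\t", index=False)
        print(f"ANOVA across categories on log|beta|: F={anova.statistic:.2f}, P={anova.p_value:.2g}")
    except ValueError as err:
        print(f"ANOVA skipped: {err}")

    # RegulomeDB trend among intergenic cis-eQTLs
    inter = cis_mrna[eqtl_cats.to_numpy() == "intergenic"]
    classes = snp_ann.reindex(inter["snp"])["regulome_class"].to_numpy()
    groups = [
        np.log(inter["beta"].abs().to_numpy()[classes == c])
        for c in sorted(np.unique(classes))
    ]
    groups = [g for g in groups if g.size > 0]
    if len(groups) >= 2:
        jt = jonckheere_terpstra(groups, n_perm=args.jt_permutations, seed=args.seed)
        print(f"Jonckheere-Terpstra trend over RegulomeDB classes: JT={jt.statistic:.0f}, "
              f"one-sided P={jt.p_value:.3f} ({jt.n_permutations} permutations)")

    # distance profile
    profile = distance_profile(cis_mrna["distance"], cis_mrna["beta"].abs(), eqtl_cats)
    with open(args.out / "distance_profile.json", "w") as fh:
        json.dump(profile, fh, indent=2)
    cum = profile["cumulative_fraction"]
    print(f"cis-eQTLs within gene / 50 kb / 500 kb: "
          f"{100*cum[0]:.0f}% / {100*cum[50_000]:.0f}% / {100*cum[500_000]:.0f}%")

    # multi-regulatory eQTLs
    both = pd.concat([cis, trans], ignore_index=True) if len(trans) else cis
    both = both.merge(annotation[["probe", "gene_id", "rna_class"]], on="probe",
                      how="left", suffixes=("", "_ann"))
    multi = find_multi_regulatory(both, annotation, probe_seqs, exon_sequences=None)
    io.write_results(multi, args.out / "multi_regulatory.tsv")
    print(f"multi-regulatory eQTLs (>= 3 coding genes): {len(multi)}")


if __name__ == "__main__":
    main()
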