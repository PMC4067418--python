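"""Reassessment of GWAS catalog records against the eQTL map.

Matches each catalog record's SNP to cis/trans eQTLs directly or through
LD (r^2 > 0.8), drops non-colocalizing matches by conditional regression,
and classifies informative records into Case 1 (map suggests a different
gene), Case 2 (map supports the reported gene), Case 3 (map prioritizes
among several reported genes) or Case 4 (trans-only effect). Compares
the result with the catalog's planted truth labels.
"""

import argparse
from pathlib import Path

import pandas as pd

from eqtlmap import io
from eqtlmap.gwas import classify_records, summarize_cases


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)  # accepted for a uniform interface
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    genotypes = io.read_genotypes(args.out / "genotypes_qc.tsv")
    annotation = io.read_annotation(args.data / "probe_annotation.tsv")
    adjusted = io.read_expression(args.out / "expression_adjusted.tsv", annotation, stage="adjusted")
    cis = io.read_results(args.out / "cis_eqtls.tsv")
    trans = io.read_results(args.out / "trans_eqtls.tsv")
    records = io.read_gwas_catalog(args.data / "gwas_catalog.tsv")

    cols = ["snp", "probe", "gene_id", "symbol", "beta", "p_value", "kind"]
    parts = []
    if len(cis):
        c = cis.copy(); c["kind"] = "cis"; parts.append(c[cols])
    if len(trans):
        t = trans.merge(annotation[["probe", "gene_id", "symbol"]], on="probe", how="left")
        t["kind"] = "trans"; parts.append(t[cols])
    eqtls = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(columns=cols)

    classifications = classify_records(records, eqtls, genotypes, adjusted)
    summary = summarize_cases(classifications, n_records=len(records))
    io.write_results(classifications, args.out / "gwas_classifications.tsv")
    io.write_results(summary, args.out / "gwas_summary.tsv")

    info = summary.set_index("case")
    print(f"{len(records)} records assessed against {len(eqtls)} eQTLs")
    print(f"informative: {int(info.loc['informative','n_records'])} "
          f"({info.loc['informative','pct_records']:.1f}%)")
    for case in ("case1", "case2", "case3", "case4"):
        print(f"  {case}: {int(info.loc[case, 'n_records'])}")

    catalog = pd.read_csv(args.data / "gwas_catalog.tsv", sep="\t")
    merged = classifications.merge(catalog[["record_id", "expected_case"]], on="record_id")
    called = merged[merged["case"] != "uninformative"]
    if len(called):
        agree = (called["case"] == called["expected_case"]).mean()
        print(f"agreement with planted truth among informative records: {100*agree:.0f}%")


if __name__ == "__main__":
    main()
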