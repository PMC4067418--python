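"""SNP quality control: missingness, Hardy-Weinberg, MAF, autosome filters.

Reads the dosage TSV, applies the QC thresholds (missing rate <= 1%,
HWE exact P >= 1e-7, MAF >= 5%, autosomes only) and writes the retained
dosages plus a per-SNP report with per-criterion flags.
"""

import argparse
from pathlib import Path

from eqtlmap import io
from eqtlmap.genotype_qc import qc_filter


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)  # accepted for a uniform interface
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    genotypes = io.read_genotypes(args.data / "genotypes.tsv")
    kept, report = qc_filter(genotypes)
    io.write_genotypes_tsv(kept, args.out / "genotypes_qc.tsv")
    report.to_csv(args.out / "qc_report.tsv", sep="\t", index=False)

    n_fail = (~report["pass"]).sum()
    print(f"{genotypes.n_snps} SNPs in, {kept.n_snps} retained, {n_fail} excluded")
    for crit in ("fail_missing", "fail_hwe", "fail_maf", "fail_sex_chrom"):
        print(f"  {crit}: {int(report[crit].sum())}")


if __name__ == "__main__":
    main()
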