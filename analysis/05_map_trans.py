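"""Trans-eQTL mapping: Bonferroni threshold plus the exclusion cascade.

Scans distant SNP-transcript pairs (different chromosome or > 500 kb),
thresholds at the family-wise 5% Bonferroni level computed from the
actual post-QC test count, then excludes candidates that (1) only
capture a cis effect through LD, (2) are LD-redundant with stronger
trans-eQTLs, (3) fail the joint model, (4) cross-hybridize into their
SNP's +/-500 kb flank, (5) target low-expressed transcripts, or
(6) fail the Kruskal-Wallis confirmation. Writes the surviving
trans-eQTLs and a full audit table with one flag column per step.
"""

import argparse
from pathlib import Path

import pandas as pd

from eqtlmap import io
from eqtlmap.association import scan_table
from eqtlmap.pipeline import count_local_pairs
from eqtlmap.trans import call_trans


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)  # accepted for a uniform interface
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    genotypes = io.read_genotypes(args.out / "genotypes_qc.tsv")
    annotation = io.read_annotation(args.data / "probe_annotation.tsv")
    adjusted = io.read_expression(args.out / "expression_adjusted.tsv", annotation, stage="adjusted")
    adjusted.normalized_medians = pd.read_csv(
        args.out / "normalized_medians.tsv", sep="\t", index_col="probe"
    )["median"]
    gene_models = io.read_gene_models(args.data / "gene_models.tsv")
    probe_models = {
        probe: gene_models[gid]
        for probe, gid in zip(annotation["probe"], annotation["gene_id"])
        if gid in gene_models
    }
    cis_calls = io.read_results(args.out / "cis_calls.tsv")
    probe_seqs = io.read_fasta(args.data / "probes.fasta")
    flank_seqs = io.read_fasta(args.data / "flanks.fasta")

    distant = scan_table(genotypes, adjusted, probe_models, mode="distant")
    n_local = count_local_pairs(genotypes, adjusted, probe_models, 500_000)
    retained, audit = call_trans(
        distant, genotypes, adjusted, cis_calls,
        probe_sequences=probe_seqs, flank_sequences=flank_seqs,
        n_local_pairs=n_local,
    )
    io.write_results(retained, args.out / "trans_eqtls.tsv")
    io.write_results(audit, args.out / "trans_audit.tsv")

    n_tests = len(distant)
    print(f"{n_tests} distant tests; threshold {audit['fwer_threshold'].iloc[0]:.2e}" if len(audit)
          else f"{n_tests} distant tests; no candidate passed the threshold")
    print(f"{len(audit)} candidates entered the cascade; {len(retained)} survived")
    for col in [c for c in audit.columns if c.startswith("pass_")]:
        n_fail = int((audit[col] == False).sum())
        if n_fail:
            print(f"  removed at {col[5:]}: {n_fail}")


if __name__ == "__main__":
    main()
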