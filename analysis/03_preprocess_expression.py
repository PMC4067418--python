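"""Expression preprocessing: normalization, probe filters, SVA adjustment.

Floors raw intensities at 1, log2-transforms, shifts each chip's 75th
percentile to 0, drops unmapped/sex-chromosome/polymorphism-overlapping
probes, estimates surrogate variables with age and sex as known
covariates, and writes the covariate-adjusted residual matrix used by
the association scans.
"""

import argparse
from pathlib import Path

import pandas as pd

from eqtlmap import io, preprocess


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    annotation = io.read_annotation(args.data / "probe_annotation.tsv")
    raw = io.read_expression(args.data / "expression_raw.tsv", annotation, stage="raw")
    covariates = pd.read_csv(args.data / "covariates.tsv", sep="\t", index_col="sample")

    normalized = preprocess.normalize_75th(raw)
    normalized, report = preprocess.filter_probes(normalized)
    svs = preprocess.estimate_surrogate_variables(normalized, covariates[["age", "sex"]], seed=args.seed)
    design = covariates[["age", "sex"]].join(svs)
    adjusted = preprocess.adjust_expression(normalized, design)

    io.write_expression(adjusted, args.out / "expression_adjusted.tsv")
    adjusted.normalized_medians.rename("median").to_csv(
        args.out / "normalized_medians.tsv", sep="\t", index_label="probe"
    )
    design.to_csv(args.out / "design_covariates.tsv", sep="\t", index_label="sample")
    report.to_csv(args.out / "probe_filter_report.tsv", sep="\t", index=False)

    print(f"{raw.n_probes} probes in, {adjusted.n_probes} after filters")
    print(f"surrogate variables found: {svs.shape[1]} (age and sex as known covariates)")
    lo, hi = normalized.values.min(), normalized.values.max()
    print(f"normalized signal range: {lo:.1f} to {hi:.1f}, median {pd.Series(normalized.values.ravel()).median():.1f}")


if __name__ == "__main__":
    main()
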