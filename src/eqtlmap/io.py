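"""Readers/writers for the on-disk formats and the pipeline configuration.

Conventions: genomic coordinates are 1-based inclusive everywhere inside
the package; BED conversion (0-based half-open) is provided here and is
bijective on round trip. Genotype dosages are recoded to count the
*minor* allele per dataset, recomputed from the observed allele
frequencies rather than trusting the VCF ALT; frequency ties at 0.5
orient to the alphabetically first allele.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from .datatypes import ExpressionMatrix, GeneModel, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Thresholds and knobs of the full pipeline (spec defaults)."""

    maf_min: float = 0.05
    missing_max: float = 0.01
    hwe_min: float = 1e-7
    cis_window: int = 500_000
    cis_fdr: float = 0.05
    n_perm_cis: int = 10
    trans_fwer: float = 0.05
    conditional_alpha: float = 0.05
    kw_alpha: float = 0.00015
    ld_match_r2: float = 0.8
    sw_match: int = 10
    sw_mismatch: int = 0
    sw_gap_open: int = -250
    sw_gap_extend: int = -100
    sw_min_frac: float = 0.30
    low_expr_percentile: float = 5.0
    multi_reg_min_genes: int = 3
    jt_permutations: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("maf_min", "missing_max", "cis_fdr", "trans_fwer",
                     "conditional_alpha", "kw_alpha", "ld_match_r2", "sw_min_frac"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.cis_window <= 0:
            raise ValueError("cis_window must be positive")
        if self.n_perm_cis < 1 or self.jt_permutations < 1:
            raise ValueError("permutation counts must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# coordinates


def to_bed_interval(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def from_bed_interval(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


# ---------------------------------------------------------------------------
# genotypes


def _orient_minor(alt_counts: np.ndarray, ref: str, alt: str) -> tuple[np.ndarray, str]:
    """Recode ALT-allele counts so the minor allele is counted.

    Ties at frequency 0.5 orient to the alphabetically first allele.
    Returns the dosage vector and the counted allele.
    """
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(alt_counts) / 2.0
    if freq > 0.5 or (freq == 0.5 and alt > ref):
        return 2.0 - alt_counts, ref
    return alt_counts, alt


def read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into a minor-allele dosage matrix.

    Multiallelic records are skipped with a warning; ``./.`` genotypes
    become NaN.
    """
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    rows, meta = [], []
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            logger.warning("skipping non-biallelic record %s at %s:%d", rec.id, rec.chrom, rec.pos)
            continue
        counts = np.full(len(samples), np.nan)
        for i, s in enumerate(samples):
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt):
                continue
            counts[i] = float(sum(gt))
        dosage, _allele = _orient_minor(counts, rec.ref, rec.alts[0])
        rows.append(dosage)
        meta.append({"snp": rec.id or f"{rec.chrom}:{rec.pos}", "chrom": rec.chrom, "pos": rec.pos})
    if not rows:
        raise ValueError(f"no biallelic records in {path}")
    return GenotypeMatrix(np.stack(rows), pd.DataFrame(meta), samples)


def write_genotypes_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as an uncompressed VCF 4.2 with GT calls (REF=A, ALT=G).

    Dosage d in {0,1,2} maps to 0/0, 0/1, 1/1 with ALT the minor allele;
    NaN becomes ``./.``.
    """
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = pd.unique(genotypes.snps["chrom"].astype(str))
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(genotypes.samples) + "\n")
        order = genotypes.snps.sort_values(["chrom", "pos"], kind="stable").index
        for i in order:
            row = genotypes.snps.loc[i]
            calls = [
                "./." if np.isnan(d) else gt_map[int(d)] for d in genotypes.dosages[i]
            ]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['snp']}\tA\tG\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    """Dosage TSV: columns snp, chrom, pos, then one column per sample."""
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("snp", "chrom", "pos"):
        if col not in frame.columns:
            raise ValueError(f"genotype TSV lacks mandatory column {col!r}")
    samples = [c for c in frame.columns if c not in ("snp", "chrom", "pos")]
    dosages = frame[samples].to_numpy(dtype=float)
    # re-orient to the minor allele per dataset
    for i in range(dosages.shape[0]):
        dosages[i], _ = _orient_minor(dosages[i], "A", "G")
    return GenotypeMatrix(dosages, frame[["snp", "chrom", "pos"]], samples)


def write_genotypes_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    frame = pd.concat(
        [
            genotypes.snps[["snp", "chrom", "pos"]].reset_index(drop=True),
            pd.DataFrame(genotypes.dosages, columns=genotypes.samples),
        ],
        axis=1,
    )
    frame.to_csv(path, sep="\t", index=False)


def read_genotypes(path: str | Path, fmt: str | None = None) -> GenotypeMatrix:
    fmt = fmt or ("vcf" if str(path).endswith(".vcf") else "tsv")
    if fmt == "vcf":
        return read_genotypes_vcf(path)
    if fmt == "tsv":
        return read_genotypes_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


# ---------------------------------------------------------------------------
# expression and annotation


def read_expression(path: str | Path, annotation: pd.DataFrame | None = None, stage: str = "normalized") -> ExpressionMatrix:
    """Expression TSV: first column ``probe``, one column per sample.

    Duplicated probe ids are rejected (duplicates must be collapsed by
    name upstream, before preprocessing).
    """
    frame = pd.read_csv(path, sep="\t")
    if "probe" not in frame.columns:
        raise ValueError("expression TSV lacks mandatory column 'probe'")
    if frame["probe"].duplicated().any():
        dups = frame.loc[frame["probe"].duplicated(), "probe"].tolist()
        raise ValueError(f"expression TSV has duplicated probe ids: {dups[:5]}")
    samples = [c for c in frame.columns if c != "probe"]
    probes = pd.DataFrame({"probe": frame["probe"]})
    if annotation is not None:
        probes = probes.merge(annotation, on="probe", how="left")
    return ExpressionMatrix(frame[samples].to_numpy(dtype=float), probes, samples, stage=stage)


def write_expression(expression: ExpressionMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(expression.values, columns=expression.samples)
    frame.insert(0, "probe", expression.probes["probe"].to_numpy())
    frame.to_csv(path, sep="\t", index=False)


ANNOTATION_COLUMNS = ["probe", "gene_id", "symbol", "rna_class", "chrom", "start", "end", "strand"]


def read_annotation(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"annotation lacks mandatory columns: {missing}")
    return frame


def write_gene_models(models: dict[str, GeneModel], path: str | Path) -> None:
    """BED-like TSV of gene models (1-based inclusive, strand column)."""
    rows = []
    seen = set()
    for model in models.values():
        if model.gene_id in seen:
            continue
        seen.add(model.gene_id)
        rows.append(
            {
                "gene_id": model.gene_id,
                "symbol": model.symbol,
                "chrom": model.chrom,
                "start": model.start,
                "end": model.end,
                "strand": model.strand,
                "exons": ";".join(f"{s}-{e}" for s, e in model.exons),
                "cds_start": model.cds_start if model.cds_start is not None else "",
                "cds_end": model.cds_end if model.cds_end is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | Path) -> dict[str, GeneModel]:
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = {}
    for _, r in frame.iterrows():
        exons = tuple(
            tuple(int(x) for x in part.split("-"))
            for part in str(r.get("exons") or "").split(";")
            if part and part != "nan"
        )
        cs = r.get("cds_start")
        ce = r.get("cds_end")
        out[r["gene_id"]] = GeneModel(
            r["gene_id"], r["symbol"], str(r["chrom"]), int(r["start"]), int(r["end"]),
            r["strand"], exons=exons,
            cds_start=int(cs) if pd.notna(cs) and cs != "" else None,
            cds_end=int(ce) if pd.notna(ce) and ce != "" else None,
        )
    return out


# ---------------------------------------------------------------------------
# sequences


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {record id: uppercased sequence}."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GWAS catalog, aliases, results


def read_gwas_catalog(path: str | Path):
    """GWAS catalog TSV with columns snp, trait, reported_genes, p."""
    from .gwas import GwasRecord

    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in ("snp", "trait", "reported_genes", "p") if c not in frame.columns]
    if missing:
        raise ValueError(f"GWAS catalog lacks mandatory columns: {missing}")
    records = []
    for i, r in frame.iterrows():
        rid = str(r["record_id"]) if "record_id" in frame.columns else f"R{i+1:03d}"
        genes = tuple(str(r["reported_genes"]).split(";")) if pd.notna(r["reported_genes"]) else ()
        records.append(GwasRecord(rid, str(r["snp"]), str(r["trait"]), genes, float(r["p"])))
    return records


def read_alias_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV alias -> canonical symbol."""
    frame = pd.read_csv(path, sep="\t")
    if not {"alias", "symbol"}.issubset(frame.columns):
        raise ValueError("alias table needs columns 'alias' and 'symbol'")
    return dict(zip(frame["alias"].astype(str), frame["symbol"].astype(str)))


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_run_summary(summary: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
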