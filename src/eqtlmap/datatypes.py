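"""Core in-memory containers shared across the pipeline.

Genotypes are held as a samples-in-columns dosage matrix (count of the
*minor* allele, 0/1/2, NaN for missing) with a SNP metadata frame.
Expression is a probe x sample matrix of log2-scale values with a probe
annotation frame carrying the gene model each probe reports on.

All genomic coordinates are 1-based inclusive throughout the package;
:mod:`eqtlmap.io` owns the converters to/from 0-based half-open BED.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

SEX_CHROMS = frozenset({"X", "Y", "chrX", "chrY", "23", "24", "XY", "MT", "chrM"})

#: columns required in a SNP metadata frame
SNP_COLUMNS = ("snp", "chrom", "pos")
#: columns required in a probe annotation frame
PROBE_COLUMNS = ("probe", "gene_id", "symbol", "rna_class", "chrom", "start", "end", "strand")


@dataclass
class GenotypeMatrix:
    """Sample x SNP minor-allele dosages plus per-SNP metadata.

    dosages: (n_snps, n_samples) float array, values in {0,1,2,NaN}.
    snps: frame with at least columns ``snp``, ``chrom``, ``pos`` (1-based).
    samples: sample identifiers, aligned with dosage columns.
    """

    dosages: np.ndarray
    snps: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.snps), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.snps)} SNPs x {len(self.samples)} samples"
            )
        missing = [c for c in SNP_COLUMNS if c not in self.snps.columns]
        if missing:
            raise ValueError(f"SNP table lacks columns: {missing}")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    def snp_index(self) -> pd.Index:
        return pd.Index(self.snps["snp"])

    def dosage(self, snp_id: str) -> np.ndarray:
        """Dosage vector for one SNP id."""
        idx = self.snps.index[self.snps["snp"] == snp_id]
        if len(idx) == 0:
            raise KeyError(f"unknown SNP id {snp_id!r}")
        return self.dosages[idx[0]]

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(self.dosages[mask], self.snps.loc[mask].reset_index(drop=True), list(self.samples))

    def reorder_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        try:
            order = [pos[s] for s in sample_ids]
        except KeyError as e:
            raise ValueError(f"sample {e.args[0]!r} absent from genotype matrix") from None
        return GenotypeMatrix(self.dosages[:, order], self.snps.copy(), list(sample_ids))


@dataclass
class ExpressionMatrix:
    """Probe x sample expression values with a stage tag.

    stage is one of ``raw`` (linear intensities), ``normalized`` (log2,
    per-sample 75th percentile shifted to 0) or ``adjusted`` (residuals
    after covariate/surrogate-variable regression).
    """

    values: np.ndarray
    probes: pd.DataFrame
    samples: list[str]
    stage: str = "raw"
    #: per-probe median on the *normalized* scale, carried through adjustment
    #: for the low-expression filter of the trans cascade.
    normalized_medians: pd.Series | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probes), len(self.samples)):
            raise ValueError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.probes)} probes x {len(self.samples)} samples"
            )
        if "probe" not in self.probes.columns:
            raise ValueError("probe table lacks column 'probe'")
        if self.probes["probe"].duplicated().any():
            dups = self.probes.loc[self.probes["probe"].duplicated(), "probe"].tolist()
            raise ValueError(f"duplicated probe ids: {dups[:5]}")
        self.probes = self.probes.reset_index(drop=True)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def probe_values(self, probe_id: str) -> np.ndarray:
        idx = self.probes.index[self.probes["probe"] == probe_id]
        if len(idx) == 0:
            raise KeyError(f"unknown probe id {probe_id!r}")
        return self.values[idx[0]]

    def subset_probes(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        med = self.normalized_medians
        if med is not None:
            med = med[np.asarray(self.probes.loc[mask, "probe"])]
        return ExpressionMatrix(
            self.values[mask],
            self.probes.loc[mask].reset_index(drop=True),
            list(self.samples),
            stage=self.stage,
            normalized_medians=med,
        )

    def with_values(self, values: np.ndarray, stage: str) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values, self.probes.copy(), list(self.samples), stage=stage,
            normalized_medians=self.normalized_medians,
        )

    def reorder_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        try:
            order = [pos[s] for s in sample_ids]
        except KeyError as e:
            raise ValueError(f"sample {e.args[0]!r} absent from expression matrix") from None
        return ExpressionMatrix(
            self.values[:, order], self.probes.copy(), list(sample_ids),
            stage=self.stage, normalized_medians=self.normalized_medians,
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene (or probe target) model with optional exon/CDS structure.

    start/end are the transcription start and end in genomic orientation
    (start <= end); TSS is ``start`` on the + strand and ``end`` on the
    - strand. Exons are 1-based inclusive (start, end) pairs; cds_start /
    cds_end delimit the translated region for coding genes.
    """

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = ()
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


def fold_change(beta: float) -> float:
    """Fold change in expression between the two homozygote classes.

    With log2 expression and a per-minor-allele coefficient beta, the
    expected difference between dosage-2 and dosage-0 homozygotes is
    2*beta log2 units, i.e. a 2**(2*|beta|)-fold change.
    """
    return float(2.0 ** (2.0 * abs(beta)))


def percent(numerator: float, denominator: float) -> float:
    """Percentage ``100 * numerator / denominator`` (denominator > 0)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * numerator / denominator
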