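"""SNP-level quality control and linkage disequilibrium.

QC drops SNPs with missing rate > 1%, Hardy-Weinberg exact-test
P < 1e-7, minor allele frequency < 5%, or a sex-chromosome location;
the boundary MAF = 5% is retained. LD between SNPs is the squared
Pearson correlation of dosage vectors over pairwise-complete samples
(composite, phase-free r^2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datatypes import SEX_CHROMS, GenotypeMatrix

logger = logging.getLogger(__name__)


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact Hardy-Weinberg equilibrium test P value.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count whose conditional probability does not exceed
    that of the observed count (the plain exact test; no mid-P).
    """
    counts = (n_hom_major, n_het, n_hom_minor)
    if any(c < 0 for c in counts):
        raise ValueError(f"genotype counts must be non-negative, got {counts}")
    n = sum(counts)
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_minor = 2 * n_hom_minor + n_het
    n_minor = min(n_minor, 2 * n - n_minor)  # orient to the rarer allele
    log_probs = _hwe_log_probs(n, n_minor)
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    obs_lp = log_probs[hets == n_het][0]
    # tolerance for ties in floating-point probabilities
    p = float(np.exp(log_probs[log_probs <= obs_lp + 1e-10]).sum())
    return min(p, 1.0)


def _hwe_log_probs(n: int, n_minor: int) -> np.ndarray:
    """Log conditional probabilities of each feasible heterozygote count.

    P(het = k | n, n_minor) for k in {n_minor mod 2, ..., n_minor} step 2.
    """
    k = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - k) // 2
    hom_major = n - hom_minor - k
    lp = (
        gammaln(n + 1)
        - gammaln(hom_major + 1)
        - gammaln(k + 1)
        - gammaln(hom_minor + 1)
        + k * np.log(2.0)
        + gammaln(n_minor + 1)
        + gammaln(2 * n - n_minor + 1)
        - gammaln(2 * n + 1)
    )
    # normalize in log space for numerical safety
    m = lp.max()
    lp -= m + np.log(np.exp(lp - m).sum())
    return lp


def snp_statistics(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP MAF, HWE exact P and missing rate (MAF after missing exclusion)."""
    d = genotypes.dosages
    n_samples = d.shape[1]
    miss = np.isnan(d)
    missing_rate = miss.mean(axis=1)
    n_obs = n_samples - miss.sum(axis=1)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(d, axis=1) / (2 * np.maximum(n_obs, 1))
    maf = np.minimum(freq, 1 - freq)
    hwe_p = np.ones(genotypes.n_snps)
    for i in range(genotypes.n_snps):
        row = d[i][~miss[i]]
        if row.size == 0:
            hwe_p[i] = np.nan
            continue
        n0 = int((row == 0).sum())
        n1 = int((row == 1).sum())
        n2 = int((row == 2).sum())
        hwe_p[i] = hwe_exact_test(n0, n1, n2)
    out = genotypes.snps.copy()
    out["maf"] = maf
    out["hwe_p"] = hwe_p
    out["missing_rate"] = missing_rate
    return out


def qc_filter(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.05,
    missing_max: float = 0.01,
    hwe_min: float = 1e-7,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the SNP QC thresholds; return retained genotypes and a report.

    A SNP is retained iff missing_rate <= missing_max, HWE-P >= hwe_min,
    MAF >= maf_min (boundary kept) and it is autosomal. The report carries
    per-SNP statistics, per-criterion flags, and a pass column.
    """
    stats = snp_statistics(genotypes)
    fail_missing = stats["missing_rate"].to_numpy() > missing_max
    fail_hwe = stats["hwe_p"].to_numpy() < hwe_min
    fail_maf = stats["maf"].to_numpy() < maf_min
    fail_sex = stats["chrom"].astype(str).isin(SEX_CHROMS).to_numpy()
    keep = ~(fail_missing | fail_hwe | fail_maf | fail_sex)
    report = stats.copy()
    report["fail_missing"] = fail_missing
    report["fail_hwe"] = fail_hwe
    report["fail_maf"] = fail_maf
    report["fail_sex_chrom"] = fail_sex
    report["pass"] = keep
    logger.info(
        "genotype QC: %d in, %d out (missing %d, HWE %d, MAF %d, sex-chrom %d)",
        len(keep), int(keep.sum()), int(fail_missing.sum()), int(fail_hwe.sum()),
        int(fail_maf.sum()), int(fail_sex.sum()),
    )
    if not keep.any():
        raise ValueError("QC removed every SNP; review thresholds")
    return genotypes.subset_snps(keep), report


@dataclass(frozen=True)
class LdResult:
    snp_a: str
    snp_b: str
    r2: float  # NaN when undefined (constant vector)
    n: int


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray, snp_a: str = "a", snp_b: str = "b") -> LdResult:
    """Squared Pearson correlation of two dosage vectors (pairwise complete).

    Returns r2 = NaN when fewer than two complete pairs exist or either
    vector is constant over the complete pairs.
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    n = int(ok.sum())
    if n < 2:
        return LdResult(snp_a, snp_b, np.nan, n)
    a, b = a[ok], b[ok]
    va = a - a.mean()
    vb = b - b.mean()
    denom = (va @ va) * (vb @ vb)
    if denom == 0:
        return LdResult(snp_a, snp_b, np.nan, n)
    r2 = float((va @ vb) ** 2 / denom)
    return LdResult(snp_a, snp_b, min(r2, 1.0), n)


def ld_r2_matrix(dosages: np.ndarray) -> np.ndarray:
    """Pairwise r^2 among the rows of a dosage matrix (no missing values)."""
    d = np.asarray(dosages, dtype=float)
    if np.isnan(d).any():
        # fall back to pairwise-complete via the scalar routine
        k = d.shape[0]
        out = np.empty((k, k))
        for i in range(k):
            for j in range(i, k):
                r2 = ld_r2(d[i], d[j]).r2
                out[i, j] = out[j, i] = r2
        return out
    c = np.corrcoef(d)
    return c**2
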