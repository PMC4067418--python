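"""Local/distant pair classification and the additive single-SNP model.

A SNP is *local* to a gene when it sits on the same chromosome within
500 kb of the nearest transcription start/end site (boundary inclusive),
and *distant* otherwise. The association model is a simple least-squares
regression of adjusted log2 expression on minor-allele dosage (0/1/2):
beta is the per-allele slope, R^2 the squared dosage-expression
correlation, and the P value a two-sided t test on the slope with n - 2
degrees of freedom. Missing dosages are dropped pairwise per SNP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Literal

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, GeneModel, GenotypeMatrix

logger = logging.getLogger(__name__)

CIS_WINDOW = 500_000


@dataclass(frozen=True)
class PairRelation:
    snp: str
    probe: str
    relation: Literal["local", "distant"]
    distance: float  # signed bp; NaN for different chromosomes


@dataclass(frozen=True)
class AssociationResult:
    snp: str
    probe: str
    beta: float
    r2: float
    p_value: float
    n: int


def signed_distance(pos: int, gene: GeneModel) -> float:
    """Signed distance from a same-chromosome SNP to a gene.

    0 inside [start, end]; otherwise distance to the nearest transcription
    start/end site, negative upstream and positive downstream of the gene
    in its transcriptional direction.
    """
    if gene.contains(pos):
        return 0.0
    if pos < gene.start:
        d = gene.start - pos
        return -float(d) if gene.strand == "+" else float(d)
    d = pos - gene.end
    return float(d) if gene.strand == "+" else -float(d)


def classify_pair(snp_chrom: str, snp_pos: int, gene: GeneModel, snp: str = "", probe: str = "", window: int = CIS_WINDOW) -> PairRelation:
    """Classify one SNP-gene pair as local or distant with its signed distance."""
    if str(snp_chrom) != str(gene.chrom):
        return PairRelation(snp, probe, "distant", float("nan"))
    d = signed_distance(int(snp_pos), gene)
    relation = "local" if abs(d) <= window else "distant"
    return PairRelation(snp, probe, relation, d)


def _assoc_stats(dosages: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorized slope/R^2/P/n for each dosage row against one phenotype.

    NaN-aware (pairwise complete per SNP). Returns (beta, r2, p, n); rows
    with constant dosage or n < 3 come back as NaN.
    """
    g = np.atleast_2d(np.asarray(dosages, dtype=float))
    y = np.asarray(y, dtype=float)
    mask = ~np.isnan(g)
    n = mask.sum(axis=1).astype(float)
    g0 = np.where(mask, g, 0.0)
    yb = np.broadcast_to(y, g.shape)
    y0 = np.where(mask, yb, 0.0)
    sx = g0.sum(axis=1)
    sy = y0.sum(axis=1)
    sxx = (g0 * g0).sum(axis=1)
    syy = (y0 * y0).sum(axis=1)
    sxy = (g0 * y0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        cxy = sxy - sx * sy / n
        beta = cxy / vx
        r2 = np.where(vy > 0, cxy**2 / (vx * vy), np.nan)
        df = n - 2
        denom = np.clip(1.0 - r2, 1e-300, None)
        t2 = r2 * df / denom
        p = stats.f.sf(t2, 1, df)  # t^2 on 1 and n-2 df == two-sided t test
    bad = (vx <= 0) | (n < 3)
    beta = np.where(bad, np.nan, beta)
    r2 = np.where(bad, np.nan, np.clip(r2, 0.0, 1.0))
    p = np.where(bad | ~np.isfinite(p), np.nan, np.clip(p, 0.0, 1.0))
    # exact fits: P underflows to 0, keep as 0
    return beta, r2, p, n.astype(int)


def fit_additive(dosage: np.ndarray, expression: np.ndarray, snp: str = "", probe: str = "") -> AssociationResult:
    """Fit the additive model for one SNP-transcript pair."""
    beta, r2, p, n = _assoc_stats(np.asarray(dosage)[None, :], expression)
    if np.isnan(beta[0]):
        raise ValueError("dosage is constant or has fewer than 3 non-missing samples")
    return AssociationResult(snp, probe, float(beta[0]), float(r2[0]), float(p[0]), int(n[0]))


def local_snp_indices(
    genotypes: GenotypeMatrix, gene: GeneModel, window: int = CIS_WINDOW
) -> np.ndarray:
    """Indices of SNPs local to a gene (same chromosome, within the window)."""
    snps = genotypes.snps
    on_chr = (snps["chrom"].astype(str) == str(gene.chrom)).to_numpy()
    if not on_chr.any():
        return np.empty(0, dtype=int)
    pos = snps["pos"].to_numpy()
    within = (pos >= gene.start - window) & (pos <= gene.end + window)
    return np.flatnonzero(on_chr & within)


def scan(
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    gene_models: dict[str, GeneModel],
    mode: Literal["local", "distant", "all"] = "local",
    window: int = CIS_WINDOW,
) -> Iterator[pd.DataFrame]:
    """Stream association results one transcript at a time.

    gene_models maps probe id -> GeneModel for the probe's target. Yields
    one frame per transcript with columns snp/probe/beta/r2/p_value/n/
    relation/distance; constant-dosage SNPs are excluded. Memory is bounded
    by the largest per-transcript SNP set.
    """
    if list(genotypes.samples) != list(expression.samples):
        raise ValueError("genotype and expression sample sets are not aligned")
    emitted = False
    snps = genotypes.snps
    pos = snps["pos"].to_numpy()
    for pi, probe_id in enumerate(expression.probes["probe"]):
        gene = gene_models.get(probe_id)
        if gene is None:
            continue
        local_idx = local_snp_indices(genotypes, gene, window)
        if mode == "local":
            idx = local_idx
        elif mode == "distant":
            keep = np.ones(genotypes.n_snps, dtype=bool)
            keep[local_idx] = False
            idx = np.flatnonzero(keep)
        else:
            idx = np.arange(genotypes.n_snps)
        if idx.size == 0:
            continue
        y = expression.values[pi]
        beta, r2, p, n = _assoc_stats(genotypes.dosages[idx], y)
        ok = ~np.isnan(beta)
        if not ok.any():
            continue
        idx = idx[ok]
        same_chr = (snps["chrom"].iloc[idx].astype(str) == str(gene.chrom)).to_numpy()
        dist = np.full(idx.size, np.nan)
        if same_chr.any():
            dist[same_chr] = [signed_distance(int(p_), gene) for p_ in pos[idx][same_chr]]
        relation = np.where(same_chr & (np.abs(dist) <= window), "local", "distant")
        frame = pd.DataFrame(
            {
                "snp": snps["snp"].iloc[idx].to_numpy(),
                "chrom": snps["chrom"].iloc[idx].to_numpy(),
                "pos": pos[idx],
                "probe": probe_id,
                "beta": beta[ok],
                "r2": r2[ok],
                "p_value": p[ok],
                "n": n[ok],
                "relation": relation,
                "distance": dist,
            }
        )
        emitted = True
        yield frame
    if not emitted:
        logger.warning("scan emitted no eligible pairs")


def scan_table(*args, **kwargs) -> pd.DataFrame:
    """Materialize :func:`scan` into a single frame (desk-scale inputs)."""
    frames = list(scan(*args, **kwargs))
    if not frames:
        return pd.DataFrame(
            columns=["snp", "chrom", "pos", "probe", "beta", "r2", "p_value", "n", "relation", "distance"]
        )
    return pd.concat(frames, ignore_index=True)
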