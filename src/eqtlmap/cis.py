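"""Cis-eQTL calling by permutation FDR on per-transcript minimum P values.

The null distribution is built by shuffling expression sample labels
against genotypes (one global shuffle per permutation round, preserving
the correlation structure among transcripts), re-running the local scan,
and keeping only each transcript's smallest P. The FDR at an observed
minimum P value p is

    FDR(p) = mean_over_permutations #{null min-P <= p} / #{observed min-P <= p},

monotonized to be non-decreasing in p and clipped to [0, 1]. Transcripts
with FDR < 5% yield at most one cis-eQTL each: the local SNP with the
smallest P, with perfect-LD ties broken to the middle genomic position.
Calls are finally screened with a Kruskal-Wallis test across genotype
classes (retained when P <= 1.5e-4).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import CIS_WINDOW, local_snp_indices, _assoc_stats, signed_distance
from .datatypes import ExpressionMatrix, GeneModel, GenotypeMatrix
from .genotype_qc import ld_r2_matrix

logger = logging.getLogger(__name__)


def _local_min_p(
    genotypes: GenotypeMatrix,
    expr_values: np.ndarray,
    probe_ids: Sequence[str],
    gene_models: dict[str, GeneModel],
    local_cache: dict[str, np.ndarray],
) -> np.ndarray:
    """Per-transcript minimum local P value (NaN when no testable local SNP)."""
    out = np.full(len(probe_ids), np.nan)
    for i, probe_id in enumerate(probe_ids):
        idx = local_cache.get(probe_id)
        if idx is None or idx.size == 0:
            continue
        _, _, p, _ = _assoc_stats(genotypes.dosages[idx], expr_values[i])
        if np.isfinite(p).any():
            out[i] = np.nanmin(p)
    return out


def _build_local_cache(
    genotypes: GenotypeMatrix,
    probe_ids: Sequence[str],
    gene_models: dict[str, GeneModel],
    window: int,
) -> dict[str, np.ndarray]:
    return {
        probe_id: local_snp_indices(genotypes, gene_models[probe_id], window)
        for probe_id in probe_ids
        if probe_id in gene_models
    }


def permute_min_p(
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    gene_models: dict[str, GeneModel],
    n_perm: int = 10,
    seed: int = 0,
    window: int = CIS_WINDOW,
    permutations: Sequence[np.ndarray] | None = None,
) -> pd.DataFrame:
    """Null per-transcript minimum P values (transcript x permutation).

    ``permutations`` is a test hook: explicit sample-index permutations to
    use instead of seeded random shuffles (e.g. the identity).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    probe_ids = list(expression.probes["probe"])
    cache = _build_local_cache(genotypes, probe_ids, gene_models, window)
    rng = np.random.default_rng(seed)
    n = expression.n_samples
    cols = {}
    for b in range(n_perm):
        if permutations is not None:
            perm = np.asarray(permutations[b])
        else:
            perm = rng.permutation(n)
        shuffled = expression.values[:, perm]
        cols[f"perm{b+1}"] = _local_min_p(genotypes, shuffled, probe_ids, gene_models, cache)
    return pd.DataFrame(cols, index=probe_ids)


def observed_min_p(
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    gene_models: dict[str, GeneModel],
    window: int = CIS_WINDOW,
) -> pd.Series:
    probe_ids = list(expression.probes["probe"])
    cache = _build_local_cache(genotypes, probe_ids, gene_models, window)
    return pd.Series(
        _local_min_p(genotypes, expression.values, probe_ids, gene_models, cache), index=probe_ids
    )


def estimate_fdr(observed: pd.Series, null_matrix: pd.DataFrame) -> pd.Series:
    """FDR at each observed per-transcript minimum P value.

    observed: per-transcript minimum P (NaN = untestable transcript).
    null_matrix: transcript x permutation null minimum P values.
    """
    if null_matrix.size == 0:
        raise ValueError("null matrix is empty")
    obs = observed.dropna()
    null_vals = np.sort(null_matrix.to_numpy().ravel())
    null_vals = null_vals[~np.isnan(null_vals)]
    n_perm = null_matrix.shape[1]
    obs_sorted = np.sort(obs.to_numpy())
    fdr = np.empty(len(obs))
    pvals = obs.to_numpy()
    n_null_le = np.searchsorted(null_vals, pvals, side="right") / n_perm
    n_obs_le = np.searchsorted(obs_sorted, pvals, side="right")
    fdr = n_null_le / n_obs_le
    # monotonize: FDR must be non-decreasing in p (step-up from the largest p)
    order = np.argsort(pvals)
    f = fdr[order]
    f = np.minimum.accumulate(f[::-1])[::-1]
    fdr[order] = f
    out = pd.Series(np.clip(fdr, 0.0, 1.0), index=obs.index)
    return out.reindex(observed.index)


def select_representative(
    tied_snps: pd.DataFrame, genotypes: GenotypeMatrix | None = None
) -> tuple[int, bool]:
    """Pick one SNP among equally significant top SNPs for a transcript.

    tied_snps: frame with columns ``snp`` and ``pos`` (rows sorted or not).
    When all pairwise dosage r^2 equal 1, the SNP at the median genomic
    position wins (even-sized sets take the lower of the two middles).
    Otherwise perfect-LD tie-breaking does not apply: the smallest-position
    SNP is chosen and flagged. Returns (row index within tied_snps,
    perfect_ld flag).
    """
    if len(tied_snps) == 1:
        return tied_snps.index[0], True
    order = tied_snps["pos"].to_numpy().argsort(kind="stable")
    perfect = True
    if genotypes is not None:
        d = np.stack([genotypes.dosage(s) for s in tied_snps["snp"]])
        r2 = ld_r2_matrix(d)
        iu = np.triu_indices(len(tied_snps), k=1)
        perfect = bool(np.all(r2[iu] > 1 - 1e-9))
    if perfect:
        mid = order[(len(order) - 1) // 2]
    else:
        logger.warning(
            "tied top SNPs not in perfect LD for transcript; choosing smallest position"
        )
        mid = order[0]
    return tied_snps.index[mid], perfect


def kruskal_wallis(dosage: np.ndarray, expression: np.ndarray) -> float:
    """Kruskal-Wallis P across the observed genotype classes (0/1/2).

    Tie correction per the standard H statistic; all-equal values give
    H = 0, P = 1. A single genotype class is untestable (ValueError).
    """
    g = np.asarray(dosage, dtype=float)
    y = np.asarray(expression, dtype=float)
    ok = ~np.isnan(g)
    g, y = g[ok], y[ok]
    groups = [y[g == v] for v in np.unique(g)]
    if len(groups) < 2:
        raise ValueError("need at least 2 genotype groups for Kruskal-Wallis")
    if np.all(y == y[0]):
        return 1.0
    return float(stats.kruskal(*groups).pvalue)


def call_cis(
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    gene_models: dict[str, GeneModel],
    fdr_max: float = 0.05,
    kw_alpha: float = 0.00015,
    n_perm: int = 10,
    seed: int = 0,
    window: int = CIS_WINDOW,
) -> pd.DataFrame:
    """Full cis-eQTL calling: scan, permutation FDR, tie-break, Kruskal-Wallis.

    Returns one row per transcript whose FDR < ``fdr_max``, with columns
    snp/chrom/pos/probe/beta/r2/p_value/n/distance/fdr/kw_p/perfect_ld_tie/
    kw_pass. Rows with kw_pass=False are cis candidates removed by the
    Kruskal-Wallis screen; they are kept in the frame (flagged) because the
    trans cascade's cis-capture filter must still condition on them.
    """
    probe_ids = list(expression.probes["probe"])
    cache = _build_local_cache(genotypes, probe_ids, gene_models, window)
    obs = observed_min_p(genotypes, expression, gene_models, window)
    null = permute_min_p(genotypes, expression, gene_models, n_perm=n_perm, seed=seed, window=window)
    fdr = estimate_fdr(obs, null)
    rows = []
    for i, probe_id in enumerate(probe_ids):
        f = fdr.get(probe_id, np.nan)
        if not np.isfinite(f) or f >= fdr_max:
            continue
        idx = cache.get(probe_id)
        y = expression.values[i]
        beta, r2, p, n = _assoc_stats(genotypes.dosages[idx], y)
        finite = np.isfinite(p)
        pmin = np.nanmin(p[finite])
        tied_mask = finite & (p == pmin)
        tied_idx = idx[tied_mask]
        tied = pd.DataFrame(
            {
                "snp": genotypes.snps["snp"].iloc[tied_idx].to_numpy(),
                "pos": genotypes.snps["pos"].iloc[tied_idx].to_numpy(),
            }
        )
        row_i, perfect = select_representative(tied, genotypes if len(tied) > 1 else None)
        snp_row = tied_idx[row_i]
        j = int(np.flatnonzero(idx == snp_row)[0])
        gene = gene_models[probe_id]
        kw_p = kruskal_wallis(genotypes.dosages[snp_row], y)
        rows.append(
            {
                "snp": genotypes.snps["snp"].iloc[snp_row],
                "chrom": genotypes.snps["chrom"].iloc[snp_row],
                "pos": int(genotypes.snps["pos"].iloc[snp_row]),
                "probe": probe_id,
                "gene_id": gene.gene_id,
                "symbol": gene.symbol,
                "beta": float(beta[j]),
                "r2": float(r2[j]),
                "p_value": float(p[j]),
                "n": int(n[j]),
                "distance": signed_distance(int(genotypes.snps["pos"].iloc[snp_row]), gene),
                "fdr": float(f),
                "kw_p": kw_p,
                "perfect_ld_tie": perfect,
                "kw_pass": kw_p <= kw_alpha,
            }
        )
    cols = [
        "snp", "chrom", "pos", "probe", "gene_id", "symbol", "beta", "r2", "p_value",
        "n", "distance", "fdr", "kw_p", "perfect_ld_tie", "kw_pass",
    ]
    out = pd.DataFrame(rows, columns=cols)
    logger.info("cis calling: %d transcripts at FDR<%g, %d pass Kruskal-Wallis",
                len(out), fdr_max, int(out["kw_pass"].sum()) if len(out) else 0)
    return out
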