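"""Expression normalization, probe filtering and covariate adjustment.

The normalization follows the microarray convention used for Agilent
single-channel data: duplicate probe spots are averaged, intensities are
floored at 1, log2-transformed, and each sample (chip) is shifted so its
75th percentile is 0. Probes without genomic coordinates, on sex
chromosomes, or overlapping known polymorphic sites are dropped; there is
deliberately no abundance filter at this stage.

Hidden expression heterogeneity is estimated with a two-step surrogate
variable analysis: residualize on the known covariates, then keep the
leading right singular vectors of the residual matrix whose variance
shares exceed a permutation null (parallel-analysis style). Adjusted
expression is the per-probe OLS residual on age, sex and the surrogate
variables.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import SEX_CHROMS, ExpressionMatrix

logger = logging.getLogger(__name__)


def collapse_duplicates(intensities: pd.DataFrame, probe_names: pd.Series | None = None) -> pd.DataFrame:
    """Average duplicated probe spots: one row per probe name.

    intensities: spot x sample frame (index = spot id). probe_names maps
    each spot to its probe name; when omitted the index is the probe name.
    """
    names = intensities.index.to_series() if probe_names is None else probe_names
    if len(names) != len(intensities):
        raise ValueError("probe-name map length does not match intensity rows")
    if names.isna().any():
        raise ValueError("probe-name map contains missing names")
    out = intensities.groupby(np.asarray(names), sort=False).mean()
    out.index.name = "probe"
    return out


def normalize_75th(intensities: pd.DataFrame | ExpressionMatrix) -> ExpressionMatrix:
    """Floor at 1, log2-transform, and shift each sample's 75th percentile to 0.

    Idempotent: a matrix already at stage ``normalized`` is only re-shifted
    (a no-op, since its per-sample 75th percentile is already 0).
    """
    if isinstance(intensities, ExpressionMatrix):
        if intensities.stage == "normalized":
            values = intensities.values - np.percentile(intensities.values, 75, axis=0)
            return intensities.with_values(values, "normalized")
        if intensities.stage != "raw":
            raise ValueError(f"cannot normalize stage {intensities.stage!r}")
        frame = pd.DataFrame(intensities.values, index=intensities.probes["probe"], columns=intensities.samples)
        probes = intensities.probes
    else:
        frame = intensities
        probes = pd.DataFrame({"probe": frame.index})
    arr = frame.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        bad = np.argwhere(~np.isfinite(arr))[0]
        raise ValueError(
            f"non-finite intensity at probe {frame.index[bad[0]]!r}, sample {frame.columns[bad[1]]!r}"
        )
    arr = np.maximum(arr, 1.0)
    arr = np.log2(arr)
    arr -= np.percentile(arr, 75, axis=0)
    em = ExpressionMatrix(arr, probes.copy().reset_index(drop=True), [str(c) for c in frame.columns], stage="normalized")
    em.normalized_medians = pd.Series(np.median(arr, axis=1), index=em.probes["probe"].to_numpy())
    return em


def filter_probes(
    expression: ExpressionMatrix,
    polymorphic_sites: pd.DataFrame | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Drop unmapped, sex-chromosome, and polymorphism-overlapping probes.

    polymorphic_sites: frame with columns ``chrom``, ``pos`` (1-based) of
    sites known polymorphic; a probe fails if its target interval
    [start, end] contains any such site. Expression abundance is *not*
    filtered here.
    """
    probes = expression.probes
    for col in ("chrom", "start", "end"):
        if col not in probes.columns:
            raise ValueError(f"probe annotation lacks column {col!r}")
    chrom = probes["chrom"].astype(str)
    no_position = probes["chrom"].isna() | probes["start"].isna() | probes["end"].isna() | (chrom == "")
    sex = chrom.isin(SEX_CHROMS) & ~no_position
    overlaps = np.zeros(len(probes), dtype=bool)
    if polymorphic_sites is not None and len(polymorphic_sites):
        for chr_name, sites in polymorphic_sites.groupby("chrom"):
            pos = np.sort(sites["pos"].to_numpy())
            on_chr = (chrom == str(chr_name)) & ~no_position
            if not on_chr.any():
                continue
            starts = probes.loc[on_chr, "start"].to_numpy(dtype=float)
            ends = probes.loc[on_chr, "end"].to_numpy(dtype=float)
            # a site falls inside [start, end] iff count(pos <= end) > count(pos < start)
            hit = np.searchsorted(pos, ends, side="right") > np.searchsorted(pos, starts, side="left")
            overlaps[np.flatnonzero(on_chr.to_numpy())] = hit
    keep = ~(no_position.to_numpy() | sex.to_numpy() | overlaps)
    report = pd.DataFrame(
        {
            "probe": probes["probe"],
            "fail_no_position": no_position.to_numpy(),
            "fail_sex_chrom": sex.to_numpy(),
            "fail_polymorphic": overlaps,
            "pass": keep,
        }
    )
    logger.info(
        "probe filter: %d in, %d out (no position %d, sex-chrom %d, polymorphic %d)",
        len(keep), int(keep.sum()), int(no_position.sum()), int(sex.sum()), int(overlaps.sum()),
    )
    return expression.subset_probes(keep), report


def _residualize(values: np.ndarray, design: np.ndarray) -> np.ndarray:
    """OLS residuals of each row of ``values`` on the columns of ``design``."""
    q, _ = np.linalg.qr(design)
    return values - (values @ q) @ q.T


def estimate_surrogate_variables(
    expression: ExpressionMatrix,
    covariates: pd.DataFrame,
    n_perm: int = 20,
    alpha: float = 0.05,
    max_k: int | None = None,
    force_k: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Estimate surrogate variables from the covariate-residual matrix.

    Residualize each probe on an intercept plus the known covariates, take
    the SVD of the residual matrix, and keep leading components whose
    variance shares exceed the permutation null built by independently
    permuting each probe's residuals across samples (``n_perm`` rounds,
    component kept while its empirical P < ``alpha``; stops at the first
    non-significant component). Returns a sample x SV frame of mutually
    orthogonal unit-norm vectors (possibly zero columns).

    ``force_k`` bypasses the significance decision and returns exactly k
    leading components.
    """
    if list(covariates.index) != list(expression.samples):
        covariates = covariates.loc[expression.samples]
    x = np.column_stack([np.ones(expression.n_samples), covariates.to_numpy(dtype=float)])
    if expression.n_samples < x.shape[1] + 2:
        raise ValueError("need at least n_covariates + 2 samples for SVA")
    resid = _residualize(expression.values, x)
    u, s, vt = np.linalg.svd(resid, full_matrices=False)
    shares = s**2 / (s**2).sum()
    limit = len(s) if max_k is None else min(max_k, len(s))
    if force_k is not None:
        k = min(force_k, limit)
    else:
        rng = np.random.default_rng(seed)
        null_shares = np.empty((n_perm, limit))
        for b in range(n_perm):
            perm = np.array([rng.permutation(row) for row in resid])
            perm = _residualize(perm, x)
            ps = np.linalg.svd(perm, compute_uv=False)
            ps = ps**2 / (ps**2).sum()
            null_shares[b] = ps[:limit]
        k = 0
        for i in range(limit):
            p = (1 + (null_shares[:, i] >= shares[i]).sum()) / (n_perm + 1)
            if p < alpha:
                k += 1
            else:
                break
    svs = vt[:k].T  # samples x k, orthonormal rows of V^T -> orthonormal columns
    # guard against re-discovering a supplied covariate
    keep = []
    for j in range(k):
        corrs = []
        for c in range(covariates.shape[1]):
            col = covariates.iloc[:, c].to_numpy(dtype=float)
            if np.std(col) == 0:
                continue
            corrs.append(abs(np.corrcoef(svs[:, j], col)[0, 1]))
        if not corrs or max(corrs) <= 0.99:
            keep.append(j)
        else:
            logger.warning("surrogate variable %d duplicates a known covariate; dropped", j + 1)
    svs = svs[:, keep]
    return pd.DataFrame(svs, index=list(expression.samples), columns=[f"SV{i+1}" for i in range(svs.shape[1])])


def adjust_expression(expression: ExpressionMatrix, covariates: pd.DataFrame) -> ExpressionMatrix:
    """Residualize each probe on an intercept plus all covariate columns.

    ``covariates`` is a sample x covariate frame (age, sex, SV1..SVK). The
    returned matrix has stage ``adjusted`` and keeps the pre-adjustment
    normalized medians as metadata for the low-expression filter.
    """
    missing = [s for s in expression.samples if s not in covariates.index]
    if missing:
        raise ValueError(f"covariate table lacks samples: {missing[:5]}")
    cov = covariates.loc[list(expression.samples)]
    design = np.column_stack([np.ones(expression.n_samples), cov.to_numpy(dtype=float)])
    names = ["intercept", *cov.columns]
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        collinear = []
        cols = design[:, :1]
        for j in range(1, design.shape[1]):
            cand = np.column_stack([cols, design[:, j]])
            if np.linalg.matrix_rank(cand) == cols.shape[1]:
                collinear.append(names[j])
            else:
                cols = cand
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    resid = _residualize(expression.values, design)
    out = expression.with_values(resid, "adjusted")
    if out.normalized_medians is None and expression.stage == "normalized":
        out.normalized_medians = pd.Series(
            np.median(expression.values, axis=1), index=expression.probes["probe"].to_numpy()
        )
    return out
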