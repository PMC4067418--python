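"""Trans-eQTL calling: Bonferroni threshold plus the exclusion cascade.

Candidates are distant SNP-transcript pairs below the family-wise
Bonferroni threshold alpha / (#probes x #SNPs - #local pairs). They then
pass, in order:

1. cis-capture filter — same-chromosome candidates whose transcript has a
   cis-eQTL (including cis candidates removed by the Kruskal-Wallis
   screen) must stay associated with the residuals after regressing out
   the cis-eQTL dosage (P < 0.05);
2. sequential conditional pruning — per transcript and candidate
   chromosome, candidates are tested in ascending-P order against running
   residuals; significant ones are kept and update the residuals,
   non-significant ones are dropped without updating;
3. joint model — all kept candidates for a transcript enter one multiple
   regression; terms with P > 0.05 are removed (single pass);
4. cross-hybridization screen — a candidate is dropped when its probe's
   sequence maps (local alignment at >= 30% of maximum score) into the
   +/-500 kb flank of the SNP;
5. low-expression filter — transcripts whose median normalized expression
   falls below the 5th percentile of the cis-regulated transcripts'
   medians are dropped;
6. Kruskal-Wallis confirmation at P <= 1.5e-4.

Missing dosages are mean-imputed inside the conditional and joint fits
(the primary scan P values remain pairwise complete-case).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .alignment import probe_maps_to_flank
from .association import _assoc_stats
from .datatypes import ExpressionMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)

FILTER_STEPS = ("cis_capture", "ld_redundant", "joint_model", "cross_hyb", "low_expression", "kw")


def bonferroni_threshold(
    n_probes: int, n_snps: int, n_local_pairs: int, family_alpha: float = 0.05
) -> float:
    """Per-test alpha for the distant-pair family: alpha / #distant tests."""
    if n_probes <= 0 or n_snps <= 0 or n_local_pairs < 0:
        raise ValueError("counts must be positive (local pairs non-negative)")
    n_tests = n_probes * n_snps - n_local_pairs
    if n_tests <= 0:
        raise ValueError("no distant tests: local pairs exhaust the grid")
    return family_alpha / n_tests


def _impute(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float).copy()
    nan = np.isnan(d)
    if nan.any():
        d[nan] = np.nanmean(d)
    return d


def _ols_residuals(y: np.ndarray, x_cols: list[np.ndarray]) -> np.ndarray:
    x = np.column_stack([np.ones(len(y)), *x_cols])
    q, _ = np.linalg.qr(x)
    return y - q @ (q.T @ y)


def _marginal_p(y: np.ndarray, g: np.ndarray) -> float:
    _, _, p, _ = _assoc_stats(g[None, :], y)
    return float(p[0]) if np.isfinite(p[0]) else 1.0


def cis_capture_filter(
    candidate_dosage: np.ndarray,
    cis_dosage: np.ndarray,
    expression: np.ndarray,
    alpha: float = 0.05,
) -> tuple[bool, float]:
    """Does the candidate stay associated after removing the cis effect?

    Regresses expression on the cis-eQTL dosage, then tests the residuals
    against the candidate dosage; returns (pass, conditional P).
    """
    y = np.asarray(expression, dtype=float)
    resid = _ols_residuals(y, [_impute(cis_dosage)])
    p = _marginal_p(resid, _impute(candidate_dosage))
    return p < alpha, p


def sequential_conditional_prune(
    candidates: pd.DataFrame,
    dosages: dict[str, np.ndarray],
    expression: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """LD-redundancy pruning for one transcript on one chromosome.

    candidates: frame with columns ``snp`` and ``p_value`` (any order);
    processed in ascending P. Returns the frame restricted to kept rows
    with an added ``conditional_p`` column.
    """
    y = np.asarray(expression, dtype=float)
    resid = y
    kept_rows = []
    cond_ps = []
    for _, row in candidates.sort_values("p_value", kind="stable").iterrows():
        g = _impute(dosages[row["snp"]])
        p = _marginal_p(resid, g)
        if p < alpha:
            kept_rows.append(row)
            cond_ps.append(p)
            resid = _ols_residuals(resid, [g])
    out = pd.DataFrame(kept_rows)
    if len(out):
        out["conditional_p"] = cond_ps
    return out


def joint_model_check(
    retained: pd.DataFrame,
    dosages: dict[str, np.ndarray],
    expression: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Single-pass joint regression over all retained candidates.

    Fits expression on every retained dosage together and drops terms with
    P > alpha. Collinear columns (in the retained order) are dropped with
    a log message before fitting. Adds a ``joint_p`` column.
    """
    if len(retained) == 0:
        return retained
    y = np.asarray(expression, dtype=float)
    snps = list(retained["snp"])
    cols = [_impute(dosages[s]) for s in snps]
    # drop later-entered collinear columns
    design = np.ones((len(y), 1))
    usable: list[int] = []
    for i, c in enumerate(cols):
        cand = np.column_stack([design, c])
        if np.linalg.matrix_rank(cand) > design.shape[1]:
            design = cand
            usable.append(i)
        else:
            logger.warning("joint model: dropping collinear trans candidate %s", snps[i])
    import statsmodels.api as sm

    x = sm.add_constant(np.column_stack([cols[i] for i in usable]))
    fit = sm.OLS(y, x).fit()
    pvals = fit.pvalues[1:]
    keep_idx = [usable[j] for j in range(len(usable)) if pvals[j] <= alpha]
    out = retained.iloc[keep_idx].copy()
    out["joint_p"] = [pvals[j] for j in range(len(usable)) if pvals[j] <= alpha]
    return out


def low_expression_cutoff(
    cis_medians: np.ndarray | pd.Series, percentile: float = 5.0, fallback: float = -4.5
) -> float:
    """Cutoff = the given percentile of cis-regulated transcripts' medians."""
    med = np.asarray(cis_medians, dtype=float)
    med = med[~np.isnan(med)]
    if med.size == 0:
        logger.warning("no cis-regulated transcripts; using absolute low-expression cutoff %g", fallback)
        return fallback
    return float(np.percentile(med, percentile))


def call_trans(
    distant_results: pd.DataFrame,
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    cis_calls: pd.DataFrame,
    probe_sequences: dict[str, str] | None = None,
    flank_sequences: dict[str, str] | None = None,
    family_alpha: float = 0.05,
    n_local_pairs: int | None = None,
    n_total_probes: int | None = None,
    conditional_alpha: float = 0.05,
    kw_alpha: float = 0.00015,
    low_expr_percentile: float = 5.0,
    low_expr_fallback: float = -4.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full trans cascade; return (trans eQTL table, audit table).

    distant_results: the distant-mode scan table (snp/chrom/pos/probe/
    beta/r2/p_value/n). cis_calls: the cis table from
    :func:`eqtlmap.cis.call_cis` (kw-failed rows included). The audit
    table holds every Bonferroni-passing candidate with one boolean column
    per cascade step (NA = not reached).
    """
    from .cis import kruskal_wallis

    n_probes = n_total_probes if n_total_probes is not None else expression.n_probes
    if n_local_pairs is None:
        n_local_pairs = 0
    threshold = bonferroni_threshold(n_probes, genotypes.n_snps, n_local_pairs, family_alpha)
    cand = distant_results[distant_results["p_value"] < threshold].copy().reset_index(drop=True)
    logger.info("trans calling: %d candidates below Bonferroni threshold %.3g", len(cand), threshold)
    for step in FILTER_STEPS:
        cand[f"pass_{step}"] = pd.array([pd.NA] * len(cand), dtype="boolean")
    cand["fwer_threshold"] = threshold
    if len(cand) == 0:
        return cand, cand

    snp_pos = {s: i for i, s in enumerate(genotypes.snps["snp"]) }
    probe_pos = {p: i for i, p in enumerate(expression.probes["probe"]) }
    probe_chrom = dict(zip(expression.probes["probe"], expression.probes.get("chrom", pd.Series(dtype=object))))

    def dosage_of(snp: str) -> np.ndarray:
        return genotypes.dosages[snp_pos[snp]]

    def expr_of(probe: str) -> np.ndarray:
        return expression.values[probe_pos[probe]]

    cis_by_probe = {r["probe"]: r for _, r in cis_calls.iterrows()} if len(cis_calls) else {}

    # 1. cis-capture filter
    alive = np.ones(len(cand), dtype=bool)
    cond_p = np.full(len(cand), np.nan)
    for i, row in cand.iterrows():
        cis_row = cis_by_probe.get(row["probe"])
        same_chrom = str(row["chrom"]) == str(probe_chrom.get(row["probe"], ""))
        if cis_row is None or not same_chrom:
            cand.loc[i, "pass_cis_capture"] = True  # filter not applicable
            continue
        ok, p = cis_capture_filter(
            dosage_of(row["snp"]), dosage_of(cis_row["snp"]), expr_of(row["probe"]), conditional_alpha
        )
        cand.loc[i, "pass_cis_capture"] = ok
        cond_p[i] = p
        alive[i] = ok
    cand["cis_conditional_p"] = cond_p

    # 2. sequential conditional pruning per (transcript, candidate chromosome)
    for (probe, _chrom), grp in cand[alive].groupby(["probe", "chrom"], sort=False):
        dos = {s: dosage_of(s) for s in grp["snp"]}
        kept = sequential_conditional_prune(grp, dos, expr_of(probe), conditional_alpha)
        kept_snps = set(kept["snp"]) if len(kept) else set()
        for i in grp.index:
            ok = cand.loc[i, "snp"] in kept_snps
            cand.loc[i, "pass_ld_redundant"] = ok
            alive[i] = ok

    # 3. joint model per transcript
    for probe, grp in cand[alive].groupby("probe", sort=False):
        dos = {s: dosage_of(s) for s in grp["snp"]}
        kept = joint_model_check(grp, dos, expr_of(probe), conditional_alpha)
        kept_snps = set(kept["snp"]) if len(kept) else set()
        for i in grp.index:
            ok = cand.loc[i, "snp"] in kept_snps
            cand.loc[i, "pass_joint_model"] = ok
            alive[i] = ok

    # 4. cross-hybridization screen
    for i in np.flatnonzero(alive):
        row = cand.loc[i]
        if probe_sequences is None or flank_sequences is None:
            cand.loc[i, "pass_cross_hyb"] = True
            continue
        probe_seq = probe_sequences.get(row["probe"])
        if probe_seq is None:
            logger.warning("no sequence for probe %s; cross-hybridization not assessable", row["probe"])
            cand.loc[i, "pass_cross_hyb"] = True
            continue
        flank = flank_sequences.get(row["snp"])
        if flank is None:
            raise ValueError(f"missing flank sequence for trans candidate SNP {row['snp']}")
        mapped = probe_maps_to_flank(probe_seq, flank)
        cand.loc[i, "pass_cross_hyb"] = not mapped
        alive[i] = not mapped

    # 5. low-expression filter
    med = expression.normalized_medians
    if med is None:
        logger.warning("no normalized medians available; low-expression filter skipped")
        for i in np.flatnonzero(alive):
            cand.loc[i, "pass_low_expression"] = True
    else:
        cis_regulated = cis_calls[cis_calls.get("kw_pass", True) == True]["probe"] if len(cis_calls) else []
        cis_med = med.reindex(cis_regulated) if len(cis_regulated) else pd.Series(dtype=float)
        cutoff = low_expression_cutoff(cis_med, low_expr_percentile, low_expr_fallback)
        for i in np.flatnonzero(alive):
            probe = cand.loc[i, "probe"]
            m = med.get(probe, np.nan)
            ok = bool(np.isnan(m) or m >= cutoff)
            cand.loc[i, "pass_low_expression"] = ok
            alive[i] = ok

    # 6. Kruskal-Wallis confirmation
    kw_ps = np.full(len(cand), np.nan)
    for i in np.flatnonzero(alive):
        row = cand.loc[i]
        try:
            kw_p = kruskal_wallis(dosage_of(row["snp"]), expr_of(row["probe"]))
        except ValueError:
            kw_p = np.nan
        kw_ps[i] = kw_p
        ok = bool(np.isfinite(kw_p) and kw_p <= kw_alpha)
        cand.loc[i, "pass_kw"] = ok
        alive[i] = ok
    cand["kw_p"] = kw_ps

    retained = cand[alive].reset_index(drop=True)
    logger.info("trans calling: %d retained after the exclusion cascade", len(retained))
    return retained, cand
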