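"""Reassessment of GWAS catalog records against the eQTL map.

A catalog record (SNP, trait, reported gene(s)) is matched to every
cis/trans eQTL whose SNP is identical to or in LD (r^2 > 0.8) with the
reported SNP. Matches whose eQTL signal persists after conditioning on
the reported SNP's genotype (conditional P < 0.05) are excluded as
non-colocalizing: the eQTL and the GWAS hit are then two distinct
factors. Surviving records are classified:

- Case 1: the eQTL-suggested gene differs from every reported gene — the
  map suggests a different candidate;
- Case 2: the suggested gene matches the (single effective) reported
  gene — the map supports the GWAS interpretation;
- Case 3: several genes were reported and the map singles out one of
  them;
- Case 4: the only surviving match is a trans-eQTL (target gene > 500 kb
  away or on another chromosome);
- uninformative: no eQTL match.

Reported gene symbols are resolved through an alias table before
comparison. When several cis matches suggest different genes, the
smallest-P eQTL determines the suggestion; all matches are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GenotypeMatrix
from .genotype_qc import ld_r2

logger = logging.getLogger(__name__)

CASES = ("case1", "case2", "case3", "case4", "excluded", "uninformative")


@dataclass(frozen=True)
class GwasRecord:
    record_id: str
    snp: str
    trait: str
    reported_genes: tuple[str, ...]
    reported_p: float | None = None


@dataclass
class CaseClassification:
    record_id: str
    snp: str
    case: str
    eqtl_snp: str | None = None
    suggested_genes: tuple[str, ...] = ()
    ld_r2: float = float("nan")
    conditional_p: float = float("nan")
    matches: pd.DataFrame | None = field(default=None, repr=False)


def resolve_symbol(symbol: str, aliases: dict[str, str] | None) -> str:
    """Canonical gene symbol via the alias table (identity when absent)."""
    if not aliases:
        return symbol
    return aliases.get(symbol, symbol)


def match_record(
    record: GwasRecord,
    eqtls: pd.DataFrame,
    genotypes: GenotypeMatrix,
    r2_min: float = 0.8,
) -> pd.DataFrame:
    """All eQTLs identical to or in LD (r^2 > r2_min) with the record's SNP.

    eqtls: combined cis/trans table with columns snp/probe/gene_id/symbol/
    p_value/beta and ``kind`` in {cis, trans}. The record's SNP must be in
    the genotype panel (records failing that are dropped upstream).
    Returns the matching rows with an added ``ld_r2`` column.
    """
    if record.snp not in set(genotypes.snps["snp"]):
        raise KeyError(f"GWAS SNP {record.snp} not in the genotype panel")
    g_rec = genotypes.dosage(record.snp)
    out_rows = []
    for _, row in eqtls.iterrows():
        if row["snp"] == record.snp:
            r2 = 1.0
        else:
            r2 = ld_r2(g_rec, genotypes.dosage(row["snp"])).r2
        if np.isfinite(r2) and r2 > r2_min:
            r = dict(row)
            r["ld_r2"] = r2
            out_rows.append(r)
    cols = list(eqtls.columns) + ["ld_r2"]
    return pd.DataFrame(out_rows, columns=cols)


def colocalization_filter(
    record_dosage: np.ndarray,
    eqtl_dosage: np.ndarray,
    target_expression: np.ndarray,
    alpha: float = 0.05,
) -> tuple[bool, float]:
    """Keep the match only when the eQTL adds nothing beyond the GWAS SNP.

    Regresses the eQTL's target expression on the GWAS SNP dosage and
    tests the residuals against the eQTL dosage. A significant conditional
    P (< alpha) means the eQTL signal persists — the eQTL and the GWAS SNP
    are two distinct factors and the record is excluded. Returns
    (keep, conditional P).
    """
    from .trans import _impute, _marginal_p, _ols_residuals

    y = np.asarray(target_expression, dtype=float)
    resid = _ols_residuals(y, [_impute(record_dosage)])
    p = _marginal_p(resid, _impute(eqtl_dosage))
    return p >= alpha, p


def classify_case(
    record: GwasRecord,
    matches: pd.DataFrame,
    aliases: dict[str, str] | None = None,
) -> CaseClassification:
    """Assign Case 1-4 given the record's colocalizing eQTL matches."""
    reported = tuple(
        resolve_symbol(g, aliases) for g in record.reported_genes if g and g == g
    )
    if matches is None or len(matches) == 0:
        return CaseClassification(record.record_id, record.snp, "uninformative")
    cis = matches[matches["kind"] == "cis"]
    if len(cis) == 0:
        top = matches.sort_values("p_value", kind="stable").iloc[0]
        return CaseClassification(
            record.record_id, record.snp, "case4",
            eqtl_snp=top["snp"],
            suggested_genes=(resolve_symbol(str(top["symbol"]), aliases),),
            ld_r2=float(top["ld_r2"]),
            conditional_p=float(top.get("conditional_p", np.nan)),
            matches=matches,
        )
    top = cis.sort_values("p_value", kind="stable").iloc[0]
    suggested = resolve_symbol(str(top["symbol"]), aliases)
    all_suggested = tuple(
        sorted({resolve_symbol(str(s), aliases) for s in cis["symbol"]})
    )
    if suggested in reported:
        case = "case3" if len(reported) > 1 else "case2"
    else:
        case = "case1"
    return CaseClassification(
        record.record_id, record.snp, case,
        eqtl_snp=top["snp"],
        suggested_genes=(suggested,) + tuple(g for g in all_suggested if g != suggested),
        ld_r2=float(top["ld_r2"]),
        conditional_p=float(top.get("conditional_p", np.nan)),
        matches=matches,
    )


def classify_records(
    records: list[GwasRecord],
    eqtls: pd.DataFrame,
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    aliases: dict[str, str] | None = None,
    r2_min: float = 0.8,
    conditional_alpha: float = 0.05,
) -> pd.DataFrame:
    """Match, filter and classify every record; returns one row per record.

    Records whose SNP is outside the genotype panel are dropped with a log
    message (mirroring the upstream exclusion of untested SNPs).
    """
    probe_pos = {p: i for i, p in enumerate(expression.probes["probe"])}
    snp_ids = set(genotypes.snps["snp"])
    rows = []
    for rec in records:
        if rec.snp not in snp_ids:
            logger.info("record %s: SNP %s not tested; dropped", rec.record_id, rec.snp)
            continue
        matches = match_record(rec, eqtls, genotypes, r2_min)
        kept_rows = []
        excluded_any = False
        cond_ps = []
        for _, m in matches.iterrows():
            probe = m["probe"]
            if probe not in probe_pos:
                continue
            keep, p = colocalization_filter(
                genotypes.dosage(rec.snp),
                genotypes.dosage(m["snp"]),
                expression.values[probe_pos[probe]],
                conditional_alpha,
            )
            m = dict(m)
            m["conditional_p"] = p
            cond_ps.append(p)
            if keep:
                kept_rows.append(m)
            else:
                excluded_any = True
        kept = pd.DataFrame(kept_rows, columns=list(matches.columns) + ["conditional_p"])
        if len(kept) == 0 and excluded_any:
            cls = CaseClassification(
                rec.record_id, rec.snp, "excluded",
                conditional_p=float(np.nanmin(cond_ps)) if cond_ps else np.nan,
            )
        else:
            cls = classify_case(rec, kept, aliases)
        rows.append(
            {
                "record_id": cls.record_id,
                "snp": cls.snp,
                "trait": rec.trait,
                "reported_genes": ";".join(rec.reported_genes),
                "case": cls.case,
                "eqtl_snp": cls.eqtl_snp,
                "suggested_genes": ";".join(cls.suggested_genes),
                "ld_r2": cls.ld_r2,
                "conditional_p": cls.conditional_p,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "record_id", "snp", "trait", "reported_genes", "case", "eqtl_snp",
            "suggested_genes", "ld_r2", "conditional_p",
        ],
    )


def summarize_cases(classifications: pd.DataFrame, n_records: int | None = None) -> pd.DataFrame:
    """Counts and percentages per case, at record and unique-SNP level."""
    if n_records is None:
        n_records = len(classifications)
    rows = []
    for case in CASES:
        sub = classifications[classifications["case"] == case] if len(classifications) else classifications
        n = len(sub)
        n_snps = sub["snp"].nunique() if n else 0
        rows.append(
            {
                "case": case,
                "n_records": n,
                "n_unique_snps": n_snps,
                "pct_records": 100.0 * n / n_records if n_records else 0.0,
            }
        )
    informative = classifications["case"].isin(["case1", "case2", "case3", "case4"]).sum() if len(classifications) else 0
    rows.append(
        {
            "case": "informative",
            "n_records": int(informative),
            "n_unique_snps": classifications.loc[
                classifications["case"].isin(["case1", "case2", "case3", "case4"]), "snp"
            ].nunique() if len(classifications) else 0,
            "pct_records": 100.0 * informative / n_records if n_records else 0.0,
        }
    )
    return pd.DataFrame(rows)
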