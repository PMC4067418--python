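"""Gene-structure annotation, enrichment, trend tests and multi-regulatory eQTLs.

Categories are assigned relative to the *target* gene only: a SNP outside
the target gene and its 1 kb flanks is intergenic even when it lies inside
another gene. Within the target gene the precedence is splicing/exonic
over UTRs over intronic; "splicing" means within 2 bp of an exon-intron
junction on the intron side, "upstream"/"downstream" mean within 1 kb of
the TSS/TES. Enrichment of a category is the fold change in the
proportion it constitutes among eQTLs versus among all local SNPs.

Trend of effect sizes across ordered classes (e.g. RegulomeDB classes
1..7) is tested with a one-sided Jonckheere-Terpstra permutation test;
category mean effects are compared by one-way ANOVA on log effects
followed by Tukey's HSD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import seeded_mapped
from .datatypes import GeneModel

logger = logging.getLogger(__name__)

GENIC_FLANK = 1_000
SPLICE_BP = 2

CATEGORIES = (
    "intergenic", "exonic", "splicing", "intronic", "3utr", "5utr",
    "upstream", "downstream", "na",
)


@dataclass(frozen=True)
class StatResult:
    test: str
    statistic: float
    p_value: float
    n_permutations: int | None = None


def assign_category(pos: int, chrom: str, gene: GeneModel) -> str:
    """Gene-structure category of a SNP relative to its target gene."""
    if str(chrom) != str(gene.chrom):
        return "intergenic"
    pos = int(pos)
    if pos < gene.start - GENIC_FLANK or pos > gene.end + GENIC_FLANK:
        return "intergenic"
    if not gene.contains(pos):
        # inside the 1 kb flank: upstream or downstream in transcriptional direction
        before = pos < gene.start
        if gene.strand == "+":
            return "upstream" if before else "downstream"
        return "downstream" if before else "upstream"
    if not gene.exons:
        return "na"
    exons = sorted(gene.exons)
    in_exon = any(s <= pos <= e for s, e in exons)
    if in_exon:
        if gene.cds_start is not None and gene.cds_end is not None:
            if pos < gene.cds_start:
                return "5utr" if gene.strand == "+" else "3utr"
            if pos > gene.cds_end:
                return "3utr" if gene.strand == "+" else "5utr"
        return "exonic"
    # intronic side: splicing when within 2 bp of a junction
    for s, e in exons:
        if 0 < s - pos <= SPLICE_BP or 0 < pos - e <= SPLICE_BP:
            return "splicing"
    return "intronic"


def enrichment(n_eqtls: int, total_eqtls: int, n_local: int, total_local: int) -> float:
    """Fold change in category proportion among eQTLs vs among local SNPs."""
    if total_eqtls <= 0 or total_local <= 0:
        raise ValueError("totals must be positive")
    if n_local == 0:
        return float("nan")
    return (n_eqtls / total_eqtls) / (n_local / total_local)


def enrichment_table(
    eqtl_categories: pd.Series,
    local_categories: pd.Series,
    eqtl_effects: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Category counts, proportions, enrichment folds and mean effects.

    eqtl_categories / local_categories: category label per cis-eQTL and
    per local SNP. eqtl_effects: optional frame indexed like
    eqtl_categories with columns ``abs_beta`` and ``r2``. Rows cover each
    observed category plus genic/intergenic rollups; enrichment is NaN
    where the category is absent among local SNPs.
    """
    genic = [c for c in CATEGORIES if c not in ("intergenic", "na")]
    total_e, total_l = len(eqtl_categories), len(local_categories)
    rows = []

    def one_row(name: str, labels: set[str]) -> dict:
        ne = int(eqtl_categories.isin(labels).sum())
        nl = int(local_categories.isin(labels).sum())
        row = {
            "category": name,
            "n_local_snps": nl,
            "local_pct": 100.0 * nl / total_l if total_l else np.nan,
            "n_eqtls": ne,
            "eqtl_pct": 100.0 * ne / total_e if total_e else np.nan,
            "enrichment": enrichment(ne, total_e, nl, total_l) if total_e and total_l else np.nan,
        }
        if eqtl_effects is not None:
            sel = eqtl_categories.isin(labels).to_numpy()
            row["mean_abs_beta"] = float(eqtl_effects["abs_beta"].to_numpy()[sel].mean()) if ne else np.nan
            row["mean_r2"] = float(eqtl_effects["r2"].to_numpy()[sel].mean()) if ne else np.nan
        return row

    rows.append(one_row("intergenic", {"intergenic"}))
    rows.append(one_row("genic", set(genic)))
    for cat in genic:
        rows.append(one_row(cat, {cat}))
    rows.append(one_row("na", {"na"}))
    return pd.DataFrame(rows)


def compare_categories(
    effects: pd.Series, categories: pd.Series, min_n: int = 5
) -> tuple[StatResult, pd.DataFrame]:
    """ANOVA on log effects across categories, with Tukey HSD pairwise table.

    Categories with fewer than ``min_n`` members are excluded before
    testing; effects must be positive (they are |beta| or R^2 of called
    eQTLs, never zero).
    """
    effects = pd.Series(np.asarray(effects, dtype=float))
    categories = pd.Series(np.asarray(categories, dtype=object))
    if (effects <= 0).any():
        raise ValueError("effects must be positive for the log transform")
    counts = categories.value_counts()
    keep_cats = counts[counts >= min_n].index
    dropped = sorted(set(counts.index) - set(keep_cats))
    if dropped:
        logger.info("compare_categories: dropping small categories %s", dropped)
    mask = categories.isin(keep_cats).to_numpy()
    if len(keep_cats) < 2:
        raise ValueError("need at least two categories with enough members")
    logs = np.log(effects[mask].to_numpy())
    labels = categories[mask].to_numpy()
    groups = [logs[labels == c] for c in keep_cats]
    f, p = stats.f_oneway(*groups)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    tukey = pairwise_tukeyhsd(logs, labels)
    pair_table = pd.DataFrame(
        data=tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return StatResult("anova", float(f), float(p)), pair_table


def jt_statistic(values: np.ndarray, class_sizes: np.ndarray) -> float:
    """Jonckheere-Terpstra statistic for values grouped in class order.

    ``values`` is the concatenation of class samples in increasing class
    order; ``class_sizes`` their lengths. JT = sum over class pairs i < j
    of #{(x in i, y in j): y > x} + 0.5 #ties.
    """
    bounds = np.concatenate([[0], np.cumsum(class_sizes)])
    jt = 0.0
    for i in range(len(class_sizes)):
        xi = values[bounds[i] : bounds[i + 1]]
        yj = values[bounds[i + 1] :]
        if xi.size == 0 or yj.size == 0:
            continue
        jt += (yj[None, :] > xi[:, None]).sum() + 0.5 * (yj[None, :] == xi[:, None]).sum()
    return float(jt)


def jonckheere_terpstra(
    samples: list[np.ndarray], n_perm: int = 100_000, seed: int = 0, batch: int = 200
) -> StatResult:
    """One-sided Jonckheere-Terpstra permutation trend test.

    samples: per-class observation arrays in the hypothesized increasing
    order. P = (1 + #{permuted JT >= observed}) / (n_perm + 1).
    """
    if len(samples) < 2:
        raise ValueError("need at least two ordered classes")
    samples = [np.asarray(s, dtype=float) for s in samples]
    if any(s.size == 0 for s in samples):
        raise ValueError("every class must be nonempty")
    sizes = np.array([s.size for s in samples])
    pooled = np.concatenate(samples)
    observed = jt_statistic(pooled, sizes)
    rng = np.random.default_rng(seed)
    n = pooled.size
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    exceed = 0
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        # b independent shuffles of the pooled values
        perm_idx = np.argsort(rng.random((b, n)), axis=1)
        vals = pooled[perm_idx]  # (b, n)
        jt = np.zeros(b)
        for i in range(len(sizes)):
            xi = vals[:, bounds[i] : bounds[i + 1]]
            yj = vals[:, bounds[i + 1] :]
            if xi.shape[1] == 0 or yj.shape[1] == 0:
                continue
            gt = (yj[:, None, :] > xi[:, :, None]).sum(axis=(1, 2))
            eq = (yj[:, None, :] == xi[:, :, None]).sum(axis=(1, 2))
            jt += gt + 0.5 * eq
        exceed += int((jt >= observed - 1e-9).sum())
        done += b
    p = (1 + exceed) / (n_perm + 1)
    return StatResult("jonckheere-terpstra", observed, p, n_permutations=n_perm)


def distance_profile(
    distances: pd.Series,
    effects: pd.Series | None = None,
    categories: pd.Series | None = None,
    thresholds: tuple[int, ...] = (0, 17_000, 50_000, 100_000, 500_000),
) -> dict:
    """Distance summary of cis-eQTLs: cumulative fractions and decay trend.

    distances: signed bp distances (0 = inside gene). Returns cumulative
    fractions of |distance| <= each threshold and, when effects are given,
    the Spearman correlation between |distance| and effect among
    intergenic eQTLs (by category when supplied, else distance != 0).
    """
    d = np.abs(np.asarray(distances, dtype=float))
    n = d.size
    cumulative = {t: float((d <= t).sum()) / n if n else np.nan for t in thresholds}
    out = {"n": n, "cumulative_fraction": cumulative}
    if effects is not None:
        eff = np.asarray(effects, dtype=float)
        if categories is not None:
            sel = np.asarray(categories) == "intergenic"
        else:
            sel = d > 0
        if sel.sum() >= 3:
            rho, p = stats.spearmanr(d[sel], eff[sel])
            out["spearman_rho"] = float(rho)
            out["spearman_p"] = float(p)
        else:
            out["spearman_rho"] = np.nan
            out["spearman_p"] = np.nan
    return out


def find_multi_regulatory(
    eqtls: pd.DataFrame,
    probe_annotation: pd.DataFrame,
    probe_sequences: dict[str, str] | None = None,
    exon_sequences: dict[str, str] | None = None,
    min_genes: int = 3,
) -> pd.DataFrame:
    """SNPs regulating >= min_genes distinct protein-coding genes.

    eqtls: a cis (or trans) eQTL table with columns snp/probe/gene_id/
    beta; probe_annotation supplies each probe's rna_class and gene_id.
    Before counting, probes whose sequence maps (same local-alignment
    scoring as the cross-hybridization screen) to the exon sequences of
    another counted gene are removed. exon_sequences maps gene_id ->
    concatenated exon sequence.
    """
    ann = probe_annotation.set_index("probe")
    rows = []
    for snp, grp in eqtls.groupby("snp", sort=False):
        entries = []
        for _, r in grp.iterrows():
            probe = r["probe"]
            if probe not in ann.index:
                continue
            if str(ann.loc[probe, "rna_class"]) != "mRNA":
                continue
            gene = r.get("gene_id")
            if gene is None or (isinstance(gene, float) and np.isnan(gene)):
                gene = ann.loc[probe, "gene_id"]
            entries.append({"probe": probe, "gene_id": gene, "beta": r["beta"]})
        if not entries:
            continue
        # cross-hybridization exclusion against the other genes' exons
        counted = []
        for e in entries:
            if probe_sequences is not None and exon_sequences is not None:
                seq = probe_sequences.get(e["probe"])
                if seq is None:
                    logger.warning("no sequence for probe %s; excluded from multi-regulatory count", e["probe"])
                    continue
                cross = False
                for other in entries:
                    if other["gene_id"] == e["gene_id"]:
                        continue
                    exons = exon_sequences.get(other["gene_id"])
                    if exons and seeded_mapped(seq, exons):
                        cross = True
                        break
                if cross:
                    continue
            counted.append(e)
        genes = sorted({e["gene_id"] for e in counted})
        if len(genes) >= min_genes:
            betas = {e["gene_id"]: e["beta"] for e in counted}
            signs = {g: np.sign(b) for g, b in betas.items()}
            rows.append(
                {
                    "snp": snp,
                    "n_genes": len(genes),
                    "genes": ";".join(str(g) for g in genes),
                    "betas": ";".join(f"{betas[g]:+.3f}" for g in genes),
                    "direction_consistent": len(set(signs.values())) == 1,
                }
            )
    return pd.DataFrame(rows, columns=["snp", "n_genes", "genes", "betas", "direction_consistent"])
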