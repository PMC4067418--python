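"""Synthetic genotype/expression/annotation/GWAS fixtures with known truth.

The generator emulates the statistical structure the pipeline assumes:
a cohort of ~300 unrelated individuals, biallelic autosomal SNPs in LD
blocks, log2 microarray expression with planted additive cis and trans
effects, age/sex covariates, latent batch factors and Gaussian noise,
plus probe/flank sequences and a GWAS catalog engineered to exercise the
Case 1-4 classification. Everything is deterministic given the plan and
its seed, and a truth table of planted effects is emitted alongside the
data for parameter-recovery tests.

LD partners are generated per haplotype by copying the causal allele
with a switch probability p = 1 - sqrt(r2_target); under equal minor
allele frequencies the realized dosage r^2 then converges to the target.
Partners with a different MAF use the same copying scheme (the attainable
maximum r^2 is lower; the realized value is what counts) and a target of
exactly 1.0 with a different MAF is rejected as unattainable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import CIS_WINDOW, signed_distance
from .datatypes import ExpressionMatrix, GeneModel, GenotypeMatrix

DEFAULT_PROBE_LENGTH = 60
#: cohort shape: 102 male / 196 female, ages 32..66
DEFAULT_SEX_RATIO = (102, 196)
AGE_RANGE = (32, 66)


@dataclass(frozen=True)
class PartnerSpec:
    """An LD partner of a causal SNP with a target dosage r^2."""

    snp: str
    pos: int
    r2: float
    maf: float | None = None  # None -> same as the causal SNP


@dataclass(frozen=True)
class LdBlockSpec:
    """A causal SNP and its LD partners on one chromosome."""

    chrom: str
    snp: str
    pos: int
    maf: float
    partners: tuple[PartnerSpec, ...] = ()
    missing_rate: float = 0.0


@dataclass(frozen=True)
class GeneSpec:
    gene_id: str
    symbol: str
    rna_class: str  # mRNA | lincRNA | other
    chrom: str
    start: int
    end: int
    strand: str
    n_probes: int = 1


@dataclass(frozen=True)
class EffectSpec:
    """A planted additive effect: beta log2 units per minor allele."""

    snp: str
    probe: str
    beta: float


@dataclass(frozen=True)
class CrossHybSpec:
    """Plant a (mutated) copy of a probe's sequence in a SNP's flank."""

    probe: str
    snp: str
    n_mismatches: int = 0


@dataclass
class SimulationPlan:
    n_samples: int
    chromosomes: list[tuple[str, int]]
    ld_blocks: list[LdBlockSpec]
    genes: list[GeneSpec]
    cis_effects: list[EffectSpec] = field(default_factory=list)
    trans_effects: list[EffectSpec] = field(default_factory=list)
    #: probe -> (age coefficient per year, sex coefficient for sex=1)
    covariate_effects: dict[str, tuple[float, float]] = field(default_factory=dict)
    #: number of latent factors and probe -> loading vector (length K)
    n_latent_factors: int = 0
    latent_loadings: dict[str, tuple[float, ...]] = field(default_factory=dict)
    noise_sd: float = 1.0
    baseline: float = 7.0
    #: probe-to-probe abundance spread (log2 SD around the baseline);
    #: microarray signal spans many log2 units across transcripts
    baseline_sd: float = 2.0
    probe_length: int = DEFAULT_PROBE_LENGTH
    flank_length: int = 5_000  # half-width of emitted trans-eQTL flanks
    cross_hyb: list[CrossHybSpec] = field(default_factory=list)
    sex_ratio: tuple[int, int] = DEFAULT_SEX_RATIO
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- plan validity -------------------------------------------------
    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least two samples")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        snp_pos: dict[str, tuple[str, int]] = {}
        for block in self.ld_blocks:
            if not 0 < block.maf <= 0.5:
                raise ValueError(f"SNP {block.snp}: MAF must be in (0, 0.5], got {block.maf}")
            if not 0 <= block.missing_rate < 1:
                raise ValueError(f"SNP {block.snp}: bad missing rate")
            snp_pos[block.snp] = (block.chrom, block.pos)
            for p in block.partners:
                if not 0 <= p.r2 <= 1:
                    raise ValueError(f"partner {p.snp}: r2 target must be in [0, 1]")
                if p.maf is not None and not 0 < p.maf <= 0.5:
                    raise ValueError(f"partner {p.snp}: MAF must be in (0, 0.5]")
                if p.r2 == 1.0 and p.maf is not None and p.maf != block.maf:
                    raise ValueError(
                        f"partner {p.snp}: r2 = 1.0 with a different MAF is unattainable"
                    )
                snp_pos[p.snp] = (block.chrom, p.pos)
        probe_gene = {probe: g for g in self.genes for probe in probe_ids(g)}
        models = {g.gene_id: gene_model(g) for g in self.genes}
        for eff, want_local in [(e, True) for e in self.cis_effects] + [
            (e, False) for e in self.trans_effects
        ]:
            if eff.snp not in snp_pos:
                raise ValueError(f"effect references unknown SNP {eff.snp}")
            if eff.probe not in probe_gene:
                raise ValueError(f"effect references unknown probe {eff.probe}")
            chrom, pos = snp_pos[eff.snp]
            gene = models[probe_gene[eff.probe].gene_id]
            local = str(chrom) == str(gene.chrom) and abs(signed_distance(pos, gene)) <= CIS_WINDOW
            if local != want_local:
                kind = "cis" if want_local else "trans"
                raise ValueError(
                    f"{kind} effect {eff.snp}->{eff.probe} violates the 500 kb locality rule"
                )

    def probe_specs(self) -> list[tuple[str, GeneSpec]]:
        return [(probe, g) for g in self.genes for probe in probe_ids(g)]


def probe_ids(gene: GeneSpec) -> list[str]:
    return [f"{gene.gene_id}_p{i+1}" for i in range(gene.n_probes)]


def gene_model(gene: GeneSpec, n_exons: int = 3) -> GeneModel:
    """Deterministic exon/CDS structure for a gene spec.

    Exons split the gene body into ``n_exons`` equal parts separated by
    introns; the CDS spans from 20% into the first exon to 80% of the
    last (so UTRs exist on both ends of coding genes).
    """
    length = gene.end - gene.start + 1
    if length < 6 * n_exons:
        exons = ((gene.start, gene.end),)
    else:
        piece = length // (2 * n_exons - 1)
        exons = tuple(
            (gene.start + 2 * i * piece, min(gene.start + (2 * i + 1) * piece - 1, gene.end))
            for i in range(n_exons)
        )
        exons = exons[:-1] + ((exons[-1][0], gene.end),)
    cds_start = cds_end = None
    if gene.rna_class == "mRNA":
        first, last = exons[0], exons[-1]
        cds_start = first[0] + max((first[1] - first[0]) // 5, 1)
        cds_end = last[0] + max(4 * (last[1] - last[0]) // 5, 1)
    return GeneModel(
        gene.gene_id, gene.symbol, gene.chrom, gene.start, gene.end, gene.strand,
        exons=exons, cds_start=cds_start, cds_end=cds_end,
    )


def _sorted_snp_table(plan: SimulationPlan) -> pd.DataFrame:
    rows = []
    for block in plan.ld_blocks:
        rows.append({"snp": block.snp, "chrom": block.chrom, "pos": block.pos})
        for p in block.partners:
            rows.append({"snp": p.snp, "chrom": block.chrom, "pos": p.pos})
    frame = pd.DataFrame(rows)
    return frame.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def generate_genotypes(plan: SimulationPlan) -> GenotypeMatrix:
    """Draw dosages: causal SNPs from two Bernoulli(MAF) haplotypes, LD
    partners by per-haplotype allele copying with the calibrated switch
    probability. Deterministic given the plan seed."""
    rng = np.random.default_rng(plan.seed)
    n = plan.n_samples
    dosage_by_snp: dict[str, np.ndarray] = {}
    for block in plan.ld_blocks:
        h = rng.random((2, n)) < block.maf  # two haplotypes
        dosage_by_snp[block.snp] = h.sum(axis=0).astype(float)
        for p in block.partners:
            maf = block.maf if p.maf is None else p.maf
            switch = 1.0 - np.sqrt(p.r2)
            replace = rng.random((2, n)) < switch
            fresh = rng.random((2, n)) < maf
            ph = np.where(replace, fresh, h)
            dosage_by_snp[p.snp] = ph.sum(axis=0).astype(float)
        if block.missing_rate > 0:
            for snp in [block.snp] + [p.snp for p in block.partners]:
                mask = rng.random(n) < block.missing_rate
                dosage_by_snp[snp][mask] = np.nan
    snps = _sorted_snp_table(plan)
    dosages = np.stack([dosage_by_snp[s] for s in snps["snp"]])
    samples = [f"S{i+1:04d}" for i in range(n)]
    return GenotypeMatrix(dosages, snps, samples)


def generate_covariates(plan: SimulationPlan, rng: np.random.Generator) -> pd.DataFrame:
    """Age ~ discrete uniform on [32, 66]; sex 0/1 at the planned ratio."""
    n = plan.n_samples
    age = rng.integers(AGE_RANGE[0], AGE_RANGE[1] + 1, size=n)
    n_male = round(n * plan.sex_ratio[0] / sum(plan.sex_ratio))
    sex = np.zeros(n, dtype=int)
    sex[rng.permutation(n)[:n_male]] = 1
    return pd.DataFrame(
        {"age": age, "sex": sex}, index=[f"S{i+1:04d}" for i in range(n)]
    )


def generate_expression(
    genotypes: GenotypeMatrix,
    plan: SimulationPlan,
    raw: bool = False,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Planted-model expression plus the covariate table.

    log2 expression = baseline + sum(beta * dosage) + covariate terms +
    latent-factor terms + N(0, noise_sd). With ``raw=True`` the matrix is
    exported as linear intensities 2**(log2 + chip offset), chip offsets
    drawn log-uniformly per sample, for normalization testing.
    """
    rng = np.random.default_rng(plan.seed + 1)
    covariates = generate_covariates(plan, rng)
    probes = annotation_table(plan)
    probe_list = list(probes["probe"])
    n_probes, n = len(probe_list), plan.n_samples
    baselines = plan.baseline + plan.baseline_sd * rng.standard_normal(n_probes)
    values = np.tile(baselines[:, None], (1, n))
    snp_index = {s: i for i, s in enumerate(genotypes.snps["snp"])}
    probe_index = {p: i for i, p in enumerate(probe_list)}
    for eff in list(plan.cis_effects) + list(plan.trans_effects):
        d = genotypes.dosages[snp_index[eff.snp]]
        d = np.where(np.isnan(d), np.nanmean(d), d)
        values[probe_index[eff.probe]] += eff.beta * d
    age = covariates["age"].to_numpy(dtype=float)
    sex = covariates["sex"].to_numpy(dtype=float)
    for probe, (b_age, b_sex) in plan.covariate_effects.items():
        values[probe_index[probe]] += b_age * age + b_sex * sex
    if plan.n_latent_factors > 0:
        factors = rng.standard_normal((plan.n_latent_factors, n))
        for probe, loadings in plan.latent_loadings.items():
            lam = np.asarray(loadings, dtype=float)
            values[probe_index[probe]] += lam @ factors
    values += rng.normal(0.0, plan.noise_sd, size=values.shape)
    samples = list(covariates.index)
    if raw:
        offsets = rng.uniform(-1.0, 1.0, size=n)  # log2-scale chip offsets
        intensities = 2.0 ** (values + offsets)
        em = ExpressionMatrix(intensities, probes, samples, stage="raw")
    else:
        em = ExpressionMatrix(values, probes, samples, stage="normalized")
        em.normalized_medians = pd.Series(
            np.median(values, axis=1), index=probe_list
        )
    return em, covariates


def annotation_table(plan: SimulationPlan) -> pd.DataFrame:
    """Probe annotation frame (probe, gene, RNA class, gene model coords)."""
    rows = []
    for probe, g in plan.probe_specs():
        rows.append(
            {
                "probe": probe,
                "gene_id": g.gene_id,
                "symbol": g.symbol,
                "rna_class": g.rna_class,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
            }
        )
    return pd.DataFrame(rows)


def gene_models_by_probe(plan: SimulationPlan) -> dict[str, GeneModel]:
    models = {g.gene_id: gene_model(g) for g in plan.genes}
    return {probe: models[g.gene_id] for probe, g in plan.probe_specs()}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _mutate(seq: str, n_mismatches: int, rng: np.random.Generator) -> str:
    if n_mismatches > len(seq):
        raise ValueError("cannot mutate more positions than the sequence length")
    pos = rng.choice(len(seq), size=n_mismatches, replace=False)
    out = list(seq)
    for i in pos:
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def generate_annotation_and_sequences(
    plan: SimulationPlan,
) -> tuple[dict[str, GeneModel], pd.DataFrame, dict[str, str], dict[str, str]]:
    """Gene models, SNP functional annotations, probe FASTA, flank FASTA.

    SNP annotations carry the gene-structure category of each planted
    cis-effect SNP relative to its target gene (other SNPs are annotated
    against the nearest gene) plus a RegulomeDB-style class 1-7. Flank
    sequences (length 2*flank_length+1, centred on the SNP) are emitted
    for every trans-effect SNP; cross-hybridization plans plant a copy of
    the chosen probe's sequence, mutated at the requested number of
    positions, into the chosen SNP's flank.
    """
    from .annotation import assign_category

    rng = np.random.default_rng(plan.seed + 2)
    models = gene_models_by_probe(plan)
    probe_seqs = {probe: _random_seq(rng, plan.probe_length) for probe, _ in plan.probe_specs()}

    snps = _sorted_snp_table(plan)
    target_by_snp: dict[str, GeneModel] = {}
    for eff in list(plan.cis_effects) + list(plan.trans_effects):
        target_by_snp.setdefault(eff.snp, models[eff.probe])
    gene_list = [gene_model(g) for g in plan.genes]
    rows = []
    for _, s in snps.iterrows():
        gene = target_by_snp.get(s["snp"])
        if gene is None and gene_list:
            same = [g for g in gene_list if str(g.chrom) == str(s["chrom"])]
            if same:
                gene = min(same, key=lambda g: abs(signed_distance(int(s["pos"]), g)))
        cat = assign_category(int(s["pos"]), s["chrom"], gene) if gene is not None else "intergenic"
        rows.append(
            {
                "snp": s["snp"],
                "chrom": s["chrom"],
                "pos": int(s["pos"]),
                "category": cat,
                "consequence": "na",
                "regulome_class": int(rng.integers(1, 8)),
            }
        )
    snp_annotation = pd.DataFrame(rows)

    flank_seqs: dict[str, str] = {}
    for eff in plan.trans_effects:
        if eff.snp not in flank_seqs:
            flank_seqs[eff.snp] = _random_seq(rng, 2 * plan.flank_length + 1)
    for spec in plan.cross_hyb:
        if spec.snp not in flank_seqs:
            flank_seqs[spec.snp] = _random_seq(rng, 2 * plan.flank_length + 1)
        flank = flank_seqs[spec.snp]
        copy = _mutate(probe_seqs[spec.probe], spec.n_mismatches, rng)
        if len(copy) > len(flank):
            raise ValueError(f"planted copy for probe {spec.probe} is longer than the flank")
        start = int(rng.integers(0, len(flank) - len(copy) + 1))
        flank_seqs[spec.snp] = flank[:start] + copy + flank[start + len(copy):]
    return models, snp_annotation, probe_seqs, flank_seqs


def truth_table(plan: SimulationPlan) -> pd.DataFrame:
    """The planted-effect reference for parameter-recovery tests."""
    rows = [
        {"snp": e.snp, "probe": e.probe, "beta": e.beta, "kind": kind}
        for kind, effects in (("cis", plan.cis_effects), ("trans", plan.trans_effects))
        for e in effects
    ]
    return pd.DataFrame(rows, columns=["snp", "probe", "beta", "kind"])


def generate_gwas_catalog(plan: SimulationPlan, eqtl_truth: pd.DataFrame | None = None) -> pd.DataFrame:
    """GWAS-catalog records engineered to exercise each classification case.

    ``eqtl_truth`` is a frame with columns snp/probe/kind (default: the
    plan's own planted-effect truth table; passing the *called* eQTL
    table instead restricts records to discovered effects). For cis
    effects the generator emits, in rotation: a record reporting a
    different gene (expected Case 1), the regulated gene itself (Case 2),
    and the regulated gene among two reported (Case 3). Each trans-only
    SNP yields a record reporting an unrelated gene (Case 4), and one
    record per catalog points at an effect-free SNP (uninformative). The
    ``expected_case`` column is the truth label.
    """
    if eqtl_truth is None:
        eqtl_truth = truth_table(plan)
    cis_effects = [
        EffectSpec(r["snp"], r["probe"], float(r.get("beta", 0.0)))
        for _, r in eqtl_truth[eqtl_truth["kind"] == "cis"].iterrows()
    ]
    trans_effects = [
        EffectSpec(r["snp"], r["probe"], float(r.get("beta", 0.0)))
        for _, r in eqtl_truth[eqtl_truth["kind"] == "trans"].iterrows()
    ]
    models = gene_models_by_probe(plan)
    symbols = [g.symbol for g in plan.genes]
    cis_snps = {e.snp for e in cis_effects}
    # records are engineered per SNP; SNPs regulating several genes are
    # skipped because their eQTL-suggested gene depends on realized data
    target_counts = pd.Series([e.snp for e in cis_effects]).value_counts()
    single_target = [e for e in cis_effects if target_counts[e.snp] == 1]
    rows = []
    rot = ["case1", "case2", "case3"]
    for i, eff in enumerate(single_target):
        target = models[eff.probe].symbol
        others = [s for s in symbols if s != target]
        case = rot[i % 3]
        if case == "case1":
            reported = [others[i % len(others)]] if others else [target]
            if reported == [target]:
                case = "case2"
        elif case == "case2":
            reported = [target]
        else:
            reported = [others[i % len(others)], target] if others else [target]
            if reported == [target]:
                case = "case2"
        rows.append(
            {
                "record_id": f"R{len(rows)+1:03d}",
                "snp": eff.snp,
                "trait": f"trait_{len(rows)+1}",
                "reported_genes": ";".join(reported),
                "p": 1e-8,
                "expected_case": case,
            }
        )
    for eff in trans_effects:
        if eff.snp in cis_snps:
            continue
        target = models[eff.probe].symbol
        others = [s for s in symbols if s != target] or [target]
        rows.append(
            {
                "record_id": f"R{len(rows)+1:03d}",
                "snp": eff.snp,
                "trait": f"trait_{len(rows)+1}",
                "reported_genes": others[0],
                "p": 1e-9,
                "expected_case": "case4",
            }
        )
    effect_snps = cis_snps | {e.snp for e in trans_effects}
    idle = [b.snp for b in plan.ld_blocks if b.snp not in effect_snps]
    if idle:
        rows.append(
            {
                "record_id": f"R{len(rows)+1:03d}",
                "snp": idle[0],
                "trait": f"trait_{len(rows)+1}",
                "reported_genes": symbols[0] if symbols else "GENE",
                "p": 1e-7,
                "expected_case": "uninformative",
            }
        )
    return pd.DataFrame(
        rows, columns=["record_id", "snp", "trait", "reported_genes", "p", "expected_case"]
    )


# ---------------------------------------------------------------------------
# the default stated world used by the analysis drivers and acceptance script


def example_plan(seed: int = 0, n_samples: int = 298) -> SimulationPlan:
    """A desk-scale cohort mirroring the study design.

    298 samples (102:196 male/female, ages 32-66), three ~12 Mb autosomes
    carrying 120 genes (mRNA-biased mix with lincRNA and other probes),
    360 SNPs in two-partner LD blocks, 24 planted cis effects with |beta|
    spanning 0.3-0.8 (the observed cis mean |beta| is ~0.33), 4 trans
    effects with |beta| ~0.5-0.9 (trans mean ~0.53), two latent factors,
    small age/sex effects and noise_sd = 1 log2 unit.
    """
    rng = np.random.default_rng(seed)
    chroms = [("1", 12_000_000), ("2", 12_000_000), ("3", 12_000_000)]
    genes: list[GeneSpec] = []
    classes = ["mRNA"] * 4 + ["lincRNA", "other"]
    gi = 0
    for chrom, _length in chroms:
        for k in range(40):
            start = 150_000 + k * 290_000
            genes.append(
                GeneSpec(
                    gene_id=f"G{gi+1:03d}",
                    symbol=f"GENE{gi+1:03d}",
                    rna_class=classes[gi % len(classes)],
                    chrom=chrom,
                    start=start,
                    end=start + 20_000,
                    strand="+" if gi % 2 == 0 else "-",
                )
            )
            gi += 1
    blocks: list[LdBlockSpec] = []
    for i, g in enumerate(genes):
        maf = float(rng.uniform(0.1, 0.5))
        pos = g.start + int(rng.integers(-80_000, 100_000))
        blocks.append(
            LdBlockSpec(
                chrom=g.chrom,
                snp=f"rs{i+1:04d}",
                pos=max(pos, 1),
                maf=round(maf, 3),
                partners=(
                    PartnerSpec(f"rs{i+1:04d}_a", max(pos, 1) + 2_000, r2=1.0),
                    PartnerSpec(f"rs{i+1:04d}_b", max(pos, 1) + 5_000, r2=0.6),
                ),
            )
        )
    # SNPs destined to fail QC: low MAF and high missingness
    for i in range(4):
        blocks.append(
            LdBlockSpec("1", f"rs_lowmaf{i+1}", 10_000 + i * 2_000, maf=0.02)
        )
        blocks.append(
            LdBlockSpec("2", f"rs_missing{i+1}", 10_000 + i * 2_000, maf=0.3, missing_rate=0.05)
        )
    probes = {g.gene_id: probe_ids(g)[0] for g in genes}
    cis_effects = []
    for j in range(24):
        g = genes[j * 5 % len(genes)]
        beta = float(rng.uniform(0.3, 0.8)) * (1 if j % 2 == 0 else -1)
        cis_effects.append(EffectSpec(f"rs{genes.index(g)+1:04d}", probes[g.gene_id], round(beta, 3)))
    # one multi-regulatory SNP: gene 63's block SNP drives three adjacent
    # coding genes (all within 500 kb), same effect direction
    for gi_, beta_ in ((61, 0.9), (62, 0.85), (63, 0.8)):
        cis_effects.append(EffectSpec("rs0063", probes[genes[gi_].gene_id], beta_))
    # trans: SNP and target on different chromosomes
    trans_effects = []
    for j in range(4):
        snp_gene = genes[j]
        target = next(g for g in genes if g.chrom != snp_gene.chrom and probes[g.gene_id] not in
                      {e.probe for e in cis_effects} | {e.probe for e in trans_effects})
        beta = float(rng.uniform(0.5, 0.9)) * (1 if j % 2 == 0 else -1)
        trans_effects.append(EffectSpec(f"rs{genes.index(snp_gene)+1:04d}", probes[target.gene_id], round(beta, 3)))
    all_probes = [p for g in genes for p in probe_ids(g)]
    loadings = {p: (0.4, -0.3) if i % 2 else (0.5, 0.2) for i, p in enumerate(all_probes)}
    covariate_effects = {p: (0.005, 0.1) for p in all_probes[::5]}
    return SimulationPlan(
        n_samples=n_samples,
        chromosomes=chroms,
        ld_blocks=blocks,
        genes=genes,
        cis_effects=cis_effects,
        trans_effects=trans_effects,
        covariate_effects=covariate_effects,
        n_latent_factors=2,
        latent_loadings=loadings,
        noise_sd=1.0,
        seed=seed,
    )
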