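# Methods

## Scope and data model

The package implements an end-to-end eQTL discovery pipeline for a cohort
of unrelated individuals with SNP-array genotypes and single-channel
microarray expression. Genotypes are minor-allele dosage vectors (0/1/2,
NaN missing), re-oriented per dataset from observed allele frequencies
(frequency ties at 0.5 orient to the alphabetically first allele).
Expression is a probe × sample matrix tagged by stage: `raw` linear
intensities, `normalized` log2 values with each sample's 75th percentile
shifted to 0, or `adjusted` covariate residuals. All genomic coordinates
are 1-based inclusive; BED converters (0-based half-open) live in
`eqtlmap.io` and are bijective on round trip.

## Genotype QC

A SNP is retained iff missing rate ≤ 1%, Hardy–Weinberg exact-test
P ≥ 1e-7, minor allele frequency ≥ 5% (the boundary is kept) and it is
autosomal. The HWE test is the plain exact conditional test: given the
observed allele counts, the P value is the sum of probabilities of all
heterozygote counts whose conditional probability does not exceed the
observed one (no mid-P correction; probabilities via log-gamma, tested
against an exact-rational enumeration oracle). LD is the squared Pearson
correlation of dosage vectors over pairwise-complete samples — composite,
phase-free r², the standard choice for unphased dosage data; haplotype
(EM) r² is a documented deviation we do not attempt. HWE is tested on all
retained samples (the cohort is unrelated; no founder restriction).

## Expression preprocessing

Duplicate probe spots are arithmetic-mean collapsed first, then
intensities are floored at 1, log2-transformed and per-sample shifted so
the 75th percentile is 0 (percentile by linear interpolation — the
convention is a documented choice). `normalize_75th` is idempotent: its
output is stage-tagged and only re-shifted (a no-op) on re-entry. Probes
without genomic coordinates, on sex chromosomes, or overlapping supplied
polymorphic sites are dropped; expression abundance is deliberately not
filtered — low expression only matters later, inside the trans cascade.

Surrogate variables are estimated by a two-step SVD variant rather than
the full iteratively re-weighted algorithm: residualize each probe on an
intercept + known covariates (age, sex), take the SVD of the residual
matrix, and keep leading right singular vectors whose variance share
exceeds a null built by permuting each probe's residuals across samples
(default 20 rounds, α = 0.05, stop at the first non-significant
component). A guard drops any component correlated > 0.99 with a known
covariate. Adjusted expression is the per-probe OLS residual on age, sex
and the surrogate variables; residuals are exactly orthogonal to the
design (QR projection), and each probe's pre-adjustment normalized median
is carried as metadata for the low-expression filter.

At desk scale (~100 probes) a strong planted genetic effect contributes a
visible share of total variance and the leading surrogate variable can
absorb part of it, mildly attenuating β̂; with realistic probe counts
(tens of thousands) this vanishes. The default synthetic world uses 120
probes, where the measured attenuation is within sampling error.

## Association model

Local = same chromosome and within 500 kb (inclusive) of the nearest
transcription start/end site; the signed distance is 0 inside the gene,
negative upstream and positive downstream in transcriptional direction.
The single-SNP model is simple least squares of adjusted expression on
dosage with pairwise complete-case handling of missing dosages and a
two-sided t test (n − 2 df) on the slope; covariates are not re-fit per
pair (two-stage adjust-then-associate). The scan streams one transcript
at a time with vectorized, NaN-aware sufficient statistics.

## cis mapping

The null distribution of each transcript's minimum local P value comes
from 10 global permutations of expression sample labels (one shuffle per
round for all transcripts, preserving inter-transcript correlation).
FDR(p) = mean-over-permutations #{null min-P ≤ p} / #{observed min-P ≤ p},
evaluated only at observed values, monotonized non-decreasing in p
(step-up) and clipped to [0, 1]. Transcripts with FDR < 5% contribute at
most one cis-eQTL: the smallest-P local SNP, with ties in perfect LD
(r² = 1) resolved to the middle genomic position (even-sized tie sets
take the lower middle — the odd case is the only defined one, the even
rule is our documented extension). Ties *not* in perfect LD have no
defined rule; we take the smallest position and flag the record. Calls
are confirmed by a Kruskal–Wallis test across observed genotype classes
(tie-corrected H, χ² P) at P ≤ 1.5e-4; failures stay in the candidate
table, flagged, because the trans cascade still conditions on them.

## Probe alignment and the cross-hybridization screen

`smith_waterman` is an affine-gap local alignment with match +10,
mismatch 0, and gap cost 250 + 100·L for a length-L gap (the engine is
Bio.Align.PairwiseAligner with open_gap_score −350/extend −100, which
realizes exactly that convention); both strands are scanned and N never
matches. A probe "maps" at ≥ 30% of its maximal score (10 × length).

Because mismatches cost nothing, an *unrestricted* local alignment
accumulates chance matches for free: across the ~L diagonals of a long
random target, the best full-probe overlap almost surely reaches 18/60
matching positions, so every random probe would "map" everywhere and the
screen would be vacuous. The original screens were run through a
seed-and-extend read mapper, which only evaluates alignments anchored on
exact spaced-seed hits — that anchoring, not the scoring, is what makes
the screen selective. `probe_maps_to_flank` and the multi-regulatory exon
screen therefore anchor the DP on shared exact 14-mers (either strand)
and align the probe only within a window around each anchor. Fourteen was
chosen so a random 60-mer shares an anchor with a random 10-kb flank with
probability ~2e-3, while planted copies with up to 3 mismatches are
guaranteed an intact 14-mer (pigeonhole) and near-copies with a handful
of mismatches retain one with high probability. The pure DP itself is
validated against an exhaustive alignment-path enumeration oracle.

## trans mapping

The family-wise threshold is α / (#probes × #SNPs − #local pairs),
computed from actual post-QC dimensions, never hard-coded. The cascade
(fixed order, each step non-expanding) is: cis-capture conditional
regression (same-chromosome candidates only, conditioning on the
transcript's cis-eQTL including Kruskal–Wallis-rejected ones; pass iff
residual association P < 0.05); sequential conditional pruning per
(transcript, candidate chromosome) in ascending P, keeping a candidate
and updating residuals only when conditionally significant; a single-pass
joint regression over all kept candidates for a transcript (terms with
P > 0.05 removed; no re-iteration — iterating after removals is
undefined in the source procedure, and one pass is the conservative
reading); the cross-hybridization screen against the SNP's flank; the
low-expression filter with cutoff at the 5th percentile (linear
interpolation) of cis-regulated transcripts' normalized medians, falling
back to an absolute −4.5 when no cis calls exist; and the Kruskal–Wallis
confirmation. Missing dosages are mean-imputed inside the conditional and
joint fits only (the primary P values stay pairwise complete-case); at
≤ 1% post-QC missingness the difference is negligible.

## Annotation statistics

Gene-structure categories are assigned against the *target* gene only:
outside the gene ± 1 kb is intergenic even inside another gene; within
the gene, splicing (≤ 2 bp into the intron from a junction) and exonic
take precedence over 5'/3' UTR (exon position relative to the CDS,
strand-aware), then intronic; the 1 kb flanks are upstream/downstream by
strand. Genes without exon structure yield `na`. Enrichment of a
category is (share among eQTLs)/(share among all local SNPs), undefined
(NaN) when the category is absent from the local SNPs. Mean effects are
compared by one-way ANOVA on natural-log effects with Tukey HSD pairwise
tests (categories with < 5 eQTLs excluded); effect trends over ordered
regulatory classes use the Jonckheere–Terpstra statistic
(Σ over class pairs i<j of #{y > x} + ½ ties) with a one-sided
permutation P = (1 + #{JT_perm ≥ JT_obs}) / (n_perm + 1), default 100,000
batched-vectorized permutations, validated against full enumeration on
tiny instances. Multi-regulatory eQTLs are SNPs associated with ≥ 3
distinct coding (mRNA) genes after removing probes whose sequence maps
into another counted gene's exons (same alignment screen); effect-
direction consistency is reported, not enforced.

## GWAS reclassification

Catalog records whose SNP is genotyped are matched to all eQTLs identical
or in LD r² > 0.8. Each match passes a colocalization check: regress the
eQTL's target expression on the GWAS SNP dosage and test the residuals
against the eQTL dosage; conditional P < 0.05 means the eQTL persists
beyond the GWAS signal — two distinct factors — and the match is
excluded. Surviving records classify as Case 1 (suggested gene differs
from every reported gene), Case 2 (matches the single effective reported
gene), Case 3 (singles out one of several reported genes) or Case 4
(only a trans-eQTL matches). When several cis matches disagree, the
smallest-P eQTL decides the suggestion (the source tables show single
per-record suggestions without stating a rule; smallest P is our
documented choice). Reported symbols resolve through an alias table
before comparison.

## Synthetic data: what it emulates and what it does not

The generator plants a stated world: 298 samples (ages discrete-uniform
32–66, sex 102:196), biallelic autosomal SNPs in LD blocks, log2
expression = probe baseline (N(7, 2) across probes, emulating the wide
abundance spread of real arrays) + Σβ·dosage + age/sex terms + latent
factors + N(0, 1) noise, with optional raw-intensity export through
per-sample log-uniform chip offsets so normalization has something to
remove. LD partners copy the causal allele per haplotype with switch
probability p = 1 − √r², giving realized dosage r² → target under equal
MAF; r² = 1 with unequal MAF is rejected as unattainable. The default
probe length is 60 nt (the array design's probe length is not public;
configurable). Planted cis |β| spans 0.3–0.8 and trans |β| 0.5–0.9,
bracketing the reported means (~0.33 cis, ~0.53 trans); two latent
factors mirror the two surrogate variables the real analysis found. The
GWAS catalog generator engineers one record per single-target cis SNP
(rotating expected Cases 1–3), one per trans-only SNP (Case 4) and one
effect-free SNP; multi-target SNPs are skipped because their "suggested
gene" depends on realized noise.

Not emulated: coalescent/population structure, haplotype phasing, sex
chromosomes, probe-level scanning artifacts, or inter-gene co-regulation
beyond the global latent factors. A green test therefore establishes
that the statistical machinery recovers planted truth under the model's
own assumptions — not that the pipeline is robust to population
stratification or array batch pathologies outside that model.

## Numerical choices and degenerate inputs

Percentiles use linear interpolation throughout. Constant dosage or
< 3 complete pairs → pair flagged untestable and excluded from scans.
All-equal expression in Kruskal–Wallis → H = 0, P = 1. Exact fits drive
the t-based P to 0 (kept as 0). FDR is clipped to [0, 1]. Collinear
columns in the joint trans model are dropped in retention order with a
log message; rank-deficient adjustment designs are an error naming the
collinear columns. Permutation tests add-one smooth their P values and
are deterministic given a seed.

## Known limitations

- The permutation FDR uses 10 rounds (as specified); FDR estimates at
  very small observed P are coarse at desk scale.
- The SVA variant is not the iteratively re-weighted original; acceptance
  is by planted-factor recovery, not by reproducing a specific component
  count on real data.
- The seeded cross-hybridization screen is slightly less sensitive than
  exhaustive DP for copies with many scattered mismatches (by design —
  see the alignment section).
- The trans joint model is single-pass; an iterated variant could remove
  additional marginal terms.
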