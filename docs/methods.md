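# Methods

## Overview

`methwas` implements a blood methylome-wide association analysis: cis
genetic prediction models for CpG methylation are trained on a reference
cohort, applied to case-control GWAS summary statistics to test genetically
predicted methylation against disease risk, fine-mapped within LD blocks,
annotated into functional categories, and triangulated against gene
expression for direction consistency. All stages run on synthetic cohorts
from the built-in generator, which also defines the conditions under which
the test suite exercises them.

## Synthetic cohort generator

**Genotypes.** Each of two haplotypes per sample is a latent standard-normal
vector with AR(1) correlation `ld_rho` inside consecutive blocks of
`block_size` variants, thresholded at Φ⁻¹(MAF): an allele is the minor/alt
allele when its latent falls below the threshold. Marginally this gives
exact Hardy–Weinberg genotype class frequencies at the drawn MAF; jointly it
gives tunable LD without an external reference panel. MAFs are uniform on
`maf_range` (default 0.05–0.5). Variants sit on one chromosome at fixed
spacing (default 1 kb), which makes cis-window and LD-block geometry fully
controlled by configuration. Monomorphic draws (possible at small n) are
repaired by flipping one haplotype so downstream covariance computations
never see a zero-variance column.

**Methylation.** Each CpG's latent (M-value-like) level is a linear
combination of `n_causal_per_cpg` causal SNPs drawn within 250 kb, rescaled
to empirical variance `cis_h2`, plus N(0, 1 − cis_h2) noise, so total latent
variance ≈ 1 and the realized cis heritability matches the configured value
(the suite checks recovery to ±0.05 at n = 5,000). Array-scale beta values
are the inverse logit of the latent. Because the rank-based inverse-normal
transform (INT) inverts any monotone map, downstream training on normalized
beta values operates on (approximately) the latent scale, which is what
makes planted-heritability recovery testable.

**Expression.** Gene g's expression is `mediation_beta` × (its CpG's latent)
+ N(0, 1): a pure methylation-mediated architecture. One gene per CpG, TSS
5 kb downstream.

**Disease.** Liability = Σ liability_effects × CpG latent + N(0, 1); cases
are the samples above the empirical (1 − prevalence) quantile, so the case
fraction is controlled exactly. Per-variant summary statistics are the MLE
and Wald SE of logistic regression of case status on dosage, computed by a
vectorized Newton solver (cross-checked against statsmodels to 1e-7 in the
suite). Under zero liability effects the per-variant Z is standard normal,
which the suite uses for calibration checks.

**Seeds.** One master seed; each stage derives its own child generator as
`SeedSequence((seed, STAGE_TAG))` with fixed integer tags, so regenerating
any stage in isolation reproduces it byte-identically (`simulate_gwas` can
therefore rebuild the methylation latents itself when no truth table is
passed).

**What the generator does not emulate:** population structure and admixture,
imputation uncertainty, X-chromosome dosage, trans effects, cell-type
heterogeneity of the molecular signal (covariates are generated but carry no
planted confounding), batch effects, and realistic meQTL effect-size
distributions — effect sizes are chosen for testability. Passing tests
demonstrate the statistical machinery is correct under its assumed model,
not that the assumptions hold in any real cohort.

## Model training

Elastic net with mixing α = 0.5 (scikit-learn `ElasticNetCV`, 50-point
penalty path), penalty chosen at the cross-validated minimum MSE (the
1-SE rule is not used; the choice is recorded in model metadata). Candidate
variants: MAF ≥ 0.05 within the cis window — inclusive |pos − cpg| ≤ 1 Mb
for the FHS-style panel, strict < 250 kb for the BIOS-style panel, matching
the two published conventions. The BIOS-style panel first requires a CpG to
have at least one marginal cis-meQTL significant at 5% BH-FDR across all
tested SNP–CpG pairs; the gate acts at CpG level and all cis variants then
enter the fit (a `restrict_to_significant` flag narrows the candidate set to
the significant pairs instead).

`cv_r2` is the squared correlation between out-of-fold predictions and the
observed values. The fold split used to *evaluate* is deliberately different
from the one used to *select* the penalty: with a shared split, penalty
selection leaks into the out-of-fold predictions and a pure-noise CpG clears
R² ≥ 0.01 noticeably more often than it should. Both splits are seeded and
deterministic.

Registry QC keeps models with cv_r2 ≥ 0.01 (inclusive) and drops any model
carrying a weighted SNP inside its CpG's probe-binding interval (49-bp
emulation: position ± 24 bp). A CpG with no recorded probe interval is
retained with a warning — exclusion requires positive evidence. Per-panel
tallies satisfy trained = passing + rejected, and two-panel union counts
follow inclusion–exclusion.

BIOS-style standardized weights are converted to the dosage scale by
dividing each weight by the variant's reference dosage SD; the prediction
variance is preserved exactly (checked to 1e-9 relative).

## Association statistic

For harmonized weights and GWAS effects, z = Σ w_l (σ_l/σ_g)(β_l/se_l) with
σ_g² = wᵀΣw from an LD reference dosage panel (sample covariance, ddof = 1;
ε·I ridge with ε = 1e-6 only if a negative eigenvalue appears). The reported
effect, Σ w_l (σ_l²/σ_g²) β_l, is a log-OR per SD of predicted methylation.
Harmonization matches by variant id with a chrom+pos fallback, negates β on
swapped alleles, and drops strand-ambiguous (A/T, C/G) variants by default.
Weights and β are then jointly oriented onto the LD panel's counted allele
— without this, σ_g picks up wrong-signed cross-terms and the statistic is
not invariant to allele recoding (the suite tests that invariance to 1e-12).

Features whose predicted variance collapses (σ_g² ≤ 1e-12, e.g. perfectly
cancelling weights) are reported as untestable with a reason, never dropped
silently. BH-FDR runs jointly across both panels; the Bonferroni threshold
is α divided by the total model count. Novelty is strict: a significant CpG
more than 500,000 bp from every known risk variant (same chromosome, else
infinite) is "novel". "LD-region" CpG removal is a user-supplied exclusion
BED applied before multiple testing — no canonical list is bundled.

## Fine-mapping

Within a block, z | c ~ N(0, Ω + v·Ω·diag(c)·Ω) over all causal
configurations with |c| ≤ `max_causal`, plus the null; prior(c) =
p^|c|(1 − p)^(k−|c|). Defaults p = 10⁻³, v = 40, max_causal = 3, ρ = 0.9 are
this package's choices and are recorded in output headers. Ω is the
correlation of model-predicted methylation across the LD panel; a ridge of
1e-6 is added when its smallest eigenvalue is below 1e-8. Likelihoods are
computed in log space via Cholesky factorization and normalized with
logsumexp. PIP_i sums the posterior of configurations containing i; the
credible set is the smallest PIP-ranked prefix (ties broken by genomic
position) whose normalized PIP mass reaches ρ. Because the null
configuration participates in normalization, credible sets can be empty
under no signal; the null is flagged as "inside the credible mass" when its
posterior exceeds 1 − ρ. Records are fine-mapped per (panel, CpG), so a CpG
modelled by both panels contributes two members.

With v = 40, a causal site's marginal z has SD √41 ≈ 6.4, which is why the
coverage simulation scales true effects to |z| ≈ 6.

## Annotation

Thirteen categories with fixed precedence (high → low): exonic/splicing,
splicing, exonic, UTR5/UTR3, UTR5, UTR3, ncRNA exonic, intronic, ncRNA
intronic, upstream/downstream, upstream, downstream, intergenic. "Exonic"
means a coding transcript's exon outside its UTRs; "splicing" means within
2 bp of an internal exon boundary on the intron side of a coding transcript;
composites fire when different transcripts/genes disagree. Flanks are 1 kb,
strand-aware. The widely used annotator this emulates does not publish its
exact precedence, so the order here is fixed and documented rather than
byte-compatible; the closed 13-label contract and the enrichment statistics
are what downstream code relies on. Enrichment is a two-proportion Pearson
chi-square (1 df, no continuity correction) of associated vs all tested
CpGs (a vs-complement mode exists); it equals the squared pooled
two-proportion z, and categories with a zero expected cell are skipped with
a note.

## Normalization and triangulation

Normalization follows the reference pipeline: quantile normalization across
samples (each sample's profile mapped to the mean sorted profile), then a
per-feature INT with the Blom offset, z = Φ⁻¹((rank − 3/8)/(n + 1/4)), then
least-squares residualization on covariates (age, sex, cell fractions,
genotype PCs), leaving feature means below 1e-8 and residuals orthogonal to
every covariate. Quantile normalization assumes a genome-scale feature
panel; on the few-feature fixtures used in unit tests it quantizes the data,
so those tests normalize with INT only (`quantile=False`). Constant features
are excluded with a warning; rank-deficient covariate matrices raise an
error naming the collinear columns.

CpG–gene pairing uses TSS within ±500 kb (configurable); correlation is
Pearson on the adjusted INT values (Spearman via flag — on INT values the
two nearly coincide). The expression-side association reuses the identical
summary statistic on gene weight models, with BH across the genes tested.
A triangulation verdict is *consistent* iff all three legs are significant
at their FDR thresholds and sign(b_m) = sign(r) × sign(b_e), *inconsistent*
if all are significant and the rule fails, *incomplete* otherwise; panels
are triangulated separately and labelled.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` use synthetic cohorts of
n = 500–5,000 samples, 20–1,200 variants and up to 600 CpGs; the end-to-end
triangulation check plants 5 liability CpGs among 10 (each mediating one
gene) at n = 5,000, cis-h² = 0.4, |mediation| = 0.5, with CpGs spaced 600 kb
apart so cis windows do not overlap and planted paths are identifiable. The
null-calibration check pools 1,200 truth-model association tests; the
credible-set coverage check simulates 500 ten-member blocks directly from
the fine-mapping model. These sizes are the package's chosen study
conditions for its properties; the statistics themselves carry no
size-dependent constants.

## Known limitations

* The association statistic inherits TWAS-style caveats: correlated
  predicted methylation across CpGs and shared model SNPs produce spurious
  but genetically real associations (the README example shows one); no
  colocalization or conditional analysis is provided.
* Fine-mapping assumes the block's Ω is estimated without error from the LD
  panel and enumerates at most `max_causal` causal sites.
* The probe-interval geometry (±24 bp) is a convention of the generator, not
  a reconstruction of any specific array's probe design.
* Logistic non-collapsibility means the summary-vs-individual-level Z
  agreement is asymptotic and tightest for modest effects; the suite checks
  |Δz| < 0.05 at liability effects of 0.15.
* Triangulation establishes sign consistency only; it is not a formal
  mediation analysis and estimates no indirect effect.
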