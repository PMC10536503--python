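# Methods

`carriergwas` re-implements, as one tested pipeline, a pedigree-informed
("carrier-augmented") genome-wide association analysis for a putatively
recessive disease in a closed breeding population — the setting of lymphoma
in Border Collies, where most affected dogs trace to common ancestors and
many unaffected relatives of cases are plausibly heterozygous carriers. The
pipeline is exercised end to end on a synthetic breed-pedigree simulator
with a planted recessive risk locus, so every stage has known truth to
recover.

## The carrier-augmented design

Under Mendelian recessive inheritance, certain pedigree positions constrain
genotype: a parent or an offspring of an affected (aa) dog carries at least
one risk allele; a grandparent or great-grandparent of two or more cases is
very likely a carrier. `pedigree.classify_cohort` encodes this as an ordered
rule set over the genotyped cohort:

1. cases with an ambiguous diagnosis are excluded (`excluded_diagnosis`);
2. optionally, T-cell cases are excluded (the disease of interest is
   predominantly B-cell);
3. confirmed cases are coded y = 2;
4. parents of ≥1 case, offspring of ≥1 case, and (great-)grandparents of
   ≥2 cases become carriers, y = 1;
5. dogs whose carrier status is uncertain — siblings and half-siblings,
   grandchildren, aunts/uncles of cases, (great-)grandparents of exactly one
   case, and any dog with estimated genome sharing PIHAT > 0.25 with a
   case — are excluded (`excluded_relative`);
6. the remainder are controls, y = 0.

Carrier rules take precedence over exclusion rules: a dog that is both a
parent of one case and a sibling of another is a carrier. Relatives that are
not genotyped still participate in rule evaluation (carrier positions are
defined by the full pedigree), but only genotyped dogs receive a status.
The binary design keeps only cases (1) and controls (0).

## Mixed-model association

The per-SNP model is y = μ + b·x + g + e with g ~ N(0, σ²g·A), where A is
the GCTA-style genetic relationship matrix: off-diagonals
(1/M)Σᵢ(x_ij−2pᵢ)(x_ik−2pᵢ)/(2pᵢ(1−pᵢ)) and the GCTA diagonal variant
1 + (1/M)Σᵢ[x²_ij−(1+2pᵢ)x_ij+2p²ᵢ]/(2pᵢ(1−pᵢ)). Variance components are
estimated once under the null model and held fixed for every SNP (the
non-LOCO MLMA convention; the candidate SNP stays in the GRM — a documented
approximation). With A eigendecomposed, V = σ²g·A + σ²e·I is diagonal in the
eigenbasis, so the scan whitens once and solves a per-SNP weighted
regression; the Wald statistic (b/SE)² is referred to χ²₁. The binary design
is analysed with the same linear mixed model, not logistic regression.

The GCTA diagonal adjustment makes finite-panel GRMs mildly indefinite;
negative eigenvalues are clipped to zero so V stays positive definite for
any positive residual variance. After minor-allele-frequency filtering the
clipped mass is negligible.

## False discovery rates

Storey q-values: π̂₀ is estimated from π₀(λ) = #{p > λ}/(m(1−λ)) on the grid
λ = 0.05, …, 0.95, smoothed with a cubic spline and evaluated at λ = 0.95;
q_(i) = min_{j≥i} π̂₀·m·p_(j)/j. "Chromosome-wise" q-values apply the
procedure independently within each chromosome. Strata with fewer than 100
p-values fix π₀ = 1, where the procedure reduces exactly to
Benjamini–Hochberg (asserted in tests). The significance threshold is
q < 0.1 throughout.

## Haplotype blocks and haplotype association

Blocks follow the Gabriel confidence-interval criterion. For each SNP pair
the |D′| likelihood is profiled on a 101-point grid (haplotype frequencies
constrained to the sample allele frequencies, D in the direction of the
two-SNP EM estimate), normalised to a posterior with a flat prior, and
summarised by a 90% highest-density interval. A pair is "strong LD" when
CI_low ≥ 0.70 and CI_high ≥ 0.98, "recombination" when CI_high < 0.90; a
span is a block when its endpoint pair is strong and ≥ 95% of its
informative pairs are strong; candidates are accepted greedily, longest
first, without overlap, within a 200 kb window and above a 0.05 MAF floor.
Defaults are the conventional Gabriel/PLINK parameters.

Within a block (≤ 20 SNPs), haplotype frequencies come from an EM algorithm
over the diplotypes consistent with each multilocus genotype, initialised at
linkage-equilibrium products, converged when the largest frequency change is
below 1e−6 (≤ 1000 iterations), with haplotypes below 1e−4 pruned. The
log-likelihood is non-decreasing across iterations (asserted in tests).
Association regresses the phenotype on each haplotype's *expected* dosage
(posterior-weighted copy number): linear for the 2/1/0 code, logistic (with
an odds ratio per dosage unit) for case/control; logistic separation is
flagged and the p-value omitted. The per-group homozygosity tables instead
use the best (maximum-posterior) diplotype; a posterior tie counts as *not*
homozygous. Samples with missing calls inside a block are excluded from the
EM — a limitation that does not bite on the simulator's complete data and is
minor after QC on real data.

## Relatedness and networks

PIHAT is the classic method-of-moments IBD estimator: expected IBS-state
probabilities given IBD state are computed from cohort allele frequencies,
observed IBS counts are inverted to Z0/Z1/Z2, truncated to [0,1] and
renormalised; PIHAT = Z2 + Z1/2. The original implementation's small-sample
bias corrections are omitted; the estimator is validated against pedigree
expectations (parent–offspring ≈ 0.5, founders ≈ 0) instead of bit-for-bit
against other software. Truncation at zero biases near-zero estimates
slightly upward; with ≥ a few thousand SNPs the founder mean stays below
0.05.

Relationship networks are mutual k-nearest-neighbour graphs (k = 10) on
either 1 − IBS/2 genotype distances or 1 − kinship pedigree distances, with
ties broken by sample id; community detection beyond connected components is
out of scope.

## REML and the liability scale

`herit.ai_reml` estimates (σ²g, σ²e) by average-information REML in the GRM
eigenbasis: start values Vp/2 each, AI steps with step-halving, an EM-REML
step whenever an AI step would leave the feasible region or decrease the
restricted likelihood, components floored at 1e−6·Vp, convergence at
|ΔlogL| < 1e−4 within 100 iterations. Near the V(G)/Vp → 1 boundary the
AI/EM iteration can crawl without meeting the tolerance — this is the
realistic regime for small, strongly ascertained case-control cohorts — so a
non-converged run finishes with the profiled restricted likelihood over the
ratio h² = σ²g/(σ²g+σ²e) (the overall scale maximises analytically),
a one-dimensional bounded optimisation that is robust at boundaries. The SE
of V(G)/Vp comes from the inverse AI matrix by the delta method. The null
(σ²g = 0) restricted likelihood has the closed form −½[(n−p)·log(RSS/(n−p))
+ log|X′X| + (n−p)] under the same constant convention, and the test is the
boundary mixture ½χ²₀ + ½χ²₁, i.e. p = ½·P(χ²₁ > LRT); a plain χ²₁ option
exists.

Observed-scale heritability from an ascertained case-control sample is
converted to the liability scale with

    c = [K(1−K)/z²] · [K(1−K)/(P(1−P))],   h²_L = c·h²_obs,  SE_L = c·SE,

where K is the assumed population prevalence, t = Φ⁻¹(1−K), z = φ(t), and
P the sample case proportion. With P = 31/150 this factor reproduces every
published liability value from its observed-scale input at prevalences
0.025/0.05/0.1 to the printed precision (asserted in the acceptance tests),
which pins the interpretation of the conversion. The SE transforms by the
same multiplicative factor.

## The synthetic-data generator

`simdata` emulates the statistical structure the analysis assumes, not canine
genetics in detail:

- **Pedigree.** Founders split evenly by sex; every female of the previous
  generation is a dam with a Poisson litter; only a fraction of males sire,
  with Dirichlet(0.3)-skewed usage (the popular-sire effect). Defaults —
  100 founders, 6 generations, sire fraction 0.25, mean litter 2.2 — were
  chosen once to give a closed population with effective size on the order
  of 100 and realized prevalence concentrated in 0.02–0.08 (12-seed check:
  10th–90th percentile 0.018–0.081, median 0.03).
- **LD.** Blockwise-exchangeable, not coalescent: each chromosome is
  partitioned into latent blocks of geometric length (mean 5 SNPs); each
  block carries 2–6 distinct haplotype variants with Dirichlet frequencies;
  founder haplotypes are drawn i.i.d. blockwise. Block columns are drawn so
  every SNP segregates within its pool above a MAF floor (0.02); with two
  variants per block, within-block r² is exactly 1. This is deliberately
  simple — it provides exactly known block boundaries for scoring the block
  finder — and it understates the decay structure of real LD.
- **Transmission.** Mendelian gene dropping with Haldane (no-interference)
  crossovers at 1 cM/Mb on a uniform map; phased truth is retained.
- **Disease.** One planted biallelic locus (founder risk-allele frequency
  0.3); P(affected | aa) = 0.5, sporadic/phenocopy rate 0.005; onset
  ~ Normal(8.7 y, SD 3.3) truncated to (0, 16] (a truncated normal, not a
  survival model, because only a mean and SD are being matched); B-cell
  immunophenotype with probability 0.85, T otherwise, then 40% of cases
  relabelled untyped.
- **Missingness** is completely at random at write time; the default is
  complete data (imputation is out of scope, so the pipeline is validated on
  complete genotypes).
- **What passing tests do not show.** The simulator has no allele-frequency
  differentiation between case and control lineages beyond the planted
  locus and drift, no genotyping error, no array ascertainment, and LD
  without distance decay inside blocks; recovery results on it bound what
  the method can do under its own assumptions, not performance on real
  array data.

A scaled-down population is much denser in close relatives than an 83,000-dog
breed database, so the exclusion rules remove proportionally more dogs here
(roughly half the genotyped cohort at the demo scale) than in a breed-wide
study; the retained case/carrier/control structure is what the association
design needs.

## Numerical choices and degenerate inputs

- QC order is mind → geno → maf with frequencies recomputed after sample
  removal; MAF removal is strict `<` (MAF exactly at the threshold is kept).
  Minor-allele ties recode alphabetically; recoding is idempotent.
- Monomorphic SNPs are kept and flagged at read, skipped in the GRM, and
  rejected by LD routines.
- Zero-variance SNPs in the scan get b = 0, p = 1, flagged.
- Stepwise selection (AIC, backward, matching the default behaviour of R's
  `step()`) thins near-collinear predictor groups (condition number > 1e10)
  keep-first with a warning; the residual degrees of freedom identity
  DF = n − (retained+1) is asserted.
- Common-ancestor ranking: birth year (unknown last), then minimum total
  path length, then id — fully deterministic.
- All randomness flows from explicit seeds; a rerun of the same pipeline
  config is byte-identical (hashed in tests).

## Problem sizes

Unit tests run at desk scale (tens to hundreds of dogs, hundreds of SNPs).
The stochastic recovery studies use 20 seeds at n ≈ 300 dogs × 5k SNPs
(REML), 20 cohorts at ≈ 150 genotyped dogs × 10k SNPs (design comparison),
and 10 seeds for block recovery; the demo pipeline is 200 dogs × 10k SNPs.
These sizes were chosen as the smallest at which the Monte-Carlo envelopes
in the tests are tight enough to be meaningful.

## Known limitations

- Non-LOCO MLMA mildly deflates signal at the candidate SNP (proximal
  contamination); acceptable at these scales and documented.
- The |D′| interval is a grid HDI with frequencies fixed at sample values,
  not a full joint likelihood; adequate for the Gabriel classification.
- Expected-dosage haplotype regression treats posterior dosages as fixed
  covariates (no phase-uncertainty propagation into SEs).
- Liability-scale estimates above 100% are reported as computed (as in the
  source analyses) rather than truncated.
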