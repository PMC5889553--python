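# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and what the tests do and do not demonstrate. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The pipeline

The package reproduces a complete single-trait genomic-evaluation workflow
for a closed purebred pig line:

1. **Phenotype editing** — records more than 3 SD from the trait mean are
   blanked (per trait; mean/SD from the input sample).
2. **Variant QC** — call rate > 0.95, autosomes only, Hardy–Weinberg
   Pearson χ² < 600 (1 df, no continuity correction, expected counts from
   observed allele frequencies), MAF > 0.05 among genotyped animals, and,
   for imputed panels, per-variant imputation accuracy > 0.95. The χ² < 600
   threshold is unusually permissive; it is reproduced verbatim as the
   benchmark condition rather than re-interpreted. Filter order (call rate →
   autosome → HWE → MAF → accuracy) is a package choice, logged per
   criterion so removal counts are auditable. Imputation accuracy is the
   percentage of concordant genotypes among non-missing pairs; the summary
   bins are <80, [80,85), [85,90), [90,95] and strictly >95 percent, so a
   variant at exactly 95% falls in the 90–95 bin — consistent with the
   "keep only > 95%" retention rule.
3. **Pedigree animal model** — REML variance components, EBV, residuals,
   corrected phenotypes; full and reduced (validation-masked) fits.
4. **Genomic prediction** — GBLUP and BayesB per marker panel; BayesCπ to
   estimate the null fraction π per panel density.
5. **Sequence branch** — per-chromosome split-and-merge BayesB scans,
   top-|effect| pre-selection, NSC/REG/CHIP classification, three-stage LD
   pruning, BayesRC on the surviving "SEQ" set with training corrected
   phenotypes (y_c2).
6. **Evaluation** — accuracy = cor(prediction, y_c1)/√h² over validation
   animals; bias = OLS slope of predictions on y_c1 (regression in that
   direction deliberately; the conventional reverse regression is available
   but never used by default); density/method contrasts as signed
   percentages 100·(acc_a − acc_b)/acc_b.

The h² in the accuracy denominator is the full-data pedigree REML estimate,
recorded in every report row. On synthetic data the report also carries
cor(GEBV, TBV) against the simulation truth — the gold standard a real
study cannot observe.

## Pedigree machinery and REML

`build_A` uses the tabular method with inbreeding; `build_A_inverse` the
Meuwissen–Luo rules with Mendelian-sampling variances
d_i = 0.5 − 0.25(F_s + F_d) (unknown parent ⇒ F = −1). Both are oracle-tested
against dense inversion.

REML for the one-record-per-animal model is computed in the eigenbasis of
the phenotyped-block relationship matrix A_pp = U diag(w) Uᵀ, where
V = σ²_a·diag(w) + σ²_e·I is diagonal and every REML quantity is
closed-form. A bounded profile-likelihood search over h² supplies the
starting point; classical EM-REML updates

```
σ²_a ← (âᵀA⁻¹â + σ²_e·tr(A⁻¹C^aa)) / n,
σ²_e ← yᵀ(y − Xb̂ − â) / (n − f)
```

then run to their fixed point (relative tolerance 1e-8). A component
collapsing below 1e-5 of the total variance is treated as a boundary
solution and pinned at a small floor — REML optima at σ²_e → 0 or σ²_a → 0
otherwise make EM crawl indefinitely. Identifiability: the first level of
each fixed-effect factor is dropped; in masked (reduced) fits a factor level
with no unmasked records gets its effect pinned to zero via a unit diagonal
so the equations stay solvable. Fixed-effect screening uses a Wald χ² per
term at P < 0.01, matching the model-selection step the pipeline assumes;
the contemporary-group × machine interaction is supported but off by
default.

`solve_mme` builds Henderson's equations with sparse A⁻¹ and an LU solve;
masked animals receive EBV through A (the parent-average identity for a
terminal masked animal is tested numerically).

## GBLUP

VanRaden method 1 with observed allele frequencies (the construction is
recorded in the GMatrix metadata); monomorphic variants are excluded and
missing dosages mean-imputed upstream. Predictions for unmasked fits are
backsolved to marker effects through the ridge identity, which makes the
GBLUP/SNP-BLUP equivalence an executable test rather than a remark. The
diagonal ridge before inverting G is 1e-8 — small enough that the
equivalence holds to 1e-6 on n=50/p=100 instances, large enough to keep
duplicate-animal G matrices invertible in double precision.

## Bayesian alphabet

Genotype covariates use the −10/0/10 coding (10·(dosage − 1)), centred by
training column means; effects are therefore 1/10 of their 0/1/2-coded
counterparts and GEBV are coding-invariant (tested). Samplers are numba
kernels with explicit seeds; identical seeds give bit-identical chains.
Posterior summaries average every post-burn-in draw (no thinning — denser
averaging only lowers Monte Carlo error; the `thin` setting is metadata).

**BayesB.** Per-locus variances σ²_j ~ scaled-inv-χ²(ν = 4.2, S), with S set
so the prior mean variance equals σ²_g/((1−π)·Σ2p(1−p)·100) (the 100 from
the ×10 coding). The locus update samples δ_j from the marginal likelihood
ratio given the current σ²_j, α_j from its conditional normal when included,
and σ²_j from its conditional (the prior when excluded). This Gibbs scheme
shares its stationary distribution with the Metropolis–Hastings variant of
the original formulation and vectorises better. Residual variance:
scaled-inv-χ²(ν = 10) centred at the REML σ²_e; fixed effects flat.

**BayesCπ.** One shared effect variance; π ~ Beta(#null+1, #non-null+1).
Two choices stabilise π on null data, where a weakly-identified shared
variance otherwise collapses and leaves π adrift: the shared variance gets a
firmer prior (ν = 10) and its prior scale is recomputed each iteration from
the *current* π (scale ∝ σ²_g/((1−π)·Σ2p(1−p)·100)), so the implied genetic
variance of the included fraction stays constant as π moves. With these,
pure-noise data yield posterior mean π ≥ 0.95 and a 1%-causal architecture
yields π̂ ≈ 0.98 (both asserted in the suite).

**BayesRC.** Standardized covariates (training means/SDs reused for
validation — prediction never peeks at validation data), four-normal
mixture with multipliers (0, 1e-4, 1e-3, 1e-2) on a fixed σ²_g (the
REML/GBLUP estimate; not resampled, following the convention of the BayesR
family), per-class Dirichlet(1,1,1,1) on mixture proportions, and a
pedigree polygenic term sampled single-site with sparse A⁻¹ (σ²_a
initialised at 0.1·σ²_g, scaled-inv-χ² conditional, ν = 4). Component
membership is sampled by exact enumeration of the four marginal
likelihoods. Posterior means of effects and component probabilities are
accumulated Rao-Blackwellised (conditional means and probabilities instead
of raw draws), which materially tightens across-chain agreement at a given
chain length. Replicate chains (default 5) run with distinct derived seeds;
the final estimate is the across-chain mean and the pairwise correlation of
per-chain posterior mean effects is reported as the convergence diagnostic.
The per-class "π" reported is the null-component proportion, but the full
per-class 4-vector is kept in the result to avoid committing to that
reading.

## Pre-selection, classes, LD pruning

Sub-datasets hold one focal chromosome's sequence variants plus the
80K-panel SNPs of all other chromosomes (polygenic background). Per trait,
the merged genome-wide ranking takes ceil(fraction·n) variants by |effect|
with ties broken by variant id — deterministic where the field's common
practice would toss a coin. The class rule table maps missense, splice-site,
frameshift, in-frame indel and stop-gain/loss terms to NSC; UTR, near-gene
(±5 kb) and non-coding-exon terms to REG; everything else (intergenic,
intronic, synonymous) to CHIP; pre-selected variants are forced into NSC
with provenance recorded.

LD pruning uses r² of dosage correlations, threshold 0.99, in windows of 50
variants bounded by 5000 kb advancing by half the count (the parameter pair
matches a common pruning idiom whose exact step is not standardised; the
semantics are recorded here and in the prune log). Of a flagged pair the
lower-MAF member is removed, ties by id — again a deterministic stand-in
for an arbitrary choice. Stage order is strict: within-class first, then
REG/CHIP against surviving NSC, then CHIP against surviving REG, so NSC
survival is never affected by later stages. A windowless configuration
reproduces an all-pairs greedy oracle exactly (tested).

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, not
any particular dataset:

* **Pedigree.** Founders, several burn-in generations with few parents
  (defaults: 7 generations of 24 sires × 72 dams, Ne ≈ 70 — the effective
  size reported for pig nucleus lines is of order 55–115), then a study
  cohort of 1363 boars from 63 sires and 439 dams in weekly batches. The
  burn-in drift calibrates the cohort's mean pairwise additive relationship
  to ≈ 0.12 (measured 0.10–0.13 across seeds by the tabular method).
* **Genotypes.** Founder allele frequencies ~ Beta(0.5, 0.5) clipped to
  [0.01, 0.99]; founders start in HWE and linkage equilibrium; LD arises
  purely from drift and co-segregation during gene-dropping. Meiosis is
  Haldane: Poisson crossover count with mean = map length in Morgans,
  uniform crossover positions, no interference; 1 cM/Mb. The realized
  recombination fraction matches the closed-form Haldane expectation within
  Monte Carlo error (tested over 2·10⁴ meioses).
* **Panels.** Nested 80K ⊂ 650K ⊂ SEQ membership; array panels sampled with
  probability ∝ MAF (common-variant ascertainment), so panel MAF spectra
  are shifted upward like commercial chips.
* **Traits.** Oligogenic architecture: few QTL restricted to two designated
  chromosomes, Gamma(0.4)-magnitude effects with random signs — the
  big-QTL feed-intake/backfat archetype. Polygenic: hundreds of small
  normal effects genome-wide — the growth-rate archetype. The QTL-effect
  distributions are modelling choices; the source data constrain only the
  qualitative contrast. Effects are rescaled so Σ2p(1−p)α² equals the
  target genetic variance; QTL are spread along the map so LD cross-terms
  stay small and the realized TBV variance lands within 10% of target at
  cohort sizes ≥ 1000 (tested).
* **Phenotypes.** y = intercept + contemporary group (weekly batch;
  ≈ cohort/24 levels, effects N(0, (0.7σ_g)²)) + machine (2 levels,
  ultrasound-type traits only, contrast 0.4σ_g) + age slope (0.02σ_g per
  day over a 140–170 d range) + TBV + normal residual with
  σ²_e = σ²_g(1−h²)/h², σ²_g taken as the realized cohort TBV variance so
  the realized h² matches the target. True fixed-effect values are stored
  for recovery tests.
* **Genotype error.** Independent substitution to another legal dosage with
  per-variant probability = rate × a logistic weight in MAF
  (0.5 + 1.5·σ(−20(MAF − 0.1))) when MAF dependence is on, emulating the
  rare-variant imputation penalty; applied only to variants outside the
  directly-genotyped 80K-like panel.
* **Annotation.** One raw term per variant from a genome-like background
  distribution (mostly intergenic/intronic); for true QTL the NSC/REG term
  probabilities are multiplied by the enrichment factor and renormalised.

What the generator does **not** emulate: mutation, selection and migration;
realistic exponential LD decay from a deep coalescent history (drift over a
handful of generations gives coarser, blockier LD); genotyping batch
effects; pedigree errors; non-normal residuals; multi-trait covariance.
Passing tests therefore demonstrate internal correctness and the expected
qualitative method behaviour under a pedigree-drift genome, not performance
guarantees on real sequence data.

## Problem sizes and defaults

Library defaults are desk-scale (3000 iterations, 600 burn-in); the
simulation default is the full 1363-boar cohort with 20,000 variants, while
tests use a 500-boar, 2,000-variant configuration and scale chain lengths
to the property being checked (e.g. five replicate BayesRC chains of
12,000–20,000 iterations for the agreement diagnostic; 1,500–2,500
iterations for directional comparisons averaged over 20 seeds). The
directional claims are asserted on means over seeds — BayesB > GBLUP on
oligogenic traits, the reverse ordering on polygenic traits, genomic
methods > pedigree BLUP when the panel tags the QTL, and a larger non-null
NSC allocation than CHIP under 10× enrichment in ≥ 18/20 seeds.

## Known limitations

* Single-trait models only; no maternal effects, no single-step H-matrix.
* The polygenic term in BayesRC mixes single-site; for very deep pedigrees
  a blocked sampler would mix better.
* EM-REML reports boundary fits at a small positive floor rather than
  exactly zero.
* BayesCπ's π is weakly identified when the shared variance is tiny; the
  dynamic prior scale mitigates but cannot remove this (posterior means on
  null data occasionally dip to ~0.93 for single seeds).
* The LD-pruning window semantics (step = half the variant count) is one of
  several idioms consistent with the stated parameter pair.
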