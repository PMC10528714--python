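# Methods

`methmr` implements a summary-statistics causal screen for DNA-methylation
sites that transmit an exposure's effect to quantitative traits, together
with a synthetic-study generator that lets every stage be validated against
known ground truth.  This note records the statistical model, the defaults
and why they were chosen, and what the synthetic validation does and does
not establish.

## The screen

The screen takes four kinds of summary statistics — cis-mQTLs for candidate
CpG sites from two independent cohorts (discovery and replication),
cis-eQTLs for genes, and GWAS associations for the traits — plus an
individual-level LD reference panel, and proceeds in the following fixed
order (each stage only sees pairs that survived the previous one):

1. **Co-localization (SMR).**  For each CpG x trait pair, the top cis-mQTL
   SNP (smallest QTL p, required to reach genome-wide significance,
   p <= 5e-8) is used as a single instrument:

       T_SMR = z_gwas^2 z_qtl^2 / (z_gwas^2 + z_qtl^2),   T_SMR ~ chi2(1)

   with the Wald ratio b_smr = b_gwas/b_qtl and delta-method SE.  Pairs
   pass at P_SMR < 5e-8.  T_SMR is bounded by the smaller of the two
   squared Z-scores, so a pair can only pass when both studies carry
   genome-wide-significant signal at the shared SNP.

2. **HEIDI.**  A small P_SMR is consistent with one shared causal variant
   (pleiotropy — which includes a genuine causal chain) or with two
   distinct variants in LD (linkage).  Under the single-variant null the
   ratio b_xy(i) = b_gwas(i)/b_qtl(i) is constant across SNPs in LD with
   the top SNP.  HEIDI selects cis SNPs with QTL p < 1.6e-3 and r2 to the
   top SNP in [0.05, 0.9] (at most 20, at least 3), forms
   d_i = b_xy(i) − b_xy(top), and refers sum(z_d_i^2) to a weighted
   chi-square mixture over the eigenvalues of the correlation matrix of
   the d_i (delta-method covariance; QTL and GWAS studies independent,
   cross-SNP correlation r_ij from the panel on both sides).  The mixture
   tail is evaluated by Imhof's numerical inversion, with closed forms for
   the one-/equal-weight cases and a Satterthwaite two-moment fallback;
   the method used is recorded in the output.  Pairs with P_HEIDI < 0.01
   are treated as linkage and not carried forward (configurable; an
   undefined P_HEIDI — too few SNPs — passes, since heterogeneity cannot
   be established).

3. **Bidirectional multi-instrument MR.**  Forward: instruments are cis
   mQTL SNPs with exposure p <= 5e-8, clumped to pairwise r2 < 0.2
   (greedy, ascending p; ties broken by position then id, so runs are
   reproducible), harmonized to the panel's counted allele.  Instruments
   whose Wald ratio is heterogeneous against the consensus (median ratio;
   per-SNP z_d test at p < 0.01, iterated to a fixed point, max 10
   rounds; the SE of d includes the median's own sampling variance) are
   removed as pleiotropic outliers — the filter is skipped below 3
   instruments.  The surviving ratios are combined by GLS,

       b_xy = (1' V^-1 b) / (1' V^-1 1),   var = 1 / (1' V^-1 1),

   where V is the exact delta-method covariance of the ratios with signed
   LD r_ij from the panel (this keeps the estimate invariant to per-SNP
   allele relabeling; with independent instruments it reduces to the
   inverse-variance-weighted mean, with one instrument to the Wald
   ratio).  Reverse: the same machinery with trait-associated SNPs as
   instruments and the CpG's methylation statistics as outcome.  A pair is
   excluded when the reverse test is significant at p < 0.05; a reverse
   test with no usable instruments counts as clean, since only observed
   reverse evidence can be filtered on.

4. **Replication.**  Forward MR is repeated with the second mQTL cohort;
   the final causal set requires discovery p < 5e-8, replication p < 5e-8,
   a HEIDI pass and no reverse-causation evidence.  Replication filters on
   p only; a significant but sign-flipped replication passes with an
   explicit `sign-discordant` flag.

5. **Expression mediation.**  For each final pair, genes whose top eQTL
   lies within 1 Mb of the CpG are chained: CpG -> expression (mQTL
   instruments, eQTL outcome) and expression -> trait (eQTL instruments,
   GWAS outcome), both at p < 5e-8.  The sign of the product of the two
   legs must match the direct CpG -> trait estimate, else the link is
   flagged `sign-inconsistent-chain`.

6. **Pathways.**  For a gene of interest, every gene set containing it is
   tested: pool member genes' eQTL SNPs at p <= 5e-8 (a SNP shared by
   several member genes keeps its largest |z|), prune to near linkage
   equilibrium (r2 < 0.05), and Spearman-correlate |z_eqtl| with |z_gwas|
   across the retained SNPs.  Absolute values are used because member
   genes may act in either direction.  The p-value uses the two-sided t
   approximation for n >= 30 and a seeded 10,000-draw permutation test
   below that; a Benjamini–Hochberg q across the tested sets is attached
   as a labelled addition.  Sets with fewer than 10 usable SNPs are not
   reported.

### Allele harmonization

All cross-study comparisons first re-express records on a common effect
allele (the panel's counted allele): direct match, allele swap (beta and
frequency flipped), or strand flip (complemented alleles).  Palindromic
A/T and C/G SNPs are aligned by allele-frequency concordance and excluded
as ambiguous when either study's minor-allele frequency exceeds 0.4 —
standard two-sample MR practice; the threshold is configurable.
Harmonization never changes |beta|, SE, p or N, and is idempotent.  The
stated p is cross-checked against 2*Phi(−|beta/se|) with a 10x tolerance
(warning only — published files round, and deep-tail t vs normal p's
legitimately diverge).

## The synthetic study

The generator produces everything the screen consumes from an explicit
individual-level causal model — summary statistics are always obtained by
per-SNP least-squares regression on simulated genotypes, never by drawing
Z-scores directly, so allele frequencies, LD and delta-method behaviour
stay internally consistent.

**Genotypes.**  Blocks of 25 SNPs; within a block, haplotypes follow a
latent Gaussian AR(1) with per-step correlation rho, thresholded at the
allele-frequency quantile (frequencies uniform on [0.05, 0.5]; Hardy–
Weinberg by construction).  The AR(1) choice matters: LD decays with
distance, so p-value clumping retains a handful of index SNPs per locus,
as it does on real data.  (An exchangeable-LD variant was rejected during
design: it makes every cis SNP survive r2 < 0.2 clumping, and GLS over
~150 redundant instruments with a finite-panel LD estimate is visibly
anti-conservative.)  Blocks sit 30 Mb apart across 22 chromosomes —
beyond any clumping window, hence independent.  About 10% of SNPs get
palindromic allele pairs (with MAF capped at 0.35 so frequency alignment
stays informative), and each emitted dataset reports a random ~30% of
SNPs on the opposite allele orientation, so the harmonization layer is
exercised on every run.

**Topologies.**  Each of 100 candidate CpGs owns one block and one label:

* `mediation` (5): three cis SNPs (variance fractions 0.15/0.10/0.06,
  spaced 8 apart, near-separable after clumping) -> CpG -> gene
  (b = 0.6) -> trait (b = ±0.35, alternating sign).  Implied causal
  effect b_cpg→trait = ±0.21.
* `pleiotropy` (10): same cis architecture, but the middle mQTL also hits
  the trait directly (variance 0.004) with no CpG -> trait path.  This is
  the multi-instrument form the outlier filter can act on; the
  single-shared-variant form is indistinguishable from causality by
  construction (it is SMR's null) and is used only for HEIDI calibration.
* `linkage` (10): SNP 0 drives the CpG (0.15), SNP 12 drives the trait
  (0.01), in a high-LD block (dosage r2 ~0.4–0.5 between them).
* `reverse` (10): two cis SNPs drive the trait (0.03/0.02) and the trait
  drives the CpG (b = 0.9).
* `null` (65): cis mQTLs only.

Traits additionally carry a polygenic background (6 loci each, variance
0.004 per locus) and contributions from "pathway" genes: per trait, 4
causal standalone genes (4 eQTLs each with spread variance fractions
0.02–0.14, gene -> trait b = 0.2) and 4 decoy genes (eQTLs, no trait
effect), which give the pathway statistic signal and null material.  The
background is what makes the reverse MR test meaningful: trait
instruments away from the CpG's locus have null methylation effects, so a
mediated (forward) CpG shows no systematic reverse signal, while a
reverse-topology CpG responds to every trait instrument with a common
ratio.  Smoking enters as an upstream binary exposure (prevalence 0.25,
±0.15 SD per CpG with alternating sign) and defines the EWAS-style
candidate list; it is independent of genotype and does not affect the MR
stages.

**Cohorts.**  Reference panel n = 500; mQTL discovery and replication
n = 2,000 each; eQTL n = 5,000; GWAS n = 20,000 — the source data scaled
to desk size (methylation panels of a few thousand, consortium GWAS much
larger), chosen so a full study simulates and screens in ~10 s on one CPU
and the multi-study acceptance run stays in minutes.  All cohorts share
the layout and true effects but draw genotypes and noise independently.
Effects are expressed per SD of genotype using the theoretical dosage SD
sqrt(2f(1−f)), keeping betas comparable across cohorts.

**Trans records.**  Each probe's emitted record set is its cis block plus
records at SNPs that are GWAS-significant for any simulated trait — a
targeted trans lookup mirroring how a reverse MR queries methylation data
at trait instruments.  Purely cis record sets would make the reverse test
degenerate (its only usable instruments would be the shared locus, where
forward and reverse Wald ratios are the same test).

**Effect-size choices** were fixed by design-time power analysis, before
any acceptance measurement, and not revisited: mediation top-SNP GWAS
z ~ 7–11 (comfortably past the 5e-8 SMR gate at n = 20,000), mQTL
z ~ 11–17 at n = 2,000, linkage trait-SNP z ~ 14 (so HEIDI sees the
heterogeneity), reverse trait-SNPs z ~ 20–24 (so the reverse filter has
instruments), background z ~ 9.

## Numerical choices

* p-values are floored at 1e-300; regression p uses the t distribution
  with n−2 df.
* Quadratic-form tails: Imhof integration (scipy `quad`, absolute
  tolerance 1e-11); if the integration error estimate exceeds 1e-4 the
  Satterthwaite approximation is used and labelled.
* GLS: if the instrument LD correlation matrix has condition number
  > 1e8, a ridge of 1e-6 is applied to the correlation factor; a still-
  singular system yields an explicit `numerical-failure` result rather
  than an estimate.
* HEIDI adds a 1e-8 ridge to the d-covariance diagonal; eigenvalues are
  clipped at zero (rank deficiency just drops null directions).
* Clumping ties (equal p) break by ascending position then SNP id.
* Monomorphic SNPs are excluded from LD queries (error) and from summary
  statistics (warning).
* Genotype simulation and the regression sweeps run in float32 (relative
  error ~1e-7, far below sampling noise); everything downstream of
  summary statistics is float64.

## What the synthetic validation shows — and what it does not

Passing the suite establishes that the statistics are computed correctly
(exact oracles for SMR, clumping, IVW), that their null behaviour is
calibrated (SMR and GSMR type-I error, HEIDI under pleiotropy, decoy
pathways uniform), and that under the generator's assumptions the
pipeline recovers planted mediation chains while flagging linkage and
reverse-causation confounds.  The generator does not emulate: realistic
human LD (AR(1) blocks have no long-range structure and uniform decay),
binary or skewed phenotypes (everything is Gaussian; a disease trait
would be a liability scale here), sample overlap between studies,
population stratification, winner's-curse in the candidate list, batch or
cell-composition structure in methylation, or trans-QTL architecture
beyond the targeted lookup described above.  Conclusions about real-data
performance are correspondingly limited; in particular the reverse-MR
filter's behaviour depends on the trait's polygenicity, which is modest
here by construction.

## Known limitations

* Single-shared-variant pleiotropy is accepted by design — it is the SMR
  null and cannot be separated from causality with these data; only
  multi-instrument heterogeneity is filterable.
* The GLS reverse test retains mild anti-conservatism (~10% of truly
  forward pairs show reverse p < 0.05 at these settings, against a
  nominal 5%) — the residual cost of many weakly-correlated instruments
  with a finite LD panel; it is absorbed by the recovery margins.
* The outlier filter's provisional estimator is the median of ratios;
  other implementations iterate a GLS estimate instead, which can differ
  on sets where more than half the instruments are invalid.
* No MR-Egger / weighted-median sensitivity estimators, no multi-trait
  co-localization, no Bayesian colocalization alternative.
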