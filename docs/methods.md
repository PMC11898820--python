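# Methods

`henpop` implements the statistical workflow of a candidate-gene SNP study
in laying hens: variant-site discovery from Sanger-consensus alignments,
per-breed marker diversity statistics, and per-SNP fixed-effect association
with egg-production traits. This note records the models, the numerical
conventions, and the design choices made where the methodology was open.

## Diversity statistics

For a biallelic locus with genotype counts (n_RR, n_RA, n_AA), n their sum:

* **Allele frequencies** by gene counting, p = (2 n_RR + n_RA) / 2n — the
  maximum-likelihood estimator for a codominant marker. Computed as exact
  rationals.
* **Expected heterozygosity** H_E = 1 − p² − q² = 2pq. No small-sample
  (2n/(2n−1)) correction is applied: the statistics are descriptive
  per-population summaries, and the uncorrected form is what the reference
  tables this package reproduces use.
* **PIC** in the biallelic Botstein form, 1 − (p² + q²) − 2p²q²
  = H_E − 2p²q², maximum 0.375 at p = 0.5. The identity PIC ≤ H_E ≤ 0.5 is
  asserted by property tests across a grid of p.
* **Hardy–Weinberg test**: Pearson χ² of observed genotype counts against
  (p²n, 2pqn, q²n), no continuity correction and no exact test. Two df
  conventions are exposed. `alleles_based` (df = 1, the statistically
  standard count: 3 classes − 1 − 1 estimated frequency) is the default and
  is what the type-I calibration targets. `classes_minus_1` (df = 2,
  critical value 5.99 at α = 0.05) is provided because some livestock
  diversity reports classify equilibrium this way; the packaged
  classification checks reproduce such a report only under df = 2.
  Monomorphic loci return χ² = 0, df = 0, flagged, and count as "in HWE".

Report rounding is half-away-from-zero on exact rational intermediates, so
boundary values such as 0.255 round to 0.26 the way a desk calculation
would, rather than following binary-float representation error.

The k-allele generalizations of H_E and PIC are not implemented: every
locus in scope is biallelic by construction (discovery excludes columns
with more than two segregating sample alleles).

## Variant-site discovery

The scan walks alignment columns against a designated reference sequence.
Coordinates are 1-based on the ungapped reference, matching "g.<pos>
<ref>><alt>" site naming; reference-gap columns (insertions relative to the
reference) are skipped without advancing the coordinate. Two-base IUPAC
codes (R, Y, S, W, K, M) are diploid heterozygotes, the Sanger
direct-sequencing convention; three/four-base codes, N and gaps are
missing. Columns with one identical non-reference base across all called
samples are still reported (a substitution fixed among samples); columns
where two alleles segregate but neither matches the reference are polarized
by the major sample allele and flagged. No indel or multi-nucleotide
calling is attempted — the intended inputs are short coding-region
amplicons where such events would invalidate the simple coordinate model
anyway.

## Association model

The fitted model is the one-way fixed-effects ANOVA Y_ij = µ + G_i + e_ij,
with G_i the genotype class at one locus (or the breed). Fitting is OLS on
the cell-means parameterization; with no covariate the LS means are exactly
the arithmetic group means (asserted to 1e-12), and the engine is verified
against a brute-force normal-equations oracle to 1e-10 relative error on
dozens of random balanced/unbalanced designs, with and without covariate.

* **Default model: pooled across breeds.** The marker-trait report has a
  single LS-means column per genotype, which is only consistent with a
  pooled one-way fit. Breed-as-additional-fixed-effect and age-as-covariate
  modes are available by option (`--model breed-factor|age-covariate`);
  in those modes LS means average breed effects equally / hold the
  covariate at its grand mean. Note that in a stratified population the
  pooled model confounds genotype with breed; the breed-factor mode is the
  appropriate choice when genotype frequencies differ by breed.
* **Pairwise comparisons** are two-sided t tests on LS-mean differences
  with the pooled residual variance and error df — unadjusted (Fisher-LSD
  style) by default, matching the common GLM letter-report convention;
  Bonferroni and Tukey–Kramer are selectable.
* **Compact letter display** uses insert-and-absorb: start from one group
  holding all levels, split every group containing both members of a
  significant pair, absorb subset groups; letters are ordered by descending
  LS mean. The partition property (a pair shares a letter iff p ≥ α) is
  property-tested on random p matrices.
* **Degenerate classes**: genotype classes with n = 1 stay in the fit but
  are excluded from letters (their SD/SE is undefined); empty classes are
  dropped with a warning; loci with fewer than two observed classes are
  reported non-testable.
* **Levene's test** uses median centering (Brown–Forsythe), the robust
  default, implemented through the same ANOVA engine and cross-checked
  against an independent implementation. Normality screening is left to
  the user; an optional within-breed |z| > 3.5 outlier filter (off by
  default, removals logged) is provided instead of an automated rule.

## Synthetic studies

The generator emulates the reference design: 117 hens (PH 59, C 20, BB 20,
LC 18), seven biallelic SNPs, eight traits. Defaults are the published
per-breed genotype frequencies (frequency-table mode, which carries the
observed Hardy–Weinberg deviations verbatim) and the published per-breed
trait means/SDs; genotype effects default to zero. Departures from HWE can
alternatively be parameterized by a single inbreeding-style F per locus and
breed, (p² + Fpq, 2pq(1−F), q² + Fpq) — the simplest mechanism producing
heterozygote deficits of the observed kind.

Traits are breed baseline + Σ per-locus genotype values (−a, d, +a) +
Gaussian noise with breed-specific SD, truncated at zero. Truncation keeps
weights/counts physical and is a deliberate slight distortion of exact
normality (negligible for the default baselines, all ≥ 2.4 SD above zero).
Egg mass (EMs) is simulated as an independent trait rather than derived
from egg number and weight; the generator makes no attempt to reproduce
inter-trait correlations, longitudinal laying curves, pedigree structure or
polygenic background. Passing calibration and power checks on these data
therefore validates the estimators under clean model conditions, not
robustness to real-data artifacts.

Every (stage, locus/trait, breed) cell draws from its own substream of the
single study seed (inverse-CDF on a uniform stream for genotypes), so
identical configs give byte-identical output files and adding a locus never
perturbs earlier draws.

Two calibration presets deserve explanation:

* **Null calibration** shares each locus's pooled genotype frequencies
  across breeds while keeping breed-specific trait baselines. Under the
  default per-breed frequencies the pooled genotype F-test has no valid
  null: genotype correlates with breed and breed shifts the traits, so
  rejections would measure stratification, not test calibration. Sharing
  the frequencies makes genotype independent of trait under H0. With this
  preset the cell-level rejection rate of the 56-cell scan sits at α
  within Monte-Carlo tolerance (200 replicates of the 117-hen design), as
  does the df = 1 HWE test on F = 0 draws (n = 500, 2000 replicates).
* **Power preset** homogenizes baselines (weighted grand mean, pooled
  within-breed SD for every breed) so the generator's noise SD equals the
  fitted model's residual SD exactly; the injected additive effect is then
  expressed in residual-SD units without ambiguity. A 1-SD additive effect
  (hom–hom gap 2 SD) at a balanced locus in the 117-hen design is detected
  with monotone LS means in well over 90% of replicates.

## Problem sizes

The packaged checks use 200 replicates for scan calibration and power,
2000 for HWE calibration, 60 random designs for the OLS oracle, and the
full 35-cell published diversity table; these sizes put Monte-Carlo
standard errors comfortably inside the asserted tolerances while keeping
the whole suite under a few minutes on one core.

## Known limitations

* Exactly two of the 35 published diversity-table rows do not recompute
  from their printed genotype counts: one PIC cell (0.50, which exceeds
  the biallelic maximum 0.375 and is almost certainly a transcribed H_E)
  and one χ² cell (printed 30.35 vs 51.22 from the printed counts under
  every convention tried). The package reproduces the correct values and
  documents rather than matches these cells.
* The per-genotype LS-means report of the reference study is not
  numerically reproducible without the raw per-hen records; it is covered
  structurally (shape, letters, p-value logic) and by
  simulation-based calibration/power checks.
* Missing-call handling is supported throughout (".", "NA"), but no
  imputation is attempted; statistics use non-missing counts only.
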