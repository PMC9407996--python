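# Methods

`milkassoc` implements the full statistical chain of a candidate-gene
association study on a paternal half-sib dairy cohort: descriptive SNP
statistics, linkage-disequilibrium structure, a pedigree animal model,
genetic-effect decomposition, and allele-differential binding-site
prediction, together with a synthetic-data generator that emulates the
cohort design so every estimator can be validated against known truth.

## The animal model

For one trait in one lactation the model is

```
y = mu + HYS + b*M + G + u + e,     u ~ N(0, A sigma_a^2),   e ~ N(0, I sigma_e^2)
```

* `HYS` — fixed herd(farm)-year-season class;
* `M` — calving age in months, a covariate with coefficient `b`;
* `G` — the genotype (or block-diplotype) factor under test;
* `u` — the random additive-genetic effect per animal, with `A` the
  pedigree numerator relationship matrix;
* `e` — i.i.d. residual.

`A` is built by the tabular method (`a_ii = 1 + F_i`, unknown parents
treated as unrelated non-inbred founders); `A^{-1}` is assembled
directly from the pedigree by Henderson's rules with the
inbreeding-adjusted Mendelian-sampling variances, and the two are
checked against each other and against a gene-dropping Monte-Carlo
oracle in the tests.

REML estimation is profiled down to the single ratio
`lambda = sigma_e^2 / sigma_a^2`.  Because each record belongs to one
animal, `Z A Z'` is the relationship matrix restricted to phenotyped
animals; one spectral decomposition of that matrix turns every profile
evaluation into `O(n p^2)` work, and `lambda` is found by a bounded
Brent search on `log(lambda)` over `[1e-4, 1e4]` (relative tolerance
1e-6; hitting a bound raises a warning since it means h^2 ~ 0 or ~ 1).
This is numerically identical to solving Henderson's mixed-model
equations at every candidate `lambda`, just cheaper; the MME (with the
sparse `A^{-1}`) are still used for BLUP of the animal effects, and the
test suite verifies the MME solution against dense generalized least
squares on small instances and the REML optimum against a 10^4-point
grid of the dense restricted likelihood.

Inference on `G` is a Wald chi-square on the genotype contrasts with
`df = levels - 1`.  LS-means are adjusted means at equal HYS weights
and the grand covariate mean (set-to-zero constraints; LS-means are
constraint-invariant), with SEs from the REML fixed-effect covariance.
Pairwise comparisons are Wald z-tests whose letter display uses the
insert-and-absorb algorithm, lowercase at 0.05 and uppercase at 0.01.
Bonferroni correction multiplies the raw p by the family size and is
deliberately left uncapped; the family is the SNPs of the same gene for
single-SNP scans (8 and 2 for the two genes of the default panel) and
the number of blocks for haplotype scans.

Choices worth making explicit, since the upstream conventions are not
fully determined: the test statistic is an asymptotic chi-square (no
denominator-degrees-of-freedom correction — at ~900 records per fit the
difference is negligible, and the type-I calibration below confirms
it); variance components are re-estimated for every trait x lactation x
marker combination; the `+/-` column in the output tables is the SE of
the adjusted mean.

## Genotype statistics

Allele frequencies are `p = f(hom1) + f(het)/2` with listwise exclusion
of missing calls.  The Hardy-Weinberg test is the classical chi-square
with expected counts `n*(p^2, 2pq, q^2)` from the observed allele
frequencies, one degree of freedom (three classes minus one minus one
estimated frequency), no continuity correction, pass flag at 0.05.
Monomorphic SNPs are reported as in equilibrium with a warning.  The
exact (Wigginton) test would be preferable for very rare alleles but is
not what the original analysis chain used; it is noted as an extension.

## LD, blocks, and diplotypes

Two-locus haplotype frequencies come from the standard EM over the
double-heterozygote ambiguity (LE-product initialization, tolerance
1e-8, at most 1000 iterations; the log-likelihood is asserted
non-decreasing).  `D' = |D|/D_max` with the usual frequency-dependent
bound.  The 90% interval on `D'` is read off the normalized profile
likelihood on a 101-point grid with allele frequencies and the sign of
`D` held at their MLEs.  Blocks follow the Gabriel
confidence-interval rule with the Haploview default thresholds: strong
LD = CI `[>=0.70, >=0.98]`, strong recombination = upper `< 0.90`, a
span is a block when >= 95% of its informative pairs are strong LD, and
maximal non-overlapping spans are kept longest-first.  Block phasing is
a multi-locus EM over all haplotypes consistent with each multilocus
genotype (block size capped at 12 SNPs, frequencies below 1e-4 pruned
between iterations); haplotypes above 0.05 are retained and labelled
H1..Hk by descending frequency, and each animal receives its
maximum-posterior consistent pair, ties broken toward the globally more
frequent haplotype.  Diplotype classes carried by fewer than 30 animals
(configurable) are excluded from association.

## Effect decomposition

From genotype LS-means, `a = (AA - BB)/2`, `d = AB - (AA + BB)/2`,
`alpha = a + (q - p) d`, where `AA` is the homozygote of the allele
with frequency `p` (the first-listed allele of the SNP); the
orientation is recorded with the result.  Swapping allele labels
negates `a` and `alpha` and fixes `d`, which the property tests assert.

## TFBS scanning

JASPAR PFMs (both the labelled and the bare 4-row dialect) become
log2-odds weight matrices with the JASPAR pseudocount convention: a
total pseudocount of 0.8 split by the background composition (uniform
by default, configurable).  The relative score of a window is
`(S - Smin)/(Smax - Smin)` where `Smin`/`Smax` are the sums of
per-column minima/maxima; uniform (zero-information) matrices are
rejected, and an ambiguous base contributes the column minimum.  For an
allele comparison every window overlapping the SNP on both strands is
scored for the reference- and alternate-substituted sequence; a TF is
present on an allele when its best window reaches the threshold (0.8 by
default), giving the gained / lost / retained / absent classification.
Only this relative-score criterion is implemented: the second tool used
upstream relies on a proprietary matrix library and its "highly
conservative core sequence" rule is not reproducible, which the output
metadata notes.  Verifying the two published site calls additionally
needs the current JASPAR matrices and the bovine flanking sequences,
which the user must supply.

## The synthetic cohort

The generator emulates the study design: 44 unrelated founder sires,
each with a uniform number of daughters out of unique unrelated founder
dams.  The default family-size range is (6, 36) — uniform with mean 21
daughters/sire, inside the cohort's observed 6-62 range — so the
default cohort is ~924 daughters; the observed extremes can be
requested explicitly.  Ten biallelic SNPs mirror the published panel:
two intra-gene blocks (5 + 2 SNPs) whose founder haplotype frequencies
are the published ones proportionally renormalized (they print to a
0.998 total), plus three independent SNPs at the published allele
frequencies.  Gene dropping transmits whole block haplotypes without
recombination and independent SNPs freely, which mirrors tight
intra-gene LD without needing a genetic map.

Phenotypes follow the analysis model generatively: five traits
(305-day milk, fat and protein yields, fat and protein percentages) on
plausible scales, two lactations with a partially overlapping cohort
(fraction 635/924 by default), HYS classes as crossed farm x year x
season effects drawn i.i.d. normal, calving age uniform per lactation,
genotype values coded `+a`/`d`/`-a`, breeding values generated down the
pedigree (founders `N(0, sigma_a^2)`, offspring the parent mean plus a
Mendelian-sampling deviate of variance `(1/2 - (F_s+F_d)/4) sigma_a^2`),
and i.i.d. residuals.  Milk truth is `sigma_a^2 = 4e5`,
`sigma_e^2 = 8e5` (phenotypic SD ~ 1100 kg, h^2 = 1/3).  The default
HYS grid is 5 farms x 3 years x 4 seasons: the real cohort's 22 farms
x 7 years x 4 seasons would put ~600 mostly-singleton fixed-effect
classes on 924 records, which no fixed-effect fit supports; ~60
populated classes keep the design estimable while preserving the
structure.  The default marker effects are a milk QTL of `a = 350 kg`
at the Block-1 tag SNP — an opposite-homozygote spread of 700 kg,
matching the magnitude of the published diplotype spread — and a
fat-yield QTL of `a = 20`, `d = 15` kg matching the magnitude implied
by the published fat-yield LS-means.  Residuals, HYS effects and
breeding values are trait-independent; genetic correlations between
traits are not simulated.

What passing recovery tests therefore show: the estimators are
consistent and calibrated under the model they assume, at the study's
design and scale.  What they do not show: robustness to genotyping
error, selection, non-normal residuals, heterogeneous variances across
farms, or genetic correlations — none of which the generator emulates.

## Validation protocols and the problem sizes used

The shared protocols in `milkassoc.evaluation` are the ones the
reproduction script re-runs:

* **REML recovery** — 20 cohorts at the default design (~924 daughters,
  44 sires); median variance-component estimates land within a few
  percent of truth (the 44-family design limits per-replicate precision
  of `sigma_a^2` to roughly 25%).
* **Additive-effect recovery** — the same 20 cohorts; the LS-mean
  contrast `(hom1 - hom2)/2` recovers `a = 20` on the fat scale.
* **Type-I calibration** — 400 null cohorts of 400 daughters (20 x 20
  families, 2x2x2 HYS); the Wald genotype test rejects at ~5%.
* **Block recovery** — 20 panels of 924 genotypes drawn i.i.d. from the
  founder haplotype frequencies (the sampling model the EM likelihood
  assumes): the two simulated spans are recovered, the ~0.02 haplotype
  is dropped by the 0.05 filter and the ~0.066 ones retained.  Under
  the full half-sib design recovery is noisier — daughters' paternal
  gametes descend from only 88 founder chromosomes, so rare-haplotype
  frequencies fluctuate and the rare-rare SNP pair occasionally loses
  its D' signal honestly — and the script reports that number
  separately.
* **Diplotype power** — with the default 350-kg QTL the Block-1
  diplotype test detects at corrected p < 0.05 in essentially all
  seeds.  A 100-kg-per-copy effect (a 200-kg spread among
  H1-combinations) is *not* reliably detectable at this cohort size and
  variance scale (~20-40% power); claims at that effect size would be
  overreach, so the power protocol takes the effect size as a
  parameter and reports what it measures.

## Numerical details and degenerate inputs

EM tolerances 1e-8; block-EM pruning threshold 1e-4 (safe for cohorts
up to ~5000: any haplotype required by one animal keeps frequency
>= 1/(2n)); REML `lambda` tolerance 1e-6 on the log scale; monomorphic
SNPs flagged and excluded from LD; degenerate D' likelihoods return the
full [0, 1] interval with a warning; all-missing SNPs are excluded with
a warning; a rank-deficient fixed-effects matrix raises an error naming
the confounded terms; single-level factors test trivially (df 0,
p = 1).  Residual variance may be exactly zero in simulations (used by
degenerate-model tests); negative variances are configuration errors.

## Known limitations

Pairwise D' CIs use the profile likelihood with nuisance frequencies
fixed at their MLEs (the convention of the original block-detection
software), not a full Bayesian or bootstrap interval.  Phasing ignores
pedigree information.  The animal model is single-trait with one record
per animal per lactation; repeatability across lactations and
multi-trait REML are out of scope.  The Wald chi-square has no
small-sample df correction.  Bonferroni families are fixed by the
per-gene rule rather than estimated from the correlation structure.
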