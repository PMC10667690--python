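# Methods

`agscreen` implements the statistical chain used to screen rice donors for
tolerance to anaerobic (flooded) conditions during germination: plot-level
phenotypes from an alpha-lattice screenhouse trial are turned into genotype
BLUPs by linear mixed models, combined with a SNP-derived genomic
relationship matrix into genomic estimated breeding values (GEBVs), scored
by a weighted selection index, and filtered by germination thresholds into
ranked donor lists. A synthetic trial generator with known ground truth
closes the loop so that every stage is testable by parameter recovery.

## Trial structure and models

A screening study consists of two calendar experiments, each with a flooded
(anaerobic) and a control (aerobic) condition. Within each
experiment-condition cell, 200 test entries and 8 checks are laid out in a
resolvable incomplete-block ("alpha lattice") design: 2 replications of 16
blocks (crates) x 14 plots; entries appear once per replication and checks
three times (200 + 8x3 = 224 = 16x14). Eight traits are analysed:
germination percentage at 14 and 21 days after seeding (DAS), seedling
height at 14 and 21 DAS (cm), culm diameter (mm), root length (cm), and
shoot and root dry matter (g). Germination percentage is
`germinated / sown * 100` per plot.

Three mixed-model layers share one engine (`MixedModel`):

* **SEA** (single experiment, one condition):
  `y = b0 + replication + block(replication) + u + e`
* **across** (both experiments of one condition): as SEA plus an experiment
  effect, with replications and blocks nested inside experiments;
* **MEA** (everything): an environment contrast for anaerobic vs aerobic,
  with experiments, replications and blocks nested inside environments.

Replications and blocks are fixed effects by default (a `blocks="random"`
switch adds blocks as an i.i.d. random term instead); the genotype effect
`u` is always random with covariance either the identity (phenotypic BLUP)
or the genomic relationship matrix (GBLUP). Fixed factors use
reference-level coding, dropping the first sorted level within each nesting
group; any residual collinearity is removed by rank-revealing QR. Rows with
missing responses are dropped and counted.

## Variance components and solutions

The two-variance model `y ~ N(Xb, s2_g Z K Z' + s2_e I)` is estimated by
EM-REML through Henderson's mixed-model equations. Each iteration solves
the MME once and updates

    s2_g <- (u' K^-1 u + s2_e tr(K^-1 C_uu)) / q
    s2_e <- (y'y - b'X'y - u'Z'y) / (n - rank X)

with `C = s2_e M^-1` the coefficient-matrix inverse. EM never leaves the
parameter space and increases the restricted likelihood monotonically; the
restricted log-likelihood is evaluated every iteration from MME byproducts
(`ln|V| + ln|X'V^-1X| = ln|R| + ln|G| + ln|M/s2_e|`) and the iteration
stops when either the largest relative parameter change or the likelihood
increment falls below the tolerance (default 1e-8, cap 500 iterations).
The likelihood stopping rule matters near boundaries: when the genetic
variance tends to zero, EM shrinks it geometrically and a pure
parameter-change criterion would never trigger. Variances are floored at
1e-10 and a fit finishing on the floor is flagged as boundary convergence.

Singular genotype covariances are handled exactly: the genotype term is
re-expressed in the eigenbasis of `K`, dropping null eigendirections. This
matters because the VanRaden relationship matrix centred with sample allele
frequencies always has a zero eigenvalue (centred dosages sum to zero
across genotypes), and solving through a ridged `K^-1` would otherwise cost
about six digits of agreement with the ridge-regression (RR-BLUP)
formulation. With the eigenbasis route, GBLUP GEBVs and RR-BLUP
marker-effect predictions coincide to machine precision, which the test
suite uses as a permanent oracle.

Derived statistics: plot-basis broad-sense heritability
`H2 = s2_g / (s2_g + s2_e)` (with random blocks the block variance enters
the denominator); prediction error variances (PEV) are the genotype block
of `s2_e M^-1`; per-genotype reliability is `1 - PEV/s2_g` clipped to
[0, 1], averaged over phenotyped genotypes for the trait-level value. Note
that with an estimated intercept the PEV of every genotype carries a
`s2_g/q` contribution from the ambiguity between the intercept and the mean
genotype effect, so the "noiseless" reliability limit is `1 - 1/q`, not 1;
at trial scale (q = 208) the distinction is negligible.

## Marker QC and the genomic relationship matrix

Dosages count alternate-allele copies (0/1/2, NaN missing). QC removes
samples first (call rate < 0.66 or heterozygosity > 0.10 — rice lines are
near-fully inbred, so high heterozygosity indicates contamination), then
markers (call rate < 0.90 or minor-allele frequency < 0.01), all
configurable. Missing cells are imputed with the marker mean `2p`, which
leaves allele frequencies unchanged. The GRM is VanRaden's first estimator
`G = ZZ' / (2 sum p_j (1-p_j))` with `Z` centred by `2p` from the sample
itself; an optional ridge (default 1e-6) is kept for interoperability but
is not needed for solvability thanks to the eigenbasis solver.

## Outlier screening

Data cleaning uses an iterative Bonferroni outlier test. Within each
(experiment, condition, trait) cell the SEA model itself is fitted
(genotype random) and conditional residuals `e = y - Xb - Zu` are
studentized with `Cov(e) = s2_e (I - H)`, `H` the hat matrix of the full
MME system, then mapped to the external (leave-one-out) scale with
`t = r sqrt((df-1)/(df-r^2))`. The observation with the largest |t| is
removed if its Bonferroni-adjusted two-sided p-value is below alpha
(default 0.05) and the model is refitted until nothing is flagged, making
the screen idempotent. Keeping the genotype effect *random* here is
essential: with genotype fixed and two replicates per entry, an outlier and
its clean partner receive symmetric residuals and the wrong one is removed
about half the time; shrinkage breaks that symmetry (measured sensitivity
rises from ~0.64 to ~1.0 for +10-sigma contamination). A cell with fewer
than two residual degrees of freedom is skipped with a warning. A pair of
aberrant replicates of the same genotype remains indistinguishable from a
genuinely extreme genotype; such plots are not flagged.

## GEBVs, selection index and donor rules

GEBVs per environment ("anaerobic" and "aerobic" fit the joined experiments
of one condition; "across" uses the MEA model) are the GBLUP genotype
effects recentred by the population-average fitted fixed part, so
germination GEBVs live on the 0-100 percent scale. Within an environment
each trait's GEBVs are standardized over genotypes (mean 0, SD 1) and
combined as `I_g = sum_t w_t x_gt` with weights
germ14:10, germ21:8, shootdm:7, height14:5, rootlen:5, height21:4,
rootdm:4, culm:3 — germination dominates because emergence through the
floodwater is the trait under selection. Standardization before weighting
is the package's resolution of an open design point: weights applied to raw
trait scales would be dominated by the percentage-scale traits and produce
indices far outside the plausible reporting range; a
`standardize=False` switch exposes the raw-scale alternative. One weight
set serves all three selection rules.

Donor rules are strict conjunctions on the index and the *phenotypic*
21-DAS germination BLUP: index >= 25 with germination >= 70% (anaerobic
rule) or >= 80% (aerobic and across rules). Checks are flagged but
retained in the lists; entry counts exclude them.

## Synthetic trial generator

The generator defines the study conditions; it is parameterised once and
not tuned against test outcomes.

* **Markers**: ~1000 SNPs, allele frequencies uniform on [0.05, 0.95],
  inbred-line genotypes with inbreeding coefficient F = 0.95 (residual
  heterozygosity ~2%, matching inbred rice panels; F = 0 recovers
  Hardy-Weinberg binomial sampling). Missingness 6% by default, matching a
  ~94% call rate. Under inbreeding the VanRaden diagonal averages ~1+F.
* **Breeding values**: marker effects i.i.d. normal per trait, mixed through
  the Cholesky factor of a fixed 8x8 genetic correlation matrix
  (germination timepoints r=0.85, growth traits moderately coupled, culm
  nearly independent); TBV = centred dosages x effects, rescaled so each
  trait's TBV variance equals `h2 x s2_p` exactly.
* **Phenotypes**: plot value = condition mean + experiment offset (0.10
  phenotypic SD) + replication offset (0.05 SD) + block effect (variance
  0.05 s2_p) + TBV + residual with variance `(1-h2) s2_p`. Condition means
  are anchored to a published flooded-vs-control screening (e.g. 14-DAS
  germination 29.4% flooded vs 98.3% control; shoot dry matter 0.025 g vs
  0.071 g); default plot-basis heritabilities are germ14 0.71, germ21 0.65,
  height14 0.50, height21 0.68, culm 0.40, rootlen 0.36, shootdm 0.56,
  rootdm 0.46; phenotypic SDs are germ 20 points, heights 4/6 cm, culm
  0.35 mm, root length 1.8 cm, shoot/root dry matter 0.009/0.0035 g,
  chosen to reproduce the published genotype-mean ranges. Germination
  becomes a count out of 30 seeds per plot by rounding and truncating the
  latent percentage; measurements are floored at zero.

The generator emulates the trial's *statistical* structure, not its
physiology: no coleoptile growth dynamics, no temperature or water-depth
model, genetic correlations identical in both conditions, and a shared TBV
across conditions (genetic correlation 1 between environments). Passing
recovery tests therefore demonstrates that the estimation chain inverts
this latent-Gaussian generative model at realistic signal levels — not that
real screenhouse data meet its assumptions. Truncation of germination at
0/100% slightly biases recovered heritability downward at the flooded mean
(~29% germination), which is visible as recovered H2 ~0.70 against a
configured 0.71.

## Numerical and design choices

* EM-REML rather than a derivative-based REML: monotone, bounded, and fast
  enough here (each iteration is one Cholesky of the ~(p+q) MME).
* Reference level = first sorted factor level; this affects fixed-effect
  reporting only, never BLUPs.
* Alpha-lattice randomization is a constrained random allocation (entries
  once, checks three times per replication, blocks filled in chunks); no
  concurrence optimisation.
* Check genotypes are generated from the same model as entries; their
  tolerant/susceptible labels are metadata.
* Ties in donor ranking break by germination BLUP, then genotype label, so
  output files are byte-reproducible.
* Deterministic seeding throughout: each generator stage draws from a
  `SeedSequence(seed, spawn_key=stage)` stream.

## Problem sizes used in tests

Unit tests run miniature lattices (20 entries + 2 checks, 2 blocks x 13
plots, 150 markers) where structure, not power, is under test. Recovery and
determinism checks run the full default geometry (208 genotypes, ~1000
markers, 4 experiment-condition cells, 1792 plots): 20 seeds for
heritability recovery, 10 seeds per heritability level for GEBV accuracy,
100 seeds for the outlier operating characteristics, and two end-to-end
pipeline runs for byte-level determinism.

## Known limitations

* Heritability is plot-basis by default; an entry-mean basis
  `s2_g/(s2_g + s2_e/r)` can be derived from the reported components but is
  not the headline number.
* Traits are fitted independently (no multi-trait REML), matching the
  analysis the package reproduces.
* No LD pruning, population-structure correction, or pedigree matrices.
* Selection-index weights are fixed economic weights; no Smith-Hazel
  optimisation.
* Germination percentages are analysed with Gaussian models, adequate away
  from the 0/100 boundaries but approximate at the aerobic ceiling.
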