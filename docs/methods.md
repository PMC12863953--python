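# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of `liabel`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## Evaluation models

Both models are single-trait animal models with contemporary-group (CG) fixed
effects and additive genetic effects whose prior covariance is the single-step
relationship matrix `H` (pedigree `A` combined with genomic `G`):

* **Linear model** — the 0/1 record is fitted directly. Variance components
  are on the observed scale; heritability `h²ₒ = σ²ₐ/(σ²ₐ+σ²ₑ)`.
* **Threshold (liability) model** — a latent standard-normal liability
  generates the record by exceeding a threshold. Identification with a single
  threshold requires fixing two quantities: the residual variance is fixed at
  1 and the threshold at 0, with the threshold's location absorbed by the CG
  effects. Heritability `h²ₗ = σ²ₐ/(σ²ₐ+1)` is on the liability scale.

### Gibbs sampler

Single-site Gibbs updates throughout (`liabel._gibbs`, compiled with numba):

* CG effects from normal full conditionals under a vague `N(0, 10¹⁰)` prior —
  numerically indistinguishable from flat, which is why undersized or
  invariant CGs must be filtered first (see *Quality control*).
* Animal effects from normal full conditionals; the prior precision
  contribution of animal *k* is row *k* of `H⁻¹/σ²ₐ`. A running vector
  `w = H⁻¹a` is updated incrementally (O(n) per site, symmetric row access)
  and refreshed against floating-point drift every 1,000 iterations, so a
  full sweep costs O(n_records + n_animals²).
* Variance components from scaled inverse chi-square full conditionals.
  Default hyperparameters ν = −2, scale = 0, i.e. flat on the variances.
* Threshold model only: each latent liability is redrawn from its normal full
  conditional truncated at 0 on the side fixed by the observed category.
  Truncated normals use the inverse-CDF method (Acklam's rational
  approximation of Φ⁻¹, |error| < 1.2·10⁻⁹) with Robert's shifted-exponential
  rejection sampler beyond 4 SD, where the CDF saturates.

Chain defaults are desk-scale: 50,000 iterations, 10,000 burn-in, thinning 50.
Production analyses of this model class commonly run 300K–1M iterations with
30K–500K burn-in; the configuration accepts those values unchanged. Variance
starting values default to half the response variance each (linear) or 0.5
(threshold) — starting far above the response scale makes the variance chain
take tens of thousands of iterations to find the posterior's range.

`solve_mme` solves Henderson's mixed-model equations with the same design
matrices and `H⁻¹` at fixed variance components. Because the Gibbs joint
posterior mean at fixed variances coincides with the MME solution, it serves
as a deterministic oracle: the test suite checks agreement within
Monte-Carlo error (batch-means standard errors) on small fixtures, plus a
closed-form ridge-shrinkage identity when `H⁻¹ = I`.

### A caution on flat variance priors with weak binary data

With a flat prior and *weak* data — few records, tiny families, or severe
case/control imbalance — the marginal posterior of σ²ₐ in the threshold model
is extremely heavy-tailed (family category patterns barely penalize large
variances), and the variance chain can wander to implausible values for long
stretches. This is a property of the posterior, not a sampler defect: on the
same data the linear model, an exact REML fit, and the Gibbs chain agree. The
practical remedies are informative family structure (see the generator
defaults below), more data, or a proper prior via the ν/scale hyperparameters.
The convergence diagnostics (Geweke, Heidelberger–Welch) flag the pathology
when it occurs.

## Relationship matrices

* `A` by the tabular (recursive) method with inbreeding; validated against
  Wright's path-counting coefficients on small pedigrees.
* `G` by centred gene contents, `G = (M−P)(M−P)′ / (2Σpᵢ(1−pᵢ))`, with
  allele frequencies observed among the genotyped animals (the base-population
  frequencies are unknowable without deeper pedigree genotyping; a `supplied`
  mode exists). The SNP panel must be at least as large as the genotyped set
  or `G` is rank-deficient and, even after blending, a noisy description of
  relationships — the test fixtures use panels ≥ the genotyped count.
* `G` is blended with `A₂₂` (default 0.95/0.05) before inversion; this is the
  standard guarantee of positive definiteness. No tuning of `G`'s mean or
  scale to `A₂₂` is applied by default.
* `H⁻¹ = A⁻¹ + block(G_b⁻¹ − A₂₂⁻¹)`, assembled densely. All inverses are
  dense (Cholesky-checked); the intended scale is ≤ ~20K animals. Sparse
  Henderson rules for `A⁻¹` are a documented optimization, not implemented.
* Pedigrees are truncated to a configurable ancestor horizon (default 3
  generations) from the anchor set, which defaults to all phenotyped or
  genotyped animals; parents beyond the horizon are recoded unknown.

## Quality control

Filter order is fixed and matters: (1) CGs with fewer than 10 phenotyped
animals, (2) CGs without phenotypic variability (all 0 or all 1 — under an
effectively flat CG prior such groups send their effect, and with it the
latent liabilities, on an unbounded random walk), (3) CGs outside the largest
sire-connected component. Connectedness uses a graph with CGs as nodes and an
edge when two CGs share at least `min_links` sires (default 1, the weakest
rule; stricter values are exposed). Re-running QC on clean data is a no-op.

Genomic QC removes SNPs failing a one-degree-of-freedom asymptotic chi-square
HWE test at p < 10⁻¹⁵ (an exact test is pointless at a threshold only
meaningful asymptotically), call rate < 0.90, or MAF < 0.02; a SNP failing
several criteria is tallied under the first, in that order. Surviving missing
genotypes are mean-imputed to 2pᵢ, which is what the `G` construction
requires. An animal call-rate filter exists but is off by default.

## Synthetic populations

The generator produces the structure the models assume, so that every
downstream stage is testable against known truth:

* **Pedigree** — discrete non-overlapping generations, random monogamous
  pairing, `offspring_per_mating` per pair, balanced sexes. `n_generations`
  counts all generations including the founders.
* **Genotypes** — neutral biallelic SNPs by gene dropping: founder allele
  counts Binomial(2, p) with p uniform in `maf_range`, offspring receiving
  one allele per parent; loci unlinked. Markers are informative about
  relationships only through family structure (the models are pedigree/
  genomic BLUP, not marker-effect models; a marker-effect variant is a
  non-goal).
* **Breeding values** — infinitesimal model: founders N(0, σ²ₐ), descendants
  midparent plus a Mendelian-sampling deviate with variance
  0.5σ²ₐ(1−(F_s+F_d)/2).
* **Liability and phenotype** — total standardized liability variance is 1,
  so σ²ₐ = h²ₗ and σ²ₑ = 1−h²ₗ, matching the threshold model's
  identification. The defect is recorded when the standardized liability
  (breeding value + residual) exceeds t = Φ⁻¹(1−α). CG labels are global,
  assigned at random within generation, and their simulated effects are
  stored separately from the liability: randomized CGs guarantee
  CG–genetics independence (so CG filters can be tested cleanly) and keep
  the realized prevalence at α by construction. A consequence worth knowing:
  the simulated binary outcome carries no CG signal, so fitted CG effects
  hover near zero — the machinery is exercised, the confounding of real
  field data is not reproduced.
* **Partial genotyping** — a random subset (`prop_genotyped`, default 0.4)
  of animals is genotyped.

Defaults describe a mid-size herd slice: 1,000 founders, 3 generations
(3,000 animals), prevalence 6% and h²ₗ = 0.35 — the centre of the 4–8%
prevalence and 0.18–0.54 liability-heritability ranges published for
morphological defects in Nellore cattle — CG effect SD 0.25 on the liability
scale, 800 SNPs.

**What the generator does not emulate:** overlapping generations, selection
(and hence trends or Bulmer effects), linkage/LD, non-random mating, CG
effects that actually shift the binary outcome, genotyping targeted at
influential animals. Passing tests therefore demonstrate correctness of the
machinery under the stated generative model, not robustness to every feature
of field data.

### Parameter-recovery fixture

Binary records inform σ²ₐ only through family resemblance. With pairs leaving
two offspring, a 3,000-animal herd at 10% prevalence carries almost no
heritability information (the exact eigendecomposition-REML oracle used
during development confirms huge sampling error). The recovery fixture in the
test suite therefore uses 150 full-sib families of 18 (300 founders, one bred
generation, n = 3,000) with a 1,500-SNP panel and 40% genotyping — a design
whose own REML value sits close to the simulated truth — and runs both models
at 50K/10K/thin-50. The tests assert that the threshold model's posterior
mean h²ₗ is within 0.10 of the simulated truth and inside its own 95% HPD,
and that the linear model's estimate, converted through the Dempster–Lerner
formula, agrees with the threshold estimate within 0.10.

## Scale conversions

* `h²ₒ = z²h²ₗ/(α(1−α))` and its exact inverse; the conversion strictly
  contracts (z² < α(1−α) for every α), so observed-scale heritabilities of
  binary traits are always below their liability-scale counterparts.
* **Variance–heritability adjustment** (approach 1): linear scaling of
  observed-scale GEBVs using the observed-scale residual variance and the
  heritability ratio. Two algebraic parses of this scaling circulate in the
  literature's flattened typesetting; both are provided
  (`parse="scale_by_ratio"`, the default, and `parse="divide"`), both are
  linear and hence rank-preserving, and neither is asserted as canonical.
* **Threshold-density adjustment** (approach 2): division by
  z\* = √((h²ₒ/h²ₗ)·α(1−α)). The square root is deliberate: only this
  reading makes z\* equal the normal ordinate φ(t) whenever h²ₒ and h²ₗ are
  Dempster–Lerner-consistent — which is what "threshold density" means — and
  the test suite asserts that identity.
* **Probability transform**: P = 1 − Φ((t − (U − μ_U))/σₑ), strictly
  increasing in the liability GEBV, with the average animal mapped exactly to
  the prevalence. The reference mean μ_U is taken over all animals in the
  table (taking it over sires only would merely shift every probability; the
  choice is exposed). σₑ defaults to 1, the liability-scale residual SD. A
  `printed` orientation flag reproduces the decreasing form
  Φ((t − μ_U − U)/σₑ) found in some published summaries. Note the identity
  anchors the *mean animal* at P = α; the mean of P across animals exceeds α
  slightly because the transform is convex below the threshold.

## Model comparison

Sires need ≥ 10 phenotyped offspring to enter selection comparisons. The top
fraction (default 10%) uses the ceiling convention k = ⌈0.10·n⌉ — the only
convention consistent with published selection counts such as 804 → 81 —
with "top" meaning *lowest* defect GEBV (most desirable; a direction flag
exists since the sign convention is not universal). Ties break by id,
deterministically. The four-way classification (both / linear-only /
threshold-only / neither) satisfies the partition identity
`both + linear_only + threshold_only + neither = n` on every input, with
`linear_only = threshold_only = k − both` for equal-size selections.
Spearman correlations are reported both over all eligible sires and over the
union of selected sires (published summaries are ambiguous about which set
was used, so both are emitted). Genetic correlations among traits are
*approximated* by Pearson correlations of GEBVs over a common sire set — a
proxy, biased toward the correlation of prediction errors, used when
multi-trait models cannot be fitted; true bivariate estimation is a non-goal.

## Convergence diagnostics

Geweke's z compares the first 10% and last 50% segment means with
batch-means spectral standard errors (20 batches); it is affine-invariant,
and a constant chain reports z = 0 with a degeneracy flag. The
Heidelberger–Welch stationarity test applies the Cramér–von Mises statistic
to the Brownian bridge of partial sums, discarding initial 10% increments up
to 50%; the halfwidth test requires the 95% Monte-Carlo halfwidth to be at
most 10% of the mean, reported as not-applicable when the mean is numerically
zero. Critical values are tabulated at α ∈ {0.10, 0.05, 0.025, 0.01}. HPD
intervals are the shortest contiguous window containing ⌈mass·n⌉ sorted
draws (never wider than the equal-tailed interval, by construction; ties in
window width resolve to the lowest window). No numeric threshold is a
pass/fail gate — |z| < 1.96 and the 5% CvM level are advisory flags.

## File formats

Plain text throughout: pedigree CSV (`animal,sire,dam`, 0 = unknown,
topological repair with a warning, cycles rejected), phenotype CSV
(`animal,cg,<trait>` with 0/1/NA), whitespace-delimited genotype matrix with
a SNP-id header (PLINK-RAW-compatible subset, strict 0/1/2/NA on input),
GEBV TSVs and relationship-matrix triplet files with `#key=value` provenance
headers, QC/diagnostic/concordance reports as JSON. The pipeline writes a
manifest with the config hash and seed; identical config and seed reproduce
identical artifacts byte-for-byte.

## Known limitations

Dense linear algebra bounds the population size (~20K animals). Single-site
Gibbs mixes slowly for variance components in large weak designs; block
updates are an obvious optimization hook. Multi-trait models, REML,
marker-effect parameterizations, metafounders, unknown-parent groups, APY,
and genotype imputation are out of scope. The AMC-style connectedness check
is a single-rule approximation (shared-sire counts), not a full genetic-link
count.
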