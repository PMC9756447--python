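# Methods

## The model and its assumptions

`pathmix` estimates the effects of gene sets ("pathways" throughout; any
GMT-defined sets work) on a quantitative trait using only single-SNP GWAS
summary statistics. The observation vector **y** contains one value per
gene: the absolute value of the estimated additive effect of the gene's
strongest SNP. The model is

    y = 1μ + Zt + e,   t ~ N(0, V σ_t²),   e ~ N(0, I σ_e²),

with Z the binary gene×pathway incidence matrix and V the Jaccard
similarity between the pathways' gene sets. The key assumptions are:

* **Known variance components.** σ_t² and σ_e² are not estimated; they are
  a fixed split of the sample variance of y (unbiased, n−1 denominator):
  σ_t² = ratio·σ_y², σ_e² = (1−ratio)·σ_y², with ratio 0.3 by default. The
  split is a modelling convention, not an estimate, so `ratio_t` is exposed
  as a parameter rather than hard-coded. REML/ML estimation is deliberately
  out of scope.
* **One SNP per gene.** "Strongest" is interpreted as the largest absolute
  effect estimate, consistent with y being absolute effects; a
  `min_pvalue` criterion is available for users who prefer significance
  over magnitude. Ties break by smaller p-value (when present), then
  lexicographic SNP id, so collapsing is order-invariant and idempotent. A
  SNP inside overlapping genes may represent each of them; discarding it
  would throw away signal.
* **Annotation-defined similarity.** V[i,j] = |Gᵢ∩Gⱼ|/|Gᵢ∪Gⱼ| is computed
  from the pathways' full gene sets as given in the GMT file, not from the
  subset of genes observed in a particular dataset: pathway similarity is a
  property of the annotation, and this keeps V identical across datasets
  that share a gene-set release.
* **Genes outside all pathways** are dropped from y by default — they
  cannot inform t and would only perturb μ̂. `keep_unmapped` retains them
  with an all-zero incidence row. Pathways with zero observed genes are
  dropped from the run and logged.

## Solving and testing

Henderson's mixed model equations are assembled explicitly with R = I σ_e²
and G = V σ_t² and solved by Cholesky factorization of the (p+1)×(p+1)
coefficient matrix; at the few-hundred-pathway scale of curated collections
this is exact, fast, and needs no iterative solver. The test suite checks
the solution against two independent closed forms (the GLS/BLUP expression
through the full n×n phenotypic covariance, and a brute-force dense inverse
of the same equations) to 1e−8 relative error or better.

Each predicted effect is tested one-sided, H₀: tᵢ ≤ 0 vs H₁: tᵢ > 0, by the
upper-tail probability of t̂ᵢ under the prior density N(0, σ_t²):
pᵢ = 1 − Φ(t̂ᵢ/σ_t). Two consequences are worth stating plainly. First,
negative predictions always give p > 0.5 and can never be significant.
Second, the reference variance is the prior variance of t, not the
prediction-error variance of the BLUP; since BLUPs are shrunken, their
realized spread is smaller than σ_t and the test is conservative — under
all-null simulations the empirical type-I error at α = 0.05 is far below
nominal (the acceptance suite measures it at ~0). The significance flag
uses p ≤ α with α = 0.05 by default. No multiple-testing correction is
applied by default; Benjamini–Hochberg is available via `--adjust bh`
(delegated to statsmodels).

## Numerical choices

* **Singular V.** Duplicate (or identical-after-intersection) gene sets
  make V exactly singular. The Jaccard kernel is positive semidefinite, so
  the only tolerance needed is for rounding: if the smallest eigenvalue of
  V falls below 1e−8, a configurable ridge (default 1e−8·I) is added and
  logged, and duplicate sets are reported as a warning. If V is still not
  positive definite at solve time, the solver raises an error naming the
  offending pathway pairs rather than returning a pseudo-inverse answer.
* **Coordinates.** Internally 1-based inclusive; BED input is converted on
  read (and back on write), GFF3 is taken as-is. Strand is carried but
  ignored for SNP overlap. Positional assignment uses an interval tree with
  an optional symmetric flank (`flank_bp`, default 0).
* **Degenerate inputs.** Constant y (no variance to partition), empty gene
  sets, and zero gene/pathway overlap are hard errors with stage-labelled
  messages, not silent NaNs. p-values are clipped to the open interval
  (0, 1) so logs and flags stay finite.
* **Determinism.** Collapsing has a total tie-break order; result tables
  sort by p-value then pathway id; writers emit floats at six significant
  digits. Two runs on the same inputs are byte-identical.

## The simulator

`pathmix.simulate` draws data from exactly the generative model the
estimator assumes: pathway effects t ~ N(0, V σ_t²) (a configurable
fraction forced to zero), residuals e ~ N(0, I σ_e²), and gene values
μ + (Zt)_g + e_g. Each gene's designated top SNP carries that value as its
effect magnitude with a random sign — the model consumes |effect|, so the
sign flip also exercises the absolute-value transform — and decoy SNPs
carry strictly smaller magnitudes (uniform 0.2–0.9 of the top), so
gene-level collapsing provably recovers the designated SNP. Genes are laid
out as non-overlapping 1 kb intervals on one synthetic chromosome;
consecutive pathways share `round(overlap_fraction·size)` genes so V has
non-trivial off-diagonals. All outputs can be emitted through the package's
own writers, making the simulator an end-to-end fixture factory.

Defaults: 40 pathways × 25 genes, overlap 0.1, 3 SNPs per gene, μ = 1,
σ_y² target 0.09, ratio 0.3. μ and σ_y² give a coefficient of variation of
0.3 for the gene-level values, typical of a well-powered GWAS effect
spectrum after collapsing and — more importantly — keeping essentially all
values positive so that |·| is benign; the variance ratio matches the
model's default split. Everything is seeded (`numpy.random.default_rng`
with per-stream keys), so identical configs give hash-identical files.

What the simulator does **not** emulate: linkage disequilibrium, allele
frequencies, genotype sampling noise, or the construction of deregressed
pseudophenotypes — the upstream GWAS is outside the model being tested.
Passing recovery and calibration tests therefore demonstrate that the
estimator correctly inverts its own generative model at realistic scale,
not that real summary statistics satisfy that model; on real data the
independence of residuals across genes (no LD between top SNPs of nearby
genes) is the assumption most likely to be violated.

## Scales used by the checked experiments

The acceptance suite runs solver equivalence on 200 random instances (≤ 30
genes, ≤ 8 pathways), null calibration on 500 all-null replicates at
40 × 25, recovery on 50 replicates at 40 × 25 plus 15 replicates at each of
5/15/45 genes per pathway, and one full-scale run at 179 pathways /
~5,000 collapsed genes / ~15,000 SNPs. These sizes were chosen to mirror a
realistic curated-pathway analysis while keeping the whole suite
comfortably within a few minutes on one CPU; the full-scale run itself
completes in about a second, the bulk of the time being the replicated
simulation experiments.

## Known limitations

* Variance components are assumed known; misspecifying `ratio_t` biases
  the shrinkage and the p-value scale (the test's conservativeness grows as
  ratio_t shrinks).
* The σ_t-based test controls type-I error but sacrifices power; a
  prediction-error-variance test would be sharper but is a different
  statistic, intentionally not implemented.
* One SNP per gene ignores allelic heterogeneity within a gene.
* The Jaccard covariance treats pathways as flat sets: gene overlap is the
  only source of correlation, with no topology or weighting.
* Per-dataset invocation only; no meta-analysis across datasets.
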