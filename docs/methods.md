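# Methods

This note documents the statistical models, numerical choices and
simulation conventions behind `magicgs`, and what its synthetic-data tests
do and do not demonstrate about real data.

## The mixed model and its variance components

For a single trait measured on plants across sequential experiments the
model is

    y = X b + Z u_a + Z u_n + e

with fixed experiment effects `b` (reference coding, first experiment as
reference), plant-to-line incidence `Z`, additive genetic effects
`u_a ~ N(0, σ²ₐ G)` where `G` is the VanRaden genomic relationship matrix,
an iid "residual genetic" line effect `u_n ~ N(0, σ²ₙ I)` capturing
genetic variation the markers miss, and residual `e ~ N(0, σ²ₑ I)`. The
BLUPs of `u_a` are the genomic estimated breeding values (GEBVs); the
total genetic value of a line is `u_a + u_n`.

**Scale of σ²ₐ.** In a fully inbred panel the diagonal of the VanRaden
`G` averages approximately `2 − (residual heterozygosity contribution)`,
so the variance among line values implied by the model is `σ²ₐ ·
mean(diag G)`, roughly twice the reported component. Heritabilities are
unaffected (PEV and σ²ₐ share the scale), but comparisons of `σ²ₐ`
against an externally defined line variance must apply the `mean(diag G)`
factor. The parameter-recovery test does exactly this.

## REML estimation

Variance components maximise the restricted likelihood via
average-information (AI) updates with EM-flavoured fallback steps and
componentwise projection onto the feasible region:

- Likelihood, scores and the AI matrix are evaluated through Henderson's
  mixed-model equations, using the identity
  `log|V| + log|X'V⁻¹X| = log|R| + log|G_b| + log|C|`, so the
  per-iteration cost scales with the number of lines (hundreds) rather
  than plants. The implementation is verified in the test suite against a
  dense-`V` likelihood and against an exhaustive grid search.
- The AI system is solved by a minimum-norm least-squares solve so that
  exactly collinear components (e.g. an identity relationship matrix,
  which makes `u_a` and `u_n` indistinguishable) still yield an ascent
  direction in the identifiable subspace.
- Step-halving line searches guarantee monotone likelihood ascent;
  candidates are clipped componentwise at a floor (1e-10 of the
  phenotypic variance for genetic components; 1e-6 for the residual,
  which must stay away from zero to keep the equations well conditioned).
- Convergence requires a relative parameter change below 1e-8 or a
  likelihood change below a noise-aware tolerance, and is confirmed by an
  EM probe step: if the probe still improves the likelihood materially,
  iteration continues. Maximum 200 iterations.
- A genetic component converging onto the zero boundary (below 1e-6 of
  the phenotypic variance) is fixed at exactly zero by dropping it and
  refitting the remainder. This reproduces the common empirical outcome
  σ²ₙ = 0, in which case the narrow- and broad-sense heritabilities
  coincide by construction.
- `G` is singular by construction (column centering), so the REML core
  lifts its spectrum by the smallest diagonal jitter that brings the
  minimum eigenvalue to 1e-6 of the maximum; the jitter is recorded. The
  GRM itself is additionally bent (smallest of 1e-8/1e-6/1e-4 on the
  diagonal) if numerically indefinite, also recorded.

**Heritabilities.** Following the prediction-error-variance formulation,
`H² = 1 − PEV_g/σ²_g` and `h² = 1 − PEV_a/σ²ₐ`, where PEV is the mean
diagonal of the BLUP prediction-error-variance matrix of the total
genetic (`u_a + u_n`) and additive estimates respectively, read off the
inverse mixed-model-equation coefficient matrix. Values outside [0, 1]
are clamped and the clamping recorded. A variant based on the mean
variance of pairwise BLUP differences exists in the literature; the
plain `1 − PEV/σ²` form is implemented as the default definition here.

**Genetic coefficient of variation.** The default is the standard
percentage form `gCV = 100·σ_g/μ` (genetic standard deviation over the
trait mean). A literal `σ²_g/μ` mode is also provided because that
variance-over-mean ratio is sometimes quoted; it is dimensionally
inconsistent with percentage-scale tables, which is why the SD form is
the default. Neither mode is asserted to be the other's equal.

**Prediction of unphenotyped lines.** The conditional route
`u_new = G_{new,train} G⁻¹_{train,train} û_train` uses a minimum-norm
solve (exact for BLUPs, which lie in the range of `G_train`); a joint
mixed-model-equation solve over training plus new lines is provided as an
independent route and the two agree to numerical precision for
positive-definite training blocks.

## Adjusted means

Line-level adjusted means come from the fixed-effects model
`trait ~ line + experiment` (OLS via statsmodels); the adjusted mean of a
line is its fitted value averaged over all experiments (estimable
marginal mean). With balanced data or a single experiment this reduces to
the raw line mean. The GBLUP default fits plant-level records with fixed
experiment effects; a means mode (one record per line, intercept only,
`u_n` dropped as confounded with the residual) exists and is what
cross-validation uses for speed.

## GWAS

Each SNP is tested by OLS of the adjusted mean on an intercept, the first
`n_pcs` genotype principal components (default 3; columns centered,
scaling optional and off by default) and the SNP dosage, with a two-sided
t-test on the dosage coefficient — equivalent to an additive-coding
general linear model scan. Collinear SNPs get missing p-values with the
reason recorded in the counts. Significance uses the Bonferroni line
`−log₁₀(α/n_SNPs)`, α = 0.05. Reported per-SNP `R²` is the partial
`t²/(t² + df)` of the dosage term given the covariates.

Regions around a significant peak are delimited within a physical window
(default 4 Mb total, i.e. ±2 Mb; a flag widens to ±4 Mb) by SNPs in LD
with the peak (`r² ≥ 0.4` by default — the boundary value is a package
choice, always recorded in the region metadata) that are themselves
significant or strongly supported (`−log₁₀(p) > 5`). With no supporting
SNP the region collapses to the peak position. No cross-trait
multiplicity adjustment is applied beyond the per-scan Bonferroni.

## Smith–Hazel index

`b = P⁻¹ G a` with `P` the sample covariance of phenotypic values across
lines (adjusted means by default; raw line means configurable), `G` the
sample covariance of additive genetic values, and economic weights
`a = 1` for the six drought traits (total dry weight, total dry-weight
growth, root dry weight, flavonol index, total water content, proline).
`P`'s condition number is reported; an optional ridge of
`1e-6 · mean(diag P)` handles near-singularity and is recorded. Index
values for unphenotyped lines always reuse the weights estimated on the
phenotyped set. Classification takes the top-k and bottom-k lines by
index with lexicographic tie-breaking. PCA of genetic values standardises
each trait and eigen-decomposes the correlation matrix, fixing signs so
each component's largest-magnitude loading is positive.

## Cross-validation

Folds partition lines (never plants) to avoid leakage between replicates
of a line. Each training set is refitted from scratch — variance
components included — in means mode, and held-out lines are predicted by
the conditional route. One predictive ability `r` per repeat is the
Pearson correlation over the pooled held-out predictions of all k folds;
the summary is the mean ± standard error over repeats. A single seeded
generator drives all repeats, and fold assignments are exported for
audit. LOOCV is the k = n single-repeat special case and matches it
exactly. Prediction accuracy divides `r` by `√h²` from the complete-data
fit (never per-fold), with the sign of `r` carried through.

## Synthetic MAGIC generator

The simulator provides every input the pipeline needs, with a truth
ledger for parameter-recovery testing. Defaults (the study conditions):
8 founders (7 from a shared allele-frequency spectrum, 1 divergent "wild"
founder from an independent U-shaped spectrum), 4 chromosomes × 60 Mb at
1 cM/Mb, 2,000 SNPs, 325 lines of which 184 are phenotyped, 5 selfing
generations, 3 experiments with 1 stress + 1 destructive-baseline plant
per MAGIC line and 3 + 3 per parent per experiment.

- **Crossing.** Per line, a random founder permutation feeds a balanced
  funnel (pairs → 4-way → 8-way) followed by selfing via single-seed
  descent; meiosis uses a Poisson crossover process on the cM map
  (Haldane, no interference). Founder-of-origin is tracked per haplotype,
  so genome shares (≈ 1/8 per founder) and residual heterozygosity
  (halving per selfing generation from the 8-way F1 level) are testable.
  The real population's exact crossing scheme and any line attrition are
  not reproduced — only the population class.
- **Traits.** Per-trait heritability is defined on the line-mean scale,
  `h² = σ²ₐ/(σ²ₐ + σ²ₙ + σ²ₑ/n_experiments)`, the scale a Cullis-type
  heritability of a replicated trial estimates; plant-level residual
  variance follows from it. QTL effects are drawn on a shared QTL set
  (default 100) and, because linkage disequilibrium among QTL distorts
  naive correlated draws, the realised line scores are whitened and
  re-mixed so the sample genetic correlations and variances match the
  configuration exactly — the result is still a linear model in QTL
  dosages with well-defined effects stored in the truth ledger. The
  residual genetic effect is likewise standardised to its target sample
  variance. Default trait settings (means, SDs, heritabilities,
  residual-genetic shares for the flavonol and water-content traits)
  sit on realistic raw scales for water-stressed eggplant.
- **Raw records.** Trait values are re-expressed as organ-level data:
  total dry weight split into root and aerial (leaf share ~ Beta, mean
  0.76), fresh weights back-computed from the water-content target via
  `FW = DW/(1 − WC/100)` with small per-organ jitter, and baseline plants
  carrying final weights minus the growth-trait value. Feasibility
  projections (e.g. root between 5% and 80% of total, growth between 10%
  and 85% of final biomass) clip extreme draws; leaf number, stem length
  and the unmodelled optical indices are plausible noise unless given
  their own trait specification.

**What passing tests show.** The generator realises the GBLUP generative
model plus the organ-level measurement layer, so recovery tests
demonstrate the estimator and pipeline are correct and calibrated under
that model at trial scale. They do not establish robustness to features
of real field data the generator omits: genotyping error, spatial trends
within experiments, genotype-by-experiment interaction, selection during
line development, or non-Gaussian trait distributions.

## Problem sizes used by the bundled checks

The test suite exercises the REML oracle at 8 lines × 50 SNPs against a
20³ likelihood grid; parameter recovery over 20 studies of 300 lines ×
2,000 SNPs; GWAS calibration and power over 20 null and 20 planted-QTL
phenotypes on a 200-line × 2,000-SNP panel; and CV consistency across 10
traits at 100 lines. `scripts/acceptance.py` runs the full pipeline at
the default 325-line desk scale with 25 five-fold repeats; these sizes
are the package's chosen desk-scale defaults, chosen to keep LD structure
realistic while remaining minute-scale.

## Known limitations

- Single-trait REML only; the index combines single-trait GBLUP fits
  (multi-trait REML is out of scope).
- No dominance or epistatic kernels, and no marker-by-environment or
  spatial modelling.
- The GWAS is the PC-corrected GLM, not a kinship-corrected mixed-model
  scan; in structured populations the family-wise error control relies on
  the PC covariates.
- `σ²ₙ` and `σ²ₑ` are weakly identified in designs with few replicates;
  estimates of either component individually carry wide sampling error
  even when their sum is stable.
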