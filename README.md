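# magicgs

Genomic selection for multi-parent (MAGIC) inbred populations evaluated
under water stress.

`magicgs` is a Python toolkit for breeders and quantitative geneticists
working with multi-parent advanced generation inter-cross (MAGIC)
populations — here modelled on an 8-founder eggplant population (seven
cultivated parents plus one wild, drought-tolerant relative) phenotyped
under deficit irrigation. It covers the full analysis chain:

1. **Genotypes** — SNP dosage matrices from VCF or CSV, minor-allele
   frequency filtering (strict `MAF > threshold`), physical-distance
   thinning, the **VanRaden genomic relationship matrix**
   `G = W W' / (2 Σ pⱼ(1−pⱼ))`, and genotype principal components.
2. **Phenotypes** — derived drought traits from raw organ fresh/dry
   weights: water contents `WC = 100·(FW−DW)/FW`, aerial/total dry
   weights, the aerial/root ratio, and growth during the stress period by
   destructive-baseline subtraction (per-line baselines for MAGIC lines,
   experiment-level baseline means for parents), plus the gravimetric
   field-capacity watering arithmetic.
3. **GBLUP** — the mixed model
   `y = Xb + Z u_a + Z u_n + e`, with `u_a ~ N(0, σ²ₐ G)` (GEBVs),
   `u_n ~ N(0, σ²ₙ I)` (residual genetic effects) and fixed experiment
   effects, fitted by average-information REML; Cullis heritabilities
   `H² = 1 − PEV/σ²_g`, `h² = 1 − PEV/σ²ₐ`; genetic coefficients of
   variation; genomic prediction of unphenotyped lines.
4. **GWAS** — per-SNP general linear model on adjusted means with
   principal-component covariates, Bonferroni threshold
   `−log₁₀(α/n_SNPs)`, and LD-based (`r²`) delimitation of associated
   regions.
5. **Selection** — the **Smith–Hazel index** `I = b'x` with
   `b = P⁻¹ G a`, tolerant/susceptible classification, genetic
   correlation matrices, and PCA of standardised genetic values.
6. **Cross-validation** — leave-one-out and repeated k-fold predictive
   ability (Pearson `r` between adjusted means and predicted GEBVs) and
   prediction accuracy `r/√h²`.
7. **Simulation** — a seeded MAGIC generator (funnel crossing, Haldane
   recombination, selfing by single-seed descent, planted QTL with a
   truth ledger) that emulates the trial design: 3 experiments, 1 stress
   + 1 baseline plant per MAGIC line and 3 + 3 per parent per experiment.

## Worked example

```python
from magicgs import SimConfig, simulate_dataset, GBLUP, filter_maf, vanraden_grm
from magicgs.phenotypes import derive_traits
from magicgs.crossval import loocv

sim = simulate_dataset(SimConfig(seed=1))          # 325 lines, 184 phenotyped
traits = derive_traits(sim.pheno)                  # 25 derived drought traits
grm = vanraden_grm(filter_maf(sim.gm, 0.04))

fit = GBLUP.from_phenotypes(traits, grm, "Total DW").fit()
print(fit.summary())
```

prints (seed 1):

```
GBLUP results: Total DW
========================================
observations: 552   lines: 184
REML log-likelihood: -365.3989  (8 iterations)

component                 estimate
sigma_a2 (additive)        0.14289
sigma_n2 (resid gen.)            0
sigma_e2 (residual)        1.18146

H2 (Cullis, total genetic): 0.242
h2 (Cullis, additive):      0.242
mean PEV (additive):        0.108303
components at zero boundary: residual_genetic
```

The additive component `sigma_a2` is expressed per unit of the genomic
relationship matrix (whose diagonal averages ≈ 2 for inbred lines); the
residual genetic component converged onto the zero boundary, so the
narrow- and broad-sense Cullis heritabilities coincide — total dry weight
variation among these lines is explained by the markers plus residual
noise. Cross-validated predictive ability and accuracy follow directly:

```python
from magicgs.gblup import adjusted_means

cv = loocv(adjusted_means(traits[traits.role == "magic"], "Total DW"),
           grm, h2=fit.h2)
print(round(cv.r, 2), round(cv.accuracy, 2))   # prints: 0.47 0.96
```

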