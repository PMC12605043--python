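# mangogp

Genomic prediction for structured perennial-crop gene pools — GBLUP/REML
with VanRaden relationship matrices, QC and LD tooling for
sequence-derived SNPs, single- and multi-locus GWAS for variant
preselection, and the validation designs used in breeding programs.

## The problem

Tree-crop breeding programs (the motivating case is a mango gene pool of
~225 accessions, 41 of which serve as breeding parents) want to predict
the genetic merit of candidates from whole-genome SNP data. Three
questions dominate that analysis:

1. How does marker density (full sequence vs LD-pruned panels) affect
   predictive ability?
2. Population structure inflates apparent predictive ability when
   subpopulations differ in both trait mean and allele frequencies —
   what happens when the top principal components of the relationship
   matrix are fitted as fixed effects?
3. Can GWAS help — either by preselecting the top-N associated variants
   for a trait-specific relationship matrix, or by fitting "reliable"
   SNPs (those found by at least two GWAS methods) as fixed effects?

`mangogp` implements that entire analysis as a tested, reusable library
plus CLI, and ships a synthetic structured-population generator so every
stage is testable end to end without any data download.

## The model

The core is the GBLUP linear mixed model

```
y = Xb + Za + e,    a ~ N(0, σ²_a G),    e ~ N(0, σ²_e I)
```

where `G` is the VanRaden (method 1) genomic relationship matrix,
`G = WW' / (2 Σ p_k(1−p_k))` with `W` the dosage matrix centred at twice
the allele frequency. `X` holds the intercept and, depending on the
model variant, numeric covariates, the top principal components of a
GRM built from an LD-pruned panel, and fixed-effect SNP dosages.
Restricted maximum likelihood is profiled down to the variance ratio
δ = σ²_e/σ²_a through one spectral decomposition of `ZGZ'` and maximised
over log δ; narrow-sense heritability is `h² = σ²_a/(σ²_a+σ²_e)` and
model fit is compared by AIC. Predictive ability is the Pearson
correlation between predicted merit and observed phenotype in a
validation set (the 41 parents, or 5-fold × 5-repeat cross-validation);
bias is the slope of observed on predicted.

Modules:

| module | contents |
| --- | --- |
| `simdata` | Balding–Nichols two-subpopulation genotypes with founder-mosaic LD, additive traits (optional major locus, ordinal liability scale), fixture writer |
| `geno_io` | VCF → dosage matrix (cyvcf2), QC cascade (depth, missingness, mean depth, MAF, exact HWE), mean imputation, blush-scale encoding |
| `ldtools` | composite-LD r², sliding-window pruning, LD-decay curves |
| `relmat` | VanRaden GRM, eigenvalue bending, GRM PCA |
| `mixedmodel` | REML/GBLUP fit, GEBVs, fixed-SNP BLUEs, heritability, AIC |
| `gwas` | single-locus scan; simplified MLMM / FarmCPU / BLINK; Bonferroni thresholds; reliable-SNP voting; genotype-class contrasts |
| `pipeline` | marker-set × model-variant scenarios, parental validation, k-fold CV, top-N preselection |

## Worked example

Simulate the default gene pool (192 + 33 accessions, Fst 0.2), give it a
trait with h² = 0.7 where one locus carries 36 % of the genetic
variance, and compare GBLUP variants under parental validation:

```python
import numpy as np
from mangogp import simdata, pipeline

cfg = simdata.SimConfig(n_snps=2000, low_depth_frac=0.02, seed=1)
sim = simdata.simulate_structured_genotypes(cfg)
pheno, truth = simdata.simulate_phenotype(
    sim.geno, sim.labels, n_qtl=20, target_h2=0.7,
    major_qtl_variance_fraction=0.36, seed=2,
)
data = pipeline.Dataset(geno=sim.geno, pheno=pheno, labels=sim.labels)
parents = tuple(np.random.default_rng(3).choice(sim.geno.ids, 41, replace=False))
config = pipeline.ScenarioConfig(
    marker_sets={"full": pipeline.MarkerSet("full"),
                 "top500_glm": pipeline.MarkerSet("top", method="glm", n=500)},
    variants=("base", "fixed_snps"),
    parental_ids=parents, seed=4, pca_prune=None,
)
report = pipeline.run_scenario(data, config)
print(report.table[["marker_set", "variant", "pa", "bias", "h2",
                    "n_fixed_snps"]].round(3).to_string(index=False))
```

prints

```
marker_set    variant    pa  bias    h2  n_fixed_snps
      full       base 0.454 1.072 0.660             0
      full fixed_snps 0.545 0.909 0.374             3
top500_glm       base 0.436 0.717 0.912             0
top500_glm fixed_snps 0.517 0.803 0.840             3
```

Reading this: predictive ability for the 41 held-out parents rises from
0.45 to 0.55 once the training-set GWAS discovers the major locus (three
reliable SNPs tag it) and its effect moves into the fixed part of the
model — and the heritability attributed to the relationship matrix drops
from 0.66 to 0.37, because the major locus no longer counts as polygenic
background. A bias near 1 means predictions are on the right scale.

The same steps are available from the shell:

```
mangogp sim --config sim.yaml --out fx --seed 3
mangogp qc --vcf fx/genotypes.vcf --out qc/
mangogp prune --vcf fx/genotypes.vcf --window 15 --step 10 --r2 0.2 --out kept.ids
mangogp fit --vcf fx/genotypes.vcf --pheno fx/phenotypes.csv --out fit.json
```

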