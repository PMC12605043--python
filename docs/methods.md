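# Methods

This note documents the statistical models, the synthetic-data design,
the numerical choices, and the limits of what the test suite shows.

## GBLUP and REML

The mixed model is `y = Xb + Za + e` with `a ~ N(0, σ²_a G)` and
`e ~ N(0, σ²_e I)`. `Z` maps phenotypic records to individuals, so
repeated records are supported through the incidence matrix; `G` covers
training and validation individuals jointly (their genotypes are known —
only validation phenotypes are held out).

REML is computed by profiling. With `K = ZGZ'` eigendecomposed once as
`USU'`, the restricted log-likelihood at variance ratio
δ = σ²_e/σ²_a is, up to a constant,

```
l_R(δ) = −½ [ (n−p)(log 2πσ̂²_a + 1) + Σ log(s_i+δ) + log det(X'H⁻¹X) ]
```

with `H = K + δI` and `σ̂²_a = y'Py/(n−p)` in closed form. The 1-D
problem over log δ is solved on [log 1e−6, log 1e6]: a 256-point coarse
scan locates the basin, bounded Brent refinement (xatol 1e−8) finishes.
Solutions within 1e−3 of a bound are flagged `boundary`. Fixed effects
are the GLS estimates at the optimum; breeding values for every
individual in `G` come from `â = G Z' H⁻¹ (y − Xb̂)`, which equals the
conditional mean given the training data. AIC is `−2 l_R + 2·2`,
counting the two variance parameters — the common REML-AIC convention,
adopted because fixed effects are already integrated out of `l_R`.

Identities used as oracles in the tests: with an in-sample-frequency
VanRaden GRM, GBLUP GEBVs equal ridge-regression SNP-BLUP with per-SNP
variance σ²_a/c (c the VanRaden denominator), checked to 1e−6; and the
optimiser must attain the maximum of a dense 1000-point grid on the same
profiled likelihood to 1e−6.

A bivariate genotype-by-age model with correlated heterogeneous
residuals is out of scope; traits measured at several ages are handled
as univariate records with age as a fixed covariate.

## GRM, bending, structure covariates

VanRaden method 1: `G = WW'/(2Σp_k(1−p_k))`, `W = M − 2p`. Allele
frequencies default to the full genotyped set (training + validation),
matching the joint-G usage above; training-only frequencies can be
supplied. Markers with `p(1−p) = 0` are dropped from numerator and
denominator with a warning. Because centring uses in-sample
frequencies, rows of `G` sum to zero exactly — `G` is always singular —
so `bend` lifts eigenvalues below a floor (default `1e−6 · trace/n`) and
reconstructs the matrix; bending is idempotent and leaves eigenvectors
untouched. Structure covariates are the top-k eigenvectors of a GRM
scaled by √eigenvalue; any full-rank linear transform of them gives the
same fixed-effect fit, so the scaling is cosmetic. PCs are computed once
on all individuals from a pruned-panel GRM: structure is a property of
the collection, genotypes carry no phenotype information, and global PCs
keep the folds of cross-validation comparable (the alternative,
re-deriving PCs per training fold, changes nothing leak-relevant).

## QC cascade

Fixed order: (1) calls with depth < 5 are set missing; (2) markers with
> 20 % missing calls are dropped; (3) markers with mean depth > 50 over
non-missing calls are dropped; (4) MAF < 0.05 (strict, from non-missing
calls); (5) exact Hardy-Weinberg test p < 1e−6. The exact test
conditions on allele counts and sums the probabilities of all
heterozygote configurations no more probable than the observed one
(≤ with a 1e−12 relative guard), computed by the standard outward
recurrence from the modal configuration; monomorphic markers return 1.
Missing calls surviving QC are mean-imputed per marker — a deliberate
simplification of haplotype-based imputation; fractional dosages are
legitimate downstream.

## LD tools

r² is the squared Pearson correlation of unphased dosages (composite
LD), over pairwise-complete observations. Pruning slides a window of 15
SNPs in steps of 10 over the retained markers of each chromosome;
within a window, while some pair exceeds the threshold, the pair with
the largest r² loses its lower-MAF member (positional tie-break: larger
position goes), and passes repeat until a full pass removes nothing —
at the fixed point no retained window contains a pair above the
threshold. Which SNP other tools would remove differs between
implementations; this rule is documented, deterministic, and verified
by an exhaustive post-scan rather than claimed identical to any tool.
LD-decay curves bin all intra-chromosomal pairs by distance; the
crossing distance interpolates linearly between bin midpoints where the
curve first drops below the threshold (left edge if the first occupied
bin is already below; missing if it never crosses).

## GWAS scans

The single-locus scan is per-marker OLS with covariates and a t-test on
the marker coefficient (the fixed-effect model behind standard
biobank-scale scanners), vectorised through QR residualisation. Markers
collinear with the covariates are skipped and listed. Significance
defaults to Bonferroni at α = 0.05 over the scan's tested markers.

The three multi-locus scans are simplified, behaviourally faithful
re-implementations — their contract is statistical (type-I error, power
ordering, null fallback), not numeric parity with any reference
implementation:

- **MLMM-style**: iterated EMMA rotation; each step refits REML given
  the current pseudo-QTN covariates, whitens, scans, and promotes the
  top marker while it passes the scan's own threshold (stopping at
  `max_steps` or when residual polygenic h² < 0.01). Promotion is gated
  on significance so a null trait selects nothing; pseudo-QTNs are
  tested against the model without their own column.
- **FarmCPU-style**: alternates a fixed-effect scan (a marker is never
  conditioned on itself or on a pseudo-QTN in its own genomic bin) with
  selection of the best marker per bin over a grid of bin sizes
  {0.5, 5, 50} Mb and counts {5, 10, 20}, keeping the combination that
  minimises the BIC of the fixed-effect model; stops when the set
  repeats.
- **BLINK-style**: no bins; candidates are p-ranked markers greedily
  filtered so no two exceed r² = 0.7, with the retained prefix length
  chosen by BIC; during the scan a marker is not conditioned on
  pseudo-QTNs in strong LD with it.

Both iterative scans fall back to the plain single-locus result when no
marker is significant in their first iteration, so a null trait returns
exactly the single-locus p-values. "Reliable SNPs" are markers
significant in at least two distinct methods; in fixed-SNP model
variants they are excluded from GRM construction, their dosages enter
`X` uncentred (centring only shifts the intercept), and their BLUEs are
added to validation GEBVs. Fixed-PC contributions are *not* added to
predicted merit: structure is treated as nuisance, whereas fixed-SNP
effects are genetic merit.

## Synthetic gene pool

The generator emulates the statistical situation the pipeline assumes:
two admixture-free subpopulations (defaults 192 and 33 individuals)
whose allele frequencies diverge per the Balding–Nichols model
(`Beta(p(1−F)/F, (1−p)(1−F)/F)` around ancestral `p ~ U(0.05, 0.95)`,
default F = 0.2), with LD from founder-mosaic copying: each
subpopulation has K founder haplotypes (default 5) and every sampled
haplotype switches founder template at `switch_rate` per bp (default
2e−5), giving near-exponential r² decay with distance. Two deliberate
design choices:

- Founder pools carry the alt allele on `round(K·p_s)` haplotypes
  rather than i.i.d. Bernoulli draws: with few founders, Bernoulli
  sampling adds drift of order `p(1−p)/K` on top of the Balding–Nichols
  variance, which would corrupt the Fst the generator is supposed to
  realise. Rounded counts keep realised divergence at the Beta draw up
  to O(1/K) granularity (Hudson-type Fst recovers F = 0.2 to within
  ±0.04 at the defaults).
- One ancestral founder *ordering* per locus is shared by both
  subpopulations, so their founder pools carry consistent ancestral LD;
  with independent placements the pooled-sample LD would largely cancel
  between subpopulations.

At the defaults the pooled panel shows mean adjacent-SNP r² ≈ 0.13 with
short-range r² ≈ 0.15 decaying within a few kb — rapid LD decay in the
spirit of a diverse outcrossing gene pool, though the generator's
short-range LD sits below a sequencing panel's (real adjacent-SNP r² is
~0.3 at WGS density). Tests that need LD-rich panels use K = 3–4
founders and lower switch rates.

Traits are additive: `n_qtl` markers get N(0,1) effects, the genetic
values are rescaled to unit variance (so shifts and residuals are in
genetic-SD units), optionally one locus is rescaled to carry an exact
fraction of the genetic variance (the quadratic in its effect accounts
for LD with the polygenic background), the residual is orthogonalised
against the genetic values and scaled so the realised h² equals the
target exactly, and an optional mean shift for subpopulation 2 creates
the structure-trait confounding the pipeline is designed to expose.
Ordinal traits (the 0–5 fruit-blush scale) are produced by
equal-quantile discretisation of a continuous liability and analysed on
the numeric scale. Synthetic read depths are Poisson(15) with an
optional fraction of calls forced below depth 5 to exercise the QC
cascade.

What the generator does *not* emulate: coalescent genealogies,
recombination-map heterogeneity, selection, admixed individuals,
genotyping error beyond depth-driven missingness, dominance/epistasis,
and genotype-environment interaction. Passing tests therefore
demonstrate correct statistical machinery and the direction of design
effects under the stated generative assumptions, not performance on any
real crop dataset.

## Study-design experiments and problem sizes

The packaged experiments reproduce three qualitative phenomena at
desk scale (panels of 225 individuals, 2000–4000 SNPs, 41-parent
hold-out validation, 20 replicate seeds):

- **Structure confounding**: a polygenic trait (200 QTLs, h² = 0.4)
  with a 2-genetic-SD subpopulation shift; fitting six GRM PCs as fixed
  effects removes the between-subpopulation signal and lowers
  predictive ability in ≥ 15/20 seeds.
- **GWAS preselection**: a sparse trait (10 QTLs, h² = 0.5, shift 1.5)
  on 4000 SNPs; a GRM from the top-200 training-GWAS markers beats the
  all-marker GRM under structure correction in ≥ 15/20 seeds.
- **Fixed-effect SNPs**: 20 QTLs, h² = 0.7, one locus at 36 % of the
  genetic variance; reliable SNPs (single-locus + FarmCPU-style vote)
  fitted as fixed effects raise predictive ability over the base model,
  and the GRM-attributed h² drops, each in ≥ 15/20 seeds.

Heritability recovery and scan calibration use unstructured panels
(n = 500, m = 2000, 40 founders) so the GBLUP model is well-specified.
Within k-fold cross-validation, GWAS discovery, preselection and
reliable-SNP voting are re-run inside every training split — the only
leak-free reading of training-only GWAS — and a poisoning test asserts
that perturbing validation phenotypes changes no training artifact.

## Numerical details and edge cases

- δ search bounds 1e−6…1e6, log-scale; variance floor 1e−12.
- Rank checks use pivoted QR and name the collinear columns.
- GRMs are symmetrised after products; PSD checks tolerate −1e−8
  relative; `bend` handles the rest.
- Collinearity of a marker with covariates: residual sum of squares
  below 1e−10 of its centred sum of squares.
- Constant vectors make r², predictive ability undefined (NaN with
  warning); constant predictions make the bias slope an error.
- Ties in preselection break by (p, chromosome, position); pruning ties
  by MAF then position. Both are deterministic.
- Fold assignment is a uniform random permutation with sizes differing
  by at most one; each repeat draws from an independently seeded stream.

## Known limitations

- Multi-locus scans are deliberately simplified; their pseudo-QTN sets
  need not match GAPIT/FarmCPU/BLINK output on the same data.
- Mean imputation understates genotype certainty relative to
  haplotype-based imputation; with the < 3 % missingness the QC
  defaults allow, the effect on GRMs is negligible.
- The generator's LD is exchangeable along the chromosome (no hotspots)
  and its short-range LD is weaker than sequencing panels exhibit.
- Single-trait, additive-only inference; no dominance GRMs, no
  multi-trait REML, no Bayesian whole-genome regression.
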