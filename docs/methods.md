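# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of each stage of the pipeline, and states what the
synthetic-data generators do and do not emulate.

## Colony-array fitness

**Model.** Observed colony size is treated as multiplicative:
`size = base × bias(row, col) × strain_effect × noise`. The spatial bias is
estimated from the reference grid — 96 control-strain colonies at
(even row, even col) of the 16×24 array, the geometry produced by up-pinning
a 96-array onto a 384-array — as a bilinear surface through the QC-passing
reference sizes. Corrected size is raw size divided by the surface value, a
dimensionless fitness relative to the control strain.

**Numerical choices.**
- Bilinear interpolation is the simplest scheme exact for an affine bias
  field. The border row and column of the plate lie outside the reference
  grid; they get *linear extrapolation* from the nearest grid cell rather
  than nearest-edge clamping, because clamping leaves up to one grid-step of
  bias uncorrected at the border (≈1–1.5% under typical gradients) whereas
  linear extrapolation keeps the affine case exact everywhere. The cost is a
  slightly higher noise sensitivity confined to the border positions.
- Reference-grid nodes that fail QC are imputed iteratively from the mean of
  their available grid neighbours before interpolation, so isolated failures
  do not distort the surface and a plate is only rejected when fewer than
  four reference colonies survive QC.
- QC thresholds: size < 10 px (600 dpi scan) flags no growth; circularity
  outside [0.85, 1.1] flags abnormal shape. Both are boundary-exclusive
  (exactly 10 px or 1.1 passes). Circularity is consumed as provided.
- The strain-consistency rule (replicate SD greater than the SD of all
  QC-passing colonies of all strains) is applied after normalization, on
  corrected sizes pooled over the whole screen: corrected values are the
  quantity being averaged, so their SD is the natural criterion. Division
  (not subtraction) by the reference surface is used throughout; resistance
  scores are described as fitness ratios, which requires the multiplicative
  reading.
- Internal controls for the signal-to-noise ratio are the QC-passing
  control-strain colonies *outside* the reference grid; the grid itself is
  consumed by normalization and would make the SNR circular.

**Limitations.** Cross-plate batch effects beyond the per-plate grid
correction are not modeled; condition/control ratios assume plate-matched
screens.

## Growth curves

Smoothing is a median filter (window 5) followed by a Gaussian filter
(σ = 3 samples), in that order; both use reflective boundaries and the
Gaussian kernel is truncated at 4σ. The fitness read-out fits an OLS line to
every contiguous 12-point window of the smoothed curve and keeps the largest
slope ("maximum slope"); goodness-of-fit is reported but not used for
selection. Slopes are reported in OD per hour with the sampling interval
recorded, because the no-growth exclusion threshold (default 0.015) is
interval-dependent and its unit is a configuration choice. For 15-min
sampling of slower screens the window is doubled to 24 points. Doubling time
is the inverse slope of an OLS fit to log2(OD); non-positive slopes are
reported as non-growing rather than an error. Differential-growth hits
between two strains use the log2 ratio of mean replicate slopes with
|log2 ratio| > 0.75; conditions where both strains stay below the no-growth
threshold are excluded first. Dose–response hit calling beyond this
threshold rule is out of scope (not reproducible from a threshold alone).

## Mixed-model GWAS

**Phenotype.** Box-Cox with maximum-likelihood λ; inputs that are not
strictly positive are shifted by `1 − min` first and the shift recorded.
Output is standardized to mean 0, variance 1, so effect sizes are in
phenotype-SD units.

**Kinship.** Centered-scaled GRM over MAF-filtered (> 5%) haploid calls:
missing calls mean-imputed per variant, columns standardized, K = ZZᵀ/m,
symmetrized, negative eigenvalues clipped at 0. LD-adaptive marker weighting
schemes are deliberately not reproduced; heritability estimates therefore
carry tolerance relative to pipelines that weight markers.

**REML.** y = μ + g + e with g ~ (0, σ²_g K), e ~ (0, σ²_e I). After
eigendecomposition of K the restricted likelihood is a smooth 1-D function
of h²; it is scanned on a 100-point grid and refined by bounded scalar
minimization, allowing boundary solutions h² = 0 or 1. The profiled total
variance has the usual (n−p) REML divisor.

**Association.** EMMAX-style: variance components fixed at their null
estimates, per-variant GLS of phenotype on intercept + allele dosage. For
variants with complete calls the scan is a closed-form 2×2 GLS vectorized in
the eigenbasis of K; variants with missing calls are solved case-wise on the
subsetted covariance (mean imputation is used only for K, never for
testing). Wald z-test with a Gaussian reference — no small-sample t
correction, which is mildly anti-conservative at small n but standard
practice; the null-calibration check quantifies the net effect. Variants
constant after missing-exclusion are skipped with a flag. No multiple-testing
correction is applied to the ranking; a BH q column is emitted for
convenience.

## Region phylogenetics

Biallelic single-base SNPs inside a 1-based inclusive window are concatenated
into a pseudo-alignment; indels and multiallelic records are dropped and
missing calls become gaps. Distances are p-distances (mismatches over
comparable sites) with pairwise deletion — a SNP-only alignment violates the
assumptions of model-corrected distances, and pairwise (rather than
complete) deletion avoids discarding strains with any missing call.
Neighbor joining is the classical Saitou–Nei Q-matrix agglomeration, made
deterministic: ties are broken by the lexicographically smallest pair of
labels, and negative branch lengths are clamped to zero with the deficit
logged. On additive inputs the method is exact, which the tests exploit.
Rooting and bootstrap support are out of scope.

## Physiology and expression summaries

- Energy charge uses Atkinson's convention (ATP + ½ADP)/(ATP + ADP + AMP).
- Enzyme rates: absorbance points below 0.2 are censored pointwise before
  the OLS fit (no imputation); concentration = A/(ε·ℓ) with
  ε = 6220 M⁻¹cm⁻¹ and ℓ = 0.5411 cm (200 µl in a 96-well plate); the blank
  trace's slope is subtracted and the result divided by culture OD.
- Metabolite tests: Welch's unpaired two-sided t with Welch–Satterthwaite
  degrees of freedom; BH across all metabolites in the table (the adjusted-p
  family is the whole measured panel). Both mean-based and median-based
  group ratios are reported, since different read-outs conventionally use
  either. Concentrations are assumed already OD-normalized upstream.
  Two groups that are both constant with equal means give p = 1.
- Gene-set overlaps: upper-tail hypergeometric P[X ≥ k] with the measured
  genes of the respective layer as background; direction-split overlaps
  pre-filter DE genes by fold-change sign. Variant Fisher-style statistics
  used by some enrichment servers may differ slightly.

## Synthetic data: what it emulates, and what it does not

One global seed expands deterministically into per-generator child seeds;
identical configurations give byte-identical outputs.

- **Plates** (16×24, 96-reference grid, 93 test strains in triplicate plus 9
  interspersed internal controls): multiplicative bias = random affine
  gradients (up to ±20% across rows, ±30% across columns) times a smooth
  log-normal field (SD 0.02), log-normal strain effects (SD 0.15, matching
  the ~10–15% fitness spread typical of wild-isolate panels), log-normal
  measurement noise (SD 0.05), and a 2% forced-QC-failure rate. Not
  emulated: pinning artifacts, neighbour effects, agar drying gradients
  beyond the smooth field.
- **Growth curves**: logistic OD(t) = K/(1+exp(−r(t−t0))) with additive
  Gaussian noise; truth stores the analytic maximum slope rK/4 at t0.
  Defaults K = 1, r = 0.4 h⁻¹, 15-min sampling over 48 h, noise SD 0.01.
  No lag-phase asymmetry, no multi-phase (diauxic) growth.
- **Population**: 161 haploid strains in two Balding–Nichols lineages
  (F = 0.4, matching strong substructure), 1,000 variants by default, one
  causal variant planted with an exact carrier count (default 18/161), a
  polygenic term with covariance h²·K from per-variant effects, and
  unit-variance residual noise. The default of 1,000 markers is a desk-scale
  choice: real panels carry ~10⁵ variants but, after linkage and clonal
  structure, an effective number of independent markers orders of magnitude
  smaller, and it is the effective number that sets the spread of the GRM
  spectrum on which variance components are identified. Admixture, clonal
  near-duplicates and LD blocks are not modeled. A companion helper draws
  phenotypes exactly from the variance-component model given a kinship, for
  parameter-recovery simulations.
- **Metabolome**: two groups (9 vs 8 samples), mean-preserving log-normal
  noise at CV 17.2% by default, per-metabolite fold changes. No
  between-batch drift or censored low-abundance values.
- **Enzyme traces**: linear NADH depletion converted through Beer–Lambert,
  additive absorbance noise, optional blank rate, truth flags points below
  the 0.2 floor. No substrate-depletion curvature.
- **Region variants**: infinite-sites mutations dropped on a random binary
  tree (branch-proportional edge choice); the stored truth tree carries
  branch lengths in realized substitutions per site, so p-distances are
  exactly additive on it. Decoy indel and multiallelic records exercise the
  biallelic-SNP filter. Edges that happen to receive zero mutations are
  honest polytomies: any resolution of them is equally supported, which the
  end-to-end test accounts for. No recombination or homoplasy.

Passing tests on these generators demonstrate correctness of the estimators
under their stated models and calibration under realistic noise levels; they
do not certify behaviour under real-data pathologies the generators omit
(batch effects, LD, image-analysis artifacts).

## Problem sizes used in the checks

The automated checks run at desk scale, chosen so the full suite completes
in well under a minute of compute: 50-seed REML recovery at n = 161,
a 5,000-variant null scan, 20 eight-taxon NJ recoveries, 2,000 null
metabolites, and single plates/curves elsewhere. All sizes are configuration
values and scale up unchanged.
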