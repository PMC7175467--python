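# phenogwas

Quantitative phenomics and association genetics for haploid yeast isolate
panels, built around the analysis chain of a colony-array fitness screen:
spatially normalized colony fitness and drug-resistance scores, mixed-model
GWAS with REML heritability, region-SNP neighbor-joining phylogenetics,
growth-curve maximum-slope fitness, and metabolite/enzyme physiology
statistics. A synthetic-data module generates every input with known ground
truth, so the whole pipeline is testable end to end without any external
downloads.

## Who this is for

Groups running arrayed colony screens of natural microbial isolates (e.g.
*Schizosaccharomyces pombe* wild-strain collections) who want a single,
tested path from raw colony-size tables and plate-reader exports to
resistance scores, heritability estimates, association hits and the
physiology statistics that follow up on them.

## The methods at the core

**Reference-grid normalization.** A 384-format (16×24) plate carries a 96
colony reference grid of the control strain, one per 2×2 block. A bilinear
surface through the QC-passing reference-colony sizes models the spatial
growth bias, and each colony's corrected size is `size / surface(row, col)`,
so the control strain scores ~1 everywhere. QC drops colonies with size
< 10 px (600 dpi) or circularity outside [0.85, 1.1]; strains whose replicate
SD exceeds the screen-wide colony SD are excluded as inconsistent. Resistance
scores are fitness ratios (condition / control screen); screen quality is
summarized as SNR = mean/SD of internal control colonies and unexplained
variance = SD(controls)/SD(all).

**Mixed-model GWAS.** Phenotypes are Box-Cox-transformed (ML λ) and
standardized. Variants are haploid 0/1 calls filtered at MAF > 5%. The
kinship matrix is the centered-scaled GRM, K = ZZᵀ/m. Variance components of
y = μ + g + e, with g ~ (0, σ²_g K), come from REML — profiled to a 1-D
problem in h² = σ²_g/(σ²_g+σ²_e) after spectral decomposition of K — and the
per-variant scan is generalized least squares with the variance components
fixed at their null estimates (EMMAX approximation), Wald p-values, BH q
column.

**Region phylogenetics.** Biallelic SNPs in a genomic window become a
pseudo-alignment (ref/alt base per strain, gaps for missing), p-distances
with pairwise deletion feed a classical Saitou–Nei neighbor-joining
agglomeration with deterministic tie-breaking; on additive matrices topology
and branch lengths are recovered exactly.

**Growth curves.** OD series are smoothed by a median filter (window 5) then
a Gaussian filter (σ = 3 samples); fitness is the maximum slope over all
12-point OLS window fits. Doubling time is 1/slope of log2(OD) vs time.
Conditions where both strains grow slower than 0.015 are excluded;
|log2 ratio| > 0.75 flags differential-growth hits.

**Physiology.** Energy charge (ATP + ½ADP)/(ATP+ADP+AMP); reduced/oxidized
redox ratios; enzyme rates from A340 traces (censoring below 0.2,
Beer–Lambert conversion with ε = 6220 M⁻¹cm⁻¹, ℓ = 0.5411 cm, blank
subtraction, per-OD normalization); glucose uptake against a linear standard
curve; oxygen-consumption slopes; biomass yield; Welch's t-test with BH
correction across metabolites. The expression module summarizes external
DESeq2/MSstats tables: DE counts at an FDR cutoff, RNA–protein fold-change
correlation, and hypergeometric gene-set overlaps.

## Worked example

Simulate a drug screen in which every strain's fitness drops to 0.7× under
the condition, score it, then run the GWAS stage on a simulated structured
panel (161 strains, two lineages, one causal variant carried by 18 strains):

```python
import numpy as np
from phenogwas import simulate as sim, colony, gwas

cfg = sim.SimConfig(seed=7)
screen = sim.simulate_screen(cfg, condition_effect=0.7)
norm = {k: colony.normalize_reference_grid(colony.apply_qc(screen[k]),
                                           screen["layout"])
        for k in ("control", "condition")}
scores = colony.resistance_scores(
    colony.strain_fitness(norm["condition"]),
    colony.strain_fitness(norm["control"]))
m = colony.screen_metrics(norm["control"])
print(f"median resistance score: {scores['score'].median():.3f}")
print(f"signal-to-noise: {m.signal_to_noise:.1f}")

calls, variants, strains, y, truth = sim.simulate_population(cfg)
G = gwas.filter_maf(gwas.GenotypeMatrix(calls, variants, strains))
K = gwas.kinship_grm(G)
pv = gwas.boxcox_transform(strains, y)
vc = gwas.reml_fit(pv.transformed, K)
assoc = gwas.lmm_scan(pv.transformed, K, G, vc=vc)
causal_pos = variants.loc[truth.causal_index, "pos"]
rank = int(np.flatnonzero(assoc["pos"].to_numpy() == causal_pos)[0]) + 1
print(f"h2 = {vc.h2:.2f}; causal variant rank {rank} of {len(assoc)}")
```

prints

```
median resistance score: 0.705
signal-to-noise: 22.7
h2 = 0.77; causal variant rank 1 of 768
```

The median score recovers the planted 0.7× condition effect; the causal
variant tops the scan. (The single-draw h² estimate is noisy by nature; its
calibration over many draws is what the acceptance script measures.)

The same stages are scriptable from the shell:

```sh
phenogwas simulate --seed 7 --out-dir sim population
phenogwas gwas --vcf sim/genotypes.vcf --pheno sim/phenotypes.tsv --out-prefix out
phenogwas phylo --vcf region.vcf --region I:3,844,243-3,847,145 --out-prefix tree
```

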