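# bayesrrc

Grouped Dirac spike-and-slab whole-genome regression for biobank-style
genotype–phenotype data: joint Bayesian estimation of SNP effects with
annotation/MAF/LD-specific mixture priors, giving per-annotation SNP
heritability, probabilistic region-level association (PPWV), fine-mapped
credible sets, and posterior-predictive genomic prediction — together with a
simulator that generates LD-blocked genotypes and phenotypes with known
genetic architecture so every component can be validated end-to-end.

It is written for statistical geneticists who want single-step joint
inference instead of the usual two-step mixed-model association + summary
statistic pipeline.

## Model

For a phenotype **y** over *N* individuals and *p* markers standardized to
unit variance, split into groups φ = 1…Φ (here: 13 location/functional
annotation categories × 3 MAF classes × a median LD-score split → up to 78
groups):

    y = 1 μ + Σ_φ X_φ β_φ + ε,    ε ~ N(0, I σ²_ε)

    β_j ~ π_0φ δ_0 + Σ_l π_lφ N(0, σ²_Gφ C_l),   C = (0.0001, 0.001, 0.01, 0.1)

Every group owns its mixture proportions π_φ and variance σ²_Gφ, so the
sparsity and effect-size distribution can differ between, say, exonic and
distal regulatory markers. Inference is Gibbs sampling with conjugate
updates (Dirichlet for π, scaled inverse-χ² for the variances) and sparse
residual updating; the marker sweep is numba-compiled (~15 ms per sweep at
N = p = 5000 on one core).

From the posterior draws the package computes:

- **per-group / per-annotation h²** — per iteration as Σ β² within the unit;
- **enrichment** — a group's share of Σ β² divided by its share of
  *in-model* markers (sparse-model definition; the classical all-markers
  denominator is reported alongside);
- **PPWV** — posterior probability that a region (50 kb window, LD block, or
  gene) contributes at least a fraction θ (default 0.001%) of the variance
  attributed to all SNPs; regions with PPWV ≥ 0.95 are called associated;
- **credible sets** — purity-pruned (pairwise R² ≥ 0.9) marker sets within
  associated LD blocks;
- **posterior-predictive prediction** — per-individual genetic-value draws
  in a new cohort, with coverage probabilities, percentile-of-risk (PCF)
  probabilities and per-annotation partial correlations.

## Worked example

```python
import bayesrrc as b

cfg = b.SimConfig(n_individuals=2000, n_markers=1000, n_causal=20, h2=0.5,
                  enrichment_setting="enriched", seed=1)
panel, y, truth, cats = b.simulate_dataset(cfg)
grouping = b.build_groups(cats, panel.realized_maf(), b.compute_ld_scores(panel))

model = b.BayesRRC(y, panel, grouping=grouping)
res = model.fit(n_iter=1500, burn_in=500, seed=2)
print(res.summary())
```

```
Grouped spike-and-slab whole-genome regression (BayesRR-RC)
===========================================================
draws: 1000  chains: 1  markers: 1000  groups: 52
h2 (sum beta^2):   0.4777  [0.4321, 0.5238]
sigma2_eps:        0.5009
in-model markers per draw (mean): 48.5

Variance by annotation category:
  exon             0.0612  [0.0460, 0.0785]
  intron           0.2488  [0.2175, 0.2812]
  1kb_promoter     0.0001  [0.0000, 0.0008]
  ...
  10-500kb_enh     0.0907  [0.0707, 0.1112]
  500kb-1Mb_tfbs   0.0746  [0.0585, 0.0943]
  total            0.4777  [0.4321, 0.5238]
```

The simulated h² of 0.5 is recovered (0.478, CI [0.43, 0.52]), the chain is
sparse (≈49 of 1000 markers in the model per draw), and the variance
concentrates in the categories that actually received it under the enriched
architecture (intron, exon, distal enhancer/TFBS bands), with near-zero
posterior mass in the categories simulated with zero variance. Region-level
association then follows from the same posterior:

```python
regions = b.define_regions(panel, "window50kb")
tab = res.ppwv(regions, theta=1e-5)
print((tab["ppwv"] >= 0.95).sum(), "of", len(tab), "regions called")
```

which calls 7 of 50 windows — all of them windows that contain a simulated
causal variant (12 windows do).

A command-line surface wraps the same pipeline:

```bash
bayesrrc simulate --out sim --n 1000 --p 500 --n-causal 10 --seed 1
bayesrrc run --bed sim.bed --pheno sim.pheno.tsv --groups sim.groups.tsv \
             --iters 2500 --burnin 500 --seed 1 --out fit
bayesrrc summarize --samples fit.samples.h5 --bed sim.bed --out fit
bayesrrc predict --samples fit.samples.h5 --bed new.bed --train-bed sim.bed \
                 --out pred.tsv
```

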