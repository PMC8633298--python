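# Methods

## Model

The phenotype **y** (N individuals, standardized to zero mean and unit
variance) is regressed jointly on p standardized SNP markers partitioned
into groups φ = 1…Φ:

    y = 1 μ + Σ_φ X_φ β_φ + ε,      ε ~ N(0, I σ²_ε)
    β_j | group φ ~ π_0φ δ_0 + Σ_{l=1..L} π_lφ N(0, σ²_Gφ C_l)

The spike δ_0 excludes a marker from the model; the slab is a scale mixture
of L = 4 zero-mean Gaussians with variances σ²_Gφ · C_l,
C = (0.0001, 0.001, 0.01, 0.1). Mixture proportions, group variance and the
component occupancies are all estimated, independently per group, so groups
can differ in both the amount of variance they carry and how polygenic that
variance is.

Groups are built by crossing 13 location/functional categories (exon,
intron, 1 kb promoter, and 1–10 kb / 10–500 kb / 500 kb–1 Mb upstream bands
each split into enhancer / TFBS / other, plus "others"), three MAF classes
(rare ≤ 0.01, low 0.01–0.05, common > 0.05), and a split at the median LD
score computed *within* each (category, MAF) cell. Location assignment is
priority-ordered (exon ≻ intron ≻ nearest upstream band, strand-aware TSS
distance); markers downstream of every gene fall to "others". Empty cells
are dropped, so Φ ≤ 78.

## Sampler

One Gibbs sweep updates, in order: the intercept (conjugate normal); every
marker effect in a fresh uniform random permutation; each group's mixture
proportions π_φ ~ Dirichlet(α + occupancy counts, spike included); each
σ²_Gφ from its scaled inverse-χ² conditional with sufficient statistic
Σ_{j in model} β_j²/C_{γ_j}; and σ²_ε from the residual sum of squares. The
marker update adds x_j β_j^old back into the residual via
r_j = x_jᵀε + (x_jᵀx_j) β_j^old, draws the component indicator from the
conjugate categorical (spike marginal π_0φ; slab l gets
log π_lφ − ½ log(1 + v_l x_jᵀx_j/σ²_ε) + r_j²/(2σ²_ε(x_jᵀx_j + σ²_ε/v_l))
with v_l = σ²_Gφ C_l), then draws β_j from
N(r_j/(x_jᵀx_j + σ²_ε/v_l), σ²_ε/(x_jᵀx_j + σ²_ε/v_l)) and updates the
residual in place. Missing genotypes are mean-imputed before
standardization, so they contribute exact zeros to every dot product.

The sweep is implemented twice: a numba kernel (float32 genotype rows,
float64 residual and coefficients; ~15 ms per sweep at N = p = 5000 on one
CPU core) used in production, and a plain-numpy reference consuming the same
pre-generated random variates, which the test suite checks agrees
draw-for-draw. Residual bookkeeping is validated against a from-scratch
reconstruction (< 1e−8·N after a full run).

### Hyperpriors and why they matter

- σ²_Gφ and σ²_ε: scaled inverse-χ² with ν₀ = 4 and scales
  s₀² = Var(y)/(2Φ) and Var(y)/2.
- π_φ: asymmetric Dirichlet with concentration 5 on the spike and 0.05 on
  each slab component (prior mean π_0 ≈ 0.96).
- Floors: σ²_ε ≥ 1e−6·Var(y); a group variance of exactly 0 disables its
  slab.

The spike-favoring Dirichlet and the ν₀ = 4 anchor are load-bearing at
moderate sample sizes. For a truly null marker the expected slab-vs-spike
Bayes factor equals exactly 1 at *any* slab variance (the √(1+λ) penalty
and the expected exponential gain cancel), so the per-group mixture
proportions evolve as a nearly neutral Pólya-type random walk driven by
their own occupancy counts. In groups of ~10² markers that walk reaches the
dense corner (π_0 → 0) and sticks there, and under a heavy-tailed ν₀ = 1
prior the group variance of such a group drifts upward without bound,
flooding region-level summaries with micro-effects. A symmetric
Dirichlet(1,…,1) makes things worse still: the +1 pseudo-count per slab
component forces a floor of null occupancy that is negligible at p ~ 10⁶
but dominant at p ~ 10³–10⁴. The asymmetric prior keeps the spike
regenerating (its pseudo-count never dies) while letting genuinely loaded
components grow their proportions from data; the stronger inverse-χ² prior
pins near-empty groups' variances near s₀². With these defaults the chain
is sparse under nulls, the genome-wide h² is recovered without bias across
architectures (see the acceptance suite), and region-level false discovery
stays controlled.

Chains are run independently from per-chain seeds; draws are thinned
post-burn-in and stored sparsely (marker index, value, component per
non-zero effect). Convergence is monitored by split-chain R̂ (flagged above
1.1) and effective sample size (via arviz) for σ²_ε, each σ²_Gφ and total
h². One caveat: the posterior *mean* of σ²_Gφ for a near-empty group is
dominated by the heavy inverse-χ² tail; tables therefore report the
posterior median for σ²_G-based quantities, and genome-wide h² is primarily
reported on the realized Σβ² scale.

## Posterior summaries

- Per-unit variance: Σ β² over the unit's in-model markers per iteration
  (groups, categories, or mixture components), with equal-tail 95% CIs.
- Enrichment (sparse definition): unit share of Σβ² divided by unit share
  of in-model markers; iterations with an empty model are skipped and
  counted. The classical definition (all-marker share denominator) is
  reported alongside.
- PIP: fraction of draws with γ_j ≠ 0, per chain and pooled; an
  "all-chains" flag marks markers exceeding a level in every chain.
- Region variance: Σ β² of the region's markers per iteration, divided by
  the iteration's total Σβ² ("share of the variance attributed to SNPs").
  θ in PPWV is a fraction of that base by default; a flag switches the base
  to unnormalized (phenotypic-scale) sums. LD covariance between in-region
  markers is deliberately ignored — the statistic is the sum of squared
  coefficients, not xᵀββᵀx.
- PPWV: fraction of iterations with region share ≥ θ (default 1e−5, i.e.
  0.001%); calls at levels 0.8/0.9/0.95.
- Credible sets: within an associated LD block, the connected component of
  the R² ≥ 0.9 graph containing the top-PIP marker (a cheap surrogate for
  the maximal clique; the exact clique is only enumerated in tests);
  singleton fallback when no pair meets the purity bound.
- Allele-substitution effects: standardized β divided by the 0/1/2 genotype
  SD.

Multi-chain summaries concatenate post-burn-in draws, except the all-chains
PIP criterion which is per chain.

## Prediction

New-cohort genotypes are standardized with the *training* means and SDs
(alleles are matched by marker id; markers missing from the new panel are
dropped and counted). Each retained draw gives ĝ = X β^(draw), yielding a
per-individual posterior predictive distribution. From it: Pearson
correlation/R² of the posterior-mean predictor (AUC by the Mann–Whitney
rank identity for binary traits, ties mid-ranked); coverage — the fraction
of draws within ±1 SD of the observed phenotype; PCF — the fraction of an
individual's draws above the top-percentile cutoff of the cohort's
posterior-mean predictor distribution (an external reference is accepted),
with odds ratios contrasting the ≥ 0.9 and ≤ 0.1 probability strata;
per-annotation partial correlations read off the inverse correlation matrix
of [y, group predictors] per draw. The ridge-theory reference
R² = h²/(1 + m/(N h²)) (m = number of causal markers) benchmarks simulated
prediction accuracy.

## Simulator

Genotypes: a latent Gaussian with exchangeable correlation within
consecutive blocks of `ld_block_size` markers (independence across blocks)
is thresholded at per-marker MAF quantiles, independently for two
haplotypes, and summed — exact Hardy–Weinberg proportions, tunable LD, MAFs
uniform over `maf_range`. Two-population structure follows a
Balding–Nichols model (subpopulation frequencies Beta-distributed around an
ancestral frequency with variance F_ST·p(1−p)), with an optional between-
population phenotype mean shift. Family structure adds a shared
common-environment draw per family.

Causal markers are chosen at random subject to pairwise R² below a
threshold (default 0.1), or as the highest-MAF marker of randomly chosen
blocks. Effects are drawn N(0, c · w^a · [p(1−p)]^b) with w the LD score
(window-summed R², self included, so w ≥ 1); exponent pairs (0,0),
(±0.25, −0.25) and (±0.25, 0.75) reproduce the standard effect-size–MAF–LD
relationships. In the enriched setting the per-category variance budget
follows fixed shares (1/6 exon, 1/3 intron, 1/12 promoter, 1/24 each
1–10 kb enh/TFBS, 1/12 each distal enh/TFBS, 0 for the "other" bands and
unannotated markers — exact fractions, summing to 1). After sampling, the
genetic values are rescaled so Var(g) = h² exactly (the factor is folded
into the recorded true effects): validation targets are then sharp per
replicate rather than fluctuating around the nominal h². The phenotype is
standardized to unit variance at the end; all components
(h² + stratification + common environment + residual) must total 1.

Simulated annotation categories are assigned to contiguous marker index
ranges from a 13-category proportion table (exons sparse, introns and
distal bands dense); real annotation inputs (gene intervals, functional
marker sets) are supported through the same assignment operation.

What the simulator does *not* emulate: realistic haplotype/recombination
structure (LD is exchangeable within fixed blocks, zero across), sequencing
or imputation error, dosages, X-chromosome inheritance, or LD between
causal and annotation structure beyond the index-range layout. Passing
tests therefore demonstrate correctness of the inference machinery under
the stated generative model, not robustness to every property of real
genotype panels.

## Problem sizes used in validation

The acceptance script runs the region-level FDR check at N = 5000, p = 5000
(blocks of 10 markers, latent correlation 0.7, 50 causal markers requested
— those falling in zero-share categories carry no effect — h² = 0.6,
enriched shares as above), 10 replicates, 2500 iterations with 500 burn-in
(2000 retained draws), calling 50 kb windows at PPWV ≥ 0.95 with
θ = 0.001%. The test suite mirrors the same checks at reduced sizes chosen
for a quick desktop run: FDR at N = p = 2500 over 3 replicates; the
18-architecture recovery grid (h² ∈ {0.1, 0.3, 0.6} × polygenicity
{15, 60, 150 causal} × {random, enriched}) at N = 3000, p = 1500; null
calibration at N = 2000, p = 1000; prediction-versus-ridge at N = 4000
(3000 train / 1000 test), p = 1000, 100 causal markers. Thresholds (FDR
≤ 5%, recovery correlation > 0.8, h² within ±0.08, null h² < 0.02) are the
same at every scale.

## Numerical choices and edge cases

- Standardization uses the population (denominator-N) SD; x_jᵀx_j is
  carried exactly per marker rather than assumed equal to N, which keeps
  the conditionals correct under float32 rounding.
- Monomorphic markers are rejected by name at standardization.
- The categorical component draw uses a single uniform against the
  cumulative normalized weights; slab components with σ²_Gφ = 0 or zero
  mixture mass get −∞ log-weight.
- Group relabelling leaves all marker-level inference invariant; because
  hyperparameter draws consume the random stream in group order, equality
  across relabelled runs is distributional, not bitwise.
- Binary traits are modelled on the observed 0/1 scale as a linear model;
  no liability-probit link.
- ld_block clumping seeds blocks at the highest-MAF unassigned marker
  (marker-index tie-break) and absorbs unassigned markers with R² above
  the threshold to the seed.
- Internal coordinates are 0-based half-open; PLINK bim positions are
  written/read 1-based. A1-allele counting is the default; `count_a2`
  flips it (effect signs depend on this).
- Empty regions get share 0 with a warning; draws with an empty model are
  skipped in enrichment (counted) and contribute zero region shares.

## Known limitations

- The σ²_G-based variance partition is prior-dominated for near-empty
  groups at desk scale (reported as posterior medians for that reason);
  the Σβ² partition is the primary estimate.
- PIPs of markers in perfect LD equilibrate slowly within a single chain
  (label switching); pooling several chains is recommended, as the
  all-chains PIP criterion does.
- No MPI/multi-node parallelism: a single-process sampler with a numba
  kernel covers the intended desk scale (p up to ~10⁵).
- The enrichment posterior is undefined at iterations with no in-model
  markers; such iterations are reported, not imputed.
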