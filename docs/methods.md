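# Methods

`somitraj` reconstructs developmental trajectories toward the somitic and
neuromesodermal fates in time-resolved single-cell RNA-seq of mouse
gastrulation, and quantifies how a knockout shifts the fate allocation of
injected cells in chimeric embryos. This note documents the models, the
numerical choices, and what the synthetic data can and cannot establish.

## The synthetic embryo

All development and validation run on a generative model with known truth
(`somitraj.simulate`). Its structure mirrors the experimental design the
pipeline targets:

- **Time course.** Nine stages, E6.5–E8.5 in quarter-day steps. Cells at
  stage *k* carry a latent pseudotime *t* ~ Normal(k/8, 0.05) truncated to
  [0, 1], so adjacent stages overlap as real embryo collections do.
- **Branching landscape.** A piecewise-linear trajectory tree in a
  10-dimensional latent space: every lineage cell moves along a shared trunk
  axis until its fate's branch time (anterior somitic 0.2; posterior somitic
  and NMP 0.5) and then along a fate-specific axis. Before a fate's branch
  time, cells of different prospective fates are statistically
  indistinguishable — a property the tests verify and the
  optimal-transport reconstruction must overcome.
- **Bystanders.** Two transcriptionally static cell types sit at fixed
  latent positions at every stage (30% of cells). They give label transfer
  and differential abundance realistic negatives and force the
  one-dimensional ordering to be computed on the trajectory continuum only.
- **Expression.** Gene means are `gain · softplus(W z + b)`; counts are
  negative-binomial (dispersion 0.1) scaled by a lognormal per-cell depth
  (σ = 0.25). Gene programs occupy fixed index blocks (shared 10%,
  per-fate 10%, per-bystander 5%, mitochondrial block of 10 genes pinned at
  a 2% count fraction, remainder noise-only). The latent→expression map is
  drawn from a dedicated `model_seed`, separate from the sampling seed:
  an atlas and its chimeras share one transcriptomic universe even when
  their cells are sampled independently.
- **Batch structure.** Two samples per stage; each sample adds a
  Normal(0, 0.15²) shift in latent space — exactly the additive structure
  MNN correction assumes.
- **Chimeras.** Replicate pools are harvested at E8.5; each pool yields a
  tdTom+ (injected) and tdTom− (host) sample. Injected-cell fate
  probabilities are the host probabilities multiplied per fate by the
  knockout bias and renormalised; the default bias (posterior somitic ×0.1,
  NMP ×2.0) plants the depletion/accumulation pattern the chimera
  statistics are built to detect. Bias ≡ 1 is the wild-type-injection
  control.
- **QC artifacts.** `spike_qc_artifacts` multiplies the mitochondrial
  block of a chosen cell fraction by 12 (pushing those cells far past 5×
  the median fraction) and binomially thins another fraction below 5,000
  total UMIs, recording truth labels.

What the generator does **not** emulate: ambient RNA, doublets (doublet
handling enters only as an excluded transferred label), read-level noise,
gene–gene correlation beyond the program structure, and cell-cycle or
spatial effects. Passing tests therefore demonstrate that the pipeline's
machinery is correct and calibrated under its own assumptions, not that it
is robust to every artifact of real droplet data.

## Quality control and normalisation

Cells are called at a minimum of 5,000 total UMIs (inclusive). The
mitochondrial rule refers each cell's mitochondrial count fraction to a
normal distribution centred on the cohort median with SD = 1.4826 × MAD;
one-sided upper-tail p-values are BH-corrected and cells fail at adjusted
p < 0.05. The percentage threshold this induces is a per-dataset output of
the rule, never an input. A zero MAD flags nothing (with a warning); the
test is one-sided because only high mitochondrial load marks damaged cells.

Size factors default to pooling/deconvolution: cells are ordered on a ring
alternating low and high library sizes, pools of sizes 21, 26, …, 101 are
summed at every ring offset, each pool total is compared to the average
pseudo-cell by a median ratio, and the per-cell factors solve the resulting
sparse system by least squares (a 1%-weight library-size anchor keeps the
system full rank). Non-positive solutions are clipped to 1% of the smallest
positive factor with a warning; factors are rescaled to mean 1. Cohorts of
fewer than 10 cells cannot form the prescribed pools and fall back to
library-size factors. Expression is log2(count/factor + 1).

Highly variable genes: per-gene variance of the log-normalised values is
regressed on the mean by lowess (span 0.05, floored so at least 30 points
support the local fit); each gene with mean ≥ 1e-3 is tested one-sided for
total variance above the trend via the χ² approximation to the scaled
variance ratio with (cells − 1) degrees of freedom, BH-corrected at 0.05.
Y-chromosome genes (when an annotation is supplied), *Xist* and *tdTomato*
are excluded regardless of variance.

## Manifold, integration and pseudotime

PCA (default 50 components) is computed on the HVG submatrix with genes
centred, not scaled; component signs are fixed by making each component's
largest-magnitude loading positive, so the embedding is exactly
reproducible. Rank-deficient inputs are zero-padded.

Batch correction is sequential MNN in PC space. The merge order is data
driven: within each stage, samples from most to fewest cells; stages from
oldest to youngest (chimera mode: within genotype, then across; ties break
lexicographically). For each merge, mutual k-NN pairs (k = 20) between the
growing reference and the incoming batch define correction vectors
(reference − incoming), averaged per incoming cell with a Gaussian kernel
(bandwidth 0.1 × the reference RMS spread). Two regimes matter:

- **Sequential integration (default, `max_rounds=1`).** A single
  match-and-shift pass. This under-corrects a large pure offset (pairs form
  part-way along it), but that conservatism is essential when the incoming
  batch carries real biological progression — repeated rounds collapse
  consecutive stages onto each other and measurably degrade trajectory
  recovery.
- **Full alignment (wide kernel, several rounds).** For two samples of the
  *same* population, or for mapping a chimera sample onto an
  already-corrected atlas, matching and shifting are repeated (≤ 8 rounds,
  stopping when the mean shift falls below 1% of the reference spread) with
  a kernel as wide as the atlas spread, so each round is close to a rigid
  translation. This removes a planted batch vector to a few percent while
  preserving within-sample structure, and maps duplicated atlas cells back
  onto themselves.

The diffusion map uses a locally adaptive Gaussian kernel (bandwidth at
each cell = distance to its 30th neighbour), symmetrised, density
normalised, and eigendecomposed via a seeded Lanczos iteration
(deterministic start vector); the trivial eigenvector is removed and a
disconnected kernel graph is an error reporting component sizes. Diffusion
pseudotime from a root cell r is the Euclidean distance between rows of the
matrix with entries λc/(1−λc)·ψc, i.e. the eigen-form of the accumulated
transition operator. The root is the cell with the most extreme first
diffusion component within a designated root population (ties to the
smallest identifier), and the first component is oriented with the root at
its negative end. Both ends of the component give reversed but equivalent
orderings; the convention only fixes the sign. In the pipeline the ordering
is computed on the trajectory continuum (bystander types are disconnected
islands and are excluded), with the earliest-stage progenitors as the root
population.

Clustering builds a shared-nearest-neighbour graph (Jaccard edge weights on
k-NN pairs) and runs igraph's seeded Louvain with resolution 0.2. Plain
modularity (resolution 1) shatters even one isotropic cloud on a kNN graph;
0.2 keeps one blob in one community while separating well-isolated groups,
the granularity wanted when subclustering a cell type.

The sliding-window expression profile evaluates, at evenly spaced points of
the pseudotime range, the mean over cells inside a window of width 10% of
the range; windows are clamped inside the range so edge windows keep full
width (window fraction 1 reduces every point to the global mean).

## Optimal-transport trajectories

For each adjacent stage pair, the coupling minimises
⟨γ, C⟩ + ε·KL(γ | a bᵀ) with squared-Euclidean cost in corrected PC space,
divided by its median so ε = 0.05 is scale-free; source and target
marginals are uniform (a growth-rate vector may reweight the source).
Sinkhorn scaling runs in a stabilised form — plain u/v iterations on a
rescaled kernel with periodic absorption of the scalings into log
potentials — to tolerance 1e-9 (L1 over both marginals) or 20,000
iterations with a warning and recorded diagnostics. The converged coupling
is projected onto the transport polytope by the standard rounding step, so
returned marginals are exact to machine precision. Two numerical limits are
documented rather than hidden: at very small ε (≲ 0.01 on a
median-normalised cost) the iteration's contraction rate degenerates and
the pre-rounding residual plateaus near the double-precision floor; and on
the full atlas one stage pair with a few isolated cells converges to ~3e-7
rather than 1e-9, which triggers the warning path.

Endpoint masses are indicators of the terminal cluster of each fate at the
last stage, normalised to unit mass per fate. Pull-back through coupling γ
is aᵢ(f) = Σⱼ [γᵢⱼ/Σᵢ′γᵢ′ⱼ]·dⱼ(f), applied recursively backward; each fate
column is renormalised to total 1 per stage so fates with larger endpoint
clusters do not trivially dominate the comparison. Cells are allocated to
every fate whose mass is at least ρ = 0.9 of their maximal fate mass
(boundary inclusive, capturing apparently uncommitted cells); cells whose
maximal mass falls below 0.1/nₜ are left unassigned as carriers of
numerically negligible mass. Allocation sets shrink monotonically in ρ.

## Trajectory statistics

Gene dynamics are summarised as the mean log2-normalised expression per
(trajectory, stage); multi-allocated cells contribute to every trajectory
they belong to. Both divergence tests operate on these per-stage means,
with the stage index centred at zero:

- **Variability screen.** Cubic polynomial versus intercept-only, F-test
  with (3, T−4) degrees of freedom, BH at 0.1 per trajectory; the screened
  set is the union over trajectories. Unweighted least squares is used (a
  cell-count weighting option exists but the defaults match the per-stage
  mean construction).
- **Pairwise divergence.** The two trajectories' points are pooled; a
  shared cubic (null) is compared against a cubic with trajectory-specific
  coefficients for all four terms (alternative), F-test with (4, 2T−8)
  degrees of freedom, BH at FDR 0.01. Numerically identical curves carry
  p = 1: zero residual in both models is no evidence of difference.

Both tests are invariant to affine recoding of the time axis and the
pairwise test is symmetric in its pair; the suite verifies both, plus
calibration on 2,000-gene null simulations and agreement with an explicit
statsmodels OLS nested comparison.

Differential expression defaults to a per-gene Welch t-test on
log2-normalised values with BH correction (log2FC = mean difference). The
covariate variant — used when comparing groups that sit at different
positions along an ordering — fits expression ~ group + centred covariate
by OLS and tests the group coefficient against the interval null
|β| ≤ 0.5 log2 units: the t-tail beyond the threshold on the observed side
is doubled and capped at 1, so an effect exactly at the threshold carries
p = 1. Signature scores are the per-cell mean of per-gene z-scores
(zero-variance genes score 0 with a warning). Gene-set overlap uses the
hypergeometric upper tail (one-sided Fisher), cross-checked in the tests
against brute-force enumeration on a 12-gene universe and against
`scipy.stats.fisher_exact`.

## Chimera statistics

Chimera samples are placed in the atlas PC basis (atlas-centred loadings
over the shared genes), each sample independently aligned onto the
corrected atlas (so no mapped sample can influence another), and each
cell's 10 nearest atlas cells recorded with distances. Cell type and stage
transfer by majority vote over the 10 neighbours, ties resolved by the
nearest neighbour carrying a tied label; cells whose transferred type is a
technical artifact label (doublet, stripped nucleus) are flagged excluded
and never enter downstream statistics. Pseudotime transfers as the mean DPT
of the 5 nearest atlas cells with a defined DPT (fewer available → averaged
with a warning; none → masked). Trajectory membership transfers as the most
common trajectory state among the 10 neighbours.

**Differential abundance** treats each sample's mapped cell-type counts as
a count vector: per cell type, a negative-binomial log-linear model with
pool-specific intercepts, one factor for WT-injected and one for
KO-injected samples, and log(library size × TMM factor) offsets
(trimmed-mean normalisation, 30% trim on log-ratios, 5% on abundance).
Dispersions are moment estimates shrunk half-way (log scale) toward the
cohort median, a light-weight analogue of shared-dispersion shrinkage. The
reported test is the Wald test of the KO-injected − WT-injected contrast,
BH-corrected at 0.1. Comparing the two injected compartments against each
other (rather than injected vs host within the knockout) avoids
contamination of the host baseline by the mutant cells' behaviour and
cancels injection-intrinsic effects.

**Relative ratio.** (injected/host on lineage A) ÷ (injected/host on
lineage B), computed per replicate pool; host-cell normalisation cancels
pool-wide composition effects. Any zero among the four counts triggers a
+0.5 continuity correction on all four, with the pool flagged. The group
statistic is the difference in mean log2 relative ratio between KO pools
and WT pools (log scale symmetrises the ratio of ratios). The null permutes
trajectory labels within each pool — preserving per-pool label totals and
every cell's tdTom status, hence the replicate structure the statistic is
built on — and the two-sided p-value is (1 + #{|T⋆| ≥ |T|})/(N+1), bounded
below by 1/(N+1) at N = 1000 permutations. Because the number of cells on
the tested lineages per pool is permutation-invariant, the pool-dropping
rule (< 2 such cells) is applied once. Pseudotime distributions of two
groups are compared by the two-sample Kolmogorov–Smirnov test.

## Pipeline and reproducibility

`run_pipeline` executes simulate → qc → hvg → integrate → order → transport
→ diverge → map → abundance → ratio-test; every stage reads its inputs from
the output directory and writes plain-text artifacts (MatrixMarket + TSV +
JSON), so stages can rerun in isolation and a run is summarised by a
resolved-configuration snapshot and a manifest of SHA-256 checksums.
Unknown configuration keys are rejected before any stage runs. All
randomness derives from the single configured seed (fixed offsets per
stage); the Lanczos eigensolver uses a deterministic start vector, so two
runs of the same configuration produce byte-identical artifacts.

Problem sizes: the default study conditions are 9 stages × 300 cells and
2,000 genes for the atlas, three replicate pools of 300 cells per chimera
genotype, 1,000 permutations for the ratio test. A complete pipeline run
takes on the order of a minute on one CPU; the statistical calibration
studies (200 null ratio cohorts, 40 + 20 abundance reruns) a few minutes.

## Known limitations

- The latent model is piecewise-linear with isotropic noise; curved
  manifolds, continuous fate probability gradients and gene-level bursting
  are not represented.
- Entropic transport at ε = 0.05 blurs couplings near branch points; the
  allocation rule absorbs this through the ρ threshold, but per-cell masses
  close to the unassigned floor are noisy.
- The NB abundance model uses Wald tests with moment dispersions rather
  than quasi-likelihood F-tests; with very few replicate pools the test is
  mildly anti-conservative for extremely rare cell types (the calibration
  run bounds the practical effect).
- TMM normalisation over a handful of cell types is coarse; large
  compositional shifts are partially absorbed into the normalisation,
  attenuating (never inflating) the measured abundance contrasts.
- Label transfer accuracy is measured against the generator's own types;
  real atlases have fuzzier type boundaries and annotation noise.
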