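# Methods

This note documents the models, numerical choices and limitations of the
package; the README gives the overview and a worked example.

## Graph construction

Connectivity is the Fisher r-to-z transform of pairwise Pearson
correlations between ROI time series. Correlations of magnitude 1 are
clipped to ±(1 − 10⁻⁷) before `atanh` so every weight is finite and
rankable; a constant ROI series is a hard error (its correlation is
undefined), as is a series shorter than 3 timepoints. Matrices are
symmetrized and the diagonal forced to exactly zero.

Proportional thresholding ranks the N(N−1)/2 upper-triangle weights by
**signed** z, most positive first; negative edges enter only if needed to
reach the target count. The target count at cost c is
round-half-away-from-zero of c·N(N−1)/2 (452 at 5% cost for N = 135), and
ties at the cutoff are broken by ascending lexicographic pair index. Both
choices are conventions — the proportional-threshold literature does not
fix a rounding, sign, or tie rule; the fixed tie-break makes the
sweep deterministic and its edge sets nested (every edge at a lower cost
persists at all higher costs). An empty graph (cost too low for N) is an
error rather than a silent degenerate output.

ROI inclusion keeps ROIs retaining at least half their voxels inside the
field-of-view mask; exactly 50% is kept, since the exclusion rule is
strictly "< 50%".

## Graph metrics

All metrics operate on binary undirected graphs and are implemented from
first principles (the test suite checks them against networkx and
brute-force oracles, which stay out of the implementation):

- **Distances** by simultaneous breadth-first search; unreachable pairs are
  infinite.
- **Characteristic path length** L averages over reachable ordered pairs
  only, the common convention for binary connectomes that may disconnect at
  5% cost. A graph with no reachable pair is an error.
- **Clustering** C_i = 2·triangles(i)/(k_i(k_i−1)), zero when k_i < 2.
- **Local efficiency** of node i is the mean of 1/d over ordered pairs of
  its neighbors, with d computed inside the subgraph induced by the
  neighborhood and 1/∞ = 0; zero when the node has fewer than two
  neighbors. Whole-network local efficiency is the unweighted mean over all
  N nodes; subnetwork values are unweighted means over declared ROI sets.
- **Modularity** follows the Newman formula with resolution γ (default 1).
  **Louvain** is the standard two-phase greedy algorithm with a seeded
  node-visit order; a move requires a strict gain (> 10⁻¹²) and ties keep
  the current community, so a seed fully determines the partition. The
  returned Q is recomputed from the final partition, so the pair is always
  internally consistent. One run per (subject, cost); no consensus
  clustering.
- **Null model**: double-edge-swap rewiring with 10·m attempted swaps,
  rejecting self-loops and multi-edges; this preserves the degree sequence
  exactly (and hence the edge count). Graphs admitting no valid swap (e.g.
  a triangle) are returned unchanged with a warning. C₀ and L₀ are means
  over independently rewired copies; the reference analysis uses 10,000
  iterations, while the analysis scripts default to 20 and the acceptance
  script to 10 so a 65-subject cohort completes in minutes — σ's
  Monte-Carlo error scales as 1/√n_iter and the moderation statistics
  operate on between-subject variation much larger than that error.
- **Small-worldness** σ = (C/C₀)/(L/L₀); σ is undefined (an error) when
  C₀ = 0, which can occur for very sparse small graphs whose nulls are
  triangle-free.

## Inference layer

The cost-repeated ANCOVA is a univariate mixed model computed by
multivariate least squares. The between-subject design uses Type-III
logic: an effects-coded (−1/+1) amyloid factor, the mean-centered
continuous predictor, their product, and mean-centered covariates, so each
single-df F is invariant to factor coding. Between-subject effects are
tested on the subject-mean metric; effect-by-cost terms are tested on
orthonormal polynomial cost contrasts with the univariate repeated-measures
F. Mauchly's W and the Greenhouse–Geisser ε come from the residual
contrast covariance E/df_e (ε clipped to [1/(p−1), 1]); the GG-scaled p is
applied when Mauchly's p < .05, and both corrected and uncorrected
p-values are always reported. With a single cost level the model reduces
exactly to an ordinary ANCOVA (verified against OLS in the tests). Missing
data are handled by listwise deletion with a logged count.

Follow-up per-cost tests are OLS regressions
`metric ~ group + memory + group:memory + age + sex + education`, reporting
the interaction t. Within-group partial correlations residualize both
variables on the covariates; p uses df = n − 2 − k. The group comparison
uses the Fisher transform with k-adjusted df (n − 3 − k per group),
matching the convention of partial-correlation comparison tools. The
"figure-style" multiplicity rule is the fixed threshold 0.05/7 ≈ 0.0071
across the seven costs; Benjamini–Hochberg at q = .05 is also implemented,
and BH rejections always contain the fixed-threshold rejections.

Group demographics use pooled-variance t-tests (computable from raw values
or from printed mean/SD/n summaries) and Pearson chi-square without
continuity correction for 2×2 tables.

## Synthetic cohort

The generator emulates the study conditions: 65 subjects with
round(0.32·65) = 21 amyloid-positive, 135 ROIs, 84 timepoints. Each ROI
belongs to one of 5 contiguous latent modules; subject s's series for ROI
r is λ_s·g_m(t) + √(1−λ_s²)·ε(t) with iid standard-normal module signals
and noise, so every series has unit variance and within-module correlation
λ_s². The subject coupling λ_s ~ Normal(0.55, 0.12) clipped to
[0.15, 0.90] makes graphs at 5–35% cost modular and small-world, and
modularity/local efficiency increase monotonically in λ_s (Spearman ρ ≈
0.97 across subjects at 15% cost in the default configuration).

Memory is word-list immediate free recall
(intercept 12.7 items) linked to the **latent** coupling, not to a computed
graph metric — avoiding circularity while guaranteeing a recoverable
metric–memory association: memory = 12.7 − 0.05·(age−mean) + 0.3·sex +
0.1·(edu−mean) + β·z(λ_s)·1[Aβ+] + Normal(0, 1). Global SUVR is drawn per
group from truncated normals (Aβ−: 1.00 ± 0.07 below the 1.11 threshold;
Aβ+: 1.32 ± 0.15 above it) so classification is consistent by
construction. Age, sex and education distributions track a cognitively
normal aging cohort and exist only to make covariate adjustment
non-trivial; sex is redrawn if a group comes out single-sex, which would
make within-group adjustment degenerate at these group sizes.

The planted slope default β = 1.06, with unit memory noise and fast-mode
metric noise 0.5, gives a population within-group partial correlation of
r = aβ/√((a²+σ_m²)(β²+σ_e²)) ≈ 0.65 — mid-range of the within-group
correlations this design is powered to compare across groups of 21 vs 44
(the analytic power of the Fisher comparison at r = 0.65 vs 0 is ~0.72;
at r = 0.60 it falls to ~0.62, too weak for a reliable group contrast at
these sizes, which is why the default sits at the upper end of the range).

**Fast matrix mode** (`generate_metric_table`) draws per-cost metric
values directly from the same latent model: metric(s,c) = μ_c + a·z(λ_s) +
Normal(0, σ_m), giving a compound-symmetric within-subject covariance.
Simulation studies of the inference layer (null calibration at 1000
replicates, planted-effect recovery at 200) use this mode; running the
full graph pipeline per replicate would add runtime but no information
about the inference layer, whose inputs the fast mode reproduces exactly.
The full time-series path is exercised end to end by the analysis scripts,
the pipeline tests, and one complete run inside the acceptance script.

What the generator does **not** emulate: hemodynamic response and temporal
autocorrelation, motion artifacts, spatially varying SNR, hierarchical or
overlapping community structure, and any real atlas geometry. Passing
tests therefore demonstrate correctness of the algorithms and calibration
of the inference under the factor model, not robustness to fMRI artifacts.
The packaged ROI metadata (which ROIs form the DMN, visual network,
hippocampus and superior temporal gyrus sets) is a synthetic stand-in with
the documented schema; swap in a real atlas mapping for real data.

## Numerical choices and degenerate inputs

- Correlation clip 10⁻⁷; z-matrix symmetrized by averaging before the
  diagonal is zeroed.
- GG ε computed with orthonormal contrasts, so sphericity of the
  population covariance gives ε = 1 exactly; sample estimates are biased
  slightly below 1 under true sphericity, which is why the ε = 1 checks use
  an exact compound-symmetric matrix.
- Partial correlations clip |r| away from 1 by 10⁻¹⁵ before the t
  transform; exact linear dependence of a variable on the covariates is an
  error, as are collinear covariates and rank-deficient ANCOVA designs
  (reported with the offending column names).
- Seeds: one global seed expands into per-stage and per-subject child
  seeds via `numpy.random.SeedSequence`; all derived seeds are reduced
  below 2³¹.

## Limitations

- Weighted-graph metric variants, alternative small-world indices and γ
  sweeps are out of scope.
- The null model defaults to degree-preserving rewiring (matching the
  randomizer the analysis is built around); an Erdős–Rényi edge-count-only
  null is available via `null_distribution(..., model="er")` because the
  verbal description "same number of edges … all connections rewired" is
  ambiguous between the two.
- The RM-ANCOVA reports univariate GG-corrected tests only; no
  multivariate (Pillai/Wilks) statistics and no mixed-effects
  reformulation.
- Group comparisons from printed summaries reproduce published t-values
  only to the precision of the printed means and SDs.
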