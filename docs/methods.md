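# Methods

This note documents the models and procedures implemented in `rhizonet`,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical corner cases.

## Synthetic communities (`rhizonet.synthetic`)

The generator emulates the product of a denoised rhizosphere amplicon
survey: a taxa × samples integer count table with a handful of replicates
per genotype × phosphorus group, plus full ground truth about what was
planted. Generation follows the logistic-normal / multinomial route:

1. A basis correlation matrix C is assembled from the design: identity
   background, block-constant module submatrices on consecutive diagonal
   positions, and hub–spoke off-diagonal entries. If the assembled matrix
   is indefinite it is repaired by clipping eigenvalues at 1e-8,
   reconstructing and rescaling to unit diagonal; the repaired matrix is
   the recorded truth, so downstream recovery tests always compare against
   the matrix actually sampled from.
2. Per sample, latent log abundances are multivariate normal with mean
   drawn once uniformly from `base_logmean_range` (shifted by
   log2-fold-change × ln 2 for biomarker taxa in their target group) and
   covariance `base_logsd² · C`. Exponentiation and closure give the
   sample's composition.
3. Library size is a gamma-mixed Poisson with mean `depth_mean` and
   dispersion `depth_dispersion` (dispersion 0 short-circuits to a
   constant depth, so the degenerate case is exactly reproducible), and
   counts are multinomial at that depth.

This is precisely the data-generating model the SparCC estimator assumes,
which makes parameter-recovery tests well-posed. Defaults (500 taxa — of
which essentially all clear the 0.01% abundance filter, matching the
400–800-taxon scale of filtered field tables — 6 replicates per group,
8 genotype × phosphorus groups, 5×10⁴ reads with dispersion 0.3, log-mean
range (0, 3), log-SD 1) are chosen as a realistic denoised survey; tests
use smaller designs sized to each property being checked (stated below).
One integer seed drives a root `SeedSequence` from which the per-stage
streams (means, latent draws, depths, multinomials) are spawned, so tables
are bit-reproducible.

What the generator does **not** emulate: read-level artefacts (chimeras,
sequencing error), taxonomy, phylogenetic signal, zero-inflation beyond
what closure + multinomial sampling produce, and environmental gradients
within a group. Passing tests therefore demonstrate correctness of the
estimators under their own model assumptions, not robustness to real-data
pathologies.

## Abundance filtering (`rhizonet.abundance`)

The prevalence filter keeps taxa whose mean across samples of the
per-sample relative abundance is strictly greater than the threshold
(default 10⁻⁴, i.e. 0.01%). The mean-of-ratios reading was chosen over
ratio-of-sums because the filter is defined per sample and averaged
"across all samples"; the two differ when library sizes vary. The filter
is idempotent and never alters surviving counts. Tables are stored
taxa-as-rows; a transposed table can only be detected via a metadata
mismatch and is reported as an error, never silently fixed. Whether the
filter is applied once globally or per network stratum is a config choice
(`filter_per_stratum`, default per stratum, since each stratum's network
is built from its own samples).

## Compositional correlation (`rhizonet.sparcc`)

The variation matrix is t_ij = Var_samples[log(x_i/x_j)], computed from
the log-fraction covariance (sample covariance, ddof 1). Under the
sparsity assumption the row sums satisfy
Σ_{j≠i} t_ij = (D−2)ω_i + Σ_j ω_j, a D × D linear system for the basis
variances ω; correlations follow as ρ_ij = (ω_i+ω_j−t_ij)/(2√(ω_iω_j)),
clipped to [−1, 1]. Strong pairs violate the assumption, so the strongest
not-yet-excluded pair with |ρ| above `exclusion_threshold` (0.1) is
iteratively removed from the system (row sums and system matrix adjusted,
everything re-solved) until none qualifies or 10% of all pairs have been
excluded. Negative ω solutions — possible for near-degenerate systems —
are floored at 1e-10 with a diagnostic count rather than yielding NaN.
At least 4 taxa are required; below that the system is underdetermined.

The point estimate is the element-wise **median** over `n_iterations`
(default 50) Dirichlet resampling rounds, each drawing per-sample
fractions from the posterior with unit pseudocount (counts + 1 as
concentration). P-values come from `n_bootstraps` (default 1000) null
datasets in which each taxon's counts are permuted independently across
samples — destroying cross-taxon association while keeping marginals —
each pushed through the same median-of-iterations estimator;
p_ij = (1 + #{|ρ_null| ≥ |ρ_obs|})/(1 + B) is two-sided and never zero.
The "50 iterations of 1,000 bootstraps" convention maps to these two
loops. A `bootstrap_iterations` override allows a cheaper p-value mode
(fewer resampling rounds per bootstrap dataset); it is off by default.

Sampling limits worth knowing: the estimator's per-pair noise is the
usual ≈ 1/√n of a correlation coefficient, so with D taxa the *maximum*
over the D(D−1)/2 null pairs grows like √(2 ln D)/√n — e.g. ≈ 0.22 for
30 taxa at n = 200. Expecting every null pair below 0.2 at that sample
size fails for any unbiased estimator; at n = 500 the typical maximum
drops to ≈ 0.14.

## Diversity and dissimilarity tests (`rhizonet.diversity`)

Shannon entropy is reported in nats (a `base` switch exists) and Chao1 in
its bias-corrected form S_obs + F1(F1−1)/(2(F2+1)); both are computed on
unrarefied counts. Bray–Curtis, PCoA (classical scaling, proportions
against the sum of positive eigenvalues), PERMANOVA and ANOSIM are
delegated to scikit-bio with explicit seeds; MRPP — absent from installed
packages — is implemented directly: delta = Σ_g (n_g/n) × mean
within-group distance, with the permutation p the plus-one-corrected
fraction of label permutations with delta ≤ observed (it is cross-checked
against R `vegan::mrpp` in the test suite). All three tests default to
999 permutations with plus-one correction, so p ∈ {k/1000} and never 0.
With very small groups the observed partition can recur among random
permutations and tie the observed statistic, so the minimum attainable p
is only reached when n is large enough that duplicated partitions are
negligible.

## Network topology (`rhizonet.network`)

Edges require p < `p_cut` (default 0.01) only; a `min_abs_rho` floor
exists but defaults to 0, since the edge rule is purely significance
based. Edge weight is ρ with its sign; isolated nodes are dropped (Zi/Pi
and cascade metrics need degree ≥ 1). Modules come from greedy
agglomerative modularity maximisation on the unweighted, sign-ignored
skeleton — modularity over signed weights is ill-defined and the
unweighted reading is the conventional one. Relative modularity is
(M − mean M_rand)/mean M_rand over `n_random` (default 100)
degree-preserving double-edge-swap rewirings (default 100 swaps per
edge). Mean local clustering counts degree-<2 nodes as 0.

Zi standardises a node's within-own-module degree against its module's
within-degree distribution (population SD; singleton modules or zero SD
give Zi = 0); Pi = 1 − Σ_s (k_is/k_i)². Roles follow the threshold table
(Zi 2.5 / Pi 0.62) with a configurable boundary convention: the default
`strict` mode requires Zi strictly > 2.5 for hubs and Pi strictly > 0.62
for connectors; an `inclusive` mode moves the boundary points into the
hub/connector classes (the two conventions circulate in the literature,
differing only on the measure-zero boundary). Every non-peripheral node
is flagged a potential keystone taxon.

## Stability metrics (`rhizonet.stability`)

**Robustness.** wMIS_i = Σ_j b_j ρ_ij / Σ_j b_j over remaining
neighbours, with b the mean relative abundance. Per replicate ⌊f·n⌋
nodes are removed uniformly, then nodes with no remaining neighbour or
wMIS ≤ 0 are removed iteratively to a fixed point; the reported value is
remaining/n. The `≤ 0` rule (rather than `< 0`) was chosen so that a node
held only by negative interactions cannot persist; it is configurable.
Defaults: f = 0.5, 100 replicates.

**Vulnerability.** Global efficiency E is the mean of 1/d(i,j) over
ordered pairs on the unweighted skeleton (1/∞ = 0; a 1/|ρ|-weighted mode
exists behind a flag). V_i = (E − E_−i)/E with E_−i normalised over the
reduced node count — the node's *relative* contribution — rather than
the fixed original n; the maximum over nodes summarises the network.
V_i can be negative (removing a peripheral node can raise mean
efficiency); E = 0 makes the quantity undefined and is an error.

**Cohesion.** Pearson correlations between taxa across samples on
untransformed relative abundances; the null expectation is the mean
correlation over `n_null` (default 200) "taxa shuffle" datasets (each
taxon permuted independently across samples), subtracted element-wise.
Each taxon's positive (negative) connectedness is the mean of the
positive (negative) corrected entries of its row — all pairs, not only
significant ones, following the method's published workflow — and
per-sample cohesion is the abundance-weighted sum, so C⁺ ≥ 0 ≥ C⁻ by
construction. Constant taxa get zero correlations with a diagnostic. The
null mean (not median) is subtracted.

## Biomarker scoring (`rhizonet.biomarkers`)

Stage 1 is a per-taxon Kruskal–Wallis test (mid-rank ties, χ²
approximation) at alpha = 0.05 on relative abundances; raw p-values are
used, matching the standard workflow, with an optional Benjamini–Hochberg
mode off by default. Stage 2 bootstraps (30 rounds, 2/3 within-group
subsampling) a two-class linear discriminant on the selected taxa scaled
to 10⁶ (for > 2 groups the contrast is each taxon's enriched group vs the
rest); the per-taxon effect size is the mean of the raw class-mean
difference magnitude and the taxon's share of the projected class-mean
difference, averaged over rounds, reported as log10, passing at ≥ 2.
Rounds that degenerate to one class are skipped and counted. Note that
the score threshold screens out low-abundance taxa but not chance
selections of abundant ones: under a fully null design an abundant
screen false positive frequently scores above 2, so the screen's alpha —
not the LDA cutoff — controls the false-selection rate.

## Pipeline (`rhizonet.pipeline`, CLI)

One config (YAML/JSON or `PipelineConfig`) drives: input or synthetic
generation → whole-study alpha/beta diversity and the three dissimilarity
tests on the stratification labels → per stratum (default genotype ×
condition): abundance filter, cohesion, SparCC, network, modules, Zi–Pi
roles, robustness and vulnerability → study-wide biomarker scoring. Every
artifact is a TSV/JSON file; the manifest records the package version,
the full config, warnings (PSD repair, ω floor, skipped strata) and a
SHA-256 per artifact. Per-stage seeds are derived from the root seed and
the stratum name by hashing, so results are independent of stratum
iteration order and a rerun with the same config is byte-identical.
Results do not depend on `--threads` (the implementation is
single-threaded by design). Strata with fewer than 3 samples, degenerate
biomarker groupings, and empty networks are skipped with manifest
warnings rather than aborting; any genuine stage failure aborts naming
the stage and stratum.

## Problem sizes used in the test suite and acceptance script

Parameter-recovery runs use 30 taxa × 200 samples (20 seeds); bootstrap
calibration 20 taxa × 60 samples × 200 bootstraps; type-I-error
simulation 1,000 null datasets of 2 × 6 samples at 999 permutations;
biomarker power 100 seeds of 30 taxa × 20/group; closed-form network
cases use 10–49-node graphs; the determinism check runs the full pipeline
twice on a 2-stratum, 20-taxon design. These sizes give stable
Monte-Carlo estimates for each property while keeping a full run of the
suite and of `scripts/acceptance.py` in the minutes range on one CPU.

## Known limitations

* SparCC assumes most pairs are uncorrelated; dense correlation
  structures bias ω and shrink ρ̂.
* The Zi–Pi classification depends on the detected partition; on small or
  weakly modular networks greedy modularity is unstable and roles should
  be read accordingly.
* Cohesion on relative abundances inherits closure-induced negative
  correlation; the taxa-shuffle null removes the mean effect but not
  higher-order compositional artefacts.
* Alpha diversity is computed on unrarefied counts; comparisons across
  very unequal library sizes conflate depth with richness (Chao1
  especially).
* The LDA effect size is a ranking device, not an error-controlled test
  (see above).
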