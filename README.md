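# rhizonet

Co-occurrence network and community-stability analysis for amplicon (ASV/OTU)
count tables, with a ground-truth synthetic community generator.

Marker-gene surveys of the rhizosphere — e.g. comparing the root microbiota
of *Arabidopsis thaliana* wild type and strigolactone mutants under low and
high phosphorus — produce taxa × samples count tables that are
*compositional*: sequencing fixes the total, so only relative abundances are
observed and naive correlations between taxon fractions are biased. This
package implements the desk half of such a study as a tested, reusable
pipeline:

* **Compositional correlation (SparCC/FastSpar algorithm).** From the
  log-ratio variation matrix t_ij = Var[log(x_i/x_j)], basis variances ω_i
  are solved under a sparsity assumption and correlations estimated as
  ρ_ij = (ω_i + ω_j − t_ij) / (2√(ω_iω_j)), with iterative exclusion of
  strongly correlated pairs, Dirichlet resampling for the point estimate
  (median of 50 iterations by default) and 1,000 within-taxon-permutation
  bootstrap datasets for two-sided p-values.
* **Signed co-occurrence networks.** Edges are correlations with p < 0.01;
  modules come from fast-greedy modularity optimisation; node roles follow
  the within-module connectivity Zi and among-module connectivity Pi scheme
  (module hubs Zi > 2.5, Pi ≤ 0.62; connectors Zi ≤ 2.5, Pi > 0.62; network
  hubs Zi > 2.5, Pi > 0.62; all non-peripherals flagged as potential
  keystone taxa).
* **Stability metrics.** Robustness = proportion of taxa surviving random
  removal of 50% of nodes plus an abundance-weighted mean-interaction-
  strength extinction cascade (100 replicates); vulnerability = each node's
  relative contribution (E − E_−i)/E to global efficiency
  E = mean over ordered pairs of 1/d(i,j); positive/negative cohesion =
  per-sample abundance-weighted sums of each taxon's average positive /
  negative null-corrected correlations ("taxa shuffle" null, 200
  randomisations), with the |negative|:positive ratio as a stability index.
* **Diversity and community tests.** Shannon (nats) and Chao1 alpha
  diversity, Bray–Curtis dissimilarity, PCoA, and the MRPP / ANOSIM /
  PERMANOVA permutation tests (999 permutations, plus-one p-values).
* **Biomarker scoring.** Kruskal–Wallis screen followed by a bootstrapped
  linear-discriminant effect size on 10⁶-scaled relative abundances
  (log10 score, pass at ≥ 2).
* **Synthetic communities.** A logistic-normal/multinomial generator with
  planted correlation modules, hub taxa and condition-specific biomarkers,
  recording the exact post-repair basis correlation matrix — so every
  stage above is testable against known ground truth without sequencing
  data.

## Worked example

```python
from rhizonet import (CommunityDesign, simulate, filter_mean_relabund,
                      to_relative, SparccParams, estimate, build_network,
                      network_stats, zi_pi, classify_roles,
                      simulate_robustness, vulnerability, cohesion)

design = CommunityDesign(
    n_taxa=40, n_samples_per_group=30, groups=[("Col-0", "LP")],
    module_spec=[(5, 0.8)], hub_spec=[], biomarker_spec=[],
    depth_mean=20000, depth_dispersion=0.3, seed=42)
table, truth = simulate(design)
table = filter_mean_relabund(table, threshold=1e-4)   # the 0.01% filter
rel = to_relative(table)

est = estimate(table, SparccParams(n_iterations=50, n_bootstraps=200, seed=0))
print(f"planted pair rho = {est.rho.iloc[0, 1]:.3f}  (truth 0.8), "
      f"p = {est.pvalue.iloc[0, 1]:.4f}")

g = build_network(est, rel, p_cut=0.01)
stats = network_stats(g, n_random=50, seed=1)
print(f"network: {stats.n_nodes} nodes, {stats.n_edges} edges, "
      f"modularity {stats.modularity:.3f}")
print("roles:", classify_roles(zi_pi(g))["role"].value_counts().to_dict())

rob = simulate_robustness(g, removal_fraction=0.5, replicates=100, seed=2)
vul = vulnerability(g)
coh = cohesion(rel, n_null=200, seed=3)
print(f"robustness = {rob.mean:.3f} +/- {rob.sd:.3f}")
print(f"global efficiency = {vul.global_efficiency:.3f}, "
      f"max vulnerability = {vul.max_vulnerability:.3f}")
print(f"mean negative:positive cohesion ratio = "
      f"{coh.cohesion['neg_pos_ratio'].mean():.3f}")
```

Output:

```
planted pair rho = 0.882  (truth 0.8), p = 0.0050
network: 17 nodes, 19 edges, modularity 0.415
roles: {'peripheral': 17}
robustness = 0.270 +/- 0.087
global efficiency = 0.151, max vulnerability = 0.143
mean negative:positive cohesion ratio = 0.889
```

The planted basis correlation of 0.8 between the first two taxa is
recovered as ρ̂ = 0.88 at the smallest attainable bootstrap p (1/201 with
200 bootstraps); at p < 0.01 and only 30 samples the remaining edges are a
mix of the planted module and borderline pairs, giving a small 17-node
network whose nodes are all peripheral (no keystone candidates). Robustness
0.27 means that on average 27% of taxa survive the 50%-removal cascade; the
cohesion ratio below 1 says positive associations outweigh negative ones.

A command-line interface mirrors the library (`rhizonet simulate`,
`filter`, `diversity`, `betatest`, `correlate`, `network`, `roles`,
`stability`, `cohesion`, `biomarkers`, and `rhizonet run --config cfg.yaml`
for the full per-stratum pipeline with a manifest of parameter echoes and
content hashes).

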