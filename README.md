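# orcnet

Multi-scale geometric analysis of differential gene-correlation networks.

`orcnet` identifies modules of genes whose expression changes in a
coordinated way in response to treatment — for example tumor transcriptomes
sampled before and during immune-checkpoint therapy — and tests whether those
modules predict clinical outcome. It is aimed at computational biologists who
have matched pre-/on-treatment expression data, a protein–protein interaction
(PPI) scaffold, and clinical follow-up, and who want module detection driven
by network geometry rather than by an arbitrary correlation cutoff.

## The method

1. **Differential correlation network.** For each patient with matched
   samples, form the expression change Δ = on-treatment − pre-treatment
   (after low-count filtering and per-sample quantile normalization). On a
   confidence-filtered PPI skeleton restricted to a core gene set and its
   interaction neighbors, each edge (i, j) carries the Pearson correlation
   ρ_ij of the patients' expression changes, mapped to a similarity
   ρ′ = (1 + ρ)/2 ∈ [0, 1] and to a transport distance w_ij = 1/ρ′.
   Shortest-path distances d over w give the network metric.

2. **Dynamic Ollivier-Ricci curvature.** Diffusion on the network is
   generated by the random-walk Laplacian L = I − K⁻¹C, where C holds the
   shifted correlations and K its row sums. At each pseudotime τ the heat
   kernel D = e^(−τL) turns every vertex into a probability distribution
   (its row of D). Per-edge curvature

   κ_ij(τ) = 1 − W₁(p_i, p_j) / d_ij

   compares endpoint distributions by exact Wasserstein-1 optimal transport
   with ground cost d. κ starts at 0 (Dirac deltas transport along the
   edge), rises toward 1 as diffusion mixes, and at intermediate scales
   separates clique-like edges (κ > 0) from bridges (κ < 0).

3. **Critical scale and modules.** Sweeping τ over a log grid (default 101
   points, log₁₀ τ ∈ [−2, 2]), the critical scale τ_crit is the first τ at
   which the 99th percentile of edge curvature reaches 0.75. The time-averaged
   integral κ̄_crit of κ(τ) up to τ_crit weights a Louvain modularity
   clustering (resolution 1) that partitions genes into modules.

4. **Clinical statistics.** Per-patient module scores (mean of each gene's
   Δ divided by its across-patient SD, sign preserved) enter a multivariable
   Cox proportional-hazards model, Kaplan-Meier median-split with log-rank
   test, Kruskal-Wallis across RECIST response groups (CR/PR vs SD vs PD),
   per-gene Wilcoxon rank-sum tests with Benjamini-Hochberg correction, and
   hypergeometric over-representation against GMT gene sets.

A synthetic-cohort generator (planted-partition topology, shared-factor
expression model, exponential survival with a planted module effect)
provides ground truth for recovery tests.

## Worked example

```python
from orcnet import SyntheticConfig, synthetic_recovery

res = synthetic_recovery(SyntheticConfig(seed=1), n_tau=21)
print(f"ARI vs planted modules: {res['ari']:.3f}")
print(f"tau_crit: {res['tau_crit']:.3f}, modules: {res['n_modules']}")
print(f"mean kappa_bar within: {res['mean_within']:.3f}, "
      f"between: {res['mean_between']:.3f}")
```

prints

```
ARI vs planted modules: 1.000
tau_crit: 3.981, modules: 4
mean kappa_bar within: 0.407, between: -0.070
```

The planted 4-module structure (120 genes, within/between edge probabilities
0.3/0.02, factor loading 2, unit noise, 100 patients) is recovered exactly;
within-module edges carry far higher integrated curvature than the
between-module bridges, which is precisely the signal the clustering uses.

The same pipeline runs from the shell on TSV artifacts:

```bash
orcnet simulate --outdir run --seed 1
orcnet all      --outdir run --seed 1        # build → curvature → cluster → score → stats
cat run/cluster_summary.json                 # n_modules, within/between means, ARI vs truth
```

Every stage writes plain TSV/JSON and can be rerun in isolation; a manifest
records the resolved configuration and seed, and reruns with one config are
byte-identical.

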