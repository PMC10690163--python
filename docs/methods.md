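# Methods

## Model

`orcnet` treats treatment response as a signal on a gene interaction network.
The object of study is the matrix of per-patient expression changes
Δ_gp = (on-treatment) − (pre-treatment) for gene g and patient p, computed on
normalized expression for patients with matched samples. Genes are vertices
of a protein-interaction skeleton; each retained edge (i, j) carries the
Pearson correlation ρ_ij of the rows Δ_i and Δ_j across patients. The
correlation is mapped affinely onto [0, 1], ρ′ = (1 + ρ)/2, and inverted to
a transport distance w_ij = 1/max(ρ′, ε): strongly co-varying genes are
close, anti-correlated genes are far apart. All-pairs shortest paths d over
w (Dijkstra) make the vertex set a finite metric space.

Diffusion of "information" on this space is generated by the random-walk
Laplacian L = I − K⁻¹C, where C is the shifted-correlation matrix restricted
to edges (zero diagonal) and K the diagonal of its row sums. The heat kernel
D(τ) = e^(−τL) is row-stochastic; row i is the distribution a unit mass at
gene i reaches after pseudotime τ. Dynamic Ollivier-Ricci curvature of an
edge,

    κ_ij(τ) = 1 − W₁(p_i(τ), p_j(τ)) / d_ij,

uses the exact Wasserstein-1 distance with ground cost d. Both limits are
pinned: κ → 0 as τ → 0 (Dirac deltas transport along the shortest path) and
κ → 1 as τ → ∞ (rows converge to the common stationary distribution).
At intermediate scales κ is positive on edges whose endpoint neighborhoods
overlap (clique-like) and negative on bridges, which is the signal used for
community detection.

The sweep uses a log-uniform grid, by default 101 points with
log₁₀ τ ∈ [−2, 2]. The critical scale τ_crit is the first grid τ at which
the 99th percentile (linear interpolation) of the edge-κ distribution
reaches 0.75; κ_crit is each edge's curvature there, and κ̄_crit is the
trapezoidal integral of κ(τ) from the smallest sampled τ to τ_crit divided
by the span (a time average, so |κ̄_crit| ≤ 1; the raw integral is also
emitted). Louvain modularity maximization with κ̄_crit as edge weights
(resolution 1, negative weights floored at 0 by default) yields the module
partition. Per-patient module scores are the mean over module genes of
Δ_gp / sd_g, where sd_g is the gene's across-patient standard deviation
(ddof = 1) — division only, no centering, so the sign of the change is
preserved. Scores feed a multivariable Cox proportional-hazards fit (all
modules jointly), a Kaplan-Meier median split with log-rank test, a
Kruskal-Wallis test across response groups (CR/PR vs SD vs PD, NE removed),
per-gene two-sample Wilcoxon rank-sum tests with Benjamini-Hochberg
correction, and upper-tail hypergeometric over-representation against GMT
gene sets (BH across sets, FDR < 0.05 flagged).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `confidence_cutoff` | 700 | minimum PPI confidence (STRING 0–1000 scale) |
| `min_degree` | 5 | one-shot degree floor on the confidence-filtered PPI graph |
| `min_count`, `min_sample_frac` | 10, 0.10 | gene kept if ≥10 raw counts in ≥10% of samples |
| `tau_min`, `tau_max`, `n_tau` | 1e−2, 1e2, 101 | log-uniform diffusion grid |
| `percentile`, `kappa_threshold` | 99, 0.75 | critical-scale rule |
| `resolution` | 1 | Louvain resolution |
| `distance_floor` ε | 1e−6 | floors ρ′ before inversion so ρ = −1 edges stay finite |
| `mass_floor` | 0 | optional truncation of diffusion supports before W₁ (0 = exact) |

## Numerical choices

- **Heat kernel.** L is similar to the symmetric normalized Laplacian via
  K^(1/2), so e^(−τL) is evaluated for every τ from a single
  eigendecomposition. Entries at the level of spectral roundoff (≲1e−15)
  may come out negative; they are clipped at 0 and rows renormalized. A
  significantly negative entry (<−1e−8) raises instead of being hidden.
- **Wasserstein-1.** The public `wasserstein_w1` solves the Kantorovich
  coupling LP restricted to the support of p − q (exact for a metric ground
  cost, since shared mass never moves) with HiGHS. The curvature sweep uses
  an equivalent min-cost-flow LP on the graph itself — exact because the
  ground cost is the shortest-path metric of the edge weights — built once
  and re-solved with warm starts for every edge and scale; when warm-start
  bindings are unavailable the same LP goes through `scipy.optimize.linprog`.
  Agreement of all routes with a brute-force full coupling LP is enforced by
  tests at 1e−8.
- **Early stopping.** Nothing downstream uses κ beyond τ_crit, so the sweep
  halts there by default; a full-grid mode exists and matches the truncated
  sweep exactly on the shared range.
- **Critical-scale rule.** "Upper 99th percentile ≥ 0.75" is read as: the
  99th percentile of the κ distribution reaches the threshold. The stricter
  reading (99% of edges ≥ 0.75) is available as `tau_crit_mode="fraction"`.
- **κ denominator.** d_ij is the shortest-path distance (guaranteeing κ ≤ 1
  and κ(τ→0) → 0); `denominator_mode="edge_weight"` substitutes the raw edge
  weight.
- **Negative modularity weights.** Louvain's null model assumes nonnegative
  weights; negative κ̄_crit values are floored at 0 by default (a negative
  bridge then simply contributes no within-module gain), with a raw
  pass-through mode for comparison.
- **Degenerate inputs.** Zero-variance genes get ρ = 0 on their edges (the
  maximal distance after shifting) with a warning rather than being dropped
  mid-pipeline; zero-variance rows pass through scoring unscaled; ties at
  the median go to the low survival group; an all-equal score vector is
  rejected where a split or Cox fit would be meaningless.
- **Ties in quantile normalization** receive the mean of the reference
  values at the tied ranks, which makes the operation idempotent.

## Synthetic cohorts and what they do (not) show

The generator plants k modules of near-equal size in an Erdős–Rényi-style
planted-partition graph (defaults: 120 genes, 4 modules, within-module edge
probability 0.3, between 0.02). Expression changes follow a single shared
factor per module: Δ_gp = a·f_{m(g),p} + σ·ε_gp with f, ε standard normal,
so same-module genes correlate at a²/(a² + σ²) (0.8 at the defaults a = 2,
σ = 1) and between-module correlations vanish. If the sampled graph is
disconnected, the minimal number of random cross-component edges (preferring
between-module pairs, to leave planted densities intact) connects it.
Survival times are exponential with hazard λ₀·exp(β·score₁), where score₁
is the planted module-1 score, β defaults to −1 (protective) and λ₀ = 0.1
sets an arbitrary time unit; censoring is an independent exponential whose
rate is calibrated to the requested censored fraction (0.2). Response
categories follow score tertiles (top → CR/PR with CR drawn at 1/3, middle
→ SD, bottom → PD) with 10% of labels reassigned at random so response-group
analyses see realistic overlap. Cohort sizes default to 100 patients for
module recovery and 200 for survival recovery.

These cohorts reproduce the block-correlation and proportional-hazards
structure the analysis assumes — nothing more. Passing recovery tests shows
the pipeline correctly extracts modular structure and survival effects when
they exist at realistic strength; it says nothing about batch effects,
non-proportional hazards, heavy-tailed expression noise, hub-dominated PPI
degree distributions, or modules of strongly unequal size, none of which are
simulated. The recovery experiments use a 21-point τ grid (the log-spacing
makes the curvature trace smooth enough that the integral and the critical
scale are stable under grid refinement); the full 101-point default is used
for single-network analyses.

## Design choices on genuinely open points

- The κ̄_crit integral is reported time-averaged (divided by the integration
  span) so its magnitude is comparable across grids and bounded by 1; the
  raw integral is written alongside it.
- Integration starts at the smallest sampled τ (1e−2), not 0: the grid is
  log-spaced, and κ ≈ 0 on the omitted sliver.
- The degree filter on the PPI graph is a single pass ("initially less than
  5"), not an iterative k-core peel; the peel is available via
  `iterative=True`.
- Gene filtering runs on raw counts first; quantile normalization is applied
  to the normalized values of the retained genes.
- The CR/PR-vs-PD per-gene contrast excludes SD patients; a flag includes
  their group mean in the report. Per-gene tests run on the scaled delta,
  consistent with module scoring; a raw-delta mode exists.
- The within/between curvature comparison uses the equal-variance two-sample
  t-test; Welch's correction is a flag.
- Cox regression uses every patient with non-missing survival, not a
  response-filtered subset.
- Module ids are assigned deterministically (decreasing size, ties by
  smallest member gene), so a fixed seed fixes the labeling, and permuting
  vertex names permutes only the labels.

## Limitations

- Exact optimal transport scales as an LP per edge per scale; networks
  beyond a few thousand genes become expensive. Entropy-regularized
  approximations are deliberately out of scope.
- τ_crit is resolved only to the grid; conclusions should not hinge on its
  third decimal.
- The six-module count reported for real cohorts of this kind is
  seed-dependent in Louvain; the seed is mandatory and recorded in every
  output.
- rlog (or any count normalization) is consumed as provided, never
  recomputed; GO-database-backed enrichment is replaced by generic GMT
  over-representation.
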