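# Methods

## Problem and model

The package finds subnetworks of a protein-interaction network (PIN) in
which an unusually large number of genes are differentially expressed
between two sample groups. The underlying idea: individual-gene inference
at n ≈ 12 samples is underpowered for subtle coordinated changes, but a
network module whose members shift together accumulates evidence. The
pipeline therefore (i) scores every gene with an empirical-Bayes moderated
t-statistic, (ii) transfers those scores onto the interactome's edges,
(iii) searches for communities of heavy edges around high-scoring seed
genes, and (iv) calibrates each community's total internal weight against a
statistic-permutation null.

### Moderated t

For gene *g* with group means m̄₁ (case), m̄₂ (control), pooled residual
variance s²_g on d_g = n₁+n₂−2 df:

- Prior (d₀, s₀²) is fitted by matching the mean and variance of
  log s²_g to a scaled-F model (digamma/trigamma moment equations; the
  trigamma inverse is solved by Newton iteration). When the observed
  spread of log-variances does not exceed chi-square sampling noise, d₀ is
  infinite and s₀² is the mean variance.
- Posterior variance s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g);
  t_g = (m̄₁−m̄₂)/(s̃_g √(1/n₁+1/n₂)), two-sided p on d₀+d_g df (normal
  reference when d₀ = ∞).
- The estimator is restricted to the two-group contrast by design; it is
  cross-checked in the test suite against Bioconductor limma (agreement to
  1e-10 on t in both the finite- and infinite-prior branches).
- Zero-variance genes are excluded from the prior fit but shrunk like any
  other gene; a gene with zero log-fold-change is reported as t = 0, p = 1.

### q-values

π₀ is estimated as a running-mean smooth (window 3) of
\#{p>λ}/(m(1−λ)) over λ ∈ {0, 0.05, …, 0.90}, evaluated at the largest λ,
falling back to the most conservative grid point if the smoother
degenerates; q_i = min_{p_j ≥ p_i} π₀ m p_j / rank(p_j), capped at 1.
Fixing π₀ = 1 reproduces Benjamini–Hochberg exactly (tested against a
brute-force step-up oracle).

### Edge weights

w_gh = (|t_g| + |t_h|) / (2·t_max) for every interaction, t_max = max |t|
over network nodes, so w ∈ [0,1] and w = 1 exactly on edges joining two
maximal-|t| genes. The displayed form of this weighting in the source
protocol is given only in words ("combined strength", "average of the
absolute regularized t-statistics", normalization "by the maximum absolute
t-statistic", range 0–1); the arithmetic-mean reconstruction here satisfies
all of them and is exposed as a pluggable `norm` function, with the t_max
scope (network vs all measured genes) selectable.

### Spin-glass module search

The community model is the weighted Reichardt–Bornholdt Potts Hamiltonian
with a configuration-model null:

H(σ) = −Σ_{i<j} (A_ij w_ij − γ·s_i s_j / 2W)·δ(σ_i, σ_j),

s = weighted node strength, W = total edge weight, q = 25 spin states,
resolution γ (protocol default 0.5). For each seed (top-|t| network genes,
ties broken lexicographically) the partition of the seed's connected
component is annealed (geometric schedule 1.0 → 0.01, cooling 0.99, n
proposals per temperature, Metropolis acceptance) and the community
containing the seed is returned. Three design points matter:

- **Partition, not single community.** Optimizing H(C) of one community in
  isolation is degenerate: for γ < 1 the whole connected component is the
  minimizer (the internal-pair null grows quadratically but the internal
  weight linearly dominates on any graph whose mean edge quality is
  positive). A two-block (in/out) variant instead favors balanced cuts.
  The full q-state partition — what the standard igraph implementation
  anneals — restores the intended resolution behavior; the seed's block is
  the module. The kernel was cross-validated against
  `igraph.community_spinglass(spins=25, gamma=0.5)` (identical seed
  communities) and against an exhaustive all-partitions oracle on ≤12-node
  graphs (restricted-growth-string enumeration; exact agreement for
  γ ∈ {0.25, 0.5, 1}).
- **Zero-temperature polish with merge moves.** After annealing, a greedy
  pass applies single-node moves *and* wholesale community merges until a
  local minimum: near the small-γ merging boundary the optimum is
  unreachable by single-node moves alone. With this polish every restart
  reaches the enumerated optimum on all test graphs.
- **Determinism.** Each seed gene gets its own annealing stream derived
  from (rng_seed, crc32(seed gene)), so results are independent of seed
  processing order; the best of `n_restarts` (default 3) restarts wins.

A seed fails (returns nothing) when it has no positive-weight incident
edge or when its community is smaller than `min_module_size` (default 10).

### Permutation significance

Modularity M(C) = total weight of edges inside C (the average per-edge
weight is reported alongside). Node statistics are permuted over all
network nodes with topology and t_max fixed; because the member set is
fixed, the permuted modularity reduces to Σ_i d_i·|t_π(i)|/(2 t_max) with
d_i the internal degree, which vectorizes. p = (1 + #{M_perm ≥ M_obs}) /
(1 + n_perm) (never zero; ties count against the module), default
n_perm = 1000. Adjusted p is Bonferroni across tested modules (the
conservative reading of "adjusted"; the raw permutation p is always
reported as well). Retained modules (p_adj ≤ α = 0.05) are ranked by
modularity with pairwise Jaccard overlap reported and optional greedy
de-duplication (off by default).

## Synthetic data: what it emulates and what it does not

`simulate_expression` draws log2 intensities N(baseline 8, σ = 1), with a
case-group mean shift (the effect, in log2 units = σ units by default) on a
chosen planted gene set; defaults mirror the motivating study design
(7 cases, 5 controls). Homoscedastic by default (matching the two-group
t model), heteroscedastic per-gene sds behind a flag.
`simulate_raw_probes` adds the raw-scale features the preprocessing stage
needs: lognormal intensities, background-corrected values that can be
negative, per-probe detection p-values, unannotated probes.
`simulate_interactome` builds a Barabási–Albert background (m = 3 by
default; uniform G(n,p) optional) with gene ids assigned by a seeded
random permutation (so planted genes do not sit on the oldest, highest-
degree nodes), then guarantees the planted module's internal density by
adding exactly ⌈density·C(k,2)⌉ internal edges.
`simulate_validation_stats` gives a chosen fraction of module genes a
statistic with the discovery sign and super-threshold magnitude (t with
6 df, matching a 4 vs 4 validation design), the rest near zero.

Not emulated: probe chemistry and spatial artifacts, correlated gene
noise, degree-correlated expression, literature bias of interactome edges.
Passing tests on this generator show the machinery is correct and the
benchmark detectable — not that effect sizes or error rates transfer to
any real interactome.

## Benchmark behavior and known limitations

The test benchmark plants a 10-gene module (internal density 0.9, effect
4σ) in a 300-node background and runs 10 seeds with n_perm = 400 at
resolution γ = 2 — matched to the planted scale, since γ = 0.5 targets the
hundred-gene modules of a ~6000-node interactome. Two properties of the
*method itself* (reproduced identically by the reference igraph
implementation) are documented here deliberately:

- **Modules extend hot cores by their first neighbors.** Any edge from a
  high-|t| gene to a null neighbor weighs ≈ 0.5 under the mean-|t|
  weighting, while its configuration-model expectation is far smaller, so
  the optimal community is the hot core plus its immediate neighborhood
  (hub-and-spokes modules — the shape of the published JAK2 module). On
  the benchmark the planted core (≥8 of 10 members, p_adj ≤ 0.05) is
  recovered in ~90% of runs, but the Jaccard overlap with the planted set
  alone plateaus near 0.55 at every resolution and background density.
- **Select-then-permute is anti-conservative under a global null.** The
  permutation p is exact for a module chosen independently of the
  statistics (measured P(p ≤ 0.05) ≈ 0.05–0.07 over 200 random-module
  tests), but communities selected around top-|t| seeds by maximizing
  statistic-weighted internal weight are by construction extreme in the
  permutation ensemble: with zero effect everywhere, roughly a third of
  benchmark runs still report a Bonferroni-significant module. Hotspot
  p-values should therefore be read as module-level summaries given the
  selection, not as calibrated family-wise error rates; a
  selection-adjusted null (re-running detection inside each permutation)
  is the in-principle fix and is out of scope for this package.

Other numerical choices: quantile-normalization ties receive the mean of
the reference quantiles they span; zeros are floored like negatives before
log2 (the floor exists to make log2 well-defined); probe collapsing
averages on the log2 scale after normalization; detection-filter threshold
is strict (<) and `min_samples` defaults to ⌈5n/12⌉; the concordance 2×2
table crosses discovery × validation signs over all shared module genes
(zero statistics count as positive), with the nominally-significant
same/opposite counts reported separately; enrichment FDR uses BH rather
than q-values because gene-set collections are small.
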