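# Methods

This note records the models, estimators and numerical choices behind
`dynstates`, the defaults and why they were chosen, and what the synthetic
validation does and does not establish.

## Generative model and synthetic cohorts

The package assumes multi-subject ROI BOLD series are generated by a
condition-specific Gaussian hidden Markov model: a K-state Markov chain with
row-stochastic transition matrix P, each state k emitting observations from
N(μ_k, Σ_k) in ROI space. The synthetic generator (`dynstates.synthetic`)
instantiates this model with fully known parameters:

- **Scale.** Defaults emulate the recording scale the package targets:
  N = 13 subjects, D = 63 regions, T = 200 volumes per condition at
  TR = 3 s. These are the generator's study conditions, not tuning knobs.
- **State means.** Drawn isotropically and rescaled so the minimum pairwise
  distance equals `separation` (default 6.0) in raw ROI units. Because the
  analysis z-scores the concatenation — whose per-channel variance includes
  the between-state spread — the raw default corresponds to roughly
  3σ-separated states in the reduced space where the HMM is actually fit.
  This is the "well separated" regime; recovery degrades gracefully below it.
- **State covariances.** Equicorrelation block matrices: within-block
  correlation 0.6, between-block 0.1 (within ≥ 3× between is enforced),
  unit variances, PSD-jittered if needed. The blocks are the planted
  spatiotemporal communities; an anesthesia-like condition keeps one block
  assignment across all states, a wake-like condition re-draws the
  ROI-to-block permutation per state.
- **Sink construction.** For a target sink stationary mass m, the sink row
  keeps self-transition 0.9 and every other row sends
  q = 0.1·m/(1−m) into the sink, the remaining mass spread uniformly. By
  symmetry the exact stationary distribution is (m, (1−m)/(K−1), …), which
  is verified by an eigen-solution at construction time (error if the mass
  is infeasible, i.e. q ≥ 1). Without a sink, P = β·I + (1−β)/K with
  stickiness β = 0.3 is doubly stochastic, so the stationary distribution is
  exactly uniform.
- **Emissions.** State Gaussian plus isotropic noise of scale `obs_noise`
  (default 0.2). A covariance of exactly zero is treated as a deterministic
  state (used only for degenerate-input tests). Subject-level heterogeneity
  is off by default; a Dirichlet `transition_jitter` can perturb per-subject
  transition rows.
- **Structural connectome.** Weighted stochastic block model on the same
  blocks: within-block weights U(0.5, 1), between-block U(0, 1)·noise
  (default noise 0.1), symmetrized, zero diagonal. Aligned with the
  anesthesia-like covariance blocks when requested.

What the generator does *not* emulate: hemodynamic convolution, scanner
drift, motion artifacts, spatial autocorrelation beyond the block structure,
or subject-specific anatomy. Passing recovery tests therefore demonstrate
estimator correctness under the model's own assumptions, not robustness to
real fMRI artifacts.

## Reduction

ROI channels are z-scored over the concatenation of all subjects (not per
subject), matching the combine-then-reduce ordering of the pipeline, then
projected onto principal components. The retained dimension comes from
Horn's parallel analysis: sample covariance eigenvalues are compared
rank-by-rank with the 95th percentile of eigenvalues from 100 null datasets
in which each column is independently permuted. Permutation (rather than
Gaussian resampling) preserves channel marginals. d is the count of leading
eigenvalues above the null before the first failure, floored at 1. No
whitening is applied: components keep their variances, which the full
covariance emission model absorbs; the choice is recorded in the run
manifest.

## HMM fitting

Fitting is maximum-likelihood Baum–Welch (EM), delegated to
`hmmlearn.GaussianHMM` with full covariances, with subject boundaries passed
so no transition is learned across recordings. Choices that matter:

- **Initialization.** Means *and* per-cluster covariances are seeded from a
  multi-start k-means (n_init = 10). Seeding every state with the global
  data covariance is pathological when states are well separated: the global
  covariance is dominated by between-state spread, the initial E-step
  responsibilities are nearly uniform, and the M-step smears an even perfect
  mean assignment (observed as merged states at larger K). Per-cluster
  covariance initialization removes this failure mode and speeds
  convergence several-fold.
- **Restarts.** Best of `n_restarts` (default 5) seeded EM runs by training
  log-likelihood. The full log-likelihood trace is recorded (EM guarantees
  it non-decreasing; tests assert it).
- **Regularization.** 1e-6 ridge on covariance diagonals guarantees PSD at
  small T.
- **Initial distribution.** Set to the stationary distribution of the
  fitted transition matrix, reflecting the resting-state stationarity
  assumption; decoding uses it as the start probability.
- **Model size.** For each candidate K (default range 2–6 for the packaged
  pipeline), fit, decode, and compute the entropy of the group-mean
  fractional occupancy; the argmax wins, ties toward smaller K. This
  criterion tends to choose models at least as large as the planted state
  count, which is the intended behavior (more states allow more complex
  dynamics); pruning then removes unexpressed states.
- **Pruning.** A state "appears" in a subject iff the subject's Viterbi
  path visits it at least once (a deterministic criterion; an FO-threshold
  alternative is available by configuration). States under the 20%
  subject-fraction threshold are removed, surviving transition rows
  renormalized, and the cohort re-decoded. The entropy/information rate is
  computed on the pruned, restandardized matrix, recorded in the manifest.

## Chain dynamics

- **Stationary distribution.** Computed as the limit from the uniform start
  of the lazy chain (P+I)/2 by repeated squaring (with row renormalization
  against floating-point drift). Laziness removes periodicity; the uniform
  start makes the result well defined for reducible chains, which pruning
  can produce. For irreducible chains this equals the unique stationary
  distribution to ~1e-15.
- **Entropy rate** uses base-2 logarithms (bits) by default, configurable
  to nats; 0·log 0 = 0.
- **Switching rate** divides state changes by (T−1)·TR — transitions, not
  samples — so the attainable ceiling is exactly 1/TR Hz.
- **Occupancy entropy** is Shannon entropy of the FO vector over log K,
  defined as 0 for K = 1.
- **Subject clustering** uses distance 1 − Pearson(FO_a, FO_b) with Ward
  linkage; constant FO vectors are an error naming the subject.

## HMGM and spatiotemporal communities

Intralayer weights are absolute ROI-space correlations of each state's
covariance (zero diagonal); interlayer coupling is ω₀·(P_sr+P_rs)/2 for
s ≠ r — modularity needs undirected weights, so the directed transition
structure is symmetrized. All layer pairs with positive symmetrized
probability are coupled (no floor). The quality function is the multilayer
Newman–Girvan form with a per-layer uniform null; a layer with no
intralayer weight contributes only coupling terms. The kernel is evaluated
through one dense (DK)×(DK) modularity matrix, which a brute-force
double-loop oracle checks to 1e-12 in the tests.

Optimization is generalized Louvain on that matrix: node sweeps in seeded
random order, each node moving to the best-gain community (ties to the
first scanned), then aggregation of communities into super-nodes, repeated
until no gain. Deterministic given the seed. On toy instances small enough
to enumerate all set partitions, the tests require the optimizer to attain
the exhaustive optimum in ≥ 90% of instances and never exceed it.

Consensus: Louvain runs over the resolution grid γ ∈ {0.8…1.2} × coupling
grid ω₀ ∈ {0.5, 1, 2} × `n_consensus_runs` seeds produce a co-classification
frequency matrix, thresholded at the mean co-classification of a
label-permuted null and re-clustered until stable (≤ 50 iterations, warning
on non-convergence). Because permuting a partition's labels preserves
community sizes, the null mean is available in closed form
Σ_c n_c(n_c−1)/(n(n−1)) averaged over runs — the implementation uses this
exact value rather than sampling permutations. Q of the consensus partition
is reported at the grid medians. Single-layer (state-wise and structural)
partitions reuse the same machinery on a one-layer HMGM with zero coupling;
with ω = 0 the multilayer result provably reduces to independent per-layer
partitions, which the tests confirm.

Layers (and, transposed, regions) are hierarchically clustered by
1 − Jaccard similarity of co-clustered pairs between induced partitions,
with Ward linkage; two layers with no co-clustered pairs at all are defined
as similarity 1 (both trivially "all singletons").

## State metrics and structure comparison

Edge weights for all graph metrics are absolute correlations (signed
matrices are retained for sensitivity analyses). Path lengths are 1/w;
global efficiency is the mean inverse shortest-path length over ordered
pairs (unreachable pairs contribute 0), normalized by the mean efficiency of
100 graphs with the upper-triangle weight multiset randomly permuted (a pure
weight shuffle; degree sequence is not preserved). The robust local
efficiency of node i averages (w_ij·w_ih·e_jh)^{1/3} over neighbor pairs,
with e_jh the inverse shortest-path length inside the neighborhood subgraph;
it reduces to the classic binary local efficiency on 0/1 graphs and scores 0
for degree < 2.

Distance correlation is Székely's sample statistic from doubly centered
distance matrices (O(n²) memory; fine at the package's scales), with a
signed variant multiplying by the sign of the Pearson correlation. AMI uses
max normalization (recorded in output metadata); ARI is standard. Condition
contrasts use two-sided Mann–Whitney U (unpaired) or Wilcoxon signed-rank
(paired), exact for small samples without ties. Permutation tests use the
add-one estimator p = (1 + #extreme)/(1 + n_perm), which cannot report an
exact zero; the AMI condition contrast permutes state labels across
conditions (an assumption, as no canonical scheme exists for it).

## Pipeline problem sizes and determinism

The packaged two-condition pipeline runs at the full emulated scale
(N = 13, D = 63, T = 200 per condition) with desk-scale analysis settings
chosen for routine use: candidate K range 2–6, 2 EM restarts, ≤ 100 EM
iterations, 10 consensus runs per grid point, 50 permutations for
efficiency nulls and parallel analysis. Validation suites use smaller
cohorts (D = 10–16) for repeated-seed recovery studies, and K = 32 with
near-spherical emissions for the large-model check that a uniform chain has
no strong sink (1/32 < 0.05 needs K > 20 by arithmetic). One global seed
expands deterministically into per-stage child seeds, so any run is
bit-identical under a fixed (config, seed) — asserted file-by-file in the
tests.

## Known limitations

- Maximum-likelihood EM replaces variational Bayes training; state-space
  semantics are identical but there is no automatic relevance determination,
  so model-size selection and pruning carry that burden.
- The multilayer modularity uses the uniform-null, all-pairs-coupled form;
  directed or adjacency-restricted couplings are out of scope.
- Distance correlation is O(n²) in memory and time; vectorized upper
  triangles at D = 63 (n = 1953) are comfortable, but much larger
  parcellations would need a tiled implementation.
- The synthetic generator's block-equicorrelation covariances make some
  ground-truth graph profiles exactly node-symmetric (e.g. constant local
  efficiency), which is degenerate for correlation measures; fitted models
  do not exhibit this.
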