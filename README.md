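# dynstates

Hidden-Markov brain-state models and spatiotemporal community analysis for
multi-subject ROI BOLD time series.

Resting-state fMRI under different conditions of consciousness (e.g. deep
anesthesia vs. wakefulness) can be summarized as a sequence of recurring
*brain states*: hidden states of a Gaussian hidden Markov model whose mean
encodes a regional activity pattern and whose covariance encodes functional
connectivity. `dynstates` is for researchers who want to fit such models to
ROI-parcellated cohorts, quantify how dominant and how temporally complex
the resulting state dynamics are, and relate the dynamic functional
organization to a structural connectome.

## What it computes

Given per-subject ROI × time matrices (one TSV per subject), the pipeline:

1. **Reduction** — z-scores each ROI channel over the concatenated cohort,
   selects a reduced dimension *d* by Horn's parallel analysis, and projects
   onto the leading principal components.
2. **HMM fitting** — maximum-likelihood Baum–Welch (best of several seeded
   restarts) for a Gaussian HMM with full covariances, respecting subject
   boundaries. The model size *K* maximizes the entropy of the group-mean
   fractional occupancy (FO); states visited by fewer than 20% of subjects
   are pruned and transition rows restandardized.
3. **Chain dynamics** — each state's *sink centrality* is its stationary
   probability π_k under the fitted transition matrix P ("strong" sinks have
   π_k ≥ 0.05); temporal complexity is the entropy (information) rate
   H = −Σ_k π_k Σ_j P_kj log₂ P_kj and the per-subject switching rate of the
   Viterbi path; subject state diversity is the normalized FO entropy.
4. **Spatiotemporal communities** — states become layers of a *hidden Markov
   graph model* (HMGM): D ROI nodes per layer, intralayer edges |corr| of
   the state's ROI covariance, and node-aligned interlayer coupling
   ω·(P_sr+P_rs)/2. Communities of (ROI, state) node-layers maximize the
   multilayer Newman–Girvan modularity

   Q = (1/2μ) Σ_ijs [A_ijs − γ k_is k_js / 2m_s] δ(g_is, g_js)
     + (1/2μ) Σ_{i,s≠r} ω_sr δ(g_is, g_ir)

   via generalized Louvain, aggregated over a (γ, ω) grid by consensus
   clustering. Fractional membership F_ic = Σ_s π_s 1[g_is = c] gives the
   long-run share of time region *i* spends in community *c*.
5. **Structure–function comparison** — per-state distance correlation of
   edge weights, degree centrality and robust local efficiency against a
   structural connectome, AMI/ARI of consensus partitions, and two-sided
   rank / permutation tests for condition contrasts.

A first-class synthetic-cohort generator plants all of this structure
(states, a dominant sink, block communities, a matching or scrambled
connectome) at the emulated study scale — 13 subjects, 63 ROIs, 200 volumes
at TR = 3 s per condition — so every stage can be validated against ground
truth.

## Worked example

```python
import numpy as np
import dynstates as ds

# plant a 4-state model with a dominant sink (stationary mass 0.4)
truth = ds.make_ground_truth(K_true=4, D=20, sink_mass=0.4,
                             block_sizes=[10, 10], seed=0)
study = ds.simulate_cohort(truth, N=13, T=200, tr=3.0, obs_noise=0.2, seed=1)

# reduce and fit
X, lengths, center, scale = ds.standardize_concatenate(study.cohort)
d = ds.horn_parallel_analysis(X, n_null=100, seed=2)
Z, rmap = ds.pca_reduce(X, d, center=center, scale=scale)
model = ds.fit_hmm(Z, lengths, K=4, n_restarts=3, seed=3, reduction=rmap)
decode = ds.decode_subjects(model, Z, lengths)

pi = ds.stationary_distribution(model.transition_matrix)
print(f"sink centralities     = {np.round(np.sort(pi)[::-1], 3)}")
print(f"entropy rate          = {ds.entropy_rate(model.transition_matrix):.3f} bits/step")

# spatiotemporal communities on the hidden Markov graph model
hmgm = ds.build_hmgm(model)
part, _ = ds.consensus_communities(hmgm, resolution_grid=[0.9, 1.0, 1.1],
                                   coupling_grid=[0.5, 1.0], n_runs=8, seed=4)
print(f"communities found     = {part.n_communities} (Q = {part.Q:.3f})")
print(f"recovery vs planted   = AMI "
      f"{ds.ami(part.labels.reshape(-1), truth.planted_labels.reshape(-1)):.2f}")
```

Output:

```
sink centralities     = [0.397 0.209 0.203 0.191]
entropy rate          = 1.369 bits/step
communities found     = 2 (Q = 0.379)
recovery vs planted   = AMI 1.00
```

The fitted top sink centrality (0.397) recovers the planted stationary mass
of 0.4; the consensus spatiotemporal partition recovers the planted two-block
community structure exactly (AMI 1.0).

## Command line

The library is also exposed as `dynstates` with subcommands
`simulate`, `reduce`, `fit`, `dynamics`, `communities`, `compare-structure`
and `report` (the full two-condition pipeline), sharing
`--config <yaml> --seed <int> --out <dir>` flags. Tables are TSV, summaries
JSON, dendrograms Newick.

```sh
dynstates report --seed 11 --out results/
```

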