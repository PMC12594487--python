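"""Hidden Markov graph models (HMGM) and spatiotemporal community detection.

An HMGM is a multilayer graph: one layer per hidden state over the same D ROI
nodes, intralayer edges weighted by the state's functional connectivity
(absolute ROI-space correlation) and node-aligned interlayer edges weighted
by the symmetrized transition probabilities.  Communities of (ROI, state)
node-layers maximize a multilayer Newman-Girvan modularity

    Q = (1/2mu) sum_{ijs} [A_ijs - gamma k_is k_js / (2 m_s)] delta(g_is, g_js)
      + (1/2mu) sum_{i, s!=r} omega_sr delta(g_is, g_ir)

optimized by a generalized Louvain algorithm and aggregated over a
(resolution x coupling) parameter grid by consensus clustering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "HMGM",
    "SpatiotemporalPartition",
    "build_hmgm",
    "multilayer_modularity",
    "genlouvain_optimize",
    "consensus_communities",
    "fractional_membership",
    "cluster_layers",
    "cluster_regions",
]

log = logging.getLogger(__name__)


@dataclass
class HMGM:
    """Multilayer state graph: K layers of D ROI nodes plus coupling."""

    layers: np.ndarray    # (K, D, D) symmetric, entries in [0, 1], zero diagonal
    coupling: np.ndarray  # (K, K) symmetric nonnegative, zero diagonal
    pi: np.ndarray        # (K,) stationary weights of the chain

    def __post_init__(self) -> None:
        K = self.layers.shape[0]
        if self.coupling.shape != (K, K):
            raise ValueError("coupling must be K x K")
        for s in range(K):
            A = self.layers[s]
            if not np.allclose(A, A.T, atol=1e-10):
                raise ValueError(f"layer {s} not symmetric")
            if np.any(A < -1e-12) or np.any(A > 1 + 1e-12):
                raise ValueError(f"layer {s} weights must lie in [0, 1]")
            if np.any(np.abs(np.diag(A)) > 1e-12):
                raise ValueError(f"layer {s} diagonal must be zero")
        if not np.allclose(self.coupling, self.coupling.T, atol=1e-10):
            raise ValueError("coupling must be symmetric")
        if np.any(np.abs(np.diag(self.coupling)) > 1e-12):
            raise ValueError("coupling diagonal must be zero")

    @property
    def n_layers(self) -> int:
        return self.layers.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.layers.shape[1]


@dataclass
class SpatiotemporalPartition:
    """Community label for every (ROI, state) node-layer."""

    labels: np.ndarray  # (D, K) int
    Q: float = np.nan
    gamma: float | None = None
    omega_scale: float | None = None
    seed: int | None = None

    @property
    def n_communities(self) -> int:
        return len(np.unique(self.labels))

    def layer_partition(self, s: int) -> np.ndarray:
        return self.labels[:, s]


def build_hmgm(model, coupling_scale: float = 1.0) -> HMGM:
    """Assemble the HMGM from a fitted state model with ROI-space covariances.

    Intralayer weights are absolute correlations derived from each state's
    ROI covariance (zero diagonal); interlayer coupling between layers s != r
    is ``coupling_scale * (P_sr + P_rs) / 2``.
    """
    from .dynamics import stationary_distribution

    if model.roi_covariances is None:
        raise ValueError("model lacks ROI-space covariances; project first")
    K = model.K
    layers = np.empty((K, *model.roi_covariances.shape[1:]))
    for s in range(K):
        C = model.roi_covariances[s]
        sd = np.sqrt(np.diag(C))
        if np.any(sd <= 0):
            raise ValueError(f"state {s} covariance is not positive definite")
        R = C / np.outer(sd, sd)
        A = np.abs(np.clip(R, -1.0, 1.0))
        np.fill_diagonal(A, 0.0)
        layers[s] = 0.5 * (A + A.T)
    P = model.transition_matrix
    omega = coupling_scale * 0.5 * (P + P.T)
    np.fill_diagonal(omega, 0.0)
    return HMGM(layers=layers, coupling=omega,
                pi=stationary_distribution(P))


# ---------------------------------------------------------------------------
# modularity matrix machinery


def _modularity_matrix(hmgm: HMGM, gamma: float, coupling_scale: float = 1.0):
    """Dense (D*K) x (D*K) multilayer modularity matrix B and total weight 2mu.

    Node-layer u = s*D + i.  Intralayer blocks carry the per-layer
    Newman-Girvan null; interlayer entries couple node i with itself across
    layer pairs.  An all-zero layer contributes only coupling terms.
    """
    K, D = hmgm.n_layers, hmgm.n_nodes
    n = D * K
    B = np.zeros((n, n))
    two_mu = 0.0
    for s in range(K):
        A = hmgm.layers[s]
        k = A.sum(axis=1)
        two_m = k.sum()
        sl = slice(s * D, (s + 1) * D)
        if two_m > 0:
            B[sl, sl] = A - gamma * np.outer(k, k) / two_m
            two_mu += two_m
        else:
            log.info("layer %d has no intralayer weight; coupling only", s)
    omega = coupling_scale * hmgm.coupling
    for s in range(K):
        for r in range(K):
            if s == r or omega[s, r] == 0:
                continue
            idx = np.arange(D)
            B[s * D + idx, r * D + idx] += omega[s, r]
    two_mu += D * float(omega.sum())
    if two_mu <= 0:
        raise ValueError("HMGM has no weight at all")
    return B, two_mu


def multilayer_modularity(
    hmgm: HMGM,
    labels: np.ndarray,
    gamma: float = 1.0,
    coupling_scale: float = 1.0,
) -> float:
    """Evaluate Q for a (D, K) label matrix under the multilayer kernel."""
    K, D = hmgm.n_layers, hmgm.n_nodes
    labels = np.asarray(labels)
    if labels.shape != (D, K):
        raise ValueError("labels must cover every (ROI, state) node-layer")
    flat = labels.T.reshape(-1)  # u = s*D + i
    B, two_mu = _modularity_matrix(hmgm, gamma, coupling_scale)
    same = flat[:, None] == flat[None, :]
    return float(np.sum(B[same]) / two_mu)


def _louvain_on_matrix(B: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Generalized Louvain on an arbitrary symmetric modularity matrix.

    Node sweeps visit nodes in seeded random order and move each node to the
    community with the largest quality gain (ties to the first-scanned
    community); levels aggregate communities into super-nodes until no move
    improves the total.  Returns integer labels (contiguous from 0).
    """
    n = B.shape[0]
    mapping = np.arange(n)
    Bl = B.copy()
    while True:
        m = Bl.shape[0]
        labels = np.arange(m)
        improved_level = False
        moved = True
        while moved:
            moved = False
            for u in rng.permutation(m):
                cu = labels[u]
                row = Bl[u]
                scores = np.bincount(labels, weights=row, minlength=labels.max() + 1)
                current = scores[cu] - row[u]  # self-term is move-invariant
                scores = scores.copy()
                scores[cu] = current
                best = int(np.argmax(scores))
                if scores[best] > current + 1e-12 and best != cu:
                    labels[u] = best
                    moved = True
                    improved_level = True
        # compact labels
        _, labels = np.unique(labels, return_inverse=True)
        if not improved_level:
            break
        c = labels.max() + 1
        if c == m:
            break
        # aggregate B over communities
        M = np.zeros((m, c))
        M[np.arange(m), labels] = 1.0
        Bl = M.T @ Bl @ M
        mapping = labels[mapping]
    _, out = np.unique(mapping, return_inverse=True)
    return out


def genlouvain_optimize(
    hmgm: HMGM,
    gamma: float = 1.0,
    coupling_scale: float = 1.0,
    seed: int = 0,
) -> SpatiotemporalPartition:
    """Locally optimal spatiotemporal partition by generalized Louvain."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    K, D = hmgm.n_layers, hmgm.n_nodes
    B, two_mu = _modularity_matrix(hmgm, gamma, coupling_scale)
    rng = np.random.default_rng(seed)
    flat = _louvain_on_matrix(B, rng)
    same = flat[:, None] == flat[None, :]
    Q = float(np.sum(B[same]) / two_mu)
    labels = flat.reshape(K, D).T
    return SpatiotemporalPartition(
        labels=labels, Q=Q, gamma=gamma, omega_scale=coupling_scale, seed=seed
    )


# ---------------------------------------------------------------------------
# consensus clustering


def _coclassification(partitions: list[np.ndarray]) -> np.ndarray:
    n = partitions[0].size
    C = np.zeros((n, n))
    for p in partitions:
        C += (p[:, None] == p[None, :]).astype(float)
    return C / len(partitions)


def _null_threshold(partitions: list[np.ndarray]) -> float:
    """Mean off-diagonal co-classification of label-permuted partitions.

    Permuting a partition's labels preserves community sizes, so the mean of
    the permutation-null co-classification matrix is the exact closed form
    sum_c n_c (n_c - 1) / (n (n - 1)), averaged over runs.
    """
    vals = []
    for p in partitions:
        n = p.size
        _, counts = np.unique(p, return_counts=True)
        vals.append(float((counts * (counts - 1)).sum() / (n * (n - 1))))
    return float(np.mean(vals))


def _consensus_flat(
    partitions: list[np.ndarray],
    n_runs: int,
    rng: np.random.Generator,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Standard consensus-clustering loop on flat label arrays."""
    coclass = _coclassification(partitions)
    current = partitions
    for _ in range(max_iter):
        C = _coclassification(current)
        thr = _null_threshold(current)
        Cthr = np.where(C >= thr, C, 0.0)
        np.fill_diagonal(Cthr, 0.0)
        if Cthr.sum() == 0:
            # everything below the null: each node alone
            return np.arange(C.shape[0]), coclass
        k = Cthr.sum(axis=1)
        B = Cthr - np.outer(k, k) / k.sum()
        runs = [
            _louvain_on_matrix(B, np.random.default_rng(int(s.generate_state(1)[0] % 2**31)))
            for s in rng.bit_generator.seed_seq.spawn(n_runs)
        ]
        first = runs[0]
        if all(np.array_equal(_canon(first), _canon(r)) for r in runs[1:]):
            return first, coclass
        current = runs
    warnings.warn("consensus clustering did not stabilize; returning last iterate")
    return current[0], coclass


def _canon(labels: np.ndarray) -> np.ndarray:
    """Canonical relabeling so identical partitions compare equal."""
    _, inv = np.unique(labels, return_index=False, return_inverse=True)
    order = {}
    out = np.empty_like(inv)
    nxt = 0
    for i, v in enumerate(inv):
        if v not in order:
            order[v] = nxt
            nxt += 1
        out[i] = order[v]
    return out


def consensus_communities(
    hmgm: HMGM,
    resolution_grid: list[float] | None = None,
    coupling_grid: list[float] | None = None,
    n_runs: int = 20,
    seed: int = 0,
) -> tuple[SpatiotemporalPartition, np.ndarray]:
    """Robust spatiotemporal communities over a parameter grid.

    Runs generalized Louvain for every (gamma, coupling scale) grid pair and
    ``n_runs`` seeds, builds the co-classification frequency matrix over all
    runs, thresholds it at the permutation-null mean, and re-clusters until
    stable.  Q of the consensus partition is reported at the central grid
    point.  Returns the partition and the (D*K) x (D*K) co-classification
    matrix (node-layer order u = s*D + i).
    """
    resolution_grid = resolution_grid or [0.8, 0.9, 1.0, 1.1, 1.2]
    coupling_grid = coupling_grid or [0.5, 1.0, 2.0]
    K, D = hmgm.n_layers, hmgm.n_nodes
    ss = np.random.SeedSequence(seed)
    n_combo = len(resolution_grid) * len(coupling_grid)
    children = ss.spawn(n_combo + 1)
    partitions: list[np.ndarray] = []
    ci = 0
    for gamma in resolution_grid:
        for om in coupling_grid:
            B, _ = _modularity_matrix(hmgm, gamma, om)
            for run_ss in children[ci].spawn(n_runs):
                rs = int(run_ss.generate_state(1)[0] % 2**31)
                partitions.append(_louvain_on_matrix(B, np.random.default_rng(rs)))
            ci += 1
    rng = np.random.default_rng(children[-1])
    flat, coclass = _consensus_flat(partitions, n_runs, rng)
    labels = flat.reshape(K, D).T
    g_mid = float(np.median(resolution_grid))
    om_mid = float(np.median(coupling_grid))
    Q = multilayer_modularity(hmgm, labels, g_mid, om_mid)
    part = SpatiotemporalPartition(
        labels=labels, Q=Q, gamma=g_mid, omega_scale=om_mid, seed=seed
    )
    return part, coclass


def fractional_membership(
    partition: SpatiotemporalPartition, pi: np.ndarray
) -> np.ndarray:
    """Stationary-weighted share of time each ROI spends in each community.

    F[i, c] = sum_s pi_s * 1[g_is = c]; every row sums to 1.
    """
    labels = partition.labels
    D, K = labels.shape
    pi = np.asarray(pi, dtype=float)
    if pi.size != K:
        raise ValueError("pi must have one entry per layer")
    comms = np.unique(labels)
    F = np.zeros((D, comms.size))
    for c_idx, c in enumerate(comms):
        F[:, c_idx] = ((labels == c) * pi[None, :]).sum(axis=1)
    return F / F.sum(axis=1, keepdims=True)


def _copair_vectors(label_matrix: np.ndarray) -> np.ndarray:
    """Boolean co-clustered-pair indicator per column of a label matrix."""
    n, m = label_matrix.shape
    iu = np.triu_indices(n, 1)
    out = np.empty((m, iu[0].size), dtype=bool)
    for j in range(m):
        lab = label_matrix[:, j]
        out[j] = lab[iu[0]] == lab[iu[1]]
    return out


def _jaccard_linkage(label_matrix: np.ndarray, n_clusters: int):
    vec = _copair_vectors(label_matrix)
    m = vec.shape[0]
    Dm = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            inter = np.sum(vec[a] & vec[b])
            union = np.sum(vec[a] | vec[b])
            jac = 1.0 if union == 0 else inter / union
            Dm[a, b] = Dm[b, a] = 1.0 - jac
    Z = linkage(squareform(Dm, checks=False), method="ward")
    flat = fcluster(Z, t=n_clusters, criterion="maxclust")
    return Z, flat, Dm


def cluster_layers(partition: SpatiotemporalPartition, n_clusters: int = 2):
    """Ward clustering of state layers by Jaccard similarity of co-clustered
    ROI pairs between the layers' induced partitions."""
    if partition.labels.shape[1] < 2:
        raise ValueError("need at least 2 layers")
    return _jaccard_linkage(partition.labels, n_clusters)


def cluster_regions(partition: SpatiotemporalPartition, n_clusters: int = 2):
    """Same construction transposed: ROIs clustered by the partitions they
    induce over state layers."""
    if partition.labels.shape[0] < 2:
        raise ValueError("need at least 2 regions")
    return _jaccard_linkage(partition.labels.T, n_clusters)
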