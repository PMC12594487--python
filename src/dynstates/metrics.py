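"""Per-state functional graph metrics and cross-state similarity.

Each hidden state induces a functional connectivity graph (absolute ROI-space
correlation) and a mean-activity map.  States are compared by (signed)
distance correlation of activity or connectivity; integration is measured by
global efficiency normalized against permuted-weight nulls, segregation by
single-layer consensus modularity, and per-region integration by a robust
weighted local efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import shortest_path
from scipy.stats import pearsonr

from .multilayer import HMGM, consensus_communities

__all__ = [
    "StateGraph",
    "state_graphs_from_model",
    "excitability",
    "distance_correlation",
    "signed_distance_correlation",
    "pairwise_state_similarity",
    "global_efficiency",
    "normalized_global_efficiency",
    "local_efficiency_robust",
    "single_layer_modularity_partition",
    "degree_centrality",
]


@dataclass
class StateGraph:
    """One state's functional graph: |corr| weights, signed corr, mean map."""

    index: int
    weights: np.ndarray              # (D, D), in [0, 1], symmetric, zero diag
    signed: np.ndarray | None = None  # (D, D) signed correlation, zero diag
    mean_activity: np.ndarray | None = None
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        W = self.weights
        if not np.allclose(W, W.T, atol=1e-10):
            raise ValueError("weights must be symmetric")
        if np.any(W < -1e-12) or np.any(W > 1 + 1e-12):
            raise ValueError("weights must lie in [0, 1]")
        if np.any(np.abs(np.diag(W)) > 1e-12):
            raise ValueError("weight diagonal must be zero")


def state_graphs_from_model(model) -> list[StateGraph]:
    """Build one StateGraph per fitted state from ROI-space parameters."""
    if model.roi_covariances is None:
        raise ValueError("model lacks ROI-space covariances; project first")
    graphs = []
    for s in range(model.K):
        C = model.roi_covariances[s]
        sd = np.sqrt(np.diag(C))
        R = np.clip(C / np.outer(sd, sd), -1.0, 1.0)
        np.fill_diagonal(R, 0.0)
        R = 0.5 * (R + R.T)
        graphs.append(
            StateGraph(
                index=s,
                weights=np.abs(R),
                signed=R,
                mean_activity=model.roi_means[s].copy(),
            )
        )
    return graphs


def excitability(mean_activity: np.ndarray) -> float:
    """Mean absolute activity of a state map (excitable high, quiescent low)."""
    return float(np.mean(np.abs(mean_activity)))


def _centered_distances(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    a = np.abs(x[:, None] - x[None, :])
    return a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()


def distance_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Szekely's sample distance correlation in [0, 1].

    Computed from doubly centered pairwise-distance matrices; detects
    nonlinear dependence that Pearson correlation misses.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 4:
        raise ValueError("inputs must have equal length >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("distance correlation undefined for constant input")
    A, B = _centered_distances(x), _centered_distances(y)
    n2 = x.size**2
    dcov2 = float((A * B).sum()) / n2
    dvarx = float((A * A).sum()) / n2
    dvary = float((B * B).sum()) / n2
    denom = np.sqrt(dvarx * dvary)
    if denom == 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / denom))


def signed_distance_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Distance correlation carrying the sign of the Pearson correlation."""
    r = pearsonr(np.ravel(x), np.ravel(y)).statistic
    return float(np.sign(r) if r != 0 else 1.0) * distance_correlation(x, y)


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], 1)
    return mat[iu]


def pairwise_state_similarity(
    states: list[StateGraph], mode: str = "connectivity", signed: bool = False
) -> np.ndarray:
    """K x K distance-correlation similarity between states.

    ``mode='activity'`` compares mean-activity maps; ``mode='connectivity'``
    compares vectorized upper triangles of the weight (or signed correlation)
    matrices.  Diagonal is 1 by convention.
    """
    if len(states) < 2:
        raise ValueError("need at least 2 states")
    if mode == "activity":
        vecs = [g.mean_activity for g in states]
    elif mode == "connectivity":
        vecs = [_upper(g.signed if signed else g.weights) for g in states]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    K = len(states)
    S = np.eye(K)
    fn = signed_distance_correlation if signed else distance_correlation
    for a in range(K):
        for b in range(a + 1, K):
            S[a, b] = S[b, a] = fn(vecs[a], vecs[b])
    return S


def global_efficiency(weights: np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered node pairs.

    Edge lengths are 1/w (absent edges unreachable); unreachable pairs
    contribute 0, so a fully disconnected graph has efficiency 0.
    """
    W = np.asarray(weights, dtype=float)
    n = W.shape[0]
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / W, np.inf)
    np.fill_diagonal(L, 0.0)
    D = shortest_path(L, method="D", directed=False)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / D, 0.0)
    return float(inv[off].mean())


def normalized_global_efficiency(
    weights: np.ndarray, n_permutations: int = 100, seed: int = 0
) -> float:
    """Global efficiency divided by its mean under random edge-weight
    permutation (upper-triangle shuffle, then symmetrized)."""
    W = np.asarray(weights, dtype=float)
    E = global_efficiency(W)
    n = W.shape[0]
    iu = np.triu_indices(n, 1)
    vals = W[iu]
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        Wp = np.zeros_like(W)
        Wp[iu] = rng.permutation(vals)
        Wp = Wp + Wp.T
        null[b] = global_efficiency(Wp)
    denom = null.mean()
    if denom == 0:
        raise ValueError("normalization undefined: permuted graphs are disconnected")
    return float(E / denom)


def local_efficiency_robust(weights: np.ndarray, node: int) -> float:
    """Robust weighted local efficiency of one node.

    Over the subgraph induced by the node's neighbors, with e_jh the inverse
    shortest-path length inside the neighborhood:

        E_loc(i) = sum_{j != h in N(i)} (w_ij w_ih e_jh)^(1/3) / (k_i (k_i-1))

    The cube root balances the two incident edge weights against the
    neighborhood path term; on 0/1 graphs this reduces to the classic binary
    local efficiency.  Nodes of degree < 2 score 0.
    """
    W = np.asarray(weights, dtype=float)
    nbrs = np.where(W[node] > 0)[0]
    k = nbrs.size
    if k < 2:
        return 0.0
    sub = W[np.ix_(nbrs, nbrs)]
    with np.errstate(divide="ignore"):
        L = np.where(sub > 0, 1.0 / sub, np.inf)
    np.fill_diagonal(L, 0.0)
    Dm = shortest_path(L, method="D", directed=False)
    with np.errstate(divide="ignore"):
        e = np.where(np.isfinite(Dm) & (Dm > 0), 1.0 / Dm, 0.0)
    w_i = W[node, nbrs]
    terms = np.cbrt(np.outer(w_i, w_i) * e)
    np.fill_diagonal(terms, 0.0)
    return float(terms.sum() / (k * (k - 1)))


def local_efficiency_all(weights: np.ndarray) -> np.ndarray:
    return np.array(
        [local_efficiency_robust(weights, i) for i in range(weights.shape[0])]
    )


def single_layer_modularity_partition(
    weights: np.ndarray,
    resolution_grid: list[float] | None = None,
    n_runs: int = 20,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Consensus Newman-Girvan communities of a single weighted graph.

    Delegates to the multilayer consensus machinery on a one-layer HMGM with
    zero coupling; returns flat labels and the consensus Q at gamma = median
    of the grid.
    """
    W = np.asarray(weights, dtype=float)
    mx = W.max()
    scaled = W / mx if mx > 1 else W
    hm = HMGM(
        layers=scaled[None, :, :],
        coupling=np.zeros((1, 1)),
        pi=np.ones(1),
    )
    part, _ = consensus_communities(
        hm,
        resolution_grid=resolution_grid or [0.8, 0.9, 1.0, 1.1, 1.2],
        coupling_grid=[1.0],
        n_runs=n_runs,
        seed=seed,
    )
    return part.labels[:, 0], part.Q


def degree_centrality(weights: np.ndarray) -> np.ndarray:
    """Node strengths (row sums) of a symmetric weight matrix."""
    W = np.asarray(weights, dtype=float)
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("weights must be symmetric")
    return W.sum(axis=1)
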