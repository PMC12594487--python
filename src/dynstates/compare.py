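"""Structure-function comparison and group statistics.

Dynamic state graphs are compared with a structural connectome through
distance correlation of edge weights, local efficiency and degree
centrality, and through AMI/ARI of consensus partitions.  Condition
contrasts use two-sided rank tests and add-one permutation tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import adjusted_mutual_info_score, adjusted_rand_score

from .metrics import (
    StateGraph,
    degree_centrality,
    distance_correlation,
    local_efficiency_all,
    single_layer_modularity_partition,
)

__all__ = [
    "ami",
    "ari",
    "compare_state_to_structure",
    "permutation_test",
    "rank_tests",
    "ComparisonReport",
]


def ami(partition_a: np.ndarray, partition_b: np.ndarray) -> float:
    """Adjusted mutual information with max normalization."""
    a, b = np.asarray(partition_a), np.asarray(partition_b)
    if a.shape != b.shape:
        raise ValueError("partitions must cover the same node set")
    return float(adjusted_mutual_info_score(a, b, average_method="max"))


def ari(partition_a: np.ndarray, partition_b: np.ndarray) -> float:
    a, b = np.asarray(partition_a), np.asarray(partition_b)
    if a.shape != b.shape:
        raise ValueError("partitions must cover the same node set")
    return float(adjusted_rand_score(a, b))


@dataclass
class ComparisonReport:
    """Per-state structure-function similarity rows for one condition."""

    state_index: list[int]
    edge_dcor: list[float]
    ami_vs_structure: list[float]
    ari_vs_structure: list[float]
    local_efficiency_dcor: list[float]
    degree_dcor: list[float]

    def to_dict(self) -> dict:
        return {
            "state_index": self.state_index,
            "edge_dcor": self.edge_dcor,
            "ami_vs_structure": self.ami_vs_structure,
            "ari_vs_structure": self.ari_vs_structure,
            "local_efficiency_dcor": self.local_efficiency_dcor,
            "degree_dcor": self.degree_dcor,
        }


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], 1)
    return mat[iu]


def compare_state_to_structure(
    state: StateGraph,
    structure_weights: np.ndarray,
    structure_partition: np.ndarray,
    state_partition: np.ndarray | None = None,
    resolution_grid: list[float] | None = None,
    n_runs: int = 20,
    seed: int = 0,
) -> dict:
    """Similarity row between one state graph and the structural connectome.

    Reports distance correlation of vectorized edge weights, AMI/ARI of the
    state's consensus partition against the structural partition, and
    distance correlations of robust local efficiency and degree centrality
    profiles.  The state partition is computed with the same single-layer
    consensus machinery when not supplied.
    """
    W = state.weights
    S = np.asarray(structure_weights, dtype=float)
    if W.shape != S.shape:
        raise ValueError("state and structure dimensions differ")
    if state_partition is None:
        state_partition, _ = single_layer_modularity_partition(
            W, resolution_grid=resolution_grid, n_runs=n_runs, seed=seed
        )
    return {
        "state_index": state.index,
        "edge_dcor": distance_correlation(_upper(W), _upper(S)),
        "ami_vs_structure": ami(state_partition, structure_partition),
        "ari_vs_structure": ari(state_partition, structure_partition),
        "local_efficiency_dcor": distance_correlation(
            local_efficiency_all(W), local_efficiency_all(S)
        ),
        "degree_dcor": distance_correlation(
            degree_centrality(W), degree_centrality(S)
        ),
    }


def permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    statistic: str = "pearson",
    n_perm: int = 999,
    seed: int = 0,
    sidedness: str = "two-sided",
) -> tuple[float, float]:
    """Add-one permutation p-value for an association statistic.

    ``p = (1 + #{permuted stat at least as extreme}) / (1 + n_perm)``; the
    add-one form never reports an exact zero.  ``statistic`` is "pearson"
    (two-sided on |r| by default) or "ami" (naturally one-sided "greater").
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if statistic == "pearson":
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError("Pearson statistic undefined for constant input")
        stat = lambda a, b: stats.pearsonr(a, b).statistic  # noqa: E731
    elif statistic == "ami":
        stat = ami
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    obs = stat(x, y)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = stat(x, rng.permutation(y))
        if sidedness == "two-sided":
            extreme = abs(perm) >= abs(obs) - 1e-12
        elif sidedness == "greater":
            extreme = perm >= obs - 1e-12
        elif sidedness == "less":
            extreme = perm <= obs + 1e-12
        else:
            raise ValueError(f"unknown sidedness {sidedness!r}")
        count += int(extreme)
    return float(obs), float((1 + count) / (1 + n_perm))


def rank_tests(
    group_a: np.ndarray, group_b: np.ndarray, paired: bool = False
) -> dict:
    """Two-sided Mann-Whitney U (unpaired) or Wilcoxon signed-rank (paired).

    Exact null distributions are used for small samples without ties; the
    normal approximation with tie correction otherwise (scipy's "auto").
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal lengths")
        if np.all(a - b == 0):
            raise ValueError("all paired differences are zero")
        res = stats.wilcoxon(a, b, alternative="two-sided", method="auto")
        name = "wilcoxon-signed-rank"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        name = "mann-whitney-u"
    return {
        "test": name,
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "sidedness": "two-sided",
    }
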