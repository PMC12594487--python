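"""Markov-chain and occupancy analytics for fitted state models.

Sink centrality is the stationary probability of a state; "strong" sinks
carry at least 5% of the stationary mass.  Temporal complexity is measured by
the switching rate of the best-fit state path and the entropy (information)
rate of the transition matrix; subject-level state diversity by the
normalized entropy of the fractional occupancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "stationary_distribution",
    "classify_strong_sinks",
    "switching_rate",
    "entropy_rate",
    "occupancy_entropy",
    "cluster_subjects_by_fo",
    "DynamicsSummary",
]


def stationary_distribution(P: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Stationary (Cesaro-limit) occupancy vector of a row-stochastic matrix.

    Computed as the limit from the uniform start of the lazy chain
    (P + I)/2, obtained by repeated squaring.  Laziness removes periodicity
    and the uniform start gives a well-defined occupancy vector even for
    reducible chains (as pruning can produce), while leaving the stationary
    distribution of every recurrent class unchanged.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be square")
    if np.any(P < -atol) or not np.allclose(P.sum(axis=1), 1.0, atol=atol):
        raise ValueError("P rows must be nonnegative and sum to 1")
    K = P.shape[0]
    M = 0.5 * (P + np.eye(K))
    for _ in range(80):
        M2 = M @ M
        M2 /= M2.sum(axis=1, keepdims=True)  # counter drift
        if np.max(np.abs(M2 - M)) < 1e-15:
            M = M2
            break
        M = M2
    pi = M.mean(axis=0)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def classify_strong_sinks(pi: np.ndarray, threshold: float = 0.05) -> list[int]:
    """Indices whose stationary probability is at least the threshold (inclusive)."""
    pi = np.asarray(pi, dtype=float)
    if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("pi must be a probability vector")
    return [int(i) for i in np.where(pi >= threshold)[0]]


def switching_rate(viterbi_path: np.ndarray, tr_seconds: float) -> float:
    """State changes per second along a best-fit path.

    The denominator is the number of transitions times TR, so a fully
    alternating path attains (but never exceeds) 1/TR Hz.
    """
    path = np.asarray(viterbi_path)
    if path.size < 2:
        raise ValueError("path must have length >= 2")
    switches = int(np.sum(path[1:] != path[:-1]))
    return switches / ((path.size - 1) * tr_seconds)


def entropy_rate(P: np.ndarray, log_base: float = 2.0) -> float:
    """Stationary-weighted expected per-step transition entropy of the chain.

    H = -sum_k pi_k sum_j P_kj log(P_kj), with 0 log 0 = 0.  Bits by default.
    """
    P = np.asarray(P, dtype=float)
    pi = stationary_distribution(P)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(P), 0.0)
    return float(-(pi @ plogp.sum(axis=1)) / math.log(log_base))


def occupancy_entropy(fo: np.ndarray, K: int | None = None) -> float:
    """Shannon entropy of a fractional-occupancy vector, normalized by log K."""
    fo = np.asarray(fo, dtype=float)
    if K is None:
        K = fo.size
    if np.any(fo < -1e-12) or abs(fo.sum() - 1.0) > 1e-8:
        raise ValueError("FO must be a probability vector")
    if K <= 1:
        return 0.0
    nz = fo[fo > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(K))


def cluster_subjects_by_fo(
    fo_matrix: np.ndarray,
    n_clusters: int = 2,
    subjects: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Ward-linkage clustering of subjects by Pearson correlation of their FO.

    Distance between two subjects is 1 - corr(FO_a, FO_b).  Returns the
    scipy linkage matrix and the flat labels at an ``n_clusters`` cut.
    """
    FO = np.asarray(fo_matrix, dtype=float)
    if FO.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    sd = FO.std(axis=1)
    flat = np.where(sd == 0)[0]
    if flat.size:
        names = [subjects[i] if subjects else f"subject {i}" for i in flat]
        raise ValueError(f"constant FO vector (correlation undefined) for: {names}")
    C = np.corrcoef(FO)
    Dm = np.clip(1.0 - C, 0.0, None)
    np.fill_diagonal(Dm, 0.0)
    Z = linkage(squareform(Dm, checks=False), method="ward")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return Z, labels


@dataclass
class DynamicsSummary:
    """All chain/occupancy metrics for one condition's fitted model."""

    stationary: np.ndarray
    strong_sinks: list[int]
    switching_rates: np.ndarray     # per subject, Hz
    entropy_rate: float
    occupancy_entropies: np.ndarray  # per subject, normalized to [0, 1]

    def to_dict(self) -> dict:
        return {
            "stationary_distribution": self.stationary.tolist(),
            "strong_sinks": self.strong_sinks,
            "switching_rates_hz": self.switching_rates.tolist(),
            "entropy_rate": self.entropy_rate,
            "occupancy_entropies": self.occupancy_entropies.tolist(),
        }


def summarize_dynamics(
    transition_matrix: np.ndarray,
    viterbi_paths: list[np.ndarray],
    fo_matrix: np.ndarray,
    tr_seconds: float,
    strong_sink_threshold: float = 0.05,
    log_base: float = 2.0,
) -> DynamicsSummary:
    pi = stationary_distribution(transition_matrix)
    K = transition_matrix.shape[0]
    return DynamicsSummary(
        stationary=pi,
        strong_sinks=classify_strong_sinks(pi, strong_sink_threshold),
        switching_rates=np.array(
            [switching_rate(p, tr_seconds) for p in viterbi_paths]
        ),
        entropy_rate=entropy_rate(transition_matrix, log_base),
        occupancy_entropies=np.array(
            [occupancy_entropy(fo, K) for fo in fo_matrix]
        ),
    )
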