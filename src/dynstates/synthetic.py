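"""Synthetic multi-subject BOLD cohorts with known hidden-state structure.

The generator plants everything the downstream analysis estimates: a Gaussian
hidden Markov model with block-structured state covariances (the planted
spatiotemporal communities), optionally a dominant "sink" state whose
stationary mass is set exactly by construction (the anesthesia-like
condition), and a weighted stochastic-block structural connectome that either
matches or scrambles the functional blocks.

Default scale follows the study design this emulates: N = 13 subjects,
D = 63 regions, T = 200 volumes at TR = 3 s per condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import RoiCohort

__all__ = [
    "GroundTruthModel",
    "SyntheticCohort",
    "make_ground_truth",
    "simulate_cohort",
    "make_structural_connectome",
]


@dataclass
class GroundTruthModel:
    """A fully specified Gaussian HMM in ROI space with planted communities.

    ``planted_labels[i, s]`` is the community of ROI ``i`` within state
    (layer) ``s``; ``base_labels`` is the block assignment shared by the
    structural connectome when it is generated aligned with this model.
    """

    means: np.ndarray            # (K, D)
    covariances: np.ndarray      # (K, D, D)
    transition_matrix: np.ndarray  # (K, K) row-stochastic
    initial_distribution: np.ndarray  # (K,)
    planted_labels: np.ndarray   # (D, K) int
    base_labels: np.ndarray      # (D,) int
    block_sizes: list[int]
    sink_index: int | None = None
    sink_mass: float | None = None

    @property
    def n_states(self) -> int:
        return self.means.shape[0]

    @property
    def n_rois(self) -> int:
        return self.means.shape[1]


@dataclass
class SyntheticCohort:
    """A RoiCohort plus the hidden state sequence that generated each subject."""

    cohort: RoiCohort
    state_sequences: list[np.ndarray]

    def __post_init__(self) -> None:
        for mat, seq in zip(self.cohort.series, self.state_sequences):
            if mat.shape[1] != len(seq):
                raise ValueError("state sequence length must equal series length")


def _stationary(P: np.ndarray) -> np.ndarray:
    """Stationary distribution by eigen-solution (verification helper)."""
    vals, vecs = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()

def _block_correlation(
    sizes: list[int], within: float, between: float, perm: np.ndarray
) -> np.ndarray:
    """Equicorrelation-block correlation matrix under a ROI permutation."""
    D = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)[perm]
    same = labels[:, None] == labels[None, :]
    C = np.where(same, within, between)
    np.fill_diagonal(C, 1.0)
    # guarantee strict positive definiteness after assembly
    w = np.linalg.eigvalsh(C)
    if w.min() < 1e-10:
        C = C + (1e-8 - w.min()) * np.eye(D)
    return C


def make_ground_truth(
    K_true: int,
    D: int,
    sink_mass: float | None = None,
    block_sizes: list[int] | None = None,
    separation: float = 6.0,
    seed: int = 0,
    shuffle_blocks_per_state: bool = False,
    within_corr: float = 0.6,
    between_corr: float = 0.1,
    sink_self: float = 0.9,
    stickiness: float = 0.3,
) -> GroundTruthModel:
    """Construct a planted Gaussian HMM.

    State means are drawn isotropically and rescaled so the minimum pairwise
    Euclidean distance equals ``separation`` in raw ROI units.  Because the
    analysis z-scores the concatenation (whose variance includes the
    between-state spread) before fitting, raw separation 6 corresponds to
    roughly 3-sigma separated states in the reduced fitting space.  Covariances are
    equicorrelation block matrices — within-block correlation ``within_corr``
    is well above 3x the between-block ``between_corr`` by default.

    Transitions: without a sink, ``stickiness*I + (1-stickiness)*J/K`` — a
    doubly stochastic matrix whose stationary distribution is exactly uniform.
    With ``sink_mass`` m, the sink row keeps ``sink_self`` on itself and every
    other row sends q = (1-sink_self)*m/(1-m) into the sink, which places
    stationary mass exactly m on the sink (verified by eigen-solution).
    """
    if K_true < 2:
        raise ValueError("K_true must be >= 2")
    if block_sizes is None:
        base = D // 3
        block_sizes = [base, base, D - 2 * base]
    if sum(block_sizes) != D:
        raise ValueError("block_sizes must sum to D")
    if within_corr < 3 * between_corr:
        raise ValueError("within-block correlation must be >= 3x between-block")
    rng = np.random.default_rng(seed)

    means = rng.normal(size=(K_true, D))
    dmin = min(
        float(np.linalg.norm(means[a] - means[b]))
        for a in range(K_true)
        for b in range(a + 1, K_true)
    )
    means *= separation / dmin

    base_labels = np.repeat(np.arange(len(block_sizes)), block_sizes)
    perms, labels = [], np.empty((D, K_true), dtype=int)
    for s in range(K_true):
        perm = rng.permutation(D) if shuffle_blocks_per_state else np.arange(D)
        perms.append(perm)
        labels[:, s] = base_labels[perm]
    covariances = np.stack(
        [_block_correlation(block_sizes, within_corr, between_corr, p) for p in perms]
    )

    sink_index = None
    if sink_mass is None:
        P = stickiness * np.eye(K_true) + (1.0 - stickiness) / K_true
    else:
        if not (0.0 < sink_mass < 1.0):
            raise ValueError("sink_mass must lie in (0, 1)")
        q = (1.0 - sink_self) * sink_mass / (1.0 - sink_mass)
        if q >= 1.0:
            raise ValueError(
                f"sink_mass={sink_mass} infeasible for sink self-transition {sink_self}"
            )
        sink_index = 0
        P = np.empty((K_true, K_true))
        P[0] = (1.0 - sink_self) / (K_true - 1)
        P[0, 0] = sink_self
        P[1:, :] = (1.0 - q) / (K_true - 1)
        P[1:, 0] = q
        pi_check = _stationary(P)
        if abs(pi_check[0] - sink_mass) > 0.02:
            raise AssertionError("sink construction failed stationary verification")
    assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)

    return GroundTruthModel(
        means=means,
        covariances=covariances,
        transition_matrix=P,
        initial_distribution=_stationary(P),
        planted_labels=labels,
        base_labels=base_labels,
        block_sizes=list(block_sizes),
        sink_index=sink_index,
        sink_mass=sink_mass,
    )


def simulate_cohort(
    model: GroundTruthModel,
    N: int = 13,
    T: int = 200,
    tr: float = 3.0,
    obs_noise: float = 0.2,
    seed: int = 0,
    condition: str = "",
    transition_jitter: float = 0.0,
) -> SyntheticCohort:
    """Sample N subjects of T volumes each from the planted HMM.

    Each subject runs its own hidden chain from the model's initial
    distribution; emissions are the state Gaussian plus isotropic noise of
    scale ``obs_noise``.  ``transition_jitter`` > 0 draws each subject's
    transition rows from a Dirichlet centred on the shared matrix
    (concentration 1/jitter); the default is a shared model.
    """
    if N < 1 or T < 1:
        raise ValueError("N and T must be >= 1")
    rng = np.random.default_rng(seed)
    K, D = model.n_states, model.n_rois
    # an exactly zero covariance means a deterministic (noise-free) state
    chols = [
        np.zeros((D, D)) if not model.covariances[k].any()
        else np.linalg.cholesky(model.covariances[k])
        for k in range(K)
    ]
    series, seqs = [], []
    for _ in range(N):
        P = model.transition_matrix
        if transition_jitter > 0:
            conc = P / transition_jitter + 1e-6
            P = np.vstack([rng.dirichlet(conc[k]) for k in range(K)])
        states = np.empty(T, dtype=int)
        states[0] = rng.choice(K, p=model.initial_distribution)
        for t in range(1, T):
            states[t] = rng.choice(K, p=P[states[t - 1]])
        X = np.empty((D, T))
        for t in range(T):
            k = states[t]
            X[:, t] = model.means[k] + chols[k] @ rng.normal(size=D)
        if obs_noise > 0:
            X += obs_noise * rng.normal(size=(D, T))
        series.append(X)
        seqs.append(states)
    labels = [f"ROI_{i:03d}" for i in range(D)]
    subjects = [f"sub-{i:02d}" for i in range(N)]
    cohort = RoiCohort(subjects, series, labels, tr, condition)
    return SyntheticCohort(cohort, seqs)


def make_structural_connectome(
    block_sizes: list[int],
    align_with: GroundTruthModel | None = None,
    noise: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted stochastic-block connectome plus its planted partition.

    Within-block weights are U(0.5, 1); between-block weights are
    U(0, 1)*noise, so ``noise=0`` gives perfectly separated blocks.  When
    ``align_with`` is given the blocks coincide with the model's base
    (covariance) blocks.
    """
    D = sum(block_sizes)
    if align_with is not None:
        if align_with.n_rois != D:
            raise ValueError("block_sizes inconsistent with aligned model")
        labels = align_with.base_labels.copy()
    else:
        labels = np.repeat(np.arange(len(block_sizes)), block_sizes)
    rng = np.random.default_rng(seed)
    same = labels[:, None] == labels[None, :]
    U = rng.uniform(size=(D, D))
    W = np.where(same, 0.5 + 0.5 * U, noise * U)
    W = np.triu(W, 1)
    W = W + W.T
    return W, labels
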