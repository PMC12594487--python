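"""Standardization, Horn parallel analysis and PCA projection.

The HMM is fit in a reduced principal-component space: ROI channels are
z-scored over the concatenation of all subjects, the retained dimension is
chosen by parallel analysis against column-permuted null data, and fitted
state parameters are mapped back to ROI space through the loadings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import RoiCohort

__all__ = [
    "ReductionMap",
    "standardize_concatenate",
    "horn_parallel_analysis",
    "pca_reduce",
    "project_state_to_roi",
]


@dataclass
class ReductionMap:
    """Linear map between ROI space and the reduced PC space.

    ``loadings`` (D x d) has orthonormal columns; ``center``/``scale`` are the
    per-ROI standardization applied before PCA; ``col_mean`` is the column
    mean removed by PCA (numerically ~0 after standardization but kept so the
    inverse map is exact).
    """

    loadings: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    col_mean: np.ndarray
    explained_variance: np.ndarray

    def __post_init__(self) -> None:
        G = self.loadings.T @ self.loadings
        if not np.allclose(G, np.eye(self.d), atol=1e-8):
            raise ValueError("loadings columns must be orthonormal")

    @property
    def d(self) -> int:
        return self.loadings.shape[1]

    @property
    def n_rois(self) -> int:
        return self.loadings.shape[0]


def standardize_concatenate(
    cohort: RoiCohort,
) -> tuple[np.ndarray, list[int], np.ndarray, np.ndarray]:
    """Concatenate subjects along time and z-score each ROI channel.

    Returns ``(X, lengths, center, scale)`` where ``X`` is time x ROI over the
    concatenation, ``lengths`` the per-subject segment lengths (so the
    concatenation can be cut back into subjects), and center/scale the per-ROI
    mean and standard deviation that were removed.
    """
    X = np.concatenate([s.T for s in cohort.series], axis=0)  # time x ROI
    lengths = [s.shape[1] for s in cohort.series]
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    zero = np.where(scale == 0)[0]
    if zero.size:
        raise ValueError(
            f"zero-variance ROI(s): {[cohort.roi_labels[i] for i in zero]}"
        )
    return (X - center) / scale, lengths, center, scale


def split_by_subject(X: np.ndarray, lengths: list[int]) -> list[np.ndarray]:
    """Cut a concatenated time x feature matrix back into subject segments."""
    if sum(lengths) != X.shape[0]:
        raise ValueError("lengths do not cover the concatenation")
    return list(np.split(X, np.cumsum(lengths)[:-1], axis=0))


def horn_parallel_analysis(
    X: np.ndarray,
    n_null: int = 100,
    percentile: float = 95.0,
    seed: int = 0,
) -> int:
    """Retained dimension by Horn's parallel analysis.

    Sample covariance eigenvalues are compared rank-by-rank with the given
    percentile of eigenvalues from null data in which every column is
    independently permuted (preserving marginals, destroying cross-channel
    structure).  ``d`` is the number of leading eigenvalues above the null
    before the first failure; at least 1 is always retained.
    """
    if n_null < 10:
        raise ValueError("n_null must be >= 10")
    rng = np.random.default_rng(seed)
    T, D = X.shape
    Xc = X - X.mean(axis=0)
    eig = np.sort(np.linalg.eigvalsh(Xc.T @ Xc / (T - 1)))[::-1]
    null = np.empty((n_null, D))
    for b in range(n_null):
        Z = np.empty_like(Xc)
        for j in range(D):
            Z[:, j] = Xc[rng.permutation(T), j]
        null[b] = np.sort(np.linalg.eigvalsh(Z.T @ Z / (T - 1)))[::-1]
    cut = np.percentile(null, percentile, axis=0)
    above = eig > cut
    d = int(np.argmin(above)) if not above.all() else D
    return max(d, 1)


def pca_reduce(
    X: np.ndarray,
    d: int,
    center: np.ndarray | None = None,
    scale: np.ndarray | None = None,
) -> tuple[np.ndarray, ReductionMap]:
    """Project time x ROI data onto its leading ``d`` principal components.

    ``center``/``scale`` are the standardization recorded by
    :func:`standardize_concatenate` (identity maps if omitted).  Component
    signs are fixed so each loading's largest-magnitude entry is positive.
    """
    T, D = X.shape
    col_mean = X.mean(axis=0)
    Xc = X - col_mean
    rank = np.linalg.matrix_rank(Xc)
    if not (1 <= d <= rank):
        raise ValueError(f"d={d} exceeds data rank {rank}")
    _, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    load = Vt[:d].T
    flip = np.sign(load[np.argmax(np.abs(load), axis=0), np.arange(d)])
    load = load * flip
    ev = (S[:d] ** 2) / (T - 1)
    rmap = ReductionMap(
        loadings=load,
        center=center if center is not None else np.zeros(D),
        scale=scale if scale is not None else np.ones(D),
        col_mean=col_mean,
        explained_variance=ev,
    )
    return Xc @ load, rmap


def project_state_to_roi(
    mean_d: np.ndarray, cov_d: np.ndarray, rmap: ReductionMap
) -> tuple[np.ndarray, np.ndarray]:
    """Map a reduced-space state (mean, covariance) back to ROI units."""
    mean_d = np.asarray(mean_d, dtype=float)
    cov_d = np.asarray(cov_d, dtype=float)
    if mean_d.shape != (rmap.d,) or cov_d.shape != (rmap.d, rmap.d):
        raise ValueError("state parameters do not match the reduction map")
    if not np.allclose(cov_d, cov_d.T, atol=1e-8):
        raise ValueError("cov_d must be symmetric")
    L = rmap.loadings
    mean_std = L @ mean_d + rmap.col_mean
    mean_roi = rmap.center + rmap.scale * mean_std
    cov_std = L @ cov_d @ L.T
    cov_roi = rmap.scale[:, None] * cov_std * rmap.scale[None, :]
    cov_roi = 0.5 * (cov_roi + cov_roi.T)
    return mean_roi, cov_roi
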