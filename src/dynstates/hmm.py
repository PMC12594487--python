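"""Gaussian HMM fitting, decoding, model-size selection and state pruning.

Fitting is maximum-likelihood Baum-Welch (best of ``n_restarts`` seeded EM
runs) on the PCA-reduced concatenation, with subject boundaries respected so
no transition is learned across recordings.  The model size is chosen to
maximize the entropy of the group-mean fractional occupancy, and states
visited by too few subjects are pruned with transition rows restandardized.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from hmmlearn.base import ConvergenceMonitor
from hmmlearn.hmm import GaussianHMM
from sklearn.cluster import KMeans

from .dynamics import stationary_distribution
from .reduction import ReductionMap, project_state_to_roi, split_by_subject

__all__ = ["FittedStateModel", "DecodeResult", "fit_hmm", "decode_subjects",
           "select_model_size", "prune_states"]

log = logging.getLogger(__name__)

_RIDGE = 1e-6  # diagonal regularization keeping covariances PSD at small T


class _TraceMonitor(ConvergenceMonitor):
    """Convergence monitor that records the full log-likelihood trace."""

    def __init__(self, tol, n_iter, verbose=False):
        super().__init__(tol, n_iter, verbose)
        self.trace: list[float] = []

    def report(self, log_prob):
        self.trace.append(float(log_prob))
        super().report(log_prob)


@dataclass
class FittedStateModel:
    """Gaussian HMM parameters in reduced space plus the ROI-space projection."""

    means: np.ndarray               # (K, d)
    covariances: np.ndarray         # (K, d, d)
    transition_matrix: np.ndarray   # (K, K)
    initial_distribution: np.ndarray
    log_likelihood: list[float] = field(default_factory=list)
    reduction: ReductionMap | None = None
    roi_means: np.ndarray | None = None
    roi_covariances: np.ndarray | None = None

    def __post_init__(self) -> None:
        P = self.transition_matrix
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition rows must sum to 1")

    @property
    def K(self) -> int:
        return self.means.shape[0]

    @property
    def d(self) -> int:
        return self.means.shape[1]

    def project_to_roi(self) -> None:
        """Fill roi_means / roi_covariances through the reduction map."""
        if self.reduction is None:
            raise ValueError("model has no reduction map")
        outs = [
            project_state_to_roi(self.means[k], self.covariances[k], self.reduction)
            for k in range(self.K)
        ]
        self.roi_means = np.stack([m for m, _ in outs])
        self.roi_covariances = np.stack([c for _, c in outs])

    def to_hmmlearn(self) -> GaussianHMM:
        hm = GaussianHMM(n_components=self.K, covariance_type="full", init_params="")
        hm.startprob_ = self.initial_distribution.copy()
        hm.transmat_ = self.transition_matrix.copy()
        hm.means_ = self.means.copy()
        hm.covars_ = self.covariances.copy()
        hm.n_features = self.d
        return hm

    # -- JSON serialization ------------------------------------------------
    def to_dict(self) -> dict:
        out = {
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "transition_matrix": self.transition_matrix.tolist(),
            "initial_distribution": self.initial_distribution.tolist(),
            "log_likelihood": list(self.log_likelihood),
        }
        if self.reduction is not None:
            r = self.reduction
            out["reduction"] = {
                "loadings": r.loadings.tolist(),
                "center": r.center.tolist(),
                "scale": r.scale.tolist(),
                "col_mean": r.col_mean.tolist(),
                "explained_variance": r.explained_variance.tolist(),
            }
        if self.roi_means is not None:
            out["roi_means"] = self.roi_means.tolist()
            out["roi_covariances"] = self.roi_covariances.tolist()
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "FittedStateModel":
        red = None
        if "reduction" in d:
            r = d["reduction"]
            red = ReductionMap(
                loadings=np.array(r["loadings"]),
                center=np.array(r["center"]),
                scale=np.array(r["scale"]),
                col_mean=np.array(r["col_mean"]),
                explained_variance=np.array(r["explained_variance"]),
            )
        return cls(
            means=np.array(d["means"]),
            covariances=np.array(d["covariances"]),
            transition_matrix=np.array(d["transition_matrix"]),
            initial_distribution=np.array(d["initial_distribution"]),
            log_likelihood=list(d.get("log_likelihood", [])),
            reduction=red,
            roi_means=np.array(d["roi_means"]) if "roi_means" in d else None,
            roi_covariances=(
                np.array(d["roi_covariances"]) if "roi_covariances" in d else None
            ),
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "FittedStateModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class DecodeResult:
    """Per-subject posteriors, Viterbi paths and fractional occupancy."""

    posteriors: list[np.ndarray]     # each T_n x K
    viterbi_paths: list[np.ndarray]  # each length T_n
    fractional_occupancy: np.ndarray  # N x K

    def __post_init__(self) -> None:
        for g in self.posteriors:
            if not np.allclose(g.sum(axis=1), 1.0, atol=1e-10):
                raise ValueError("posterior rows must sum to 1")
        fo = self.fractional_occupancy
        if np.any(fo < -1e-12) or not np.allclose(fo.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("fractional occupancy must be a probability vector")

    @property
    def group_mean_fo(self) -> np.ndarray:
        return self.fractional_occupancy.mean(axis=0)


def _regularize(cov: np.ndarray) -> np.ndarray:
    cov = 0.5 * (cov + np.swapaxes(cov, -1, -2))
    d = cov.shape[-1]
    return cov + _RIDGE * np.eye(d)


def fit_hmm(
    X: np.ndarray,
    lengths: list[int],
    K: int,
    n_restarts: int = 5,
    tol: float = 1e-4,
    max_iter: int = 200,
    seed: int = 0,
    reduction: ReductionMap | None = None,
) -> FittedStateModel:
    """Best-of-restarts ML Gaussian HMM on a boundary-aware concatenation.

    Each restart runs EM from a different seeded initialization; the restart
    with the highest training log-likelihood wins.  The stored initial
    distribution is the stationary distribution of the fitted transition
    matrix (resting-state stationarity assumption).
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if X.shape[0] < 10 * K:
        raise ValueError("need at least 10*K total samples")
    ss = np.random.SeedSequence(seed)
    restart_seeds = [int(s.generate_state(1, dtype=np.uint32)[0] % (2**31))
                     for s in ss.spawn(n_restarts)]
    best, best_score, best_trace = None, -np.inf, None
    for rs in restart_seeds:
        hm = GaussianHMM(
            n_components=K,
            covariance_type="full",
            n_iter=max_iter,
            tol=tol,
            min_covar=_RIDGE,
            random_state=rs,
            init_params="st",
        )
        hm.monitor_ = _TraceMonitor(hm.tol, hm.n_iter, hm.verbose)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                # Multi-start k-means initialization of means AND per-cluster
                # covariances.  A single k-means run routinely merges states
                # at larger K, and seeding every state with the global data
                # covariance (dominated by between-state spread) makes the
                # first E-step smear even a perfect mean assignment.
                km = KMeans(n_clusters=K, n_init=10, random_state=rs).fit(X)
                hm.means_ = km.cluster_centers_
                dim = X.shape[1]
                covs = np.empty((K, dim, dim))
                global_cov = np.cov(X.T) + _RIDGE * np.eye(dim)
                for k in range(K):
                    pts = X[km.labels_ == k]
                    if pts.shape[0] > dim + 1:
                        covs[k] = np.cov(pts.T) + _RIDGE * np.eye(dim)
                    else:
                        covs[k] = global_cov
                hm.covars_ = covs
                hm.fit(X, lengths)
            score = float(hm.score(X, lengths))
        except (ValueError, np.linalg.LinAlgError) as exc:
            # degenerate restart (e.g. a state starved of responsibility mass)
            log.warning("restart with seed %d failed: %s", rs, exc)
            continue
        if not np.isfinite(score):
            continue
        if score > best_score:
            best, best_score, best_trace = hm, score, list(hm.monitor_.trace)
    if best is None:
        raise RuntimeError("all EM restarts failed")
    P = np.asarray(best.transmat_)
    P = P / P.sum(axis=1, keepdims=True)
    model = FittedStateModel(
        means=np.asarray(best.means_),
        covariances=_regularize(np.asarray(best.covars_)),
        transition_matrix=P,
        initial_distribution=stationary_distribution(P),
        log_likelihood=best_trace,
        reduction=reduction,
    )
    if reduction is not None:
        model.project_to_roi()
    return model


def decode_subjects(
    model: FittedStateModel, X: np.ndarray, lengths: list[int]
) -> DecodeResult:
    """Forward-backward posteriors, Viterbi path and FO for every subject."""
    if X.shape[1] != model.d:
        raise ValueError("data dimension does not match the model")
    hm = model.to_hmmlearn()
    posteriors, paths, fo = [], [], []
    for Xs in split_by_subject(X, lengths):
        gamma = hm.predict_proba(Xs)
        path = hm.predict(Xs)
        gamma = gamma / gamma.sum(axis=1, keepdims=True)
        posteriors.append(gamma)
        paths.append(path.astype(int))
        fo.append(gamma.mean(axis=0))
    return DecodeResult(posteriors, paths, np.vstack(fo))


def _entropy(p: np.ndarray, base: float = 2.0) -> float:
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(base))


def select_model_size(
    X: np.ndarray,
    lengths: list[int],
    candidate_K_range: tuple[int, int],
    n_restarts: int = 5,
    tol: float = 1e-4,
    max_iter: int = 200,
    seed: int = 0,
    reduction: ReductionMap | None = None,
    log_base: float = 2.0,
) -> tuple[int, dict[int, float], dict[int, FittedStateModel]]:
    """Pick K maximizing the entropy of the group-mean fractional occupancy.

    Every candidate K in the inclusive range is fitted and decoded; ties are
    broken toward the smaller model.  Returns the chosen K, the per-K entropy
    diagnostics and the fitted models (so the winner need not be refit).
    """
    lo, hi = candidate_K_range
    if hi < lo:
        raise ValueError("empty candidate range")
    diagnostics: dict[int, float] = {}
    models: dict[int, FittedStateModel] = {}
    ss = np.random.SeedSequence(seed)
    for K, child in zip(range(lo, hi + 1), ss.spawn(hi - lo + 1)):
        kseed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        model = fit_hmm(X, lengths, K, n_restarts, tol, max_iter, kseed, reduction)
        dec = decode_subjects(model, X, lengths)
        diagnostics[K] = _entropy(dec.group_mean_fo, log_base)
        models[K] = model
    best_K = min(diagnostics)
    for K in sorted(diagnostics):
        if diagnostics[K] > diagnostics[best_K]:
            best_K = K
    return best_K, diagnostics, models


def prune_states(
    model: FittedStateModel,
    decode: DecodeResult,
    pruning_fraction: float,
    X: np.ndarray,
    lengths: list[int],
) -> tuple[FittedStateModel, DecodeResult]:
    """Remove states expressed in too few subjects and restandardize rows.

    A state "appears" in a subject when the subject's Viterbi path visits it
    at least once.  States visited by fewer than ``pruning_fraction`` of
    subjects are deleted, surviving transition rows are renormalized to sum
    to one, and the pruned model is re-decoded.
    """
    if not (0 < pruning_fraction < 1):
        raise ValueError("pruning_fraction must lie in (0, 1)")
    N = len(decode.viterbi_paths)
    visited = np.zeros((N, model.K), dtype=bool)
    for n, path in enumerate(decode.viterbi_paths):
        visited[n, np.unique(path)] = True
    frac = visited.mean(axis=0)
    keep = frac >= pruning_fraction
    if not keep.any():
        raise ValueError("pruning threshold removed every state")
    if keep.all():
        return model, decode
    idx = np.where(keep)[0]
    P = model.transition_matrix[np.ix_(idx, idx)]
    rows = P.sum(axis=1, keepdims=True)
    P = np.where(rows > 0, P / np.where(rows > 0, rows, 1.0), 1.0 / len(idx))
    pruned = FittedStateModel(
        means=model.means[idx],
        covariances=model.covariances[idx],
        transition_matrix=P,
        initial_distribution=stationary_distribution(P),
        log_likelihood=list(model.log_likelihood),
        reduction=model.reduction,
        roi_means=model.roi_means[idx] if model.roi_means is not None else None,
        roi_covariances=(
            model.roi_covariances[idx] if model.roi_covariances is not None else None
        ),
    )
    return pruned, decode_subjects(pruned, X, lengths)
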