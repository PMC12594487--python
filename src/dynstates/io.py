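"""File formats, cohort containers and seeded randomness.

All matrices travel as tab-separated text without headers (row i = ROI i);
model parameters and partitions are JSON.  Floats are written with 17
significant digits so that a write/read round trip is bitwise exact.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "RoiCohort",
    "read_matrix",
    "write_matrix",
    "read_roi_cohort",
    "write_roi_cohort",
    "read_connectome",
    "stage_seed",
]

_FLOAT_FMT = "%.17g"


def stage_seed(seed: int, stage: str) -> int:
    """Derive a reproducible per-stage child seed (< 2**31) from a global seed.

    The stage name is folded in through a CRC so that stages draw independent
    streams while two runs with the same (seed, stage) always agree.
    """
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode("utf-8"))])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def read_matrix(path: str | Path) -> np.ndarray:
    path = Path(path)
    try:
        mat = np.loadtxt(path, delimiter="\t", dtype=float, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell while parsing {path}: {exc}") from exc
    return mat


def write_matrix(path: str | Path, mat: np.ndarray) -> None:
    np.savetxt(path, np.atleast_2d(np.asarray(mat, dtype=float)), fmt=_FLOAT_FMT, delimiter="\t")


def _read_labels(path: str | Path) -> list[str]:
    with open(path) as fh:
        labels = [line.strip() for line in fh if line.strip()]
    if not labels:
        raise ValueError(f"empty label file: {path}")
    return labels


@dataclass
class RoiCohort:
    """Per-subject ROI x time BOLD matrices with shared region labels.

    Every subject matrix has ``D = len(roi_labels)`` rows in label order;
    columns are volumes sampled every ``tr_seconds`` seconds.
    """

    subjects: list[str]
    series: list[np.ndarray]
    roi_labels: list[str]
    tr_seconds: float
    condition: str = ""

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if len(self.subjects) != len(self.series):
            raise ValueError("one series per subject required")
        D = len(self.roi_labels)
        if D < 2:
            raise ValueError("need at least 2 ROIs")
        self.series = [np.asarray(s, dtype=float) for s in self.series]
        for sid, mat in zip(self.subjects, self.series):
            if mat.ndim != 2 or mat.shape[0] != D:
                raise ValueError(
                    f"subject {sid!r}: expected {D} ROI rows, got shape {mat.shape}"
                )
            if mat.shape[1] < 2:
                raise ValueError(f"subject {sid!r}: needs at least 2 volumes")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)


def read_roi_cohort(
    paths: list[str | Path],
    roi_label_path: str | Path,
    tr: float,
    condition: str = "",
) -> RoiCohort:
    """Load one TSV matrix per subject plus the shared ROI label list."""
    labels = _read_labels(roi_label_path)
    series, subjects = [], []
    D = None
    for p in paths:
        mat = read_matrix(p)
        if mat.shape[0] != len(labels):
            raise ValueError(
                f"{p}: {mat.shape[0]} rows but {len(labels)} ROI labels"
            )
        if D is None:
            D = mat.shape[0]
        elif mat.shape[0] != D:
            raise ValueError(f"{p}: row count {mat.shape[0]} differs from {D}")
        subjects.append(Path(p).stem)
        series.append(mat)
    return RoiCohort(subjects, series, labels, float(tr), condition)


def write_roi_cohort(cohort: RoiCohort, out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for sid, mat in zip(cohort.subjects, cohort.series):
        p = out_dir / f"{sid}.tsv"
        write_matrix(p, mat)
        written.append(p)
    with open(out_dir / "roi_labels.txt", "w") as fh:
        fh.write("\n".join(cohort.roi_labels) + "\n")
    with open(out_dir / "cohort.json", "w") as fh:
        json.dump(
            {
                "subjects": cohort.subjects,
                "tr_seconds": cohort.tr_seconds,
                "condition": cohort.condition,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    return written


def load_roi_cohort_dir(out_dir: str | Path) -> RoiCohort:
    out_dir = Path(out_dir)
    with open(out_dir / "cohort.json") as fh:
        meta = json.load(fh)
    paths = [out_dir / f"{sid}.tsv" for sid in meta["subjects"]]
    cohort = read_roi_cohort(
        paths, out_dir / "roi_labels.txt", meta["tr_seconds"], meta["condition"]
    )
    cohort.subjects = list(meta["subjects"])
    return cohort


def read_connectome(
    path: str | Path,
    roi_label_path: str | Path | None = None,
    target_labels: list[str] | None = None,
    atol: float = 1e-8,
) -> tuple[np.ndarray, list[str] | None]:
    """Load a weighted structural adjacency matrix.

    Enforces symmetry (within ``atol``) and nonnegative weights, zeroes the
    diagonal, and — when both a label file and cohort target labels are given —
    reorders rows/columns to the cohort's ROI order.
    """
    W = read_matrix(path)
    if W.shape[0] != W.shape[1]:
        raise ValueError(f"connectome must be square, got {W.shape}")
    if np.max(np.abs(W - W.T)) > atol:
        raise ValueError("connectome is asymmetric beyond tolerance 1e-8")
    if np.min(W) < 0:
        raise ValueError("connectome has negative weights")
    W = W.copy()
    np.fill_diagonal(W, 0.0)
    labels = _read_labels(roi_label_path) if roi_label_path is not None else None
    if labels is not None and target_labels is not None:
        if sorted(labels) != sorted(target_labels):
            raise ValueError("connectome labels do not match cohort labels")
        order = [labels.index(lab) for lab in target_labels]
        W = W[np.ix_(order, order)]
        labels = list(target_labels)
    return W, labels


@dataclass
class RunManifest:
    """Record of the choices made during a run, for reproducibility."""

    seed: int
    entries: dict = field(default_factory=dict)

    def record(self, key: str, value) -> None:
        self.entries[key] = value

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, **self.entries}, fh, indent=1, sort_keys=True)
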