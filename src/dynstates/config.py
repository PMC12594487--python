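"""Run configuration shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Knobs for the full analysis.

    candidate_K_range : inclusive (low, high) interval of HMM sizes scanned by
        maximum-occupancy-entropy model selection; low must be >= 2.
    pruning_fraction : a state is dropped when it is visited (Viterbi) by fewer
        than this fraction of subjects (default 0.20).
    strong_sink_threshold : stationary probability at or above which a state is
        a "strong sink" (default 0.05, inclusive).
    entropy_log_base : 2 for bits (default) or "e" for nats.
    resolution_grid / coupling_grid : modularity resolution gamma values and
        interlayer coupling scales swept by consensus community detection.
    """

    candidate_K_range: tuple[int, int] = (2, 8)
    pruning_fraction: float = 0.20
    strong_sink_threshold: float = 0.05
    entropy_log_base: float | str = 2
    resolution_grid: list[float] = field(default_factory=lambda: [0.8, 0.9, 1.0, 1.1, 1.2])
    coupling_grid: list[float] = field(default_factory=lambda: [0.5, 1.0, 2.0])
    n_restarts: int = 5
    n_permutations: int = 100
    n_consensus_runs: int = 20
    tol: float = 1e-4
    max_iter: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.candidate_K_range
        if lo < 2 or hi < lo:
            raise ValueError("candidate_K_range lower bound must be >= 2 and <= upper")
        if not (0 < self.pruning_fraction < 1):
            raise ValueError("pruning_fraction must lie in (0, 1)")
        if not self.resolution_grid or not self.coupling_grid:
            raise ValueError("parameter grids must be non-empty")
        for name in ("n_restarts", "n_permutations", "n_consensus_runs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")

    @property
    def log_base(self) -> float:
        import math

        return math.e if self.entropy_log_base in ("e", "nats") else float(self.entropy_log_base)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "candidate_K_range" in raw:
            raw["candidate_K_range"] = tuple(raw["candidate_K_range"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["candidate_K_range"] = list(data["candidate_K_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
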