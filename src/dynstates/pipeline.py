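"""End-to-end synthetic study: simulate, reduce, fit, analyze, compare.

`run_pipeline` generates a two-condition synthetic cohort (an anesthesia-like
condition with a planted dominant sink state and structure-aligned functional
blocks, and a wake-like condition with uniform dynamics and per-state
re-shuffled blocks), runs every analysis stage on each condition, compares
both against the shared structural connectome, and writes all result tables
under an output directory.  Every stage draws its randomness from a child
seed of the one global seed, so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .compare import compare_state_to_structure, rank_tests
from .config import RunConfig
from .dynamics import summarize_dynamics
from .hmm import decode_subjects, prune_states, select_model_size
from .io import RunManifest, stage_seed, write_matrix, write_roi_cohort
from .metrics import (
    excitability,
    normalized_global_efficiency,
    state_graphs_from_model,
)
from .multilayer import (
    build_hmgm,
    cluster_layers,
    consensus_communities,
    fractional_membership,
)
from .reduction import horn_parallel_analysis, pca_reduce, standardize_concatenate
from .synthetic import make_ground_truth, make_structural_connectome, simulate_cohort

__all__ = ["StudyDesign", "simulate_study", "analyze_condition", "run_pipeline"]

CONDITIONS = ("anesthesia", "wake")


@dataclass
class StudyDesign:
    """Scale and planted structure of the synthetic study.

    Defaults mirror the recording scale this pipeline emulates: 13 subjects,
    63 regions, 200 volumes per 10-min condition at TR = 3 s, with a
    4-state generative model whose anesthesia-like condition plants a sink
    state of stationary mass 0.4.
    """

    N: int = 13
    D: int = 63
    T: int = 200
    tr: float = 3.0
    K_true: int = 4
    sink_mass: float = 0.4
    separation: float = 6.0
    obs_noise: float = 0.2
    structure_noise: float = 0.1

    @property
    def block_sizes(self) -> list[int]:
        n_blocks = 3
        base = self.D // n_blocks
        sizes = [base] * (n_blocks - 1)
        sizes.append(self.D - base * (n_blocks - 1))
        return sizes


def simulate_study(design: StudyDesign, seed: int) -> dict:
    """Ground-truth models, cohorts for both conditions, and the connectome."""
    truth = {
        "anesthesia": make_ground_truth(
            design.K_true,
            design.D,
            sink_mass=design.sink_mass,
            block_sizes=design.block_sizes,
            separation=design.separation,
            seed=stage_seed(seed, "truth-anesthesia"),
            shuffle_blocks_per_state=False,
        ),
        "wake": make_ground_truth(
            design.K_true,
            design.D,
            sink_mass=None,
            block_sizes=design.block_sizes,
            separation=design.separation,
            seed=stage_seed(seed, "truth-wake"),
            shuffle_blocks_per_state=True,
        ),
    }
    cohorts = {
        cond: simulate_cohort(
            truth[cond],
            N=design.N,
            T=design.T,
            tr=design.tr,
            obs_noise=design.obs_noise,
            seed=stage_seed(seed, f"cohort-{cond}"),
            condition=cond,
        )
        for cond in CONDITIONS
    }
    structure, structure_labels = make_structural_connectome(
        design.block_sizes,
        align_with=truth["anesthesia"],
        noise=design.structure_noise,
        seed=stage_seed(seed, "structure"),
    )
    return {
        "truth": truth,
        "cohorts": cohorts,
        "structure": structure,
        "structure_labels": structure_labels,
    }


def analyze_condition(cohort, config: RunConfig, seed: int) -> dict:
    """All per-condition stages: reduce, fit+select, prune, decode, dynamics,
    communities, per-state graphs."""
    X, lengths, center, scale = standardize_concatenate(cohort)
    d = horn_parallel_analysis(
        X, n_null=config.n_permutations, seed=stage_seed(seed, "parallel-analysis")
    )
    Z, rmap = pca_reduce(X, d, center=center, scale=scale)

    K, diagnostics, models = select_model_size(
        Z,
        lengths,
        config.candidate_K_range,
        n_restarts=config.n_restarts,
        tol=config.tol,
        max_iter=config.max_iter,
        seed=stage_seed(seed, "hmm-fit"),
        reduction=rmap,
        log_base=config.log_base,
    )
    model = models[K]
    decode = decode_subjects(model, Z, lengths)
    model, decode = prune_states(model, decode, config.pruning_fraction, Z, lengths)

    dyn = summarize_dynamics(
        model.transition_matrix,
        decode.viterbi_paths,
        decode.fractional_occupancy,
        cohort.tr_seconds,
        strong_sink_threshold=config.strong_sink_threshold,
        log_base=config.log_base,
    )

    hmgm = build_hmgm(model, coupling_scale=1.0)
    partition, coclass = consensus_communities(
        hmgm,
        resolution_grid=config.resolution_grid,
        coupling_grid=config.coupling_grid,
        n_runs=config.n_consensus_runs,
        seed=stage_seed(seed, "communities"),
    )
    memberships = fractional_membership(partition, hmgm.pi)
    graphs = state_graphs_from_model(model)
    return {
        "reduced_dim": d,
        "reduction": rmap,
        "chosen_K": K,
        "selection_diagnostics": diagnostics,
        "model": model,
        "decode": decode,
        "dynamics": dyn,
        "hmgm": hmgm,
        "partition": partition,
        "coclassification": coclass,
        "memberships": memberships,
        "state_graphs": graphs,
    }


def _linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    n = len(leaf_names)

    def node(i: int, parent_h: float) -> str:
        if i < n:
            return f"{leaf_names[i]}:{parent_h:.6g}"
        row = Z[i - n]
        h = row[2]
        left = node(int(row[0]), h / 2)
        right = node(int(row[1]), h / 2)
        return f"({left},{right}):{max(parent_h - h, 0.0):.6g}"

    root_h = Z[-1, 2]
    return node(2 * n - 2, root_h) + ";"


def _compare_condition_to_structure(
    result: dict, structure: np.ndarray, structure_partition: np.ndarray, seed: int
) -> pd.DataFrame:
    rows = []
    for s, graph in enumerate(result["state_graphs"]):
        # reuse the state's layer partition from the multilayer consensus
        rows.append(
            compare_state_to_structure(
                graph,
                structure,
                structure_partition,
                state_partition=result["partition"].layer_partition(s),
                seed=stage_seed(seed, f"compare-state-{s}"),
            )
        )
    return pd.DataFrame(rows)


def run_pipeline(
    out_dir: str | Path,
    config: RunConfig | None = None,
    design: StudyDesign | None = None,
) -> dict:
    """Run the full synthetic study and write all outputs under ``out_dir``.

    Returns the report dictionary that is also written as ``report.json``.
    """
    config = config or RunConfig()
    design = design or StudyDesign()
    seed = config.seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=seed)
    manifest.record("design", vars(design).copy())

    sim = simulate_study(design, seed)
    write_matrix(out / "structural_connectome.tsv", sim["structure"])
    from .metrics import single_layer_modularity_partition

    structure_partition, structure_Q = single_layer_modularity_partition(
        sim["structure"],
        resolution_grid=config.resolution_grid,
        n_runs=config.n_consensus_runs,
        seed=stage_seed(seed, "structure-communities"),
    )

    report: dict = {"seed": seed, "conditions": {}}
    compare_frames = {}
    for cond in CONDITIONS:
        syn = sim["cohorts"][cond]
        cdir = out / cond
        cdir.mkdir(exist_ok=True)
        write_roi_cohort(syn.cohort, cdir / "cohort")
        res = analyze_condition(syn.cohort, config, stage_seed(seed, f"analysis-{cond}"))
        res["model"].save(cdir / "model.json")
        fo = pd.DataFrame(
            res["decode"].fractional_occupancy,
            index=syn.cohort.subjects,
            columns=[f"state_{k}" for k in range(res["model"].K)],
        )
        fo.to_csv(cdir / "fractional_occupancy.tsv", sep="\t", float_format="%.10g")
        dyn = res["dynamics"]
        with open(cdir / "dynamics.json", "w") as fh:
            json.dump(dyn.to_dict(), fh, indent=1, sort_keys=True)

        part = res["partition"]
        D, K = part.labels.shape
        pdf = pd.DataFrame(
            {
                "roi": np.repeat(syn.cohort.roi_labels, K),
                "state": np.tile(np.arange(K), D),
                "community": part.labels.reshape(-1),
            }
        )
        pdf.to_csv(cdir / "partition.tsv", sep="\t", index=False)
        write_matrix(cdir / "coclassification.tsv", res["coclassification"])
        memb = pd.DataFrame(
            res["memberships"],
            index=syn.cohort.roi_labels,
            columns=[f"community_{c}" for c in range(res["memberships"].shape[1])],
        )
        memb.to_csv(cdir / "fractional_membership.tsv", sep="\t", float_format="%.10g")
        if K >= 2:
            Zl, _, _ = cluster_layers(part)
            (cdir / "layer_dendrogram.nwk").write_text(
                _linkage_to_newick(Zl, [f"state_{k}" for k in range(K)]) + "\n"
            )

        frame = _compare_condition_to_structure(
            res, sim["structure"], structure_partition, stage_seed(seed, f"compare-{cond}")
        )
        frame.to_csv(cdir / "structure_comparison.tsv", sep="\t", index=False,
                     float_format="%.10g")
        compare_frames[cond] = frame

        nge = [
            normalized_global_efficiency(
                g.weights, n_permutations=config.n_permutations,
                seed=stage_seed(seed, f"nge-{cond}-{g.index}"),
            )
            for g in res["state_graphs"]
        ]
        report["conditions"][cond] = {
            "reduced_dim": int(res["reduced_dim"]),
            "chosen_K": int(res["chosen_K"]),
            "K_after_pruning": int(res["model"].K),
            "stationary_distribution": dyn.stationary.tolist(),
            "strong_sinks": dyn.strong_sinks,
            "max_sink_centrality": float(dyn.stationary.max()),
            "entropy_rate_bits": float(dyn.entropy_rate),
            "mean_switching_rate_hz": float(dyn.switching_rates.mean()),
            "mean_occupancy_entropy": float(dyn.occupancy_entropies.mean()),
            "modularity_Q": float(part.Q),
            "mean_excitability": float(
                np.mean([excitability(g.mean_activity) for g in res["state_graphs"]])
            ),
            "normalized_global_efficiency": [float(v) for v in nge],
            "mean_ami_vs_structure": float(frame["ami_vs_structure"].mean()),
            "mean_edge_dcor_vs_structure": float(frame["edge_dcor"].mean()),
        }
        report["conditions"][cond]["_result"] = res  # in-memory only

    contrasts = {}
    for column in ("ami_vs_structure", "edge_dcor"):
        contrasts[column] = rank_tests(
            compare_frames["anesthesia"][column].to_numpy(),
            compare_frames["wake"][column].to_numpy(),
            paired=False,
        )
    report["structure_contrasts"] = contrasts
    report["structure_Q"] = float(structure_Q)
    report["structure_partition"] = structure_partition.tolist()

    serializable = {
        k: (
            {c: {kk: vv for kk, vv in d.items() if kk != "_result"}
             for c, d in v.items()}
            if k == "conditions"
            else v
        )
        for k, v in report.items()
    }
    with open(out / "report.json", "w") as fh:
        json.dump(serializable, fh, indent=1, sort_keys=True)
    manifest.save(out / "manifest.json")
    return report
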