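"""Configuration, orchestration, and wild-type vs mutant report assembly.

``run_pipeline`` ties the stages together in analysis order — trajectory
input (file or synthetic), fluctuation statistics, cross-correlation and
PCA, the contact-gated residue network with optimal/suboptimal paths,
optional interface-interaction detection, and the end-state free-energy
ledger — writing each artifact as CSV/TSV/JSON plus a manifest holding the
exact configuration and seed, so every number in a report is reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import read_pdb_file, select_calpha
from .correlation import dccm, pca, project, threshold_dccm
from .energetics import (
    B_DEFAULT,
    GAMMA_DEFAULT,
    BindingSummary,
    binding_summary,
    read_components_csv,
    residue_decomposition,
)
from .fluctuations import rmsd_series, rmsf, window_stats
from .interactions import find_all_interactions, records_frame, residue_interaction_census
from .network import PathResult, build_graph, compare_pathways, contact_map, path_table, suboptimal_paths
from .synthetic import PlantedModel, make_chain, sample_correlated_trajectory

logger = logging.getLogger("allopath")

__all__ = ["RunConfig", "run_pipeline", "compare_systems"]


@dataclass
class RunConfig:
    """All tunables of one pipeline run, serialized into every output dir."""

    output_dir: str = "allopath_out"
    seed: int = 0

    # input: either a multi-model PDB path or a synthetic trajectory spec
    trajectory_path: str | None = None
    synthetic_n_res: int = 40
    synthetic_geometry: str = "helix"
    synthetic_n_frames: int = 2000
    synthetic_amplitude: float = 1.0
    synthetic_pairs: list[tuple[int, int, float]] = field(default_factory=list)

    # analysis window: fraction of frames discarded as equilibration burn-in
    burn_in_fraction: float = 0.25
    dccm_threshold: float = 0.3
    # least-squares fit each frame before statistics; disable for synthetic
    # trajectories, which are generated in a common frame of reference
    superpose: bool = True

    # residue-network parameters
    contact_mode: str = "ca"
    contact_cutoff: float = 4.5
    ca_cutoff: float = 8.0
    occupancy: float = 0.75
    exclude_neighbors: int = 2
    path_offset: int = 20
    length_scale: int = 100
    max_paths: int = 10000
    queries: list[tuple[int, int]] = field(default_factory=list)

    # interface-interaction detection
    interaction_chains: tuple[str, str] | None = None

    # energetics: per-frame component CSV (frame, role, E_vdW, ...)
    energy_components_csv: str | None = None
    gamma: float = GAMMA_DEFAULT
    b: float = B_DEFAULT
    entropy_term: float = 0.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.queries = [tuple(q) for q in cfg.queries]
        cfg.synthetic_pairs = [tuple(p) for p in cfg.synthetic_pairs]
        if cfg.interaction_chains is not None:
            cfg.interaction_chains = tuple(cfg.interaction_chains)
        return cfg

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["queries"] = [list(q) for q in self.queries]
        out["synthetic_pairs"] = [list(p) for p in self.synthetic_pairs]
        if self.interaction_chains is not None:
            out["interaction_chains"] = list(self.interaction_chains)
        return out


def _load_trajectory(config: RunConfig):
    if config.trajectory_path:
        return read_pdb_file(config.trajectory_path)
    corr = np.eye(config.synthetic_n_res)
    for i, j, rho in config.synthetic_pairs:
        corr[i, j] = corr[j, i] = rho
    model = PlantedModel(
        reference=make_chain(config.synthetic_n_res, config.synthetic_geometry),
        target_corr=corr,
        amplitude=config.synthetic_amplitude,
        n_frames=config.synthetic_n_frames,
        seed=config.seed,
    )
    return sample_correlated_trajectory(model)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle to ``config.output_dir``.

    Returns a dict with the in-memory results (series, matrices, path
    results, tables) alongside the paths of the written artifacts.  Any
    stage failure raises with the stage name in the message.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"artifacts": {}}
    stage = "setup"

    def write_csv(frame: pd.DataFrame, name: str) -> None:
        path = outdir / name
        frame.to_csv(path, index=False)
        report["artifacts"][name] = str(path)

    try:
        stage = "input"
        t0 = time.perf_counter()
        traj = _load_trajectory(config)
        selection = select_calpha(traj.topology)
        burn_in = int(config.burn_in_fraction * traj.n_frames)
        window = (burn_in, traj.n_frames)
        logger.info("input: %d frames, %d residues, window=%s (%.2fs)",
                    traj.n_frames, len(selection), window, time.perf_counter() - t0)

        stage = "fluctuations"
        series = rmsd_series(traj, traj.frame_structure(0), selection,
                             superpose=config.superpose)
        stats = window_stats(series, *window)
        write_csv(pd.DataFrame({"frame": np.arange(traj.n_frames), "rmsd": series}), "rmsd.csv")
        fluct = rmsf(traj, selection, window, superpose=config.superpose)
        write_csv(
            pd.DataFrame({"residue": selection.labels(traj.topology), "rmsf": fluct}),
            "rmsf.csv",
        )
        report["rmsd_stats"] = stats
        logger.info("fluctuations: rmsd %.3f ± %.3f Å over window", stats.mean, stats.sd)

        stage = "correlation_pca"
        matrix = dccm(traj, selection, window, superpose=config.superpose)
        thresholded = threshold_dccm(matrix, config.dccm_threshold)
        dccm_path = outdir / "dccm.tsv"
        np.savetxt(dccm_path, matrix.values, delimiter="\t", fmt="%.6f")
        report["artifacts"]["dccm.tsv"] = str(dccm_path)
        pca_result = pca(traj, selection, window, superpose=config.superpose)
        write_csv(
            pd.DataFrame({"mode": np.arange(1, len(pca_result.eigenvalues) + 1),
                          "eigenvalue": pca_result.eigenvalues}),
            "pca_eigenvalues.csv",
        )
        scores = project(traj, selection, pca_result, k=2, window=window,
                         superpose=config.superpose)
        write_csv(
            pd.DataFrame({"frame": np.arange(window[0], window[1]),
                          "pc1": scores[:, 0], "pc2": scores[:, 1]}),
            "pca_projections.csv",
        )
        report["dccm"] = matrix
        report["pca"] = pca_result

        stage = "network_paths"
        contacts = contact_map(
            traj,
            cutoff=config.contact_cutoff,
            occupancy=config.occupancy,
            mode=config.contact_mode,
            ca_cutoff=config.ca_cutoff,
            exclude_neighbors=config.exclude_neighbors,
            window=window,
        )
        graph = build_graph(thresholded, contacts, scale=config.length_scale)
        write_csv(graph.edge_list_frame(), "graph_edges.csv")
        graph.write_graphml(outdir / "graph.graphml")
        report["artifacts"]["graph.graphml"] = str(outdir / "graph.graphml")
        report["graph"] = graph
        path_results: dict[tuple[int, int], PathResult] = {}
        if config.queries:
            table = path_table(graph, config.queries,
                               offset=config.path_offset, max_paths=config.max_paths)
            write_csv(table, "path_table.csv")
            for query in config.queries:
                path_results[query] = suboptimal_paths(
                    graph, *query, offset=config.path_offset, max_paths=config.max_paths
                )
            with open(outdir / "paths.json", "w") as handle:
                json.dump(
                    {
                        f"{s}-{t}": {
                            "optimal_path": r.optimal_path,
                            "optimal_length": r.optimal_length,
                            "n_residues": r.n_residues,
                            "suboptimal_count": r.suboptimal_count,
                            "node_frequency": r.node_frequency,
                            "truncated": r.truncated,
                        }
                        for (s, t), r in path_results.items()
                    },
                    handle,
                    indent=2,
                )
            report["artifacts"]["paths.json"] = str(outdir / "paths.json")
        report["path_results"] = path_results

        stage = "interactions"
        if config.interaction_chains is not None:
            records = find_all_interactions(
                traj.frame_structure(traj.n_frames - 1), config.interaction_chains
            )
            write_csv(records_frame(records), "interactions.csv")
            write_csv(residue_interaction_census(records), "interaction_census.csv")
            report["interactions"] = records

        stage = "energetics"
        if config.energy_components_csv:
            roles = read_components_csv(config.energy_components_csv)
            summary = binding_summary(
                roles["complex"], roles["receptor"], roles["ligand"],
                entropy_term=config.entropy_term, gamma=config.gamma, b=config.b,
            )
            write_csv(summary.to_frame(), "energy_summary.csv")
            report["binding_summary"] = summary

        stage = "manifest"
        manifest = {
            "config": config.to_dict(),
            "seed": config.seed,
            "versions": {"allopath": __version__, "numpy": np.__version__},
            "artifacts": sorted(report["artifacts"]),
        }
        with open(outdir / "manifest.json", "w") as handle:
            json.dump(manifest, handle, indent=2)
        report["manifest"] = manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return report


def compare_systems(report_a: dict, report_b: dict,
                    decomposition_threshold: float = 0.3) -> dict:
    """Wild-type vs mutant comparison of two pipeline reports.

    Produces a per-pathway verdict by the three-criterion rule (shorter
    optimal path, fewer involved residues, more suboptimal paths = stronger
    allosteric relationship; conflicts are reported as ambiguous with the
    majority noted) and, when both reports carry per-residue energies, the
    flagged residue differences.
    """
    paths_a = report_a.get("path_results", {})
    paths_b = report_b.get("path_results", {})
    if set(paths_a) != set(paths_b):
        raise ValueError("reports cover different path queries")
    rows = []
    for query in paths_a:
        ra, rb = paths_a[query], paths_b[query]
        rows.append(
            {
                "source": query[0],
                "sink": query[1],
                "length_a": ra.optimal_length,
                "length_b": rb.optimal_length,
                "n_residues_a": ra.n_residues,
                "n_residues_b": rb.n_residues,
                "subopt_a": ra.suboptimal_count,
                "subopt_b": rb.suboptimal_count,
                "verdict": compare_pathways(ra, rb),
            }
        )
    out: dict = {"pathways": pd.DataFrame(rows)}

    decomp_a = report_a.get("residue_energies")
    decomp_b = report_b.get("residue_energies")
    if decomp_a is not None and decomp_b is not None:
        out["residues"] = residue_decomposition(
            decomp_a, decomp_b, threshold=decomposition_threshold
        )
    if "binding_summary" in report_a and "binding_summary" in report_b:
        out["energy"] = BindingSummary.comparison_table(
            report_a["binding_summary"], report_b["binding_summary"]
        )
    return out
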