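"""Run configuration and end-to-end pipeline assembly.

A flat YAML (or dict) configuration with stage parameters defaulting to
the protocol values used throughout the package: 2.5 Å cluster merge
cutoff, 4.5 Å / 0.75 contact occupancy, 30% interaction-report
threshold, trailing 20% energy window, top 5 PCA modes.  Unknown keys
are rejected; every parameter is echoed into the run manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .io import read_pdb, select

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    # inputs
    trajectory: str | None = None  # multi-model PDB
    reference: str | None = None  # single-model PDB; defaults to frame 0
    energy_table: str | None = None  # long-format TSV
    # selections
    fit_selection: str = "name CA"
    measure_selection: str | None = None
    # stage parameters
    cluster_cutoff: float = 2.5  # Å
    cluster_stride: int = 1
    contact_cutoff: float = 4.5  # Å
    contact_occupancy: float = 0.75
    neighbor_exclusion: int = 2
    interaction_threshold: float = 0.30
    energy_window_fraction: float = 0.2
    n_modes: int = 5
    equilibration_cut: float | None = None  # ns; None → first half dropped
    helix_range: tuple[int, int] | None = None
    seed: int = 0
    stages: list[str] = field(
        default_factory=lambda: ["rmsd", "rmsf", "cluster", "network", "pca"]
    )

    KNOWN_STAGES = ("rmsd", "rmsf", "cluster", "network", "pca", "interactions", "energy", "helix")

    def validate(self) -> None:
        if self.cluster_cutoff <= 0:
            raise ValueError("cluster_cutoff must be positive")
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be positive")
        if not 0 < self.contact_occupancy <= 1:
            raise ValueError("contact_occupancy must be in (0, 1]")
        if not 0 <= self.interaction_threshold <= 1:
            raise ValueError("interaction_threshold must be in [0, 1]")
        if not 0 < self.energy_window_fraction <= 1:
            raise ValueError("energy_window_fraction must be in (0, 1]")
        if self.n_modes < 1:
            raise ValueError("n_modes must be ≥ 1")
        if self.cluster_stride < 1:
            raise ValueError("cluster_stride must be ≥ 1")
        unknown = set(self.stages) - set(self.KNOWN_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "helix_range" in data and data["helix_range"] is not None:
            data = {**data, "helix_range": tuple(data["helix_range"])}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d.get("helix_range") is not None:
            d["helix_range"] = list(d["helix_range"])
        return d


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the configured stages in dependency order.

    Writes per-stage CSV/TSV outputs and a manifest JSON (inputs,
    parameters, version) under ``out_dir``; returns the manifest dict.
    Raises with the failing stage named.
    """
    import pandas as pd

    config.validate()
    if config.trajectory is None:
        raise ValueError("config.trajectory is required")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    topology, series = read_pdb(config.trajectory)
    if config.reference:
        _, ref_series = read_pdb(config.reference)
        reference = ref_series.coords[0]
    else:
        reference = series.coords[0]
    fit_sel = select(topology, config.fit_selection)
    meas_sel = (
        select(topology, config.measure_selection)
        if config.measure_selection
        else fit_sel
    )

    manifest: dict = {
        "version": __version__,
        "parameters": config.to_dict(),
        "outputs": {},
    }

    def _stage(name):
        return name in config.stages

    try:
        if _stage("rmsd"):
            from .superpose import rmsd_series

            vals = rmsd_series(series, reference, fit_sel, meas_sel)
            df = pd.DataFrame(
                {"frame": np.arange(series.n_frames), "time_ns": series.times, "rmsd_A": vals}
            )
            df.to_csv(out / "rmsd.csv", index=False, float_format="%.6f")
            manifest["outputs"]["rmsd"] = "rmsd.csv"

        if _stage("rmsf"):
            from .superpose import rmsf_profile

            prof = rmsf_profile(
                series, topology, meas_sel, fit_sel, config.equilibration_cut
            )
            pd.DataFrame(
                {"residue": list(prof), "rmsf_A": list(prof.values())}
            ).to_csv(out / "rmsf.csv", index=False, float_format="%.6f")
            manifest["outputs"]["rmsf"] = "rmsf.csv"

        if _stage("helix") and config.helix_range:
            from .superpose import subrange_rmsd

            vals, counts, edges = subrange_rmsd(
                series, topology, reference, config.helix_range, fit_sel
            )
            pd.DataFrame(
                {"frame": np.arange(series.n_frames), "rmsd_A": vals}
            ).to_csv(out / "helix_rmsd.csv", index=False, float_format="%.6f")
            manifest["outputs"]["helix"] = "helix_rmsd.csv"

        if _stage("cluster"):
            from .cluster import average_linkage, pairwise_rmsd_matrix

            mat = pairwise_rmsd_matrix(series, fit_sel, meas_sel, stride=config.cluster_stride)
            summary = average_linkage(mat, config.cluster_cutoff)
            rows = [
                {
                    "cluster_id": i,
                    "population_percent": c.population_percent,
                    "centroid_frame": c.centroid_frame * config.cluster_stride,
                    "n_members": len(c.members),
                }
                for i, c in enumerate(summary.clusters)
            ]
            pd.DataFrame(rows).to_csv(out / "clusters.csv", index=False, float_format="%.4f")
            manifest["outputs"]["cluster"] = "clusters.csv"

        if _stage("network"):
            from .network import (
                build_contact_graph,
                build_node_trajectory,
                correlation_matrix,
                girvan_newman,
                network_edge_table,
                weight_edges,
            )

            graph = build_contact_graph(
                topology,
                series,
                cutoff=config.contact_cutoff,
                min_occupancy=config.contact_occupancy,
                neighbor_exclusion=config.neighbor_exclusion,
            )
            nodes = build_node_trajectory(topology, series)
            c = correlation_matrix(nodes)
            weighted = weight_edges(graph, c, nodes.node_ids)
            partition = (
                girvan_newman(weighted) if weighted.number_of_edges() else None
            )
            pd.DataFrame(network_edge_table(weighted, partition)).to_csv(
                out / "network_edges.tsv", sep="\t", index=False, float_format="%.6f"
            )
            if partition:
                rows = [
                    {"node": n, "community": i, "critical": n in partition.critical_nodes}
                    for i, comm in enumerate(partition.communities)
                    for n in sorted(comm)
                ]
                pd.DataFrame(rows).to_csv(out / "communities.csv", index=False)
            manifest["outputs"]["network"] = "network_edges.tsv"

        if _stage("pca"):
            from .modes import covariance_pca, mode_rmsf
            from .network import build_node_trajectory

            nodes = build_node_trajectory(topology, series)
            modes = covariance_pca(nodes.displacements, n_modes=config.n_modes)
            pd.DataFrame(
                {
                    "mode": np.arange(1, modes.n_modes + 1),
                    "eigenvalue_A2": modes.eigenvalues,
                }
            ).to_csv(out / "pca_eigenvalues.csv", index=False, float_format="%.8f")
            rmsf1 = mode_rmsf(modes, 0)
            pd.DataFrame({"node": nodes.node_ids, "mode1_rmsf_A": rmsf1}).to_csv(
                out / "pca_mode1_rmsf.csv", index=False, float_format="%.6f"
            )
            manifest["outputs"]["pca"] = "pca_eigenvalues.csv"

        if _stage("interactions"):
            from .interactions import detect_interactions, interaction_fractions

            events = detect_interactions(topology, series)
            table, report = interaction_fractions(
                events, series.n_frames, config.interaction_threshold
            )
            table.to_csv(out / "interaction_fractions.csv", index=False, float_format="%.4f")
            report.to_csv(out / "interaction_report.csv", index=False, float_format="%.4f")
            manifest["outputs"]["interactions"] = "interaction_fractions.csv"

        if _stage("energy") and config.energy_table:
            from .energy import (
                binding_energy_per_frame,
                group_components,
                load_energy_table,
                summarize_window,
            )

            df = load_energy_table(config.energy_table)
            dg = binding_energy_per_frame(df)
            grouped = group_components(df)
            summary = summarize_window(dg, grouped, config.energy_window_fraction)
            with open(out / "energy_summary.json", "w") as fh:
                json.dump(
                    {
                        "dE_mean": summary.de_mean,
                        "dE_sd": summary.de_sd,
                        "grouped_mean": summary.grouped_mean,
                        "grouped_sd": summary.grouped_sd,
                        "window": list(summary.window),
                    },
                    fh,
                    indent=2,
                )
            manifest["outputs"]["energy"] = "energy_summary.json"
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
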