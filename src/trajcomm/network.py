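"""Correlation-based dynamical network analysis of MD trajectories.

The model: one node per residue (Cα position; a ligand contributes one
node at its heavy-atom centroid).  An edge joins two residues whose
heavy atoms come within a distance cutoff (default 4.5 Å) for at least a
minimum fraction of frames (default 0.75).  Edges are weighted by
w_ij = −log|C_ij|, where C_ij is the normalized cross-correlation of the
node displacement vectors,

    C_ij = ⟨Δr_i · Δr_j⟩ / (⟨|Δr_i|²⟩ ⟨|Δr_j|²⟩)^½ ,

so strongly correlated pairs get short edges: the weight acts as an
information-transfer distance.  Communities are found with the
Girvan–Newman edge-removal algorithm (weighted betweenness, stop at
maximum modularity), and the highest-betweenness edge between each pair
of communities — with its endpoints — is flagged critical.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .io import STANDARD_AA, FrameSeries, Selection, Topology
from .superpose import superpose_series

logger = logging.getLogger(__name__)

DEFAULT_CONTACT_CUTOFF = 4.5  # Å, heavy-atom contact distance
DEFAULT_MIN_OCCUPANCY = 0.75  # fraction of frames ("at least 75%")
#: Alternative occupancy preset ("over 70%") kept for comparisons.
RELAXED_MIN_OCCUPANCY = 0.70
DEFAULT_NEIGHBOR_EXCLUSION = 2  # sequence neighbors excluded from contacts
CORRELATION_FLOOR = 1e-12  # |C| floor keeping −log|C| finite


class NetworkError(ValueError):
    pass


@dataclass
class NodeTrajectory:
    """Aligned, mean-removed node positions: one node per residue.

    ``displacements`` has shape (n_frames, n_nodes, 3) with the temporal
    mean removed per node; ``positions`` are the aligned raw positions.
    """

    node_ids: list[str]
    positions: np.ndarray
    displacements: np.ndarray
    residue_keys: list[tuple[str, int, str]] = field(default_factory=list)


def build_node_trajectory(
    topology: Topology,
    series: FrameSeries,
    ligand_atom: str | None = None,
    start: int = 0,
    align: bool = True,
) -> NodeTrajectory:
    """Extract per-residue node positions from an aligned trajectory.

    Protein residues are represented by their Cα; each ligand residue by
    its heavy-atom centroid (or a named atom via ``ligand_atom``).  The
    series is aligned on protein Cα with a two-pass fit to the ensemble
    mean before displacements are taken.  Water is ignored.

    ``align=False`` skips the fit for series already expressed in the
    fitted frame (e.g. synthetic ensembles generated without rigid-body
    motion); re-fitting such data would subtract the per-frame centroid
    noise and bias small-system correlations.
    """
    by_res = topology.atoms_by_residue()
    ca_idx = [
        i
        for i, a in enumerate(topology.atoms)
        if a.name.upper() == "CA" and a.residue_name in STANDARD_AA
    ]
    if len(ca_idx) < 3:
        raise NetworkError("need at least 3 protein Cα atoms to align")
    fit_sel = Selection(tuple(ca_idx), "protein CA")
    if align:
        aligned = superpose_series(series, fit_sel, start=start)
    else:
        aligned = series.coords[start:]

    node_ids: list[str] = []
    keys: list[tuple[str, int, str]] = []
    cols: list[np.ndarray] = []
    for key, atom_ids in by_res.items():
        chain, num, name = key
        if name in STANDARD_AA:
            ca = [i for i in atom_ids if topology.atoms[i].name.upper() == "CA"]
            if not ca:
                logger.warning("residue %s_%d has no CA; skipped as node", name, num)
                continue
            cols.append(aligned[:, ca[0]])
        elif topology.atoms[atom_ids[0]].is_ligand:
            if ligand_atom is not None:
                pick = [i for i in atom_ids if topology.atoms[i].name.upper() == ligand_atom.upper()]
                if not pick:
                    raise NetworkError(f"ligand atom {ligand_atom!r} not found in {name}_{num}")
                cols.append(aligned[:, pick[0]])
            else:
                heavy = [i for i in atom_ids if topology.atoms[i].is_heavy]
                if not heavy:
                    raise NetworkError(f"ligand residue {name}_{num} has no heavy atoms")
                cols.append(aligned[:, heavy].mean(axis=1))
        else:  # water or other skipped species
            continue
        node_ids.append(f"{name}_{num}")
        keys.append(key)
    positions = np.stack(cols, axis=1)
    displacements = positions - positions.mean(axis=0)
    return NodeTrajectory(node_ids, positions, displacements, keys)


def build_contact_graph(
    topology: Topology,
    series: FrameSeries,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    min_occupancy: float = DEFAULT_MIN_OCCUPANCY,
    neighbor_exclusion: int = DEFAULT_NEIGHBOR_EXCLUSION,
) -> nx.Graph:
    """Residue contact graph from heavy-atom proximity occupancy.

    An edge (i, j) is retained iff any heavy-atom pair across residues i
    and j lies within ``cutoff`` in at least ``min_occupancy`` of the
    frames.  Residue pairs within ``neighbor_exclusion`` positions along
    the same chain are excluded (trivial covalent contacts).  Water is
    ignored.  Node names are ``RESNAME_NUMBER`` labels; edges carry an
    ``occupancy`` attribute.
    """
    by_res = topology.atoms_by_residue()
    node_keys = [
        k
        for k in by_res
        if k[2] in STANDARD_AA or topology.atoms[by_res[k][0]].is_ligand
    ]
    heavy_per_node: list[np.ndarray] = []
    for k in node_keys:
        heavy = np.array([i for i in by_res[k] if topology.atoms[i].is_heavy], dtype=int)
        if len(heavy) == 0:
            raise NetworkError(f"residue {k[2]}_{k[1]} has no heavy atoms")
        heavy_per_node.append(heavy)
    labels = [f"{k[2]}_{k[1]}" for k in node_keys]
    # sequence position within each chain, protein residues only
    seq_pos: dict[int, tuple[str, int]] = {}
    counters: dict[str, int] = {}
    for idx, k in enumerate(node_keys):
        if k[2] in STANDARD_AA:
            counters[k[0]] = counters.get(k[0], 0) + 1
            seq_pos[idx] = (k[0], counters[k[0]])

    atom_to_node = np.full(topology.n_atoms, -1, dtype=int)
    for idx, heavy in enumerate(heavy_per_node):
        atom_to_node[heavy] = idx
    heavy_all = np.nonzero(atom_to_node >= 0)[0]

    n_nodes = len(node_keys)
    counts = np.zeros((n_nodes, n_nodes), dtype=np.int64)
    for f in range(series.n_frames):
        tree = cKDTree(series.coords[f, heavy_all])
        seen: set[tuple[int, int]] = set()
        for a, b in tree.query_pairs(cutoff):
            na, nb = atom_to_node[heavy_all[a]], atom_to_node[heavy_all[b]]
            if na == nb:
                continue
            pair = (na, nb) if na < nb else (nb, na)
            seen.add(pair)
        for pair in seen:
            counts[pair] += 1

    g = nx.Graph()
    g.add_nodes_from(labels)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if i in seq_pos and j in seq_pos:
                ci, pi = seq_pos[i]
                cj, pj = seq_pos[j]
                if ci == cj and abs(pi - pj) <= neighbor_exclusion:
                    continue
            occ = counts[i, j] / series.n_frames
            if occ >= min_occupancy:
                g.add_edge(labels[i], labels[j], occupancy=float(occ))
    return g


def correlation_matrix(node_traj: NodeTrajectory) -> np.ndarray:
    """Normalized displacement cross-correlation C_ij over frames.

    Raises :class:`NetworkError` naming any zero-variance node, for
    which the correlation is undefined.
    """
    d = node_traj.displacements
    if d.shape[0] < 2:
        raise NetworkError("correlation requires at least 2 frames")
    inner = np.einsum("tik,tjk->ij", d, d) / d.shape[0]
    var = np.diag(inner).copy()
    dead = np.nonzero(var <= 0)[0]
    if len(dead):
        names = ", ".join(node_traj.node_ids[i] for i in dead)
        raise NetworkError(f"zero-variance node(s): {names}")
    c = inner / np.sqrt(np.outer(var, var))
    np.clip(c, -1.0, 1.0, out=c)
    np.fill_diagonal(c, 1.0)
    return c


def weight_edges(graph: nx.Graph, c: np.ndarray, node_ids: list[str]) -> nx.Graph:
    """Attach w = −ln|C| weights (and |C| affinities) to contact edges.

    |C| is floored at 1e−12 (logged) to keep weights finite.
    """
    index = {n: i for i, n in enumerate(node_ids)}
    g = graph.copy()
    floored = 0
    for u, v, data in g.edges(data=True):
        try:
            cij = float(c[index[u], index[v]])
        except KeyError as exc:
            raise NetworkError(f"edge endpoint {exc.args[0]!r} has no correlation entry") from exc
        mag = abs(cij)
        if mag < CORRELATION_FLOOR:
            mag = CORRELATION_FLOOR
            floored += 1
        data["correlation"] = cij
        data["affinity"] = mag
        data["weight"] = -math.log(mag)
    if floored:
        logger.warning("floored |C| on %d edge(s) to keep weights finite", floored)
    return g


def edge_betweenness(graph: nx.Graph) -> dict[tuple[str, str], float]:
    """Weighted edge betweenness: shortest paths use w as length.

    Unnormalized sum over unordered node pairs with equal splitting
    among degenerate shortest paths.
    """
    weight = "weight" if any("weight" in d for _, _, d in graph.edges(data=True)) else None
    raw = nx.edge_betweenness_centrality(graph, weight=weight, normalized=False)
    return {_edge_key(u, v): val for (u, v), val in raw.items()}


def _edge_key(u, v) -> tuple:
    return (u, v) if str(u) <= str(v) else (v, u)


@dataclass
class CommunityPartition:
    communities: list[frozenset]
    modularity: float
    critical_nodes: set = field(default_factory=set)
    critical_edges: set = field(default_factory=set)

    def label_of(self) -> dict:
        return {n: i for i, comm in enumerate(self.communities) for n in comm}


def _affinity_graph(graph: nx.Graph) -> nx.Graph:
    """Copy of the graph with an ``affinity`` (coupling strength) per edge.

    Modularity needs an affinity, not a distance: where only the −log|C|
    distance ``weight`` is present, affinity = exp(−w) = |C|; with no
    weights at all every edge counts 1.
    """
    g = graph.copy()
    for _, _, data in g.edges(data=True):
        if "affinity" not in data:
            data["affinity"] = math.exp(-data["weight"]) if "weight" in data else 1.0
    return g


def _modularity(affinity_graph: nx.Graph, communities: list[frozenset]) -> float:
    return nx.community.modularity(affinity_graph, communities, weight="affinity")


def _components(graph: nx.Graph) -> list[frozenset]:
    comps = [frozenset(c) for c in nx.connected_components(graph)]
    return sorted(comps, key=lambda c: sorted(map(str, c)))


def girvan_newman(graph: nx.Graph) -> CommunityPartition:
    """Girvan–Newman community detection with a modularity stop rule.

    Repeatedly removes the edge of highest weighted betweenness (ties:
    lexicographically smallest edge) and returns the connected-component
    partition of highest modularity seen along the removal sequence
    (ties: the earliest, i.e. coarsest, partition).  Modularity is
    evaluated on edge affinities |C| (see :func:`_affinity_graph`).
    """
    if graph.number_of_nodes() == 0:
        raise NetworkError("empty graph")
    aff = _affinity_graph(graph)
    work = graph.copy()
    best = _components(work)
    best_q = _modularity(aff, best) if graph.number_of_edges() else 0.0
    while work.number_of_edges():
        bw = edge_betweenness(work)
        top = max(bw.values())
        candidates = sorted(
            (e for e, v in bw.items() if abs(v - top) <= 1e-12 * max(1.0, top)),
            key=lambda e: (str(e[0]), str(e[1])),
        )
        work.remove_edge(*candidates[0])
        partition = _components(work)
        q = _modularity(aff, partition)
        if q > best_q + 1e-12:
            best_q, best = q, partition
    part = CommunityPartition(communities=best, modularity=float(best_q))
    part.critical_nodes, part.critical_edges = critical_elements(part, graph)
    return part


def critical_elements(
    partition: CommunityPartition, graph: nx.Graph
) -> tuple[set, set]:
    """Highest-betweenness inter-community edge per community pair.

    For each pair of communities joined by at least one edge of the
    original graph, the connecting edge of highest (weighted)
    betweenness is critical; its endpoints are critical nodes.
    """
    if len(partition.communities) < 2 or graph.number_of_edges() == 0:
        return set(), set()
    bw = edge_betweenness(graph)
    label = partition.label_of()
    per_pair: dict[tuple[int, int], list[tuple]] = {}
    for u, v in graph.edges():
        cu, cv = label[u], label[v]
        if cu == cv:
            continue
        pair = (min(cu, cv), max(cu, cv))
        per_pair.setdefault(pair, []).append(_edge_key(u, v))
    nodes: set = set()
    edges: set = set()
    for pair, elist in per_pair.items():
        elist.sort(key=lambda e: (-bw[e], str(e[0]), str(e[1])))
        u, v = elist[0]
        edges.add((u, v))
        nodes.update((u, v))
    return nodes, edges


def network_edge_table(graph: nx.Graph, partition: CommunityPartition | None = None):
    """Flat per-edge records for TSV export."""
    bw = edge_betweenness(graph)
    label = partition.label_of() if partition else {}
    rows = []
    for u, v, data in graph.edges(data=True):
        key = _edge_key(u, v)
        rows.append(
            {
                "node_i": key[0],
                "node_j": key[1],
                "occupancy": data.get("occupancy", float("nan")),
                "correlation": data.get("correlation", float("nan")),
                "weight": data.get("weight", float("nan")),
                "betweenness": bw[key],
                "community_i": label.get(key[0], -1),
                "community_j": label.get(key[1], -1),
                "critical": bool(partition and key in partition.critical_edges),
            }
        )
    rows.sort(key=lambda r: (r["node_i"], r["node_j"]))
    return rows
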