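"""Independent brute-force oracles used to validate the library.

Everything here is deliberately naive (exhaustive enumeration, O(n³)
loops) and shares no code with the implementation under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# Weighted edge betweenness by exhaustive shortest-path enumeration
# ---------------------------------------------------------------------------

def _weights(graph):
    w = {}
    for u, v, data in graph.edges(data=True):
        w[(u, v)] = w[(v, u)] = float(data.get("weight", 1.0))
    return w


def _floyd_warshall(nodes, w):
    dist = {u: {v: math.inf for v in nodes} for u in nodes}
    for u in nodes:
        dist[u][u] = 0.0
    for (u, v), wt in w.items():
        dist[u][v] = min(dist[u][v], wt)
    for k in nodes:
        for i in nodes:
            for j in nodes:
                nd = dist[i][k] + dist[k][j]
                if nd < dist[i][j]:
                    dist[i][j] = nd
    return dist


def _all_shortest_paths(graph, w, dist, s, t, tol=1e-10):
    """Every shortest s→t path, found by distance-pruned DFS."""
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(list(path))
            return
        for v in graph.neighbors(u):
            if v in path:
                continue
            walked = sum(w[(path[i], path[i + 1])] for i in range(len(path) - 1))
            if abs(walked + w[(u, v)] + dist[v][t] - dist[s][t]) <= tol:
                extend(path + [v])

    extend([s])
    return paths


def brute_force_edge_betweenness(graph):
    """Unnormalized weighted edge betweenness over unordered node pairs."""
    nodes = sorted(graph.nodes, key=str)
    w = _weights(graph)
    dist = _floyd_warshall(nodes, w)
    bw = {tuple(sorted(e, key=str)): 0.0 for e in graph.edges}
    for s, t in itertools.combinations(nodes, 2):
        if math.isinf(dist[s][t]):
            continue
        paths = _all_shortest_paths(graph, w, dist, s, t)
        share = 1.0 / len(paths)
        for path in paths:
            for a, b in zip(path, path[1:]):
                bw[tuple(sorted((a, b), key=str))] += share
    return bw


# ---------------------------------------------------------------------------
# Modularity (direct double-sum formula) and exhaustive Girvan–Newman
# ---------------------------------------------------------------------------

def direct_modularity(graph, communities):
    """Q = (1/2m) Σ_ij (A_ij − k_i k_j / 2m) δ(c_i, c_j) on edge affinities."""
    nodes = sorted(graph.nodes, key=str)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        aff = data.get("affinity")
        if aff is None:
            aff = math.exp(-data["weight"]) if "weight" in data else 1.0
        a[index[u], index[v]] = a[index[v], index[u]] = aff
    two_m = a.sum()
    if two_m == 0:
        return 0.0
    k = a.sum(axis=1)
    label = {}
    for c, comm in enumerate(communities):
        for node in comm:
            label[index[node]] = c
    q = 0.0
    for i in range(n):
        for j in range(n):
            if label[i] == label[j]:
                q += a[i, j] - k[i] * k[j] / two_m
    return q / two_m


def girvan_newman_oracle(graph):
    """Naive re-implementation of the edge-removal community search.

    Removes the highest-betweenness edge (brute-force betweenness, ties
    lexicographic), tracking the connected-component partition of
    maximum direct-formula modularity.
    """
    import networkx as nx

    work = graph.copy()
    best = _components(work)
    best_q = direct_modularity(graph, best) if graph.number_of_edges() else 0.0
    while work.number_of_edges():
        bw = brute_force_edge_betweenness(work)
        top = max(bw.values())
        cands = sorted(
            (e for e, v in bw.items() if abs(v - top) <= 1e-12 * max(1.0, top)),
            key=lambda e: (str(e[0]), str(e[1])),
        )
        work.remove_edge(*cands[0])
        part = _components(work)
        q = direct_modularity(graph, part)
        if q > best_q + 1e-12:
            best_q, best = q, part
    return best, best_q


def _components(graph):
    import networkx as nx

    return sorted(
        (frozenset(c) for c in nx.connected_components(graph)),
        key=lambda c: sorted(map(str, c)),
    )


def best_bipartition_modularity(graph):
    """Exhaustive best 2-partition (and the trivial 1-partition) by modularity."""
    nodes = sorted(graph.nodes, key=str)
    best, best_q = [frozenset(nodes)], direct_modularity(graph, [frozenset(nodes)])
    rest = nodes[1:]
    for r in range(len(rest) + 1):
        for combo in itertools.combinations(rest, r):
            side_a = frozenset([nodes[0], *combo])
            side_b = frozenset(n for n in nodes if n not in side_a)
            if not side_b:
                continue
            part = [side_a, side_b]
            q = direct_modularity(graph, part)
            if q > best_q + 1e-12:
                best, best_q = part, q
    return set(best), best_q


# ---------------------------------------------------------------------------
# Naive O(n³) average-linkage agglomeration
# ---------------------------------------------------------------------------

def naive_average_linkage(matrix, cutoff):
    """Merge the closest pair of clusters (average distance) while ≤ cutoff."""
    matrix = np.asarray(matrix, dtype=float)
    clusters = [[i] for i in range(matrix.shape[0])]
    while len(clusters) > 1:
        best_pair, best_d = None, math.inf
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([matrix[i, j] for i in clusters[a] for j in clusters[b]])
                if d < best_d - 1e-12:
                    best_pair, best_d = (a, b), d
        if best_d > cutoff:
            break
        a, b = best_pair
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return {frozenset(c) for c in clusters}


# ---------------------------------------------------------------------------
# Naive contact-edge scan
# ---------------------------------------------------------------------------

def naive_contact_edges(topology, series, cutoff, min_occupancy, neighbor_exclusion):
    """All-pairs heavy-atom distance scan reproducing the contact criteria."""
    from trajcomm.io import STANDARD_AA

    by_res = topology.atoms_by_residue()
    keys = [
        k for k in by_res
        if k[2] in STANDARD_AA or topology.atoms[by_res[k][0]].is_ligand
    ]
    heavy = {
        k: [i for i in by_res[k] if topology.atoms[i].is_heavy] for k in keys
    }
    pos = {}
    counter = {}
    for k in keys:
        if k[2] in STANDARD_AA:
            counter[k[0]] = counter.get(k[0], 0) + 1
            pos[k] = (k[0], counter[k[0]])
    edges = set()
    for a in range(len(keys)):
        for b in range(a + 1, len(keys)):
            ka, kb = keys[a], keys[b]
            if ka in pos and kb in pos and pos[ka][0] == pos[kb][0]:
                if abs(pos[ka][1] - pos[kb][1]) <= neighbor_exclusion:
                    continue
            hits = 0
            for f in range(series.n_frames):
                found = False
                for i in heavy[ka]:
                    for j in heavy[kb]:
                        if np.linalg.norm(series.coords[f, i] - series.coords[f, j]) <= cutoff:
                            found = True
                            break
                    if found:
                        break
                hits += found
            if hits / series.n_frames >= min_occupancy:
                edges.add(frozenset((f"{ka[2]}_{ka[1]}", f"{kb[2]}_{kb[1]}")))
    return edges


# ---------------------------------------------------------------------------
# Naive interaction scan (hydrophobic + donor/acceptor hydrogen bonds)
# ---------------------------------------------------------------------------

def naive_interaction_scan(topology, series):
    """Plain-loop hbond/hydrophobic detection with the package's criteria."""
    from trajcomm.io import STANDARD_AA

    atoms = topology.atoms
    n = len(atoms)
    coords0 = series.coords[0]

    def bonded(i, j):
        d = np.linalg.norm(coords0[i] - coords0[j])
        both_heavy = atoms[i].is_heavy and atoms[j].is_heavy
        return d <= (1.7 if both_heavy else 1.2) and d > 0

    neighbors = [[j for j in range(n) if j != i and bonded(i, j)] for i in range(n)]
    polar = {"N", "O", "S"}

    def apolar_c(i):
        return atoms[i].element.upper() == "C" and not any(
            atoms[j].element.upper() in polar for j in neighbors[i]
        )

    def angle(p, vertex, q):
        v1, v2 = p - vertex, q - vertex
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))

    events = set()
    for f in range(series.n_frames):
        c = series.coords[f]
        for i in range(n):
            for j in range(n):
                ai, aj = atoms[i], atoms[j]
                prot_i = ai.residue_name in STANDARD_AA
                prot_j = aj.residue_name in STANDARD_AA
                # hydrophobic (i protein C, j ligand C)
                if (
                    prot_i and aj.is_ligand and apolar_c(i) and apolar_c(j)
                    and np.linalg.norm(c[i] - c[j]) <= 3.6
                ):
                    events.add((f, f"{ai.residue_name}_{ai.residue_number}", aj.name, "hydrophobic"))
                # hbond with i = donor heavy, j = acceptor
                if (
                    ai.element.upper() in polar
                    and aj.element.upper() in {"N", "O"}
                    and ((prot_i and aj.is_ligand) or (ai.is_ligand and prot_j))
                ):
                    for h in neighbors[i]:
                        if atoms[h].element.upper() != "H":
                            continue
                        if np.linalg.norm(c[h] - c[j]) > 2.5:
                            continue
                        if angle(c[i], c[h], c[j]) < 120.0:
                            continue
                        heavies = [x for x in neighbors[j] if atoms[x].is_heavy]
                        if heavies and not any(
                            angle(c[x], c[j], c[h]) >= 90.0 for x in heavies
                        ):
                            continue
                        res = (
                            f"{ai.residue_name}_{ai.residue_number}"
                            if prot_i
                            else f"{aj.residue_name}_{aj.residue_number}"
                        )
                        lig = aj.name if aj.is_ligand else ai.name
                        events.add((f, res, lig, "hbond"))
    return events
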