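"""Dynamical network model: contacts, correlations, weights, communities."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from trajcomm.io import FrameSeries, select
from trajcomm.network import (
    NetworkError,
    NodeTrajectory,
    build_contact_graph,
    build_node_trajectory,
    correlation_matrix,
    critical_elements,
    edge_betweenness,
    girvan_newman,
    weight_edges,
)
from trajcomm.synth import EnsembleSpec, make_reference, sample_correlated_ensemble

from _oracles import (
    best_bipartition_modularity,
    brute_force_edge_betweenness,
    girvan_newman_oracle,
    naive_contact_edges,
)


def _static_series(ref: FrameSeries, n_frames: int) -> FrameSeries:
    return FrameSeries(np.repeat(ref.coords, n_frames, axis=0))


def _node_traj(disp: np.ndarray) -> NodeTrajectory:
    disp = disp - disp.mean(axis=0)
    ids = [f"ALA_{i + 1}" for i in range(disp.shape[1])]
    return NodeTrajectory(ids, disp, disp)


def _two_cliques(k: int = 5):
    g = nx.Graph()
    for base in (0, k):
        for i in range(k):
            for j in range(i + 1, k):
                g.add_edge(base + i, base + j)
    g.add_edge(0, k)
    return g


class TestContactGraph:
    def test_close_pair_has_full_occupancy(self):
        topology, ref = make_reference(6)
        coords = ref.coords.copy()
        # move residue 6 next to residue 1 (sequence distance 5 > exclusion)
        ca1 = coords[0, 0]
        for a_idx, atom in enumerate(topology.atoms):
            if atom.residue_number == 6:
                coords[0, a_idx] = ca1 + [0.0, 0.0, 3.0 if atom.name == "CA" else 4.0]
        series = _static_series(FrameSeries(coords), 4)
        g = build_contact_graph(topology, series, cutoff=4.5, min_occupancy=0.75)
        assert g.has_edge("ALA_1", "ALA_6")
        assert g.edges["ALA_1", "ALA_6"]["occupancy"] == 1.0

    def test_occupancy_boundary_is_inclusive(self):
        """74/100 frames in contact at threshold 0.75 → no edge; 75 → edge."""
        topology, ref = make_reference(6)
        near = ref.coords.copy()
        far = ref.coords.copy()
        for a_idx, atom in enumerate(topology.atoms):
            if atom.residue_number == 6:
                near[0, a_idx] = ref.coords[0, 0] + [0, 0, 3.0]
                far[0, a_idx] = ref.coords[0, 0] + [0, 0, 50.0]
        for n_near, expect_edge in ((74, False), (75, True)):
            coords = np.concatenate(
                [np.repeat(near, n_near, axis=0), np.repeat(far, 100 - n_near, axis=0)]
            )
            g = build_contact_graph(topology, FrameSeries(coords), min_occupancy=0.75)
            assert g.has_edge("ALA_1", "ALA_6") is expect_edge

    def test_sequence_neighbors_excluded(self):
        topology, ref = make_reference(10, "helix")
        series = _static_series(ref, 2)
        g = build_contact_graph(topology, series, neighbor_exclusion=2)
        for i, j in g.edges:
            ni, nj = int(i.split("_")[1]), int(j.split("_")[1])
            assert abs(ni - nj) > 2

    def test_matches_naive_distance_scan(self):
        topology, ref = make_reference(10, "helix")
        series = _static_series(ref, 3)
        for excl in (0, 2):
            g = build_contact_graph(topology, series, neighbor_exclusion=excl)
            ours = {frozenset(e) for e in g.edges}
            oracle = naive_contact_edges(topology, series, 4.5, 0.75, excl)
            assert ours == oracle

    def test_ligand_contributes_a_node(self):
        topology, ref = make_reference(8, "helix", with_ligand=True)
        series = _static_series(ref, 2)
        g = build_contact_graph(topology, series, neighbor_exclusion=0)
        assert any(n.startswith("LIG") for n in g.nodes)


class TestCorrelationMatrix:
    def test_identical_displacements_give_one(self, rng):
        d = rng.normal(size=(200, 1, 3))
        disp = np.concatenate([d, d], axis=1)
        c = correlation_matrix(_node_traj(disp))
        assert c[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_inverted_displacements_give_minus_one(self, rng):
        d = rng.normal(size=(200, 1, 3))
        disp = np.concatenate([d, -d], axis=1)
        c = correlation_matrix(_node_traj(disp))
        assert c[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_planted_block_recovered(self):
        block = list(range(4, 14))
        topology, series = sample_correlated_ensemble(
            EnsembleSpec(n_residues=30, blocks=[(block, 0.6)], n_frames=4000, seed=31)
        )
        nodes = build_node_trajectory(topology, series, align=False)
        c = correlation_matrix(nodes)
        intra = c[np.ix_(block, block)][np.triu_indices(len(block), 1)]
        outside = [i for i in range(30) if i not in block]
        inter = c[np.ix_(block, outside)]
        assert intra.mean() == pytest.approx(0.6, abs=0.03)
        assert np.abs(inter).mean() < 0.03

    def test_zero_variance_node_is_named(self, rng):
        disp = rng.normal(size=(100, 3, 3))
        disp[:, 1, :] = 0.0
        with pytest.raises(NetworkError, match="ALA_2"):
            correlation_matrix(_node_traj(disp))

    @given(
        hnp.arrays(
            dtype=np.float64,
            shape=st.tuples(st.integers(4, 30), st.integers(2, 6), st.just(3)),
            elements=st.floats(min_value=-5.0, max_value=5.0, allow_nan=False),
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_symmetric_unit_diagonal_property(self, disp):
        traj = _node_traj(disp)
        if np.any(np.einsum("tik,tik->i", traj.displacements, traj.displacements) <= 0):
            return  # degenerate node: undefined correlation, covered elsewhere
        c = correlation_matrix(traj)
        np.testing.assert_allclose(c, c.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(c), 1.0, atol=1e-12)
        assert np.all(np.abs(c) <= 1.0 + 1e-12)


class TestWeightEdges:
    @pytest.mark.parametrize(
        "cij,expected",
        [(1.0, 0.0), (math.exp(-1.0), 1.0), (0.5, math.log(2.0)), (-0.5, math.log(2.0))],
    )
    def test_known_weights(self, cij, expected):
        g = nx.Graph([("A", "B")])
        c = np.array([[1.0, cij], [cij, 1.0]])
        w = weight_edges(g, c, ["A", "B"])
        assert w.edges["A", "B"]["weight"] == pytest.approx(expected, abs=1e-12)

    def test_zero_correlation_floored_and_logged(self, caplog):
        g = nx.Graph([("A", "B")])
        c = np.array([[1.0, 0.0], [0.0, 1.0]])
        with caplog.at_level("WARNING"):
            w = weight_edges(g, c, ["A", "B"])
        assert np.isfinite(w.edges["A", "B"]["weight"])
        assert "floored" in caplog.text

    def test_weight_monotone_decreasing_in_correlation(self):
        g = nx.Graph([("A", "B")])
        weights = []
        for cij in (0.1, 0.3, 0.6, 0.9, 1.0):
            c = np.array([[1.0, cij], [cij, 1.0]])
            weights.append(weight_edges(g, c, ["A", "B"]).edges["A", "B"]["weight"])
        assert weights == sorted(weights, reverse=True)
        assert all(w >= 0 for w in weights)


class TestEdgeBetweenness:
    def test_path_graph_closed_form(self):
        g = nx.path_graph(["A", "B", "C"])
        bw = edge_betweenness(g)
        assert bw[("A", "B")] == pytest.approx(2.0)
        assert bw[("B", "C")] == pytest.approx(2.0)

    def test_bridge_has_strictly_maximal_betweenness(self):
        g = _two_cliques(5)
        bw = edge_betweenness(g)
        bridge = bw[(0, 5)]
        assert all(v < bridge for e, v in bw.items() if e != (0, 5))

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        g = nx.gnp_random_graph(n, 0.6, seed=int(rng.integers(1 << 30)))
        for u, v in g.edges:
            g.edges[u, v]["weight"] = float(rng.uniform(0.5, 2.0))
        if g.number_of_edges() == 0:
            return
        ours = edge_betweenness(g)
        oracle = brute_force_edge_betweenness(g)
        assert set(ours) == set(oracle)
        for e in ours:
            assert ours[e] == pytest.approx(oracle[e], abs=1e-9)


class TestGirvanNewman:
    def test_complete_graph_single_community(self):
        part = girvan_newman(nx.complete_graph(5))
        assert len(part.communities) == 1
        assert part.critical_edges == set()

    def test_two_cliques_split_at_bridge(self):
        g = _two_cliques(5)
        part = girvan_newman(g)
        got = {frozenset(c) for c in part.communities}
        assert got == {frozenset(range(5)), frozenset(range(5, 10))}
        best, best_q = best_bipartition_modularity(g)
        assert got == {frozenset(c) for c in best}
        assert part.modularity == pytest.approx(best_q, abs=1e-9)

    def test_planted_three_blocks_recovered(self):
        hits = 0
        n_draws = 10
        for seed in range(n_draws):
            g = nx.planted_partition_graph(3, 8, 0.9, 0.05, seed=seed)
            part = girvan_newman(nx.Graph(g))
            got = {frozenset(c) for c in part.communities}
            planted = {frozenset(range(b * 8, (b + 1) * 8)) for b in range(3)}
            hits += got == planted
        assert hits >= n_draws - 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_reimplementation(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(4, 9))
        g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1 << 30)))
        for u, v in g.edges:
            g.edges[u, v]["weight"] = float(rng.uniform(0.5, 2.0))
        if g.number_of_edges() == 0:
            return
        part = girvan_newman(g)
        oracle_part, oracle_q = girvan_newman_oracle(g)
        assert {frozenset(c) for c in part.communities} == {frozenset(c) for c in oracle_part}
        assert part.modularity == pytest.approx(oracle_q, abs=1e-9)

    def test_relabeling_invariance(self, rng):
        g = _two_cliques(4)
        mapping = {n: f"n{(n * 7) % 8}" for n in g.nodes}
        relabeled = nx.relabel_nodes(g, mapping)
        p1 = girvan_newman(g)
        p2 = girvan_newman(relabeled)
        mapped = {frozenset(mapping[n] for n in c) for c in p1.communities}
        assert mapped == {frozenset(c) for c in p2.communities}

    def test_recovered_modularity_at_least_planted(self):
        for seed in range(5):
            g = nx.planted_partition_graph(2, 8, 0.9, 0.05, seed=seed)
            g = nx.Graph(g)
            part = girvan_newman(g)
            planted = [frozenset(range(8)), frozenset(range(8, 16))]
            planted_q = nx.community.modularity(g, planted)
            assert part.modularity >= planted_q - 1e-9

    def test_empty_graph_rejected(self):
        with pytest.raises(NetworkError):
            girvan_newman(nx.Graph())


class TestCriticalElements:
    def test_single_bridge_and_endpoints(self):
        part = girvan_newman(_two_cliques(5))
        assert part.critical_edges == {(0, 5)}
        assert part.critical_nodes == {0, 5}

    def test_parallel_bridges_only_higher_betweenness_kept(self):
        g = _two_cliques(4)  # bridge (0, 4), uniform weights
        g.add_edge(1, 5)
        # make the (1, 5) bridge long so shortest paths avoid it
        for u, v in g.edges:
            g.edges[u, v]["weight"] = 1.0
        g.edges[1, 5]["weight"] = 10.0
        part = girvan_newman(g)
        assert {frozenset(c) for c in part.communities} == {
            frozenset(range(4)),
            frozenset(range(4, 8)),
        }
        assert part.critical_edges == {(0, 4)}

    def test_single_community_empty_sets(self):
        part = girvan_newman(nx.complete_graph(4))
        nodes, edges = critical_elements(part, nx.complete_graph(4))
        assert nodes == set() and edges == set()


class TestEndToEndOnSyntheticTrajectory:
    def test_contact_correlation_community_pipeline(self):
        """Two spatially separate, internally correlated halves of a helix
        split into two communities."""
        n = 16
        blocks = [(list(range(0, 8)), 0.8), (list(range(8, 16)), 0.8)]
        topology, series = sample_correlated_ensemble(
            EnsembleSpec(n_residues=n, geometry="helix", sigma=0.3,
                         blocks=blocks, n_frames=500, seed=41)
        )
        g = build_contact_graph(topology, series, cutoff=7.0, min_occupancy=0.5,
                                neighbor_exclusion=0)
        nodes = build_node_trajectory(topology, series, align=False)
        c = correlation_matrix(nodes)
        weighted = weight_edges(g, c, nodes.node_ids)
        part = girvan_newman(weighted)
        label = part.label_of()
        first = {label[f"ALA_{i}"] for i in range(1, 9)}
        second = {label[f"ALA_{i}"] for i in range(9, 17)}
        assert len(first) == 1 and len(second) == 1 and first != second
        assert part.critical_nodes
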