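"""Prior-knowledge network reading, pruning, distances, and spectral radius."""

import numpy as np
import pytest

from phosphodyn import pkn


def _write_edges(tmp_path, rows, header="source\ttarget\tsign"):
    path = tmp_path / "net.tsv"
    path.write_text(header + "\n" + "\n".join(rows) + ("\n" if rows else ""))
    return path


class TestReadNetwork:
    def test_three_line_file(self, tmp_path):
        path = _write_edges(tmp_path, ["A\tB\t1", "B\tC\t-1"])
        net = pkn.read_network(path)
        assert net.node_ids == ["A", "B", "C"]
        assert net.n_edges == 2
        assert net.sign_matrix[net.node_index("B"), net.node_index("A")] == 1
        assert net.sign_matrix[net.node_index("C"), net.node_index("B")] == -1

    def test_sign_token_words(self, tmp_path):
        path = _write_edges(tmp_path, ["A\tB\tactivation", "B\tC\tinhibition",
                                       "C\tD\tstimulation"])
        net = pkn.read_network(path)
        signs = dict(((s, t), sg) for s, t, sg in net.edges)
        assert signs == {("A", "B"): 1, ("B", "C"): -1, ("C", "D"): 1}

    def test_empty_file_errors(self, tmp_path):
        path = _write_edges(tmp_path, [])
        with pytest.raises(ValueError, match="no edges"):
            pkn.read_network(path)

    def test_duplicate_edge_collapsed(self, tmp_path):
        path = _write_edges(tmp_path, ["A\tB\t1", "A\tB\t1"])
        assert pkn.read_network(path).n_edges == 1

    def test_conflicting_duplicate_rejected(self, tmp_path):
        path = _write_edges(tmp_path, ["A\tB\t1", "A\tB\t-1"])
        with pytest.raises(ValueError, match="A->B"):
            pkn.read_network(path)

    def test_missing_column_errors(self, tmp_path):
        path = _write_edges(tmp_path, ["A\tB"], header="source\ttarget")
        with pytest.raises(ValueError, match="missing columns"):
            pkn.read_network(path)

    def test_unmappable_sign_errors(self, tmp_path):
        path = _write_edges(tmp_path, ["A\tB\tmaybe"])
        with pytest.raises(ValueError, match="unmappable sign"):
            pkn.read_network(path)

    def test_custom_dialect(self, tmp_path):
        path = _write_edges(tmp_path, ["A\tB\t1"], header="from\tto\tmode")
        net = pkn.read_network(path, dialect={"source": "from", "target": "to",
                                              "sign": "mode"})
        assert net.edges == [("A", "B", 1)]


def _brute_force_reachable(edges, source):
    """Independent BFS oracle over an adjacency dict."""
    adj = {}
    for s, t, _ in edges:
        adj.setdefault(s, []).append(t)
    seen = {source}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj.get(u, []):
                if v not in seen:
                    seen.add(v)
                    nxt.append(v)
        frontier = nxt
    return seen


class TestPruneReachable:
    def test_chain_with_isolated_node(self):
        net = pkn.network_from_edges(
            ["A", "B", "C", "D"], [("A", "B", 1), ("B", "C", 1)])
        pruned = pkn.prune_reachable(net, "A")
        assert pruned.node_ids == ["A", "B", "C"]

    def test_source_without_out_edges_is_singleton(self):
        net = pkn.network_from_edges(["A", "B"], [("A", "B", 1)])
        pruned = pkn.prune_reachable(net, "B")
        assert pruned.node_ids == ["B"]
        assert pruned.n_edges == 0

    def test_unknown_source(self, tiny_network):
        with pytest.raises(KeyError):
            pkn.prune_reachable(tiny_network, "nope")

    def test_matches_bfs_oracle_on_random_digraph(self):
        rng = np.random.default_rng(7)
        nodes = [f"n{i}" for i in range(50)]
        edges = []
        seen = set()
        for _ in range(120):
            s, t = rng.choice(nodes, size=2, replace=False)
            if (s, t) not in seen:
                seen.add((str(s), str(t)))
                edges.append((str(s), str(t), 1))
        net = pkn.network_from_edges(nodes, edges)
        for source in ("n0", "n17", "n42"):
            pruned = pkn.prune_reachable(net, source)
            assert set(pruned.node_ids) == _brute_force_reachable(edges, source)

    def test_idempotent_and_subgraph(self, tiny_network):
        once = pkn.prune_reachable(tiny_network, "R")
        twice = pkn.prune_reachable(once, "R")
        assert once.node_ids == twice.node_ids
        assert set(once.edges) <= set(tiny_network.edges)


class TestPruneByWeight:
    def _tnet(self):
        net = pkn.network_from_edges(
            ["A", "B", "C", "D"],
            [("A", "B", 1), ("B", "C", -1), ("C", "D", 1)])
        W = np.zeros((4, 4))
        idx = {n: i for i, n in enumerate(net.node_ids)}
        W[idx["B"], idx["A"]] = 0.05
        W[idx["C"], idx["B"]] = -0.2
        W[idx["D"], idx["C"]] = 0.1
        return pkn.TrainedNetwork(net, W)

    def test_boundary_kept(self):
        pruned = pkn.prune_by_weight(self._tnet(), 0.1)
        kept = {(s, t) for s, t, _ in pruned.base.edges}
        assert kept == {("B", "C"), ("C", "D")}  # 0.05 dropped, 0.1 kept

    def test_threshold_zero_is_identity(self):
        tnet = self._tnet()
        pruned = pkn.prune_by_weight(tnet, 0.0)
        assert pruned.base.edges == tnet.base.edges

    def test_threshold_above_max_empties(self):
        assert pkn.prune_by_weight(self._tnet(), 0.5).base.n_edges == 0

    def test_negative_threshold_errors(self):
        with pytest.raises(ValueError):
            pkn.prune_by_weight(self._tnet(), -0.1)

    def test_composition_equals_max_threshold(self):
        tnet = self._tnet()
        a = pkn.prune_by_weight(pkn.prune_by_weight(tnet, 0.08), 0.15)
        b = pkn.prune_by_weight(tnet, 0.15)
        assert a.base.edges == b.base.edges


class TestShortestDistance:
    def test_chain(self):
        net = pkn.network_from_edges(["A", "B", "C"],
                                     [("A", "B", 1), ("B", "C", 1)])
        assert pkn.shortest_signaling_distance(net, "A", "C") == 2

    def test_self_distance_zero(self, tiny_network):
        assert pkn.shortest_signaling_distance(tiny_network, "R", "R") == 0

    def test_unreachable_sentinel(self):
        net = pkn.network_from_edges(["A", "B"], [("A", "B", 1)])
        assert pkn.shortest_signaling_distance(net, "B", "A") == pkn.UNREACHABLE

    def test_unknown_node(self, tiny_network):
        with pytest.raises(KeyError):
            pkn.shortest_signaling_distance(tiny_network, "R", "nope")

    def test_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        nodes = [f"n{i}" for i in range(30)]
        edges = []
        seen = set()
        for _ in range(70):
            s, t = rng.choice(nodes, size=2, replace=False)
            if (s, t) not in seen:
                seen.add((str(s), str(t)))
                edges.append((str(s), str(t), 1))
        net = pkn.network_from_edges(nodes, edges)
        adj = {}
        for s, t, _ in edges:
            adj.setdefault(s, []).append(t)

        def enumerate_shortest(src, dst, max_len=6):
            # exhaustive breadth-limited path expansion, no library calls
            if src == dst:
                return 0
            frontier = {src}
            visited = {src}
            for depth in range(1, max_len + 1):
                frontier = {v for u in frontier for v in adj.get(u, [])}
                if dst in frontier:
                    return depth
                visited |= frontier
            return None

        for src in ("n1", "n5"):
            for dst in ("n2", "n9", "n20"):
                expected = enumerate_shortest(src, dst)
                got = pkn.shortest_signaling_distance(net, src, dst)
                if expected is not None:
                    assert got == expected
                else:
                    assert got == pkn.UNREACHABLE or got > 6


class TestSpectralRadius:
    def test_identity(self):
        assert pkn.spectral_radius(np.eye(4), 5) == pytest.approx(1.0)

    def test_diagonal_dominant(self):
        W = np.diag([0.2, -0.9])
        assert pkn.spectral_radius(W, 100) == pytest.approx(0.9, abs=1e-6)

    def test_non_square_errors(self):
        with pytest.raises(ValueError):
            pkn.spectral_radius(np.ones((2, 3)))

    def test_within_5pct_of_eig_oracle_on_random(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            W = np.abs(rng.normal(size=(8, 8)))  # positive: real dominant eig
            rho_true = max(abs(np.linalg.eigvals(W)))
            rho_est = pkn.spectral_radius(W, 50)
            assert abs(rho_est - rho_true) / rho_true < 0.05

    def test_accuracy_monotone_on_symmetric(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(6, 6))
        W = (A + A.T) / 2
        rho_true = max(abs(np.linalg.eigvals(W)))
        errs = [abs(pkn.spectral_radius(W, k) - rho_true) for k in (2, 8, 32)]
        assert errs[0] >= errs[1] - 1e-12 and errs[1] >= errs[2] - 1e-12

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        W = rng.normal(size=(5, 5))
        rho, grad = pkn.spectral_radius_with_grad(W, 5)
        eps = 1e-6
        for idx in [(0, 1), (2, 2), (4, 0)]:
            Wp, Wm = W.copy(), W.copy()
            Wp[idx] += eps
            Wm[idx] -= eps
            num = (pkn.spectral_radius(Wp, 5) - pkn.spectral_radius(Wm, 5)) / (2 * eps)
            assert grad[idx] == pytest.approx(num, rel=1e-4, abs=1e-8)

    def test_zero_matrix(self):
        assert pkn.spectral_radius(np.zeros((3, 3)), 5) == 0.0


def test_summary_counts(tiny_network):
    s = tiny_network.summary()
    assert s["n_nodes"] == 4 and s["n_edges"] == 4
    assert s["n_activating"] == 3 and s["n_inhibiting"] == 1
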