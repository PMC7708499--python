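"""Multilayer measures against closed forms and brute-force spectral oracles."""

from __future__ import annotations

import numpy as np
import pytest

from primatenet.indices import LAYERS
from primatenet.multiplex import (
    MultiplexNetwork,
    aggregate_layers,
    build_multiplex,
    edge_overlap,
    eigenvector_centrality,
    eigenvector_versatility,
    global_edge_overlap,
    layer_density,
    multiplex_density,
    quantum_jsd,
    rank_report,
    reducibility,
    strength,
    von_neumann_entropy,
)


def complete_graph(n: int, w: float = 1.0) -> np.ndarray:
    return w * (np.ones((n, n)) - np.eye(n))


def random_layers(rng, n=6, L=4, density=0.5):
    layers = []
    for _ in range(L):
        m = rng.random((n, n)) * (rng.random((n, n)) < density)
        np.fill_diagonal(m, 0.0)
        if not m.any():
            m[0, 1] = rng.random() + 0.1
        layers.append(m)
    return layers


def make_net(layers, names=None):
    n = layers[0].shape[0]
    nodes = [f"n{i}" for i in range(n)]
    names = names or [f"l{i}" for i in range(len(layers))]
    return MultiplexNetwork(nodes=nodes, layer_names=names, layers=layers)


# ---------------------------------------------------------------------------


class TestBuildMultiplex:
    def _table(self, n=7, group="G", value=0.5):
        import pandas as pd

        ids = [f"{group}{i}" for i in range(n)]
        rows = []
        for s in ids:
            for r in ids:
                if s == r:
                    continue
                for layer in LAYERS:
                    rows.append(dict(group=group, sender=s, receiver=r, layer=layer,
                                     count=1, denominator=2, index=value,
                                     weighted=value))
        return pd.DataFrame(rows)

    def test_seven_nodes_four_7x7_layers(self):
        net = build_multiplex(self._table(), "G")
        assert net.n_nodes == 7 and net.n_layers == 4
        assert all(m.shape == (7, 7) for m in net.layers)
        assert net.layer_names == list(LAYERS)

    def test_weighted_entries_in_unit_interval(self):
        net = build_multiplex(self._table(), "G", weight="weighted")
        for m in net.layers:
            assert m.min() >= 0 and m.max() <= 1

    def test_missing_rows_rejected(self):
        table = self._table().iloc[:-1]
        with pytest.raises(ValueError, match="dyad rows"):
            build_multiplex(table, "G")

    def test_diagonal_must_be_zero(self):
        m = np.ones((3, 3))
        with pytest.raises(ValueError, match="diagonal"):
            make_net([m])


class TestDensities:
    def test_extremes(self):
        zero, full = np.zeros((5, 5)), complete_graph(5)
        assert layer_density(zero) == 0.0
        assert layer_density(full) == 1.0

    def test_printed_edge_counts_reproduce_multiplex_densities(self):
        # 7 nodes, 4 layers: 168 possible edges; 139 and 166 present
        rng = np.random.default_rng(0)
        for present, expected in [(139, 139 / 168), (166, 166 / 168)]:
            slots = [(l, i, j) for l in range(4) for i in range(7) for j in range(7) if i != j]
            chosen = rng.choice(len(slots), size=present, replace=False)
            layers = [np.zeros((7, 7)) for _ in range(4)]
            for k in chosen:
                l, i, j = slots[k]
                layers[l][i, j] = rng.random() * 0.9 + 0.1
            net = make_net(layers)
            assert multiplex_density(net) == pytest.approx(expected)
        assert round(139 / 168, 2) == 0.83
        assert round(166 / 168, 2) == 0.99

    def test_aggregate_at_least_as_dense_as_layers(self):
        rng = np.random.default_rng(1)
        net = make_net(random_layers(rng))
        agg_density = layer_density(aggregate_layers(net))
        assert all(agg_density >= layer_density(m) for m in net.layers)


class TestStrength:
    def test_isolated_and_star(self):
        star = np.zeros((4, 4))
        star[0, 1] = star[0, 2] = star[0, 3] = 1.0
        assert strength(star, 0) == 3.0
        assert strength(np.zeros((4, 4)), 2) == 0.0

    def test_matches_row_plus_column_sums(self):
        rng = np.random.default_rng(2)
        m = rng.random((5, 5))
        np.fill_diagonal(m, 0)
        oracle = m.sum(axis=1) + m.sum(axis=0)
        assert np.allclose(strength(m), oracle)


class TestEigenvectorCentrality:
    def test_complete_graph_all_ones(self):
        scores = eigenvector_centrality(complete_graph(5, 0.3))
        assert np.allclose(scores, 1.0)

    def test_path_center_dominates(self):
        path = np.zeros((3, 3))
        path[0, 1] = path[1, 0] = path[1, 2] = path[2, 1] = 1.0
        scores = eigenvector_centrality(path)
        # power-iteration oracle (shifted to damp bipartite oscillation)
        v = np.ones(3)
        shifted = path + np.eye(3)
        for _ in range(200):
            v = shifted @ v
            v /= np.linalg.norm(v)
        oracle = v / v.max()
        assert np.allclose(scores, oracle, atol=1e-8)
        assert scores[1] == 1.0 and scores[0] < 1.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        m = rng.random((6, 6))
        np.fill_diagonal(m, 0)
        assert np.allclose(eigenvector_centrality(m), eigenvector_centrality(10 * m))

    def test_matches_networkx(self):
        import networkx as nx

        rng = np.random.default_rng(4)
        m = rng.random((6, 6))
        np.fill_diagonal(m, 0)
        sym = (m + m.T) / 2
        g = nx.from_numpy_array(sym)
        nx_scores = nx.eigenvector_centrality_numpy(g, weight="weight")
        oracle = np.array([nx_scores[i] for i in range(6)])
        oracle /= oracle.max()
        assert np.allclose(eigenvector_centrality(m), oracle, atol=1e-8)

    def test_empty_layer_zeros_with_warning(self):
        with pytest.warns(UserWarning, match="empty layer"):
            assert not eigenvector_centrality(np.zeros((4, 4))).any()


class TestAggregateLayers:
    def test_identity_union_and_cellwise_sum(self):
        rng = np.random.default_rng(5)
        layers = random_layers(rng, n=5)
        net = make_net(layers)
        assert np.array_equal(aggregate_layers(net, ["l0"]), layers[0])
        assert np.allclose(aggregate_layers(net), sum(layers))
        a = np.zeros((5, 5)); a[0, 1] = 1
        b = np.zeros((5, 5)); b[2, 3] = 1
        union = aggregate_layers(make_net([a, b]))
        assert union[0, 1] == 1 and union[2, 3] == 1 and union.sum() == 2

    def test_empty_subset_rejected(self):
        net = make_net(random_layers(np.random.default_rng(6)))
        with pytest.raises(ValueError):
            aggregate_layers(net, [])


class TestVersatility:
    def test_identical_layers_match_single_layer_ranking(self):
        rng = np.random.default_rng(7)
        m = rng.random((6, 6))
        np.fill_diagonal(m, 0)
        net = make_net([m.copy() for _ in range(4)])
        vers = eigenvector_versatility(net, omega=1.0)
        cent = eigenvector_centrality(m)
        assert np.array_equal(np.argsort(vers), np.argsort(cent))

    def test_matches_brute_force_supra_eigendecomposition(self):
        # independent construction: 3-node 2-layer toy, explicit supra matrix
        a = np.zeros((3, 3)); a[0, 1] = a[1, 0] = 1.0
        b = np.zeros((3, 3)); b[1, 2] = b[2, 1] = 0.5
        net = make_net([a, b])
        omega = 0.3
        supra = np.zeros((6, 6))
        supra[:3, :3] = (a + a.T) / 2
        supra[3:, 3:] = (b + b.T) / 2
        supra[:3, 3:] = omega * np.eye(3)
        supra[3:, :3] = omega * np.eye(3)
        vals, vecs = np.linalg.eig(supra)
        lead = np.abs(vecs[:, np.argmax(vals.real)].real)
        oracle = lead[:3] + lead[3:]
        oracle /= oracle.max()
        assert np.allclose(eigenvector_versatility(net, omega=omega), oracle, atol=1e-8)

    def test_scale_invariance_with_omega(self):
        rng = np.random.default_rng(8)
        layers = random_layers(rng, n=5, L=3)
        net = make_net(layers)
        scaled = make_net([7.0 * m for m in layers])
        assert np.allclose(
            eigenvector_versatility(net, omega=0.5),
            eigenvector_versatility(scaled, omega=3.5),
        )

    def test_single_layer_specialist_can_outrank_generalist(self):
        # node 0 very strong in layer A only; node 1 mediocre everywhere
        a = np.zeros((3, 3)); a[0, 2] = a[2, 0] = 10.0
        b = np.zeros((3, 3)); b[1, 2] = b[2, 1] = 1.0
        a[1, 2] = a[2, 1] = 1.0
        b[0, 2] = b[2, 0] = 0.1
        net = make_net([a, b])
        vers = eigenvector_versatility(net, omega=0.01)
        assert vers[0] > vers[1]

    def test_nonpositive_omega_rejected(self):
        net = make_net(random_layers(np.random.default_rng(9)))
        with pytest.raises(ValueError):
            eigenvector_versatility(net, omega=0.0)


class TestEdgeOverlap:
    def test_self_overlap_is_one(self):
        rng = np.random.default_rng(10)
        m = random_layers(rng, n=4, L=1)[0]
        assert edge_overlap(m, m) == 1.0

    def test_enumeration_example(self):
        a = np.zeros((4, 4)); a[1, 2] = a[2, 3] = 1.0
        b = np.zeros((4, 4)); b[2, 3] = b[3, 1] = 1.0
        assert edge_overlap(a, b) == pytest.approx(1 / 3)
        assert edge_overlap(a, b, norm="min") == pytest.approx(1 / 2)

    def test_disjoint_supports_zero(self):
        a = np.zeros((3, 3)); a[0, 1] = 1
        b = np.zeros((3, 3)); b[1, 2] = 1
        assert edge_overlap(a, b) == 0.0

    def test_global_overlap_intersection_over_union(self):
        a = np.zeros((3, 3)); a[0, 1] = a[1, 2] = 1
        b = np.zeros((3, 3)); b[0, 1] = b[2, 0] = 1
        c = np.zeros((3, 3)); c[0, 1] = c[1, 0] = 1
        net = make_net([a, b, c])
        assert global_edge_overlap(net) == pytest.approx(1 / 4)

    def test_empty_layers_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert edge_overlap(np.zeros((3, 3)), np.zeros((3, 3))) == 0.0


class TestVonNeumannEntropy:
    def test_single_edge_zero_bits(self):
        m = np.zeros((2, 2)); m[0, 1] = m[1, 0] = 1.0
        assert von_neumann_entropy(m) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n", range(3, 9))
    def test_complete_graph_closed_form(self, n):
        assert von_neumann_entropy(complete_graph(n)) == pytest.approx(
            np.log2(n - 1), abs=1e-9
        )

    def test_scale_invariance(self):
        rng = np.random.default_rng(11)
        m = random_layers(rng, n=6, L=1)[0]
        for c in (0.01, 3.0, 250.0):
            assert von_neumann_entropy(c * m) == pytest.approx(
                von_neumann_entropy(m), abs=1e-10
            )

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError, match="zero total weight"):
            von_neumann_entropy(np.zeros((3, 3)))


def brute_force_jsd(a: np.ndarray, b: np.ndarray) -> float:
    """Independent JSD via explicit density operators and scipy entropy."""
    from scipy.linalg import eigh
    from scipy.stats import entropy as shannon

    def rho(m):
        sym = (m + m.T) / 2
        lap = np.diag(sym.sum(1)) - sym
        return lap / np.trace(lap)

    ra, rb = rho(a), rho(b)

    def h(r):
        vals = np.clip(eigh(r, eigvals_only=True), 0, None)
        return shannon(vals, base=2)

    return float(np.sqrt(max(h((ra + rb) / 2) - (h(ra) + h(rb)) / 2, 0.0)))


class TestQuantumJSD:
    def test_identical_layers_zero(self):
        m = complete_graph(4)
        assert quantum_jsd(m, m) == pytest.approx(0.0, abs=1e-9)

    def test_symmetry_and_range_on_random_pairs(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            a, b = random_layers(rng, n=5, L=2)
            d_ab, d_ba = quantum_jsd(a, b), quantum_jsd(b, a)
            assert abs(d_ab - d_ba) < 1e-12
            assert 0.0 <= d_ab <= 1.0

    def test_matches_brute_force_oracle(self):
        k3 = complete_graph(3)
        p3 = np.zeros((3, 3)); p3[0, 1] = p3[1, 0] = p3[1, 2] = p3[2, 1] = 1.0
        assert quantum_jsd(k3, p3) == pytest.approx(brute_force_jsd(k3, p3), abs=1e-9)
        rng = np.random.default_rng(13)
        for _ in range(10):
            a, b = random_layers(rng, n=6, L=2)
            assert quantum_jsd(a, b) == pytest.approx(brute_force_jsd(a, b), abs=1e-9)

    def test_empty_layer_rejected(self):
        with pytest.raises(ValueError):
            quantum_jsd(np.zeros((3, 3)), complete_graph(3))


class TestReducibility:
    def test_four_layers_take_exactly_three_merges(self):
        rng = np.random.default_rng(14)
        net = make_net(random_layers(rng, n=7, L=4))
        result = reducibility(net)
        assert len(result.merge_sequence) == 3
        assert len(result.relative_entropy_curve) == 4
        assert result.relative_entropy_curve[-1] == pytest.approx(0.0, abs=1e-12)

    def test_duplicated_layers_merge_first_at_zero_distance(self):
        rng = np.random.default_rng(15)
        base = random_layers(rng, n=5, L=3)
        net = make_net([base[0], base[0].copy(), base[1], base[2]])
        result = reducibility(net)
        step, (a, b), dist = result.merge_sequence[0]
        assert {frozenset(a), frozenset(b)} == {frozenset(["l0"]), frozenset(["l1"])}
        assert dist == pytest.approx(0.0, abs=1e-8)

    def test_copies_of_one_layer_lose_nothing(self):
        rng = np.random.default_rng(16)
        m = random_layers(rng, n=5, L=1)[0]
        net = make_net([m.copy() for _ in range(4)])
        result = reducibility(net)
        # aggregation of identical layers loses no information at any step
        assert np.allclose(result.relative_entropy_curve, 0.0, atol=1e-9)
        assert all(d == pytest.approx(0.0, abs=1e-8) for _, _, d in result.merge_sequence)

    def test_sum_vs_mean_aggregation_invariant(self):
        # entropy is scale-invariant, so summing or averaging merged layers
        # yields the same curve; scaling all layers must not change results
        rng = np.random.default_rng(17)
        layers = random_layers(rng, n=6, L=4)
        r1 = reducibility(make_net(layers))
        r2 = reducibility(make_net([0.5 * m for m in layers]))
        assert np.allclose(r1.relative_entropy_curve, r2.relative_entropy_curve)
        assert np.allclose(r1.jsd_matrix, r2.jsd_matrix)

    def test_structurally_distinct_layers_favour_four(self):
        # disjoint-support layers: maximal information in the full multiplex
        rng = np.random.default_rng(18)
        hits = 0
        for _ in range(10):
            perm = rng.permutation(24)
            slots = [(i, j) for i in range(7) for j in range(7) if i < j]
            layers = [np.zeros((7, 7)) for _ in range(4)]
            for k, s in enumerate(perm):
                i, j = slots[s % len(slots)]
                w = rng.random() + 0.2
                layers[k % 4][i, j] = layers[k % 4][j, i] = w
            net = make_net(layers)
            if reducibility(net).optimal_n_layers == 4:
                hits += 1
        assert hits >= 8

    def test_single_layer_rejected(self):
        net = make_net(random_layers(np.random.default_rng(19), L=1))
        with pytest.raises(ValueError):
            reducibility(net)


class TestRankReport:
    def test_identical_layers_identical_ranks(self):
        rng = np.random.default_rng(20)
        m = rng.random((5, 5))
        np.fill_diagonal(m, 0)
        net = make_net([m.copy() for _ in range(4)],
                       names=list(LAYERS))
        report = rank_report(net)
        ranks = report.ranks
        for col in ranks.columns[1:]:
            assert (ranks[col] == ranks[ranks.columns[0]]).all()

    def test_ranks_match_sorting_oracle(self):
        rng = np.random.default_rng(21)
        net = make_net(random_layers(rng, n=6, L=4))
        report = rank_report(net)
        for ring in report.scores.columns:
            scores = report.scores[ring].to_numpy()
            # dense-rank oracle: position of each score among unique values
            uniq = np.sort(np.unique(scores))[::-1]
            oracle = np.array([int(np.where(uniq == s)[0][0]) + 1 for s in scores])
            assert np.array_equal(report.ranks[ring].to_numpy(), oracle)

    def test_scores_max_normalised(self):
        rng = np.random.default_rng(22)
        net = make_net(random_layers(rng, n=5, L=4))
        report = rank_report(net)
        for ring in report.scores.columns:
            assert report.scores[ring].max() == pytest.approx(1.0)
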