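import time

import numpy as np
import pytest
from conftest import random_graph

from ioqw import graph_io
from ioqw.graph_io import Graph, all_pairs_shortest_path, generate_random, load_fixture
from ioqw.ioqw_core import (
    build_coin,
    build_evolution,
    build_shift,
    initial_state,
    measurement_vector,
    observe,
    rank_nodes,
)


class TestBuildCoin:
    def test_triangle_entries(self, triangle):
        C = build_coin(triangle).C
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(C[off], -1 / 3)
        assert np.allclose(np.diag(C), 1.0)

    def test_path3_distance_two_entry(self, path3):
        C = build_coin(path3).C
        assert C[path3.index("1"), path3.index("3")] == pytest.approx(0.5)

    def test_disconnected_pairs_zero(self):
        g = Graph.from_label_pairs([("a", "b"), ("c", "d")])
        C = build_coin(g).C
        assert C[g.index("a"), g.index("c")] == 0.0
        assert C[g.index("b"), g.index("d")] == 0.0

    def test_symmetric(self, karate):
        C = build_coin(karate).C
        assert np.allclose(C, C.T)

    def test_fraction_variant_edge_entry(self, triangle):
        C = build_coin(triangle, variant="fraction").C
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(C[off], 1 / 3)

    def test_unknown_variant_rejected(self, triangle):
        with pytest.raises(ValueError, match="variant"):
            build_coin(triangle, variant="bogus")

    def test_max_coin_distance_truncates(self, path3):
        C = build_coin(path3, max_coin_distance=1).C
        assert C[path3.index("1"), path3.index("3")] == 0.0


class TestBuildShift:
    def test_path3_middle_row(self, path3):
        Ahat = build_shift(path3).Ahat
        mid = path3.index("2")
        assert np.allclose(sorted(Ahat[mid]), [0.0, 0.5, 0.5])

    def test_identity_block(self, path3):
        S = build_shift(path3).S
        assert np.allclose(S[:3, :3], np.eye(3))
        assert np.allclose(S[:3, 3:], 0.0)
        assert np.allclose(S[3:, :3], 0.0)

    def test_star_center_row_uniform(self):
        g = load_fixture("star(5)")
        Ahat = build_shift(g).Ahat
        center = g.index("1")
        row = np.delete(Ahat[center], center)
        assert np.allclose(row, 0.25)

    def test_rows_sum_to_one(self, karate):
        Ahat = build_shift(karate).Ahat
        assert np.allclose(Ahat.sum(axis=1), 1.0, atol=1e-12)


class TestBuildEvolution:
    def test_zero_steps_identity(self, path3):
        u = build_evolution(build_shift(path3), build_coin(path3), t=0)
        assert np.allclose(u.U, np.eye(6))

    def test_single_step_blocks(self, path3):
        c = build_coin(path3)
        s = build_shift(path3)
        u = build_evolution(s, c, t=1)
        assert np.allclose(u.Ct, c.C)
        assert np.allclose(u.Bt, s.Ahat @ c.C)

    def test_two_steps_is_square_of_one(self, karate):
        c, s = build_coin(karate), build_shift(karate)
        u1 = build_evolution(s, c, t=1)
        u2 = build_evolution(s, c, t=2)
        assert np.allclose(u2.U, u1.U @ u1.U)

    def test_blockdiag_matches_dense_power(self, karate):
        # structure oracle: power of the full 2N x 2N walk operator
        c, s = build_coin(karate), build_shift(karate)
        N = karate.N
        L = np.zeros((2 * N, 2 * N))
        L[:N, :N] = c.C
        L[N:, N:] = c.C
        dense = np.linalg.matrix_power(s.S @ L, 2)
        assert np.allclose(build_evolution(s, c, t=2).U, dense, atol=1e-10)

    def test_negative_steps_rejected(self, path3):
        with pytest.raises(ValueError):
            build_evolution(build_shift(path3), build_coin(path3), t=-1)


class TestInitialStateAndMeasurement:
    def test_initial_state_uniform_unit_norm(self):
        g = Graph.from_label_pairs([("a", "b")])
        psi = initial_state(g)
        assert np.allclose(psi, 0.5)
        assert np.linalg.norm(psi) == pytest.approx(1.0, abs=1e-12)

    def test_path3_middle_probe(self, path3):
        m = measurement_vector(path3, "2")
        ends = [path3.index("1"), path3.index("3")]
        assert np.allclose(m[ends], 0.5)
        assert np.allclose(m[[3 + e for e in ends]], 0.5)
        assert np.count_nonzero(m) == 4

    def test_star_leaf_sees_center_degree(self):
        g = load_fixture("star(5)")
        m = measurement_vector(g, "2")  # a leaf; center degree 4, M = 4
        center = g.index("1")
        assert m[center] == pytest.approx(1.0)
        assert m[g.N + center] == pytest.approx(1.0)
        assert np.count_nonzero(m) == 2

    def test_isolated_node_zero_probe(self):
        g = Graph.from_label_pairs([("a", "b")], isolated=["z"])
        assert np.count_nonzero(measurement_vector(g, "z")) == 0

    def test_unknown_node_rejected(self, path3):
        with pytest.raises(KeyError):
            measurement_vector(path3, "99")


class TestObserveAndRank:
    def test_scores_nonnegative(self, karate):
        assert all(v >= 0 for v in rank_nodes(karate).scores.values())

    def test_vertex_transitive_graph_scores_equal(self, cycle6):
        scores = np.array(list(rank_nodes(cycle6).scores.values()))
        assert np.allclose(scores, scores[0], atol=1e-10)

    def test_scaling_initial_state_preserves_ranking(self, karate):
        c, s = build_coin(karate), build_shift(karate)
        u = build_evolution(s, c, t=2)
        psi = initial_state(karate)
        base = observe(u, psi, karate)
        scaled = observe(u, 3.0 * psi, karate)
        assert scaled.ranking == base.ranking
        for lab in karate.labels:
            assert scaled.scores[lab] == pytest.approx(9.0 * base.scores[lab])

    def test_karate_top3(self, karate):
        assert rank_nodes(karate).top(3) == ("1", "34", "3")

    def test_karate_top10_set(self, karate):
        expected = {"1", "34", "3", "33", "2", "14", "4", "8", "9", "32"}
        assert set(rank_nodes(karate).top(10)) == expected

    def test_scores_do_not_sum_to_one(self, karate):
        # the walk is intentionally non-unitary: only the initial state is
        # normalized, and the shift operator contracts the move sector
        total = sum(rank_nodes(karate).scores.values())
        assert abs(total - 1.0) > 0.01
        S = build_shift(karate).S
        assert not np.allclose(S @ S.T, np.eye(2 * karate.N))

    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_permutation_equivariance(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            g = random_graph(rng, n_max=20)
            base = rank_nodes(g).scores
            perm = rng.permutation(g.N)
            relabel = {g.labels[i]: f"p{perm[i]}" for i in range(g.N)}
            g2 = Graph.from_label_pairs(
                [(relabel[g.labels[u]], relabel[g.labels[v]]) for u, v in g.edge_index],
                isolated=[relabel[lab] for lab in g.labels],
            )
            permuted = rank_nodes(g2).scores
            for lab in g.labels:
                assert permuted[relabel[lab]] == pytest.approx(
                    base[lab], rel=1e-9, abs=1e-12
                )

    def test_disconnected_graph_warns_and_isolated_scores_zero(self):
        g = Graph.from_label_pairs([("a", "b")], isolated=["z"])
        with pytest.warns(UserWarning, match="disconnected"):
            dist = rank_nodes(g)
        assert dist.scores["z"] == 0.0
        assert dist.ranking[-1] == "z"

    def test_empty_graph_rejected(self):
        g = Graph(labels=(), edge_index=np.empty((0, 2), dtype=np.int64))
        with pytest.raises(ValueError):
            rank_nodes(g)


def test_runtime_medium_scale_graph():
    # distances dominate at O(N*M); a 2000-node scale-free graph with
    # mean degree ~8 must rank well within a minute on one CPU
    g = generate_random("ba", 2000, seed=3, m=4)
    t0 = time.time()
    dist = rank_nodes(g)
    elapsed = time.time() - t0
    assert len(dist.ranking) == 2000
    assert elapsed < 60.0
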