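import warnings

import numpy as np
import pytest

from _oracles import (
    floyd_warshall,
    global_measures_bruteforce,
    nodal_measures_bruteforce,
    random_threshold_graph,
)
from hemimeg.graph import (
    ThresholdedGraph,
    absolute_threshold,
    extract_quadrant,
    global_measures,
    nodal_measures,
    proportional_threshold,
    shortest_path_lengths,
)


def _graph(weights):
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    density = np.count_nonzero(np.triu(w, 1)) / (n * (n - 1) / 2)
    return ThresholdedGraph(w, density)


TRIANGLE = _graph([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
PATH3 = _graph([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
W_TRIANGLE = _graph([[0, 1, 1], [1, 0, 0.5], [1, 0.5, 0]])
DYADS = _graph(
    [[0, 1, 0, 0], [1, 0, 0, 0], [0, 0, 0, 1], [0, 0, 1, 0]]
)


class TestQuadrants:
    def test_block_constant(self, atlas):
        m = np.full((246, 246), 9.0)
        m[:123, :123] = 1.0
        m[123:, 123:] = 2.0
        np.testing.assert_array_equal(extract_quadrant(m, atlas, "left"), 1.0)
        np.testing.assert_array_equal(extract_quadrant(m, atlas, "right"), 2.0)

    def test_symmetric_in_symmetric_out(self, atlas):
        rng = np.random.default_rng(0)
        m = rng.random((246, 246))
        m = (m + m.T) / 2
        q = extract_quadrant(m, atlas, "right")
        assert np.allclose(q, q.T)

    def test_slicing_oracle(self, atlas):
        rng = np.random.default_rng(1)
        m = rng.random((246, 246))
        np.testing.assert_array_equal(
            extract_quadrant(m, atlas, "left"), m[:123, :123]
        )
        np.testing.assert_array_equal(
            extract_quadrant(m, atlas, "right"), m[123:, 123:]
        )

    def test_wrong_size(self, atlas):
        with pytest.raises(ValueError, match="246"):
            extract_quadrant(np.zeros((10, 10)), atlas, "left")

    def test_bad_side(self, atlas):
        with pytest.raises(ValueError, match="side"):
            extract_quadrant(np.zeros((246, 246)), atlas, "up")


class TestProportionalThreshold:
    def test_five_nodes_keeps_one_edge(self):
        rng = np.random.default_rng(2)
        m = rng.random((5, 5))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        g = proportional_threshold(m, 0.10)
        assert np.count_nonzero(np.triu(g.weights, 1)) == 1

    def test_tie_break_lexicographic(self):
        m = np.ones((5, 5)) - np.eye(5)
        g = proportional_threshold(m, 0.10)
        iu = np.argwhere(np.triu(g.weights, 1) > 0)
        np.testing.assert_array_equal(iu, [[0, 1]])

    def test_sorting_oracle(self):
        rng = np.random.default_rng(3)
        m = rng.random((20, 20))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        density = 0.3
        g = proportional_threshold(m, density)
        iu, ju = np.triu_indices(20, 1)
        k = int(round(density * 20 * 19 / 2))
        order = sorted(zip(-m[iu, ju], iu, ju))[:k]
        expect = np.zeros_like(m)
        for negw, i, j in order:
            expect[i, j] = expect[j, i] = -negw
        np.testing.assert_allclose(g.weights, expect)

    def test_retained_weights_unchanged(self):
        rng = np.random.default_rng(4)
        m = rng.random((12, 12))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        g = proportional_threshold(m, 0.25)
        kept = g.weights > 0
        np.testing.assert_array_equal(g.weights[kept], m[kept])

    def test_density_bounds(self):
        m = np.zeros((4, 4))
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError, match="density"):
                proportional_threshold(m, bad)

    def test_asymmetric_rejected(self):
        m = np.zeros((4, 4))
        m[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            proportional_threshold(m, 0.5)


class TestAbsoluteThreshold:
    def test_cutoff(self):
        m = np.array([[0, 0.05, 0.2], [0.05, 0, 0.3], [0.2, 0.3, 0]])
        g = absolute_threshold(m, 0.1)
        np.testing.assert_allclose(
            g.weights, [[0, 0, 0.2], [0, 0, 0.3], [0.2, 0.3, 0]]
        )
        assert g.density == pytest.approx(2 / 3)

    def test_negative_cutoff(self):
        with pytest.raises(ValueError, match="cutoff"):
            absolute_threshold(np.zeros((3, 3)), -1.0)


class TestShortestPaths:
    def test_triangle(self):
        np.testing.assert_allclose(
            shortest_path_lengths(TRIANGLE), 1 - np.eye(3)
        )

    def test_three_path(self):
        d = shortest_path_lengths(PATH3)
        assert d[0, 2] == 2.0

    def test_floyd_warshall_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            w = random_threshold_graph(rng, 30, 0.15)
            g = _graph(w)
            d = shortest_path_lengths(g)
            np.testing.assert_allclose(d, floyd_warshall(g.lengths), atol=1e-12)


class TestGlobalMeasures:
    def test_triangle(self):
        gm = global_measures(TRIANGLE)
        assert (gm.ge, gm.cpl, gm.transitivity) == (1.0, 1.0, 1.0)

    def test_three_path(self):
        gm = global_measures(PATH3)
        assert gm.ge == pytest.approx(5 / 6)
        assert gm.cpl == pytest.approx(4 / 3)
        assert gm.transitivity == 0.0

    def test_two_dyads(self):
        gm = global_measures(DYADS)
        assert gm.ge == pytest.approx(1 / 3)
        assert gm.cpl == pytest.approx(1.0)

    def test_weighted_triangle_transitivity(self):
        gm = global_measures(W_TRIANGLE)
        assert gm.transitivity == pytest.approx(0.5 ** (1 / 3))

    def test_empty_graph(self):
        g = _graph(np.zeros((4, 4)))
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            gm = global_measures(g)
        assert gm.ge == 0.0
        assert np.isnan(gm.cpl)
        assert any("disconnected" in str(w.message).lower() or "no connected"
                   in str(w.message).lower() or "cpl" in str(w.message).lower()
                   for w in rec)

    def test_uniform_weight_scaling(self):
        # all retained weights equal w: GE scales by w, CPL by 1/w vs binary
        rng = np.random.default_rng(6)
        mask = random_threshold_graph(rng, 10, 0.4) > 0
        binary = mask.astype(float)
        w = 0.37
        gm_bin = global_measures(_graph(binary))
        gm_w = global_measures(_graph(w * binary))
        assert gm_w.ge == pytest.approx(w * gm_bin.ge)
        assert gm_w.cpl == pytest.approx(gm_bin.cpl / w)
        # T is scale invariant (normalized by max weight)
        assert gm_w.transitivity == pytest.approx(gm_bin.transitivity)


class TestNodalMeasures:
    def test_triangle(self):
        nm = nodal_measures(TRIANGLE)
        np.testing.assert_allclose(nm.cc, 1.0)
        np.testing.assert_allclose(nm.ne, 1.0)
        np.testing.assert_allclose(nm.bc, 0.0)
        np.testing.assert_allclose(nm.evc, 1 / np.sqrt(3))

    def test_three_path(self):
        nm = nodal_measures(PATH3)
        np.testing.assert_allclose(nm.bc, [0.0, 0.5, 0.0])
        np.testing.assert_allclose(nm.ne, [0.75, 1.0, 0.75])

    def test_weighted_triangle_cc(self):
        nm = nodal_measures(W_TRIANGLE)
        np.testing.assert_allclose(nm.cc, 0.5 ** (1 / 3))

    def test_raw_bc_flag(self):
        nm = nodal_measures(PATH3, normalized_bc=False)
        np.testing.assert_allclose(nm.bc, [0.0, 1.0, 0.0])

    def test_evc_unit_norm_nonnegative(self):
        rng = np.random.default_rng(7)
        nm = nodal_measures(_graph(random_threshold_graph(rng, 15, 0.3)))
        assert np.linalg.norm(nm.evc) == pytest.approx(1.0)
        assert np.all(nm.evc >= 0)


class TestOracleEquivalence:
    def test_random_graphs_match_bruteforce(self):
        rng = np.random.default_rng(8)
        for k in range(30):
            n = int(rng.integers(4, 13))
            density = rng.uniform(0.2, 0.8)
            w = random_threshold_graph(rng, n, density)
            g = _graph(w)
            ge, cpl, t = global_measures_bruteforce(w)
            gm = global_measures(g)
            assert gm.ge == pytest.approx(ge, abs=1e-9)
            if np.isnan(cpl):
                assert np.isnan(gm.cpl)
            else:
                assert gm.cpl == pytest.approx(cpl, abs=1e-9)
            assert gm.transitivity == pytest.approx(t, abs=1e-9)
            cc, ne, bc, evc = nodal_measures_bruteforce(w)
            nm = nodal_measures(g)
            np.testing.assert_allclose(nm.cc, cc, atol=1e-9)
            np.testing.assert_allclose(nm.ne, ne, atol=1e-9)
            np.testing.assert_allclose(nm.bc, bc, atol=1e-9)
            np.testing.assert_allclose(np.abs(nm.evc), np.abs(evc), atol=1e-7)

    def test_betweenness_matches_networkx(self):
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(5, 20))
            w = random_threshold_graph(rng, n, 0.4)
            g = _graph(w)
            nm = nodal_measures(g, normalized_bc=False)
            gx = nx.Graph()
            gx.add_nodes_from(range(n))
            for i in range(n):
                for j in range(i + 1, n):
                    if w[i, j] > 0:
                        gx.add_edge(i, j, weight=1.0 / w[i, j])
            ref = nx.betweenness_centrality(gx, weight="weight", normalized=False)
            np.testing.assert_allclose(
                nm.bc, [ref[i] for i in range(n)], atol=1e-8
            )

    def test_transitivity_is_not_mean_cc(self):
        # a star plus one triangle is irregular: T != mean(CC)
        w = np.zeros((5, 5))
        for j in (1, 2, 3, 4):
            w[0, j] = w[j, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        gm = global_measures(_graph(w))
        nm = nodal_measures(_graph(w))
        assert abs(gm.transitivity - nm.cc.mean()) > 1e-3
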