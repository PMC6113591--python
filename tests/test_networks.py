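"""Bipartite network generation, NODF, modularity, and rewiring."""

import itertools

import numpy as np
import pytest

from vmibench.networks import (InteractionNetwork, bipartite_modularity,
                               load_network, make_max_modular,
                               make_max_nested, nodf, rewire_toward,
                               save_network)


def brute_force_max_nodf(N, n_ones):
    """Exhaustive maximum NODF over all N x N matrices with ``n_ones`` ones
    and no empty rows or columns."""
    best = -1.0
    for ones in itertools.combinations(range(N * N), n_ones):
        M = np.zeros((N, N), dtype=bool)
        M.ravel()[list(ones)] = True
        if not (M.any(axis=0).all() and M.any(axis=1).all()):
            continue
        best = max(best, nodf(M))
    return best


def barber_q(M, row_labels, col_labels):
    """Barber bipartite modularity of a given partition, from its definition."""
    A = M.astype(float)
    m = A.sum()
    k = A.sum(axis=1)
    d = A.sum(axis=0)
    q = 0.0
    for i in range(A.shape[0]):
        for j in range(A.shape[1]):
            if row_labels[i] == col_labels[j]:
                q += A[i, j] - k[i] * d[j] / m
    return q / m


class TestMaxNested:
    def test_staircase_n10(self):
        net = make_max_nested(10, 0.55)
        assert net.M.sum() == 55
        assert nodf(net) == pytest.approx(100.0)
        # rows are prefixes with strictly decreasing degrees
        assert (np.diff(net.M.sum(axis=1)) == -1).all()

    def test_full_matrix(self):
        net = make_max_nested(2, 1.0)
        assert net.M.all()

    def test_matches_exhaustive_maximum(self):
        # 4x4 with 10 ones: compare against brute-force search
        net = make_max_nested(4, 0.625)
        assert net.M.sum() == 10
        assert nodf(net) == pytest.approx(brute_force_max_nodf(4, 10))

    @pytest.mark.parametrize("N,F", [(4, 0.1), (3, 0.0), (3, 1.2)])
    def test_rejects_bad_fill(self, N, F):
        with pytest.raises(ValueError):
            make_max_nested(N, F)

    def test_surplus_and_deficit_fills(self):
        # N=50 at F=0.55 needs more ones than the strict staircase holds
        net = make_max_nested(50, 0.55)
        assert net.M.sum() == round(0.55 * 2500)
        net.validate()
        # deficit: fewer ones than the strict staircase
        net = make_max_nested(5, 0.4)
        assert net.M.sum() == 10
        net.validate()


class TestMaxModular:
    def test_two_full_blocks(self):
        net = make_max_modular(10, 0.5, 2)
        assert net.M.sum() == 50
        assert net.M[:5, :5].all() and net.M[5:, 5:].all()
        assert not net.M[:5, 5:].any()

    def test_identity_for_unit_blocks(self):
        net = make_max_modular(2, 0.5, 2)
        assert (net.M == np.eye(2, dtype=bool)).all()

    def test_two_three_blocks_exact_fill(self):
        net = make_max_modular(6, 0.5, 2)
        assert net.M.sum() == 18
        assert net.M[:3, :3].all() and net.M[3:, 3:].all()

    def test_rejects_incompatible(self):
        with pytest.raises(ValueError):
            make_max_modular(10, 0.5, 3)     # modules do not divide N
        with pytest.raises(ValueError):
            make_max_modular(10, 0.8, 2)     # fill exceeds block capacity


class TestNodf:
    def test_hand_computed_staircase(self):
        # all six pairs have decreasing fill and perfect overlap
        M = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0]])
        assert nodf(M) == pytest.approx(100.0)

    def test_hand_computed_partial(self):
        # row pairs contribute 100 once; column pairs once; 200/6 total
        M = np.array([[1, 1, 0], [0, 1, 1], [1, 0, 0]])
        assert nodf(M) == pytest.approx(200.0 / 6.0)

    def test_identical_rows_give_zero(self):
        M = np.ones((4, 3))
        assert nodf(M) == 0.0

    def test_degree_sorting_invariance_and_range(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            M = rng.random((6, 6)) < 0.5
            M[M.sum(axis=1) == 0, 0] = True
            M[0, M.sum(axis=0) == 0] = True
            v = nodf(M)
            assert 0.0 <= v <= 100.0
            order_r = np.argsort(-M.sum(axis=1), kind="stable")
            order_c = np.argsort(-M.sum(axis=0), kind="stable")
            assert nodf(M[order_r][:, order_c]) == pytest.approx(v)


class TestBipartiteModularity:
    @pytest.mark.parametrize("k", [2, 5])
    def test_equal_disconnected_blocks(self, k):
        net = make_max_modular(10, 1.0 / k, k)
        qb, qb_norm = bipartite_modularity(net)
        assert qb == pytest.approx(1.0 - 1.0 / k, abs=1e-10)
        assert qb_norm == pytest.approx(1.0, abs=1e-9)

    def test_all_ones_has_no_structure(self):
        qb, _ = bipartite_modularity(np.ones((6, 6)))
        assert qb <= 1e-9

    def test_matches_exhaustive_bipartition_search(self):
        M = np.array([[1, 1, 0, 0],
                      [1, 1, 0, 0],
                      [0, 0, 1, 1],
                      [0, 1, 1, 1]])
        best = max(
            barber_q(M, rl, cl)
            for rl in itertools.product([0, 1], repeat=4)
            for cl in itertools.product([0, 1], repeat=4))
        qb, _ = bipartite_modularity(M)
        assert qb == pytest.approx(best, abs=1e-10)


class TestRewiring:
    def test_already_at_target_returns_unchanged(self, nested10):
        out = rewire_toward(nested10, "nodf", nested10.structure_value,
                            np.random.default_rng(0))
        assert (out.M == nested10.M).all()

    def test_conserves_fill_and_nonempty(self, nested10):
        out = rewire_toward(nested10, "nodf", 60.0,
                            np.random.default_rng(1))
        assert out.M.sum() == nested10.M.sum()
        out.validate()
        assert nodf(out) <= 60.0 + 1.0

    def test_lower_target_gives_lower_nodf(self, nested10):
        rng = np.random.default_rng(2)
        high = rewire_toward(nested10, "nodf", 90.0, rng)
        rng = np.random.default_rng(2)
        low = rewire_toward(nested10, "nodf", 70.0, rng)
        assert nodf(low) < nodf(high) <= 100.0

    def test_modularity_rewiring(self):
        net = make_max_modular(10, 0.5, 2)
        out = rewire_toward(net, "modularity", 0.6, np.random.default_rng(0))
        assert out.M.sum() == net.M.sum()
        out.validate()
        assert bipartite_modularity(out)[1] <= 0.65

    def test_target_above_current_rejected(self, nested10):
        low = rewire_toward(nested10, "nodf", 70.0, np.random.default_rng(4))
        with pytest.raises(ValueError):
            rewire_toward(low, "nodf", 95.0, np.random.default_rng(0))


def test_network_roundtrip(tmp_path, nested10):
    path = tmp_path / "net.csv"
    save_network(nested10, path)
    back = load_network(path)
    assert (back.M == nested10.M).all()
    assert back.structure_label == "nested"
    assert back.structure_value == pytest.approx(nested10.structure_value)
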