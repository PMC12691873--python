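import numpy as np
import pytest

from mesfsurv import (
    build_adjacency,
    candidate_set,
    doubly_center,
    eigendecompose,
    make_lattice,
    select_eigenvectors,
)
from mesfsurv.mesf import read_basis_csv, write_basis_csv

from conftest import moran_oracle


@pytest.fixture(scope="module")
def basis44(rook44):
    return eigendecompose(doubly_center(rook44), rook44)


class TestDoublyCenter:
    def test_two_region_hand_computation(self):
        g = build_adjacency(["a", "b"], [("a", "b")])
        expected = np.array([[-0.5, 0.5], [0.5, -0.5]])
        assert np.allclose(doubly_center(g), expected)

    def test_annihilates_constants(self, rook44):
        mcm = doubly_center(rook44)
        assert np.allclose(mcm @ np.ones(rook44.n), 0.0, atol=1e-12)
        assert np.allclose(mcm.sum(axis=0), 0.0, atol=1e-12)
        assert np.allclose(mcm, mcm.T)

    def test_edgeless_graph_gives_zero_matrix(self):
        g = build_adjacency(["a", "b", "c"], [])
        assert np.allclose(doubly_center(g), 0.0)

    def test_single_region_rejected(self):
        g = build_adjacency(["a"], [])
        with pytest.raises(ValueError):
            doubly_center(g)


class TestEigendecompose:
    def test_two_region_closed_form(self):
        g = build_adjacency(["a", "b"], [("a", "b")])
        # full spectrum of MCM is {0, -1}; the 0 belongs to the constant
        mcm = doubly_center(g)
        full = np.sort(np.linalg.eigvalsh(mcm))
        assert np.allclose(full, [-1.0, 0.0])
        basis = eigendecompose(mcm, g)
        assert basis.m == 1
        assert np.isclose(basis.eigenvalues[0], -1.0)
        assert np.allclose(np.abs(basis.vectors[:, 0]), 1 / np.sqrt(2))
        assert np.sign(basis.vectors[0, 0]) > 0  # deterministic sign

    def test_orthonormal_and_centered(self, basis44):
        E = basis44.vectors
        assert np.allclose(E.T @ E, np.eye(basis44.m), atol=1e-8)
        assert np.max(np.abs(E.sum(axis=0))) <= 1e-8 * np.sqrt(basis44.n)

    def test_mc_proportional_to_eigenvalue(self, basis44, rook44):
        expected = (rook44.n / rook44.s0) * basis44.eigenvalues
        assert np.allclose(basis44.mc, expected, atol=1e-8)

    def test_mc_equals_direct_moran_of_column(self, basis44, rook44):
        C = rook44.matrix()
        for j in [0, 3, 7, basis44.m - 1]:
            got = moran_oracle(basis44.vectors[:, j], C)
            assert np.isclose(got, basis44.mc[j], atol=1e-8)

    def test_trace_identity(self, basis44, rook44):
        # diag(C) = 0 so trace(MCM) = -S0/n; dropped constant had eigenvalue 0
        assert np.isclose(
            basis44.eigenvalues.sum(), -rook44.s0 / rook44.n, atol=1e-10
        )

    def test_relabeling_permutes_rows(self):
        g = make_lattice(3, 3, rule="rook")
        perm = np.random.default_rng(1).permutation(g.n)
        ids = [g.region_ids[k] for k in perm]
        g2 = build_adjacency(ids, list(g.edges))
        b1 = eigendecompose(doubly_center(g), g)
        b2 = eigendecompose(doubly_center(g2), g2)
        assert np.allclose(b1.eigenvalues, b2.eigenvalues, atol=1e-10)
        # same eigenvalue -> same column up to row permutation (and sign fix)
        pos = {r: i for i, r in enumerate(g2.region_ids)}
        rows = [pos[r] for r in g.region_ids]
        lam = b1.eigenvalues
        distinct = np.abs(np.subtract.outer(lam, lam)) > 1e-9
        for j in range(b1.m):  # only well-separated eigenvalues are comparable
            if np.sum(~distinct[j]) == 1:
                v1 = b1.vectors[:, j]
                v2 = b2.vectors[rows, j]
                assert np.allclose(v1, v2, atol=1e-8) or np.allclose(
                    v1, -v2, atol=1e-8
                )

    def test_asymmetric_input_rejected(self, rook44):
        bad = doubly_center(rook44)
        bad[0, 1] += 1e-3
        with pytest.raises(ValueError, match="symmetric"):
            eigendecompose(bad, rook44)


class TestCandidateSet:
    def test_threshold_one_keeps_only_max(self, basis44):
        idx = candidate_set(basis44, 1.0)
        mc_max = basis44.mc.max()
        assert idx == [int(i) for i in np.flatnonzero(basis44.mc >= mc_max)]
        assert len(idx) >= 1

    def test_quarter_threshold_brute_force(self, basis44, rook44):
        idx = candidate_set(basis44, 0.25)
        C = rook44.matrix()
        mc = np.array(
            [moran_oracle(basis44.vectors[:, j], C) for j in range(basis44.m)]
        )
        expected = np.flatnonzero(mc >= 0.25 * mc.max())
        assert idx == [int(i) for i in expected]
        assert all(basis44.mc[j] > 0 for j in idx)

    def test_edgeless_graph_empty(self):
        g = build_adjacency(["a", "b", "c"], [])
        basis = eigendecompose(doubly_center(g), g)
        assert candidate_set(basis) == []

    def test_bad_threshold(self, basis44):
        with pytest.raises(ValueError):
            candidate_set(basis44, 0.0)


class TestSelectEigenvectors:
    def test_exact_representation(self, basis44):
        j = 2
        target = 3.0 * basis44.vectors[:, j]
        sel = select_eigenvectors(target, basis44, list(range(6)))
        assert sel.selected_indices == (j,)
        assert np.isclose(sel.r_squared, 1.0)
        assert np.allclose(sel.residual, 0.0, atol=1e-10)

    def test_decomposition_identity_and_mean(self, basis44):
        rng = np.random.default_rng(3)
        target = rng.standard_normal(basis44.n) + 5.0
        sel = select_eigenvectors(target, basis44, list(range(basis44.m)),
                                  alpha_enter=0.5)
        assert np.allclose(sel.ssre + sel.residual, target)  # exact identity
        assert np.isclose(sel.target_mean, target.mean())
        assert np.isclose(sel.ssre.mean(), 0.0, atol=1e-10)

    def test_white_noise_false_entry_rate(self):
        # with orthogonal candidates and a pure-noise target the expected
        # number of entries is ~alpha per candidate
        g = make_lattice(12, 12, rule="rook")
        basis = eigendecompose(doubly_center(g), g)
        cands = list(range(100))
        rng = np.random.default_rng(2024)
        counts = []
        for _ in range(200):
            y = rng.standard_normal(g.n)
            sel = select_eigenvectors(y, basis, cands, alpha_enter=0.05)
            counts.append(len(sel.selected_indices))
        assert abs(np.mean(counts) - 5.0) <= 2.0

    def test_stepwise_r2_below_full_ols(self, basis44):
        rng = np.random.default_rng(9)
        y = rng.standard_normal(basis44.n)
        cands = list(range(8))
        sel = select_eigenvectors(y, basis44, cands, alpha_enter=0.2)
        yc = y - y.mean()
        E = basis44.vectors[:, cands]
        full_r2 = float(((E.T @ yc) ** 2).sum() / (yc @ yc))
        assert sel.r_squared <= full_r2 + 1e-12

    def test_moran_moves_into_ssre(self, rook1010):
        from mesfsurv import morans_i

        basis = eigendecompose(doubly_center(rook1010), rook1010)
        rng = np.random.default_rng(17)
        target = (
            4.0 * basis.vectors[:, 0]
            + 3.0 * basis.vectors[:, 1]
            + 0.3 * rng.standard_normal(rook1010.n)
        )
        cands = candidate_set(basis, 0.25)
        sel = select_eigenvectors(target, basis, cands)
        assert len(sel.selected_indices) >= 1
        i_ssre = morans_i(sel.ssre, rook1010).i_value
        i_resid = morans_i(sel.residual, rook1010).i_value
        assert i_ssre >= i_resid

    def test_non_finite_target_rejected(self, basis44):
        bad = np.full(basis44.n, np.nan)
        with pytest.raises(ValueError):
            select_eigenvectors(bad, basis44, [0])

    def test_empty_candidates_empty_selection(self, basis44):
        y = np.random.default_rng(0).standard_normal(basis44.n)
        sel = select_eigenvectors(y, basis44, [])
        assert sel.selected_indices == ()
        assert np.allclose(sel.ssre, 0.0)


def test_basis_csv_round_trip(tmp_path, rook44):
    basis = eigendecompose(doubly_center(rook44), rook44)
    csv_p, meta_p = tmp_path / "basis.csv", tmp_path / "basis.json"
    write_basis_csv(basis, csv_p, meta_p)
    b2 = read_basis_csv(csv_p, meta_p, rook44)
    assert np.allclose(b2.vectors, basis.vectors)
    assert np.allclose(b2.eigenvalues, basis.eigenvalues)
    other = make_lattice(2, 2, rule="rook")
    with pytest.raises(ValueError):
        read_basis_csv(csv_p, meta_p, other)
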