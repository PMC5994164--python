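import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from osteopem import (
    PhyloTree,
    build_influence,
    build_pem,
    compute_edge_weights,
    target_scores,
    training_basis_with_targets,
)

from conftest import random_tree, shared_path_matrix_oracle


class TestInfluenceMatrix:
    def test_two_tip(self):
        infl = build_influence(PhyloTree.from_newick("(A:1,B:1);"))
        assert infl.tip_labels == ["A", "B"]
        np.testing.assert_array_equal(infl.matrix, [[1, 0], [0, 1]])

    def test_three_tip_hand_derived(self, three_tip_tree):
        # preorder edges: root->(AB), (AB)->A, (AB)->B, root->C
        infl = build_influence(three_tip_tree)
        np.testing.assert_array_equal(
            infl.matrix, [[1, 1, 0, 0], [1, 0, 1, 0], [0, 0, 0, 1]]
        )
        np.testing.assert_array_equal(infl.edge_lengths, [1, 1, 1, 2])

    def test_row_sums_equal_tip_depth_in_edges(self, rng):
        tree = random_tree(9, rng)
        infl = build_influence(tree)
        for i, tip in enumerate(tree.tips()):
            depth = 0
            node = tip
            while node.parent is not None:
                depth += 1
                node = node.parent
            assert infl.matrix[i].sum() == depth

    def test_single_tip_rejected(self):
        with pytest.raises(ValueError, match="at least 2 tips"):
            build_influence(PhyloTree.from_newick("(A:1);"))


class TestEdgeWeights:
    @pytest.mark.parametrize(
        "b,a,expected", [(4.0, 0.0, 2.0), (9.0, 1.0, 1.0), (0.0, 0.5, 0.0)]
    )
    def test_weight_formula(self, b, a, expected):
        w = compute_edge_weights(np.array([b]), a=a, psi=1.0)
        assert w.weights[0] == pytest.approx(expected)

    def test_zero_branch_at_a_one_keeps_psi(self):
        w = compute_edge_weights(np.array([0.0]), a=1.0, psi=2.5)
        assert w.weights[0] == pytest.approx(2.5)

    @pytest.mark.parametrize("a,psi", [(-0.1, 1.0), (1.1, 1.0), (0.5, 0.0), (0.5, -1.0)])
    def test_parameter_validation(self, a, psi):
        with pytest.raises(ValueError):
            compute_edge_weights(np.array([1.0]), a=a, psi=psi)

    @given(
        b=st.floats(min_value=0.0, max_value=1e3),
        a=st.floats(min_value=0.0, max_value=1.0),
        psi=st.floats(min_value=1e-3, max_value=10.0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_weight_closed_form_and_monotonicity(self, b, a, psi):
        w = compute_edge_weights(np.array([b, b + 1.0]), a=a, psi=psi).weights
        assert w[0] == pytest.approx(psi * b ** ((1 - a) / 2))
        assert w[0] <= w[1]  # weights grow with branch length for a <= 1


class TestBasis:
    def test_bm_covariance_three_tips(self, three_tip_tree):
        infl = build_influence(three_tip_tree)
        w = compute_edge_weights(infl, a=0.0)
        Bw = infl.matrix * w.weights
        np.testing.assert_allclose(
            Bw @ Bw.T, [[2, 1, 0], [1, 2, 0], [0, 0, 2]], atol=1e-12
        )

    def test_bm_limit_matches_shared_path_oracle(self, rng):
        """With a = 0 the weighted influence Gram matrix is BM covariance."""
        for _ in range(100):
            tree = random_tree(int(rng.integers(2, 17)), rng)
            infl = build_influence(tree)
            w = compute_edge_weights(infl, a=0.0)
            Bw = infl.matrix * w.weights
            np.testing.assert_allclose(
                Bw @ Bw.T, shared_path_matrix_oracle(tree), atol=1e-10
            )

    def test_orthonormal_centred_columns(self, rng):
        for n in (3, 8, 16):
            basis = build_pem(
                *self._basis_inputs(random_tree(n, rng), a=0.3)
            )
            r = basis.rank
            assert r <= n - 1
            np.testing.assert_allclose(basis.U.T @ basis.U, np.eye(r), atol=1e-10)
            np.testing.assert_allclose(basis.U.sum(axis=0), 0.0, atol=1e-10)
            assert np.all(np.diff(basis.d) <= 1e-12)

    @staticmethod
    def _basis_inputs(tree, a, psi=1.0):
        infl = build_influence(tree)
        return infl, compute_edge_weights(infl, a=a, psi=psi)

    def test_psi_scale_equivariance(self, rng):
        tree = random_tree(10, rng)
        b1 = build_pem(*self._basis_inputs(tree, a=0.2, psi=1.0))
        b3 = build_pem(*self._basis_inputs(tree, a=0.2, psi=3.0))
        np.testing.assert_allclose(b3.d, 3.0 * b1.d, rtol=1e-12)
        np.testing.assert_allclose(b3.U, b1.U, atol=1e-10)  # sign convention fixed

    def test_sign_convention_first_nonzero_positive(self, rng):
        basis = build_pem(*self._basis_inputs(random_tree(12, rng), a=0.0))
        for k in range(basis.rank):
            col = basis.U[:, k]
            nz = np.flatnonzero(np.abs(col) > 1e-12 * np.abs(col).max())
            assert col[nz[0]] > 0

    def test_rank_zero_rejected(self):
        tree = PhyloTree.from_newick("(A:0,B:0);")
        infl = build_influence(tree)
        w = compute_edge_weights(infl, a=0.0)
        with pytest.raises(ValueError, match="rank 0"):
            build_pem(infl, w)

    def test_dimension_mismatch_rejected(self, three_tip_tree):
        infl = build_influence(three_tip_tree)
        w = compute_edge_weights(np.ones(3), a=0.0)
        with pytest.raises(ValueError, match="dimension mismatch"):
            build_pem(infl, w)


class TestTargetScores:
    def test_training_rows_reproduce_U(self, rng):
        tree = random_tree(11, rng)
        infl = build_influence(tree)
        w = compute_edge_weights(infl, a=0.4)
        basis = build_pem(infl, w)
        Bw = infl.matrix * w.weights
        for i in range(infl.n_tips):
            np.testing.assert_allclose(
                target_scores(basis, Bw[i]), basis.U[i], atol=1e-10
            )

    def test_column_means_row_scores_zero(self, rng):
        tree = random_tree(7, rng)
        infl = build_influence(tree)
        w = compute_edge_weights(infl, a=0.0)
        basis = build_pem(infl, w)
        np.testing.assert_allclose(
            target_scores(basis, basis.col_means), 0.0, atol=1e-12
        )

    def test_dimension_check(self, three_tip_tree):
        infl = build_influence(three_tip_tree)
        w = compute_edge_weights(infl, a=0.0)
        basis = build_pem(infl, w)
        with pytest.raises(ValueError, match="edges"):
            target_scores(basis, np.ones(2))

    def test_fossil_only_edges_do_not_move_scores(self, rng):
        """A grafted tip's pendant edge is invisible to the training basis."""
        from osteopem import GraftSpec

        tree = random_tree(8, rng)
        labels = tree.tip_labels()
        lab = labels[3]
        grafted = tree.graft_tips(
            [GraftSpec("fossil", lab, tree.find(lab).length / 2, 0.4)]
        )
        basis, scores = training_basis_with_targets(
            grafted, labels, ["fossil"], a=0.0
        )
        # scoring must be insensitive to the pendant length: regraft with a
        # different pendant and compare
        grafted2 = tree.graft_tips(
            [GraftSpec("fossil", lab, tree.find(lab).length / 2, 2.0)]
        )
        basis2, scores2 = training_basis_with_targets(
            grafted2, labels, ["fossil"], a=0.0
        )
        np.testing.assert_allclose(scores["fossil"], scores2["fossil"], atol=1e-10)
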