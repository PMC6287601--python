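"""Phylogenetic covariance, squared-change parsimony, signal tests, PLS."""

import numpy as np
import pytest

from micrasym.landmark_io import read_newick
from micrasym.phylo import (
    phylo_cov,
    phylo_gls_mean,
    phylo_pls,
    phylo_signal_test,
    prune_to,
    squared_change_parsimony,
)
from micrasym.simulate import simulate_tree


def _pectinate(n):
    inner = "(t1:1,t2:1)"
    for i in range(3, n + 1):
        inner = f"({inner}:1,t{i}:1)"
    return read_newick(inner + ";")


class TestPhyloCov:
    def test_two_tip_tree(self):
        C = phylo_cov(read_newick("(A:1,B:1);"))
        np.testing.assert_allclose(C.to_numpy(), np.eye(2))

    def test_nested_tree_shared_paths(self):
        C = phylo_cov(read_newick("((A:1,B:1):0.5,C:1.5);"))
        assert C.loc["A", "B"] == pytest.approx(0.5)
        assert C.loc["A", "A"] == pytest.approx(1.5)
        assert C.loc["A", "C"] == 0.0

    def test_star_tree_is_identity(self):
        C = phylo_cov(read_newick("(A:1,B:1,C:1,D:1);"))
        np.testing.assert_allclose(C.to_numpy(), np.eye(4))

    def test_positive_semidefinite(self):
        tree = simulate_tree(10, seed=3)
        C = phylo_cov(tree).to_numpy()
        np.testing.assert_allclose(C, C.T)
        assert np.linalg.eigvalsh(C).min() > -1e-12


class TestSquaredChangeParsimony:
    def test_two_tips_unit_branches(self):
        tree = read_newick("(A:1,B:1);")
        res = squared_change_parsimony(tree, np.array([[0.0], [2.0]]), labels=["A", "B"])
        assert res.root_state(tree)[0] == pytest.approx(1.0)
        assert res.q_total == pytest.approx(2.0)

    def test_star_root_is_the_mean(self):
        tree = read_newick("(A:1,B:1,C:1);")
        res = squared_change_parsimony(
            tree, np.array([[0.0], [3.0], [6.0]]), labels=["A", "B", "C"]
        )
        assert res.root_state(tree)[0] == pytest.approx(3.0)
        assert res.q_total == pytest.approx(18.0)

    def test_branch_length_weighting(self):
        # min a^2/1 + (3-a)^2/2 -> a = 1, Q = 3
        tree = read_newick("(A:1,B:2);")
        res = squared_change_parsimony(tree, np.array([[0.0], [3.0]]), labels=["A", "B"])
        assert res.root_state(tree)[0] == pytest.approx(1.0)
        assert res.q_total == pytest.approx(3.0)

    def test_q_zero_iff_tips_identical(self):
        tree = simulate_tree(6, seed=1)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        res = squared_change_parsimony(tree, np.ones((6, 3)), labels=labels)
        assert res.q_total == pytest.approx(0.0, abs=1e-20)
        rng = np.random.default_rng(2)
        res2 = squared_change_parsimony(tree, rng.normal(size=(6, 3)), labels=labels)
        assert res2.q_total > 0
        assert res2.optimality_residual < 1e-8

    def test_q_is_rotation_invariant(self):
        tree = simulate_tree(8, seed=4)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        rng = np.random.default_rng(5)
        X = rng.normal(size=(8, 4))
        Qx = squared_change_parsimony(tree, X, labels=labels).q_total
        O, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        Qr = squared_change_parsimony(tree, X @ O, labels=labels).q_total
        assert Qr == pytest.approx(Qx, rel=1e-10)

    def test_tip_label_mismatch_raises(self):
        tree = read_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="mismatch"):
            squared_change_parsimony(tree, np.zeros((2, 1)), labels=["A", "X"])


class TestPhyloSignal:
    def test_star_tree_q_is_permutation_invariant(self):
        tree = read_newick("(A:1,B:1,C:1,D:1,E:1);")
        rng = np.random.default_rng(6)
        res = phylo_signal_test(
            tree, rng.normal(size=(5, 3)), labels=list("ABCDE"), n_perm=199, seed=0
        )
        assert res.p_value == 1.0

    def test_constant_tip_data_ties_at_zero(self):
        tree = simulate_tree(6, seed=7)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        res = phylo_signal_test(tree, np.ones((6, 2)), labels=labels, n_perm=99, seed=0)
        assert res.q_observed == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_brownian_data_reject_and_iid_do_not(self):
        """Power >= 0.8 for Brownian tip data on a pectinate tree; nominal
        rejection for exchangeable (iid) data."""
        tree = _pectinate(19)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        C = phylo_cov(tree, labels).to_numpy()
        chol = np.linalg.cholesky(C)
        rng = np.random.default_rng(8)
        n_sims = 100
        rej_bm = rej_iid = 0
        for _ in range(n_sims):
            bm = chol @ rng.normal(size=(19, 3))
            p = phylo_signal_test(tree, bm, labels=labels, n_perm=199,
                                  seed=int(rng.integers(2**31))).p_value
            rej_bm += p <= 0.05
            iid = rng.normal(size=(19, 3))
            p = phylo_signal_test(tree, iid, labels=labels, n_perm=199,
                                  seed=int(rng.integers(2**31))).p_value
            rej_iid += p <= 0.05
        assert rej_bm / n_sims >= 0.8
        assert 0.0 <= rej_iid / n_sims <= 0.12

    def test_seed_reproducibility_and_p_never_zero(self):
        tree = simulate_tree(8, seed=9)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        X = np.random.default_rng(10).normal(size=(8, 2))
        a = phylo_signal_test(tree, X, labels=labels, n_perm=199, seed=42)
        b = phylo_signal_test(tree, X, labels=labels, n_perm=199, seed=42)
        assert a.p_value == b.p_value > 0


class TestGlsMean:
    def test_identity_covariance_gives_column_means(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(5, 3))
        np.testing.assert_allclose(phylo_gls_mean(np.eye(5), X), X.mean(axis=0))

    def test_constant_rows_return_the_constant(self):
        tree = read_newick("((A:1,B:1):0.5,C:1.5);")
        C = phylo_cov(tree).to_numpy()
        X = np.full((3, 2), 7.5)
        np.testing.assert_allclose(phylo_gls_mean(C, X), [7.5, 7.5])

    def test_three_tip_hand_computed_value(self):
        # C = [[1.5,.5,0],[.5,1.5,0],[0,0,1.5]], X = (0,0,6):
        # 1'C^-1 1 = 5/3, 1'C^-1 X = 4 -> a = 2.4
        tree = read_newick("((A:1,B:1):0.5,C:1.5);")
        C = phylo_cov(tree).to_numpy()
        a = phylo_gls_mean(C, np.array([[0.0], [0.0], [6.0]]))
        assert a[0] == pytest.approx(2.4)


class TestPhyloPls:
    def test_identical_blocks_are_perfectly_integrated(self):
        tree = simulate_tree(8, seed=12)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        X = np.random.default_rng(13).normal(size=(8, 4))
        res = phylo_pls(tree, X, X, labels=labels, n_perm=99, seed=0)
        assert res.r_pls == pytest.approx(1.0, abs=1e-9)
        assert res.p_value == pytest.approx(1 / 100)

    def test_block_rotation_invariance(self):
        tree = simulate_tree(9, seed=14)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        rng = np.random.default_rng(15)
        X = rng.normal(size=(9, 4))
        Y = rng.normal(size=(9, 3))
        r0 = phylo_pls(tree, X, Y, labels=labels, n_perm=9, seed=0).r_pls
        Ox, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        Oy, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        r1 = phylo_pls(tree, X @ Ox, Y @ Oy, labels=labels, n_perm=9, seed=0).r_pls
        assert r1 == pytest.approx(r0, abs=1e-10)

    def test_species_mismatch_lists_offenders(self):
        import pandas as pd

        tree = simulate_tree(5, seed=16)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        X = pd.DataFrame(np.zeros((5, 2)), index=labels)
        Y = pd.DataFrame(np.zeros((5, 2)), index=labels[:-1] + ["ghost"])
        with pytest.raises(ValueError, match="ghost"):
            phylo_pls(tree, X, Y, n_perm=9, seed=0)

    def test_determinism_under_seed(self):
        tree = simulate_tree(7, seed=17)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        rng = np.random.default_rng(18)
        X, Y = rng.normal(size=(7, 3)), rng.normal(size=(7, 3))
        a = phylo_pls(tree, X, Y, labels=labels, n_perm=199, seed=3)
        b = phylo_pls(tree, X, Y, labels=labels, n_perm=199, seed=3)
        assert a.p_value == b.p_value > 0
        assert a.r_pls == b.r_pls


class TestPrune:
    def test_pruned_tree_keeps_path_lengths(self):
        tree = read_newick("((A:1,B:1):0.5,(C:0.5,D:0.5):1);")
        pruned = prune_to(tree, ["A", "C", "D"])
        C = phylo_cov(pruned)
        assert sorted(C.index) == ["A", "C", "D"]
        assert C.loc["C", "D"] == pytest.approx(1.0)
        assert C.loc["A", "A"] == pytest.approx(1.5)
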