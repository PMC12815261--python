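"""Collapse algorithm vs. the brute-force definition, summaries, distances."""

import numpy as np
import pytest

from ptbt import (InputError, TraitMatrix, assign_node_ids, collapse_tree,
                  parse_newick, patristic_matrix, summarize_cells, yule_tree)

from conftest import random_tree


def brute_force_cells(tree, W_ids):
    """Independent oracle: each leaf's cell is its maximal ancestor whose
    subtree is disjoint from W, found by scanning upward from the leaf."""
    protected = {tree.id_index()[w] for w in W_ids}
    contains = {}
    for v in tree.postorder():
        contains[v] = v in protected or any(contains[c] for c in tree.children[v])
    cells = {}
    for leaf in tree.leaf_indices:
        anc = leaf
        while True:
            p = tree.parent[anc]
            if p < 0 or contains[p]:
                break
            anc = p
        cells.setdefault(anc, set()).add(tree.name[leaf])
    return sorted(frozenset(s) for s in cells.values())


class TestHandCases:
    def test_empty_w_single_cell(self, balanced4):
        cs = collapse_tree(balanced4, set())
        assert len(cs.cells) == 1
        assert sorted(cs.cells[0].leaf_names) == ["A", "B", "C", "D"]

    def test_all_internals_identity(self, balanced4):
        W = {balanced4.clade_id[v] for v in balanced4.internal_indices}
        cs = collapse_tree(balanced4, W)
        assert len(cs.cells) == balanced4.n_leaves
        assert cs.tree.n_leaves == balanced4.n_leaves
        # every protected node survives as an internal node of T_W
        kept = {cs.tree.clade_id[v] for v in cs.tree.internal_indices}
        assert W <= kept

    def test_root_only_two_cells(self, balanced4):
        cs = collapse_tree(balanced4, {"c000002"})
        memberships = sorted(tuple(sorted(c.leaf_names)) for c in cs.cells)
        assert memberships == [("A", "B"), ("C", "D")]

    def test_unknown_node_rejected(self, balanced4):
        with pytest.raises(InputError, match="c999999"):
            collapse_tree(balanced4, {"c999999"})

    def test_leaf_in_w_ignored_with_warning(self, balanced4, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            cs = collapse_tree(balanced4, {"A", "c000002"})
        assert len(cs.cells) == 2
        assert "ignoring 1 leaves" in caplog.text


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        t = random_tree(int(rng.integers(5, 120)), seed,
                        multifurcating=bool(seed % 2))
        internals = [t.clade_id[v] for v in t.internal_indices]
        W = set(rng.choice(internals,
                           size=int(rng.integers(0, len(internals) + 1)),
                           replace=False))
        cs = collapse_tree(t, W)
        got = sorted(frozenset(c.leaf_names) for c in cs.cells)
        assert got == brute_force_cells(t, W)

    def test_partition_invariant(self):
        t = random_tree(80, seed=7)
        rng = np.random.default_rng(7)
        internals = [t.clade_id[v] for v in t.internal_indices]
        W = set(rng.choice(internals, size=20, replace=False))
        cs = collapse_tree(t, W)
        all_members = [nm for c in cs.cells for nm in c.leaf_names]
        assert sorted(all_members) == sorted(t.leaf_names)
        assert int(cs.sizes.sum()) == t.n_leaves

    def test_cell_count_weakly_increasing_in_w(self):
        t = random_tree(60, seed=17)
        rng = np.random.default_rng(17)
        internals = [t.clade_id[v] for v in t.internal_indices]
        order = list(rng.permutation(internals))
        prev = 0
        for k in (0, 5, 15, 30, len(order)):
            count = len(collapse_tree(t, set(order[:k])).cells)
            assert count >= prev
            prev = count

    def test_connected_w_cell_count_identity(self):
        """Binary tree, W a root-containing connected subtree:
        |cells| = |W| + 1."""
        t = yule_tree(64, seed=23)
        # breadth-first prefix from the root is a connected internal subtree
        W_idx = set()
        frontier = [t.root]
        while frontier and len(W_idx) < 20:
            v = frontier.pop(0)
            W_idx.add(v)
            frontier.extend(c for c in t.children[v] if not t.is_leaf(c))
        W = {t.clade_id[v] for v in W_idx}
        cs = collapse_tree(t, W)
        assert len(cs.cells) == len(W) + 1


class TestSummaries:
    def _cells(self, balanced4):
        return collapse_tree(balanced4, {"c000002"})

    def test_median_and_positive_fraction(self):
        t = assign_node_ids(parse_newick("((A:1,B:1,C:1):1,(D:1,E:1):1);"))
        tm = TraitMatrix(t.leaf_names, ["cont", "bin"],
                         np.array([[1, 1], [2, 0], [10, 0], [4, 1], [5, 1.]]),
                         ["continuous", "binary"])
        cs = collapse_tree(t, {t.clade_id[t.root]})
        summ = summarize_cells(cs, tm, "none")
        assert summ.loc[cs.cells[0].cell_id, "cont"] == pytest.approx(2.0)
        assert summ.loc[cs.cells[0].cell_id, "bin"] == pytest.approx(1 / 3)
        assert summ.loc[cs.cells[1].cell_id, "bin"] == pytest.approx(1.0)

    def test_singleton_cell_equals_leaf(self, balanced4):
        W = {balanced4.clade_id[v] for v in balanced4.internal_indices}
        cs = collapse_tree(balanced4, W)
        tm = TraitMatrix(balanced4.leaf_names, ["x"],
                         np.array([[1.0], [2.0], [3.0], [4.0]]), ["continuous"])
        summ = summarize_cells(cs, tm, "none")
        np.testing.assert_allclose(summ["x"].to_numpy(), [1, 2, 3, 4])

    def test_zscore_scaling_columns(self, balanced4):
        cs = collapse_tree(balanced4, {"c000002"})
        tm = TraitMatrix(balanced4.leaf_names, ["x"],
                         np.array([[1.0], [2.0], [30.0], [40.0]]), ["continuous"])
        summ = summarize_cells(cs, tm, "zscore")
        assert summ["x"].mean() == pytest.approx(0.0, abs=1e-12)
        assert summ["x"].std(ddof=0) == pytest.approx(1.0)


class TestPatristic:
    def test_two_cell_distance(self, balanced4):
        cs = collapse_tree(balanced4, {"c000002"})
        D = patristic_matrix(cs.tree)
        assert D.iloc[0, 1] == pytest.approx(2.0)
        np.testing.assert_allclose(np.diag(D), 0.0)

    def test_caterpillar_hand_path(self):
        t = assign_node_ids(parse_newick("((((A:1,B:1):1,C:1):1,D:1):1,E:1);"))
        D = patristic_matrix(t)
        assert D.loc["A", "E"] == pytest.approx(5.0)
        assert D.loc["C", "D"] == pytest.approx(3.0)

    def test_metric_axioms_on_random_trees(self):
        for seed in range(5):
            t = random_tree(25, seed, multifurcating=bool(seed % 2))
            D = patristic_matrix(t).to_numpy()
            assert np.allclose(D, D.T)
            assert (D[~np.eye(len(D), dtype=bool)] > 0).all()
            # triangle inequality
            m = len(D)
            assert (D[:, :, None] + D[None, :, :] >= D[:, None, :] - 1e-9).all()
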