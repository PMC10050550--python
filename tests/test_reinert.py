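import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emadhc.reinert import (
    DegenerateSplitError,
    ParameterError,
    initial_bipartition,
    min_cluster_size,
    phi2,
    prune_small_clusters,
    refine_bipartition,
    run_dhc,
)

from conftest import make_table
from oracles import (
    block_separable_table,
    exhaustive_best_phi2,
    phi2_scipy,
    random_binary_table,
)


class TestPhi2:
    @pytest.mark.parametrize(
        "top,bottom,expected",
        [
            ((2, 2, 0, 0), (0, 0, 2, 2), 1.0),  # disjoint vocabularies
            ((3, 1), (3, 1), 0.0),  # identical profiles -> independence
            ((2, 0), (1, 1), 1.3333333333 / 4),
        ],
    )
    def test_hand_computed_values(self, top, bottom, expected):
        assert phi2(top, bottom) == pytest.approx(expected)

    def test_matches_general_purpose_contingency_routine(self, rng):
        for _ in range(50):
            a = rng.integers(0, 5, size=6)
            b = rng.integers(0, 5, size=6)
            if a.sum() == 0 or b.sum() == 0:
                continue
            assert phi2(a, b) == pytest.approx(phi2_scipy(a, b))

    def test_all_zero_side_is_degenerate(self):
        with pytest.raises(DegenerateSplitError):
            phi2((0, 0), (1, 2))

    def test_zero_total_columns_contribute_nothing(self):
        assert phi2((2, 0, 0), (0, 2, 0)) == phi2((2, 0), (0, 2))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 6), min_size=2, max_size=8),
        st.data(),
    )
    def test_bounded_between_zero_and_one(self, top, data):
        bottom = data.draw(
            st.lists(st.integers(0, 6), min_size=len(top), max_size=len(top))
        )
        if sum(top) == 0 or sum(bottom) == 0:
            return
        value = phi2(top, bottom)
        assert 0.0 <= value <= 1.0 + 1e-12


class TestInitialBipartition:
    def test_two_block_table_splits_exactly(self, two_block_table):
        split = initial_bipartition(two_block_table)
        assert not split.degenerate
        assert split.phi2 == pytest.approx(1.0)
        sides = {frozenset(split.left_units), frozenset(split.right_units)}
        assert sides == {frozenset({"a", "b"}), frozenset({"c", "d"})}

    def test_identical_rows_flagged_degenerate(self):
        table = make_table([[1, 0, 1]] * 4)
        assert initial_bipartition(table).degenerate

    def test_single_unit_degenerate(self):
        assert initial_bipartition(make_table([[1, 0]])).degenerate

    def test_cut_is_optimal_over_first_axis_ordering(self, rng):
        # the returned phi2 must equal the best contiguous cut of the CA order
        from emadhc.reinert import _phi2, ca_first_axis_coordinates

        for _ in range(20):
            X = random_binary_table(rng, 8, 6)
            table = make_table(X)
            split = initial_bipartition(table)
            if split.degenerate:
                continue
            coords = ca_first_axis_coordinates(X.astype(float))
            order = np.lexsort((np.arange(8), coords))
            best = max(
                _phi2(
                    X[order[: k + 1]].sum(axis=0).astype(float),
                    X[order[k + 1 :]].sum(axis=0).astype(float),
                )
                for k in range(7)
            )
            assert split.phi2 == pytest.approx(best)

    def test_deterministic(self, rng):
        X = random_binary_table(rng, 10, 6)
        table = make_table(X)
        s1 = initial_bipartition(table)
        s2 = initial_bipartition(table)
        assert s1.left_units == s2.left_units and s1.phi2 == s2.phi2


class TestRefineBipartition:
    def test_optimal_split_is_fixed_point(self, two_block_table):
        split = initial_bipartition(two_block_table)
        refined = refine_bipartition(two_block_table, split)
        assert refined.converged
        assert refined.n_reassignment_passes == 1
        assert set(refined.left_units) == set(split.left_units)
        assert refined.phi2 == pytest.approx(1.0)

    def test_misassigned_unit_moves_home(self):
        # 5 units, two disjoint-vocabulary blocks; u2 starts on the wrong side
        X = [
            [1, 1, 0, 0],
            [1, 1, 0, 0],
            [1, 1, 0, 0],
            [0, 0, 1, 1],
            [0, 0, 1, 1],
        ]
        table = make_table(X, unit_ids=list("abcde"))
        from emadhc.reinert import SplitResult

        bad = SplitResult(left_units=("a", "b"), right_units=("c", "d", "e"), phi2=0.0)
        bad.phi2 = phi2(
            np.array(X)[[0, 1]].sum(axis=0), np.array(X)[[2, 3, 4]].sum(axis=0)
        )
        refined = refine_bipartition(table, bad)
        assert refined.phi2 == pytest.approx(1.0)
        assert set(refined.left_units) == {"a", "b", "c"}

    def test_never_beats_exhaustive_and_matches_on_blocks(self, rng):
        for _ in range(30):
            X = random_binary_table(rng, rng.integers(4, 11), rng.integers(3, 7))
            table = make_table(X)
            split = initial_bipartition(table)
            if split.degenerate:
                continue
            refined = refine_bipartition(table, split)
            best = exhaustive_best_phi2(X)
            assert refined.phi2 <= best + 1e-9
            assert refined.phi2 >= split.phi2 - 1e-12
        for _ in range(10):
            X, _labels = block_separable_table(rng, (3, 4))
            table = make_table(X)
            refined = refine_bipartition(table, initial_bipartition(table))
            assert refined.phi2 == pytest.approx(exhaustive_best_phi2(X))

    def test_trace_strictly_increasing_and_terminates(self, rng):
        for _ in range(25):
            X = random_binary_table(rng, 12, 8)
            table = make_table(X)
            split = initial_bipartition(table)
            if split.degenerate:
                continue
            refined = refine_bipartition(table, split)
            assert refined.converged
            trace = [split.phi2] + refined.phi2_trace
            assert all(b > a for a, b in zip(trace, trace[1:]))

    def test_moves_never_empty_a_side(self, rng):
        for _ in range(10):
            X = random_binary_table(rng, 5, 4)
            table = make_table(X)
            split = initial_bipartition(table)
            if split.degenerate:
                continue
            refined = refine_bipartition(table, split)
            assert len(refined.left_units) >= 1 and len(refined.right_units) >= 1


class TestRunDHC:
    def _four_block_table(self, rng):
        X, labels = block_separable_table(rng, (5, 6, 7, 8), forms_per_block=4)
        return make_table(X), labels

    def test_four_disjoint_blocks_recovered_exactly(self, rng):
        table, labels = self._four_block_table(rng)
        tree = run_dhc(table, n_terminal=4)
        leaf_sets = {frozenset(leaf.unit_ids) for leaf in tree.leaves()}
        true_sets = set()
        for k in set(labels):
            true_sets.add(
                frozenset(uid for uid, lab in zip(table.unit_ids, labels) if lab == k)
            )
        assert leaf_sets == true_sets

    def test_n_terminal_two_is_exactly_the_root_split(self, two_block_table):
        tree = run_dhc(two_block_table, n_terminal=2)
        assert len(tree.leaves()) == 2
        assert tree.nodes[tree.root_id].children is not None

    def test_n_terminal_below_two_rejected(self, two_block_table):
        with pytest.raises(ParameterError):
            run_dhc(two_block_table, n_terminal=1)

    def test_children_partition_parent_everywhere(self, rng):
        X = random_binary_table(rng, 40, 12)
        tree = run_dhc(make_table(X), n_terminal=6)
        for node in tree.nodes.values():
            if node.children:
                left, right = (tree.nodes[c] for c in node.children)
                assert set(left.unit_ids) | set(right.unit_ids) == set(node.unit_ids)
                assert not set(left.unit_ids) & set(right.unit_ids)

    def test_determinism_identical_trees(self, rng):
        X = random_binary_table(rng, 30, 10)
        t1 = run_dhc(make_table(X), n_terminal=5)
        t2 = run_dhc(make_table(X), n_terminal=5)
        assert t1.to_json() == t2.to_json()

    def test_newick_export_is_well_formed(self, two_block_table):
        tree = run_dhc(two_block_table, n_terminal=2)
        nwk = tree.to_newick()
        assert nwk.endswith(";") and nwk.count("(") == nwk.count(")")


class TestPruning:
    def test_min_cluster_size_is_ceiling_of_corpus_over_requested(self):
        assert min_cluster_size(8_793, 20) == 440
        assert min_cluster_size(100, 20) == 5
        assert min_cluster_size(101, 20) == 6

    def test_all_leaves_above_threshold_unchanged(self, two_block_table):
        tree = run_dhc(two_block_table, n_terminal=2)
        prune_small_clusters(tree, 4, 2)
        assert not any(leaf.pruned for leaf in tree.leaves())
        assert tree.classification_rate == 1.0

    def test_small_leaf_units_become_unclassified_with_conservation(self, rng):
        X, _labels = block_separable_table(rng, (2, 9), forms_per_block=3)
        table = make_table(X)
        tree = run_dhc(table, n_terminal=2)
        prune_small_clusters(tree, 11, 3)  # threshold ceil(11/3) = 4
        kept = sum(leaf.size for leaf in tree.kept_leaves())
        assert kept + len(tree.unclassified_units) + len(tree.unclassifiable_units) == 11
        assert tree.classification_rate == pytest.approx(kept / 11)

    def test_classification_rate_accounts_for_unclassifiable_rows(self, rng):
        X, _labels = block_separable_table(rng, (5, 6), forms_per_block=3)
        table = make_table(X)
        table.unclassifiable_units = ["zz1", "zz2"]
        tree = run_dhc(table, n_terminal=2)
        prune_small_clusters(tree)
        assert tree.n_corpus_texts == 13
        kept = sum(leaf.size for leaf in tree.kept_leaves())
        assert tree.classification_rate == pytest.approx(kept / 13)
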