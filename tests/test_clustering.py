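import numpy as np
import pandas as pd
import pytest

from renalmark import (
    ExpressionMatrix,
    gen_expression,
    hcluster,
    median_center,
    read_cdt_gtr,
    write_cdt_gtr,
)

from _oracles import naive_hcluster


def _matrix(values: np.ndarray, prefix="g") -> ExpressionMatrix:
    rows = [f"{prefix}{i}" for i in range(values.shape[0])]
    cols = [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=rows, columns=cols),
        groups=pd.Series(["normal"] * len(cols), index=cols),
    )


class TestMedianCenter:
    def test_odd_length_row(self):
        m = _matrix(np.array([[1.0, 2.0, 3.0]]))
        out = median_center(m)
        assert list(out.values.iloc[0]) == [-1.0, 0.0, 1.0]

    def test_constant_row_becomes_zero(self):
        m = _matrix(np.array([[7.0, 7.0, 7.0, 7.0]]))
        assert (median_center(m).values.to_numpy() == 0).all()

    def test_every_row_median_zero_and_idempotent(self):
        matrix, _ = gen_expression(200, {"normal": 15, "T1": 15}, seed=40)
        once = median_center(matrix)
        meds = once.values.median(axis=1).to_numpy()
        assert np.all(np.abs(meds) < 1e-12)
        twice = median_center(once)
        assert np.allclose(once.values.to_numpy(), twice.values.to_numpy())


class TestHcluster:
    def test_two_items_single_merge(self):
        m = _matrix(np.array([[1.0, 2.0, 3.0], [3.0, 1.0, 2.0]]))
        tree = hcluster(m, axis="genes")
        assert len(tree.merges) == 1
        assert sorted(tree.merges[0][:2]) == [0, 1]

    def test_identical_rows_merge_first_with_similarity_one(self):
        m = _matrix(np.array([
            [1.0, 2.0, 3.0, 4.0],
            [2.0, 4.0, 6.0, 8.0],   # perfectly correlated with row 0
            [4.0, 1.0, 3.0, 2.0],
        ]))
        tree = hcluster(m, axis="genes")
        left, right, sim = tree.merges[0]
        assert {left, right} == {0, 1}
        assert sim == pytest.approx(1.0, abs=1e-12)

    def test_constant_row_rejected_under_correlation(self):
        m = _matrix(np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]))
        with pytest.raises(ValueError, match="g0"):
            hcluster(m, axis="genes")

    @pytest.mark.parametrize("linkage", ["average", "single", "complete"])
    def test_merge_sequence_matches_naive_oracle(self, linkage):
        rng = np.random.default_rng(41)
        X = rng.normal(size=(12, 8))
        m = _matrix(X)
        tree = hcluster(m, axis="genes", linkage=linkage)
        expected = naive_hcluster(X, metric="correlation", linkage=linkage)
        assert [(l, r) for l, r, _ in tree.merges] == [(l, r) for l, r, _ in expected]
        for (_, _, a), (_, _, b) in zip(tree.merges, expected):
            assert a == pytest.approx(b, abs=1e-9)

    def test_tie_break_prefers_lowest_original_index(self):
        # three mutually equidistant profiles: pairwise correlations equal
        X = np.array([
            [1.0, 0.0, 0.0, 1.0],
            [0.0, 1.0, 0.0, 1.0],
            [0.0, 0.0, 1.0, 1.0],
        ])
        tree = hcluster(_matrix(X), axis="genes")
        assert tuple(tree.merges[0][:2]) == (0, 1)

    def test_row_order_invariance_with_distinct_distances(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(9, 7))
        m1 = _matrix(X)
        tree1 = hcluster(m1, axis="genes")
        perm = rng.permutation(9)
        m2 = ExpressionMatrix(
            values=pd.DataFrame(X[perm], index=[f"g{i}" for i in perm],
                                columns=m1.values.columns),
            groups=m1.groups,
        )
        tree2 = hcluster(m2, axis="genes")
        # same sets of leaf ids merged, in the same order
        def merged_sets(tree):
            L = tree.n_leaves
            members = {i: frozenset([tree.leaf_ids[i]]) for i in range(L)}
            out = []
            for node, (l, r, _s) in enumerate(tree.merges, start=L):
                members[node] = members[l] | members[r]
                out.append(members[node])
            return out

        assert merged_sets(tree1) == merged_sets(tree2)

    def test_samples_axis(self):
        matrix, _ = gen_expression(30, {"normal": 6, "T1": 6}, seed=43)
        tree = hcluster(matrix, axis="samples")
        assert tree.n_leaves == 12
        assert len(tree.merges) == 11


class TestCdtGtr:
    def test_file_line_counts_for_2x2(self, tmp_path):
        m = _matrix(np.array([[1.0, 2.0], [2.0, 1.0]]))
        gt = hcluster(m, axis="genes", distance="euclidean")
        st = hcluster(m, axis="samples", distance="euclidean")
        files = write_cdt_gtr(m, gt, st, tmp_path / "out")
        cdt = (tmp_path / "out.cdt").read_text().splitlines()
        assert len(cdt) == 3 + 2  # header, AID, EWEIGHT + 2 data rows
        assert len((tmp_path / "out.gtr").read_text().splitlines()) == 1
        assert len((tmp_path / "out.atr").read_text().splitlines()) == 1

    def test_node_ids_sequential_in_merge_order(self, tmp_path):
        matrix, _ = gen_expression(6, {"normal": 4, "T1": 4}, seed=44)
        c = median_center(matrix)
        gt = hcluster(c, axis="genes")
        st = hcluster(c, axis="samples")
        write_cdt_gtr(c, gt, st, tmp_path / "out")
        lines = (tmp_path / "out.gtr").read_text().splitlines()
        assert [ln.split("\t")[0] for ln in lines] == [f"NODE{j}X" for j in range(1, 6)]

    def test_round_trip_recovers_trees_and_values(self, tmp_path):
        matrix, _ = gen_expression(10, {"normal": 5, "T1": 5}, seed=45)
        c = median_center(matrix)
        gt = hcluster(c, axis="genes")
        st = hcluster(c, axis="samples")
        write_cdt_gtr(c, gt, st, tmp_path / "out")
        df, gt2, st2 = read_cdt_gtr(tmp_path / "out")
        assert gt2.merges == gt.merges
        assert st2.merges == st.merges
        assert gt2.leaf_order == gt.leaf_order
        assert st2.leaf_order == st.leaf_order
        assert list(df.index) == list(c.values.index)
        assert np.array_equal(df.to_numpy(), c.values.to_numpy())
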