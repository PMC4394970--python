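import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from renalmark import (
    ExpressionMatrix,
    PipelineConfig,
    de_test,
    fold_change,
    gen_expression,
    group_summaries,
    stage_trend,
)

from _oracles import welch_t_pvalue


class TestFoldChange:
    @pytest.mark.parametrize(
        "case,control,expected",
        [
            (23.22495, 6.23674, 3.723893),
            (36.49804, 13.1029, 2.785493),
        ],
    )
    def test_printed_mean_ratios(self, case, control, expected):
        assert fold_change(case, control) == pytest.approx(expected, abs=1e-4)

    def test_equal_means_give_unity(self):
        assert fold_change(5.0, 5.0) == 1.0

    def test_pseudocount_required_for_zero_control(self):
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0, pseudocount=0.0)
        assert fold_change(1.0, 0.0, pseudocount=1.0) == 2.0

    @given(
        a=st.floats(min_value=0.01, max_value=1e6),
        b=st.floats(min_value=0.01, max_value=1e6),
    )
    @settings(max_examples=50, deadline=None)
    def test_reciprocal_identity(self, a, b):
        assert fold_change(a, b) * fold_change(b, a) == pytest.approx(1.0, rel=1e-12)


def _matrix_from_arrays(case: np.ndarray, ctrl: np.ndarray) -> ExpressionMatrix:
    n_case, n_ctrl = case.shape[1], ctrl.shape[1]
    cols = [f"t{i}" for i in range(n_case)] + [f"n{i}" for i in range(n_ctrl)]
    values = pd.DataFrame(np.hstack([case, ctrl]),
                          index=[f"g{i}" for i in range(case.shape[0])], columns=cols)
    groups = pd.Series(["T1"] * n_case + ["normal"] * n_ctrl, index=cols)
    return ExpressionMatrix(values=values, groups=groups)


class TestDeTest:
    def test_identical_groups_give_p_one_fc_one(self):
        block = np.tile(np.array([[1.0, 2.0, 3.0]]), (5, 1))
        m = _matrix_from_arrays(block, block)
        calls = de_test(m, "T1", "normal")
        assert all(c.p_value == 1.0 and c.fc == 1.0 and not c.passes for c in calls)

    def test_planted_genes_recovered_with_low_false_positives(self):
        hits_all, fps_all = [], []
        for seed in range(3):
            m, truth = gen_expression(2000, {"normal": 30, "T1": 30}, n_de=100,
                                      effect_log2=2.0, seed=seed)
            calls = de_test(m, "T1", "normal")
            hits_all.append(sum(c.passes for c in calls if c.feature in truth.de_genes_up))
            fps_all.append(sum(c.passes for c in calls if c.feature not in truth.de_genes_up))
        assert all(h >= 90 for h in hits_all)
        assert all(fp <= 0.01 * 1900 for fp in fps_all)

    def test_statistic_matches_first_principles_welch(self):
        rng = np.random.default_rng(12)
        case = rng.lognormal(3, 1, size=(1, 12))
        ctrl = rng.lognormal(2, 1, size=(1, 15))
        m = _matrix_from_arrays(case, ctrl)
        call = de_test(m, "T1", "normal")[0]
        p_expected, _ = welch_t_pvalue(np.log2(case[0] + 1), np.log2(ctrl[0] + 1))
        assert call.p_value == pytest.approx(p_expected, abs=1e-10)

    def test_null_p_values_approximately_uniform(self):
        m, _ = gen_expression(2000, {"normal": 30, "T1": 30}, n_de=0, seed=0)
        calls = de_test(m, "T1", "normal")
        frac = np.mean([c.p_value <= 0.01 for c in calls])
        assert 0.005 <= frac <= 0.02

    def test_mannwhitney_alternative_available(self):
        m, truth = gen_expression(200, {"normal": 15, "T1": 15}, n_de=20,
                                  effect_log2=3.0, seed=4)
        cfg = PipelineConfig(de_method="mannwhitney")
        calls = de_test(m, "T1", "normal", cfg)
        hits = sum(c.passes for c in calls if c.feature in truth.de_genes_up)
        assert hits >= 15

    def test_missing_group_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            de_test(small_matrix, "T9", "normal")


class TestGroupSummaries:
    def test_constant_group(self, small_matrix):
        s = group_summaries(small_matrix, "gC", ["normal", "T1"])
        assert s[0].mean == 2.0 and s[0].sd == 0.0 and s[0].sem == 0.0

    def test_printed_sem_relation(self):
        # cohort of 31 controls: SEM = SD / sqrt(31)
        rng = np.random.default_rng(0)
        v = rng.normal(0, 1, 31)
        v = 6.23674 + (v - v.mean()) * (6.064987 / v.std(ddof=1))
        cols = [f"s{i}" for i in range(31)]
        m = ExpressionMatrix(
            values=pd.DataFrame([v], index=["gX"], columns=cols),
            groups=pd.Series(["normal"] * 31, index=cols),
        )
        s = group_summaries(m, "gX", ["normal"])[0]
        assert s.sem == pytest.approx(1.089304, abs=1e-4)

    def test_matches_two_pass_oracle_and_order_invariance(self):
        rng = np.random.default_rng(5)
        v = rng.lognormal(2, 1, 17)
        cols = [f"s{i}" for i in range(17)]
        m = ExpressionMatrix(
            values=pd.DataFrame([v], index=["g"], columns=cols),
            groups=pd.Series(["a"] * 17, index=cols),
        )
        s = group_summaries(m, "g", ["a"])[0]
        mean = sum(v) / len(v)
        sd = (sum((x - mean) ** 2 for x in v) / (len(v) - 1)) ** 0.5
        assert s.mean == pytest.approx(mean, abs=1e-12)
        assert s.sd == pytest.approx(sd, abs=1e-12)
        perm = rng.permutation(17)
        m2 = ExpressionMatrix(
            values=pd.DataFrame([v[perm]], index=["g"], columns=[cols[i] for i in perm]),
            groups=pd.Series(["a"] * 17, index=[cols[i] for i in perm]),
        )
        s2 = group_summaries(m2, "g", ["a"])[0]
        assert s2.mean == pytest.approx(s.mean, rel=1e-12)
        assert s2.sd == pytest.approx(s.sd, rel=1e-12)


class TestStageTrend:
    def _trend_matrix(self, values_by_group):
        cols, groups, vals = [], [], []
        for g, vs in values_by_group.items():
            for i, v in enumerate(vs):
                cols.append(f"{g}_{i}")
                groups.append(g)
                vals.append(v)
        m = ExpressionMatrix(
            values=pd.DataFrame([vals], index=["g"], columns=cols),
            groups=pd.Series(groups, index=cols),
            ordinal_rank={"normal": 0, "T1": 1, "T2": 2, "T3": 3},
        )
        return m

    def test_perfect_monotone_trend(self):
        # one sample per ordered group: expression strictly increasing
        # with stage rank gives a Spearman statistic of exactly 1
        groups = [f"T{i}" for i in range(8)]
        cols = [f"{g}_0" for g in groups]
        m = ExpressionMatrix(
            values=pd.DataFrame([list(range(1, 9))], index=["g"], columns=cols),
            groups=pd.Series(groups, index=cols),
            ordinal_rank={g: i for i, g in enumerate(groups)},
        )
        rho, p = stage_trend(m, "g", groups, n_permutations=2000, seed=0)
        assert rho == pytest.approx(1.0, abs=1e-12)
        assert p < 0.01

    def test_flat_data_returns_zero_statistic(self):
        m = self._trend_matrix({"normal": [2, 2], "T1": [2, 2], "T2": [2, 2], "T3": [2, 2]})
        rho, p = stage_trend(m, "g", ["normal", "T1", "T2", "T3"])
        assert (rho, p) == (0.0, 1.0)

    def test_null_statistic_small_and_p_spread(self):
        rng = np.random.default_rng(6)
        ps = []
        for seed in range(10):
            shuffled = rng.permutation(np.arange(16.0))
            m = self._trend_matrix({
                "normal": shuffled[:4], "T1": shuffled[4:8],
                "T2": shuffled[8:12], "T3": shuffled[12:],
            })
            _, p = stage_trend(m, "g", ["normal", "T1", "T2", "T3"],
                               n_permutations=200, seed=seed)
            ps.append(p)
        # under the null the permutation p-values should spread out
        assert min(ps) > 0.001 and max(ps) > 0.2
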