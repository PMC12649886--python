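"""First-principles statistics against closed-form and library oracles."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from osteoflow.core import InputError
from osteoflow.stats import (StatsError, anova_2x2, ddct, ddct_condition_tests,
                             fisher_lsd, t_test)

# hand-computed oracle for the fixed 2x2 dataset with cells
# {1,2}, {3,4}, {5,6}, {11,12} (2 observations per cell):
# grand mean 5.5; SS_A = 72, SS_B = 32, SS_AB = 8, SS_error = 2,
# df = (1, 1, 1, 4), MS_error = 0.5, F = (144, 64, 16)
HAND_Y = np.array([1.0, 2, 3, 4, 5, 6, 11, 12])
HAND_A = np.array(["a1", "a1", "a1", "a1", "a2", "a2", "a2", "a2"])
HAND_B = np.array(["b1", "b1", "b2", "b2", "b1", "b1", "b2", "b2"])


class TestTTest:
    def test_identical_groups(self):
        t, df, p = t_test([1.0, 2, 3], [1.0, 2, 3])
        assert (t, p) == (0.0, 1.0)
        assert df == 4

    def test_clear_separation(self):
        t, df, p = t_test([1.0, 2, 3], [11.0, 12, 13])
        assert p < 0.01

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        for variant, equal_var in (("student", True), ("welch", False)):
            a, b = rng.normal(0, 1, 12), rng.normal(0.4, 2, 9)
            t, df, p = t_test(a, b, variant)
            ref = sps.ttest_ind(a, b, equal_var=equal_var)
            assert t == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_zero_variance_unequal_means(self):
        t, _, p = t_test([1.0, 1.0], [2.0, 2.0])
        assert np.isinf(t) and p == 0.0

    def test_too_small_group_rejected(self):
        with pytest.raises(StatsError):
            t_test([1.0], [1.0, 2.0])

    def test_null_calibration_quick(self):
        """Type-I error near alpha on a small null Monte-Carlo."""
        rng = np.random.default_rng(1)
        rejections = sum(
            t_test(rng.normal(0, 1, 8), rng.normal(0, 1, 8))[2] <= 0.05
            for _ in range(1000))
        assert 0.03 <= rejections / 1000 <= 0.07


class TestAnova:
    def test_hand_oracle(self):
        table = anova_2x2(HAND_Y, HAND_A, HAND_B, a_name="A", b_name="B")
        assert table["A"]["ss"] == pytest.approx(72.0, rel=1e-12)
        assert table["B"]["ss"] == pytest.approx(32.0, rel=1e-12)
        assert table["A:B"]["ss"] == pytest.approx(8.0, rel=1e-12)
        assert table["error"]["ss"] == pytest.approx(2.0, rel=1e-12)
        assert [table[k]["df"] for k in ("A", "B", "A:B", "error")] == [1, 1, 1, 4]
        assert table["A"]["F"] == pytest.approx(144.0, rel=1e-12)
        assert table["B"]["F"] == pytest.approx(64.0, rel=1e-12)
        assert table["A:B"]["F"] == pytest.approx(16.0, rel=1e-12)

    def test_ss_decomposition_identity(self):
        rng = np.random.default_rng(2)
        y = rng.normal(0, 1, 40)
        a = np.repeat(["a1", "a2"], 20)
        b = np.tile(np.repeat(["b1", "b2"], 10), 2)
        table = anova_2x2(y, a, b)
        ss_total = float(np.sum((y - y.mean()) ** 2))
        parts = sum(table[k]["ss"] for k in ("condition", "pmd", "condition:pmd",
                                             "error"))
        assert parts == pytest.approx(ss_total, rel=1e-9)
        assert sum(table[k]["df"] for k in table.sources) == len(y) - 1

    def test_matches_statsmodels_balanced(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "y": rng.normal(0, 1, 24),
            "a": np.repeat(["a1", "a2"], 12),
            "b": np.tile(np.repeat(["b1", "b2"], 6), 2),
        })
        table = anova_2x2(df["y"].to_numpy(), df["a"].to_numpy(), df["b"].to_numpy())
        ref = sm.stats.anova_lm(ols("y ~ C(a) * C(b)", df).fit(), typ=2)
        assert table["condition"]["F"] == pytest.approx(ref.loc["C(a)", "F"], rel=1e-9)
        assert table["pmd"]["F"] == pytest.approx(ref.loc["C(b)", "F"], rel=1e-9)
        assert table["condition:pmd"]["p"] == pytest.approx(
            ref.loc["C(a):C(b)", "PR(>F)"], rel=1e-9)

    def test_matches_statsmodels_unbalanced_type2(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        rng = np.random.default_rng(4)
        a = np.array(["a1"] * 13 + ["a2"] * 9)
        b = np.array((["b1"] * 6 + ["b2"] * 7) + (["b1"] * 5 + ["b2"] * 4))
        y = rng.normal(0, 1, 22) + (a == "a2") * 0.5 + (b == "b2") * 0.2
        table = anova_2x2(y, a, b)
        df = pd.DataFrame({"y": y, "a": a, "b": b})
        ref = sm.stats.anova_lm(ols("y ~ C(a) * C(b)", df).fit(), typ=2)
        assert table["condition"]["ss"] == pytest.approx(
            ref.loc["C(a)", "sum_sq"], rel=1e-9)
        assert table["pmd"]["ss"] == pytest.approx(ref.loc["C(b)", "sum_sq"], rel=1e-9)
        assert table["condition:pmd"]["ss"] == pytest.approx(
            ref.loc["C(a):C(b)", "sum_sq"], rel=1e-9)

    def test_t_squared_equals_f_on_two_groups(self):
        # with a constant second factor the table reduces to a one-way ANOVA
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 10)
        t, _, p_t = t_test(a, b)
        table = anova_2x2(np.concatenate([a, b]),
                          np.repeat(["g1", "g2"], 10), np.repeat(["b1"], 20))
        assert t ** 2 == pytest.approx(table["condition"]["F"], rel=1e-9)
        assert p_t == pytest.approx(table["condition"]["p"], rel=1e-9)

    def test_constant_cells_flagged_degenerate(self):
        y = np.array([5.0] * 8)
        table = anova_2x2(y, HAND_A, HAND_B)
        assert table.degenerate
        assert table["error"]["ss"] == 0.0
        assert np.isnan(table["condition"]["F"])

    def test_empty_cell_rejected(self):
        with pytest.raises(StatsError):
            anova_2x2([1.0, 2, 3, 4], ["a1", "a1", "a2", "a2"],
                      ["b1", "b1", "b2", "b2"])  # (a1, b2) has no data


class TestFisherLsd:
    def make(self, cells):
        y, a, b = [], [], []
        for (ai, bj), vals in cells.items():
            y.extend(vals)
            a.extend([ai] * len(vals))
            b.extend([bj] * len(vals))
        table = anova_2x2(np.array(y), np.array(a), np.array(b))
        means = {k: float(np.mean(v)) for k, v in cells.items()}
        ns = {k: len(v) for k, v in cells.items()}
        return table, means, ns

    def test_equal_means_share_one_letter(self):
        rng = np.random.default_rng(6)
        cells = {(a, b): (5.0 + rng.normal(0, 0.05, 6)).tolist()
                 for a in ("a1", "a2") for b in ("b1", "b2")}
        table, means, ns = self.make(cells)
        _, letters = fisher_lsd(table, means, ns)
        assert len(set(letters.values())) == 1

    def test_outlying_cell_isolated(self):
        rng = np.random.default_rng(7)
        cells = {(a, b): (5.0 + rng.normal(0, 0.3, 6)).tolist()
                 for a in ("a1", "a2") for b in ("b1", "b2")}
        cells[("a2", "b2")] = (25.0 + rng.normal(0, 0.3, 6)).tolist()
        table, means, ns = self.make(cells)
        pairwise, letters = fisher_lsd(table, means, ns)
        outlier = letters[("a2", "b2")]
        others = [v for k, v in letters.items() if k != ("a2", "b2")]
        assert all(set(outlier).isdisjoint(o) for o in others)
        assert (pairwise["p"] <= 1).all() and (pairwise["p"] >= 0).all()

    def test_letters_stable_under_input_order(self):
        rng = np.random.default_rng(8)
        cells = {(a, b): (rng.normal(5 + 3 * (a == "a2"), 0.3, 5)).tolist()
                 for a in ("a1", "a2") for b in ("b1", "b2")}
        table, means, ns = self.make(cells)
        _, l1 = fisher_lsd(table, means, ns)
        reordered = dict(reversed(list(means.items())))
        _, l2 = fisher_lsd(table, reordered, ns)
        assert l1 == l2


class TestDdct:
    def table(self, folds_by_gene, n=3, hk_ct=12.0):
        rows = []
        for cond in ("control", "disuse"):
            for i in range(n):
                sample = f"{cond}_{i}"
                rows.append({"sample": sample, "condition": cond,
                             "gene": "18S", "ct": hk_ct})
                for gene, fold in folds_by_gene.items():
                    ct = 24.0 - (np.log2(fold) if cond == "disuse" else 0.0)
                    rows.append({"sample": sample, "condition": cond,
                                 "gene": gene, "ct": ct})
        return pd.DataFrame(rows)

    def test_identities(self):
        res = ddct(self.table({"g": 2.0}), housekeeping="18S", reference="control")
        ctrl = res[res.condition == "control"]
        dis = res[res.condition == "disuse"]
        assert np.allclose(ctrl["delta_delta_ct"], 0.0)
        assert np.allclose(ctrl["fold"], 1.0)       # ddCt = 0 -> fold 1
        assert np.allclose(dis["delta_delta_ct"], -1.0)
        assert np.allclose(dis["fold"], 2.0)        # ddCt = -1 -> fold 2

    def test_missing_housekeeping_names_sample(self):
        table = self.table({"g": 2.0})
        table = table[~((table["sample"] == "disuse_1") & (table.gene == "18S"))]
        with pytest.raises(InputError, match="disuse_1"):
            ddct(table)

    def test_condition_tests_report_folds(self):
        out = ddct_condition_tests(ddct(self.table({"g": 4.0}, n=4)))
        assert out.loc[0, "mean_fold"] == pytest.approx(4.0)
        assert out.loc[0, "p"] == 0.0  # zero noise: exact separation
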