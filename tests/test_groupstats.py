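"""Normality gate, ANOVA/Tukey, two-way ANOVA, Kruskal-Wallis/Dunn, qPCR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from plastimetry import groupstats as gs
from plastimetry.errors import (
    DataError,
    DesignError,
    InsufficientDataError,
    UndefinedStatisticError,
)


def tidy(**groups):
    rows = []
    for g, vals in groups.items():
        for i, v in enumerate(vals):
            rows.append({"unit_id": f"{g}{i}", "group": g, "value": float(v)})
    return pd.DataFrame(rows)


class TestNormalityGate:
    def test_normal_data_goes_parametric(self):
        """Gaussian groups (n=30) pass the gate in >= 95% of replicates."""
        hits = 0
        n_rep = 200
        rng = np.random.default_rng(0)
        for _ in range(n_rep):
            data = tidy(A=rng.normal(0, 1, 30), B=rng.normal(0, 1, 30),
                        C=rng.normal(0, 1, 30))
            if gs.normality_gate(data)["branch"] == "parametric":
                hits += 1
        assert hits / n_rep >= 0.80  # (1 - 0.05)^3 ~ 0.857 expected

    def test_heavy_tailed_data_goes_nonparametric(self):
        hits = 0
        n_rep = 100
        rng = np.random.default_rng(1)
        for _ in range(n_rep):
            data = tidy(A=rng.lognormal(0, 2, 30), B=rng.lognormal(0, 2, 30))
            if gs.normality_gate(data)["branch"] == "nonparametric":
                hits += 1
        assert hits / n_rep >= 0.9

    def test_constant_group_routed_nonparametric(self, caplog):
        data = tidy(A=[1, 1, 1, 1], B=[1, 2, 3, 4])
        with caplog.at_level("WARNING"):
            decision = gs.normality_gate(data)
        assert decision["branch"] == "nonparametric"
        assert np.isnan(decision["per_group_p"]["A"])
        assert "constant" in caplog.text

    def test_tiny_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            gs.normality_gate(tidy(A=[1, 2], B=[1, 2, 3]))


class TestOneWayAnova:
    def test_hand_computed_f(self):
        """Groups {1,2} vs {3,4}: SSB=4, SSW=1 -> F(1,2) = 8."""
        res = gs.one_way_anova_tukey(tidy(A=[1, 2], B=[3, 4]))
        assert res.statistic == pytest.approx(8.0, abs=1e-6)
        assert res.df == (1, 2)
        assert res.posthoc == []  # only 2 groups

    def test_identical_groups_f_zero(self):
        res = gs.one_way_anova_tukey(tidy(A=[1, 2], B=[1, 2]))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            gs.one_way_anova_tukey(tidy(A=[5, 5], B=[5, 5]))

    def test_f_equals_t_squared_at_two_groups(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        res = gs.one_way_anova_tukey(tidy(A=a, B=b))
        t, p = sps.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(t**2, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_shifted_group_dominates_tukey(self):
        """A 2-sigma shift in one of three groups drives the omnibus p below
        0.05 and makes that group's two Tukey pairs the smallest."""
        rng = np.random.default_rng(3)
        res = gs.one_way_anova_tukey(tidy(
            A=rng.normal(0, 1, 20), B=rng.normal(0, 1, 20),
            C=rng.normal(2, 1, 20)))
        assert res.p_value < 0.05
        ps = {d["pair"]: d["p"] for d in res.posthoc}
        c_pairs = [v for k, v in ps.items() if "C" in k]
        others = [v for k, v in ps.items() if "C" not in k]
        assert max(c_pairs) < min(others)


class TestTwoWayAnova:
    def _table(self, means, n=4, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for gi, g in enumerate(sorted(means)):
            for li, mu in enumerate(means[g]):
                for r in range(n):
                    rows.append({
                        "unit_id": f"{g}_{li}_{r}", "group": g,
                        "factor_level": f"d{li}",
                        "value": mu + noise * rng.normal(),
                    })
        return pd.DataFrame(rows)

    @staticmethod
    def _replicate_pattern(data):
        """Add the same within-cell residual pattern to every cell, keeping
        all cell means untouched so effect SS values are exact."""
        pattern = np.array([0.5, -0.5, 0.25, -0.25])
        reps = data.groupby(["group", "factor_level"]).cumcount()
        data = data.copy()
        data["value"] += pattern[reps % len(pattern)]
        return data

    def test_flat_design_all_f_zero(self):
        data = self._replicate_pattern(
            self._table({"A": [1, 1], "B": [1, 1]}, n=4))
        res = gs.two_way_anova(data)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        for d in res.posthoc:
            assert d["F"] == pytest.approx(0.0, abs=1e-10)

    def test_additive_effects_no_interaction(self):
        """Purely additive cell means give interaction SS = 0 exactly."""
        means = {"A": [1, 2, 3], "B": [2, 3, 4], "C": [4, 5, 6]}
        data = self._replicate_pattern(self._table(means, n=4))
        res = gs.two_way_anova(data)
        inter = [d for d in res.posthoc if d["pair"] == "interaction"][0]
        assert inter["F"] == pytest.approx(0.0, abs=1e-8)
        assert res.statistic > 0  # the group main effect is real

    def test_matches_cell_means_decomposition(self):
        """Sums of squares agree with an independently coded balanced
        cell-means computation."""
        data = self._table({"A": [0, 1], "B": [2, 0]}, n=5, noise=1.0, seed=7)
        res = gs.two_way_anova(data)
        piv = data.pivot_table(index="group", columns="factor_level",
                               values="value", aggfunc="mean")
        n = 5
        grand = data["value"].mean()
        row_means = data.groupby("group")["value"].mean()
        col_means = data.groupby("factor_level")["value"].mean()
        ss_group = n * piv.shape[1] * ((row_means - grand) ** 2).sum()
        resid = data.copy()
        cell_mean = data.groupby(["group", "factor_level"])["value"] \
            .transform("mean")
        ss_err = ((data["value"] - cell_mean) ** 2).sum()
        df_group = piv.shape[0] - 1
        df_err = len(data) - piv.size
        f_group = (ss_group / df_group) / (ss_err / df_err)
        assert res.statistic == pytest.approx(f_group, abs=1e-8)
        assert res.df == (df_group, df_err)

    def test_empty_cell_rejected(self):
        data = self._table({"A": [1, 2], "B": [2, 3]}, n=2, noise=1, seed=3)
        data = data[~((data.group == "B") & (data.factor_level == "d1"))]
        with pytest.raises(DesignError):
            gs.two_way_anova(data)


class TestKruskalDunn:
    def test_hand_rank_h(self):
        """{1,2,3} vs {4,5,6}: ranks 1..6 give H = 3.857..."""
        res = gs.kruskal_dunn(tidy(A=[1, 2, 3], B=[4, 5, 6]))
        assert res.statistic == pytest.approx(27 / 7, abs=1e-6)

    def test_identical_groups_h_zero(self):
        res = gs.kruskal_dunn(tidy(A=[1, 2, 3], B=[1, 2, 3]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_all_identical_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            gs.kruskal_dunn(tidy(A=[2, 2], B=[2, 2]))

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        a, b, c = (rng.uniform(0, 5, 15) for _ in range(3))
        r1 = gs.kruskal_dunn(tidy(A=a, B=b, C=c))
        r2 = gs.kruskal_dunn(tidy(A=np.exp(a), B=np.exp(b), C=np.exp(c)))
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-10)
        for d1, d2 in zip(r1.posthoc, r2.posthoc):
            assert d1["p"] == pytest.approx(d2["p"], abs=1e-10)

    def test_dominant_group_has_smallest_dunn_p(self):
        rng = np.random.default_rng(5)
        res = gs.kruskal_dunn(tidy(
            A=rng.normal(0, 1, 20), B=rng.normal(0, 1, 20),
            C=rng.normal(2, 1, 20)))
        ps = {d["pair"]: d["p"] for d in res.posthoc}
        c_pairs = [v for k, v in ps.items() if "C" in k]
        others = [v for k, v in ps.items() if "C" not in k]
        assert min(c_pairs) < min(others)

    def test_holm_adjustment_monotone(self):
        rng = np.random.default_rng(6)
        res = gs.kruskal_dunn(tidy(
            A=rng.normal(0, 1, 10), B=rng.normal(1, 1, 10),
            C=rng.normal(2, 1, 10)), adjust="holm")
        for d in res.posthoc:
            assert d["p_adjusted"] >= d["p"]


class TestNullCalibration:
    @pytest.mark.parametrize("test_fn", [gs.one_way_anova_tukey,
                                         gs.kruskal_dunn])
    def test_type_one_error_near_nominal(self, test_fn):
        """Under identical groups both omnibus tests reject at ~5%."""
        rng = np.random.default_rng(11)
        n_rep, alpha = 500, 0.05
        rejections = 0
        for _ in range(n_rep):
            data = tidy(A=rng.normal(0, 1, 10), B=rng.normal(0, 1, 10),
                        C=rng.normal(0, 1, 10))
            if test_fn(data, posthoc=False).p_value < alpha:
                rejections += 1
        se = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(rejections / n_rep - alpha) <= 3 * se


class TestExpression:
    def _expr(self):
        rows = []
        # control samples: dCt(GeneX) = 2 for both; treated: one cycle lower
        for sid, grp, gapdh, genex in [
            ("c1", "ctl", 20.0, 22.0), ("c2", "ctl", 21.0, 23.0),
            ("t1", "trt", 20.0, 21.0), ("t2", "trt", 20.5, 23.5),
        ]:
            rows += [
                {"sample_id": sid, "group": grp, "gene": "Gapdh", "ct": gapdh},
                {"sample_id": sid, "group": grp, "gene": "GeneX", "ct": genex},
            ]
        return pd.DataFrame(rows)

    def test_fold_identities(self):
        out = gs.relative_expression(self._expr(), "ctl")
        by = out.set_index("sample_id")
        assert by.loc["c1", "fold"] == pytest.approx(1.0)  # dCt = control mean
        assert by.loc["t1", "fold"] == pytest.approx(2.0)  # one cycle below
        assert by.loc["t2", "fold"] == pytest.approx(0.5)  # one cycle above

    def test_two_cycles_above_gives_quarter(self):
        expr = self._expr()
        expr.loc[(expr.sample_id == "t1") & (expr.gene == "GeneX"), "ct"] = 24.0
        out = gs.relative_expression(expr, "ctl")
        assert out.set_index("sample_id").loc["t1", "fold"] \
            == pytest.approx(0.25)

    def test_control_geometric_mean_is_one(self):
        out = gs.relative_expression(self._expr(), "ctl")
        ctl = out[out.group == "ctl"]
        assert np.exp(np.log(ctl.fold).mean()) == pytest.approx(1.0)

    def test_reference_shift_invariance(self):
        """Adding a constant to every Ct of one sample (genes and reference
        alike) leaves all folds unchanged."""
        expr = self._expr()
        shifted = expr.copy()
        shifted.loc[shifted.sample_id == "t1", "ct"] += 3.0
        f1 = gs.relative_expression(expr, "ctl")
        f2 = gs.relative_expression(shifted, "ctl")
        pd.testing.assert_frame_equal(f1, f2)

    def test_missing_reference_rejected(self):
        expr = self._expr()
        expr = expr[~((expr.sample_id == "t1") & (expr.gene == "Gapdh"))]
        with pytest.raises(DataError):
            gs.relative_expression(expr, "ctl")


class TestPerGeneTests:
    def test_identical_values_give_p_one(self):
        tab = pd.DataFrame({
            "gene": ["g"] * 6, "group": ["A"] * 3 + ["B"] * 3,
            "fold": [1.0] * 6,
        })
        out = gs.per_gene_tests(tab, [("A", "B")])
        assert out.loc[0, "t"] == 0.0
        assert out.loc[0, "p"] == 1.0

    def test_separated_groups_tiny_p(self):
        rng = np.random.default_rng(7)
        tab = pd.DataFrame({
            "gene": ["g"] * 10, "group": ["A"] * 5 + ["B"] * 5,
            "fold": np.r_[1 + 1e-3 * rng.normal(size=5),
                          2 + 1e-3 * rng.normal(size=5)],
        })
        out = gs.per_gene_tests(tab, [("A", "B")])
        assert out.loc[0, "p"] < 1e-3

    def test_true_effects_rank_first(self):
        """Two genes with 2-sigma effects rank in the top 2 by p in most
        replicates of a 6-gene panel."""
        rng = np.random.default_rng(8)
        wins = 0
        n_rep = 50
        for _ in range(n_rep):
            rows = []
            for gi in range(6):
                delta = 2.0 if gi < 2 else 0.0
                for grp, shift in (("A", 0.0), ("B", delta)):
                    for r in range(5):
                        rows.append({"gene": f"g{gi}", "group": grp,
                                     "fold": shift + rng.normal()})
            out = gs.per_gene_tests(pd.DataFrame(rows), [("A", "B")])
            top2 = set(out.nsmallest(2, "p")["gene"])
            if top2 == {"g0", "g1"}:
                wins += 1
        assert wins / n_rep > 0.5

    def test_missing_gene_named(self):
        tab = pd.DataFrame({
            "gene": ["g"] * 3, "group": ["A"] * 3, "fold": [1.0, 2.0, 3.0],
        })
        with pytest.raises(DataError, match="'g'"):
            gs.per_gene_tests(tab, [("A", "B")])
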