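import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import cardiomet as cm


class TestMeanCi:
    def test_known_small_sample(self):
        cell = cm.mean_ci([1.0, 2.0, 3.0])
        assert cell.mean == pytest.approx(2.0)
        # SD 1, t_{0.975,2}=4.303, /sqrt(3)
        assert cell.ci_high - cell.mean == pytest.approx(2.484, abs=1e-3)

    def test_constant_vector_zero_width(self):
        cell = cm.mean_ci([5.0, 5.0, 5.0, 5.0])
        assert cell.ci_low == cell.mean == cell.ci_high == 5.0

    def test_round_trips_with_ci_to_sd(self, rng):
        vals = rng.normal(10, 3, size=32)
        cell = cm.mean_ci(vals)
        assert cm.ci_to_sd(cell.mean, cell.ci_low, cell.ci_high, cell.n) == pytest.approx(
            np.std(vals, ddof=1), rel=1e-10
        )

    def test_single_value_rejected(self):
        with pytest.raises(cm.ValidationError):
            cm.mean_ci([1.0])


class TestPercentDifference:
    @pytest.mark.parametrize(
        "ref,cmp_,expected",
        [(123.1, 97.4, -20.9), (86.8, 93.1, 7.3), (5.0, 5.0, 0.0)],
    )
    def test_published_convention(self, ref, cmp_, expected):
        from cardiomet.utils import round_half_up

        assert round_half_up(cm.percent_difference(ref, cmp_), 1) == expected

    @given(a=st.floats(1, 1000), b=st.floats(1, 1000))
    def test_reciprocal_identity(self, a, b):
        d1 = cm.percent_difference(a, b)
        d2 = cm.percent_difference(b, a)
        assert (1 + d1 / 100) * (1 + d2 / 100) == pytest.approx(1.0, rel=1e-12)

    def test_zero_reference_rejected(self):
        with pytest.raises(cm.ValidationError):
            cm.percent_difference(0.0, 5.0)


class TestNormalityScreen:
    def test_null_rarely_rejected(self):
        rng = np.random.default_rng(0)
        rejections = sum(cm.normality_p(rng.normal(size=32)) < 0.05 for _ in range(1000))
        assert rejections <= 100  # nominal 5% level, allow 10%

    def test_skewed_alternative_usually_rejected(self):
        rng = np.random.default_rng(1)
        rejections = sum(cm.normality_p(rng.lognormal(sigma=1.0, size=32)) < 0.05 for _ in range(200))
        assert rejections > 100  # majority of seeds

    def test_constant_sample_rejected(self):
        with pytest.raises(cm.ValidationError):
            cm.normality_p([2.0] * 10)

    def test_out_of_range_n_rejected(self):
        with pytest.raises(cm.ValidationError):
            cm.normality_p([1.0, 2.0])


def _oracle_ols(X, y):
    """Normal equations by explicit inversion, with classical t-tests."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    s2 = resid @ resid / df
    se = np.sqrt(np.diag(s2 * XtX_inv))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return beta, se, p


class TestAncovaTwoGroup:
    def test_identical_groups_null_effect(self):
        y = np.array([1.0, 2.5, 2.0, 4.0, 1.0, 2.5, 2.0, 4.0])  # not collinear with age
        group = np.array(["A"] * 4 + ["B"] * 4)
        age = np.array([20.0, 30, 40, 50] * 2)
        sex = np.array(["F", "F", "M", "M"] * 2)
        res = cm.ancova_two_group(y, group, age, sex)
        assert res.estimate == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0, abs=1e-9)

    def test_fixed_design_matches_normal_equations(self):
        # small printed design: 6 subjects, 2 groups
        y = np.array([10.0, 12.0, 11.5, 15.0, 16.5, 14.0])
        group = np.array(["A", "A", "A", "B", "B", "B"])
        age = np.array([25.0, 35.0, 45.0, 28.0, 38.0, 48.0])
        sex = np.array(["F", "M", "F", "M", "F", "M"])
        res = cm.ancova_two_group(y, group, age, sex)
        X = np.column_stack([np.ones(6), (group == "B").astype(float), age, (sex == "M").astype(float)])
        beta, se, p = _oracle_ols(X, y)
        assert res.params.to_numpy() == pytest.approx(beta, abs=1e-10)
        assert res.pvalue == pytest.approx(p[1], abs=1e-10)

    def test_reduces_to_equal_variance_t_test(self, rng):
        y = rng.normal(size=20)
        group = np.array(["A"] * 10 + ["B"] * 10)
        res = cm.ancova_two_group(y, group)  # no covariates
        t = stats.ttest_ind(y[10:], y[:10], equal_var=True)
        assert res.pvalue == pytest.approx(t.pvalue, abs=1e-12)
        assert res.estimate == pytest.approx(y[10:].mean() - y[:10].mean(), abs=1e-12)

    def test_constant_sex_covariate_dropped(self, caplog):
        rng = np.random.default_rng(5)
        y = rng.normal(size=12)
        group = np.array(["A"] * 6 + ["B"] * 6)
        age = rng.uniform(20, 50, 12)
        sex = np.array(["F"] * 12)
        with caplog.at_level("WARNING", logger="cardiomet"):
            res = cm.ancova_two_group(y, group, age, sex)
        assert "sex" in caplog.text
        assert "sex" not in res.params.index

    def test_rank_variant_is_location_invariant(self, rng):
        y = rng.normal(size=24)
        group = np.array(["A"] * 12 + ["B"] * 12)
        age = rng.uniform(20, 50, 24)
        sex = np.array(["F", "M"] * 12)
        a = cm.ancova_two_group(y, group, age, sex, rank=True)
        b = cm.ancova_two_group(np.exp(y), group, age, sex, rank=True)  # monotone transform
        assert a.pvalue == pytest.approx(b.pvalue, abs=1e-12)

    def test_power_at_published_effect_size(self, default_specs):
        # body-weight gap between the cohorts is enormous relative to noise
        import dataclasses

        hits = 0
        n_sims = 200
        for i in range(n_sims):
            pws = cm.generate_cohort(dataclasses.replace(default_specs[0], seed=10_000 + i))
            eob = cm.generate_cohort(dataclasses.replace(default_specs[1], seed=20_000 + i))
            df = pd.concat([pws.to_dataframe(), eob.to_dataframe()], ignore_index=True)
            res = cm.ancova_two_group(df["weight"], df["group"], df["age"], df["sex"], reference="EOB")
            if res.estimate < 0 and res.pvalue < 0.001:
                hits += 1
        assert hits >= 0.95 * n_sims


class TestFourGroupComparison:
    @staticmethod
    def _covariates(rng, n):
        return rng.uniform(20, 50, n), rng.choice(["F", "M"], n)

    def test_identical_groups_no_pairs_either_path(self, rng):
        n = 64
        y = rng.normal(size=n)
        group = np.repeat(["g1", "g2", "g3", "g4"], n // 4)
        age, sex = self._covariates(rng, n)
        for normal in (True, False):
            ph = cm.four_group_comparison(y, group, age, sex, normal=normal)
            assert ph.significant_pairs == []
            assert all(v == "" for v in ph.letters.values())

    def test_shifted_group_flagged_against_all(self):
        hits = 0
        n_sims = 100
        for i in range(n_sims):
            r = np.random.default_rng(i)
            y = r.normal(size=64)
            group = np.repeat(["g1", "g2", "g3", "g4"], 16)
            y[group == "g3"] += 5.0  # 5 SD shift
            age, sex = self._covariates(r, 64)
            ph = cm.four_group_comparison(y, group, age, sex, normal=True)
            if all(ph.significant("g3", other) for other in ("g1", "g2", "g4")):
                hits += 1
        assert hits >= 95

    def test_pair_lookup_is_symmetric(self, rng):
        y = rng.normal(size=40)
        group = np.repeat(["a", "b", "c", "d"], 10)
        ph = cm.four_group_comparison(y, group)
        for a, b in [("a", "b"), ("c", "a"), ("d", "b")]:
            assert ph.p(a, b) == ph.p(b, a)

    def test_letters_mark_significant_pairs(self):
        r = np.random.default_rng(3)
        y = r.normal(size=64)
        group = np.repeat(["g1", "g2", "g3", "g4"], 16)
        y[group == "g4"] += 6.0
        ph = cm.four_group_comparison(y, group)
        for a, b in ph.significant_pairs:
            shared = set(ph.letters[a]) & set(ph.letters[b])
            assert shared, f"pair ({a},{b}) significant but shares no letter"

    def test_empty_subgroup_rejected(self, rng):
        y = rng.normal(size=30)
        group = np.repeat(["a", "b", "c"], 10)
        with pytest.raises(cm.ValidationError):
            cm.four_group_comparison(y, group)


class TestCohortComparisonModel:
    def test_two_group_fit_table(self, panels):
        results = cm.CohortComparison(panels, variables=["weight", "bmr", "glucose"]).fit()
        table = results.table
        assert list(table["variable"]) == ["weight", "bmr", "glucose"]
        assert ((table["p_adjusted"] >= 0) & (table["p_adjusted"] <= 1)).all()
        assert set(table["method"]) <= {"parametric", "rank"}
        # massive body-size difference must be detected
        weight = table[table["variable"] == "weight"].iloc[0]
        assert weight["p_adjusted"] < 0.001 and weight["estimate"] < 0

    def test_percent_diff_matches_cell_means(self, panels):
        results = cm.CohortComparison(panels, variables=["bmr"]).fit()
        row = results.rows[0]
        expected = cm.percent_difference(row.cells["EOB"].mean, row.cells["PWS"].mean)
        assert row.percent_diff == pytest.approx(expected)

    def test_four_group_fit_emits_letters(self, panels):
        df = panels.assign(subgroup=panels["group"] + " " + panels["mets_status"])
        results = cm.CohortComparison(df, variables=["weight", "mets_z"], group="subgroup").fit()
        row = results.rows[1]
        assert row.letters is not None
        assert set(row.letters) == set(df["subgroup"].unique())

    def test_summary_renders(self, panels):
        text = cm.CohortComparison(panels, variables=["weight"]).fit().summary()
        assert "weight" in text and "EOB" in text
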