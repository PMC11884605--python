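import numpy as np
import pytest
from scipy import stats as sps

from conftest import make_two_class_table
from metajac.mvstats import (
    cohens_d,
    fit_oplsda,
    fit_pca,
    permutation_validity,
    screen_metabolites,
    vip_scores,
)
from metajac.table import MetaboliteTable


class TestCohensD:
    def test_power_analysis_inputs(self):
        assert cohens_d(20.0, 10.0) == pytest.approx(2.0)

    @pytest.mark.parametrize("diff, sd, expected", [(0.0, 3.0, 0.0), (2.5, 2.5, 1.0)])
    def test_degenerate_and_unit(self, diff, sd, expected):
        assert cohens_d(diff, sd) == pytest.approx(expected)

    def test_nonpositive_sd(self):
        with pytest.raises(ValueError):
            cohens_d(1.0, 0.0)


class TestPca:
    def test_collinear_data_one_component(self):
        x = np.linspace(1, 10, 30)
        tab = MetaboliteTable([f"s{i}" for i in range(30)], ["c"] * 30,
                              ["a", "b"], np.column_stack([x, 3 * x]))
        res = fit_pca(tab, 1, scaling="center")
        assert res.r2x[0] > 0.999

    def test_scores_orthogonal_and_r2x_matches_eigen_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 6)) @ np.diag([3, 2, 1.5, 1, 0.5, 0.2])
        tab = MetaboliteTable([f"s{i}" for i in range(50)], ["c"] * 50,
                              [f"m{j}" for j in range(6)], np.abs(X) + 1)
        res = fit_pca(tab, 4, scaling="center")
        G = res.scores.T @ res.scores
        assert np.allclose(G, np.diag(np.diag(G)), atol=1e-8)
        # eigen oracle on the centered covariance
        Xc = tab.values - tab.values.mean(axis=0)
        ev = np.sort(np.linalg.eigvalsh(np.cov(Xc, rowvar=False)))[::-1]
        assert np.allclose(res.r2x, ev[:4] / ev.sum(), atol=1e-10)
        assert np.all(np.diff(res.r2x_cum) >= 0) and res.r2x_cum[-1] <= 1

    def test_too_many_components(self):
        tab = make_two_class_table(0, n=10, p=3)
        with pytest.raises(ValueError):
            fit_pca(tab, 10)


class TestOplsDa:
    def test_separated_classes_fit_well(self):
        m = fit_oplsda(make_two_class_table(0, shift=6.0), classes=("A", "B"), seed=0)
        assert m.r2y_cum > 0.9
        assert m.q2_cum > 0.5
        assert 0 <= m.r2x_cum <= 1

    def test_null_data_has_no_predictive_power(self):
        q2 = [
            fit_oplsda(make_two_class_table(s, shift=0.0), classes=("A", "B"), seed=s).q2_cum
            for s in range(10)
        ]
        assert max(q2) <= 0.1

    def test_q2_never_beats_r2y(self):
        for s in range(6):
            m = fit_oplsda(make_two_class_table(s, shift=2.0), classes=("A", "B"), seed=s)
            assert m.q2_cum <= m.r2y_cum + 1e-9

    def test_duplicated_informative_metabolite_keeps_predictions(self):
        tab = make_two_class_table(1, shift=6.0)
        dup = MetaboliteTable(
            sample_ids=list(tab.sample_ids),
            conditions=list(tab.conditions),
            metabolites=tab.metabolites + ["met0_copy"],
            values=np.column_stack([tab.values, tab.values[:, 0]]),
        )
        m1 = fit_oplsda(tab, classes=("A", "B"), seed=1)
        m2 = fit_oplsda(dup, classes=("A", "B"), seed=1)
        assert m1.predict(tab.values) == m2.predict(dup.values)

    def test_fold_reduction_warns(self):
        tab = make_two_class_table(2, n=8)
        with pytest.warns(UserWarning, match="cv_folds"):
            m = fit_oplsda(tab, classes=("A", "B"), cv_folds=7, seed=0)
        assert m.cv_folds <= 4

    def test_tiny_class_rejected(self):
        tab = make_two_class_table(3, n=40)
        tab.conditions = ["A"] * 39 + ["B"]
        with pytest.raises(ValueError, match=">= 2"):
            fit_oplsda(tab, classes=("A", "B"), seed=0)


class TestVip:
    def test_single_variable_is_one(self):
        tab = make_two_class_table(0, p=1, shift=4.0)
        m = fit_oplsda(tab, classes=("A", "B"), seed=0, n_ortho=0)
        assert m.vip == pytest.approx([1.0])

    def test_informative_above_one_noise_below(self):
        m = fit_oplsda(make_two_class_table(4, shift=5.0), classes=("A", "B"), seed=4)
        assert m.vip[0] > 1.0 > np.median(m.vip[1:])

    def test_mean_square_is_exactly_one(self):
        for s in range(5):
            m = fit_oplsda(make_two_class_table(s, shift=float(s)), classes=("A", "B"), seed=s)
            assert np.mean(vip_scores(m) ** 2) == pytest.approx(1.0, abs=1e-6)


class TestPermutation:
    def test_record_defaults_and_p_value_range(self):
        tab = make_two_class_table(0)
        m = fit_oplsda(tab, classes=("A", "B"), seed=0)
        rec = permutation_validity(tab, ("A", "B"), m, n_perm=200, seed=0)
        assert rec.n_perm == 200
        assert 1 / 201 <= rec.p_value() <= 1.0

    def test_separated_data_valid(self):
        hits = 0
        for s in range(3):
            tab = make_two_class_table(s, shift=6.0)
            m = fit_oplsda(tab, classes=("A", "B"), seed=s)
            hits += permutation_validity(tab, ("A", "B"), m, n_perm=50, seed=s).valid
        assert hits == 3

    def test_noise_data_invalid(self):
        hits = 0
        for s in range(3):
            tab = make_two_class_table(s + 50, shift=0.0)
            m = fit_oplsda(tab, classes=("A", "B"), seed=s)
            hits += permutation_validity(tab, ("A", "B"), m, n_perm=50, seed=s).valid
        assert hits == 0


class TestScreen:
    def test_fold_change_arithmetic(self):
        rng = np.random.default_rng(0)
        a = rng.normal(2.0, 0.01, size=(10, 1))
        b = rng.normal(4.0, 0.01, size=(10, 1))
        tab = MetaboliteTable([f"s{i}" for i in range(20)], ["A"] * 10 + ["B"] * 10,
                              ["m"], np.vstack([a, b]))
        res = screen_metabolites(tab, ["A", "B"], np.array([1.5]))
        assert res.table["fold_change"][0] == pytest.approx(1.0, abs=0.01)

    def test_equal_means_zero_fold_change(self):
        vals = np.tile(np.array([[3.0]]), (8, 1))
        tab = MetaboliteTable([f"s{i}" for i in range(8)], ["A"] * 4 + ["B"] * 4,
                              ["m"], vals)
        res = screen_metabolites(tab, ["A", "B"], np.array([0.5]))
        assert res.table["fold_change"][0] == 0.0

    def test_selection_rule_conjunction(self):
        """Exhaustive 2x2 check: selected iff VIP > 1 and p < 0.05."""
        rng = np.random.default_rng(1)
        n = 12
        sep = np.concatenate([rng.normal(5, 0.3, n), rng.normal(9, 0.3, n)])  # p < 0.05
        same = rng.normal(5, 0.3, 2 * n)  # p >= 0.05
        tab = MetaboliteTable(
            [f"s{i}" for i in range(2 * n)],
            ["A"] * n + ["B"] * n,
            ["sig_hi", "sig_lo", "null_hi", "null_lo"],
            np.column_stack([sep, sep, same, same]),
        )
        vip = np.array([1.2, 0.8, 1.2, 0.8])
        res = screen_metabolites(tab, ["A", "B"], vip)
        assert list(res.table["selected"]) == [True, False, False, False]
        assert res.selected() == ["sig_hi"]

    def test_anova_two_groups_equals_t_squared(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 15), rng.normal(0.8, 1, 15)
        t = sps.ttest_ind(a, b, equal_var=True)
        f = sps.f_oneway(a, b)
        assert f.statistic == pytest.approx(t.statistic**2, abs=1e-10)
        assert f.pvalue == pytest.approx(t.pvalue, abs=1e-10)

    def test_multigroup_uses_anova(self):
        rng = np.random.default_rng(3)
        X = rng.normal(5, 1, size=(30, 2))
        X[20:, 0] += 4
        tab = MetaboliteTable([f"s{i}" for i in range(30)],
                              ["A"] * 10 + ["B"] * 10 + ["C"] * 10,
                              ["m1", "m2"], X)
        res = screen_metabolites(tab, ["A", "B", "C"], np.array([1.5, 1.5]))
        assert res.table["p_value"][0] < 0.05 < res.table["p_value"][1]

    def test_small_group_rejected(self):
        tab = make_two_class_table(0, n=40)
        with pytest.raises(ValueError, match="groups|2 samples"):
            screen_metabolites(tab, ["A"], np.ones(10))
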