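"""Frequentist and Bayesian group statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from gammadcm.microcircuit import ConfigurationError
from gammadcm.stats import (
    BayesResult,
    GroupSummary,
    UndefinedStatisticError,
    bf_best_ratio,
    bonferroni,
    jzs_bf,
    jzs_bf_from_t,
    mixed_anova,
    pearson,
    t_test,
)


class TestTTest:
    def test_cohort_age_summaries_reproduce_reported_p(self):
        # pooled t-tests from group size/mean/SD summaries of the two cohorts
        res = t_test(GroupSummary(29, 41.1, 10.1), GroupSummary(27, 44.7, 8.5))
        assert round(res.p, 2) == 0.16
        males = t_test(GroupSummary(18, 41.6, 9.4), GroupSummary(19, 44.2, 8.8))
        assert round(males.p, 1) == 0.4

    def test_identical_groups_give_null_result(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = t_test(x, x)
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    def test_pooled_df_and_welch_df(self):
        a, b = GroupSummary(10, 0.0, 1.0), GroupSummary(14, 0.5, 3.0)
        assert t_test(a, b, "pooled").df == 22
        w = t_test(a, b, "welch").df
        assert 13 < w < 22          # Satterthwaite df between min(n)-1 and pooled

    def test_agrees_with_permutation_oracle(self, rng):
        x = rng.normal(0.0, 1.0, 6)
        y = rng.normal(1.0, 1.0, 6)
        res = t_test(x, y, "pooled")
        pooled = np.r_[x, y]
        n_perm = 100_000
        idx = np.argsort(rng.random((n_perm, 12)), axis=1)
        perm = pooled[idx]
        d = perm[:, :6].mean(axis=1) - perm[:, 6:].mean(axis=1)
        p_perm = np.mean(np.abs(d) >= abs(x.mean() - y.mean()) - 1e-12)
        mc_err = 3 * np.sqrt(p_perm * (1 - p_perm) / n_perm)
        # permutation and t reference distributions agree for normal data
        assert abs(res.p - p_perm) < max(0.02, 5 * mc_err)

    def test_zero_variance_everywhere_rejected(self):
        x = np.ones(5)
        with pytest.raises(UndefinedStatisticError):
            t_test(x, x + 1.0)


class TestMixedAnova:
    @staticmethod
    def _dataset(rng, n_per_group=10, group_shift=0.0):
        n = 2 * n_per_group
        subj_effect = rng.normal(0, 1.0, n)
        rows = []
        for i in range(n):
            g = "a" if i < n_per_group else "b"
            for cond in ("v", "o"):
                val = subj_effect[i] + rng.normal(0, 1.0)
                if g == "b":
                    val += group_shift
                rows.append({"subject": i, "group": g, "condition": cond,
                             "value": val})
        return pd.DataFrame(rows)

    def test_injected_group_effect_found_interaction_absent(self, rng):
        fg, fi = [], []
        for _ in range(50):
            df = self._dataset(rng, group_shift=1.5)
            res = mixed_anova(df)
            fg.append(res["group"].statistic)
            fi.append(res["interaction"].statistic)
        assert np.mean(fg) > 5.0
        assert np.mean(fi) == pytest.approx(1.0, abs=0.5)

    def test_matches_regression_oracle(self, rng):
        # reduce the 2x2 mixed design to two independent OLS problems on
        # per-subject means (between) and differences (within/interaction)
        for _ in range(5):
            df = self._dataset(rng)
            wide = df.pivot_table(index=["subject", "group"],
                                  columns="condition", values="value").reset_index()
            mean = wide[["o", "v"]].mean(axis=1).values
            diff = (wide["o"] - wide["v"]).values
            g = np.where(wide["group"] == "b", 0.5, -0.5)
            n = len(mean)
            X = np.column_stack([np.ones(n), g])

            def f_stats(y):
                beta = np.linalg.lstsq(X, y, rcond=None)[0]
                resid = y - X @ beta
                mse = resid @ resid / (n - 2)
                covb = mse * np.linalg.inv(X.T @ X)
                return beta**2 / np.diag(covb)

            f_between = f_stats(mean)[1]
            f_within, f_inter = f_stats(diff)
            res = mixed_anova(df)
            assert res["group"].statistic == pytest.approx(f_between, abs=1e-8)
            assert res["within"].statistic == pytest.approx(f_within, abs=1e-8)
            assert res["interaction"].statistic == pytest.approx(f_inter, abs=1e-8)

    def test_constant_response_rejected(self):
        df = self._dataset(np.random.default_rng(0))
        df["value"] = 1.0
        with pytest.raises(UndefinedStatisticError):
            mixed_anova(df)

    def test_missing_cells_name_subjects(self, rng):
        df = self._dataset(rng).drop(index=[0])
        with pytest.raises(ConfigurationError, match="0"):
            mixed_anova(df)


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = pearson(x, 2 * x)
        assert res.statistic == pytest.approx(1.0)
        assert res.p < 1e-12

    def test_agrees_with_permutation_oracle(self, rng):
        x = rng.normal(0, 1, 20)
        y = 0.5 * x + rng.normal(0, 1, 20)
        res = pearson(x, y)
        n_perm = 100_000
        xc = (x - x.mean()) / x.std()
        yc = (y - y.mean()) / y.std()
        perm_idx = np.argsort(rng.random((n_perm, 20)), axis=1)
        r_perm = (xc[None, :] * yc[perm_idx]).mean(axis=1)
        p_perm = np.mean(np.abs(r_perm) >= abs(res.statistic) - 1e-12)
        assert abs(res.p - p_perm) < 0.02

    def test_null_p_values_are_uniform(self):
        # analytic p-values under independence should pass a KS uniformity test
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(1000):
            x = rng.normal(0, 1, 20)
            y = rng.normal(0, 1, 20)
            ps.append(pearson(x, y).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            pearson(np.ones(5), np.arange(5.0))


class TestBonferroni:
    def test_reported_corrections(self):
        # 8 coupling parameters form the comparison family
        assert bonferroni(5.7e-4, 8) == pytest.approx(4.56e-3)
        assert round(bonferroni(5.7e-4, 8), 4) == 0.0046
        assert bonferroni(0.005, 8) == pytest.approx(0.04)

    def test_caps_at_one_and_identity_at_m1(self):
        assert bonferroni(0.5, 8) == 1.0
        assert bonferroni(0.123, 1) == 0.123

    def test_never_decreases(self):
        for p in (0.0, 1e-5, 0.02, 0.7, 1.0):
            for m in (1, 2, 10):
                assert bonferroni(p, m) >= p


class TestJZSBayesFactor:
    def test_null_result_favors_null(self):
        res = jzs_bf_from_t(0.0, 50, 50)
        assert res.bf10 < 1.0

    def test_matches_dense_quadrature_oracle(self):
        # brute-force trapezoid integration of the same mixture integral
        fixtures = [(2.5, 29, 27), (0.8, 15, 15), (4.0, 10, 12),
                    (1.6, 40, 35), (3.2, 8, 8)]
        r = np.sqrt(2) / 2
        for t, n1, n2 in fixtures:
            df = n1 + n2 - 2
            ne = n1 * n2 / (n1 + n2)
            g = np.geomspace(1e-8, 1e6, 200_001)
            integrand = ((1 + ne * g) ** -0.5
                         * (1 + t * t / ((1 + ne * g) * df)) ** (-(df + 1) / 2)
                         * (2 * np.pi) ** -0.5 * r * g ** -1.5
                         * np.exp(-r * r / (2 * g)))
            alt = np.trapezoid(integrand, g)
            null = (1 + t * t / df) ** (-(df + 1) / 2)
            expected = alt / null
            got = jzs_bf_from_t(t, n1, n2).bf10
            assert got == pytest.approx(expected, rel=5e-4)

    def test_agrees_with_independent_implementation(self):
        pg = pytest.importorskip("pingouin")
        for t, n1, n2 in [(2.2, 29, 27), (3.5, 20, 25)]:
            ours = jzs_bf_from_t(t, n1, n2).bf10
            theirs = float(pg.bayesfactor_ttest(t, n1, n2))
            assert ours == pytest.approx(theirs, rel=1e-3)

    def test_monotone_in_effect_size(self):
        bfs = [jzs_bf_from_t(t, 28, 28).bf10 for t in np.linspace(0, 5, 11)]
        assert np.all(np.diff(bfs) > 0)

    def test_detects_moderate_effect(self):
        # two groups separated by d = 0.8 at the study's sample sizes
        rng = np.random.default_rng(5)
        bfs = []
        for _ in range(100):
            x = rng.normal(0.0, 1.0, 28)
            y = rng.normal(0.8, 1.0, 30)
            bfs.append(jzs_bf(x, y).bf10)
        assert np.median(bfs) > 3.0


class TestBfBestRatio:
    def test_best_parameter_gets_unity(self):
        ratios = bf_best_ratio({"g4": 8.3, "g7": 2.7, "g5": 0.3})
        assert ratios["g4"] == 1.0
        assert ratios["g7"] == pytest.approx(8.3 / 2.7)

    def test_single_parameter(self):
        assert bf_best_ratio({"g4": 5.0})["g4"] == 1.0

    def test_elementwise_division(self):
        vals = {"a": 2.0, "b": 4.0, "c": 0.5}
        ratios = bf_best_ratio(vals)
        for k, v in vals.items():
            assert ratios[k] == pytest.approx(4.0 / v)

    def test_nonpositive_rejected(self):
        with pytest.raises(ConfigurationError):
            bf_best_ratio({"a": 1.0, "b": 0.0})
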