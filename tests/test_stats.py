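"""RCBD ANOVA, protected LSD, regression R^2 and box summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import saltscreen as ss
from saltscreen.stats import UnbalancedDesignError, _anova_from_cube

from conftest import make_table


def cube_to_table(y, trait="PH"):
    g, s, r = y.shape
    treatments = ["control", "moderate", "high"][:s]
    rows = [(f"g{i}", treatments[j], k + 1, trait, float(y[i, j, k]))
            for i in range(g) for j in range(s) for k in range(r)]
    return make_table(rows)


def brute_force_ss(y):
    """Defining double sums of the fixed-effects RCBD decomposition, evaluated
    with explicit Python loops (independent of the vectorised implementation)."""
    g, s, r = y.shape
    grand = sum(y[i, j, k] for i in range(g) for j in range(s) for k in range(r)) / (g * s * r)
    gm = [sum(y[i, j, k] for j in range(s) for k in range(r)) / (s * r) for i in range(g)]
    sm = [sum(y[i, j, k] for i in range(g) for k in range(r)) / (g * r) for j in range(s)]
    bm = [sum(y[i, j, k] for i in range(g) for j in range(s)) / (g * s) for k in range(r)]
    cm = [[sum(y[i, j, k] for k in range(r)) / r for j in range(s)] for i in range(g)]
    ss_total = sum((y[i, j, k] - grand) ** 2
                   for i in range(g) for j in range(s) for k in range(r))
    ss_g = s * r * sum((m - grand) ** 2 for m in gm)
    ss_s = g * r * sum((m - grand) ** 2 for m in sm)
    ss_b = g * s * sum((m - grand) ** 2 for m in bm)
    ss_gs = r * sum((cm[i][j] - gm[i] - sm[j] + grand) ** 2
                    for i in range(g) for j in range(s))
    ss_e = sum((y[i, j, k] - cm[i][j] - bm[k] + grand) ** 2
               for i in range(g) for j in range(s) for k in range(r))
    return {"block": ss_b, "genotype": ss_g, "salinity": ss_s,
            "genotype:salinity": ss_gs, "error": ss_e, "total": ss_total}


class TestRcbdAnova:
    @pytest.mark.parametrize("g,s,r,seed", [(2, 2, 2, 0), (3, 3, 2, 1),
                                            (5, 3, 4, 2), (4, 2, 3, 3)])
    def test_matches_brute_force_oracle(self, g, s, r, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(10, 2, size=(g, s, r))
        at = ss.rcbd_anova(cube_to_table(y), "PH")
        oracle = brute_force_ss(y)
        for src, expected in oracle.items():
            got = at.table.loc[src, "ss"]
            assert got == pytest.approx(expected, rel=1e-8, abs=1e-10), src
        # additive decomposition and design degrees of freedom
        parts = at.table.drop(index="total")["ss"].sum()
        assert parts == pytest.approx(at.table.loc["total", "ss"], rel=1e-8)
        assert at.table.loc["block", "df"] == r - 1
        assert at.table.loc["genotype", "df"] == g - 1
        assert at.table.loc["salinity", "df"] == s - 1
        assert at.table.loc["genotype:salinity", "df"] == (g - 1) * (s - 1)

    def test_matches_statsmodels(self):
        """Independent cross-check against an OLS sequential ANOVA."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, size=(4, 3, 3))
        table = cube_to_table(y)
        df = table.rename(columns={"replicate": "block"})
        fit = smf.ols("value ~ C(block) + C(genotype) + C(treatment)"
                      " + C(genotype):C(treatment)", data=df).fit()
        smtab = sm.stats.anova_lm(fit, typ=1)
        at = ss.rcbd_anova(table, "PH")
        assert at.table.loc["genotype", "ss"] == pytest.approx(
            smtab.loc["C(genotype)", "sum_sq"], rel=1e-8)
        assert at.table.loc["genotype:salinity", "F"] == pytest.approx(
            smtab.loc["C(genotype):C(treatment)", "F"], rel=1e-8)
        assert at.table.loc["salinity", "p"] == pytest.approx(
            smtab.loc["C(treatment)", "PR(>F)"], rel=1e-8)

    def test_pure_genotype_effect_leaves_other_sources_null(self):
        y = np.zeros((3, 3, 2))
        for i in range(3):
            y[i] = 10.0 + i  # depends on genotype only
        at = ss.rcbd_anova(cube_to_table(y), "PH")
        assert at.table.loc["salinity", "ss"] == pytest.approx(0, abs=1e-12)
        assert at.table.loc["genotype:salinity", "ss"] == pytest.approx(0, abs=1e-12)
        assert at.table.loc["genotype", "ss"] > 0

    def test_constant_data_not_computable(self):
        y = np.full((2, 3, 2), 7.0)
        at = ss.rcbd_anova(cube_to_table(y), "PH")
        assert (at.table["ss"].abs() < 1e-12).all()
        assert np.isnan(at.table.loc["genotype", "F"])
        assert at.table.loc["genotype", "stars"] == "NS"

    def test_unbalanced_data_rejected_with_pointer(self):
        y = np.zeros((2, 3, 2))
        table = cube_to_table(y).iloc[:-1]  # drop one cell
        with pytest.raises(UnbalancedDesignError, match="missing-cell report"):
            ss.rcbd_anova(table, "PH")

    def test_null_type_one_error_calibrated(self):
        """Genotype F-test rejects at ~alpha under pure-noise trials."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_trials = 1000
        for _ in range(n_trials):
            parts = _anova_from_cube(rng.normal(0, 1, size=(6, 3, 4)))
            df_g, ss_g = parts["genotype"]
            df_e, ss_e = parts["error"]
            F = (ss_g / df_g) / (ss_e / df_e)
            if sps.f.sf(F, df_g, df_e) < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_trials <= 0.07


class TestStars:
    @pytest.mark.parametrize("p,code", [(0.0005, "***"), (0.005, "**"),
                                        (0.03, "*"), (0.2, "NS"), (np.nan, "NS")])
    def test_thresholds(self, p, code):
        assert ss.star_code(p) == code


class TestFisherLsd:
    def _anova(self, mse, df_error, p_factor):
        tbl = pd.DataFrame(
            {"df": [3, 1, 2, 2, df_error, df_error + 8],
             "ss": [0, 0, 0, 0, mse * df_error, 0],
             "ms": [0, 0, 0, 0, mse, np.nan],
             "F": [np.nan] * 6, "p": [np.nan, np.nan, p_factor, np.nan, np.nan, np.nan],
             "stars": [""] * 6},
            index=["block", "genotype", "salinity", "genotype:salinity", "error", "total"])
        return ss.AnovaTable(trait="PH", table=tbl, n_genotypes=2, n_treatments=3, n_blocks=4)

    def test_lsd_value_from_t_quantile(self):
        at = self._anova(mse=4.0, df_error=12, p_factor=0.001)
        means = pd.Series({"control": 0.0, "moderate": 10.0, "high": 20.0})
        res = ss.fisher_lsd(at, means, r=4)
        assert res.lsd == pytest.approx(sps.t.ppf(0.975, 12) * np.sqrt(2), rel=1e-12)
        assert res.lsd == pytest.approx(3.081, abs=2e-3)
        assert res.comparisons_performed
        assert len(res.significant_pairs) == 3

    def test_zero_mse_flags_any_unequal_pair(self):
        at = self._anova(mse=0.0, df_error=12, p_factor=0.001)
        means = pd.Series({"a": 1.0, "b": 1.0, "c": 2.0})
        res = ss.fisher_lsd(at, means, r=4)
        assert res.lsd == 0
        assert res.pairs[("a", "b")] is False
        assert res.pairs[("a", "c")] is True

    def test_protection_rule_blocks_all_pairs(self):
        at = self._anova(mse=4.0, df_error=12, p_factor=0.50)
        means = pd.Series({"a": 0.0, "b": 100.0})
        res = ss.fisher_lsd(at, means, r=4)
        assert not res.comparisons_performed
        assert res.significant_pairs == []

    def test_invalid_replication_rejected(self):
        at = self._anova(mse=4.0, df_error=12, p_factor=0.01)
        with pytest.raises(ValueError, match="r must be positive"):
            ss.fisher_lsd(at, pd.Series({"a": 1.0, "b": 2.0}), r=0)


class TestRegressionR2:
    def test_perfect_line(self):
        x = np.arange(5.0)
        fit = ss.regression_r2(x, 2 * x + 1)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.slope == pytest.approx(2.0)

    def test_constant_y_convention(self):
        fit = ss.regression_r2([1, 2, 3, 4], [5, 5, 5, 5])
        assert fit.r2 == 0.0

    def test_hand_computed_example(self):
        fit = ss.regression_r2([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert fit.r2 == pytest.approx(0.64)
        assert fit.slope == pytest.approx(0.8)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ss.regression_r2([2, 2, 2], [1, 2, 3])

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = 1.5 * x + rng.normal(size=30)
        base = ss.regression_r2(x, y).r2
        assert ss.regression_r2(3 * x - 7, -2 * y + 11).r2 == pytest.approx(base, rel=1e-10)


class TestBoxplotSummary:
    def test_one_to_hundred_percentiles(self):
        out = ss.boxplot_summary({"all": np.arange(1, 101, dtype=float)})["all"]
        assert out.p5 == pytest.approx(5.95)
        assert out.q1 == pytest.approx(25.75)
        assert out.median == pytest.approx(50.5)
        assert out.q3 == pytest.approx(75.25)
        assert out.p95 == pytest.approx(95.05)
        assert out.p5 <= out.q1 <= out.median <= out.q3 <= out.p95

    def test_constant_group_collapses(self):
        out = ss.boxplot_summary({"g": np.full(10, 3.3)})["g"]
        assert out.p5 == out.q1 == out.median == out.q3 == out.p95 == 3.3
        assert out.outliers == []

    def test_extreme_point_is_outlier(self):
        vals = np.concatenate([np.ones(50), [1000.0]])
        out = ss.boxplot_summary({"g": vals})["g"]
        assert 1000.0 in out.outliers

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ss.boxplot_summary({"g": np.array([])})
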