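"""Tests of the statistical stage: imputation, tests, models, importance."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb, expit

import statsmodels.api as sm

from glucopcs.analysis import (
    ImputationConfig,
    fisher_exact,
    fit_issi2_model,
    fit_logistic_univariable,
    impute_chained,
    lmm_random_intercept,
    pearson_chi2,
    rf_importance,
    spearman_map,
    welch_t,
    welch_t_samples,
)
from glucopcs.simulate import (
    MEASUREMENT_COLUMNS,
    GeneratorConfig,
    generate_cohort,
    inject_missingness,
)


class TestImputation:
    def test_complete_cohort_unchanged(self, cohort_small):
        out = impute_chained(cohort_small, ImputationConfig(m=3, seed=0))
        assert out.equals(cohort_small)

    def test_observed_cells_untouched_bitwise(self, cohort_small):
        holey = inject_missingness(cohort_small, 8, seed=1)
        out = impute_chained(holey, ImputationConfig(m=5, seed=2))
        for col in MEASUREMENT_COLUMNS:
            obs = holey[col].notna()
            assert np.array_equal(
                out.loc[obs, col].to_numpy(), holey.loc[obs, col].to_numpy()
            )
            assert out[col].notna().all()

    def test_deterministic_under_seed(self, cohort_small):
        holey = inject_missingness(cohort_small, 5, seed=1)
        a = impute_chained(holey, ImputationConfig(m=3, seed=7))
        b = impute_chained(holey, ImputationConfig(m=3, seed=7))
        assert a.equals(b)

    def test_error_below_marginal_sd(self):
        truth = generate_cohort(GeneratorConfig(n_subjects=300, seed=4))
        holey = inject_missingness(truth, 30, seed=9)
        out = impute_chained(holey, ImputationConfig(m=10, seed=3))
        mask = holey[list(MEASUREMENT_COLUMNS)].isna()
        for col in MEASUREMENT_COLUMNS:
            if not mask[col].any():
                continue
            err = np.abs(out.loc[mask[col], col] - truth.loc[mask[col], col])
            assert err.mean() < truth[col].std()

    def test_averaging_reduces_dispersion(self):
        truth = generate_cohort(GeneratorConfig(n_subjects=100, seed=5))
        holey = inject_missingness(truth, 10, seed=2)
        mask = holey[list(MEASUREMENT_COLUMNS)].isna().to_numpy()

        def runs(m, seeds):
            vals = []
            for s in seeds:
                out = impute_chained(holey, ImputationConfig(m=m, seed=s))
                vals.append(out[list(MEASUREMENT_COLUMNS)].to_numpy()[mask])
            return np.array(vals)

        seeds = [11, 22, 33, 44]
        disp_m1 = runs(1, seeds).std(axis=0).mean()
        disp_m50 = runs(50, seeds).std(axis=0).mean()
        assert disp_m50 < disp_m1

    def test_entirely_missing_column_rejected(self, cohort_small):
        bad = cohort_small.copy()
        bad["g30"] = np.nan
        with pytest.raises(ValueError, match="entirely missing"):
            impute_chained(bad, ImputationConfig(m=2, seed=0))


class TestWelch:
    def test_identical_groups(self):
        res = welch_t(5.0, 1.0, 20, 5.0, 1.0, 20)
        assert res.t == 0.0 and res.p == pytest.approx(1.0)

    def test_age_contrast_from_printed_summaries(self):
        # GDM vs NGT age summaries of a 67-woman cohort
        res = welch_t(36.67, 4.63, 6, 29.08, 4.68, 61)
        assert res.t == pytest.approx(3.83, abs=0.01)
        assert 5.0 < res.df < 7.0
        assert res.p < 0.05

    def test_raw_equals_summary(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(0, 1, 40), rng.normal(0.4, 1.7, 25)
        raw = welch_t_samples(x, y)
        summ = welch_t(x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y))
        assert raw.t == pytest.approx(summ.t, abs=1e-12)
        assert raw.df == pytest.approx(summ.df, abs=1e-12)
        assert raw.p == pytest.approx(summ.p, abs=1e-12)

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            welch_t(1.0, 1.0, 10, 2.0, 1.0, 1)


def _chi2_by_hand(table):
    t = np.asarray(table, dtype=float)
    rows, cols, n = t.sum(1), t.sum(0), t.sum()
    expected = np.outer(rows, cols) / n
    return ((t - expected) ** 2 / expected).sum()


def _fisher_by_enumeration(table):
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d
    p_obs = comb(c1, a) * comb(n - c1, r1 - a) / comb(n, r1)
    total = 0.0
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        px = comb(c1, x) * comb(n - c1, r1 - x) / comb(n, r1)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return total


class TestContingency:
    def test_printed_primiparity_p(self):
        chi2, p = pearson_chi2([[41, 20], [4, 2]])
        assert p == pytest.approx(0.978, abs=2e-3)

    def test_printed_family_history_p(self):
        _, p = pearson_chi2([[20, 40], [3, 3]])
        assert p == pytest.approx(0.413, abs=2e-3)

    def test_proportional_table_null(self):
        chi2, p = pearson_chi2([[10, 10], [5, 5]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_chi2_matches_hand_formula(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            t = rng.integers(1, 60, size=(2, 2))
            chi2, _ = pearson_chi2(t)
            assert chi2 == pytest.approx(_chi2_by_hand(t), abs=1e-10)

    def test_fisher_printed_multiparous_history_p(self):
        assert fisher_exact([[3, 17], [2, 0]]) == pytest.approx(0.043, abs=1e-3)

    def test_fisher_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            t = rng.integers(0, 12, size=(2, 2))
            if t.sum(0).min() == 0 or t.sum(1).min() == 0:
                continue
            assert fisher_exact(t) == pytest.approx(_fisher_by_enumeration(t), abs=1e-12)

    def test_bad_tables_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2([[1, -2], [3, 4]])
        with pytest.raises(ValueError):
            pearson_chi2([[0, 0], [3, 4]])


class TestLogistic:
    def test_null_recovery_large_n(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(10_000)
        y = (rng.random(10_000) < 0.3).astype(float)
        fit = fit_logistic_univariable(y, x)
        assert 0.9 < fit.odds_ratio < 1.1
        assert fit.ci_low < fit.odds_ratio < fit.ci_high

    def test_known_coefficient_recovered_within_3_se(self):
        rng = np.random.default_rng(2)
        n, beta = 10_000, -2.0
        x = rng.standard_normal(n)
        y = (rng.random(n) < expit(-1.0 + beta * x)).astype(float)
        fit = fit_logistic_univariable(y, x)
        oracle = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert abs(fit.beta - beta) < 3 * oracle.bse[1]
        # profile CI brackets the estimate and roughly matches Wald at large n
        wald = oracle.conf_int()[1]
        assert fit.ci_low == pytest.approx(math.exp(wald[0]), rel=0.05)
        assert fit.ci_high == pytest.approx(math.exp(wald[1]), rel=0.05)

    def test_or_scaling_per_001_units(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(2000)
        y = (rng.random(2000) < expit(0.5 * x)).astype(float)
        per_unit = fit_logistic_univariable(y, x, scale=1.0)
        per_centi = fit_logistic_univariable(y, x, scale=0.01)
        assert per_centi.odds_ratio == pytest.approx(per_unit.odds_ratio**0.01, rel=1e-9)

    def test_small_sample_separation_flagged(self):
        # 6 events among 67 with a perfectly separating score
        x = np.concatenate([np.linspace(0, 1, 61), np.linspace(2, 3, 6)])
        y = np.concatenate([np.zeros(61), np.ones(6)])
        fit = fit_logistic_univariable(y, x)
        assert fit.separation or not np.isfinite(fit.ci_high)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(4)
        n, reps = 200, 2000
        hits = 0
        for _ in range(reps):
            x = rng.standard_normal(n)
            y = (rng.random(n) < 0.25).astype(float)
            hits += fit_logistic_univariable(y, x, ci=False).p < 0.05
        assert 0.03 < hits / reps < 0.07

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic_univariable(np.zeros(20), np.arange(20.0))
        with pytest.raises(ValueError):
            fit_logistic_univariable(np.r_[np.ones(5), np.zeros(5)], np.ones(10))


class TestRandomForestImportance:
    def test_pure_noise_importances_near_zero(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.standard_normal((500, 5)), columns=list("abcde"))
        y = (rng.random(500) < 0.4).astype(int)
        imp = rf_importance(X, y, ntree=1000, seed=1)
        assert np.all(np.abs(imp.table["importance"]) < 0.01)

    def test_planted_signal_ranks_first(self):
        rng = np.random.default_rng(6)
        n = 400
        latent = rng.standard_normal(n)
        y = (latent + 0.4 * rng.standard_normal(n) > 0.5).astype(int)
        X = pd.DataFrame(
            {
                "signal": np.tanh(latent),  # monotone transform of the risk
                "noise1": rng.standard_normal(n),
                "noise2": rng.standard_normal(n),
                "noise3": rng.standard_normal(n),
            }
        )
        imp = rf_importance(X, y, ntree=1000, seed=2)
        assert imp.table["predictor"].iloc[0] == "signal"

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.standard_normal((150, 3)), columns=list("abc"))
        y = (rng.random(150) < 0.5).astype(int)
        a = rf_importance(X, y, ntree=200, seed=3)
        b = rf_importance(X, y, ntree=200, seed=3)
        assert a.table.equals(b.table)

    def test_single_class_rejected(self):
        X = pd.DataFrame({"a": np.arange(50.0)})
        with pytest.raises(ValueError):
            rf_importance(X, np.zeros(50, dtype=int), ntree=200)


class TestIssi2Model:
    def test_exact_linear_relationship(self):
        rng = np.random.default_rng(8)
        scores = pd.DataFrame(
            rng.standard_normal((100, 3)), columns=["PCS1", "PCS2", "PCS3"]
        )
        y = 1.0 + 2.0 * scores["PCS1"] - 0.5 * scores["PCS2"] - 3.0 * scores["PCS3"]
        m = fit_issi2_model(y, scores)
        assert m.r_squared == pytest.approx(1.0, abs=1e-10)
        assert m.coef["PCS1"] == pytest.approx(2.0, abs=1e-8)

    def test_independent_noise_r_squared_near_null(self):
        rng = np.random.default_rng(9)
        n = 500
        scores = pd.DataFrame(
            rng.standard_normal((n, 3)), columns=["PCS1", "PCS2", "PCS3"]
        )
        m = fit_issi2_model(rng.standard_normal(n), scores)
        assert m.r_squared < 0.03  # E[R^2] = 3/(n-1) under the null

    def test_synthetic_cohort_sign_pattern(self, scored_large):
        sc = scored_large
        m = fit_issi2_model(sc.panels.loc[sc.v1, "issi2"], sc.scores.pcs.loc[sc.v1])
        assert m.coef["PCS1"] > 0
        assert m.coef["PCS2"] < 0
        assert m.coef["PCS3"] < 0

    def test_collinear_scores_rejected(self):
        scores = pd.DataFrame({"PCS1": np.arange(20.0), "PCS2": np.arange(20.0) * 2,
                               "PCS3": np.ones(20)})
        with pytest.raises(ValueError, match="collinear"):
            fit_issi2_model(np.arange(20.0), scores)


class TestMixedModel:
    @staticmethod
    def _simulate(n_subj, delta_v2, tau, seed):
        rng = np.random.default_rng(seed)
        u = tau * rng.standard_normal(n_subj)
        rows = []
        for s in range(n_subj):
            for visit in ("V1", "V2", "V3"):
                if visit == "V3" and s % 3:
                    continue  # unbalanced, like postpartum dropout
                mu = {"V1": 0.0, "V2": delta_v2, "V3": 0.1}[visit]
                rows.append((mu + u[s] + 0.5 * rng.standard_normal(), visit, f"S{s}"))
        return pd.DataFrame(rows, columns=["y", "visit", "subject"])

    def test_zero_between_subject_variance(self):
        df = self._simulate(150, 0.3, tau=0.0, seed=1)
        res = lmm_random_intercept(df["y"], df["visit"], df["subject"])
        assert res.intercept_var < 0.05 * df["y"].var()

    def test_visit_effect_recovered_within_3_se(self):
        delta = -0.4
        df = self._simulate(500, delta, tau=0.6, seed=2)
        res = lmm_random_intercept(df["y"], df["visit"], df["subject"])
        name = [ix for ix in res.fe_params.index if "V2" in ix][0]
        assert abs(res.fe_params[name] - delta) < 3 * res.fe_se[name]
        assert res.p_global < 1e-6

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(3)
        base = self._simulate(60, 0.0, tau=0.5, seed=4)
        ps = []
        for _ in range(200):
            perm = base.copy()
            perm["visit"] = rng.permutation(perm["visit"].to_numpy())
            ps.append(lmm_random_intercept(perm["y"], perm["visit"], perm["subject"]).p_global)
        ps = np.asarray(ps)
        assert stats.kstest(ps, "uniform")[1] > 0.01
        assert 0.0 <= np.mean(ps < 0.05) <= 0.11

    def test_single_visit_falls_back_to_ols(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {"y": rng.standard_normal(60),
             "visit": ["V1", "V2", "V3"] * 20,
             "subject": [f"S{j}" for j in range(60)]}
        )
        with pytest.warns(UserWarning, match="falling back"):
            res = lmm_random_intercept(df["y"], df["visit"], df["subject"])
        assert res.method == "ols"


class TestSpearmanMap:
    def test_monotone_transform_gives_unit_rho(self):
        x = np.linspace(-2, 2, 50)
        out = spearman_map(
            pd.DataFrame({"PCS1": x}), pd.DataFrame({"idx": np.exp(x)})
        )
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_independent_pairs_near_zero(self):
        rng = np.random.default_rng(10)
        out = spearman_map(
            pd.DataFrame({"PCS1": rng.standard_normal(1000)}),
            pd.DataFrame({"idx": rng.standard_normal(1000)}),
        )
        assert abs(out.loc[0, "rho"]) < 0.1

    def test_constant_column_flagged(self):
        out = spearman_map(
            pd.DataFrame({"PCS1": np.arange(10.0)}),
            pd.DataFrame({"idx": np.ones(10)}),
        )
        assert math.isnan(out.loc[0, "rho"])
        assert out.loc[0, "flag"] == "constant column"

    def test_synthetic_cohort_sign_pattern(self, scored_large):
        sc = scored_large
        v1 = pd.Series(np.where(sc.v1, "V1", "other"))
        out = spearman_map(
            sc.scores.pcs, sc.panels[["matsuda", "sec_total", "homa_ir"]], visit=v1
        )
        out = out.set_index(["visit", "score", "index"])
        assert out.loc[("V1", "PCS1", "matsuda"), "rho"] > 0.6
        assert out.loc[("V1", "PCS1", "sec_total"), "rho"] < -0.3
        assert out.loc[("V1", "PCS3", "homa_ir"), "rho"] > 0.3
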