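"""Oracle and simulation tests for design-based weighted regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import bioaging_mixtures as bm
from bioaging_mixtures import synthdata
from bioaging_mixtures.surveyreg import wald_test
from conftest import score_clocks


def brute_force_wls(y, X, w):
    """Direct evaluation of the printed matrix formulas."""
    W = np.diag(w)
    A = X.T @ W @ X
    beta = np.linalg.solve(A, X.T @ W @ y)
    return beta, A


def brute_force_taylor_cov(y, X, w, beta, strata, psu):
    """Literal transcription of the stratum/PSU score-variance formula."""
    resid = y - X @ beta
    z = X * (w * resid)[:, None]
    V = np.zeros((X.shape[1], X.shape[1]))
    for s in np.unique(strata):
        rows = strata == s
        totals = []
        for p in np.unique(psu[rows]):
            totals.append(z[rows & (psu == p)].sum(axis=0))
        T = np.asarray(totals)
        n_h = len(T)
        D = T - T.mean(axis=0)
        V += n_h / (n_h - 1) * (D.T @ D)
    A = X.T @ np.diag(w) @ X
    Ainv = np.linalg.inv(A)
    return Ainv @ V @ Ainv


def random_instance(rng, n=50, p=3, n_strata=5, psus=2):
    X = np.column_stack([np.ones(n), rng.normal(0, 1, (n, p - 1))])
    beta_true = rng.normal(0, 1, p)
    y = X @ beta_true + rng.normal(0, 1, n)
    w = rng.uniform(0.5, 3.0, n)
    strata = np.arange(n) % n_strata
    psu = (np.arange(n) // n_strata) % psus
    return y, X, w, strata, psu


class TestWeightedLM:
    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            y, X, w, strata, psu = random_instance(rng)
            design = bm.SurveyDesign(strata, psu, w)
            res = bm.fit_weighted_lm(y, X, design)
            beta_bf, _ = brute_force_wls(y, X, w)
            np.testing.assert_allclose(res.beta, beta_bf, atol=1e-8)
            cov_bf = brute_force_taylor_cov(y, X, w, beta_bf, strata, psu)
            np.testing.assert_allclose(res.cov, cov_bf, atol=1e-8)

    def test_equal_weights_single_stratum_matches_ols_and_hc(self):
        rng = np.random.default_rng(7)
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(0, 1, n)])
        y = X @ np.array([1.0, 2.0]) + rng.normal(0, 1, n)
        design = bm.SurveyDesign(np.zeros(n), np.arange(n), np.ones(n))
        res = bm.fit_weighted_lm(y, X, design)
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(res.beta, beta_ols, atol=1e-10)
        # HC0-style robust SE, brute force
        resid = y - X @ beta_ols
        Ainv = np.linalg.inv(X.T @ X)
        meat = (X * resid[:, None]).T @ (X * resid[:, None])
        hc0 = np.sqrt(np.diag(Ainv @ meat @ Ainv))
        assert np.all(np.abs(res.se / hc0 - 1) < 0.10)

    def test_weight_invariance_under_row_duplication(self):
        rng = np.random.default_rng(9)
        y, X, w, strata, psu = random_instance(rng)
        res = bm.fit_weighted_lm(y, X, bm.SurveyDesign(strata, psu, w))
        y2 = np.concatenate([y, y])
        X2 = np.vstack([X, X])
        w2 = np.concatenate([w / 2, w / 2])
        res2 = bm.fit_weighted_lm(
            y2, X2, bm.SurveyDesign(np.tile(strata, 2), np.tile(psu, 2), w2))
        np.testing.assert_allclose(res.beta, res2.beta, atol=1e-10)

    def test_taylor_close_to_jackknife(self):
        # delete-one-PSU jackknife (JKn) oracle on a 20-strata design
        rng = np.random.default_rng(13)
        n, n_strata = 2000, 20
        X = np.column_stack([np.ones(n), rng.normal(0, 1, (n, 2))])
        y = X @ np.array([1.0, -0.5, 0.8]) + rng.normal(0, 2, n)
        w = rng.uniform(0.5, 3.0, n)
        strata = np.arange(n) % n_strata
        psu = (np.arange(n) // n_strata) % 2
        res = bm.fit_weighted_lm(y, X, bm.SurveyDesign(strata, psu, w))
        cov_jk = np.zeros((3, 3))
        beta_full, _ = brute_force_wls(y, X, w)
        for s in range(n_strata):
            for p_lab in (0, 1):
                drop = (strata == s) & (psu == p_lab)
                w_adj = w.copy()
                w_adj[drop] = 0.0
                w_adj[(strata == s) & ~drop] *= 2.0  # n_h/(n_h-1) reweighting
                beta_d, _ = brute_force_wls(y, X, w_adj)
                d = beta_d - beta_full
                cov_jk += 0.5 * np.outer(d, d)  # (n_h-1)/n_h = 1/2
        ratio = res.se / np.sqrt(np.diag(cov_jk))
        assert np.all(np.abs(ratio - 1) < 0.15)

    def test_singular_design_named(self):
        rng = np.random.default_rng(15)
        n = 60
        x = rng.normal(0, 1, n)
        X = pd.DataFrame({"const": 1.0, "a": x, "b": 2 * x})
        design = bm.SurveyDesign(np.arange(n) % 5, np.arange(n) // 5 % 2,
                                 np.ones(n))
        with pytest.raises(ValueError, match="b"):
            bm.fit_weighted_lm(rng.normal(0, 1, n), X, design)

    def test_lonely_psu_rules(self):
        rng = np.random.default_rng(17)
        n = 60
        strata = np.r_[np.zeros(10), np.arange(n - 10) % 5 + 1]
        psu = np.r_[np.zeros(10), (np.arange(n - 10) // 5) % 2]
        X = np.column_stack([np.ones(n), rng.normal(0, 1, n)])
        y = rng.normal(0, 1, n)
        with pytest.raises(ValueError, match="single PSU"):
            bm.fit_weighted_lm(
                y, X, bm.SurveyDesign(strata, psu, np.ones(n),
                                      lonely_psu="fail"))
        res_c = bm.fit_weighted_lm(
            y, X, bm.SurveyDesign(strata, psu, np.ones(n),
                                  lonely_psu="adjacent-collapse"))
        res_z = bm.fit_weighted_lm(
            y, X, bm.SurveyDesign(strata, psu, np.ones(n),
                                  lonely_psu="certainty"))
        assert np.all(np.isfinite(res_c.se)) and np.all(np.isfinite(res_z.se))
        np.testing.assert_allclose(res_c.beta, res_z.beta)

    def test_pvalues_in_unit_interval_and_ci_contains_beta(self):
        rng = np.random.default_rng(19)
        y, X, w, strata, psu = random_instance(rng, n=80)
        res = bm.fit_weighted_lm(y, X, bm.SurveyDesign(strata, psu, w))
        p = res.pvalues()
        assert np.all((p >= 0) & (p <= 1))
        lo, hi = res.conf_int()
        assert np.all((lo <= res.beta) & (res.beta <= hi))


class TestTrend:
    def _cohort_with_linear_quartile_effect(self, seed, slope):
        rng = np.random.default_rng(seed)
        n = 1200
        x = rng.lognormal(0, 1, n)
        _, q = bm.quartile_categorize(x, None)
        y = slope * q + rng.normal(0, 0.3, n)
        df = pd.DataFrame({"y": y, "q": q, "x": x})
        design = bm.SurveyDesign(np.arange(n) % 20, (np.arange(n) // 20) % 2,
                                 np.ones(n))
        return df, design

    def test_forced_monotone_trend(self):
        df, design = self._cohort_with_linear_quartile_effect(23, -1.0)
        Xc = pd.DataFrame({"const": np.ones(len(df))})
        p = bm.quartile_trend_test(df["y"], df["q"], Xc, design)
        assert p < 1e-6

    def test_quartile_and_trend_agree_under_linear_truth(self):
        df, design = self._cohort_with_linear_quartile_effect(29, -0.5)
        Xc = pd.DataFrame({"const": np.ones(len(df))})
        dummies = pd.get_dummies(df["q"], prefix="q", drop_first=True).astype(float)
        res = bm.fit_weighted_lm(df["y"], pd.concat([Xc, dummies], axis=1),
                                 design)
        X_tr = Xc.copy()
        X_tr["trend"] = df["q"].astype(float)
        res_tr = bm.fit_weighted_lm(df["y"], X_tr, design)
        beta_q4 = res["q_4"]["beta"]
        slope = res_tr["trend"]["beta"]
        assert abs(beta_q4 - 3 * slope) < 0.1

    def test_null_trend_p_uniform(self):
        # Kolmogorov-Smirnov on trend p-values over replicates of a null
        rng = np.random.default_rng(31)
        pvals = []
        for _ in range(200):
            n = 300
            x = rng.lognormal(0, 1, n)
            _, q = bm.quartile_categorize(x, None)
            y = rng.normal(0, 1, n)
            design = bm.SurveyDesign(np.arange(n) % 15,
                                     (np.arange(n) // 15) % 2, np.ones(n))
            Xc = pd.DataFrame({"const": np.ones(n)})
            pvals.append(bm.quartile_trend_test(y, q, Xc, design))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_rejects_single_occupied_quartile(self):
        n = 40
        design = bm.SurveyDesign(np.arange(n) % 4, (np.arange(n) // 4) % 2,
                                 np.ones(n))
        with pytest.raises(ValueError, match="occupied"):
            bm.quartile_trend_test(np.ones(n), np.ones(n, dtype=int),
                                   pd.DataFrame({"const": np.ones(n)}), design)


class TestRCS:
    def test_linear_beyond_boundary_knot(self):
        knots = np.array([1.0, 2.0, 4.0, 6.0])
        x = np.linspace(6.5, 12.0, 40)
        basis = bm.rcs_basis(x, knots)
        # second differences vanish beyond the last knot for every column
        d2 = np.diff(basis, 2, axis=0)
        assert np.max(np.abs(d2)) < 1e-9

    def test_coincident_knots_rejected(self):
        with pytest.raises(ValueError, match="knots"):
            bm.rcs_basis(np.linspace(0, 1, 10), [0.2, 0.2, 0.6, 0.9])

    def test_quadratic_truth_detected(self):
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            n = 2000
            x = rng.normal(0, 1, n)
            y = 0.5 * x**2 + rng.normal(0, 1, n)
            design = bm.SurveyDesign(np.arange(n) % 30,
                                     (np.arange(n) // 30) % 2, np.ones(n))
            fit = bm.rcs_fit(y, x, None, design)
            hits += fit.p_nonlinear < 0.01
        assert hits >= 8

    def test_curve_zero_at_reference(self):
        rng = np.random.default_rng(37)
        n = 500
        x = rng.normal(0, 1, n)
        y = x + rng.normal(0, 1, n)
        design = bm.SurveyDesign(np.arange(n) % 10, (np.arange(n) // 10) % 2,
                                 np.ones(n))
        ref = float(np.median(x))
        fit = bm.rcs_fit(y, x, None, design, grid=np.array([ref]))
        assert abs(fit.curve["estimate"].iloc[0]) < 1e-12


class TestSubgroups:
    def test_constructed_heterogeneity_recovered(self):
        rng = np.random.default_rng(41)
        n = 2000
        g = np.where(rng.uniform(size=n) < 0.5, "A", "B")
        x = rng.normal(0, 1, n)
        y = np.where(g == "A", 1.0, -1.0) * x + rng.normal(0, 1, n)
        df = pd.DataFrame({
            "y": y, "x": x, "grp": g,
            "age": rng.uniform(20, 80, n),
            "sex": rng.choice(["F", "M"], n),
            "race": rng.choice(["W", "B", "M", "O"], n),
            "stratum": np.arange(n) % 30, "psu": (np.arange(n) // 30) % 2,
            "weight": np.ones(n),
        })
        res = bm.subgroup_interaction(df, "y", "x", "model1", "grp")
        betas = dict(zip(res.table["level"], res.table["beta"]))
        assert betas["A"] > 0.7 and betas["B"] < -0.7
        assert res.p_interaction < 0.01

    def test_two_level_wald_equals_t_squared(self):
        rng = np.random.default_rng(43)
        n = 400
        y, X, w, strata, psu = random_instance(rng, n=n, p=3, n_strata=20)
        res = bm.fit_weighted_lm(y, X, bm.SurveyDesign(strata, psu, w))
        term = res.terms[2]
        t2 = (res.beta[2] / res.se[2]) ** 2
        wt = wald_test(res, [term])
        assert abs(wt.statistic - t2) < 1e-8

    def test_null_interaction_rate(self):
        rng = np.random.default_rng(47)
        rej = 0
        R = 100
        for _ in range(R):
            n = 400
            g = np.where(rng.uniform(size=n) < 0.5, "A", "B")
            x = rng.normal(0, 1, n)
            y = 0.5 * x + rng.normal(0, 1, n)
            df = pd.DataFrame({
                "y": y, "x": x, "grp": g,
                "age": rng.uniform(20, 80, n),
                "sex": rng.choice(["F", "M"], n),
                "race": rng.choice(["W", "B", "M", "O"], n),
                "stratum": np.arange(n) % 20, "psu": (np.arange(n) // 20) % 2,
                "weight": np.ones(n),
            })
            res = bm.subgroup_interaction(df, "y", "x", "model1", "grp")
            rej += res.p_interaction < 0.05
        assert 0.01 <= rej / R <= 0.11


class TestDescriptives:
    def test_classical_limit(self):
        rng = np.random.default_rng(53)
        n = 400
        y = rng.normal(10, 2, n)
        df = pd.DataFrame({
            "y": y, "sex": rng.choice(["F", "M"], n),
            "stratum": np.zeros(n), "psu": np.arange(n),
            "weight": np.ones(n),
        })
        out = bm.weighted_descriptives(df, ["y"], [], by="sex",
                                       design=bm.SurveyDesign.from_table(df))
        row = out[out.variable == "y"].iloc[0]
        assert abs(row["overall"] - y.mean()) < 1e-9
        classical_se = y.std(ddof=1) / np.sqrt(n)
        assert abs(row["overall_se"] / classical_se - 1) < 1e-9

    def test_weight_rescale_invariance(self, small_exposed):
        design = bm.SurveyDesign.from_table(small_exposed)
        scaled = bm.SurveyDesign(design.strata, design.psu,
                                 design.weights * 7.3)
        a = bm.weighted_descriptives(small_exposed, ["age"], ["race"],
                                     design=design)
        b = bm.weighted_descriptives(small_exposed, ["age"], ["race"],
                                     design=scaled)
        pd.testing.assert_frame_equal(a, b)

    def test_proportions_sum_to_one(self, small_exposed):
        design = bm.SurveyDesign.from_table(small_exposed)
        out = bm.weighted_descriptives(small_exposed, [], ["race", "smoke"],
                                       design=design)
        for var in ("race", "smoke"):
            sub = out[out.variable == var]
            assert abs(sub["overall"].sum() - 100.0) < 1e-8
            for g in ("Female", "Male"):
                assert abs(sub[g].sum() - 100.0) < 1e-8
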