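"""Logistic/Wald machinery, permutation correction, and exact tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

import metbc
from metbc.enrichment import _BatchedScan


def _random_logistic_data(rng, n=400, k=2, beta=None):
    X = pd.DataFrame({"intercept": np.ones(n)})
    for j in range(k):
        X[f"x{j}"] = rng.normal(size=n)
    beta = beta if beta is not None else np.zeros(k + 1)
    eta = X.to_numpy() @ beta
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return y, X


class TestFitLogistic:
    def test_null_coefficient_near_zero(self):
        rng = np.random.default_rng(0)
        y, X = _random_logistic_data(rng, n=10000)
        fit = metbc.fit_logistic(y, X)
        z, p = metbc.wald_test(fit, "x0")
        assert abs(fit.params["x0"]) < 0.1
        assert abs(z) < 3.5

    def test_saturated_2x2_closed_form(self):
        """Coefficient equals log OR; SE equals sqrt(sum of 1/n_ij)."""
        n11, n10, n01, n00 = 40, 60, 25, 75
        y = np.array([1] * n11 + [1] * n01 + [0] * n10 + [0] * n00, float)
        x = np.array([1] * n11 + [0] * n01 + [1] * n10 + [0] * n00, float)
        X = pd.DataFrame({"intercept": 1.0, "x": x})
        fit = metbc.fit_logistic(y, X)
        log_or = np.log(n11 * n00 / (n10 * n01))
        se = np.sqrt(1 / n11 + 1 / n10 + 1 / n01 + 1 / n00)
        assert fit.params["x"] == pytest.approx(log_or, abs=1e-6)
        assert fit.se()["x"] == pytest.approx(se, abs=1e-6)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(3)
        y, X = _random_logistic_data(rng, n=500, k=3,
                                     beta=np.array([0.2, 0.5, -0.3, 0.0]))
        fit = metbc.fit_logistic(y, X)
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), ref.params.to_numpy(),
                                   atol=1e-8)
        np.testing.assert_allclose(fit.se().to_numpy(), ref.bse.to_numpy(),
                                   atol=1e-6)

    def test_direction_agrees_with_lrt(self):
        """Wald and likelihood-ratio tests agree in sign/strength ordering."""
        import statsmodels.api as sm
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = 120
            y, X = _random_logistic_data(
                rng, n=n, k=1, beta=np.array([0.0, rng.normal(scale=0.7)]))
            if y.sum() in (0, n):
                continue
            fit = metbc.fit_logistic(y, X)
            if fit.penalized:
                continue
            z, p_wald = metbc.wald_test(fit, "x0")
            full = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            null = sm.GLM(y, X[["intercept"]],
                          family=sm.families.Binomial()).fit()
            lrt = 2 * (full.llf - null.llf)
            p_lrt = stats.chi2.sf(lrt, df=1)
            # both significant or both not, at a generous split point
            assert (p_wald < 0.2) == (p_lrt < 0.2) or abs(p_wald - p_lrt) < 0.15

    def test_separation_triggers_firth(self):
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1], float)
        x = np.array([0, 0, 0, 0, 1, 1, 1, 1], float)
        X = pd.DataFrame({"intercept": 1.0, "x": x})
        fit = metbc.fit_logistic(y, X)
        assert fit.separation_flag and fit.penalized
        assert np.isfinite(fit.params).all()
        assert np.isfinite(fit.se()).all()

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        X = pd.DataFrame({"intercept": 1.0, "a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            metbc.fit_logistic((rng.random(50) < 0.5).astype(float), X)

    def test_planted_esr1_effect_extremely_significant(self):
        """18.3% vs 2.2% at the study's group sizes gives p far below 1e-10."""
        rng = np.random.default_rng(6)
        n_met, n_loc = 5034, 4512
        y = np.r_[np.ones(n_met), np.zeros(n_loc)]
        x = np.r_[(rng.random(n_met) < 0.183), (rng.random(n_loc) < 0.022)]
        X = pd.DataFrame({"intercept": 1.0, "esr1": x.astype(float)})
        fit = metbc.fit_logistic(y, X)
        _, p = metbc.wald_test(fit, "esr1")
        assert p < 1e-10


class TestWald:
    def test_zero_coefficient_p_one(self):
        fit = metbc.LogisticFit(
            params=pd.Series({"intercept": 0.3, "x": 0.0}),
            cov=pd.DataFrame(np.eye(2) * 0.04,
                             index=["intercept", "x"], columns=["intercept", "x"]),
            converged=True, iterations=3)
        z, p = metbc.wald_test(fit, "x")
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_normal_quantile_identity(self):
        se = 0.5
        fit = metbc.LogisticFit(
            params=pd.Series({"intercept": 0.0, "x": 1.959964 * se}),
            cov=pd.DataFrame(np.eye(2) * se**2,
                             index=["intercept", "x"], columns=["intercept", "x"]),
            converged=True, iterations=3)
        _, p = metbc.wald_test(fit, "x")
        assert p == pytest.approx(0.05, abs=1e-5)


class TestScan:
    def _null_inputs(self, rng, n=1500, F=30):
        feats = pd.DataFrame((rng.random((n, F)) < 0.08).astype(float),
                             columns=[f"g{i}_mut" for i in range(F)])
        y = (rng.random(n) < 0.5).astype(float)
        cov = pd.DataFrame({"er": rng.random(n), "her2": (rng.random(n) < 0.1).astype(float),
                            "tmb": rng.gamma(4, 1.5, n)})
        return feats, y, cov

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(7)
        feats, y, cov = self._null_inputs(rng, n=3000, F=60)
        res = metbc.enrichment_scan(feats, y, cov, min_count=5)
        frac = (res["p_raw"].dropna() < 0.05).mean()
        assert frac < 0.15  # ~5% expected, allow generous MC slack

    def test_min_count_skips(self):
        rng = np.random.default_rng(8)
        feats, y, cov = self._null_inputs(rng, n=500, F=5)
        feats["rare_mut"] = 0.0
        feats.loc[:8, "rare_mut"] = 1.0  # 9 events
        res = metbc.enrichment_scan(feats, y, cov, min_count=10)
        row = res[res["feature"] == "rare_mut"].iloc[0]
        assert np.isnan(row["p_raw"]) and "skipped" in row["note"]

    def test_scan_equivariant_under_sample_order(self):
        rng = np.random.default_rng(9)
        feats, y, cov = self._null_inputs(rng, n=600, F=10)
        perm = rng.permutation(600)
        r1 = metbc.enrichment_scan(feats, y, cov, min_count=5)
        r2 = metbc.enrichment_scan(feats.iloc[perm].reset_index(drop=True),
                                   y[perm], cov.iloc[perm].reset_index(drop=True),
                                   min_count=5)
        m1 = r1.set_index("feature")["p_raw"].sort_index()
        m2 = r2.set_index("feature")["p_raw"].sort_index()
        np.testing.assert_allclose(m1.to_numpy(), m2.to_numpy(), rtol=1e-8)

    def test_planted_ctcf_effect_detected(self):
        """2% vs 0.9% at the study's sizes is significant under covariates."""
        rng = np.random.default_rng(10)
        n_met, n_loc = 5034, 4512
        y = np.r_[np.ones(n_met), np.zeros(n_loc)]
        n = n_met + n_loc
        feats = pd.DataFrame({
            "CTCF_mut": np.r_[(rng.random(n_met) < 0.02),
                              (rng.random(n_loc) < 0.009)].astype(float),
            "null_mut": (rng.random(n) < 0.05).astype(float),
        })
        cov = pd.DataFrame({"er": rng.random(n), "her2": (rng.random(n) < 0.09).astype(float),
                            "tmb": rng.gamma(4, 1.5, n)})
        res = metbc.enrichment_scan(feats, y, cov, min_count=10)
        row = res[res["feature"] == "CTCF_mut"].iloc[0]
        assert row["p_raw"] < 1e-3
        assert row["odds_ratio"] > 1

    def test_batched_matches_single_fit(self):
        rng = np.random.default_rng(11)
        feats, y, cov = self._null_inputs(rng, n=800, F=6)
        scanner = _BatchedScan(feats.to_numpy(), cov.to_numpy())
        b, se, z, p, _ = scanner.wald(y)
        X = pd.concat([pd.Series(1.0, index=range(800), name="intercept"),
                       feats["g2_mut"], cov], axis=1)
        fit = metbc.fit_logistic(y, X)
        assert b[2] == pytest.approx(fit.params["g2_mut"], abs=1e-6)
        assert se[2] == pytest.approx(fit.se()["g2_mut"], abs=1e-6)


class TestMaxT:
    def test_p_corrected_bounds_and_monotone(self):
        rng = np.random.default_rng(12)
        n, F = 800, 12
        feats = pd.DataFrame((rng.random((n, F)) < 0.1).astype(float),
                             columns=[f"g{i}" for i in range(F)])
        y = (rng.random(n) < 0.5).astype(float)
        cov = pd.DataFrame({"c": rng.normal(size=n)})
        res = metbc.maxt_permutation_correct(feats, y, cov, n_perm=100, seed=1,
                                             min_count=5)
        ok = res.dropna(subset=["p_raw"])
        assert (ok["p_corrected"] >= ok["p_raw"] - 1e-12).all()
        assert ok["p_corrected"].between(0, 1).all()

    def test_raw_p_one_gives_corrected_one(self):
        y = np.r_[np.ones(100), np.zeros(100)]
        feats = pd.DataFrame({"bal": np.r_[np.ones(50), np.zeros(50),
                                           np.ones(50), np.zeros(50)]})
        cov = pd.DataFrame(index=range(200))
        res = metbc.maxt_permutation_correct(feats, y, cov, n_perm=50, seed=2,
                                             min_count=1)
        row = res.iloc[0]
        assert row["p_raw"] > 0.9
        assert row["p_corrected"] > 0.9

    def test_single_feature_equals_raw_permutation_p(self):
        """With one feature, min-p correction is that feature's own
        permutation p."""
        rng = np.random.default_rng(13)
        n = 300
        y = (rng.random(n) < 0.5).astype(float)
        x = (rng.random(n) < 0.3).astype(float)
        feats = pd.DataFrame({"only": x})
        cov = pd.DataFrame({"c": rng.normal(size=n)})
        res = metbc.maxt_permutation_correct(feats, y, cov, n_perm=300, seed=3,
                                             min_count=1)
        p_corr = res.iloc[0]["p_corrected"]
        # independent oracle: direct permutation p of the same Wald statistic
        scanner = _BatchedScan(x[:, None], cov.to_numpy())
        _, _, _, p_obs, _ = scanner.wald(y)
        rng2 = np.random.default_rng(3)
        hits = 0
        for _ in range(300):
            _, _, _, p_b, _ = scanner.wald(rng2.permutation(y))
            hits += p_b[0] <= p_obs[0]
        oracle = (1 + hits) / 301
        assert p_corr == pytest.approx(oracle, abs=0.05)

    def test_n_perm_validation(self):
        with pytest.raises(ValueError):
            metbc.maxt_permutation_correct(
                pd.DataFrame({"a": [0.0, 1.0]}), np.array([0.0, 1.0]),
                pd.DataFrame(index=range(2)), n_perm=0)


class TestSiteScan:
    def test_restriction_identity(self):
        """One site vs local equals the plain scan on that subset."""
        rng = np.random.default_rng(14)
        n = 600
        groups = pd.Series(["local"] * 300 + ["metastasis"] * 300)
        sites = pd.Series(["breast"] * 300 + ["liver"] * 300)
        feats = pd.DataFrame({"g_mut": (rng.random(n) < 0.15).astype(float)})
        cov = pd.DataFrame({"c": rng.normal(size=n)})
        per_site = metbc.site_specific_scan(feats, sites, groups, cov, min_count=5)
        y = groups.eq("metastasis").astype(float).to_numpy()
        direct = metbc.enrichment_scan(feats, y, cov, min_count=5)
        assert per_site["liver"].iloc[0]["p_raw"] == pytest.approx(
            direct.iloc[0]["p_raw"], rel=1e-9)

    def test_planted_notch1_site_specificity(self):
        """NOTCH1 at 8.8% in skin vs 4.5% local is found for skin, not liver."""
        rng = np.random.default_rng(15)
        n_loc, n_skin, n_liver = 4512, 600, 1400
        groups = pd.Series(["local"] * n_loc + ["metastasis"] * (n_skin + n_liver))
        sites = pd.Series(["breast"] * n_loc + ["skin"] * n_skin
                          + ["liver"] * n_liver)
        p_notch = np.r_[np.full(n_loc, 0.045), np.full(n_skin, 0.088),
                        np.full(n_liver, 0.045)]
        n = len(groups)
        feats = pd.DataFrame({
            "NOTCH1_mut": (rng.random(n) < p_notch).astype(float),
            "other_mut": (rng.random(n) < 0.10).astype(float)})
        cov = pd.DataFrame({"c": rng.normal(size=n)})
        per_site = metbc.site_specific_scan(feats, sites, groups, cov, min_count=10)
        p_skin = per_site["skin"].set_index("feature").loc["NOTCH1_mut", "p_raw"]
        p_liver = per_site["liver"].set_index("feature").loc["NOTCH1_mut", "p_raw"]
        assert p_skin < 0.01
        assert p_liver > 0.01


class TestFisher:
    def test_identical_rows_p_one(self):
        assert metbc.fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_zero_margin_p_one(self):
        assert metbc.fisher_exact_2x2([[0, 0], [3, 7]]) == pytest.approx(1.0)

    def test_negative_entries_error(self):
        with pytest.raises(ValueError):
            metbc.fisher_exact_2x2([[1, -1], [2, 3]])

    def test_2x2_matches_hypergeometric_enumeration(self):
        """50 random small-margin tables vs brute-force enumeration."""
        rng = np.random.default_rng(16)
        for _ in range(50):
            t = rng.integers(0, 16, size=(2, 2))
            r0, r1 = t.sum(axis=1)
            c0 = t.sum(axis=0)[0]
            n = t.sum()
            if n == 0:
                continue
            # enumerate all tables with these margins
            lo, hi = max(0, c0 - r1), min(r0, c0)
            def logp(a):
                return (gammaln(r0 + 1) + gammaln(r1 + 1) + gammaln(c0 + 1)
                        + gammaln(n - c0 + 1) - gammaln(n + 1)
                        - gammaln(a + 1) - gammaln(r0 - a + 1)
                        - gammaln(c0 - a + 1) - gammaln(r1 - c0 + a + 1))
            lp_obs = logp(t[0, 0])
            p_enum = sum(np.exp(logp(a)) for a in range(lo, hi + 1)
                         if logp(a) <= lp_obs + 1e-9)
            assert metbc.fisher_exact_2x2(t) == pytest.approx(min(1.0, p_enum),
                                                              abs=1e-9)

    def test_rxc_reduces_to_2x2(self):
        t = [[3, 9], [7, 2]]
        assert metbc.fisher_exact_rxc(t) == pytest.approx(
            metbc.fisher_exact_2x2(t))

    def test_rxc_mc_matches_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            t = rng.integers(0, 5, size=(2, 3))
            if t.sum() == 0 or (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            p_exact = metbc.fisher_exact_rxc(t)
            p_mc = metbc.fisher_exact_rxc(t, n_mc=20000, seed=1,
                                          max_enumeration=0)
            se = np.sqrt(p_exact * (1 - p_exact) / 20000)
            assert abs(p_mc - p_exact) < 3 * se + 2 / 20001

    def test_rxc_null_p_roughly_uniform(self):
        """Independence-generated 4x5 tables give dispersed p-values."""
        rng = np.random.default_rng(18)
        ps = []
        for _ in range(40):
            rows = rng.multinomial(60, np.full(4, 0.25))
            t = np.array([rng.multinomial(r, np.full(5, 0.2)) for r in rows])
            ps.append(metbc.fisher_exact_rxc(t, n_mc=2000, seed=int(rng.integers(1e6))))
        ps = np.array(ps)
        assert ps.min() < 0.5 and ps.max() > 0.5
        assert 0.2 < ps.mean() < 0.8


class TestMannWhitney:
    def test_identical_multisets_p_near_one(self):
        a = [1, 2, 3, 4, 5]
        _, p = metbc.compare_counts(a, a)
        assert p > 0.9

    def test_u_equals_pairwise_win_count(self):
        a = [3, 1, 4, 1, 5, 9, 2, 6]
        b = [2, 7, 1, 8]
        u, _ = metbc.compare_counts(a, b)
        wins = sum(0.5 if x == y else float(x > y)
                   for x, y in itertools.product(a, b))
        assert u == pytest.approx(wins)

    def test_planted_count_shift_significant(self):
        """Mean 6.7 vs 5.6 short variants at the study sizes: p < 1e-6."""
        rng = np.random.default_rng(19)
        met = rng.poisson(6.7, 5034)
        loc = rng.poisson(5.6, 4512)
        _, p = metbc.compare_counts(met, loc)
        assert p < 1e-6
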