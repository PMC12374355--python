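"""Residualization, Mahalanobis/PERMANOVA, partial Spearman, FDR, LC model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from fluidconn.stats import (
    fdr_adjust,
    fit_lc_reserve_model,
    mahalanobis_distances,
    orthogonal_poly,
    partial_spearman,
    permanova,
    residualize,
    split_possible_probable,
    validate_cohort,
)

from oracles import bh_adjust_direct, mahalanobis_direct


class TestResidualize:
    def test_orthogonal_covariate_returns_centered(self, rng):
        n = 64
        cov = np.tile([1.0, -1.0], n // 2)
        values = rng.normal(size=n)
        values -= values @ cov / (cov @ cov) * cov  # force exact orthogonality
        res = residualize(values, cov)
        assert np.allclose(res, values - values.mean(), atol=1e-10)

    def test_perfect_fit_gives_zero(self, rng):
        age = rng.uniform(50, 80, 40)
        res = residualize(2.0 * age, age)
        assert np.allclose(res, 0.0, atol=1e-10)

    def test_matches_normal_equation_oracle(self, rng):
        n = 50
        cov = rng.normal(size=(n, 2))
        values = rng.normal(size=n)
        design = np.column_stack([np.ones(n), cov])
        beta = np.linalg.solve(design.T @ design, design.T @ values)
        assert np.allclose(residualize(values, cov), values - design @ beta, atol=1e-10)

    def test_idempotent(self, rng):
        cov = rng.normal(size=(30, 1))
        res = residualize(rng.normal(size=30), cov)
        assert np.allclose(residualize(res, cov), res, atol=1e-10)

    def test_missing_rows_stay_nan(self, rng):
        values = rng.normal(size=20)
        values[3] = np.nan
        res = residualize(values, rng.normal(size=20))
        assert np.isnan(res[3]) and np.isfinite(np.delete(res, 3)).all()

    def test_rank_deficiency_rejected(self, rng):
        cov = np.ones((30, 1))  # collinear with the intercept
        with pytest.raises(ValueError, match="rank"):
            residualize(rng.normal(size=30), cov)


class TestMahalanobis:
    def test_whitened_features_reduce_to_euclidean(self, rng):
        x = rng.normal(size=(40, 3))
        # decorrelate and scale to exactly unit sample covariance
        xc = x - x.mean(axis=0)
        chol = np.linalg.cholesky(np.cov(xc, rowvar=False, ddof=1))
        white = np.linalg.solve(chol, xc.T).T
        d = mahalanobis_distances(white)
        euclid = np.sqrt(((white[:, None] - white[None, :]) ** 2).sum(-1))
        assert np.allclose(d, euclid, atol=1e-10)

    def test_duplicate_rows_distance_zero(self, rng):
        x = rng.normal(size=(15, 2))
        x[7] = x[2]
        d = mahalanobis_distances(x)
        assert d[2, 7] == pytest.approx(0.0, abs=1e-12)

    def test_matches_explicit_inverse_oracle(self, rng):
        x = rng.normal(size=(20, 3))
        assert np.allclose(mahalanobis_distances(x), mahalanobis_direct(x), atol=1e-8)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=(30, 3))
        a = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        transformed = x @ a.T + rng.normal(size=3)
        assert np.allclose(
            mahalanobis_distances(x), mahalanobis_distances(transformed), atol=1e-8
        )

    def test_singular_covariance_rejected(self, rng):
        x = rng.normal(size=(20, 2))
        x = np.column_stack([x, x[:, 0] + x[:, 1]])  # exact collinearity
        with pytest.raises(ValueError, match="singular|reduce"):
            mahalanobis_distances(x)

    def test_more_features_than_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            mahalanobis_distances(rng.normal(size=(4, 6)))


class TestPermanova:
    def test_univariate_equals_classical_anova(self, rng):
        vals = rng.normal(size=36)
        vals[12:24] += 0.8
        groups = np.repeat(["a", "b", "c"], 12)
        d = np.abs(vals[:, None] - vals[None, :])
        res = permanova(d, groups, n_perm=99, seed=0)
        f = sstats.f_oneway(vals[:12], vals[12:24], vals[24:]).statistic
        assert res.pseudo_F == pytest.approx(f, abs=1e-8)

    def test_matches_skbio(self, rng):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        x = rng.normal(size=(24, 3))
        x[8:16] += 0.5
        groups = np.repeat(["g1", "g2", "g3"], 8)
        d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
        res = permanova(d, groups, n_perm=99, seed=0)
        sk = sk_permanova(DistanceMatrix(d), list(groups), permutations=99)
        assert res.pseudo_F == pytest.approx(float(sk["test statistic"]), abs=1e-10)

    def test_minimum_p_bound(self, rng):
        vals = np.concatenate([rng.normal(0, 0.1, 10), rng.normal(50, 0.1, 10)])
        groups = np.repeat(["a", "b"], 10)
        d = np.abs(vals[:, None] - vals[None, :])
        res = permanova(d, groups, n_perm=199, seed=0)
        assert res.p >= 1.0 / (res.n_perm + 1)
        assert res.p == pytest.approx(1.0 / 200, abs=1e-12)

    def test_strong_separation_highly_significant(self, rng):
        x = rng.normal(size=(30, 2))
        x[15:] += 5.0  # 5 pooled SDs
        groups = np.repeat(["a", "b"], 15)
        d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
        res = permanova(d, groups, n_perm=2000, seed=3)
        assert res.p <= 0.001

    def test_degenerate_constant_distances(self):
        d = np.ones((12, 12)) - np.eye(12)
        res = permanova(d, np.repeat(["a", "b"], 6), n_perm=99, seed=0)
        assert np.isnan(res.pseudo_F) and np.isnan(res.p)

    def test_pairwise_posthocs(self, rng):
        x = rng.normal(size=(30, 2))
        x[:10] += 4.0
        groups = np.repeat(["a", "b", "c"], 10)
        d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
        res = permanova(d, groups, n_perm=499, seed=1, pairwise=True)
        assert len(res.pairwise) == 3
        table = {pair: (f, p, pf) for pair, f, p, pf in res.pairwise}
        assert table[("a", "b")][1] < 0.05
        assert table[("a", "c")][1] < 0.05
        assert table[("b", "c")][1] > 0.05

    def test_determinism_under_seed(self, rng):
        vals = rng.normal(size=20)
        d = np.abs(vals[:, None] - vals[None, :])
        groups = np.repeat(["a", "b"], 10)
        r1 = permanova(d, groups, n_perm=500, seed=9)
        r2 = permanova(d, groups, n_perm=500, seed=9)
        assert r1.p == r2.p

    def test_input_validation(self, rng):
        with pytest.raises(ValueError):
            permanova(np.eye(4), ["a", "a", "a", "b"], n_perm=9, seed=0)


class TestPartialSpearman:
    def test_monotone_transform_rho_one(self, rng):
        x = rng.normal(size=40)
        rho, _ = partial_spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_covariate_mediated_association_vanishes(self, rng):
        n = 200
        c = rng.normal(size=n)
        x = c + 0.01 * rng.normal(size=n)
        y = c.copy()
        rho_raw, _ = partial_spearman(x, y)
        rho_partial, _ = partial_spearman(x, y, covariates=c)
        assert rho_raw > 0.9
        assert abs(rho_partial) < 0.2

    def test_null_pvalues_uniform(self, rng):
        pvals = []
        for _ in range(300):
            x = rng.normal(size=60)
            y = rng.normal(size=60)
            pvals.append(partial_spearman(x, y)[1])
        assert sstats.kstest(pvals, "uniform").pvalue > 0.01

    def test_sidedness(self, rng):
        x = rng.normal(size=80)
        y = x + rng.normal(size=80)
        _, p_two = partial_spearman(x, y, alternative="two-sided")
        _, p_greater = partial_spearman(x, y, alternative="greater")
        _, p_less = partial_spearman(x, y, alternative="less")
        assert p_greater == pytest.approx(p_two / 2, rel=1e-9)
        assert p_less > 0.5

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            partial_spearman([1, 2, 3], [1, 2, 3])


class TestFDR:
    def test_hand_computed_stepup(self):
        out = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.0321])[0] == pytest.approx(0.0321, abs=1e-12)

    def test_all_ones(self):
        assert np.allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_direct_implementation(self, rng):
        p = rng.uniform(size=25)
        assert np.allclose(fdr_adjust(p), bh_adjust_direct(p), atol=1e-12)

    def test_never_below_raw(self, rng):
        p = rng.uniform(size=40)
        assert np.all(fdr_adjust(p) >= p - 1e-15)

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])


class TestOrthogonalPoly:
    def test_orthonormal_and_centered(self, rng):
        x = rng.normal(size=30)
        basis = orthogonal_poly(x, 2)
        assert abs(basis[:, 0].sum()) < 1e-10  # orthogonal to intercept
        assert abs(basis[:, 1].sum()) < 1e-10
        assert basis[:, 0] @ basis[:, 1] == pytest.approx(0.0, abs=1e-10)
        assert np.linalg.norm(basis[:, 0]) == pytest.approx(1.0, abs=1e-12)
        assert np.linalg.norm(basis[:, 1]) == pytest.approx(1.0, abs=1e-12)

    def test_sign_convention(self):
        x = np.arange(10.0)
        basis = orthogonal_poly(x, 2)
        assert np.corrcoef(basis[:, 0], x)[0, 1] > 0.99  # linear term rises with x
        assert basis[0, 1] > 0 and basis[-1, 1] > 0  # quadratic term convex


# tiny fixed dataset; expected values computed independently with
# R: lm(y ~ poly(x, 2) * factor(g))
_R_Y = [-0.004, -0.4256, 0.366, 0.7799, -1.9936, -0.3219, 0.7015, -0.08,
        -0.1622, -0.4706, 0.3925, 0.9276, -0.0025, 0.5116, -0.0792, -0.0345,
        0.3666, -0.1165, 0.0081, 0.2447, -0.0677, -0.0748, 0.4243, 0.1898]
_R_X = [0.3047, -1.04, 0.7505, 0.9406, -1.951, -1.3022, 0.1278, -0.3162,
        -0.0168, -0.853, 0.8794, 0.7778, 0.066, 1.1272, 0.4675, -0.8593,
        0.3688, -0.9589, 0.8785, -0.0499, -0.1849, -0.6809, 1.2225, -0.1545]
_R_COEFS = [-0.148382246500, 2.546100123019, -0.965813983281,
            0.373591232785, -0.487752225086, 0.874739151117]
_R_F = 22.34157
_R_P = 3.854836e-07


class TestLCReserveModel:
    def test_poly_interaction_fit_matches_r_oracle(self):
        import statsmodels.api as sm

        y = np.array(_R_Y)
        x = np.array(_R_X)
        g = np.array([0.0, 1.0] * 12)
        basis = orthogonal_poly(x, 2)
        design = np.column_stack(
            [np.ones(24), basis[:, 0], basis[:, 1], g,
             basis[:, 0] * g, basis[:, 1] * g]
        )
        fit = sm.OLS(y, design).fit()
        assert np.allclose(fit.params, _R_COEFS, atol=1e-9)
        assert fit.fvalue == pytest.approx(_R_F, rel=1e-5)
        assert fit.f_pvalue == pytest.approx(_R_P, rel=1e-4)

    def _table(self, rng, n=103, quadratic_low=-0.5, noise=0.3):
        age = rng.uniform(55, 80, n)
        lc = rng.normal(size=n)
        reserve = rng.normal(size=n)
        low = reserve <= np.median(reserve)
        y = 0.3 * lc + quadratic_low * lc**2 * low + rng.normal(0, noise, n)
        return pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "group": ["HC"] * n,
                "age": age,
                "lc_cr": lc,
                "premorbid_iq": reserve,
                "fluidity_delta": y,
            }
        )

    def test_recovers_low_reserve_concavity(self, rng):
        fit = fit_lc_reserve_model(
            self._table(rng), "fluidity_delta", "lc_cr", "premorbid_iq"
        )
        # the quadratic term in the low-reserve (reference) subgroup is concave
        assert fit.coefficients["poly2"] < 0
        assert fit.p["poly2"] < 0.05
        # and the interaction cancels it in the high-reserve subgroup
        assert fit.coefficients["poly2:group_high"] > 0
        assert fit.n_obs == 103
        assert fit.overall_df == (5, 97)

    def test_constant_reserve_rejected(self, rng):
        table = self._table(rng)
        table["premorbid_iq"] = 1.0
        # constant reserve leaves nothing to median-split: the residualized
        # score is identically zero
        with pytest.raises(ValueError):
            fit_lc_reserve_model(table, "fluidity_delta", "lc_cr", "premorbid_iq")

    def test_too_few_cases_rejected(self, rng):
        table = self._table(rng, n=10)
        with pytest.raises(ValueError, match="20"):
            fit_lc_reserve_model(table, "fluidity_delta", "lc_cr", "premorbid_iq")


class TestCohortHelpers:
    def test_split_possible_probable(self):
        table = pd.DataFrame(
            {
                "subject_id": ["a", "b", "c", "d", "e"],
                "group": ["MCI-LB", "MCI-LB", "MCI-LB", "HC", "MCI-LB"],
                "n_core_features": [1, 3, np.nan, 0, 2],
            }
        )
        out = split_possible_probable(table)
        got = dict(zip(out["subject_id"], out["group"]))
        assert got["a"] == "possible MCI-LB"
        assert got["b"] == "probable MCI-LB"
        assert got["e"] == "probable MCI-LB"
        assert got["d"] == "HC"
        assert "c" not in got  # unclassified subject excluded

    def test_negative_counts_rejected(self):
        table = pd.DataFrame(
            {"subject_id": ["a"], "group": ["MCI-LB"], "n_core_features": [-1]}
        )
        with pytest.raises(ValueError):
            split_possible_probable(table)

    def test_validate_cohort(self):
        good = pd.DataFrame({"subject_id": ["a", "b"], "group": ["HC", "MCI-LB"]})
        validate_cohort(good)
        with pytest.raises(ValueError, match="duplicated"):
            validate_cohort(
                pd.DataFrame({"subject_id": ["a", "a"], "group": ["HC", "HC"]})
            )
        with pytest.raises(ValueError, match="unknown"):
            validate_cohort(
                pd.DataFrame({"subject_id": ["a"], "group": ["Martian"]})
            )
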