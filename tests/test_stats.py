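"""Statistical layer: enumeration oracles, GLM limits, adjustment properties."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from matesite import stats as ms


# ---------------------------------------------------------------------------
# Mann-Whitney

def mwu_enumeration(x, y):
    """Oracle: exact two-sided p over all assignments of pooled values."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def ustat(xs, ys):
        return sum(
            (xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys
        )

    mean = n1 * len(y) / 2.0
    d_obs = abs(ustat(x, y) - mean)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        chosen = set(idx)
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        total += 1
        if abs(ustat(xs, ys) - mean) >= d_obs - 1e-12:
            hits += 1
    return min(1.0, hits / total)


class TestMannWhitney:
    def test_fully_separated_example(self):
        r = ms.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert r.statistic_value == 0.0
        assert r.p_value == pytest.approx(0.1)
        assert "exact" in r.method_detail

    def test_identical_samples(self):
        r = ms.mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert r.statistic_value == pytest.approx(8.0)  # n^2 / 2
        assert r.p_value > 0.9

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=8), rng.normal(0.5, 1, size=9)
        a = ms.mann_whitney_u(x, y)
        b = ms.mann_whitney_u(np.exp(x), np.exp(y))
        assert a.p_value == pytest.approx(b.p_value)
        assert a.statistic_value == pytest.approx(b.statistic_value)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ms.mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 4), (3, 6), (5, 5)])
    def test_exact_p_matches_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # tie-free
            x, y = pooled[:n1], pooled[n1:]
            got = ms.mann_whitney_u(x, y)
            assert got.p_value == pytest.approx(mwu_enumeration(x, y), abs=1e-12)


# ---------------------------------------------------------------------------
# Anderson-Darling

def ad2_direct_summation(x, y):
    """Oracle: naive loop translation of the midrank two-sample statistic."""
    pooled = sorted(list(x) + list(y))
    distinct = sorted(set(pooled))
    N = len(pooled)
    total = 0.0
    for sample in (list(x), list(y)):
        inner = 0.0
        for j, z in enumerate(distinct):
            lj = pooled.count(z)
            Bj = sum(1 for v in pooled if v < z) + lj / 2.0
            fij = sample.count(z)
            Mij = sum(1 for v in sample if v < z) + fij / 2.0
            denom = Bj * (N - Bj) - N * lj / 4.0
            if denom > 0:
                inner += lj / N * (N * Mij - len(sample) * Bj) ** 2 / denom
        total += inner / len(sample)
    return (N - 1) / N * total


class TestAndersonDarling:
    def test_statistic_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            x = rng.integers(0, 6, size=rng.integers(2, 9)).astype(float)
            y = rng.integers(0, 6, size=rng.integers(2, 9)).astype(float)
            assert ms._ad2_statistic(x, y) == pytest.approx(
                ad2_direct_summation(x, y), rel=1e-12
            )

    def test_statistic_nonnegative(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            x, y = rng.normal(size=5), rng.normal(size=6)
            assert ms._ad2_statistic(x, y) >= 0.0

    def test_degenerate_identical_values(self):
        r = ms.anderson_darling_2sample([3.0, 3.0], [3.0, 3.0])
        assert r.statistic_value == 0.0 and r.p_value == 1.0

    def test_full_separation_small_sample(self):
        # C(4,2) = 6 equally likely splits; both "extreme" labelings tie,
        # so the enumeration p is 2/6 and the permutation estimate must agree
        r = ms.anderson_darling_2sample([1.0, 2.0], [100.0, 101.0],
                                        n_perm=3000, seed=0)
        assert r.p_value == pytest.approx(2 / 6, abs=0.03)

    def test_permutation_matches_exhaustive_enumeration_n3(self):
        x = np.array([1.0, 4.0, 6.0])
        y = np.array([2.0, 9.0, 11.0])
        obs = ms._ad2_statistic(x, y)
        pooled = np.concatenate([x, y])
        hits = total = 0
        for idx in itertools.combinations(range(6), 3):
            chosen = set(idx)
            xs = pooled[list(idx)]
            ys = pooled[[i for i in range(6) if i not in chosen]]
            total += 1
            if ms._ad2_statistic(xs, ys) >= obs - 1e-12:
                hits += 1
        exact = hits / total
        r = ms.anderson_darling_2sample(x, y, n_perm=4000, seed=3)
        # permutation estimate within binomial MC error of the exact value
        se = np.sqrt(exact * (1 - exact) / 4000)
        assert abs(r.p_value - exact) < 4 * se + 1e-3

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(4)
        ps = []
        for s in range(40):
            x, y = rng.normal(size=12), rng.normal(size=12)
            ps.append(
                ms.anderson_darling_2sample(x, y, n_perm=200, seed=s).p_value
            )
        ps = np.array(ps)
        assert 0.25 < ps.mean() < 0.75
        assert (ps < 0.2).mean() < 0.5


# ---------------------------------------------------------------------------
# GLMM

class TestGLMM:
    def test_flat_prior_single_group_matches_logit(self):
        df = pd.DataFrame({"y": [1] * 3 + [0] * 7, "g": ["a"] * 10})
        fit = ms.fit_glmm(df, "y", [], "g", prior_sd=np.inf)
        assert fit.converged
        assert fit.coef[0] == pytest.approx(logit(0.3), abs=1e-4)
        assert fit.random_effects["g"] < 0.01  # variance driven to zero

    def test_flat_prior_zero_variance_matches_glm_oracle(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(0)
        n = 200
        x = rng.normal(size=n)
        g = np.repeat(np.arange(20), 10)
        y = rng.binomial(1, 1 / (1 + np.exp(0.3 - 0.8 * x)))
        df = pd.DataFrame({"y": y, "x": x, "g": g})
        fit = ms.fit_glmm(df, "y", ["x"], "g", prior_sd=np.inf, random_sd=0.0)
        glm = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
        assert np.allclose(fit.coef, np.asarray(glm.params), atol=1e-5)
        assert np.allclose(fit.se, np.asarray(glm.bse), atol=1e-3)

    def test_complete_separation_stays_finite(self):
        df = pd.DataFrame(
            {"y": [0] * 10 + [1] * 10, "lev": ["a"] * 10 + ["b"] * 10,
             "g": list(range(20))}
        )
        fit = ms.fit_glmm(df, "y", ["lev"], "g", prior_sd=2.5)
        assert fit.converged
        assert np.all(np.abs(fit.coef) < 8 * 2.5)  # bounded by the prior pull
        assert np.all(np.isfinite(fit.se))

    def test_parameter_recovery_with_random_intercepts(self):
        rng = np.random.default_rng(5)
        hits = 0
        reps = 20
        for _ in range(reps):
            n_groups, per = 50, 8
            g = np.repeat(np.arange(n_groups), per)
            x = rng.normal(size=n_groups * per)
            u = rng.normal(0, 1.0, n_groups)
            y = rng.binomial(1, 1 / (1 + np.exp(-(0.8 * x + u[g]))))
            df = pd.DataFrame({"y": y, "x": x, "g": g})
            fit = ms.fit_glmm(df, "y", ["x"], "g", prior_sd=np.inf)
            i = fit.coef_names.index("x")
            lo = fit.coef[i] - 1.96 * fit.se[i]
            hi = fit.coef[i] + 1.96 * fit.se[i]
            hits += lo <= 0.8 <= hi
        # 95% CI should cover the generating slope in most replicates
        assert hits >= int(0.8 * reps)

    def test_gaussian_family_matches_group_means_structure(self):
        rng = np.random.default_rng(6)
        g = np.repeat(np.arange(10), 20)
        u = rng.normal(0, 2.0, 10)
        y = 5.0 + u[g] + rng.normal(0, 1.0, 200)
        df = pd.DataFrame({"y": y, "g": g})
        fit = ms.fit_glmm(df, "y", [], "g", family="gaussian", prior_sd=np.inf)
        assert fit.converged
        assert fit.coef[0] == pytest.approx(y.mean(), abs=0.8)
        assert 1.0 < fit.random_effects["g"] < 3.5
        assert 0.7 < fit.residual_sd < 1.4


class TestWald:
    def _fit(self, seed, effect=0.0):
        rng = np.random.default_rng(seed)
        g = np.tile(np.arange(20), 4)
        lev = np.repeat(["a", "b"], 40)
        u = rng.normal(0, 0.7, 20)
        eta = 0.2 + u[g] + np.where(lev == "b", effect, 0.0)
        y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        return ms.fit_glmm(
            pd.DataFrame({"y": y, "lev": lev, "g": g}), "y", ["lev"], "g"
        )

    def test_single_coefficient_block_is_z_squared(self):
        fit = self._fit(0, effect=1.0)
        w = ms.wald_factor_test(fit, "lev")
        i = fit.factor_info["lev"]["coef_idx"][0]
        assert w.statistic_value == pytest.approx(
            (fit.coef[i] / fit.se[i]) ** 2, rel=1e-6
        )

    def test_orthogonal_block_is_sum_of_z_squares(self):
        fit = ms.GLMMFit(
            family="binomial",
            coef_names=["(Intercept)", "f[b]", "f[c]"],
            coef=np.array([0.0, 1.0, -2.0]),
            se=np.array([0.5, 0.5, 1.0]),
            vcov=np.diag([0.25, 0.25, 1.0]),
            random_effects={}, residual_sd=None, prior_sd=2.5,
            converged=True, n_obs=10,
            factor_info={"f": {"levels": ["a", "b", "c"], "coef_idx": [1, 2]}},
        )
        w = ms.wald_factor_test(fit, "f")
        assert w.statistic_value == pytest.approx((1 / 0.5) ** 2 + (-2 / 1) ** 2)

    def test_unconverged_fit_refused(self):
        fit = self._fit(1)
        fit.converged = False
        with pytest.raises(ValueError, match="converge"):
            ms.wald_factor_test(fit, "lev")


class TestPairwise:
    def _three_level_fit(self, seed=2, effects=(0.0, 0.8, 0.0)):
        rng = np.random.default_rng(seed)
        lev = np.repeat(["a", "b", "c"], 40)
        g = np.tile(np.arange(20), 6)
        eta = np.select([lev == "a", lev == "b", lev == "c"], effects)
        y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        return ms.fit_glmm(
            pd.DataFrame({"y": y, "lev": lev, "g": g}), "y", ["lev"], "g"
        )

    def test_two_levels_adjusted_equals_unadjusted(self):
        rng = np.random.default_rng(3)
        lev = np.repeat(["a", "b"], 30)
        y = rng.binomial(1, 0.5, 60)
        fit = ms.fit_glmm(
            pd.DataFrame({"y": y, "lev": lev, "g": np.tile(np.arange(15), 4)}),
            "y", ["lev"], "g",
        )
        out = ms.pairwise_comparisons(fit, "lev")
        assert out["p_adjusted"].iloc[0] == pytest.approx(
            out["p_unadjusted"].iloc[0], rel=1e-6
        )

    def test_single_step_dominates_bonferroni(self):
        fit = self._three_level_fit()
        ss = ms.pairwise_comparisons(fit, "lev", "single-step")
        bf = ms.pairwise_comparisons(fit, "lev", "bonferroni")
        assert (ss["p_adjusted"] <= bf["p_adjusted"] + 1e-9).all()
        assert (ss["p_adjusted"] >= ss["p_unadjusted"] - 1e-9).all()

    def test_null_simulation_large_adjusted_p(self):
        fit = self._three_level_fit(seed=9, effects=(0.3, 0.3, 0.3))
        out = ms.pairwise_comparisons(fit, "lev")
        assert (out["p_adjusted"] > 0.2).all()

    def test_simultaneous_ci_consistent_with_alpha(self):
        fit = self._three_level_fit()
        out = ms.pairwise_comparisons(fit, "lev", alpha=0.05)
        covers_zero = (out["ci_low"] <= 0) & (out["ci_high"] >= 0)
        assert (covers_zero == (out["p_adjusted"] > 0.05)).all()

    def test_numeric_covariate_is_not_a_factor(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {"y": rng.binomial(1, 0.5, 80), "x": rng.normal(size=80),
             "g": np.tile(np.arange(20), 4)}
        )
        fit = ms.fit_glmm(df, "y", ["x"], "g")
        with pytest.raises(ValueError, match="factor"):
            ms.pairwise_comparisons(fit, "x")
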