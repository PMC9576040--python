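"""Statistical layer: rank tests, two-sample Anderson-Darling, and
separation-robust mixed models.

The monitoring data lead to two recurring statistical problems:

* comparisons of small, tied, non-normal samples (seasons detected,
  time-at-large, return-interval distributions) — handled by the
  Mann-Whitney U test and the two-sample Anderson-Darling test; and
* proportions of events across factor levels with repeated measures per
  shark and levels containing no events at all (complete or quasi-complete
  separation) — handled by binomial/Poisson/Gaussian mixed models fitted by
  maximum a posteriori with weakly informative zero-mean normal priors on
  the fixed effects and normal random intercepts integrated out by a
  Laplace approximation. The prior keeps every coefficient finite under
  separation while leaving well-identified coefficients essentially
  unpenalized.

Factor-level hypotheses are tested with Wald chi-square statistics on the
coefficient block, and all pairwise level comparisons use a single-step
multivariate-normal adjustment over the contrast correlation matrix
(Tukey-style simultaneous inference on the link scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps

FAMILIES = ("binomial", "poisson", "gaussian")


@dataclass(frozen=True)
class TestResult:
    statistic_name: str
    statistic_value: float
    p_value: float
    n1: int
    n2: int
    method_detail: str

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# Rank tests

def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U with midrank tie handling.

    Exact enumeration when n1 + n2 <= 12 and the pooled sample is tie-free,
    else the tie-corrected normal approximation. The reported U counts wins
    of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    if x.size + y.size <= 12 and tie_free:
        method, detail = "exact", "exact enumeration"
    else:
        method, detail = "asymptotic", "normal approximation with tie correction"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult("U", float(res.statistic), float(res.pvalue), x.size, y.size,
                      detail)


def _ad2_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Raw two-sample Anderson-Darling statistic, midrank (tie-adjusted) form.

    Computed over the distinct pooled values z_j with pooled multiplicities
    l_j: with B_j the midrank pooled count through z_j and M_ij the midrank
    count for sample i,

        A2 = (N-1)/N * sum_i 1/n_i * sum_j l_j/N *
             (N M_ij - n_i B_j)^2 / (B_j (N - B_j) - N l_j / 4).

    Null expectation is 1 (k - 1 for k samples). Degenerate pooled samples
    (a single distinct value) give 0.
    """
    pooled = np.concatenate([x, y])
    N = pooled.size
    vals, lj = np.unique(pooled, return_counts=True)
    Bj = np.cumsum(lj) - lj / 2.0
    denom = Bj * (N - Bj) - N * lj / 4.0
    ok = denom > 0
    total = 0.0
    for sample in (x, y):
        fij = np.zeros(vals.size)
        np.add.at(fij, np.searchsorted(vals, sample), 1.0)
        Mij = np.cumsum(fij) - fij / 2.0
        num = (N * Mij - sample.size * Bj) ** 2
        total += (lj[ok] / N * num[ok] / denom[ok]).sum() / sample.size
    return (N - 1) / N * total


def anderson_darling_2sample(
    x,
    y,
    p_method: str = "permutation",
    n_perm: int = 2000,
    seed: int | None = None,
) -> TestResult:
    """Two-sample Anderson-Darling test on the pooled empirical distribution.

    The p-value is computed by label permutation of the pooled sample
    (default 2000 resamples, add-one estimator) or by the asymptotic
    interpolation of the standardized statistic. Identical degenerate
    samples give statistic 0 and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least two observations")
    obs = _ad2_statistic(x, y)
    if np.unique(np.concatenate([x, y])).size == 1:
        return TestResult("AD", 0.0, 1.0, x.size, y.size, "degenerate pooled sample")
    if p_method == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([x, y])
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if _ad2_statistic(perm[: x.size], perm[x.size:]) >= obs - 1e-12:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
        detail = f"permutation ({n_perm} resamples)"
    elif p_method == "asymptotic":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sps.anderson_ksamp([x, y])
        p = float(np.clip(res.pvalue, 0.0, 1.0))
        detail = "asymptotic interpolation (p capped to [0.001, 0.25])"
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return TestResult("AD", float(obs), float(p), x.size, y.size, detail)


# ---------------------------------------------------------------------------
# MAP-regularized mixed models

@dataclass
class GLMMFit:
    """A fitted mixed model (MAP estimates, Laplace-integrated intercepts)."""

    family: str
    coef_names: list[str]
    coef: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    random_effects: dict[str, float]      # grouping factor -> intercept SD
    residual_sd: float | None
    prior_sd: float
    converged: bool
    n_obs: int
    factor_info: dict = field(default_factory=dict, repr=False)
    n_groups: dict = field(default_factory=dict, repr=False)

    def coefficients(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef, "se": self.se}, index=self.coef_names
        )


def _build_design(data: pd.DataFrame, fixed: list[str]):
    n = len(data)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    factor_info: dict[str, dict] = {}
    for term in fixed:
        col = data[term]
        if (
            col.dtype == object
            or isinstance(col.dtype, pd.CategoricalDtype)
            or col.dtype == bool
        ):
            if isinstance(col.dtype, pd.CategoricalDtype):
                levels = list(col.cat.categories)
            else:
                levels = sorted(col.dropna().unique())
            if len(levels) < 2:
                raise ValueError(f"factor {term!r} needs >= 2 levels")
            idx = []
            for lv in levels[1:]:
                idx.append(len(names))
                names.append(f"{term}[{lv}]")
                cols.append((col == lv).to_numpy(dtype=float))
            factor_info[term] = {"levels": levels, "coef_idx": idx}
        else:
            factor_info[term] = {"levels": None, "coef_idx": [len(names)]}
            names.append(term)
            cols.append(col.to_numpy(dtype=float))
    return np.column_stack(cols), names, factor_info


def _loglik_parts(y, m, eta, family, sigma_e):
    """Per-observation log-likelihood, d/d eta, and -d2/d eta2 (weights)."""
    if family == "binomial":
        mu = special.expit(eta)
        ll = y * eta - m * np.logaddexp(0.0, eta)
        return ll, y - m * mu, np.maximum(m * mu * (1 - mu), 1e-10)
    if family == "poisson":
        mu = np.exp(np.clip(eta, -30, 30))
        ll = y * eta - mu - special.gammaln(y + 1)
        return ll, y - mu, np.maximum(mu, 1e-10)
    # gaussian, identity link
    r = y - eta
    ll = -0.5 * (r**2 / sigma_e**2 + np.log(2 * np.pi * sigma_e**2))
    return ll, r / sigma_e**2, np.full_like(eta, 1.0 / sigma_e**2)


def _inner_mode(y, m, X, beta, Z, sigmas_u, family, sigma_e, u0=None):
    """Newton ascent of the joint log density over the random intercepts."""
    q = Z.shape[1]
    u = np.zeros(q) if u0 is None else u0.copy()
    d_inv = 1.0 / sigmas_u**2
    H = np.eye(q)
    for _ in range(100):
        eta = X @ beta + Z @ u
        _, g_eta, w = _loglik_parts(y, m, eta, family, sigma_e)
        grad = Z.T @ g_eta - d_inv * u
        H = Z.T @ (w[:, None] * Z)
        H[np.diag_indices(q)] += d_inv
        step = np.linalg.solve(H, grad)
        u = u + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = X @ beta + Z @ u
    ll, _, w = _loglik_parts(y, m, eta, family, sigma_e)
    H = Z.T @ (w[:, None] * Z)
    H[np.diag_indices(q)] += d_inv
    return u, H, float(ll.sum())


def fit_glmm(
    data: pd.DataFrame,
    response: str,
    fixed,
    groups,
    family: str = "binomial",
    prior_sd: float = 2.5,
    trials: str | None = None,
    random_sd: float | None = None,
    maxiter: int = 200,
) -> GLMMFit:
    """MAP fit of a GLMM with normal priors on the fixed effects.

    Parameters
    ----------
    data : tidy frame with one row per observation.
    response : response column. For the binomial family either a 0/1
        indicator or a success count combined with a ``trials`` column.
    fixed : fixed-effect column name(s); object/categorical/bool columns are
        treatment-coded against their first level, numeric columns enter
        linearly. An intercept is always included (unpenalized slopes and
        penalized alike share the same ``prior_sd``).
    groups : grouping factor column name(s); each contributes independent
        normal random intercepts whose SD is estimated.
    prior_sd : SD of the independent zero-mean normal priors on the fixed
        effects (link scale); ``np.inf`` removes the regularization. The
        prior is the separation-robust device: with levels containing no
        events the likelihood alone has no maximum, the posterior does.
    random_sd : fix every random-intercept SD at this value instead of
        estimating it (0 collapses the model to an ordinary GLM, the
        oracle limit used in validation).

    Random intercepts are integrated out with a Laplace approximation
    (exact for the Gaussian family); variance parameters are optimized on
    the log scale with the fixed effects. Standard errors come from the
    inverse finite-difference Hessian of the negative log marginal
    posterior.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    fixed = [fixed] if isinstance(fixed, str) else list(fixed)
    groups = [groups] if isinstance(groups, str) else list(groups)
    y = data[response].to_numpy(dtype=float)
    m = data[trials].to_numpy(dtype=float) if trials else np.ones_like(y)
    if family == "binomial" and ((y < 0) | (y > m)).any():
        raise ValueError("binomial response must satisfy 0 <= y <= trials")
    X, names, factor_info = _build_design(data, fixed)
    n, p = X.shape

    z_cols, group_sizes = [], {}
    for g in groups:
        codes, levels = pd.factorize(data[g], sort=True)
        ind = np.zeros((n, len(levels)))
        ind[np.arange(n), codes] = 1.0
        z_cols.append(ind)
        group_sizes[g] = len(levels)
    Z = np.hstack(z_cols)
    q_per = [group_sizes[g] for g in groups]
    estimate_sigma = random_sd is None
    fixed_sig = None if estimate_sigma else max(float(random_sd), 1e-4)
    n_sig = len(groups) if estimate_sigma else 0
    n_var = n_sig + (1 if family == "gaussian" else 0)

    def unpack(theta):
        beta = theta[:p]
        if estimate_sigma:
            sig_u = np.exp(theta[p:p + len(groups)])
        else:
            sig_u = np.full(len(groups), fixed_sig)
        sig_e = np.exp(theta[-1]) if family == "gaussian" else None
        return beta, sig_u, sig_e

    def nll(theta):
        beta, sig_u, sig_e = unpack(theta)
        sigmas = np.repeat(sig_u, q_per)
        u, H, ll = _inner_mode(y, m, X, beta, Z, sigmas, family, sig_e)
        sign, logdet = np.linalg.slogdet(H)
        if sign <= 0:
            return 1e10
        lp = (
            ll
            - 0.5 * np.sum(u**2 / sigmas**2)
            - np.sum(np.log(sigmas))
            + 0.5 * Z.shape[1] * np.log(2 * np.pi)
            - 0.5 * logdet
        )
        if np.isfinite(prior_sd):
            lp -= 0.5 * np.sum(beta**2) / prior_sd**2
        return -lp if np.isfinite(lp) else 1e10

    # start at the null model intercept
    theta0 = np.zeros(p + n_var)
    rate = np.clip(y.sum() / max(m.sum(), 1.0), 1e-4, 1 - 1e-4)
    if family == "binomial":
        theta0[0] = special.logit(rate)
    elif family == "poisson":
        theta0[0] = np.log(max(y.mean(), 1e-4))
    else:
        theta0[0] = y.mean()
        theta0[-1] = np.log(max(y.std(), 1e-3))
    bounds = [(None, None)] * p + [(-7.0, 5.0)] * n_var
    res = optimize.minimize(
        nll, theta0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-9},
    )
    theta = res.x
    beta, sig_u, sig_e = unpack(theta)

    # finite-difference Hessian of the objective for standard errors
    h = 1e-4 * np.maximum(1.0, np.abs(theta))
    k = theta.size
    hess = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = nll(theta + ei + ej)
            fpm = nll(theta + ei - ej)
            fmp = nll(theta - ei + ej)
            fmm = nll(theta - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    try:
        vcov_full = np.linalg.inv(hess)
        vcov = vcov_full[:p, :p]
        if not np.all(np.diag(vcov) > 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        # variance components at the boundary: condition on them
        vcov = np.linalg.pinv(hess[:p, :p])
    se = np.sqrt(np.maximum(np.diag(vcov), 0.0))
    converged = bool(res.success and np.all(np.isfinite(beta)) and
                     np.all(np.isfinite(se)))
    return GLMMFit(
        family=family,
        coef_names=names,
        coef=beta,
        se=se,
        vcov=vcov,
        random_effects={g: float(s) for g, s in zip(groups, sig_u)},
        residual_sd=float(sig_e) if sig_e is not None else None,
        prior_sd=prior_sd,
        converged=converged,
        n_obs=n,
        factor_info=factor_info,
        n_groups=group_sizes,
    )


def wald_factor_test(fit: GLMMFit, factor: str) -> TestResult:
    """Wald chi-square test of a factor's coefficient block (H0: all zero)."""
    if not fit.converged:
        raise ValueError("fit did not converge; refusing downstream tests")
    if factor not in fit.factor_info:
        raise KeyError(f"factor {factor!r} not in model")
    idx = fit.factor_info[factor]["coef_idx"]
    c = fit.coef[idx]
    V = fit.vcov[np.ix_(idx, idx)]
    if np.linalg.cond(V) > 1e12:
        raise np.linalg.LinAlgError(
            f"singular coefficient covariance (cond={np.linalg.cond(V):.2e})"
        )
    chi2 = float(c @ np.linalg.solve(V, c))
    df = len(idx)
    return TestResult(
        f"chi2(df={df})", chi2, float(sps.chi2.sf(chi2, df)),
        fit.n_obs, df, "Wald test on the factor coefficient block",
    )


def _mvn_central_prob(t: float, corr: np.ndarray) -> float:
    """P(|Z_j| <= t for all j) for Z ~ MVN(0, corr)."""
    k = corr.shape[0]
    dist = sps.multivariate_normal(
        mean=np.zeros(k), cov=corr + 1e-10 * np.eye(k), allow_singular=True
    )
    return float(dist.cdf(np.full(k, t), lower_limit=np.full(k, -t)))


def pairwise_comparisons(
    fit: GLMMFit, factor: str, adjust: str = "single-step", alpha: float = 0.05
) -> pd.DataFrame:
    """All pairwise level comparisons of a factor on the link scale.

    ``single-step`` adjusts p-values and intervals through the joint
    multivariate-normal distribution of the contrast z-statistics (the
    Tukey-style adjustment appropriate for non-orthogonal model contrasts);
    ``bonferroni`` and ``none`` are fallbacks. Simultaneous CIs use the
    critical value consistent with the adjusted alpha.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; refusing downstream tests")
    info = fit.factor_info.get(factor)
    if info is None or info["levels"] is None or len(info["levels"]) < 2:
        raise ValueError(f"{factor!r} is not a factor with >= 2 levels")
    levels = info["levels"]
    p = len(fit.coef)
    rows_l = {}
    for lv in levels:
        v = np.zeros(p)
        if lv != levels[0]:
            v[info["coef_idx"][levels[1:].index(lv)]] = 1.0
        rows_l[lv] = v
    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
    C = np.array([rows_l[a] - rows_l[b] for a, b in pairs])
    est = C @ fit.coef
    Vc = C @ fit.vcov @ C.T
    se = np.sqrt(np.maximum(np.diag(Vc), 1e-300))
    z = est / se
    p_un = 2 * sps.norm.sf(np.abs(z))
    k = len(pairs)
    if adjust == "single-step":
        d = np.sqrt(np.diag(Vc))
        corr = Vc / np.outer(d, d)
        p_adj = np.array([1.0 - _mvn_central_prob(abs(zi), corr) for zi in z])
        crit = optimize.brentq(
            lambda t: _mvn_central_prob(t, corr) - (1 - alpha),
            sps.norm.ppf(1 - alpha / 2) - 1e-9,
            sps.norm.ppf(1 - alpha / (2 * k)) + 1.0,
        )
    elif adjust == "bonferroni":
        p_adj = np.minimum(1.0, k * p_un)
        crit = sps.norm.ppf(1 - alpha / (2 * k))
    elif adjust == "none":
        p_adj = p_un.copy()
        crit = sps.norm.ppf(1 - alpha / 2)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    p_adj = np.clip(np.maximum(p_adj, p_un), 0.0, 1.0)
    return pd.DataFrame(
        {
            "level_a": [a for a, _ in pairs],
            "level_b": [b for _, b in pairs],
            "estimate": est,
            "se": se,
            "z": z,
            "p_unadjusted": p_un,
            "p_adjusted": p_adj,
            "ci_low": est - crit * se,
            "ci_high": est + crit * se,
        }
    )
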