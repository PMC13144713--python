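"""Outcome-side models: attentional-problems factor, standardized
regressions, correlations and percentile-bootstrap indirect effects.

The attentional-problems battery (multi-informant indicators) is reduced to
a single latent factor by maximum-likelihood one-factor analysis with
regression-method scores.  Association models report unstandardized b,
standardized beta (= b * sd(x) / sd(y)), SE, z and p per predictor; with
missing data the coefficients come from the ML multivariate-normal solution
via expectation-maximization.  Indirect (mediation) effects are the product
of the X->M and M->Y|X path coefficients with seeded case-resampling
percentile bootstrap intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

__all__ = [
    "FactorModel",
    "RegressionResult",
    "MediationResult",
    "fit_one_factor",
    "fit_regression",
    "estimate_indirect",
    "pearson_correlation",
]


@dataclass
class FactorModel:
    loadings: pd.Series
    uniquenesses: pd.Series
    scores: pd.Series          # standardized to mean 0, SD 1
    loglik: float
    n: int
    warning: Optional[str] = None


@dataclass
class RegressionResult:
    table: pd.DataFrame        # index predictors (+ const): b, beta, se, z, p
    n: int
    missing_method: str
    r_squared: float = np.nan

    def beta(self, name: str) -> float:
        return float(self.table.loc[name, "beta"])

    def b(self, name: str) -> float:
        return float(self.table.loc[name, "b"])


@dataclass
class MediationResult:
    a_path: float              # X -> M
    b_path: float              # M -> Y | X
    direct: float              # c'
    total: float               # c
    indirect: float            # a * b (unstandardized)
    indirect_std: float        # same on z-scored X, M, Y
    ci_low: float
    ci_high: float
    ci_low_std: float
    ci_high_std: float
    level: float
    n_boot: int
    seed: int
    n: int
    n_redrawn: int = 0


def fit_one_factor(indicators: pd.DataFrame, standardize_scores: bool = True) -> FactorModel:
    """ML one-factor model (factor variance fixed at 1, free loadings and
    uniquenesses) with regression-method factor scores.

    For three indicators the model is just-identified and the ML loadings
    match the closed-form solution from the sample covariances.
    """
    X = indicators.to_numpy(dtype=float)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 indicators for a one-factor model")
    if np.isnan(X).any():
        raise ValueError("indicators must be complete; impute or drop first")
    n, p = X.shape
    if n <= p:
        raise ValueError("need more subjects than indicators")
    mu = X.mean(axis=0)
    S = np.cov(X.T, ddof=0)
    if np.linalg.eigvalsh(S).min() <= 1e-10:
        raise np.linalg.LinAlgError("indicator covariance is not positive definite")

    # start from the first principal component
    w_, v_ = np.linalg.eigh(S)
    lam0 = v_[:, -1] * np.sqrt(max(w_[-1] - np.median(w_[:-1]), 0.1))
    if lam0.sum() < 0:
        lam0 = -lam0
    th0 = np.concatenate([lam0, np.log(np.maximum(np.diag(S) - lam0 ** 2, 0.05))])

    def nll(th):
        lam = th[:p]
        psi = np.exp(th[p:])
        sigma = np.outer(lam, lam) + np.diag(psi)
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return 1e12
        logdet = 2 * np.log(np.diag(chol)).sum()
        inv = np.linalg.inv(sigma)
        return 0.5 * n * (p * np.log(2 * np.pi) + logdet + np.trace(S @ inv))

    res = minimize(nll, th0, method="L-BFGS-B",
                   options={"maxiter": 5000, "ftol": 1e-13, "gtol": 1e-10})
    lam = res.x[:p]
    psi = np.exp(res.x[p:])
    if lam.sum() < 0:   # sign is unidentified; orient positively
        lam = -lam
    sigma = np.outer(lam, lam) + np.diag(psi)
    # regression-method scores: E[f | y] = lam' Sigma^-1 (y - mu)
    weights = np.linalg.solve(sigma, lam)
    scores = (X - mu) @ weights
    if standardize_scores:
        scores = (scores - scores.mean()) / scores.std(ddof=0)
    warning = None
    if (lam ** 2).sum() / np.trace(S) < 0.05:
        warning = ("factor explains under 5% of indicator variance; "
                   "indicators are nearly uncorrelated")
    return FactorModel(
        loadings=pd.Series(lam, index=indicators.columns),
        uniquenesses=pd.Series(psi, index=indicators.columns),
        scores=pd.Series(scores, index=indicators.index, name="factor"),
        loglik=float(-res.fun), n=n, warning=warning,
    )


def _em_mvnorm(X: np.ndarray, tol: float = 1e-8, max_iter: int = 500):
    """EM for the MLE of a multivariate normal with arbitrary missingness."""
    n, p = X.shape
    mu = np.nanmean(X, axis=0)
    cov = np.diag(np.nanvar(X, axis=0) + 1e-6)
    obs = ~np.isnan(X)
    ll_old = -np.inf
    for _ in range(max_iter):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        ll = 0.0
        keys = obs @ (1 << np.arange(p))
        for key in np.unique(keys):
            idx = np.where(keys == key)[0]
            m = obs[idx[0]]
            o = np.where(m)[0]
            mis = np.where(~m)[0]
            Xo = X[np.ix_(idx, o)]
            if len(o) == 0:
                xfill = np.tile(mu, (len(idx), 1))
                sum_x += xfill.sum(axis=0)
                sum_xx += len(idx) * (cov + np.outer(mu, mu))
                continue
            Soo = cov[np.ix_(o, o)]
            chol = np.linalg.cholesky(Soo + 1e-12 * np.eye(len(o)))
            dev = Xo - mu[o]
            sol = np.linalg.solve(chol, dev.T)
            ll += -0.5 * (len(idx) * (len(o) * np.log(2 * np.pi)
                          + 2 * np.log(np.diag(chol)).sum()) + (sol ** 2).sum())
            xfull = np.empty((len(idx), p))
            xfull[:, o] = Xo
            if len(mis):
                B = np.linalg.solve(Soo, cov[np.ix_(o, mis)])
                xfull[:, mis] = mu[mis] + dev @ B
                Cmm = cov[np.ix_(mis, mis)] - cov[np.ix_(mis, o)] @ B
            sum_x += xfull.sum(axis=0)
            sum_xx += xfull.T @ xfull
            if len(mis):
                add = np.zeros((p, p))
                add[np.ix_(mis, mis)] = len(idx) * Cmm
                sum_xx += add
        mu = sum_x / n
        cov = sum_xx / n - np.outer(mu, mu)
        cov = (cov + cov.T) / 2
        if abs(ll - ll_old) < tol * (1 + abs(ll)):
            break
        ll_old = ll
    return mu, cov, ll


def fit_regression(
    y: pd.Series,
    X: pd.DataFrame,
    standardize: bool = True,
    missing: str = "complete",
    n_boot_se: int = 200,
    seed: int = 0,
) -> RegressionResult:
    """Linear regression with b, beta, SE, z and p per predictor.

    ``missing='complete'`` drops incomplete rows and uses OLS.
    ``missing='fiml'`` estimates the joint normal model by EM and derives
    the regression from the ML mean/covariance (equal to OLS when nothing
    is missing); its SEs come from a seeded case bootstrap.
    Standardized beta is b * sd(x) / sd(y) computed post-fit.
    """
    names = list(X.columns)
    data = pd.concat([y.rename("__y__"), X], axis=1)
    if data.shape[0] <= len(names) + 1:
        raise ValueError("need n > number of predictors + 1")
    M = data.to_numpy(dtype=float)

    # collinearity guard on complete rows
    comp = M[~np.isnan(M).any(axis=1)]
    if comp.shape[0] > len(names) + 1:
        Xc = np.column_stack([np.ones(len(comp)), comp[:, 1:]])
        if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
            corr = pd.DataFrame(comp[:, 1:], columns=names).corr().abs()
            np.fill_diagonal(corr.values, 0)
            i, j = np.unravel_index(np.nanargmax(corr.values), corr.shape)
            raise ValueError(
                f"perfectly collinear predictors (e.g. {names[i]} and {names[j]})")

    has_missing = np.isnan(M).any()
    if missing == "complete" or not has_missing:
        arr = comp
        n = len(arr)
        yv, Xv = arr[:, 0], arr[:, 1:]
        Xd = np.column_stack([np.ones(n), Xv])
        b, *_ = np.linalg.lstsq(Xd, yv, rcond=None)
        resid = yv - Xd @ b
        dof = n - Xd.shape[1]
        s2 = resid @ resid / dof
        covb = s2 * np.linalg.inv(Xd.T @ Xd)
        se = np.sqrt(np.diag(covb))
        sd_x = Xv.std(axis=0, ddof=0)
        sd_y = yv.std(ddof=0)
        r2 = 1 - resid.var() / yv.var() if yv.var() > 0 else np.nan
        method = "complete-case OLS"
    elif missing == "fiml":
        mu, cov, _ = _em_mvnorm(M)
        Sxx = cov[1:, 1:]
        Sxy = cov[1:, 0]
        bx = np.linalg.solve(Sxx, Sxy)
        b0 = mu[0] - mu[1:] @ bx
        b = np.concatenate([[b0], bx])
        n = len(M)
        sd_x = np.sqrt(np.diag(Sxx))
        sd_y = np.sqrt(cov[0, 0])
        r2 = float(Sxy @ bx / cov[0, 0]) if cov[0, 0] > 0 else np.nan
        rng = np.random.default_rng(seed)
        bs = np.empty((n_boot_se, len(b)))
        for k in range(n_boot_se):
            idx = rng.integers(0, n, n)
            mu_b, cov_b, _ = _em_mvnorm(M[idx], tol=1e-6, max_iter=200)
            bxb = np.linalg.solve(cov_b[1:, 1:], cov_b[1:, 0])
            bs[k] = np.concatenate([[mu_b[0] - mu_b[1:] @ bxb], bxb])
        se = bs.std(axis=0, ddof=1)
        method = "normal-model ML (EM) with bootstrap SEs"
    else:
        raise ValueError(f"unknown missing-data method {missing!r}")

    zstat = np.divide(b, se, out=np.full_like(b, np.nan), where=se > 0)
    pvals = 2 * stats.norm.sf(np.abs(zstat))
    beta = np.concatenate([[np.nan], b[1:] * sd_x / sd_y]) if standardize \
        else np.full_like(b, np.nan)
    table = pd.DataFrame(
        {"b": b, "beta": beta, "se": se, "z": zstat, "p": pvals},
        index=["const"] + names)
    return RegressionResult(table=table, n=int(n), missing_method=method,
                            r_squared=float(r2))


def _paths(yv, mv, xv, C):
    """a, b, c', c for one dataset (columns already aligned)."""
    n = len(yv)
    Xa = np.column_stack([np.ones(n), xv, C])
    a = np.linalg.lstsq(Xa, mv, rcond=None)[0][1]
    Xb = np.column_stack([np.ones(n), mv, xv, C])
    coefs = np.linalg.lstsq(Xb, yv, rcond=None)[0]
    bpath, cprime = coefs[1], coefs[2]
    c = np.linalg.lstsq(Xa, yv, rcond=None)[0][1]
    return a, bpath, cprime, c


def estimate_indirect(
    x: pd.Series,
    m: pd.Series,
    y: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
    n_boot: int = 10_000,
    level: float = 95.0,
    seed: int = 0,
) -> MediationResult:
    """Indirect effect of x on y through m with percentile bootstrap CI.

    The indirect effect is a * b (a: m ~ x [+cov]; b: coefficient of m in
    y ~ m + x [+cov]); on complete data c = c' + a*b exactly.  The
    standardized version repeats the computation on z-scored x, m, y.
    Rank-deficient bootstrap resamples are redrawn (count reported).
    """
    frames = [x.rename("__x__"), m.rename("__m__"), y.rename("__y__")]
    if covariates is not None and covariates.shape[1] > 0:
        frames.append(covariates)
    data = pd.concat(frames, axis=1).dropna()
    n = len(data)
    if n < 50:
        raise ValueError(f"mediation needs n >= 50 complete cases, got {n}")
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    arr = data.to_numpy(dtype=float)
    xv, mv, yv = arr[:, 0], arr[:, 1], arr[:, 2]
    C = arr[:, 3:]
    zs = lambda u: (u - u.mean()) / u.std(ddof=0)
    a, b, cp, c = _paths(yv, mv, xv, C)
    a_s, b_s, cp_s, c_s = _paths(zs(yv), zs(mv), zs(xv), C)

    rng = np.random.default_rng(seed)
    n_redrawn = 0
    if C.shape[1] == 0:
        # no covariates: the two path regressions reduce to closed forms in
        # the resample moments, so the bootstrap vectorises (chunked to cap
        # memory)
        def chunk_ab(idx, xa, ma, ya):
            X, M, Y = xa[idx], ma[idx], ya[idx]
            Xc = X - X.mean(axis=1, keepdims=True)
            Mc = M - M.mean(axis=1, keepdims=True)
            Yc = Y - Y.mean(axis=1, keepdims=True)
            Sxx = np.einsum("ij,ij->i", Xc, Xc)
            Sxm = np.einsum("ij,ij->i", Xc, Mc)
            Smm = np.einsum("ij,ij->i", Mc, Mc)
            Smy = np.einsum("ij,ij->i", Mc, Yc)
            Sxy = np.einsum("ij,ij->i", Xc, Yc)
            aa = Sxm / Sxx
            det = Smm * Sxx - Sxm ** 2
            bb = (Smy * Sxx - Sxy * Sxm) / det
            return aa * bb
        ab = np.empty(n_boot)
        ab_s = np.empty(n_boot)
        xs, ms, ys = zs(xv), zs(mv), zs(yv)
        chunk = max(1, int(2e7 // n))
        done = 0
        while done < n_boot:
            B = min(chunk, n_boot - done)
            idx = rng.integers(0, n, (B, n))
            ab[done:done + B] = chunk_ab(idx, xv, mv, yv)
            ab_s[done:done + B] = chunk_ab(idx, xs, ms, ys)
            done += B
    else:
        ab = np.empty(n_boot)
        ab_s = np.empty(n_boot)
        k = 0
        p_full = 3 + C.shape[1]
        while k < n_boot:
            idx = rng.integers(0, n, n)
            Xb = np.column_stack([np.ones(n), mv[idx], xv[idx], C[idx]])
            if np.linalg.matrix_rank(Xb) < p_full:
                n_redrawn += 1
                continue
            aa, bb, _, _ = _paths(yv[idx], mv[idx], xv[idx], C[idx])
            ab[k] = aa * bb
            aas, bbs, _, _ = _paths(zs(yv)[idx], zs(mv)[idx], zs(xv)[idx], C[idx])
            ab_s[k] = aas * bbs
            k += 1
    alpha = (100.0 - level) / 2.0
    lo, hi = np.percentile(ab, [alpha, 100 - alpha])
    lo_s, hi_s = np.percentile(ab_s, [alpha, 100 - alpha])
    return MediationResult(
        a_path=float(a), b_path=float(b), direct=float(cp), total=float(c),
        indirect=float(a * b), indirect_std=float(a_s * b_s),
        ci_low=float(lo), ci_high=float(hi),
        ci_low_std=float(lo_s), ci_high_std=float(hi_s),
        level=level, n_boot=n_boot, seed=seed, n=n, n_redrawn=n_redrawn,
    )


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r with two-sided p from the t transform; complete pairs only."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
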