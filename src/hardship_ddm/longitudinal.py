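"""Material-hardship scoring and the fixed-loading latent growth curve.

Hardship is measured as eight yes/no economic-deprivation items (food,
housing, utilities, healthcare, finances) at child ages 1, 3, 5 and 9.
Each wave is scored as an item sum (0-8) and cumulative hardship as the
sum over waves (0-32).

The latent growth curve model (LGCM) treats the four wave sums y_w as

    y_w = i + lambda_w * s + e_w,     lambda = (0, 2, 4, 6),

with (i, s) bivariate normal and homoscedastic residuals.  Estimation is
maximum likelihood under multivariate normality; missing waves enter
through the full-information (casewise) likelihood.  On complete data the
model is exactly a random-intercept-random-slope mixed model, which tests
exploit as an independent oracle.  Per-subject (i, s) factor scores are
empirical-Bayes (regression-method) posterior means, so their variance is
shrunk below the estimated latent variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

WAVE_AGES = (1, 3, 5, 9)
LOADINGS = (0.0, 2.0, 4.0, 6.0)
N_ITEMS = 8
MIN_ITEMS_OBSERVED = 6  # rescale wave sum if >= 6 of 8 items observed, else wave missing

__all__ = [
    "HardshipScores",
    "GrowthFit",
    "GrowthScores",
    "score_hardship",
    "fit_lgcm",
    "factor_scores",
]


@dataclass
class HardshipScores:
    """Per-subject wave sums (0-8) and cumulative sum over observed waves."""

    wave_sums: pd.DataFrame     # index subject_id, columns wave ages, NaN = missing wave
    cumulative: pd.Series       # sum over observed waves

    @property
    def n_subjects(self) -> int:
        return len(self.wave_sums)


@dataclass
class GrowthFit:
    loadings: tuple
    mean_i: float
    mean_s: float
    var_i: float
    var_s: float
    cov_is: float
    resid_var: float
    loglik: float
    n: int
    se_mean_i: float = np.nan
    se_mean_s: float = np.nan
    heywood: bool = False
    converged: bool = True

    @property
    def latent_cov(self) -> np.ndarray:
        return np.array([[self.var_i, self.cov_is], [self.cov_is, self.var_s]])


@dataclass
class GrowthScores:
    scores: pd.DataFrame  # index subject_id, columns ['i', 's']
    dropped: list = field(default_factory=list)  # subjects with zero observed waves


def score_hardship(items: pd.DataFrame) -> HardshipScores:
    """Score a long-format item table (subject_id, wave_age, item1..item8).

    Item values must be 0, 1 or missing.  A wave with at least 6 observed
    items is rescaled to the 8-item metric (sum * 8 / n_observed); with
    fewer the wave is set missing.  Cumulative hardship sums observed
    waves.
    """
    item_cols = [f"item{i}" for i in range(1, N_ITEMS + 1)]
    missing = [c for c in ["subject_id", "wave_age", *item_cols] if c not in items.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    vals = items[item_cols].to_numpy(dtype=float)
    ok = np.isnan(vals) | (vals == 0) | (vals == 1)
    if not ok.all():
        bad = np.argwhere(~ok)[0]
        raise ValueError(
            f"item values must be 0, 1 or missing; offending row {items.index[bad[0]]}, "
            f"column {item_cols[bad[1]]}")
    n_obs = (~np.isnan(vals)).sum(axis=1)
    sums = np.nansum(vals, axis=1)
    wave_sum = np.where(n_obs >= MIN_ITEMS_OBSERVED, sums * N_ITEMS / np.maximum(n_obs, 1), np.nan)

    tmp = pd.DataFrame({
        "subject_id": items["subject_id"].to_numpy(),
        "wave_age": items["wave_age"].to_numpy(),
        "wave_sum": wave_sum,
    })
    wide = tmp.pivot_table(index="subject_id", columns="wave_age", values="wave_sum",
                           dropna=False)
    wide = wide.reindex(columns=list(WAVE_AGES))
    cumulative = wide.sum(axis=1, skipna=True)
    return HardshipScores(wave_sums=wide, cumulative=cumulative)


def _unpack(theta: np.ndarray) -> tuple:
    mu = theta[:2]
    sd_i, sd_s, sd_e = np.exp(theta[2]), np.exp(theta[3]), np.exp(theta[5])
    rho = np.tanh(theta[4])
    psi = np.array([[sd_i ** 2, rho * sd_i * sd_s], [rho * sd_i * sd_s, sd_s ** 2]])
    return mu, psi, sd_e ** 2


def _pattern_groups(Y: np.ndarray):
    obs = ~np.isnan(Y)
    keys = obs @ (1 << np.arange(Y.shape[1]))
    for key in np.unique(keys):
        idx = np.where(keys == key)[0]
        mask = obs[idx[0]]
        if mask.sum() == 0:
            continue
        yield idx, mask


def _lgcm_loglik(theta: np.ndarray, Y: np.ndarray, lam: np.ndarray) -> float:
    mu, psi, ve = _unpack(theta)
    total = 0.0
    for idx, mask in _pattern_groups(Y):
        L = np.column_stack([np.ones(mask.sum()), lam[mask]])
        sigma = L @ psi @ L.T + ve * np.eye(mask.sum())
        mean = L @ mu
        yo = Y[np.ix_(idx, np.where(mask)[0])]
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return -np.inf
        dev = yo - mean
        sol = np.linalg.solve(chol, dev.T)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        k = mask.sum()
        total += -0.5 * (len(idx) * (k * np.log(2 * np.pi) + logdet) + (sol ** 2).sum())
    return total


def fit_lgcm(
    wave_sums: pd.DataFrame,
    loadings: Sequence[float] = LOADINGS,
    min_waves: int = 2,
) -> GrowthFit:
    """ML fit of the fixed-loading growth model with FIML missing handling.

    ``wave_sums`` is wide (one column per wave age, NaN for missing waves);
    subjects with fewer than ``min_waves`` observed waves are dropped from
    estimation.  Near-zero variance estimates are flagged as boundary
    (Heywood-style) solutions rather than errors.
    """
    lam = np.asarray(loadings, dtype=float)
    Y = wave_sums.to_numpy(dtype=float)
    n_obs = (~np.isnan(Y)).sum(axis=1)
    Y = Y[n_obs >= min_waves]
    if len(Y) < 10:
        raise ValueError(f"need at least 10 subjects with >= {min_waves} waves")

    # moment-based start: per-wave means regressed on loadings
    wmean = np.nanmean(Y, axis=0)
    X = np.column_stack([np.ones(len(lam)), lam])
    beta = np.linalg.lstsq(X, wmean, rcond=None)[0]
    resid = np.nanvar(Y - (beta[0] + beta[1] * lam), axis=0).mean()
    theta0 = np.array([beta[0], beta[1],
                       0.5 * np.log(max(resid, 1e-3)),
                       np.log(max(abs(beta[1]) * 0.5, 1e-2)),
                       0.0,
                       0.5 * np.log(max(resid * 0.5, 1e-3))])

    def nll(th):
        ll = _lgcm_loglik(th, Y, lam)
        return -ll if np.isfinite(ll) else 1e12

    best = None
    for shift in (0.0, -1.0, 1.0):
        th = theta0.copy()
        th[2:4] += shift
        res = minimize(nll, th, method="L-BFGS-B",
                       bounds=[(-50, 50), (-50, 50), (-8, 8), (-8, 8), (-5, 5), (-8, 8)],
                       options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
    res = best
    mu, psi, ve = _unpack(res.x)
    loglik = -res.fun

    # numeric observed information for the latent-mean SEs
    se_i = se_s = np.nan
    try:
        h = 1e-4
        H = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                tpp = res.x.copy(); tpp[i] += h; tpp[j] += h
                tpm = res.x.copy(); tpm[i] += h; tpm[j] -= h
                tmp_ = res.x.copy(); tmp_[i] -= h; tmp_[j] += h
                tmm = res.x.copy(); tmm[i] -= h; tmm[j] -= h
                H[i, j] = (nll(tpp) - nll(tpm) - nll(tmp_) + nll(tmm)) / (4 * h * h)
        cov = np.linalg.inv(H)
        se_i, se_s = np.sqrt(np.maximum(np.diag(cov), 0))
    except np.linalg.LinAlgError:
        pass

    heywood = bool(psi[0, 0] < 1e-5 or psi[1, 1] < 1e-7 or ve < 1e-5)
    return GrowthFit(
        loadings=tuple(lam), mean_i=float(mu[0]), mean_s=float(mu[1]),
        var_i=float(psi[0, 0]), var_s=float(psi[1, 1]), cov_is=float(psi[0, 1]),
        resid_var=float(ve), loglik=float(loglik), n=len(Y),
        se_mean_i=float(se_i), se_mean_s=float(se_s),
        heywood=heywood, converged=bool(res.success),
    )


def factor_scores(fit: GrowthFit, wave_sums: pd.DataFrame) -> GrowthScores:
    """Empirical-Bayes (regression-method) per-subject (i, s) scores.

    Subjects with partial waves are scored from their observed waves;
    subjects with none are dropped with notice.
    """
    lam = np.asarray(fit.loadings, dtype=float)
    psi = fit.latent_cov
    mu = np.array([fit.mean_i, fit.mean_s])
    Y = wave_sums.to_numpy(dtype=float)
    out = np.full((len(Y), 2), np.nan)
    dropped = []
    for idx, mask in _pattern_groups(Y):
        L = np.column_stack([np.ones(mask.sum()), lam[mask]])
        sigma = L @ psi @ L.T + fit.resid_var * np.eye(mask.sum())
        gain = psi @ L.T @ np.linalg.inv(sigma)
        dev = Y[np.ix_(idx, np.where(mask)[0])] - L @ mu
        out[idx] = mu + dev @ gain.T
    for i in range(len(Y)):
        if np.isnan(out[i]).any():
            dropped.append(wave_sums.index[i])
    scores = pd.DataFrame(out, index=wave_sums.index, columns=["i", "s"]).dropna()
    return GrowthScores(scores=scores, dropped=dropped)
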