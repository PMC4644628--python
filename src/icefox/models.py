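"""Inferential models for hotspot joining and length of stay.

Two model contracts:

* a mixed logistic regression of whether an animal joined a hotspot on a
  single distance predictor, with crossed random intercepts for animal and
  hotspot, fit by maximum likelihood with a Laplace approximation to the
  marginal likelihood (the standard GLMM approach);
* a linear mixed model of (optionally log-transformed) days at a hotspot on
  a single predictor with a hotspot random intercept, fit by ML through
  statsmodels' MixedLM.

Each fit is compared against its null (same random structure, no fixed
predictor) with a likelihood-ratio test on 1 degree of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from scipy.special import expit

import statsmodels.api as sm


@dataclass
class ModelFit:
    model: str
    predictor: str
    coef: float
    se: float
    loglik: float
    n: int
    n_params: int
    chi2: float | None = None
    df: int | None = None
    pvalue: float | None = None
    converged: bool = True


def lrt(fit: ModelFit, null_fit: ModelFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of a fit against a nested null.

    chi2 = 2*(loglik_full - loglik_null); df = parameter difference.
    """
    if fit.n != null_fit.n:
        raise ValueError("models were not fitted to the same data")
    df = fit.n_params - null_fit.n_params
    if df < 1:
        raise ValueError("models are not nested (no extra parameters)")
    chi2 = max(0.0, 2.0 * (fit.loglik - null_fit.loglik))
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return chi2, df, p


# ------------------------------------------------- Laplace mixed logistic

_LOG_SIG_MIN, _LOG_SIG_MAX = -8.0, 3.0


def _glmm_laplace_loglik(theta, y, X, fox_idx, hot_idx, n_f, n_h,
                         return_mode: bool = False):
    """Laplace-approximated marginal log-likelihood of the crossed
    random-intercept logistic model at theta = (beta..., log sd_fox,
    log sd_hotspot). With ``return_mode`` also returns the random-effect
    mode and the conditional weights at the mode."""
    p_fix = X.shape[1]
    beta = theta[:p_fix]
    ls = np.clip(theta[p_fix:], _LOG_SIG_MIN, _LOG_SIG_MAX)
    d = np.concatenate([
        np.full(n_f, np.exp(2.0 * ls[0])),
        np.full(n_h, np.exp(2.0 * ls[1])),
    ])
    q = n_f + n_h
    xb = X @ beta
    b = np.zeros(q)
    hid = n_f + hot_idx

    def joint(bv):
        e = xb + bv[fox_idx] + bv[hid]
        return np.sum(y * e - np.logaddexp(0.0, e)) - 0.5 * np.sum(bv**2 / d)

    # damped Newton for the joint mode of the random effects; the joint
    # objective is strictly concave, so backtracking guarantees ascent
    fb = joint(b)
    H = np.empty((q, q))
    for _ in range(100):
        eta = xb + b[fox_idx] + b[hid]
        p = expit(eta)
        w = p * (1.0 - p)
        resid = y - p
        g = np.zeros(q)
        np.add.at(g, fox_idx, resid)
        np.add.at(g, hid, resid)
        g -= b / d
        H[:] = 0.0
        np.add.at(H, (fox_idx, fox_idx), w)
        np.add.at(H, (hid, hid), w)
        np.add.at(H, (fox_idx, hid), w)
        np.add.at(H, (hid, fox_idx), w)
        H[np.diag_indices(q)] += 1.0 / d
        try:
            step = linalg.solve(H, g, assume_a="pos")
        except linalg.LinAlgError:
            return -np.inf
        scale = 1.0
        for _ in range(40):
            b_new = b + scale * step
            f_new = joint(b_new)
            if f_new >= fb:
                break
            scale *= 0.5
        if f_new < fb:
            break
        moved = np.max(np.abs(scale * step))
        b, fb = b_new, f_new
        if moved < 1e-9:
            break
    # curvature at the converged mode
    eta = xb + b[fox_idx] + b[hid]
    p = expit(eta)
    w = p * (1.0 - p)
    H[:] = 0.0
    np.add.at(H, (fox_idx, fox_idx), w)
    np.add.at(H, (hid, hid), w)
    np.add.at(H, (fox_idx, hid), w)
    np.add.at(H, (hid, fox_idx), w)
    H[np.diag_indices(q)] += 1.0 / d
    bern = np.sum(y * eta - np.logaddexp(0.0, eta))
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        return -np.inf
    ll = float(bern - 0.5 * np.sum(b**2 / d) - 0.5 * np.sum(np.log(d)) - 0.5 * logdet)
    if return_mode:
        return ll, b, w, H
    return ll


def _glmm_se(theta, y, X, fox_idx, hot_idx, n_f, n_h, index):
    """SE of one fixed effect from the inverse of the numeric Hessian of the
    Laplace negative log-likelihood over all parameters (fixed effects and
    log-SDs) — the convention glmer reports. Falls back to the conditional
    Schur-complement SE when the full Hessian is not positive definite
    (e.g. a variance estimated at the zero boundary)."""
    k = len(theta)
    h = 1e-3 * (1.0 + np.abs(theta))

    def nll(t):
        return -_glmm_laplace_loglik(t, y, X, fox_idx, hot_idx, n_f, n_h)

    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                nll(theta + ei + ej) - nll(theta + ei - ej)
                - nll(theta - ei + ej) + nll(theta - ei - ej)
            ) / (4.0 * h[i] * h[j])
    if np.all(np.isfinite(H)) and np.all(np.linalg.eigvalsh(H) > 0):
        v = linalg.inv(H)[index, index]
        if v > 0:
            return float(np.sqrt(v))
    cov = _glmm_beta_cov(theta, y, X, fox_idx, hot_idx, n_f, n_h)
    if cov is not None and cov[index, index] > 0:
        return float(np.sqrt(cov[index, index]))
    return float("nan")


def _glmm_beta_cov(theta, y, X, fox_idx, hot_idx, n_f, n_h):
    """Fixed-effect covariance conditional on the variance parameters: the
    (beta, beta) block of the inverse joint Hessian over (random effects,
    beta) at the mode."""
    out = _glmm_laplace_loglik(theta, y, X, fox_idx, hot_idx, n_f, n_h,
                               return_mode=True)
    if not isinstance(out, tuple):
        return None
    _, b, w, H = out
    hid = n_f + hot_idx
    p_fix = X.shape[1]
    q = n_f + n_h
    XtWX = X.T @ (w[:, None] * X)
    XtWZ = np.zeros((p_fix, q))
    for j in range(p_fix):
        np.add.at(XtWZ[j], fox_idx, w * X[:, j])
        np.add.at(XtWZ[j], hid, w * X[:, j])
    try:
        schur = XtWX - XtWZ @ linalg.solve(H, XtWZ.T, assume_a="pos")
        return linalg.inv(schur)
    except linalg.LinAlgError:
        return None


def _fit_glmm(y, X, fox_idx, hot_idx, n_f, n_h):
    """Maximize the Laplace marginal likelihood. Returns (theta, loglik,
    success)."""
    p_fix = X.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            beta0 = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=50).params
            beta0 = np.clip(beta0, -5.0, 5.0)
        except Exception:
            beta0 = np.zeros(p_fix)
    x0 = np.concatenate([beta0, [np.log(0.5), np.log(0.5)]])

    def nll(theta):
        return -_glmm_laplace_loglik(theta, y, X, fox_idx, hot_idx, n_f, n_h)

    res = optimize.minimize(
        nll, x0, method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8},
    )
    # one restart from the solution guards against simplex collapse
    res = optimize.minimize(
        nll, res.x, method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-7, "fatol": 1e-9},
    )
    return res.x, -res.fun, bool(res.success) and np.isfinite(res.fun)


JOINING_PREDICTORS = ("distance_to_hotspot", "coast_distance")


def fit_joining_model(records: pd.DataFrame, predictor: str) -> ModelFit:
    """Mixed logistic regression of ``joined`` on one distance predictor with
    crossed random intercepts for animal and hotspot, plus an LRT against the
    null model without the predictor (df = 1).

    ``records`` needs columns animal_id, hotspot_id, joined and the
    predictor.
    """
    if predictor not in JOINING_PREDICTORS:
        raise ValueError(f"predictor must be one of {JOINING_PREDICTORS}")
    y = records["joined"].to_numpy(dtype=float)
    if records["animal_id"].nunique() < 2 or records["hotspot_id"].nunique() < 2:
        raise ValueError("need at least 2 animals and 2 hotspots")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    fox_codes, _ = pd.factorize(records["animal_id"])
    hot_codes, _ = pd.factorize(records["hotspot_id"])
    n_f = int(fox_codes.max()) + 1
    n_h = int(hot_codes.max()) + 1
    xvals = records[predictor].to_numpy(dtype=float)
    X_full = np.column_stack([np.ones_like(xvals), xvals])
    X_null = X_full[:, :1]

    th_f, ll_f, ok_f = _fit_glmm(y, X_full, fox_codes, hot_codes, n_f, n_h)
    th_n, ll_n, ok_n = _fit_glmm(y, X_null, fox_codes, hot_codes, n_f, n_h)

    se = _glmm_se(th_f, y, X_full, fox_codes, hot_codes, n_f, n_h, index=1)
    full = ModelFit("logistic_mixed", predictor, float(th_f[1]), se,
                    ll_f, len(records), 4, converged=ok_f and np.isfinite(se))
    null = ModelFit("logistic_mixed", "1", float(th_n[0]), float("nan"),
                    ll_n, len(records), 3, converged=ok_n)
    full.chi2, full.df, full.pvalue = lrt(full, null)
    return full


# ------------------------------------------------------ linear mixed model

STAY_PREDICTORS = ("arrival_day", "travel_distance")


def fit_stay_model(
    records: pd.DataFrame,
    predictor: str,
    log_response: bool | None = None,
) -> ModelFit:
    """Linear mixed model of days at a hotspot on one predictor with a
    hotspot random intercept, ML fit, LRT against the null (df = 1).

    The response is log-transformed for the travel-distance analysis only
    (the default when ``log_response`` is None).
    """
    if predictor not in STAY_PREDICTORS:
        raise ValueError(f"predictor must be one of {STAY_PREDICTORS}")
    if log_response is None:
        log_response = predictor == "travel_distance"
    counts = records.groupby("hotspot_id").size()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("need at least 2 hotspots with at least 2 records each")
    y = records["days_at_hotspot"].to_numpy(dtype=float)
    if log_response:
        if np.any(y <= 0):
            raise ValueError("days_at_hotspot must be positive to log-transform")
        y = np.log(y)
    xvals = records[predictor].to_numpy(dtype=float)
    groups = records["hotspot_id"].to_numpy()
    X_full = np.column_stack([np.ones_like(xvals), xvals])

    if np.ptp(y) == 0.0:  # degenerate constant response
        full = ModelFit("linear_mixed", predictor, 0.0, 0.0, float("inf"),
                        len(records), 4, chi2=0.0, df=1, pvalue=1.0,
                        converged=False)
        return full

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res_f = sm.MixedLM(y, X_full, groups=groups).fit(reml=False)
        res_n = sm.MixedLM(y, X_full[:, :1], groups=groups).fit(reml=False)

    full = ModelFit(
        "linear_mixed", predictor, float(res_f.params[1]), float(res_f.bse[1]),
        float(res_f.llf), len(records), 4, converged=bool(res_f.converged),
    )
    null = ModelFit(
        "linear_mixed", "1", float(res_n.params[0]), float(res_n.bse[0]),
        float(res_n.llf), len(records), 3, converged=bool(res_n.converged),
    )
    full.chi2, full.df, full.pvalue = lrt(full, null)
    return full


# --------------------------------------------- synthetic validation data

def simulate_joining_data(
    rng: np.random.Generator,
    n_foxes: int = 21,
    n_hotspots: int = 5,
    beta0: float = -1.0,
    beta1: float = 0.0,
    sigma_fox: float = 0.7,
    sigma_hotspot: float = 0.7,
    distance_range: tuple[float, float] = (1.0, 40.0),
) -> pd.DataFrame:
    """One joining record per fox-hotspot pair under a known logistic GLMM;
    used for type-I-error and sign-recovery checks of the joining model."""
    u = rng.normal(0.0, sigma_fox, n_foxes)
    v = rng.normal(0.0, sigma_hotspot, n_hotspots)
    rows = []
    for f in range(n_foxes):
        for h in range(n_hotspots):
            dist = rng.uniform(*distance_range)
            eta = beta0 + beta1 * dist + u[f] + v[h]
            rows.append(
                {
                    "animal_id": f"F{f:02d}",
                    "hotspot_id": f"H{h}",
                    "joined": int(rng.random() < expit(eta)),
                    "distance_to_hotspot": dist,
                    "coast_distance": dist,
                }
            )
    return pd.DataFrame(rows)


def simulate_stay_data(
    rng: np.random.Generator,
    n_hotspots: int = 5,
    foxes_per_hotspot: tuple[int, int] = (4, 12),
    intercept: float = 5.0,
    slope: float = 0.0,
    sigma_hotspot: float = 0.8,
    sigma_resid: float = 1.2,
    arrival_range: tuple[float, float] = (0.0, 14.0),
) -> pd.DataFrame:
    """Stay records under a known linear mixed model (continuous positive
    response), for sign-recovery and coverage checks of the stay model."""
    rows = []
    v = rng.normal(0.0, sigma_hotspot, n_hotspots)
    for h in range(n_hotspots):
        n = int(rng.integers(foxes_per_hotspot[0], foxes_per_hotspot[1] + 1))
        for f in range(n):
            arrival = rng.uniform(*arrival_range)
            days = intercept + slope * arrival + v[h] + rng.normal(0.0, sigma_resid)
            rows.append(
                {
                    "animal_id": f"F{h}{f:02d}",
                    "hotspot_id": f"H{h}",
                    "days_at_hotspot": max(days, 0.1),
                    "arrival_day": arrival,
                    "travel_distance": arrival,
                }
            )
    return pd.DataFrame(rows)
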