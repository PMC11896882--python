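"""Linear models for liana community structure.

Workflow: after scaling the explanatory variables, fit a Gaussian linear
model for each structure response (N_L, BA_L, QMD_L), select predictors by
stepwise AIC (both directions, starting from the full model), and check for
pseudo-replication from the nested sampling design with a random-intercept
model fitted by restricted maximum likelihood (REML), comparing restricted
log-likelihoods with and without the random term by a likelihood-ratio test.

The AIC convention is the Gaussian profile form

    AIC = n * log(RSS / n) + 2 * (p + 1)

with ``p`` mean parameters (intercept included) plus one variance parameter;
additive constants are dropped consistently so only differences matter.

The random-intercept model is y = X b + Z u + e with u ~ N(0, s2 * lam) per
group.  REML profiles out b and s2, leaving a 1-D optimisation over the
variance ratio lam >= 0; lam = 0 recovers the ordinary least-squares
restricted likelihood with the same constant, so the LR statistic
2 * (ll(lam_hat) - ll(0)) is nonnegative by construction.  The LR p-value
uses a plain chi-square with 1 df, which is conservative for a variance
component on the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ModelFit",
    "RandomEffectTest",
    "ols_fit",
    "gaussian_aic",
    "stepwise_select",
    "reml_random_intercept",
    "lr_test_random_effect",
]


@dataclass
class ModelFit:
    response: str
    predictors: list[str]
    coefficients: pd.DataFrame  # estimate, ci_lo, ci_hi per term (incl. intercept)
    r_squared: float
    f_statistic: float
    aic: float
    n: int

    def __post_init__(self) -> None:
        est = self.coefficients["estimate"]
        if not ((self.coefficients["ci_lo"] <= est).all()
                and (est <= self.coefficients["ci_hi"]).all()):
            raise ValueError("confidence bounds do not bracket estimates")


@dataclass
class RandomEffectTest:
    grouping: str
    loglik_with: float
    loglik_without: float
    lr: float
    p_value: float
    variance_ratio: float


def _design(X: pd.DataFrame, predictors: list[str], n: int) -> np.ndarray:
    cols = [np.ones(n)] + [X[c].to_numpy(dtype=float) for c in predictors]
    return np.column_stack(cols)


def ols_fit(y: pd.Series | np.ndarray, X: pd.DataFrame,
            predictors: list[str] | None = None,
            response: str = "y") -> ModelFit:
    """Least squares with an intercept, normal-theory 95% CIs, R^2, F, AIC."""
    if predictors is None:
        predictors = list(X.columns)
    yv = np.asarray(y, dtype=float)
    n = yv.size
    p = len(predictors) + 1
    if n <= p:
        raise ValueError(f"n={n} too small for {p} mean parameters")
    M = _design(X, predictors, n)
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    beta, _, _, _ = np.linalg.lstsq(M, yv, rcond=None)
    resid = yv - M @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((yv - yv.mean()) ** 2))
    sigma2 = rss / (n - p)
    cov = sigma2 * np.linalg.inv(M.T @ M)
    se = np.sqrt(np.diag(cov))
    tcrit = stats.t.ppf(0.975, n - p)
    coef = pd.DataFrame({
        "estimate": beta,
        "ci_lo": beta - tcrit * se,
        "ci_hi": beta + tcrit * se,
    }, index=["Intercept", *predictors])
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    if predictors and rss > 0:
        f = ((tss - rss) / len(predictors)) / sigma2
    else:
        f = float("nan")
    return ModelFit(
        response=response, predictors=list(predictors), coefficients=coef,
        r_squared=max(0.0, r2), f_statistic=f,
        aic=gaussian_aic(n, rss, p), n=n,
    )


def gaussian_aic(n: int, rss: float, p_mean: int) -> float:
    """Profile-Gaussian AIC; ``p_mean`` mean parameters, +1 for the variance."""
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * (p_mean + 1)


def stepwise_select(y: pd.Series | np.ndarray, X: pd.DataFrame,
                    response: str = "y") -> ModelFit:
    """Greedy bidirectional AIC search starting from the full model.

    At each step every single add and drop is scored; the move with the
    lowest AIC is taken if it improves on the current model.  Exact ties are
    broken toward fewer predictors (a drop beats an add, and the incumbent
    beats an equal-AIC add).
    """
    full = list(X.columns)
    current = list(full)
    best = ols_fit(y, X, current, response)
    while True:
        candidates: list[tuple[float, int, list[str]]] = []
        for c in current:
            sub = [v for v in current if v != c]
            fit_aic = ols_fit(y, X, sub, response).aic
            candidates.append((fit_aic, len(sub), sub))
        for c in full:
            if c not in current:
                sup = current + [c]
                candidates.append((ols_fit(y, X, sup, response).aic, len(sup), sup))
        if not candidates:
            break
        candidates.sort(key=lambda t: (t[0], t[1]))
        aic_new, _, chosen = candidates[0]
        # strict improvement required for a larger model; ties accepted only
        # when they shrink the model
        if aic_new < best.aic - 1e-12 or (aic_new <= best.aic + 1e-12 and len(chosen) < len(current)):
            current = chosen
            best = ols_fit(y, X, current, response)
        else:
            break
    return best


# ---------------------------------------------------------------------------
# REML random intercept
# ---------------------------------------------------------------------------


def _reml_loglik(lam: float, yv: np.ndarray, M: np.ndarray,
                 gidx: list[np.ndarray]) -> float:
    """Restricted log-likelihood profiled over beta and sigma2, at ratio lam.

    Uses the Woodbury identity per group: V_g^-1 = I - lam/(1+lam*n_g) * J.
    """
    n, p = M.shape
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    ytVy = 0.0
    logdetV = 0.0
    for idx in gidx:
        Xg = M[idx]
        yg = yv[idx]
        ng = idx.size
        shrink = lam / (1.0 + lam * ng)
        sx = Xg.sum(axis=0)
        sy = yg.sum()
        XtVX += Xg.T @ Xg - shrink * np.outer(sx, sx)
        XtVy += Xg.T @ yg - shrink * sx * sy
        ytVy += yg @ yg - shrink * sy * sy
        logdetV += np.log1p(lam * ng)
    sign, logdetXVX = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtVX, XtVy)
    rss = ytVy - XtVy @ beta  # r' V^-1 r
    if rss <= 0:
        return -np.inf
    sigma2 = rss / (n - p)
    return -0.5 * (logdetV + logdetXVX + (n - p) * (np.log(2 * np.pi * sigma2) + 1.0))


@dataclass
class RandomInterceptFit:
    variance_ratio: float          # var(group) / var(residual)
    sigma2_resid: float
    sigma2_group: float
    loglik_restricted: float
    beta: np.ndarray
    converged: bool = True
    grouping: str = "group"


def reml_random_intercept(y: pd.Series | np.ndarray, X: pd.DataFrame,
                          groups: pd.Series | np.ndarray,
                          predictors: list[str] | None = None,
                          grouping: str = "group") -> RandomInterceptFit:
    """Profile-REML fit of a Gaussian random-intercept model."""
    if predictors is None:
        predictors = list(X.columns)
    yv = np.asarray(y, dtype=float)
    n = yv.size
    M = _design(X, predictors, n)
    codes = pd.Series(np.asarray(groups)).astype("category").cat.codes.to_numpy()
    if codes.max() < 1:
        raise ValueError("need at least 2 groups")
    gidx = [np.flatnonzero(codes == g) for g in range(codes.max() + 1)]

    def neg(u: float) -> float:
        return -_reml_loglik(np.exp(u), yv, M, gidx)

    # coarse log-scale grid then local refinement; lam = 0 always considered
    grid = np.concatenate([[-np.inf], np.linspace(-12, 8, 41)])
    vals = np.array([_reml_loglik(0.0 if not np.isfinite(u) else np.exp(u), yv, M, gidx)
                     for u in grid])
    k = int(np.nanargmax(vals))
    converged = True
    if k == 0:
        lam_hat, ll_hat = 0.0, vals[0]
    else:
        lo = grid[max(k - 1, 1)]
        hi = grid[min(k + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-8})
        converged = bool(res.success)
        if not converged:
            raise RuntimeError(f"REML optimisation did not converge: {res.message}")
        lam_hat, ll_hat = float(np.exp(res.x)), -float(res.fun)
        if _reml_loglik(0.0, yv, M, gidx) >= ll_hat:
            lam_hat, ll_hat = 0.0, _reml_loglik(0.0, yv, M, gidx)
    # recover beta and variances at lam_hat
    p = M.shape[1]
    XtVX = np.zeros((p, p)); XtVy = np.zeros(p); ytVy = 0.0
    for idx in gidx:
        Xg, yg, ng = M[idx], yv[idx], idx.size
        shrink = lam_hat / (1.0 + lam_hat * ng)
        sx, sy = Xg.sum(axis=0), yg.sum()
        XtVX += Xg.T @ Xg - shrink * np.outer(sx, sx)
        XtVy += Xg.T @ yg - shrink * sx * sy
        ytVy += yg @ yg - shrink * sy * sy
    beta = np.linalg.solve(XtVX, XtVy)
    sigma2 = float((ytVy - XtVy @ beta) / (n - p))
    return RandomInterceptFit(
        variance_ratio=lam_hat, sigma2_resid=sigma2,
        sigma2_group=lam_hat * sigma2, loglik_restricted=ll_hat,
        beta=beta, converged=converged, grouping=grouping,
    )


def lr_test_random_effect(y: pd.Series | np.ndarray, X: pd.DataFrame,
                          groups: pd.Series | np.ndarray,
                          predictors: list[str] | None = None,
                          grouping: str = "group") -> RandomEffectTest:
    """LR test of the random intercept: 2 * (ll_REML(with) - ll_REML(without))."""
    fit = reml_random_intercept(y, X, groups, predictors, grouping)
    if predictors is None:
        predictors = list(X.columns)
    yv = np.asarray(y, dtype=float)
    M = _design(X, predictors, yv.size)
    codes = pd.Series(np.asarray(groups)).astype("category").cat.codes.to_numpy()
    gidx = [np.flatnonzero(codes == g) for g in range(codes.max() + 1)]
    ll0 = _reml_loglik(0.0, yv, M, gidx)
    lr = max(0.0, 2.0 * (fit.loglik_restricted - ll0))
    return RandomEffectTest(
        grouping=grouping, loglik_with=fit.loglik_restricted,
        loglik_without=ll0, lr=lr, p_value=float(stats.chi2.sf(lr, df=1)),
        variance_ratio=fit.variance_ratio,
    )
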