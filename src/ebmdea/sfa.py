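"""Stage 2: stochastic frontier regression of input slacks on the environment.

Each input's Stage-1 slack S is modelled as

    S_i = z_i' beta + v_i + u_i,    v ~ N(0, sigma_v^2),  u ~ |N(0, sigma_u^2)|

i.e. a half-normal *cost-type* frontier: slack above the environmental
frontier is one-sided management inefficiency u, the symmetric part v is
statistical noise. Parameters are reported in the (sigma^2, gamma)
convention of Coelli's FRONTIER program, sigma^2 = sigma_u^2 + sigma_v^2 and
gamma = sigma_u^2 / sigma^2, so gamma near 1 means inefficiency dominates
noise in the composed error.

The observation-level log-likelihood is

    ln 2 - ln sigma + ln phi(eps/sigma) + ln Phi(eps*lambda/sigma),

with eps = S - Z beta and lambda = sqrt(gamma/(1-gamma)). The JLMS
conditional expectation E[u | eps] splits each residual into inefficiency
and noise; the classic three-stage harmonization then levels every
observation up to the worst observed environment and worst luck:

    X*_i = X_i + [max_j f_j - f_i] + [max_j v_j - v_i]  >=  X_i.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit

__all__ = [
    "SFAModel",
    "SlackDecomposition",
    "fit_slack_frontier",
    "jlms_decompose",
    "adjust_inputs",
    "lr_mixed_chisq_test",
    "MixedChisqResult",
]

_SQRT_2_PI = np.sqrt(2.0 / np.pi)


@dataclass
class SFAModel:
    beta: np.ndarray          # incl. intercept (first element)
    sigma_sq: float           # sigma_u^2 + sigma_v^2
    gamma: float              # sigma_u^2 / sigma^2, in [0, 1)
    loglik: float
    lr_stat: float            # 2*(loglik - loglik_OLS), one-sided
    converged: bool
    n_obs: int
    beta_se: np.ndarray | None = None
    gamma_boundary: bool = False

    @property
    def sigma_u_sq(self):
        return self.gamma * self.sigma_sq

    @property
    def sigma_v_sq(self):
        return (1.0 - self.gamma) * self.sigma_sq


@dataclass
class SlackDecomposition:
    f_hat: np.ndarray   # fitted environmental component Z beta
    u_hat: np.ndarray   # E[u | eps], management inefficiency, >= 0
    v_hat: np.ndarray   # residual - u_hat (noise)


def _design(Z):
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.ndim != 2:
        raise ValueError("Z must be 2-D")
    return np.column_stack([np.ones(Z.shape[0]), Z])


def _loglik(params, S, Zd):
    """Half-normal cost-frontier log-likelihood; params = (beta, ln s2, logit g)."""
    p = Zd.shape[1]
    beta = params[:p]
    sigma_sq = np.exp(params[p])
    gamma = np.clip(expit(params[p + 1]), 1e-12, 1 - 1e-12)
    sigma = np.sqrt(sigma_sq)
    lam = np.sqrt(gamma / (1.0 - gamma))
    eps = S - Zd @ beta
    z = eps / sigma
    ll = (np.log(2.0) - np.log(sigma) + stats.norm.logpdf(z)
          + stats.norm.logcdf(z * lam))
    return float(np.sum(ll))


def _ols(S, Zd):
    beta, *_ = np.linalg.lstsq(Zd, S, rcond=None)
    resid = S - Zd @ beta
    n = len(S)
    s2 = float(resid @ resid) / n
    ll = -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)
    return beta, resid, s2, ll


def fit_slack_frontier(S, Z, tol=1e-8) -> SFAModel:
    """Maximum-likelihood fit of the half-normal frontier to slacks S given Z.

    Starts from corrected OLS and multi-starts over gamma in {0.1, 0.5, 0.9}
    (fixed order, so the fit is deterministic). Raises on non-convergence of
    every start; flags gamma pinned at the boundary.
    """
    S = np.asarray(S, dtype=float).ravel()
    Zd = _design(Z)
    n, p = Zd.shape
    if len(S) != n:
        raise ValueError("S and Z have different numbers of observations")
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} observations, got {n}")
    if np.linalg.matrix_rank(Zd) < p:
        raise ValueError("Z is rank deficient after adding an intercept")

    beta_ols, resid, s2_ols, ll_ols = _ols(S, Zd)

    # COLS hint for sigma_u from the third central moment of OLS residuals;
    # the composed error v + u is positively skewed, m3 = su^3 sqrt(2/pi)(4/pi - 1)
    m3 = float(np.mean(resid ** 3))
    su2_cols = max((m3 / (_SQRT_2_PI * (4.0 / np.pi - 1.0))) ** (2.0 / 3.0), 1e-8) \
        if m3 > 0 else 1e-8

    best = None
    neg = lambda th: -_loglik(th, S, Zd)
    starts = []
    for g0 in (0.1, 0.5, 0.9):
        # match total residual variance: var(eps) = s2*(1 - 2g/pi)
        s2_0 = max(s2_ols / (1.0 - 2.0 * g0 / np.pi), 1e-10)
        su = np.sqrt(g0 * s2_0)
        b0 = beta_ols.copy()
        b0[0] -= su * _SQRT_2_PI       # OLS intercept absorbs E[u]
        starts.append(np.concatenate([b0, [np.log(s2_0), logit(g0)]]))
    g_cols = min(max(su2_cols / max(su2_cols + s2_ols - su2_cols * (1 - 2 / np.pi),
                                    1e-10), 1e-4), 1 - 1e-4)
    b0 = beta_ols.copy()
    b0[0] -= np.sqrt(su2_cols) * _SQRT_2_PI
    starts.append(np.concatenate(
        [b0, [np.log(max(su2_cols * 2 / np.pi + s2_ols, 1e-10)), logit(g_cols)]]))

    for x0 in starts:
        res = optimize.minimize(neg, x0, method="BFGS",
                                options={"gtol": tol, "maxiter": 2000})
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is not None and not best.success:
        polish = optimize.minimize(neg, best.x, method="Nelder-Mead",
                                   options={"xatol": 1e-10, "fatol": 1e-12,
                                            "maxiter": 5000})
        if np.isfinite(polish.fun) and polish.fun <= best.fun:
            polish.success = True
            best = polish

    # gamma = 0 boundary: the likelihood degenerates to OLS exactly, so OLS is
    # always an admissible candidate; take it when no interior start beats it
    if best is None or -best.fun < ll_ols:
        return SFAModel(
            beta=beta_ols, sigma_sq=s2_ols, gamma=0.0, loglik=ll_ols,
            lr_stat=0.0, converged=True, n_obs=n,
            beta_se=_ols_beta_se(Zd, s2_ols), gamma_boundary=True,
        )

    theta = best.x
    beta = theta[:p]
    sigma_sq = float(np.exp(theta[p]))
    gamma = float(expit(theta[p + 1]))
    loglik = -float(best.fun)
    lr = max(2.0 * (loglik - ll_ols), 0.0)

    # standard errors for beta from the numerical Hessian (delta method not
    # needed for beta, which enters untransformed)
    beta_se = None
    try:
        H = _num_hessian(neg, theta)
        cov = np.linalg.inv(H)
        d = np.diag(cov)[:p]
        if np.all(d > 0):
            beta_se = np.sqrt(d)
    except np.linalg.LinAlgError:
        pass

    return SFAModel(
        beta=beta, sigma_sq=sigma_sq, gamma=gamma, loglik=loglik,
        lr_stat=lr, converged=bool(best.success), n_obs=n, beta_se=beta_se,
        gamma_boundary=bool(gamma < 1e-4 or gamma > 1 - 1e-4),
    )


def _ols_beta_se(Zd, s2):
    try:
        cov = s2 * np.linalg.inv(Zd.T @ Zd)
        return np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        return None


def _num_hessian(f, x, h=1e-5):
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h * h)
    return H


def jlms_decompose(S, Z, model: SFAModel) -> SlackDecomposition:
    """JLMS conditional-expectation split of each residual into (u, v).

    u_hat_i = mu*_i + sigma* phi(mu*_i/sigma*) / Phi(mu*_i/sigma*), with
    mu*_i = eps_i sigma_u^2 / sigma^2 and sigma*^2 = sigma_u^2 sigma_v^2 / sigma^2.
    The inverse Mills ratio is evaluated in the log domain, so extreme
    negative ratios never divide by zero. f + u + v reconstructs S exactly.
    """
    S = np.asarray(S, dtype=float).ravel()
    Zd = _design(Z)
    f_hat = Zd @ model.beta
    eps = S - f_hat
    su2, sv2 = model.sigma_u_sq, model.sigma_v_sq
    if su2 <= 0:
        u_hat = np.zeros_like(eps)
    else:
        mu_star = eps * su2 / model.sigma_sq
        sigma_star = np.sqrt(su2 * sv2 / model.sigma_sq)
        if sigma_star <= 0:
            u_hat = np.maximum(eps, 0.0)    # noiseless limit: u = eps_+
        else:
            r = mu_star / sigma_star
            mills = np.exp(stats.norm.logpdf(r) - stats.norm.logcdf(r))
            u_hat = mu_star + sigma_star * mills
    u_hat = np.maximum(u_hat, 0.0)
    v_hat = eps - u_hat
    return SlackDecomposition(f_hat=f_hat, u_hat=u_hat, v_hat=v_hat)


def adjust_inputs(X, f_hat, v_hat):
    """Level inputs up to the least favorable environment and worst luck.

    X*_i = X_i + [max_j f_j - f_i] + [max_j v_j - v_i]; both brackets are
    nonnegative, so X* >= X, with equality only where both maxima are attained.
    """
    X = np.asarray(X, dtype=float).ravel()
    f_hat = np.asarray(f_hat, dtype=float).ravel()
    v_hat = np.asarray(v_hat, dtype=float).ravel()
    if not (len(X) == len(f_hat) == len(v_hat)):
        raise ValueError("X, f_hat and v_hat must have equal lengths")
    return X + (f_hat.max() - f_hat) + (v_hat.max() - v_hat)


# ---------------------------------------------------------------------------
# one-sided likelihood-ratio test at the gamma = 0 boundary
# ---------------------------------------------------------------------------

@dataclass
class MixedChisqResult:
    lr_stat: float
    df: int
    p_value: float
    critical_value: float
    level: float
    reject: bool


def _mixed_chisq_sf(x, df):
    """Survival function of the equal-weights chi-square mixture (Kodde-Palm)."""
    if x <= 0:
        return 1.0
    weights = np.array([
        math.comb(df, i) for i in range(df + 1)], dtype=float) / 2 ** df
    sf = 0.0   # chi2_0 mass at zero contributes nothing for x > 0
    for i in range(1, df + 1):
        sf += weights[i] * stats.chi2.sf(x, i)
    return float(sf)


def lr_mixed_chisq_test(lr_stat, df, level=0.05) -> MixedChisqResult:
    """One-sided LR test of gamma = 0 against the mixed chi-square null.

    Under the null the LR statistic follows an equal-weights mixture of
    chi-square distributions with 0..df degrees of freedom (the inefficiency
    variance sits on the boundary of the parameter space); for df = 1 the 5%
    critical value is 2.706 rather than the naive 3.841.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    lr_stat = max(float(lr_stat), 0.0)      # clip tiny negatives
    p = _mixed_chisq_sf(lr_stat, df)
    crit = optimize.brentq(lambda x: _mixed_chisq_sf(x, df) - level, 1e-12, 200.0)
    return MixedChisqResult(lr_stat=lr_stat, df=int(df), p_value=p,
                            critical_value=float(crit), level=level,
                            reject=bool(lr_stat > crit))
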