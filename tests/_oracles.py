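"""Independent brute-force oracles used to cross-check the library-backed
statistics: explicit-sum OLS, textbook Bartlett/ANOVA formulas, and direct
numerical maximization of count-model likelihoods.  Nothing here imports
from tactqg's statistical code paths."""

import numpy as np
from scipy import optimize, special


def ols_slope_se(x, y):
    """Simple-regression slope and SE from explicit sums."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    xc, yc = x - x.mean(), y - y.mean()
    b = np.sum(xc * yc) / np.sum(xc * xc)
    a = y.mean() - b * x.mean()
    resid = y - a - b * x
    s2 = np.sum(resid**2) / (n - 2)
    se = np.sqrt(s2 / np.sum(xc * xc))
    return b, se


def ols_normal_equations(X, y):
    """Coefficients and SEs via (X'X)^{-1} X'y and the classical covariance."""
    X, y = np.asarray(X, float), np.asarray(y, float)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    s2 = resid @ resid / dof
    se = np.sqrt(np.diag(s2 * XtX_inv))
    return beta, se


def bartlett_k2(groups):
    """Textbook Bartlett statistic over a list of 1-d arrays."""
    groups = [np.asarray(g, float) for g in groups]
    k = len(groups)
    ni = np.array([len(g) for g in groups])
    si2 = np.array([g.var(ddof=1) for g in groups])
    N = ni.sum()
    sp2 = np.sum((ni - 1) * si2) / (N - k)
    num = (N - k) * np.log(sp2) - np.sum((ni - 1) * np.log(si2))
    den = 1 + (np.sum(1.0 / (ni - 1)) - 1.0 / (N - k)) / (3 * (k - 1))
    return num / den


def anova_f(groups):
    """One-way ANOVA F from between/within mean squares."""
    groups = [np.asarray(g, float) for g in groups]
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    dfb, dfw = len(groups) - 1, len(allv) - len(groups)
    return (ssb / dfb) / (ssw / dfw), dfb, dfw


def poisson_loglik(beta, X, y):
    eta = X @ beta
    return np.sum(y * eta - np.exp(eta) - special.gammaln(y + 1))


def max_poisson_loglik(X, y, x0=None):
    """Direct numerical maximization of the Poisson log-likelihood."""
    X, y = np.asarray(X, float), np.asarray(y, float)
    x0 = np.zeros(X.shape[1]) if x0 is None else np.asarray(x0, float)
    res = optimize.minimize(lambda b: -poisson_loglik(b, X, y), x0, method="BFGS",
                            options={"gtol": 1e-12, "maxiter": 500})
    return res.x, -res.fun


def nb2_loglik(params, X, y):
    """NB2 log-likelihood; params = (beta..., alpha), var = mu + alpha mu^2."""
    beta, alpha = params[:-1], params[-1]
    mu = np.exp(X @ beta)
    size = 1.0 / alpha
    return np.sum(
        special.gammaln(y + size) - special.gammaln(size) - special.gammaln(y + 1)
        + size * np.log(size / (size + mu)) + y * np.log(mu / (size + mu))
    )


def max_nb2_loglik(X, y, x0):
    res = optimize.minimize(lambda p: -nb2_loglik(p, X, y), x0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 5000})
    return res.x, -res.fun
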