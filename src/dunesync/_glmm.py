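"""Lightweight mixed-model fitters used by the demography and window-scan modules.

Two estimators live here:

* :func:`fit_binomial_mixed` — binomial/Bernoulli GLMM with a logit link and
  one grouping factor carrying either a random intercept or a correlated
  random (intercept, slope) pair.  Estimation is maximum likelihood under a
  Laplace approximation: for candidate variance parameters, the joint
  penalized log-likelihood is maximized over fixed effects and random modes
  by Newton iterations, and the marginal likelihood is corrected with the
  log-determinant of the random-effect block of the Hessian.  Because the
  grouping factor partitions the rows, that block is block-diagonal with
  1x1 or 2x2 blocks, and every Newton step is solved through the Schur
  complement on the (small) fixed-effect block — each step costs O(n p d)
  rather than a dense solve in n.

* :func:`fit_gaussian_mixed` — Gaussian LMM with a single random intercept,
  fit by full maximum likelihood with the fixed effects and residual
  variance profiled out, leaving a one-dimensional search over the
  variance ratio.

Both return Wald standard errors conditional on the estimated variance
parameters, the standard approximation for mixed-model software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit

__all__ = ["MixedFit", "fit_binomial_mixed", "fit_gaussian_mixed"]

_LOG_SD_LO, _LOG_SD_HI = np.log(1e-4), np.log(8.0)


@dataclass
class MixedFit:
    """Result of a mixed-model fit."""

    beta: np.ndarray               # fixed-effect estimates
    beta_se: np.ndarray            # Wald SEs (conditional on variance params)
    ranef: np.ndarray              # (q,) or (q, 2) posterior modes / BLUPs
    vcomp: dict[str, float]        # variance parameters on the SD/corr scale
    loglik: float                  # marginal log-likelihood at the optimum
    n: int                         # number of observations (trials summed)
    k: int                         # parameter count incl. variance components
    converged: bool
    family: str = "binomial"
    resid_sd: float | None = None  # Gaussian only
    message: str = ""
    group_labels: np.ndarray | None = field(default=None, repr=False)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    @property
    def aicc(self) -> float:
        denom = self.n - self.k - 1
        if denom <= 0:
            return np.inf
        return self.aic + 2.0 * self.k * (self.k + 1) / denom


def _group_index(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels, idx = np.unique(groups, return_inverse=True)
    return labels, idx


class _BinomialLaplace:
    """Inner machinery for one dataset; reused across outer variance evals."""

    def __init__(self, X, succ, trials, gidx, q, u=None):
        self.X = X
        self.s = succ.astype(float)
        self.t = trials.astype(float)
        self.g = gidx
        self.q = q
        self.u = u                      # slope covariate or None
        self.d = 1 if u is None else 2
        self.n, self.p = X.shape
        self.beta = np.zeros(self.p)
        self.b = np.zeros((q, self.d))
        # crude intercept start
        pbar = np.clip(self.s.sum() / self.t.sum(), 1e-3, 1 - 1e-3)
        if np.allclose(X[:, 0], 1.0):
            self.beta[0] = np.log(pbar / (1 - pbar))

    def _sigma(self, theta):
        if self.d == 1:
            sd = np.exp(theta[0])
            return np.array([[sd * sd]])
        sd0, sd1 = np.exp(theta[0]), np.exp(theta[1])
        # clip keeps Sigma invertible when the fit is singular (|rho| -> 1)
        rho = np.tanh(np.clip(theta[2], -3.0, 3.0))
        return np.array([[sd0 * sd0, rho * sd0 * sd1],
                         [rho * sd0 * sd1, sd1 * sd1]])

    def _eta(self, beta, b):
        eta = self.X @ beta + b[self.g, 0]
        if self.d == 2:
            eta = eta + b[self.g, 1] * self.u
        return eta

    def _penalized_loglik(self, beta, b, prec):
        eta = self._eta(beta, b)
        ll = float(np.sum(self.s * eta - self.t * np.logaddexp(0.0, eta)))
        pen = 0.5 * float(np.einsum("gi,ij,gj->", b, prec, b))
        return ll - pen

    def inner(self, theta, max_iter=60, tol=1e-9):
        """Joint Newton over (beta, b) for fixed variance parameters."""
        sigma = self._sigma(theta)
        prec = np.linalg.inv(sigma)
        beta, b = self.beta.copy(), self.b.copy()
        f = self._penalized_loglik(beta, b, prec)
        ok = False
        for _ in range(max_iter):
            eta = self._eta(beta, b)
            mu = expit(eta)
            w = np.maximum(self.t * mu * (1.0 - mu), 1e-12)
            r = self.s - self.t * mu
            # gradient
            g_beta = self.X.T @ r
            g_b = np.zeros((self.q, self.d))
            np.add.at(g_b[:, 0], self.g, r)
            if self.d == 2:
                np.add.at(g_b[:, 1], self.g, r * self.u)
            g_b -= b @ prec
            # Hessian pieces via per-group reductions
            WX = self.X * w[:, None]
            A = self.X.T @ WX                                 # p x p
            B = np.zeros((self.p, self.q, self.d))
            D = np.zeros((self.q, self.d, self.d))
            for j in range(self.p):
                np.add.at(B[j, :, 0], self.g, WX[:, j])
            np.add.at(D[:, 0, 0], self.g, w)
            if self.d == 2:
                wu = w * self.u
                for j in range(self.p):
                    np.add.at(B[j, :, 1], self.g, self.X[:, j] * wu)
                np.add.at(D[:, 0, 1], self.g, wu)
                D[:, 1, 0] = D[:, 0, 1]
                np.add.at(D[:, 1, 1], self.g, wu * self.u)
            D += prec[None, :, :]
            Dinv = np.linalg.inv(D)
            # Schur complement on the fixed-effect block
            BDinv = np.einsum("pgd,gde->pge", B, Dinv)
            S = A - np.einsum("pge,qge->pq", BDinv, B)
            rhs = g_beta - np.einsum("pgd,gd->p", BDinv, g_b)
            try:
                d_beta = np.linalg.solve(S, rhs)
            except np.linalg.LinAlgError:
                return None
            d_b = np.einsum("gde,ge->gd", Dinv,
                            g_b - np.einsum("pgd,p->gd", B, d_beta))
            # step halving on the penalized objective
            step = 1.0
            for _ in range(30):
                nb = beta + step * d_beta
                nbb = b + step * d_b
                fn = self._penalized_loglik(nb, nbb, prec)
                if np.isfinite(fn) and fn >= f - 1e-12:
                    break
                step *= 0.5
            else:
                return None
            moved = fn - f
            beta, b, f = nb, nbb, fn
            if moved < tol and float(np.abs(g_beta).max(initial=0.0)) < 1e-6 * (
                    1.0 + abs(f)):
                ok = True
                break
            if moved < tol:
                ok = True
                break
        # Laplace correction at the mode
        eta = self._eta(beta, b)
        mu = expit(eta)
        w = np.maximum(self.t * mu * (1.0 - mu), 1e-12)
        D = np.zeros((self.q, self.d, self.d))
        np.add.at(D[:, 0, 0], self.g, w)
        if self.d == 2:
            wu = w * self.u
            np.add.at(D[:, 0, 1], self.g, wu)
            D[:, 1, 0] = D[:, 0, 1]
            np.add.at(D[:, 1, 1], self.g, wu * self.u)
        Hbb = D + prec[None, :, :]
        sign, ld_h = np.linalg.slogdet(Hbb)
        _, ld_s = np.linalg.slogdet(sigma)
        laplace = f - 0.5 * (self.q * ld_s + float(ld_h.sum()))
        self.beta, self.b = beta, b  # warm start for the next theta
        return laplace, beta, b, ok

    def beta_cov(self, theta, beta, b):
        """Fixed-effect covariance from the Schur complement at the optimum."""
        sigma = self._sigma(theta)
        prec = np.linalg.inv(sigma)
        eta = self._eta(beta, b)
        mu = expit(eta)
        w = np.maximum(self.t * mu * (1.0 - mu), 1e-12)
        WX = self.X * w[:, None]
        A = self.X.T @ WX
        B = np.zeros((self.p, self.q, self.d))
        D = np.zeros((self.q, self.d, self.d))
        for j in range(self.p):
            np.add.at(B[j, :, 0], self.g, WX[:, j])
        np.add.at(D[:, 0, 0], self.g, w)
        if self.d == 2:
            wu = w * self.u
            for j in range(self.p):
                np.add.at(B[j, :, 1], self.g, self.X[:, j] * wu)
            np.add.at(D[:, 0, 1], self.g, wu)
            D[:, 1, 0] = D[:, 0, 1]
            np.add.at(D[:, 1, 1], self.g, wu * self.u)
        D += prec[None, :, :]
        Dinv = np.linalg.inv(D)
        BDinv = np.einsum("pgd,gde->pge", B, Dinv)
        S = A - np.einsum("pge,qge->pq", BDinv, B)
        return np.linalg.inv(S)


def fit_binomial_mixed(X: np.ndarray, succ: np.ndarray, trials: np.ndarray,
                       groups: np.ndarray,
                       slope_covariate: np.ndarray | None = None) -> MixedFit:
    """Binomial-logit GLMM with one grouping factor (Laplace ML).

    ``succ``/``trials`` allow aggregated binomial rows; pass ``trials`` of
    ones for Bernoulli data.  With ``slope_covariate`` given, each group
    carries a correlated random (intercept, slope-on-covariate) pair;
    otherwise a random intercept only.  Raises ``ValueError`` on a constant
    response (complete separation: no finite MLE exists).
    """
    X = np.asarray(X, float)
    succ = np.asarray(succ, float)
    trials = np.asarray(trials, float)
    if succ.sum() == 0 or (trials - succ).sum() == 0:
        raise ValueError("constant response: complete separation, no finite MLE")
    labels, gidx = _group_index(np.asarray(groups))
    q = len(labels)
    u = None if slope_covariate is None else np.asarray(slope_covariate, float)
    eng = _BinomialLaplace(X, succ, trials, gidx, q, u)
    cache: dict[tuple, tuple] = {}

    def negloglik(theta):
        theta = np.atleast_1d(theta)
        key = tuple(np.round(theta, 10))
        if key not in cache:
            res = eng.inner(np.atleast_1d(theta))
            cache[key] = res
        res = cache[key]
        if res is None:
            return 1e10
        return -res[0]

    if eng.d == 1:
        opt = minimize_scalar(negloglik, bounds=(_LOG_SD_LO, _LOG_SD_HI),
                              method="bounded", options={"xatol": 1e-5})
        theta_hat = np.array([opt.x])
        outer_ok = opt.success
    else:
        start = np.array([np.log(0.3), np.log(0.3), 0.0])
        opt = minimize(negloglik, start, method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-7, "maxfev": 400})
        theta_hat = opt.x
        theta_hat[0] = np.clip(theta_hat[0], _LOG_SD_LO, _LOG_SD_HI)
        theta_hat[1] = np.clip(theta_hat[1], _LOG_SD_LO, _LOG_SD_HI)
        outer_ok = opt.success
    res = eng.inner(theta_hat)
    if res is None:
        raise RuntimeError("inner Newton failed at the selected variance point")
    loglik, beta, b, inner_ok = res
    cov = eng.beta_cov(theta_hat, beta, b)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    if eng.d == 1:
        vcomp = {"re_sd": float(np.exp(theta_hat[0]))}
        n_theta = 1
    else:
        vcomp = {"re_sd_intercept": float(np.exp(theta_hat[0])),
                 "re_sd_slope": float(np.exp(theta_hat[1])),
                 "re_corr": float(np.tanh(np.clip(theta_hat[2], -3.0, 3.0)))}
        n_theta = 3
    return MixedFit(
        beta=beta, beta_se=se, ranef=b if eng.d == 2 else b[:, 0],
        vcomp=vcomp, loglik=float(loglik), n=int(trials.sum()),
        k=X.shape[1] + n_theta, converged=bool(outer_ok and inner_ok),
        family="binomial", group_labels=labels)


def fit_gaussian_mixed(X: np.ndarray, y: np.ndarray,
                       groups: np.ndarray) -> MixedFit:
    """Gaussian LMM with a single random intercept, profiled full ML.

    The variance ratio ``lambda = var_group / var_resid`` is optimized on a
    log grid with Brent refinement; fixed effects and the residual variance
    have closed forms given the ratio.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    labels, gidx = _group_index(np.asarray(groups))
    q = len(labels)
    n, p = X.shape
    if n <= p + 2:
        raise ValueError("too few observations for the fixed-effect design")
    ng = np.bincount(gidx, minlength=q).astype(float)
    XtX = X.T @ X
    Xty = X.T @ y
    # per-group column sums of X and y
    GX = np.zeros((q, p))
    for j in range(p):
        np.add.at(GX[:, j], gidx, X[:, j])
    Gy = np.bincount(gidx, weights=y, minlength=q)

    def profile(lam):
        c = lam / (1.0 + lam * ng)                      # (q,)
        A = XtX - GX.T @ (GX * c[:, None])
        rhs = Xty - GX.T @ (c * Gy)
        try:
            beta = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            return None
        resid = y - X @ beta
        Gr = np.bincount(gidx, weights=resid, minlength=q)
        rss_v = float(resid @ resid - np.sum(c * Gr * Gr))
        if rss_v <= 0:
            return None
        sigma2 = rss_v / n
        ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) \
             - 0.5 * float(np.sum(np.log1p(lam * ng)))
        return ll, beta, sigma2, A, Gr

    def neg(loglam):
        res = profile(np.exp(loglam))
        return 1e10 if res is None else -res[0]

    opt = minimize_scalar(neg, bounds=(-14.0, 8.0), method="bounded",
                          options={"xatol": 1e-6})
    lam = float(np.exp(opt.x))
    best = profile(lam)
    ols = profile(0.0)
    if ols is not None and (best is None or ols[0] >= best[0]):
        lam, best = 0.0, ols
    if best is None:
        raise RuntimeError("Gaussian mixed-model profile failed")
    ll, beta, sigma2, A, Gr = best
    cov = np.linalg.inv(A) * sigma2
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    shrink = lam * ng / (1.0 + lam * ng)
    blup = np.where(ng > 0, shrink * Gr / np.maximum(ng, 1.0), 0.0)
    return MixedFit(
        beta=beta, beta_se=se, ranef=blup,
        vcomp={"re_sd": float(np.sqrt(lam * sigma2))},
        loglik=float(ll), n=n, k=p + 2, converged=bool(opt.success),
        family="gaussian", resid_sd=float(np.sqrt(sigma2)),
        group_labels=labels)
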