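"""Random-intercept linear mixed models with Satterthwaite F-tests.

Model: y_ij = x_ij' beta + b_i + e_ij, with b_i ~ N(0, sigma_b^2) per group
(participant) and e_ij ~ N(0, sigma_e^2), estimated by restricted maximum
likelihood.  Because each group's covariance is sigma_e^2 I + sigma_b^2 J,
everything reduces to per-group sums via the Sherman-Morrison identity

    (I + lam J)^{-1} = I - lam / (1 + n lam) J,      lam = sigma_b^2 / sigma_e^2,

so the REML criterion is profiled down to a 1-D search over log lam.

The F-test of a single fixed effect uses Satterthwaite's approximation for
the denominator degrees of freedom: with C(theta) = c' (X' V(theta)^{-1} X)^{-1} c
the variance of the contrast and A the asymptotic covariance of the variance
components (twice the inverse Hessian of the REML deviance, obtained by
central finite differences), df = 2 C^2 / (g' A g) where g is the gradient of
C in theta.  This is the same delta-method construction the standard R
implementation uses.

Cook's distances are computed on the whitened (GLS-transformed) fixed-effects
regression, so one number per observation measures its influence on beta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

from wardsense.errors import ValidationError

_LOG_LAM_BOUNDS = (-18.0, 12.0)
_SINGULAR_LAM = 1e-7


@dataclass
class SatterthwaiteTest:
    """F-test of one fixed effect with Satterthwaite denominator df."""

    coef: str
    estimate: float
    se: float
    F: float
    df_num: int
    df_den: float
    p_value: float


@dataclass
class RandomInterceptFit:
    """REML fit of a random-intercept model."""

    beta: np.ndarray
    beta_se: np.ndarray
    exog_names: list[str]
    sigma2_b: float
    sigma2_e: float
    deviance: float  # -2 * restricted log-likelihood
    n_obs: int
    n_groups: int
    singular: bool
    # internals needed for tests and diagnostics
    _y: np.ndarray = field(repr=False, default=None)
    _X: np.ndarray = field(repr=False, default=None)
    _codes: np.ndarray = field(repr=False, default=None)

    @property
    def lam(self) -> float:
        return self.sigma2_b / self.sigma2_e if self.sigma2_e > 0 else 0.0

    def params(self) -> dict[str, float]:
        return dict(zip(self.exog_names, self.beta))


class _Sums:
    """Per-group sufficient statistics for the collapsed REML algebra."""

    def __init__(self, y: np.ndarray, X: np.ndarray, codes: np.ndarray):
        self.n, self.p = X.shape
        G = codes.max() + 1
        self.G = G
        self.ng = np.bincount(codes, minlength=G).astype(float)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.sx = np.zeros((G, self.p))  # X_g' 1
        np.add.at(self.sx, codes, X)
        self.sy = np.bincount(codes, weights=y, minlength=G)  # 1' y_g

    def gls(self, lam: float):
        """Return (XtVX, XtVy, yVy, logdet_Vbar) at ratio lam (unit sigma_e)."""
        c = lam / (1.0 + self.ng * lam)
        XtVX = self.XtX - (self.sx * c[:, None]).T @ self.sx
        XtVy = self.Xty - self.sx.T @ (c * self.sy)
        yVy = self.yty - float(c @ (self.sy**2))
        logdet = float(np.log1p(self.ng * lam).sum())
        return XtVX, XtVy, yVy, logdet


def _profiled_deviance(sums: _Sums, lam: float) -> tuple[float, np.ndarray, float]:
    """Profiled REML deviance (up to constant), GLS beta, and sigma_e^2."""
    XtVX, XtVy, yVy, logdet = sums.gls(lam)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = yVy - float(beta @ XtVy)
    rss = max(rss, 1e-300)
    df = sums.n - sums.p
    sign, ld_xtvx = np.linalg.slogdet(XtVX)
    dev = df * np.log(rss / df) + logdet + ld_xtvx + df * (1.0 + np.log(2.0 * np.pi))
    return dev, beta, rss / df


def reml_deviance(
    y: np.ndarray, X: np.ndarray, codes: np.ndarray, sigma2_b: float, sigma2_e: float
) -> float:
    """-2 restricted log-likelihood at given variance components."""
    sums = _Sums(np.asarray(y, float), np.asarray(X, float), codes)
    lam = sigma2_b / sigma2_e
    XtVX, XtVy, yVy, logdet_bar = sums.gls(lam)
    beta = np.linalg.solve(XtVX, XtVy)
    rss_bar = yVy - float(beta @ XtVy)
    n, p = sums.n, sums.p
    _, ld = np.linalg.slogdet(XtVX / sigma2_e)
    return (
        (n - p) * np.log(2.0 * np.pi)
        + n * np.log(sigma2_e)
        + logdet_bar
        + ld
        + rss_bar / sigma2_e
    )


def _as_codes(groups) -> np.ndarray:
    _, codes = np.unique(np.asarray(groups), return_inverse=True)
    return codes


def fit_random_intercept(
    y, X, groups, exog_names: list[str] | None = None
) -> RandomInterceptFit:
    """REML fit of y = X beta + b_group + e.

    X must include the intercept column.  Raises ValidationError when there
    are fewer than 2 groups or not enough observations to estimate both
    variance components.  A boundary solution (sigma_b^2 -> 0) is reported
    with ``singular=True``, not as an error.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    codes = _as_codes(groups)
    n, p = X.shape
    G = codes.max() + 1
    if G < 2:
        raise ValidationError(f"need >= 2 groups, got {G}")
    if n < p + 2:
        raise ValidationError(f"insufficient data: n={n} observations for p={p} fixed effects")
    if np.bincount(codes).max() < 2:
        raise ValidationError("need at least one group with >= 2 observations")

    sums = _Sums(y, X, codes)
    res = minimize_scalar(
        lambda u: _profiled_deviance(sums, np.exp(u))[0],
        bounds=_LOG_LAM_BOUNDS,
        method="bounded",
        options={"xatol": 1e-10},
    )
    lam = float(np.exp(res.x))
    dev0, _, _ = _profiled_deviance(sums, 0.0)
    if dev0 <= res.fun:  # boundary (OLS) at least as good
        lam = 0.0
    dev, beta, s2e = _profiled_deviance(sums, lam)
    singular = lam < _SINGULAR_LAM
    if singular:
        lam = 0.0
        dev, beta, s2e = _profiled_deviance(sums, 0.0)
    XtVX, _, _, _ = sums.gls(lam)
    cov_beta = s2e * np.linalg.inv(XtVX)
    names = exog_names or [f"x{j}" for j in range(p)]
    return RandomInterceptFit(
        beta=beta,
        beta_se=np.sqrt(np.diag(cov_beta)),
        exog_names=list(names),
        sigma2_b=lam * s2e,
        sigma2_e=s2e,
        deviance=float(dev),
        n_obs=n,
        n_groups=int(G),
        singular=singular,
        _y=y,
        _X=X,
        _codes=codes,
    )


def _contrast_variance(sums: _Sums, c: np.ndarray, sigma2_b: float, sigma2_e: float) -> float:
    lam = sigma2_b / sigma2_e
    XtVX, _, _, _ = sums.gls(lam)
    return sigma2_e * float(c @ np.linalg.solve(XtVX, c))


def satterthwaite_ftest(fit: RandomInterceptFit, coef: int | str) -> SatterthwaiteTest:
    """F-test of one fixed-effect coefficient with Satterthwaite df.

    For a singular fit (no between-group variance) the model collapses to
    ordinary least squares and the classical residual df n - p is used.
    """
    j = fit.exog_names.index(coef) if isinstance(coef, str) else int(coef)
    y, X, codes = fit._y, fit._X, fit._codes
    sums = _Sums(y, X, codes)
    n, p = X.shape
    c = np.zeros(p)
    c[j] = 1.0
    theta = np.array([fit.sigma2_b, fit.sigma2_e])
    C = _contrast_variance(sums, c, max(theta[0], 0.0), theta[1])

    if fit.singular:
        df_den = float(n - p)
    else:
        # delta method on the REML deviance, all derivatives by central FD
        h = np.maximum(1e-4 * np.abs(theta), 1e-8)
        if theta[0] - h[0] <= 0:
            h[0] = theta[0] / 2.0

        def dev(t):
            return reml_deviance(y, X, codes, t[0], t[1])

        H = np.zeros((2, 2))
        f0 = dev(theta)
        for a in range(2):
            ea = np.zeros(2)
            ea[a] = h[a]
            H[a, a] = (dev(theta + ea) - 2.0 * f0 + dev(theta - ea)) / h[a] ** 2
        e0 = np.array([h[0], 0.0])
        e1 = np.array([0.0, h[1]])
        H[0, 1] = H[1, 0] = (
            dev(theta + e0 + e1) - dev(theta + e0 - e1) - dev(theta - e0 + e1) + dev(theta - e0 - e1)
        ) / (4.0 * h[0] * h[1])

        grad = np.zeros(2)
        for a in range(2):
            ea = np.zeros(2)
            ea[a] = h[a]
            tp, tm = theta + ea, theta - ea
            grad[a] = (
                _contrast_variance(sums, c, tp[0], tp[1])
                - _contrast_variance(sums, c, tm[0], tm[1])
            ) / (2.0 * h[a])

        try:
            A = 2.0 * np.linalg.inv(H)
            denom = float(grad @ A @ grad)
        except np.linalg.LinAlgError:
            denom = 0.0
        df_den = 2.0 * C**2 / denom if denom > 0 else float(n - p)
        df_den = float(np.clip(df_den, 1.0, n - p))

    est = float(fit.beta[j])
    if C < 1e-30 or not np.isfinite(C):  # degenerate (e.g. constant outcome)
        F = 0.0 if abs(est) < 1e-8 else np.inf
    else:
        F = est**2 / C
    pval = float(stats.f.sf(F, 1, df_den))
    return SatterthwaiteTest(
        coef=fit.exog_names[j],
        estimate=est,
        se=float(np.sqrt(C)),
        F=float(F),
        df_num=1,
        df_den=df_den,
        p_value=pval,
    )


def whitened_design(fit: RandomInterceptFit) -> tuple[np.ndarray, np.ndarray]:
    """GLS-whitened (y, X): transformed errors are homoscedastic N(0, sigma_e^2).

    Per group, V_bar^{-1/2} = I - c J with c = (1 - 1/sqrt(1 + n lam)) / n.
    """
    y, X, codes = fit._y, fit._X, fit._codes
    lam = fit.lam
    yt, Xt = y.copy(), X.copy()
    for g in np.unique(codes):
        m = codes == g
        ng = m.sum()
        cg = (1.0 - 1.0 / np.sqrt(1.0 + ng * lam)) / ng
        yt[m] -= cg * y[m].sum()
        Xt[m] -= cg * X[m].sum(axis=0)
    return yt, Xt


def cooks_distances(fit: RandomInterceptFit) -> np.ndarray:
    """Cook's distance per observation from the whitened fixed-effects design."""
    yt, Xt = whitened_design(fit)
    n, p = Xt.shape
    XtXinv = np.linalg.inv(Xt.T @ Xt)
    hat = np.einsum("ij,jk,ik->i", Xt, XtXinv, Xt)
    beta = XtXinv @ (Xt.T @ yt)
    e = yt - Xt @ beta
    s2 = float(e @ e) / (n - p)
    if s2 <= 0 or not np.isfinite(s2):  # perfect fit: nothing is influential
        return np.zeros(n)
    hat = np.clip(hat, 0.0, 1.0 - 1e-12)
    return e**2 * hat / (p * s2 * (1.0 - hat) ** 2)


def cooks_outliers(fit: RandomInterceptFit, threshold: float | None = None) -> np.ndarray:
    """Row positions whose Cook's distance exceeds the threshold (default 4/n)."""
    d = cooks_distances(fit)
    thr = threshold if threshold is not None else 4.0 / fit.n_obs
    return np.flatnonzero(d > thr)
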