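"""Linear mixed models with crossed random intercepts.

Fits y = X beta + sum_f Z_f u_f + e with u_f ~ N(0, s2_f I) for each
grouping factor f (e.g. participant and trial order) and e ~ N(0, s2 I),
by profiled (restricted) maximum likelihood over the variance ratios
theta_f = s2_f / s2.

Because only random intercepts are involved, the marginal covariance is
W = I + sum_f theta_f Z_f Z_f' and all likelihood quantities reduce, via
the Woodbury identity, to dense algebra on the q x q matrix Z'Z where
q = total number of random-effect levels (tens to low hundreds here).
Each likelihood evaluation is then O(q^3), making a fit take milliseconds
where a generic mixed-model solver takes tens of seconds. Coefficient
degrees of freedom use a Satterthwaite approximation computed by finite
differences of the REML criterion in the variance parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular

__all__ = ["LMMResult", "fit_lmm"]

_THETA_MAX = 1e8
_TINY_VAR = 1e-12


@dataclass
class LMMResult:
    """Fitted crossed random-intercept mixed model."""

    fe_names: list[str]
    params: np.ndarray
    bse: np.ndarray
    df: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    sigma2: float  # residual variance
    vc: dict[str, float]  # variance components, per factor
    llf: float
    aic: float
    reml: bool
    nobs: int
    fitted: np.ndarray  # X beta + Z u (BLUPs)
    ranef: dict[str, np.ndarray]
    converged: bool
    singular: bool
    cov_params: np.ndarray = field(repr=False, default=None)

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.fe_names,
                "estimate": self.params,
                "se": self.bse,
                "df": self.df,
                "t": self.tvalues,
                "p": self.pvalues,
            }
        )

    def predict_fixed(self, X: np.ndarray) -> np.ndarray:
        """Population-level prediction (random effects at their mean, 0)."""
        return np.asarray(X, dtype=np.float64) @ self.params


class _Workspace:
    """Precomputed cross-products; everything the likelihood needs."""

    def __init__(self, y: np.ndarray, X: np.ndarray, codes: list[np.ndarray]):
        self.n, self.p = X.shape
        self.nlevels = [int(c.max()) + 1 if c.size else 0 for c in codes]
        self.q = int(sum(self.nlevels))
        self.codes = codes
        offsets = np.cumsum([0] + self.nlevels)
        self.slices = [slice(offsets[i], offsets[i + 1]) for i in range(len(codes))]

        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        # Z'X, Z'y via per-factor group sums
        ZtX = np.zeros((self.q, self.p))
        Zty = np.zeros(self.q)
        for sl, c, nl in zip(self.slices, codes, self.nlevels):
            for j in range(self.p):
                ZtX[sl, j] = np.bincount(c, weights=X[:, j], minlength=nl)
            Zty[sl] = np.bincount(c, weights=y, minlength=nl)
        self.ZtX = ZtX
        self.Zty = Zty
        # Z'Z: diagonal blocks are level counts; off-diagonal are cross-tabs
        ZtZ = np.zeros((self.q, self.q))
        for sl, c, nl in zip(self.slices, codes, self.nlevels):
            ZtZ[sl, sl] = np.diag(np.bincount(c, minlength=nl))
        for a in range(len(codes)):
            for b in range(a + 1, len(codes)):
                tab = np.zeros((self.nlevels[a], self.nlevels[b]))
                np.add.at(tab, (codes[a], codes[b]), 1.0)
                ZtZ[self.slices[a], self.slices[b]] = tab
                ZtZ[self.slices[b], self.slices[a]] = tab.T
        self.ZtZ = ZtZ

    def _chol_M(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cholesky of M = I + D^1/2 Z'Z D^1/2 and the D^1/2 diagonal."""
        if self.q == 0:
            return np.zeros((0, 0)), np.zeros(0)
        dsqrt = np.concatenate(
            [np.full(nl, np.sqrt(max(t, 0.0))) for t, nl in zip(theta, self.nlevels)]
        )
        M = self.ZtZ * np.outer(dsqrt, dsqrt)
        M[np.diag_indices_from(M)] += 1.0
        return np.linalg.cholesky(M), dsqrt

    def gls(self, theta: np.ndarray):
        """GLS quantities at variance ratios theta.

        Returns (beta, XtWiX, rss, logdet_W, logdet_XtWiX).
        """
        L, dsqrt = self._chol_M(theta)
        logdet_W = 2.0 * float(np.log(np.diag(L)).sum())

        if self.q > 0:
            # a'W^-1 b = a'b - (Z'a)' D^1/2 M^-1 D^1/2 (Z'b)
            A = dsqrt[:, None] * self.ZtX  # D^1/2 Z'X
            c = dsqrt * self.Zty
            VA = solve_triangular(L, A, lower=True)
            vc_ = solve_triangular(L, c, lower=True)
            XtWiX = self.XtX - VA.T @ VA
            XtWiy = self.Xty - VA.T @ vc_
            ytWiy = self.yty - float(vc_ @ vc_)
        else:
            XtWiX = self.XtX.copy()
            XtWiy = self.Xty.copy()
            ytWiy = self.yty

        beta = np.linalg.solve(XtWiX, XtWiy)
        rss = max(ytWiy - float(beta @ XtWiy), 0.0)
        sign, logdet_XtWiX = np.linalg.slogdet(XtWiX)
        return beta, XtWiX, rss, logdet_W, logdet_XtWiX

    def neg2ll_profiled(self, theta: np.ndarray, reml: bool) -> float:
        n, p = self.n, self.p
        try:
            _, _, rss, logdet_W, logdet_XtWiX = self.gls(theta)
        except np.linalg.LinAlgError:
            return np.inf
        if reml:
            s2 = max(rss / (n - p), _TINY_VAR * self.yty / n + 1e-300)
            return (n - p) * (np.log(2 * np.pi * s2) + 1) + logdet_W + logdet_XtWiX
        s2 = max(rss / n, _TINY_VAR * self.yty / n + 1e-300)
        return n * (np.log(2 * np.pi * s2) + 1) + logdet_W

    def neg2ll_reml_unprofiled(self, var_params: np.ndarray) -> float:
        """REML criterion as a function of (s2_f..., s2) — for Satterthwaite."""
        *s2f, s2 = var_params
        if s2 <= 0 or any(v < 0 for v in s2f):
            return np.inf
        theta = np.array(s2f) / s2
        n, p = self.n, self.p
        try:
            _, _, rss, logdet_W, logdet_XtWiX = self.gls(theta)
        except np.linalg.LinAlgError:
            return np.inf
        return (
            (n - p) * np.log(2 * np.pi * s2)
            + logdet_W
            + logdet_XtWiX
            + rss / s2
        )

    def cov_beta(self, var_params: np.ndarray) -> np.ndarray:
        *s2f, s2 = var_params
        theta = np.array(s2f) / s2
        _, XtWiX, _, _, _ = self.gls(theta)
        return s2 * np.linalg.inv(XtWiX)


def _satterthwaite_df(ws: _Workspace, var_params: np.ndarray) -> np.ndarray | None:
    """Per-coefficient Satterthwaite df via finite differences.

    df_i = 2 C_ii^2 / (g_i' Vg g_i) with C = cov(beta_hat), g_i the gradient
    of C_ii in the variance parameters, and Vg the asymptotic covariance of
    the variance-parameter estimates (2 x inverse Hessian of the REML
    criterion). Returns None when the Hessian is unusable.
    """
    k = len(var_params)
    steps = np.maximum(np.abs(var_params) * 1e-4, 1e-8)

    def cii(vp: np.ndarray) -> np.ndarray:
        return np.diag(ws.cov_beta(vp))

    # gradient of each C_ii (p x k); forward-shift at the zero boundary
    grads = np.zeros((ws.p, k))
    for j in range(k):
        hi = var_params.copy()
        lo = var_params.copy()
        hi[j] += steps[j]
        lo[j] -= steps[j]
        if lo[j] < 0:
            lo[j] = var_params[j]
            denom = steps[j]
        else:
            denom = 2 * steps[j]
        grads[:, j] = (cii(hi) - cii(lo)) / denom

    # numerical Hessian of the (unprofiled) REML criterion
    f0 = ws.neg2ll_reml_unprofiled(var_params)
    H = np.zeros((k, k))
    for a in range(k):
        for b in range(a, k):
            ea = np.zeros(k)
            eb = np.zeros(k)
            ea[a] = steps[a]
            eb[b] = steps[b]
            fpp = ws.neg2ll_reml_unprofiled(var_params + ea + eb)
            fpm = ws.neg2ll_reml_unprofiled(var_params + ea - eb)
            fmp = ws.neg2ll_reml_unprofiled(var_params - ea + eb)
            fmm = ws.neg2ll_reml_unprofiled(var_params - ea - eb)
            if not np.all(np.isfinite([fpp, fpm, fmp, fmm])):
                return None
            H[a, b] = H[b, a] = (fpp - fpm - fmp + fmm) / (4 * steps[a] * steps[b])
    try:
        Vg = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    C0 = cii(var_params)
    denom = np.einsum("ij,jk,ik->i", grads, Vg, grads)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = 2.0 * C0**2 / denom
    df[~np.isfinite(df)] = ws.n - ws.p
    return np.clip(df, 1.0, ws.n - ws.p)


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    factors: dict[str, np.ndarray] | None = None,
    fe_names: list[str] | None = None,
    reml: bool = True,
    df_method: str = "satterthwaite",
) -> LMMResult:
    """Fit a linear mixed model with random intercepts for each factor.

    Parameters
    ----------
    y
        Response vector, length n.
    X
        Fixed-effect design matrix (n, p), including the intercept column.
    factors
        Mapping factor name -> integer level codes (length n). Empty or
        None reduces to ordinary least squares.
    reml
        Restricted ML (default, for coefficient tables) or plain ML (for
        AIC comparisons across fixed-effect structures).
    df_method
        "satterthwaite" (default) or "residual" (df = n - p).
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n, p) aligned with y")
    factors = dict(factors or {})
    names = list(factors)
    codes = []
    for f in names:
        c = np.asarray(factors[f]).ravel()
        if c.size != y.size:
            raise ValueError(f"factor {f!r} length mismatch")
        codes.append(np.unique(c, return_inverse=True)[1])  # contiguous codes

    ws = _Workspace(y, X, codes)
    n, p = ws.n, ws.p
    nf = len(names)

    converged = True
    if nf == 0:
        theta = np.zeros(0)
    else:
        res = optimize.minimize(
            lambda t: ws.neg2ll_profiled(t, reml),
            x0=np.ones(nf),
            method="L-BFGS-B",
            bounds=[(0.0, _THETA_MAX)] * nf,
        )
        theta = res.x
        converged = bool(res.success)

    beta, XtWiX, rss, logdet_W, logdet_XtWiX = ws.gls(theta)
    denom = (n - p) if reml else n
    sigma2 = rss / denom
    singular = sigma2 <= _TINY_VAR * max(ws.yty / n, 1.0)
    sigma2_safe = max(sigma2, 1e-300)

    if reml:
        neg2ll = (n - p) * (np.log(2 * np.pi * sigma2_safe) + 1) + logdet_W + logdet_XtWiX
    else:
        neg2ll = n * (np.log(2 * np.pi * sigma2_safe) + 1) + logdet_W
    llf = -0.5 * neg2ll
    k_params = p + nf + 1
    aic = neg2ll + 2 * k_params

    cov = sigma2 * np.linalg.inv(XtWiX)
    bse = np.sqrt(np.maximum(np.diag(cov), 0.0))

    var_params = np.append(theta * sigma2, sigma2)
    df = None
    if df_method == "satterthwaite" and nf > 0 and not singular:
        df = _satterthwaite_df(ws, var_params)
    if df is None:
        df = np.full(p, float(n - p))

    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(bse > 0, beta / bse, np.inf * np.sign(beta))
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)

    # BLUPs: u = D Z' W^-1 r
    resid = y - X @ beta
    ranef: dict[str, np.ndarray] = {}
    fitted = X @ beta
    if nf > 0:
        L, dsqrt = ws._chol_M(theta)
        Ztr = np.zeros(ws.q)
        for sl, c, nl in zip(ws.slices, codes, ws.nlevels):
            Ztr[sl] = np.bincount(c, weights=resid, minlength=nl)
        tmp = solve_triangular(L, dsqrt * Ztr, lower=True)
        tmp = solve_triangular(L.T, tmp, lower=False)
        ZtWir = Ztr - ws.ZtZ @ (dsqrt * tmp)
        for f, sl, t, c in zip(names, ws.slices, theta, codes):
            u = t * ZtWir[sl]
            ranef[f] = u
            fitted = fitted + u[c]

    return LMMResult(
        fe_names=list(fe_names) if fe_names is not None else [f"x{i}" for i in range(p)],
        params=beta,
        bse=bse,
        df=df,
        tvalues=np.asarray(tvals),
        pvalues=np.asarray(pvals),
        sigma2=float(sigma2),
        vc={f: float(t * sigma2) for f, t in zip(names, theta)},
        llf=float(llf),
        aic=float(aic),
        reml=reml,
        nobs=n,
        fitted=fitted,
        ranef=ranef,
        converged=converged,
        singular=bool(singular),
        cov_params=cov,
    )
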