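"""Linear mixed models with one random intercept and optional AR(1) errors.

The model is

    y = X beta + Z b + e,   b_g ~ N(0, sigma_b^2),
    Corr(e_gi, e_gj) = phi^|t_i - t_j|  within group g (AR(1)),

fitted by profiled maximum likelihood or REML: for given variance ratio
lambda = sigma_b^2 / sigma_e^2 and autocorrelation phi, the fixed effects
and the residual scale have closed-form generalized-least-squares
solutions, leaving a 1- or 2-parameter optimization.  Group covariance
matrices are factorized once per distinct within-group time pattern, so
balanced panels (every species observed on the same year grid) cost a
single small Cholesky per likelihood evaluation.

Wald t-statistics use the residual degrees of freedom n - p; they are
asymptotic approximations, as is the chi-square reference distribution of
:func:`lrt`, which always compares ML fits (REML fits are refitted
automatically).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

PHI_BOUND = 0.999
_LAM_MIN, _LAM_MAX = 1e-10, 1e10


class RankDeficiencyError(ValueError):
    """Fixed-effects design matrix is not full column rank."""


class ConvergenceError(RuntimeError):
    """Variance-parameter optimization failed to converge."""


class NonNestedError(ValueError):
    """Likelihood-ratio test requested for non-nested models."""


@dataclass
class LRTResult:
    statistic: float
    df: int
    pvalue: float

    def __post_init__(self):
        if self.df < 0:
            raise ValueError("LRT df cannot be negative")


def _patterns(groups: np.ndarray, times: np.ndarray):
    """Group row indices by (sorted within group by time), keyed by the
    within-group time vector so identical patterns share factorizations."""
    order: dict = {}
    for g in pd.unique(groups):
        rows = np.where(groups == g)[0]
        rows = rows[np.argsort(times[rows], kind="mergesort")]
        key = tuple(times[rows])
        order.setdefault(key, []).append(rows)
    out = []
    for key, rowlists in order.items():
        out.append((np.asarray(key, dtype=float), np.vstack(rowlists)))
    return out


class _Profile:
    """Profiled -2 log-likelihood over (log lambda [, atanh-scaled phi])."""

    def __init__(self, y, X, patterns, reml, ar1):
        self.y = y
        self.X = X
        self.patterns = patterns
        self.reml = reml
        self.ar1 = ar1
        self.n, self.p = X.shape

    def theta_to_params(self, theta):
        lam = float(np.clip(np.exp(theta[0]), _LAM_MIN, _LAM_MAX))
        phi = PHI_BOUND * np.tanh(theta[1]) if self.ar1 else 0.0
        return lam, phi

    def components(self, theta):
        lam, phi = self.theta_to_params(theta)
        p = self.p
        XtWX = np.zeros((p, p))
        XtWy = np.zeros(p)
        ytWy = 0.0
        logdet = 0.0
        for tvec, idx in self.patterns:
            T = len(tvec)
            g = idx.shape[0]
            if self.ar1 and T > 1 and phi != 0.0:
                gaps = np.abs(tvec[:, None] - tvec[None, :])
                R = np.abs(phi) ** gaps
                if phi < 0.0:  # integer-lag sign flip (gaps are year counts)
                    R *= np.where(np.round(gaps).astype(int) % 2 == 1, -1.0, 1.0)
            else:
                R = np.eye(T)
            W = lam * np.ones((T, T)) + R
            c, low = linalg.cho_factor(W, lower=True)
            logdet += g * 2.0 * np.sum(np.log(np.diag(c)))
            Winv = linalg.cho_solve((c, low), np.eye(T))
            Y = self.y[idx]                      # (g, T)
            Xg = self.X[idx]                     # (g, T, p)
            WiY = Y @ Winv                       # (g, T)
            ytWy += float(np.einsum("gt,gt->", WiY, Y))
            XtWy += np.einsum("gtp,gt->p", Xg, WiY)
            WiX = np.einsum("ts,gsp->gtp", Winv, Xg)
            XtWX += np.einsum("gtp,gtq->pq", Xg, WiX)
        beta = linalg.solve(XtWX, XtWy, assume_a="pos")
        rss = max(ytWy - float(beta @ XtWy), 1e-300)
        return lam, phi, XtWX, beta, rss, logdet

    def neg2ll(self, theta):
        n, p = self.n, self.p
        try:
            lam, phi, XtWX, beta, rss, logdet = self.components(theta)
        except np.linalg.LinAlgError:
            return 1e12
        if self.reml:
            sigma2 = rss / (n - p)
            sign, ld_xtwx = np.linalg.slogdet(XtWX)
            if sign <= 0:
                return 1e12
            return (
                (n - p) * np.log(2.0 * np.pi * sigma2)
                + logdet
                + ld_xtwx
                + (n - p)
            )
        sigma2 = rss / n
        return n * np.log(2.0 * np.pi * sigma2) + logdet + n


@dataclass
class LMMFit:
    """A fitted mixed model; coefficient table plus variance components."""

    names: list[str]
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    sigma_group: float
    sigma_resid: float
    phi: float
    se_phi: float
    loglik: float
    method: str  # "ML" or "REML"
    n_obs: int
    n_groups: int
    df_resid: int
    ar1: bool
    boundary: list[str] = field(default_factory=list)
    _design: dict = field(default_factory=dict, repr=False)

    def refit(self, reml: bool) -> "LMMFit":
        d = self._design
        return fit_lmm(
            d["y"], d["X"], d["groups"], times=d["times"],
            ar1=self.ar1, reml=reml, names=self.names,
        )

    def to_dict(self) -> dict:
        return {
            "coefficients": {
                name: {
                    "estimate": float(self.params[name]),
                    "se": float(self.bse[name]),
                    "t": float(self.tvalues[name]),
                    "p": float(self.pvalues[name]),
                }
                for name in self.names
            },
            "sigma_group": self.sigma_group,
            "sigma_resid": self.sigma_resid,
            "phi": self.phi if self.ar1 else None,
            "se_phi": self.se_phi if self.ar1 else None,
            "loglik": self.loglik,
            "method": self.method,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "boundary": list(self.boundary),
        }

    def summary(self) -> str:
        lines = [
            f"Linear mixed model ({self.method}), n = {self.n_obs}, "
            f"groups = {self.n_groups}, logLik = {self.loglik:.3f}",
            f"random-intercept SD = {self.sigma_group:.4f}, "
            f"residual SD = {self.sigma_resid:.4f}"
            + (f", AR(1) phi = {self.phi:.3f}" if self.ar1 else ""),
            f"{'term':<24}{'beta':>12}{'SE':>12}{'t':>9}{'p':>9}",
        ]
        for name in self.names:
            lines.append(
                f"{name:<24}{self.params[name]:>12.4f}{self.bse[name]:>12.4f}"
                f"{self.tvalues[name]:>9.2f}{self.pvalues[name]:>9.3f}"
            )
        if self.boundary:
            lines.append("boundary warnings: " + ", ".join(self.boundary))
        return "\n".join(lines)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
    aliased = sorted(names[j] for j in piv[rank:])
    raise RankDeficiencyError(
        "rank-deficient fixed-effects design; aliased terms: " + ", ".join(aliased)
    )


def _start_values(y, X, groups, times, ar1):
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    total_var = max(resid.var(), 1e-12)
    frame = pd.DataFrame({"g": groups, "r": resid})
    gmeans = frame.groupby("g")["r"].mean()
    sizes = frame.groupby("g")["r"].size()
    gvar = float(gmeans.var()) if len(gmeans) > 1 else 0.0
    if not np.isfinite(gvar):
        gvar = 0.0
    between = max(gvar - total_var / max(float(sizes.mean()), 1.0), 0.0)
    lam0 = np.clip(between / total_var, 1e-4, 1e4)
    theta = [np.log(lam0)]
    if ar1:
        num = den = 0.0
        for _, sub in frame.assign(t=times).groupby("g"):
            r = sub.sort_values("t")["r"].to_numpy()
            if len(r) > 2:
                num += float(r[1:] @ r[:-1])
                den += float(r @ r)
        phi0 = np.clip(num / den if den > 0 else 0.0, -0.9, 0.9)
        theta.append(np.arctanh(phi0 / PHI_BOUND))
    return np.asarray(theta)


def fit_lmm(
    y,
    X,
    groups,
    times=None,
    ar1: bool = False,
    reml: bool = True,
    names: list[str] | None = None,
) -> LMMFit:
    """Fit the random-intercept (+ optional AR(1)) model.

    Parameters
    ----------
    y, X : response vector and fixed-effects design matrix (with intercept
        column included by the caller).  ``X`` may be a DataFrame, in which
        case its columns provide the term names.
    groups : grouping factor for the random intercept (one level per
        species, or per year, depending on the design).
    times : within-group ordering variable for the AR(1) correlation;
        defaults to observation order within group.
    ar1 : estimate a first-order autocorrelation of the residuals within
        groups (requires longitudinal grouping).
    reml : REML (default, used for Wald t-tests) or ML (used for LRTs).
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if names is None:
            names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=float).ravel()
    groups = np.asarray(groups)
    n, p = X.shape
    if len(y) != n or len(groups) != n:
        raise ValueError("y, X and groups must have matching lengths")
    if times is None:
        times = np.zeros(n)
        for g in pd.unique(groups):
            rows = np.where(groups == g)[0]
            times[rows] = np.arange(len(rows))
    times = np.asarray(times, dtype=float)
    _check_rank(X, names)

    patterns = _patterns(groups, times)
    prof = _Profile(y, X, patterns, reml=reml, ar1=ar1)

    starts = [_start_values(y, X, groups, times, ar1)]
    starts.append(np.zeros(1 + int(ar1)))
    best = None
    for s in starts:
        res = optimize.minimize(
            prof.neg2ll,
            s,
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 2000, "maxfev": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun) or best.fun >= 1e12:
        raise ConvergenceError(f"optimizer failed: {best}")

    theta = best.x
    lam, phi, XtWX, beta, rss, _ = prof.components(theta)
    sigma2 = rss / (n - p) if reml else rss / n
    cov_beta = sigma2 * linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov_beta))
    tvals = beta / se
    df_resid = n - p
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    loglik = -0.5 * best.fun

    boundary = []
    if lam <= 1e-8:
        boundary.append("random-intercept variance at zero boundary")
    if ar1 and abs(phi) >= 0.99 * PHI_BOUND:
        boundary.append("AR(1) phi at boundary")

    se_phi = float("nan")
    if ar1:
        se_phi = _se_phi(prof, theta)

    idx = pd.Index(names)
    fit = LMMFit(
        names=names,
        params=pd.Series(beta, index=idx),
        bse=pd.Series(se, index=idx),
        tvalues=pd.Series(tvals, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        sigma_group=float(np.sqrt(lam * sigma2)),
        sigma_resid=float(np.sqrt(sigma2)),
        phi=float(phi),
        se_phi=se_phi,
        loglik=float(loglik),
        method="REML" if reml else "ML",
        n_obs=n,
        n_groups=len(pd.unique(groups)),
        df_resid=df_resid,
        ar1=ar1,
        boundary=boundary,
        _design={"y": y, "X": pd.DataFrame(X, columns=names), "groups": groups,
                 "times": times},
    )
    return fit


def _se_phi(prof: _Profile, theta: np.ndarray) -> float:
    """Delta-method SE of phi from the numerical profile-likelihood Hessian."""
    k = len(theta)
    h = 1e-4
    H = np.zeros((k, k))
    f0 = prof.neg2ll(theta)
    for i in range(k):
        for j in range(i, k):
            ei = np.eye(k)[i] * h
            ej = np.eye(k)[j] * h
            if i == j:
                f1 = prof.neg2ll(theta + ei)
                f2 = prof.neg2ll(theta - ei)
                H[i, i] = (f1 - 2 * f0 + f2) / h**2
            else:
                fpp = prof.neg2ll(theta + ei + ej)
                fpm = prof.neg2ll(theta + ei - ej)
                fmp = prof.neg2ll(theta - ei + ej)
                fmm = prof.neg2ll(theta - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h**2)
    H *= 0.5  # Hessian of -loglik, not of -2 loglik
    var_z = float("nan")
    try:
        cov = linalg.inv(H)
        var_z = cov[-1, -1]
    except linalg.LinAlgError:
        pass
    if not np.isfinite(var_z) or var_z <= 0:
        # variance-ratio direction flat (boundary); condition on it
        if H[-1, -1] > 0:
            var_z = 1.0 / H[-1, -1]
        else:
            return float("nan")
    dphi_dz = PHI_BOUND * (1.0 - np.tanh(theta[-1]) ** 2)
    return float(dphi_dz * np.sqrt(var_z))


def lrt(full: LMMFit, reduced: LMMFit) -> LRTResult:
    """Likelihood-ratio test of nested fixed-effects structures.

    Both fits are refitted by ML if necessary.  The statistic is clamped
    at zero when optimizer noise makes the nested optimum marginally
    better; the df is the fixed-effect parameter-count difference.
    """
    if not set(reduced.names) <= set(full.names):
        raise NonNestedError(
            "reduced-model terms are not a subset of the full model's"
        )
    if full.n_obs != reduced.n_obs:
        raise NonNestedError("models were fitted to different numbers of rows")
    if full.method != "ML":
        full = full.refit(reml=False)
    if reduced.method != "ML":
        reduced = reduced.refit(reml=False)
    df = len(full.names) - len(reduced.names)
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return LRTResult(float(stat), int(df), p)
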