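"""Mixed-effects models for the showing analysis.

Two model families, both with a single random intercept per dog-owner pair
(the repeated unit of the design):

* binomial-logit GLMM for success (correct vs incorrect choice), fitted by
  maximum likelihood with the random effect integrated out by Gauss-Hermite
  quadrature (the Laplace approximation is the 1-node special case; the
  default 25 nodes is effectively exact for one scalar random effect);
* Gaussian LMM for effort / correct-showing proportion, fitted by REML
  (closed-form profiling of the fixed effects and residual variance), with
  Satterthwaite-approximate denominator degrees of freedom for the
  t-statistics.

Model selection follows an AIC-compare-then-LRT scheme: among candidate
fits on identical rows the smallest AIC wins, and nested pairs get a
chi-square likelihood-ratio test.  Fits that fail to converge under the
gradient-based optimizer are automatically refitted with a derivative-free
fallback and flagged.

Fixed-effect "formulas" are lists of column names of the prepared
observation table; :func:`add_nested_time_columns` builds the nested time
coding (phases within trials within sessions) used throughout: a session
main effect, a trial slope within each session, and a phase contrast
within each session.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from scipy.special import logsumexp
from numpy.polynomial.hermite import hermgauss

__all__ = [
    "ModelFit",
    "ModelComparison",
    "fit_logistic_glmm",
    "fit_gaussian_lmm",
    "fit_success_glmm",
    "fit_effort_lmm",
    "select_model_aic",
    "add_nested_time_columns",
    "TIME_TERMS",
]

#: Nested time coding: session main effect, trial slope within each session
#: (centered mid-session so the session contrast is evaluated mid-trial),
#: phase contrast within each session.
TIME_TERMS: tuple[str, ...] = (
    "session2", "trial_s1", "trial_s2", "phase2_s1", "phase2_s2",
)


def add_nested_time_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Add the nested time dummies/slopes and the condition dummy."""
    out = df.copy()
    out["session2"] = (out["session"] == 2).astype(float)
    out["trial_s1"] = np.where(out["session"] == 1, out["trial"] - 2.5, 0.0)
    out["trial_s2"] = np.where(out["session"] == 2, out["trial"] - 2.5, 0.0)
    out["phase2_s1"] = ((out["session"] == 1) & (out["phase"] == 2)).astype(float)
    out["phase2_s2"] = ((out["session"] == 2) & (out["phase"] == 2)).astype(float)
    out["condition_far"] = (out["condition"] == "far").astype(float)
    return out


@dataclass
class ModelFit:
    """A fitted mixed model (coefficients on the linear-predictor scale)."""

    family: str  # "binomial-logit" | "gaussian"
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    stat: np.ndarray  # Wald z (GLMM) or t (LMM)
    stat_name: str
    p: np.ndarray
    df: np.ndarray | None  # Satterthwaite df per coefficient (LMM only)
    sigma_u2: float
    sigma_e2: float | None
    loglik: float
    k_params: int
    n: int
    rows_index: tuple
    converged: bool
    optimizer: str
    method: str  # "ml" | "reml"

    @property
    def aic(self) -> float:
        return 2.0 * self.k_params - 2.0 * self.loglik

    def coef_table(self) -> pd.DataFrame:
        tab = pd.DataFrame({
            "term": self.names, "estimate": self.beta, "se": self.se,
            self.stat_name: self.stat, "p": self.p,
        })
        if self.df is not None:
            tab.insert(4, "df", self.df)
        return tab

    def summary(self) -> str:
        head = (f"{self.family} mixed model ({self.method.upper()}), "
                f"n = {self.n}, random intercept sd = {math.sqrt(self.sigma_u2):.3f}"
                + ("" if self.sigma_e2 is None
                   else f", residual sd = {math.sqrt(self.sigma_e2):.3f}"))
        tail = (f"logLik = {self.loglik:.2f}, AIC = {self.aic:.2f}, "
                f"optimizer = {self.optimizer}"
                + ("" if self.converged else "  [NOT CONVERGED]"))
        return "\n".join([head, self.coef_table().to_string(index=False,
                                                            float_format=lambda v: f"{v:10.4f}"),
                          tail])


@dataclass
class ModelComparison:
    """AIC comparison (plus LRTs for declared nested pairs)."""

    labels: list[str]
    fits: list[ModelFit]
    aic: list[float]
    delta_aic: list[float]
    selected: int
    lrt: list[dict] = field(default_factory=list)

    @property
    def selected_label(self) -> str:
        return self.labels[self.selected]

    def summary(self) -> str:
        lines = ["model comparison (smallest AIC selected):"]
        for i, (lab, a, d) in enumerate(zip(self.labels, self.aic, self.delta_aic)):
            mark = " <- selected" if i == self.selected else ""
            lines.append(f"  {lab:40s} AIC = {a:9.2f}  dAIC = {d:7.2f}{mark}")
        for r in self.lrt:
            lines.append(
                f"  LRT {r['small']} vs {r['large']}: "
                f"chi2({r['df']}) = {r['chi2']:.2f}, p = {r['p']:.4g}"
            )
        return "\n".join(lines)


def _design(df: pd.DataFrame, response: str, fixed: list[str],
            group: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], pd.Index]:
    """Listwise-complete design matrices; raises on singular design."""
    cols = [response, *fixed, group]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"columns not in table: {missing}")
    sub = df[cols].dropna()
    if sub.empty:
        raise ValueError("no complete rows after listwise exclusion")
    y = sub[response].to_numpy(float)
    X = np.column_stack([np.ones(len(sub))] + [sub[c].to_numpy(float) for c in fixed])
    names = ["(intercept)", *fixed]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "singular design: a fixed effect is constant or collinear "
            f"(terms: {names})"
        )
    codes, _ = pd.factorize(sub[group])
    return y, X, codes.astype(np.int64), names, sub.index


# ---------------------------------------------------------------------------
# binomial-logit GLMM
# ---------------------------------------------------------------------------

def _glmm_nll_factory(y, X, gidx, n_groups, n_quad):
    nodes, weights = hermgauss(n_quad)
    log_w = np.log(weights) - 0.5 * math.log(math.pi)
    sign = np.where(y > 0.5, -1.0, 1.0)  # logp = -log(1 + exp(sign * eta_k))
    one_hot = np.zeros((len(y), n_groups))
    one_hot[np.arange(len(y)), gidx] = 1.0

    def nll(params: np.ndarray) -> float:
        beta, s = params[:-1], params[-1]
        sigma = math.exp(s)
        eta = X @ beta
        u = math.sqrt(2.0) * sigma * nodes  # (K,)
        # (K, n): per-observation bernoulli log-likelihood at each node
        logp = -np.logaddexp(0.0, sign[None, :] * (eta[None, :] + u[:, None]))
        s_kg = logp @ one_hot  # (K, G) group sums
        ll = logsumexp(s_kg + log_w[:, None], axis=0).sum()
        return -ll if np.isfinite(ll) else 1e12

    return nll


def _plain_logistic_nll_factory(y, X):
    sign = np.where(y > 0.5, -1.0, 1.0)

    def nll(beta: np.ndarray) -> float:
        return float(np.logaddexp(0.0, sign * (X @ beta)).sum())

    return nll


def _numeric_hessian(f, x, step=1e-4):
    k = len(x)
    H = np.empty((k, k))
    h = step * np.maximum(1.0, np.abs(x))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = f(x + ei + ej); fpm = f(x + ei - ej)
            fmp = f(x - ei + ej); fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def fit_logistic_glmm(
    df: pd.DataFrame,
    response: str,
    fixed: list[str],
    group: str = "pair",
    *,
    n_quad: int = 25,
    fix_sigma: float | None = None,
) -> ModelFit:
    """Binomial-logit mixed model with a random intercept per *group*.

    Maximum likelihood; the random intercept is integrated out with
    ``n_quad``-node Gauss-Hermite quadrature.  Rows with a missing value in
    any used column are excluded listwise.  On optimizer failure the model
    is refitted with a derivative-free fallback and the fit flagged.

    ``fix_sigma=0`` pins the random-intercept SD at zero, collapsing to
    ordinary logistic regression (used for oracle comparisons).
    """
    y, X, gidx, names, rows = _design(df, response, fixed, group)
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError(f"response {response!r} must be binary 0/1")
    n_groups = int(gidx.max()) + 1
    p = X.shape[1]

    if fix_sigma is not None and fix_sigma == 0.0:
        nll0 = _plain_logistic_nll_factory(y, X)
        res = optimize.minimize(nll0, np.zeros(p), method="BFGS",
                                options={"gtol": 1e-8, "maxiter": 500})
        beta = res.x
        H = _numeric_hessian(nll0, beta)
        cov = np.linalg.inv(H)
        se = np.sqrt(np.diag(cov))
        z = beta / se
        return ModelFit(
            family="binomial-logit", names=names, beta=beta, se=se, stat=z,
            stat_name="z", p=2.0 * sps.norm.sf(np.abs(z)), df=None,
            sigma_u2=0.0, sigma_e2=None, loglik=-res.fun, k_params=p,
            n=len(y), rows_index=tuple(rows), converged=bool(res.success),
            optimizer="bfgs", method="ml",
        )

    nll = _glmm_nll_factory(y, X, gidx, n_groups, n_quad)
    # warm start from ordinary logistic
    nll0 = _plain_logistic_nll_factory(y, X)
    start_beta = optimize.minimize(nll0, np.zeros(p), method="BFGS",
                                   options={"maxiter": 200}).x
    x0 = np.append(start_beta, math.log(0.5))
    bounds = [(None, None)] * p + [(-8.0, 3.0)]

    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-12})
    optimizer, converged = "l-bfgs-b", bool(res.success)
    if not converged or not np.isfinite(res.fun):
        res2 = optimize.minimize(nll, res.x, method="Nelder-Mead",
                                 options={"maxiter": 4000, "xatol": 1e-8,
                                          "fatol": 1e-10})
        if res2.fun <= res.fun:
            res = res2
        optimizer, converged = "l-bfgs-b+nelder-mead", bool(res2.success)

    est = res.x
    beta, s_hat = est[:p], est[p]
    sigma_u2 = math.exp(2.0 * s_hat)
    H = _numeric_hessian(nll, est)
    try:
        cov = np.linalg.inv(H)
        se_full = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        # variance at the boundary: fall back to the fixed-effect block
        cov_b = np.linalg.inv(_numeric_hessian(lambda b: nll(np.append(b, s_hat)), beta))
        se_full = np.append(np.sqrt(np.maximum(np.diag(cov_b), 0.0)), math.nan)
    se = se_full[:p]
    z = beta / se
    return ModelFit(
        family="binomial-logit", names=names, beta=beta, se=se, stat=z,
        stat_name="z", p=2.0 * sps.norm.sf(np.abs(z)), df=None,
        sigma_u2=sigma_u2, sigma_e2=None, loglik=-res.fun, k_params=p + 1,
        n=len(y), rows_index=tuple(rows), converged=converged,
        optimizer=optimizer, method="ml",
    )


# ---------------------------------------------------------------------------
# Gaussian LMM
# ---------------------------------------------------------------------------

def _lmm_pieces(y, X, gidx, n_groups):
    """Per-group slices (views) for the random-intercept algebra."""
    order = np.argsort(gidx, kind="stable")
    y_o, X_o, g_o = y[order], X[order], gidx[order]
    starts = np.searchsorted(g_o, np.arange(n_groups))
    ends = np.append(starts[1:], len(y_o))
    return [(y_o[a:b], X_o[a:b]) for a, b in zip(starts, ends)]


def _lmm_profile(lam: float, pieces, n, p):
    """GLS beta, profiled residual variance and the log-det terms at lambda."""
    A = 0.0
    b = 0.0
    logdet_v = 0.0
    for yg, Xg in pieces:
        ng = len(yg)
        c = lam / (1.0 + lam * ng)
        logdet_v += math.log1p(lam * ng)
        Xs, ys = Xg.sum(axis=0), yg.sum()
        A = A + Xg.T @ Xg - c * np.outer(Xs, Xs)
        b = b + Xg.T @ yg - c * Xs * ys
    beta = np.linalg.solve(A, b)
    q = 0.0
    for yg, Xg in pieces:
        ng = len(yg)
        c = lam / (1.0 + lam * ng)
        rg = yg - Xg @ beta
        q += rg @ rg - c * rg.sum() ** 2
    return beta, q, logdet_v, A


def _lmm_neg2ll(lam, pieces, n, p, reml):
    beta, q, logdet_v, A = _lmm_profile(lam, pieces, n, p)
    if reml:
        dof = n - p
        sigma_e2 = q / dof
        sign, logdet_a = np.linalg.slogdet(A)
        # log|X'V^-1 X| = log|A| - p log(sigma_e2); combined with log|V| =
        # n log(sigma_e2) + logdet_v this leaves (n-p) log(sigma_e2) overall
        return (dof * math.log(2.0 * math.pi * sigma_e2) + dof
                + logdet_v + logdet_a)
    sigma_e2 = q / n
    return n * math.log(2.0 * math.pi * sigma_e2) + n + logdet_v


def _lmm_loglik_theta(theta, pieces, n, p, reml):
    """REML/ML log-likelihood as a function of (sigma_u2, sigma_e2) unprofiled."""
    su2, se2 = theta
    if se2 <= 0:
        return -np.inf
    su2 = max(su2, 0.0)  # finite-difference steps may cross the boundary
    lam = su2 / se2
    beta, q, logdet_v, A = _lmm_profile(lam, pieces, n, p)
    ll = -0.5 * (n * math.log(2.0 * math.pi * se2) + logdet_v + q / se2)
    if reml:
        sign, logdet_a = np.linalg.slogdet(A)
        ll -= 0.5 * (logdet_a - p * math.log(se2))
        ll += 0.5 * p * math.log(2.0 * math.pi)  # REML constant (lme4 convention)
    return ll


def _lmm_beta_cov(theta, pieces):
    """(X' V^-1 X)^-1 at theta = (sigma_u2, sigma_e2)."""
    su2, se2 = theta
    A = 0.0
    for yg, Xg in pieces:
        ng = len(yg)
        c = su2 / (se2 + su2 * ng)
        Xs = Xg.sum(axis=0)
        A = A + (Xg.T @ Xg - c * np.outer(Xs, Xs)) / se2
    return np.linalg.inv(A)


def _satterthwaite_df(theta, pieces, n, p, reml):
    """Satterthwaite denominator df per coefficient.

    df_j = 2 f_j^2 / (g_j' A g_j) with f_j(theta) the j-th diagonal of the
    fixed-effect covariance, g_j its gradient in theta = (sigma_u2,
    sigma_e2), and A the asymptotic covariance of theta-hat from the
    observed information of the (RE)ML likelihood.
    """
    ll = lambda th: _lmm_loglik_theta(th, pieces, n, p, reml)
    H = _numeric_hessian(lambda th: -ll(th), np.asarray(theta, float),
                         step=1e-5)
    try:
        acov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.full(p, float(n - p))
    f0 = np.diag(_lmm_beta_cov(theta, pieces))
    grads = np.empty((p, 2))
    for i in range(2):
        h = 1e-5 * max(1.0, abs(theta[i]))
        tp = np.array(theta, float); tp[i] += h
        tm = np.array(theta, float); tm[i] = max(tm[i] - h, 1e-12)
        fp = np.diag(_lmm_beta_cov(tp, pieces))
        fm = np.diag(_lmm_beta_cov(tm, pieces))
        grads[:, i] = (fp - fm) / (tp[i] - tm[i])
    df = np.empty(p)
    for j in range(p):
        denom = grads[j] @ acov @ grads[j]
        df[j] = 2.0 * f0[j] ** 2 / denom if denom > 0 else float(n - p)
    # guard against pathological curvature estimates
    return np.clip(df, 1.0, 10.0 * n)


def fit_gaussian_lmm(
    df: pd.DataFrame,
    response: str,
    fixed: list[str],
    group: str = "pair",
    *,
    reml: bool = True,
) -> ModelFit:
    """Gaussian mixed model with a random intercept per *group*.

    REML by default (use ``reml=False`` for ML fits when comparing models
    with different fixed effects by AIC/LRT).  t-statistics carry
    Satterthwaite-approximate denominator degrees of freedom.
    """
    y, X, gidx, names, rows = _design(df, response, fixed, group)
    if y.std() == 0:
        raise ValueError(f"response {response!r} has zero variance")
    n, p = X.shape
    n_groups = int(gidx.max()) + 1
    pieces = _lmm_pieces(y, X, gidx, n_groups)

    obj = lambda t: _lmm_neg2ll(math.exp(t), pieces, n, p, reml)
    res = optimize.minimize_scalar(obj, bounds=(-15.0, 15.0), method="bounded",
                                   options={"xatol": 1e-10})
    # the boundary sigma_u2 = 0 is not in the open search range; check it
    lam_hat = math.exp(res.x)
    if _lmm_neg2ll(0.0, pieces, n, p, reml) < res.fun:
        lam_hat = 0.0
    converged = bool(res.success) if lam_hat > 0 else True

    beta, q, logdet_v, A = _lmm_profile(lam_hat, pieces, n, p)
    dof = n - p if reml else n
    sigma_e2 = q / dof
    sigma_u2 = lam_hat * sigma_e2
    loglik = _lmm_loglik_theta((sigma_u2, sigma_e2), pieces, n, p, reml)

    cov_beta = _lmm_beta_cov((sigma_u2, sigma_e2), pieces)
    se = np.sqrt(np.diag(cov_beta))
    t = beta / se
    df_sat = _satterthwaite_df((sigma_u2, sigma_e2), pieces, n, p, reml)
    pvals = 2.0 * sps.t.sf(np.abs(t), df_sat)
    return ModelFit(
        family="gaussian", names=names, beta=beta, se=se, stat=t,
        stat_name="t", p=pvals, df=df_sat, sigma_u2=sigma_u2,
        sigma_e2=sigma_e2, loglik=loglik, k_params=p + 2, n=n,
        rows_index=tuple(rows), converged=converged,
        optimizer="bounded-scalar", method="reml" if reml else "ml",
    )


# ---------------------------------------------------------------------------
# convenience wrappers and model selection
# ---------------------------------------------------------------------------

def fit_success_glmm(rows: pd.DataFrame, fixed: list[str] | None = None,
                     **kwargs) -> ModelFit:
    """Success GLMM on an observation table (nested time columns added)."""
    if fixed is None:
        fixed = ["prop_correct_showing", *TIME_TERMS]
    return fit_logistic_glmm(add_nested_time_columns(rows), "success",
                             list(fixed), **kwargs)


def fit_effort_lmm(rows: pd.DataFrame, fixed: list[str] | None = None,
                   response: str = "effort", **kwargs) -> ModelFit:
    """Effort (or correct-showing) LMM on an observation table."""
    if fixed is None:
        fixed = list(TIME_TERMS)
    return fit_gaussian_lmm(add_nested_time_columns(rows), response,
                            list(fixed), **kwargs)


def select_model_aic(
    fits: list[ModelFit],
    labels: list[str] | None = None,
    nested: list[tuple[int, int]] | None = None,
) -> ModelComparison:
    """Pick the smallest-AIC fit; chi-square LRTs for declared nested pairs.

    All fits must be estimated on identical rows (AIC is not comparable
    otherwise) with the same estimation method.  Ties go to the earliest
    candidate in declaration order.
    """
    if not fits:
        raise ValueError("no fits to compare")
    if labels is None:
        labels = [f"model_{i}" for i in range(len(fits))]
    rows0, method0 = fits[0].rows_index, fits[0].method
    for f in fits[1:]:
        if f.rows_index != rows0:
            raise ValueError("fits are on differing row sets; AIC not comparable")
        if f.method != method0:
            raise ValueError("fits mix ML and REML; refit with one method")
    aics = [f.aic for f in fits]
    best = min(aics)
    selected = next(i for i, a in enumerate(aics) if a == best)
    lrt = []
    for i_small, i_large in (nested or []):
        small, large = fits[i_small], fits[i_large]
        ddf = large.k_params - small.k_params
        if ddf <= 0:
            raise ValueError(
                f"pair ({labels[i_small]}, {labels[i_large]}) is not nested "
                "small-in-large"
            )
        chi2 = max(2.0 * (large.loglik - small.loglik), 0.0)
        lrt.append({"small": labels[i_small], "large": labels[i_large],
                    "chi2": chi2, "df": ddf, "p": sps.chi2.sf(chi2, ddf)})
    return ModelComparison(labels=list(labels), fits=list(fits), aic=aics,
                           delta_aic=[a - best for a in aics],
                           selected=selected, lrt=lrt)
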