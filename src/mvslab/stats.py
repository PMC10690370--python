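"""Statistical analyses for MVS cohort data.

The continuous outcomes (period statistics of SPV) are analyzed with an
ordinary least-squares model ``value ~ condition + subject``: the subject
term absorbs between-subject level differences in a small repeated-measures
cohort.  Condition summaries are estimated marginal means (predictions
averaged over the subject levels), and pairwise contrasts are Tukey-adjusted
by default.  Ordinal vertigo intensity ratings are analyzed with a
cumulative-link (proportional-odds) model with a subject random intercept
whose marginal likelihood is integrated by Gauss-Hermite quadrature; with
very small cohorts where the random-effect variance is weakly identified a
ridge-penalized refit is used and flagged.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.stats import f as f_dist
from scipy.stats import norm, studentized_range, t as t_dist

from .errors import DesignError, InsufficientDataError

ALPHA = 0.05


@dataclass
class ConditionFit:
    """OLS condition-effect fit with estimated marginal means.

    ``emmeans`` has one row per condition: estimate, SE and the symmetric
    95% CI.  ``f_stat``/``p_value`` test the overall condition effect.
    """

    conditions: list
    emmeans: pd.DataFrame
    f_stat: float
    p_value: float
    df_resid: int
    coef: np.ndarray
    emm_cov: np.ndarray  # covariance of the marginal-mean estimates
    sigma2: float


class RegressionResult(NamedTuple):
    slope: float
    intercept: float
    r2: float
    adj_r2: float


def _check_design(df: pd.DataFrame) -> tuple:
    conds = sorted(df["condition"].unique(), key=float)
    subjects = sorted(df["subject"].astype(str).unique())
    if len(conds) < 2:
        raise DesignError("need at least 2 conditions")
    if len(subjects) < 2:
        raise DesignError("need at least 2 subjects")
    cell = df.groupby(["subject", "condition"]).size()
    missing = [
        (s, c)
        for s in subjects
        for c in conds
        if (s, c) not in cell.index
    ]
    if missing:
        raise DesignError(
            "design has empty subject x condition cells: "
            + ", ".join(f"({s}, {c:g})" for s, c in missing)
        )
    return conds, subjects


def fit_condition_model(
    values: Sequence[float],
    conditions: Sequence,
    subjects: Sequence,
) -> ConditionFit:
    """Fit ``value ~ condition + subject`` by OLS.

    Marginal means per condition are predictions averaged over subjects; in
    a balanced design they coincide with the raw condition means.  The
    overall condition p-value is from the F-test of the condition block.
    """
    df = pd.DataFrame({
        "value": np.asarray(values, float),
        "condition": [float(c) for c in conditions],
        "subject": [str(s) for s in subjects],
    })
    conds, subj = _check_design(df)
    k, S = len(conds), len(subj)
    n = len(df)

    # design: intercept + condition dummies (ref = first) + subject dummies
    X = np.zeros((n, 1 + (k - 1) + (S - 1)))
    X[:, 0] = 1.0
    for j, c in enumerate(conds[1:]):
        X[:, 1 + j] = (df["condition"] == c).to_numpy(float)
    for j, s in enumerate(subj[1:]):
        X[:, k + j] = (df["subject"] == s).to_numpy(float)
    y = df["value"].to_numpy()

    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise DesignError("design matrix is rank deficient")
    resid = y - X @ beta
    df_resid = n - X.shape[1]
    if df_resid <= 0:
        raise DesignError("no residual degrees of freedom")
    sse = float(resid @ resid)
    sigma2 = sse / df_resid
    xtx_inv = np.linalg.inv(X.T @ X)
    cov_beta = sigma2 * xtx_inv

    # marginal means: L rows average the subject dummies
    L = np.zeros((k, X.shape[1]))
    L[:, 0] = 1.0
    for j in range(1, k):
        L[j, j] = 1.0
    L[:, k:] = 1.0 / S
    emm = L @ beta
    emm_cov = L @ cov_beta @ L.T
    se = np.sqrt(np.clip(np.diag(emm_cov), 0.0, None))
    tcrit = t_dist.ppf(1.0 - ALPHA / 2.0, df_resid)
    emmeans = pd.DataFrame({
        "condition": conds,
        "mean": emm,
        "se": se,
        "ci_low": emm - tcrit * se,
        "ci_high": emm + tcrit * se,
    })

    # F-test of the condition block (reduced model: intercept + subject)
    Xr = np.delete(X, range(1, k), axis=1)
    beta_r, _, _, _ = np.linalg.lstsq(Xr, y, rcond=None)
    sse_r = float(np.sum((y - Xr @ beta_r) ** 2))
    df_num = k - 1
    if sse <= 1e-12 * max(1.0, float(y @ y)):
        # degenerate: residual variance zero
        f_stat = 0.0 if sse_r - sse <= 1e-12 else float("inf")
        p_value = 1.0 if f_stat == 0.0 else 0.0
    else:
        f_stat = ((sse_r - sse) / df_num) / sigma2
        p_value = float(f_dist.sf(f_stat, df_num, df_resid))

    return ConditionFit(
        conditions=conds,
        emmeans=emmeans,
        f_stat=float(f_stat),
        p_value=p_value,
        df_resid=df_resid,
        coef=beta,
        emm_cov=emm_cov,
        sigma2=sigma2,
    )


def pairwise_contrasts(
    fit: ConditionFit,
    adjust: str = "tukey",
    pairs: Optional[Sequence[tuple]] = None,
) -> pd.DataFrame:
    """All pairwise condition contrasts from a fitted condition model.

    Each row holds the difference of marginal means, its SE, the (Tukey- or
    un-) adjusted p-value, and the percent difference of the second member
    relative to the first, computed on unrounded magnitudes:
    ``100 * (|m_a| - |m_b|) / |m_a|``.
    """
    if adjust not in ("tukey", "none"):
        raise DesignError(f"unknown adjustment {adjust!r}")
    conds = fit.conditions
    k = len(conds)
    means = dict(zip(conds, fit.emmeans["mean"]))
    idx = {c: i for i, c in enumerate(conds)}
    if pairs is None:
        pairs = list(itertools.combinations(conds, 2))
    rows = []
    for a, b in pairs:
        ia, ib = idx[a], idx[b]
        diff = means[a] - means[b]
        var = fit.emm_cov[ia, ia] + fit.emm_cov[ib, ib] - 2.0 * fit.emm_cov[ia, ib]
        se = float(np.sqrt(max(var, 0.0)))
        if se == 0.0:
            p = 1.0 if diff == 0 else 0.0
            tstat = 0.0 if diff == 0 else float("inf")
        else:
            tstat = diff / se
            if adjust == "tukey":
                q = abs(tstat) * np.sqrt(2.0)
                p = float(studentized_range.sf(q, k, fit.df_resid))
            else:
                p = float(2.0 * t_dist.sf(abs(tstat), fit.df_resid))
        pct = float("nan") if means[a] == 0 else 100.0 * (abs(means[a]) - abs(means[b])) / abs(means[a])
        rows.append({
            "a": a, "b": b,
            "difference": float(diff), "se": se, "t": float(tstat),
            "p_value": min(max(p, 0.0), 1.0),
            "percent_difference": pct,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ordinal intensity model
# ---------------------------------------------------------------------------


@dataclass
class OrdinalFit:
    """Cumulative-link (proportional-odds) fit with subject random intercept."""

    categories: list
    cutpoints: np.ndarray
    coef: dict
    se: dict
    p_values: dict
    sigma_u: float
    loglik: float
    converged: bool
    penalized: bool

    def category_probs(self, x_row: dict) -> np.ndarray:
        """Fitted marginal category probabilities for one covariate setting."""
        eta = sum(self.coef[name] * x_row.get(name, 0.0) for name in self.coef)
        cum = special.expit(self.cutpoints - eta)
        cum = np.concatenate([[0.0], cum, [1.0]])
        return np.diff(cum)


def _ordinal_nll(theta, y, X, subj_idx, n_subj, n_cut, gh_x, gh_w, penalty):
    """Negative marginal log-likelihood, Gauss-Hermite over subject intercepts."""
    zeta = np.empty(n_cut)
    zeta[0] = theta[0]
    if n_cut > 1:
        zeta[1:] = theta[0] + np.cumsum(np.exp(theta[1:n_cut]))
    beta = theta[n_cut:-1]
    sigma = np.exp(theta[-1])
    eta = X @ beta if X.shape[1] else np.zeros(len(y))
    nodes = np.sqrt(2.0) * sigma * gh_x  # (Q,)
    # per-observation, per-node category log-probability
    shift = eta[:, None] + nodes[None, :]
    hi = np.where(y[:, None] < n_cut, zeta[np.minimum(y, n_cut - 1)][:, None] - shift, np.inf)
    lo = np.where(y[:, None] > 0, zeta[np.maximum(y - 1, 0)][:, None] - shift, -np.inf)
    p = special.expit(hi) - special.expit(lo)
    logp = np.log(np.clip(p, 1e-300, None))
    ll = 0.0
    for s in range(n_subj):
        rows = subj_idx == s
        contrib = logp[rows].sum(axis=0)  # (Q,)
        m = contrib.max()
        ll += m + np.log(np.sum(gh_w * np.exp(contrib - m)) / np.sqrt(np.pi))
    pen = penalty * (np.sum(beta**2) + theta[-1] ** 2 + 1e-2 * np.sum(theta[:n_cut] ** 2))
    return -ll + pen


def fit_ordinal_intensity(
    ratings: Sequence[str],
    conditions: Sequence,
    phases: Sequence[str],
    subjects: Sequence,
    categories: Sequence[str] = ("none", "low", "moderate", "high"),
    n_quad: int = 21,
    penalty_on_separation: float = 0.5,
) -> OrdinalFit:
    """Proportional-odds model of ordinal intensity with subject random intercept.

    Fixed effects: condition (dummy-coded against the shortest duration) and
    phase (exit vs entry).  The subject intercept is integrated out by
    Gauss-Hermite quadrature.  When the fit shows signs of complete
    separation (runaway coefficients) or fewer than two observed categories,
    a ridge-penalized refit is performed and flagged via ``penalized`` and a
    warning.
    """
    cat_index = {c: i for i, c in enumerate(categories)}
    y = np.array([cat_index[r] for r in ratings], dtype=int)
    cond = np.array([float(c) for c in conditions])
    phase = np.array([str(p) for p in phases])
    subj = np.array([str(s) for s in subjects])
    if y.size < 4:
        raise InsufficientDataError("too few ratings for an ordinal fit")
    conds = sorted(set(cond))
    subj_levels = sorted(set(subj))
    subj_idx = np.array([subj_levels.index(s) for s in subj])
    names = [f"condition[{c:g}]" for c in conds[1:]] + ["phase[exit]"]
    X = np.column_stack(
        [(cond == c).astype(float) for c in conds[1:]] + [(phase == "exit").astype(float)]
    )
    n_cut = len(categories) - 1
    gh_x, gh_w = np.polynomial.hermite.hermgauss(n_quad)

    degenerate = len(set(y)) < 2

    def run(penalty):
        theta0 = np.concatenate([[0.0], np.zeros(n_cut - 1), np.zeros(X.shape[1]), [0.0]])
        res = optimize.minimize(
            _ordinal_nll, theta0,
            args=(y, X, subj_idx, len(subj_levels), n_cut, gh_x, gh_w, penalty),
            method="BFGS", options={"maxiter": 500, "gtol": 1e-6},
        )
        return res

    res = run(0.0 if not degenerate else penalty_on_separation)
    beta_hat = res.x[n_cut:-1]
    separated = degenerate or (not res.success and np.max(np.abs(beta_hat), initial=0.0) > 8.0) \
        or np.max(np.abs(beta_hat), initial=0.0) > 15.0
    penalized = False
    if separated:
        warnings.warn(
            "ordinal fit shows separation or degenerate categories; "
            "refitting with a ridge penalty",
            RuntimeWarning,
            stacklevel=2,
        )
        res = run(penalty_on_separation)
        penalized = True

    theta = res.x
    zeta = np.empty(n_cut)
    zeta[0] = theta[0]
    if n_cut > 1:
        zeta[1:] = theta[0] + np.cumsum(np.exp(theta[1:n_cut]))
    beta = theta[n_cut:-1]
    sigma = float(np.exp(theta[-1]))

    # numerical Hessian for standard errors (central differences)
    se = {}
    pvals = {}
    try:
        hess = _numeric_hessian(
            lambda th: _ordinal_nll(th, y, X, subj_idx, len(subj_levels), n_cut,
                                    gh_x, gh_w, penalty_on_separation if penalized else 0.0),
            theta,
        )
        cov = np.linalg.inv(hess)
        sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        for i, name in enumerate(names):
            s_i = sd[n_cut + i]
            se[name] = float(s_i)
            z = beta[i] / s_i if s_i > 0 else np.inf
            pvals[name] = float(2.0 * norm.sf(abs(z)))
    except np.linalg.LinAlgError:
        for i, name in enumerate(names):
            se[name] = float("nan")
            pvals[name] = float("nan")

    return OrdinalFit(
        categories=list(categories),
        cutpoints=zeta,
        coef=dict(zip(names, beta.astype(float))),
        se=se,
        p_values=pvals,
        sigma_u=sigma,
        loglik=-float(res.fun),
        converged=bool(res.success),
        penalized=penalized,
    )


def _numeric_hessian(f, x, eps: float = 1e-4) -> np.ndarray:
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += eps; xpp[j] += eps
            xpm = x.copy(); xpm[i] += eps; xpm[j] -= eps
            xmp = x.copy(); xmp[i] -= eps; xmp[j] += eps
            xmm = x.copy(); xmm[i] -= eps; xmm[j] -= eps
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4.0 * eps**2)
    return H


def duration_regression(durations: Sequence[float], peaks: Sequence[float]) -> RegressionResult:
    """OLS of peak SPV magnitude on entry/exit duration.

    Returns slope, intercept, R-squared and the adjusted R-squared
    ``1 - (1 - R2) * (n - 1) / (n - 2)``.  Constant responses give R2 = 0 by
    contract; fewer than 3 points raise :class:`InsufficientDataError`.
    """
    d = np.asarray(durations, float)
    p = np.abs(np.asarray(peaks, float))
    if d.size < 3:
        raise InsufficientDataError("duration regression needs at least 3 points")
    if d.size != p.size:
        raise InsufficientDataError("durations and peaks must have equal length")
    if np.ptp(d) == 0:
        raise InsufficientDataError("durations are all identical")
    A = np.column_stack([d, np.ones_like(d)])
    (slope, intercept), *_ = np.linalg.lstsq(A, p, rcond=None)
    fitted = slope * d + intercept
    ss_tot = float(np.sum((p - p.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 0.0
    else:
        r2 = 1.0 - float(np.sum((p - fitted) ** 2)) / ss_tot
    n = d.size
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionResult(slope=float(slope), intercept=float(intercept),
                            r2=float(r2), adj_r2=float(adj))
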