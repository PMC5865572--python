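"""Maximum-likelihood estimation engines: linear mixed model and Cox PH.

The LME fitter maximizes the profiled ML deviance of the model

    y_ij = beta0 + beta1 * t_ij [+ beta2 * t_ij * arm_i] + b0i + b1i t_ij
           + b2i t_ij^2 + e_ij

with b_i ~ MVN(0, D) and e ~ N(0, sigma^2).  The marginal covariance is
reduced to per-subject 3x3 algebra (relative-Cholesky parametrization
D = sigma^2 * Lam Lam'), making one deviance evaluation cheap enough for
Monte-Carlo power studies.  Fitting is ML (never REML) so likelihood-ratio
tests across fixed-effect specifications are valid.

Cox proportional-hazards fitting delegates to lifelines (Efron ties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["LMEFit", "CoxFit", "fit_lme", "fit_cox", "likelihood_ratio_test"]


# ---------------------------------------------------------------------------
# data preparation shared with the joint-model fitter


@dataclass
class LongArrays:
    """Padded per-subject arrays of the longitudinal table."""

    t: np.ndarray        # (n, J) visit times, 0-padded
    y: np.ndarray        # (n, J) observed scores, 0-padded
    mask: np.ndarray     # (n, J) True where a real observation exists
    arm: np.ndarray      # (n,)
    n_obs: np.ndarray    # (n,) observations per subject
    subject_id: np.ndarray

    @property
    def n_total(self) -> int:
        return int(self.n_obs.sum())


def long_arrays(dataset) -> LongArrays:
    """Reshape a TrialDataset's long table into padded per-subject arrays."""
    long = dataset.longitudinal
    surv = dataset.survival
    sid = long.subject_id.to_numpy()
    order = {s: k for k, s in enumerate(surv.subject_id)}
    rows = np.array([order[s] for s in sid])
    n = len(order)
    counts = np.bincount(rows, minlength=n)
    J = int(counts.max())
    t = np.zeros((n, J))
    y = np.zeros((n, J))
    mask = np.zeros((n, J), dtype=bool)
    # long table is ordered by subject and time within subject
    pos = np.zeros(n, dtype=int)
    tm = long.time_months.to_numpy()
    ys = long.alsfrs_r.to_numpy()
    for k in range(len(sid)):
        i = rows[k]
        j = pos[i]
        t[i, j] = tm[k]
        y[i, j] = ys[k]
        mask[i, j] = True
        pos[i] += 1
    return LongArrays(t=t, y=y, mask=mask, arm=surv.arm.to_numpy(float),
                      n_obs=counts, subject_id=surv.subject_id.to_numpy())


def _design(la: LongArrays, include_treatment: bool):
    """Fixed design (n, J, p) and random design (n, J, 3), padded rows zeroed."""
    t = la.t
    cols = [np.ones_like(t), t]
    if include_treatment:
        cols.append(t * la.arm[:, None])
    X = np.stack(cols, axis=-1) * la.mask[:, :, None]
    Z = np.stack([np.ones_like(t), t, t * t], axis=-1) * la.mask[:, :, None]
    return X, Z


# ---------------------------------------------------------------------------
# results


@dataclass
class LMEFit:
    params: dict            # intercept, time, time_arm (if present)
    bse: dict
    cov_re: np.ndarray      # estimated D (3x3)
    sigma: float
    loglik: float
    converged: bool
    diagonal_refit: bool = False
    p_treatment: float | None = None
    cov_params: np.ndarray | None = None
    n_obs: int = 0

    @property
    def fe_names(self):
        return list(self.params)


@dataclass
class CoxFit:
    log_hr: float
    se: float
    loglik: float
    n_events: int
    p_value: float


# ---------------------------------------------------------------------------
# profiled ML deviance


class _LMEProblem:
    def __init__(self, la: LongArrays, include_treatment: bool):
        X, Z = _design(la, include_treatment)
        self.p = X.shape[-1]
        self.N = la.n_total
        self.y = la.y * la.mask
        self.ZtZ = np.einsum("nja,njb->nab", Z, Z)
        self.ZtX = np.einsum("nja,njp->nap", Z, X)
        self.Zty = np.einsum("nja,nj->na", Z, self.y)
        self.XtX = np.einsum("njp,njq->pq", X, X)
        self.Xty = np.einsum("njp,nj->p", X, self.y)
        self.yty = float((self.y ** 2).sum())
        self.X, self.Z = X, Z

    @staticmethod
    def lam(theta):
        L = np.zeros((3, 3))
        L[np.tril_indices(3)] = theta
        return L

    def _core(self, theta):
        """Profiled quantities at relative Cholesky theta (6,)."""
        L = self.lam(theta)
        A = np.einsum("ab,nbc,cd->nad", L.T, self.ZtZ, L) + np.eye(3)
        cho = np.linalg.cholesky(A)
        LtZtX = np.einsum("ab,nbp->nap", L.T, self.ZtX)
        LtZty = np.einsum("ab,nb->na", L.T, self.Zty)
        rhs = np.concatenate([LtZtX, LtZty[:, :, None]], axis=2)
        sol = np.linalg.solve(A, rhs)          # A^{-1} [L'Z'X, L'Z'y]
        XtWX = self.XtX - np.einsum("nap,naq->pq", LtZtX, sol[:, :, : self.p])
        XtWy = self.Xty - np.einsum("nap,na->p", LtZtX, sol[:, :, self.p])
        yWy = self.yty - float(np.einsum("na,na->", LtZty, sol[:, :, self.p]))
        logdet = 2.0 * np.log(np.diagonal(cho, axis1=1, axis2=2)).sum()
        return L, A, XtWX, XtWy, yWy, logdet

    def deviance(self, theta):
        try:
            _, _, XtWX, XtWy, yWy, logdet = self._core(theta)
            beta = np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError:
            return 1e12
        rss = yWy - beta @ XtWy
        if rss <= 0 or not np.isfinite(rss):
            return 1e12
        sigma2 = rss / self.N
        return self.N * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdet

    def deviance_and_grad(self, theta):
        """Profiled deviance and its analytic gradient in theta.

        The profiled beta-hat makes the rss term stationary (envelope
        theorem), leaving  d dev = rss'/sigma2 + d logdet:
        d(r'W^-1 r)/dLam = -2 q (Lam' q)' with q = Z'W^-1 r, and
        d logdet A/dLam = 2 Z'Z Lam A^-1, accumulated over subjects.
        """
        tril = np.tril_indices(3)
        try:
            L, A, XtWX, XtWy, yWy, logdet = self._core(theta)
            beta = np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError:
            return 1e12, np.zeros(6)
        rss = yWy - beta @ XtWy
        if rss <= 0 or not np.isfinite(rss):
            return 1e12, np.zeros(6)
        sigma2 = rss / self.N
        dev = self.N * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdet
        Ztr = self.Zty - np.einsum("nap,p->na", self.ZtX, beta)
        LtZtr = np.einsum("ab,nb->na", L.T, Ztr)
        sol = np.linalg.solve(A, LtZtr[..., None])[..., 0]     # A^-1 L'Z'r
        q = Ztr - np.einsum("nab,bc,nc->na", self.ZtZ, L, sol)
        Ltq = np.einsum("ab,nb->na", L.T, q)
        g_rss = -2.0 * np.einsum("na,nb->ab", q, Ltq)
        Ainv = np.linalg.inv(A)
        g_det = 2.0 * np.einsum("nab,bc,ncd->ad", self.ZtZ, L, Ainv)
        G = g_rss / sigma2 + g_det
        return dev, G[tril]

    def solution(self, theta):
        L, A, XtWX, XtWy, yWy, logdet = self._core(theta)
        beta = np.linalg.solve(XtWX, XtWy)
        sigma2 = (yWy - beta @ XtWy) / self.N
        cov_beta = sigma2 * np.linalg.inv(XtWX)
        D = sigma2 * (L @ L.T)
        loglik = -0.5 * (self.N * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdet)
        return beta, cov_beta, D, float(np.sqrt(sigma2)), float(loglik), (L, A)

    def eb_modes(self, theta, beta, sigma):
        """Empirical-Bayes modes and posterior covariances of b_i.

        The posterior (given longitudinal data only) is Gaussian with mean
        Lam A^{-1} Lam' Z'(y - X beta) and covariance sigma^2 Lam A^{-1} Lam'.
        """
        L, A, *_ = self._core(theta)
        beta = np.asarray(beta)
        r = self.Zty - np.einsum("nap,p->na", self.ZtX, beta)   # Z'(y - Xb)
        Ltr = np.einsum("ab,nb->na", L.T, r)
        sol = np.linalg.solve(A, Ltr[..., None])[..., 0]
        bhat = np.einsum("ab,nb->na", L, sol)
        Ainv = np.linalg.inv(A)
        cov = sigma ** 2 * np.einsum("ab,nbc,dc->nad", L, Ainv, L)
        return bhat, cov


_DEFAULT_START_SDS = np.array([4.0, 0.3, 0.02])


def fit_lme(dataset, include_treatment: bool = True,
            fixed_variance: tuple[np.ndarray, float] | None = None,
            start_sds: np.ndarray | None = None) -> LMEFit:
    """ML fit of the LME with random intercept, slope and quadratic time.

    ``include_treatment`` adds the treatment-time interaction (no arm main
    effect: randomization guarantees equal baselines).  The two-sided Wald
    p-value of the interaction is reported as ``p_treatment``.

    ``fixed_variance=(D, sigma)`` skips variance estimation and returns the
    GLS fixed-effect solution under the supplied variance components
    (used for oracle checks and degenerate noise-free inputs).
    """
    la = long_arrays(dataset)
    prob = _LMEProblem(la, include_treatment)
    diagonal_refit = False
    if fixed_variance is not None:
        D, sigma = fixed_variance
        beta, cov_beta, loglik = _gls_fixed(prob, la, np.asarray(D, float), float(sigma),
                                            include_treatment)
        theta = None
        Dhat, sig = np.asarray(D, float), float(sigma)
        converged = True
    else:
        # start: relative Cholesky from a residual-scale guess
        sds = _DEFAULT_START_SDS if start_sds is None else np.asarray(start_sds, float)
        beta0 = np.linalg.lstsq(prob.XtX, prob.Xty, rcond=None)[0]
        rss0 = prob.yty - 2 * beta0 @ prob.Xty + beta0 @ prob.XtX @ beta0
        sig0 = np.sqrt(max(rss0 / prob.N, 1e-6)) / np.sqrt(2.0)
        L0 = np.diag(sds / sig0)
        x0 = L0[np.tril_indices(3)]
        res = optimize.minimize(prob.deviance_and_grad, x0, jac=True,
                                method="L-BFGS-B",
                                options={"maxiter": 200, "ftol": 1e-10})
        converged = bool(res.success)
        if not converged:
            res2 = optimize.minimize(prob.deviance, res.x, method="Nelder-Mead",
                                     options={"maxiter": 2000, "fatol": 1e-8,
                                              "xatol": 1e-8})
            if res2.fun <= res.fun:
                res = res2
            converged = bool(res2.success)
        theta = res.x
        beta, cov_beta, Dhat, sig, loglik, _ = prob.solution(theta)
        # near-singular covariance: refit with diagonal D
        if np.linalg.cond(Dhat) > 1e8 or np.any(np.diag(Dhat) < 1e-12):
            mask = np.eye(3)[np.tril_indices(3)].astype(bool)

            def dev_diag(d):
                th = np.zeros(6)
                th[mask] = d
                return prob.deviance(th)

            rd = optimize.minimize(dev_diag, np.abs(theta[mask]) + 1e-4,
                                   method="Nelder-Mead",
                                   options={"maxiter": 1000})
            theta = np.zeros(6)
            theta[mask] = rd.x
            beta, cov_beta, Dhat, sig, loglik, _ = prob.solution(theta)
            diagonal_refit = True
            converged = bool(rd.success)
    names = ["intercept", "time"] + (["time_arm"] if include_treatment else [])
    params = dict(zip(names, map(float, beta)))
    bse = dict(zip(names, map(float, np.sqrt(np.diag(cov_beta)))))
    p_trt = None
    if include_treatment:
        z = params["time_arm"] / bse["time_arm"]
        p_trt = float(2.0 * stats.norm.sf(abs(z)))
    fit = LMEFit(params=params, bse=bse, cov_re=Dhat, sigma=sig,
                 loglik=float(loglik), converged=converged,
                 diagonal_refit=diagonal_refit, p_treatment=p_trt,
                 cov_params=cov_beta, n_obs=prob.N)
    fit._theta = theta          # relative Cholesky, reused by the joint fitter
    fit._problem = prob
    return fit


def _gls_fixed(prob: _LMEProblem, la: LongArrays, D: np.ndarray, sigma: float,
               include_treatment: bool):
    """Exact GLS with known variance components (direct per-subject solves)."""
    X, Z = prob.X, prob.Z
    n, J, p = X.shape
    XtWX = np.zeros((p, p))
    XtWy = np.zeros(p)
    loglik = 0.0
    for i in range(n):
        m = la.mask[i]
        Xi, Zi, yi = X[i][m], Z[i][m], (la.y * la.mask)[i][m]
        Vi = Zi @ D @ Zi.T + sigma ** 2 * np.eye(int(m.sum()))
        Vinv = np.linalg.inv(Vi)
        XtWX += Xi.T @ Vinv @ Xi
        XtWy += Xi.T @ Vinv @ yi
    beta = np.linalg.solve(XtWX, XtWy)
    for i in range(n):
        m = la.mask[i]
        Xi, Zi, yi = X[i][m], Z[i][m], (la.y * la.mask)[i][m]
        Vi = Zi @ D @ Zi.T + sigma ** 2 * np.eye(int(m.sum()))
        r = yi - Xi @ beta
        sign, logdet = np.linalg.slogdet(Vi)
        loglik -= 0.5 * (logdet + r @ np.linalg.solve(Vi, r)
                         + int(m.sum()) * np.log(2 * np.pi))
    return beta, np.linalg.inv(XtWX), float(loglik)


# ---------------------------------------------------------------------------
# Cox proportional hazards (lifelines, Efron ties)


def fit_cox(survival: pd.DataFrame, include_treatment: bool = True) -> CoxFit:
    """Partial-likelihood Cox fit of treatment on the survival table.

    Raises ``ValueError`` when the table contains no events (the power
    engine records such replicates as non-rejections).
    """
    n_events = int(survival.status.sum())
    if n_events < 1:
        raise ValueError("Cox model undefined: no events in dataset")
    if not include_treatment:
        raise ValueError("the Cox engine is only used with a treatment term")
    if survival.arm.nunique() < 2:
        raise ValueError("treatment contrast undefined: single-arm data")
    from lifelines import CoxPHFitter

    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(survival[["time_months", "status", "arm"]],
                duration_col="time_months", event_col="status")
    log_hr = float(cph.params_["arm"])
    se = float(cph.standard_errors_["arm"])
    p = float(2.0 * stats.norm.sf(abs(log_hr / se)))
    return CoxFit(log_hr=log_hr, se=se, loglik=float(cph.log_likelihood_),
                  n_events=n_events, p_value=p)


def likelihood_ratio_test(ll_null: float, ll_alt: float, df: int,
                          slack: float = 1e-6) -> float:
    """Upper-tail chi-square p-value of 2*(ll_alt - ll_null).

    ``ll_alt`` below ``ll_null`` beyond numerical slack signals optimizer
    failure and raises instead of returning an invalid test.
    """
    if ll_alt < ll_null - slack:
        raise ValueError(
            f"alternative log-likelihood {ll_alt} below null {ll_null}: "
            "nested-model ordering violated (optimizer failure)"
        )
    lr = max(2.0 * (ll_alt - ll_null), 0.0)
    return float(stats.chi2.sf(lr, df))
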