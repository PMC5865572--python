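"""The six decision procedures for a simulated two-arm ALS trial.

Every strategy maps one trial dataset to a p-value and a reject/accept
decision at two-sided alpha = 0.05:

``cox``              treatment log-HR in a Cox PH model (survival only)
``lme``              treatment-time interaction in the LME (function only)
``cox_lme_omnibus``  Hommel (step-up) combination of the two p-values
``composite``        Cox PH on time to death or 6-point ALSFRS-R loss
``cafs``             joint-rank (survival first, then functional change)
                     compared between arms by a rank-sum test
``jm_omnibus``       2-df likelihood-ratio test of nested joint models
                     (treatment in neither vs in both submodels)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import joint
from .fitting import fit_cox, fit_lme, likelihood_ratio_test

__all__ = [
    "StrategyResult",
    "cox_strategy",
    "lme_strategy",
    "hommel_omnibus",
    "cox_lme_omnibus_strategy",
    "composite_event_times",
    "composite_strategy",
    "cafs_scores",
    "cafs_strategy",
    "jm_omnibus_strategy",
    "analyze_trial",
    "STRATEGIES",
]

ALPHA = 0.05
COMPOSITE_DROP = 6.0


@dataclass
class StrategyResult:
    strategy: str
    p_value: float
    reject: bool
    effects: dict = field(default_factory=dict)
    converged: bool = True
    extra: dict = field(default_factory=dict)


def _decide(p: float, alpha: float = ALPHA) -> bool:
    return bool(p < alpha)


def cox_strategy(dataset, alpha: float = ALPHA) -> StrategyResult:
    """Survival-only analysis: Wald test of the treatment log-HR."""
    fit = fit_cox(dataset.survival, include_treatment=True)
    return StrategyResult("cox", fit.p_value, _decide(fit.p_value, alpha),
                          effects={"log_hr": fit.log_hr, "se": fit.se})


def lme_strategy(dataset, alpha: float = ALPHA) -> StrategyResult:
    """Function-only analysis: Wald test of the treatment-time interaction."""
    fit = fit_lme(dataset, include_treatment=True)
    return StrategyResult("lme", fit.p_treatment,
                          _decide(fit.p_treatment, alpha),
                          effects={"slope_difference": fit.params["time_arm"],
                                   "se": fit.bse["time_arm"]},
                          converged=fit.converged)


def hommel_omnibus(p_cox: float, p_lme: float, alpha: float = ALPHA):
    """Hommel step-up combination of the Cox and LME p-values.

    Returns ``(reject, adjusted)``: the global decision (treatment called
    effective when either adjusted p-value clears ``alpha``) and the
    Hommel-adjusted p-values.  For two hypotheses the procedure coincides
    with Hochberg: reject the global null iff max(p) <= alpha or
    min(p) <= alpha/2.
    """
    ps = np.array([p_cox, p_lme], dtype=float)
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rej, adj, *_ = multipletests(ps, alpha=alpha, method="hommel")
    return bool(rej.any()), adj


def cox_lme_omnibus_strategy(dataset, alpha: float = ALPHA) -> StrategyResult:
    cox = cox_strategy(dataset, alpha)
    lme = lme_strategy(dataset, alpha)
    reject, adj = hommel_omnibus(cox.p_value, lme.p_value, alpha)
    return StrategyResult("cox_lme_omnibus", float(adj.min()), reject,
                          effects={**cox.effects, **lme.effects},
                          converged=lme.converged,
                          extra={"adjusted_p": adj.tolist()})


def composite_event_times(dataset) -> pd.DataFrame:
    """Per-subject time to death or first observed 6-point ALSFRS-R drop.

    Functional events are dated at the visit where the drop is first
    observed (no interpolation); the composite event time is the earlier
    of the functional event and death, censored at follow-up otherwise.
    """
    scores, times = dataset.visit_matrices()
    if np.isnan(scores[:, 0]).any():
        raise ValueError("baseline ALSFRS-R required for every subject")
    surv = dataset.survival
    base = scores[:, 0]
    dropped = scores[:, 1:] <= (base[:, None] - COMPOSITE_DROP)
    dropped &= ~np.isnan(scores[:, 1:])
    any_drop = dropped.any(axis=1)
    first = np.argmax(dropped, axis=1) + 1
    func_time = np.where(any_drop, times[np.arange(len(base)), first], np.inf)
    death_time = np.where(surv.status.to_numpy() == 1,
                          surv.time_months.to_numpy(), np.inf)
    event_time = np.minimum(func_time, death_time)
    status = np.isfinite(event_time)
    time = np.where(status, event_time, surv.time_months.to_numpy())
    return pd.DataFrame({
        "subject_id": surv.subject_id.to_numpy(),
        "arm": surv.arm.to_numpy(),
        "time_months": time,
        "status": status.astype(int),
    })


def composite_strategy(dataset, alpha: float = ALPHA) -> StrategyResult:
    """Cox PH (Efron ties) on the composite endpoint."""
    comp = composite_event_times(dataset)
    fit = fit_cox(comp, include_treatment=True)
    return StrategyResult("composite", fit.p_value, _decide(fit.p_value, alpha),
                          effects={"log_hr": fit.log_hr, "se": fit.se},
                          extra={"event_fraction": float(comp.status.mean())})


def _cafs_score_matrix(dataset) -> np.ndarray:
    """Antisymmetric pairwise win/loss matrix of the CAFS ranking."""
    surv = dataset.survival
    T = surv.time_months.to_numpy(float)
    d = surv.status.to_numpy(int)
    scores, _ = dataset.visit_matrices()
    change = scores - scores[:, :1]
    # carry the last available change forward so the "latest common visit
    # index" is well-defined even with interior gaps
    valid = ~np.isnan(change)
    idx = np.maximum.accumulate(np.where(valid, np.arange(change.shape[1]), 0),
                                axis=1)
    change_ff = np.take_along_axis(np.where(valid, change, 0.0), idx, axis=1)
    last = idx[:, -1]

    beats = (d[None, :] == 1) & (T[:, None] > T[None, :])   # i outlives j's death
    u = beats.astype(np.int8) - beats.T.astype(np.int8)

    k = np.minimum(last[:, None], last[None, :])
    ci = np.take_along_axis(change_ff, k, axis=1)           # change_i at k[i, j]
    cj = np.take_along_axis(change_ff.T, k, axis=0)         # change_j at k[i, j]
    func = np.sign(ci - cj).astype(np.int8)
    u = np.where(u == 0, func, u)
    np.fill_diagonal(u, 0)
    return u


def cafs_scores(dataset) -> np.ndarray:
    """Joint-rank (CAFS) scores, one total per subject.

    For each ordered pair (i, j), survival is compared first: i scores +1
    over j when j died and i's follow-up exceeds j's death time (and -1
    symmetrically); when survival is indeterminate (both censored, or the
    survivor's censoring precedes the other's death) the change from
    baseline in observed ALSFRS-R at the latest scheduled visit index
    available to both is compared, the smaller loss scoring +1.  Exact
    ties score 0.  The pairwise matrix is antisymmetric by construction;
    each subject's total is the row sum.
    """
    return _cafs_score_matrix(dataset).sum(axis=1).astype(float)


def cafs_strategy(dataset, alpha: float = ALPHA, method: str = "ranksum",
                  n_perm: int = 2000, seed: int | None = None) -> StrategyResult:
    """CAFS joint-rank test between arms.

    ``method='ranksum'`` (default) uses the two-sample rank-sum test with
    normal approximation and tie correction on the subject scores;
    ``method='permutation'`` permutes arm labels instead.
    """
    totals = cafs_scores(dataset)
    arm = dataset.survival.arm.to_numpy()
    x, y = totals[arm == 1], totals[arm == 0]
    if np.all(totals == totals[0]):
        p = 1.0
    elif method == "ranksum":
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="asymptotic").pvalue)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        obs = x.mean() - y.mean()
        perm = np.empty(n_perm)
        for b in range(n_perm):
            lab = rng.permutation(arm)
            perm[b] = totals[lab == 1].mean() - totals[lab == 0].mean()
        p = float((np.sum(np.abs(perm) >= abs(obs)) + 1) / (n_perm + 1))
    else:
        raise ValueError(f"unknown CAFS method {method!r}")
    return StrategyResult("cafs", p, _decide(p, alpha),
                          effects={"mean_score_treated": float(x.mean()),
                                   "mean_score_placebo": float(y.mean())})


def jm_omnibus_strategy(dataset, alpha: float = ALPHA,
                        n_quad: int = joint.DEFAULT_GH_NODES,
                        n_time_quad: int = joint.DEFAULT_TIME_NODES) -> StrategyResult:
    """2-df likelihood-ratio omnibus test of nested joint models.

    Fits the no-treatment joint model and the model with both the
    treatment-time interaction and the direct hazard effect on shared
    quadrature, then compares by a chi-square(2) LRT.  The treatment's
    individual (trajectory-adjusted) effects from the larger model are
    reported alongside the global p-value.
    """
    data = joint.prepare_joint_data(dataset, n_quad=n_quad,
                                    n_time_quad=n_time_quad)
    jm1 = joint.fit_joint_model(dataset, include_treatment=False, data=data)
    # warm start embeds the null optimum (beta_int = gamma = 0), which
    # guarantees the nested ordering after optimization; an independent
    # staged start is tried only when the warm fit misbehaves
    warm = np.insert(np.append(jm1.theta, 0.0), 2, 0.0)
    jm2 = joint.fit_joint_model(dataset, include_treatment=True, data=data,
                                start=warm)
    if not jm2.converged or jm2.loglik < jm1.loglik - 1e-6:
        jm2b = joint.fit_joint_model(dataset, include_treatment=True, data=data)
        if jm2b.loglik > jm2.loglik:
            jm2 = jm2b
    p = likelihood_ratio_test(jm1.loglik, jm2.loglik, df=2)
    converged = jm1.converged and jm2.converged
    return StrategyResult(
        "jm_omnibus", p, _decide(p, alpha),
        effects={"beta_int": jm2.estimates["beta_int"],
                 "gamma": jm2.estimates["gamma"],
                 "alpha_assoc": jm2.estimates["alpha"]},
        converged=converged,
        extra={"loglik_null": jm1.loglik, "loglik_alt": jm2.loglik})


STRATEGIES = {
    "cox": cox_strategy,
    "lme": lme_strategy,
    "cox_lme_omnibus": cox_lme_omnibus_strategy,
    "composite": composite_strategy,
    "cafs": cafs_strategy,
    "jm_omnibus": jm_omnibus_strategy,
}


def analyze_trial(dataset, strategy: str, alpha: float = ALPHA, **kwargs) -> StrategyResult:
    """Run one named strategy on a dataset."""
    try:
        fn = STRATEGIES[strategy]
    except KeyError:
        raise ValueError(
            f"unknown strategy {strategy!r}; choose from {sorted(STRATEGIES)}")
    return fn(dataset, alpha=alpha, **kwargs)
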