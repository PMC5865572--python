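"""Latent ALSFRS-R trajectory, conditional hazard, and event-time generation.

The generator is a shared-random-effects joint model.  Subject ``i`` carries
random effects ``b = (b0, b1, b2)`` and a latent trajectory

    m(t) = (beta0 + b0) + (beta1 * (1 - slope_reduction * treated) + b1) * t
           + b2 * t**2

The hazard of death conditions on the current latent value,

    h(t) = h0(t) * exp(gamma * treated + alpha * m(t)),
    h0(t) = (shape/scale) * (t/scale)**(shape - 1)

so treatment improves survival directly (``gamma``) or indirectly through
slower functional loss (``slope_reduction`` acting via ``alpha``).  The
cumulative hazard has no closed form when ``alpha != 0``; it is computed by
fixed-order Gauss-Legendre quadrature and inverted by bracketed bisection
to draw event times.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import least_squares

from .params import JointModelParameters

__all__ = [
    "trajectory_value",
    "hazard_value",
    "cumulative_hazard",
    "sample_event_time",
    "sample_event_times",
    "marginal_survival",
    "calibrate_weibull",
]

GL_NODES_PER_MONTH = 15
ROOT_TOL_MONTHS = 1e-6


def _poly_coefs(params: JointModelParameters, b, treated):
    """Per-subject quadratic coefficients (c0, c1, c2) of the latent value."""
    b = np.asarray(b, dtype=float)
    b0, b1, b2 = b[..., 0], b[..., 1], b[..., 2]
    treated = np.asarray(treated, dtype=float)
    c0 = params.beta0 + b0
    c1 = params.beta1 * (1.0 - params.slope_reduction * treated) + b1
    c2 = b2
    return c0, c1, c2


def trajectory_value(params: JointModelParameters, b, treated, t):
    """Latent (noise-free) ALSFRS-R value at time ``t`` months.

    ``b`` is a 3-vector (or (..., 3) array) of random effects; ``treated``
    an indicator.  The value is not clamped to the instrument range.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    c0, c1, c2 = _poly_coefs(params, b, treated)
    out = c0 + c1 * t + c2 * t * t
    return float(out) if out.ndim == 0 else out


def _log_hazard(params: JointModelParameters, c0, c1, c2, treated, t):
    """log h(t) for arrays broadcastable against t (t > 0)."""
    rho, lam = params.weibull_shape, params.weibull_scale
    m = c0 + c1 * t + c2 * t * t
    if params.clamp_trajectory:
        m = np.clip(m, 0.0, 48.0)
    return (
        math.log(rho / lam)
        + (rho - 1.0) * (np.log(t) - math.log(lam))
        + params.gamma * np.asarray(treated, dtype=float)
        + params.alpha * m
    )


def hazard_value(params: JointModelParameters, b, treated, t):
    """Conditional hazard of death (per month) at time ``t`` > 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("hazard requires t > 0 (baseline hazard is defined for t > 0)")
    c0, c1, c2 = _poly_coefs(params, b, treated)
    out = np.exp(_log_hazard(params, c0, c1, c2, treated, t))
    return float(out) if out.ndim == 0 else out


def _gl_panel(nodes: int):
    """Gauss-Legendre nodes/weights on [0, 1]."""
    x, w = np.polynomial.legendre.leggauss(nodes)
    return 0.5 * (x + 1.0), 0.5 * w


def _cum_hazard_panels(params, c0, c1, c2, treated, horizon, nodes_per_month):
    """Cumulative hazard at unit-month panel edges, vectorized over subjects.

    Returns ``(edges, H_edges)`` with ``H_edges[..., k]`` the cumulative
    hazard at ``edges[k]``.
    """
    edges = np.arange(0.0, horizon + 1e-12, 1.0)
    if edges[-1] < horizon - 1e-12:
        edges = np.append(edges, horizon)
    x01, w01 = _gl_panel(nodes_per_month)
    lo, hi = edges[:-1], edges[1:]
    width = hi - lo  # (P,)
    t_nodes = lo[:, None] + width[:, None] * x01[None, :]  # (P, K)
    shape = np.shape(c0)
    c0_ = np.asarray(c0, dtype=float).reshape(shape + (1, 1))
    c1_ = np.asarray(c1, dtype=float).reshape(shape + (1, 1))
    c2_ = np.asarray(c2, dtype=float).reshape(shape + (1, 1))
    tr = np.asarray(treated, dtype=float).reshape(np.shape(treated) + (1, 1))
    logh = _log_hazard(params, c0_, c1_, c2_, tr, t_nodes)
    # guard against overflow at extreme parameter values probed by solvers;
    # exp(700) is effectively an infinite hazard but keeps arithmetic finite
    panel = np.einsum("...pk,k->...p", np.exp(np.minimum(logh, 700.0)), w01) * width
    H = np.concatenate(
        [np.zeros(shape + (1,)), np.cumsum(panel, axis=-1)], axis=-1
    )
    if not np.all(np.isfinite(H)):
        raise FloatingPointError("cumulative-hazard quadrature produced non-finite values")
    return edges, H


def cumulative_hazard(params: JointModelParameters, b, treated, t,
                      nodes_per_month: int = GL_NODES_PER_MONTH):
    """Cumulative hazard H(t) = integral of h over (0, t].

    Gauss-Legendre quadrature with ``nodes_per_month`` nodes on each
    unit-month panel of [0, t]; H(0) = 0.
    """
    t = float(t)
    if t < 0:
        raise ValueError("time must be nonnegative")
    if t == 0.0:
        return 0.0
    c0, c1, c2 = _poly_coefs(params, np.asarray(b, dtype=float), treated)
    edges, H = _cum_hazard_panels(params, c0, c1, c2, treated, t, nodes_per_month)
    return float(H[..., -1])


def _partial_panel_integral(params, c0, c1, c2, treated, lo, t, x01, w01):
    """Integral of the hazard over [lo, t] per subject (vectorized)."""
    width = t - lo
    s = lo[:, None] + width[:, None] * x01[None, :]
    logh = _log_hazard(
        params, c0[:, None], c1[:, None], c2[:, None],
        np.asarray(treated, dtype=float).reshape(-1, 1), s,
    )
    return np.exp(logh) @ w01 * width


def sample_event_times(params: JointModelParameters, b, treated, u, horizon,
                       nodes_per_month: int = GL_NODES_PER_MONTH,
                       tol: float = ROOT_TOL_MONTHS):
    """Vectorized inverse-transform sampling of death times.

    Solves H(T) = -log(u) per subject; subjects whose cumulative hazard at
    ``horizon`` never reaches the target are administratively censored.

    Returns ``(times, observed)`` arrays.
    """
    b = np.atleast_2d(np.asarray(b, dtype=float))
    n = b.shape[0]
    treated = np.broadcast_to(np.asarray(treated, dtype=float), (n,))
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0.0) | (u >= 1.0)):
        raise ValueError("u must lie strictly inside (0, 1)")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    c0, c1, c2 = _poly_coefs(params, b, treated)
    edges, H = _cum_hazard_panels(params, c0, c1, c2, treated, horizon, nodes_per_month)
    target = -np.log(u)
    observed = H[:, -1] >= target
    times = np.full(n, float(horizon))
    idx = np.nonzero(observed)[0]
    if idx.size:
        # locate crossing panel, then bisect within it
        Hev = H[idx]
        tev = target[idx]
        panel = np.argmax(Hev >= tev[:, None], axis=1) - 1  # crossing panel index
        panel = np.clip(panel, 0, len(edges) - 2)
        lo = edges[panel]
        hi = edges[panel + 1]
        base = Hev[np.arange(idx.size), panel]
        resid = tev - base  # integral needed beyond panel start
        x01, w01 = _gl_panel(nodes_per_month)
        c0e, c1e, c2e, tre = c0[idx], c1[idx], c2[idx], treated[idx]
        a, bnd = lo.copy(), hi.copy()
        fa = -resid
        fb = _partial_panel_integral(params, c0e, c1e, c2e, tre, lo, hi, x01, w01) - resid
        if np.any(fb < -1e-9):
            raise FloatingPointError(
                "event-time root not bracketed despite H(horizon) >= -log(u)"
            )
        n_iter = max(1, int(np.ceil(np.log2((hi - lo).max() / tol))))
        for _ in range(n_iter):
            mid = 0.5 * (a + bnd)
            fm = _partial_panel_integral(params, c0e, c1e, c2e, tre, lo, mid, x01, w01) - resid
            neg = fm < 0
            a = np.where(neg, mid, a)
            bnd = np.where(neg, bnd, mid)
        times[idx] = 0.5 * (a + bnd)
    return times, observed


def sample_event_time(params: JointModelParameters, b, treated, u, horizon,
                      nodes_per_month: int = GL_NODES_PER_MONTH):
    """Single-subject version of :func:`sample_event_times`."""
    t, obs = sample_event_times(params, np.asarray(b)[None, :], [treated], [u],
                                horizon, nodes_per_month)
    return float(t[0]), bool(obs[0])


def _draw_random_effects(params: JointModelParameters, n: int, rng: np.random.Generator):
    return rng.standard_normal((n, 3)) @ params.re_chol().T


def marginal_survival(params: JointModelParameters, times, mc_n: int = 100_000,
                      seed: int | None = None, treated: float = 0.0,
                      b: np.ndarray | None = None):
    """Monte-Carlo marginal survival S(t) = E_b[exp(-H(t))].

    ``b`` may be supplied to reuse a common random-number draw across
    calls (as calibration does).
    """
    times = np.asarray(times, dtype=float)
    if b is None:
        rng = np.random.default_rng(seed)
        b = _draw_random_effects(params, int(mc_n), rng)
    c0, c1, c2 = _poly_coefs(params, b, treated)
    horizon = float(times.max())
    edges, H = _cum_hazard_panels(params, c0, c1, c2, treated, horizon,
                                  GL_NODES_PER_MONTH)
    # interpolate H at requested times (exact when times hit panel edges)
    Ht = np.empty((b.shape[0], times.size))
    for k, t in enumerate(times):
        j = np.searchsorted(edges, t)
        if j < len(edges) and abs(edges[j] - t) < 1e-9:
            Ht[:, k] = H[:, j]
        else:
            x01, w01 = _gl_panel(GL_NODES_PER_MONTH)
            lo = edges[j - 1]
            Ht[:, k] = H[:, j - 1] + _partial_panel_integral(
                params, c0, c1, c2, np.broadcast_to(treated, c0.shape),
                np.full(b.shape[0], lo), np.full(b.shape[0], t), x01, w01)
    return np.exp(-Ht).mean(axis=0)


def calibrate_weibull(params: JointModelParameters,
                      targets: dict[float, float] | None = None,
                      mc_n: int = 100_000, seed: int = 0,
                      tol: float = 5e-3, max_iter: int = 60):
    """Solve Weibull (shape, scale) so marginal placebo survival hits targets.

    ``targets`` maps time (months) to survival probability; the default is
    the calibration pair {12: 0.865, 18: 0.642}.  A 2-D root search on
    (log shape, log scale) drives Monte-Carlo marginal survival (common
    random numbers across iterations) to the targets.

    Returns ``(shape, scale)``; raises ``RuntimeError`` with the best
    residuals on failure.
    """
    if targets is None:
        targets = {12.0: 0.865, 18.0: 0.642}
    times = np.array(sorted(targets), dtype=float)
    goals = np.array([targets[t] for t in times])
    if not (np.all(np.diff(goals) < 0) and np.all((goals > 0) & (goals < 1))):
        raise ValueError("targets must be strictly decreasing survival probabilities in (0,1)")
    if len(times) != 2:
        raise ValueError("calibration expects exactly two targets")
    if mc_n < 10_000:
        raise ValueError("mc_n too small for a stable calibration")
    rng = np.random.default_rng(seed)
    b = _draw_random_effects(params, int(mc_n), rng)

    from dataclasses import replace as _replace

    def residuals(x):
        shape, scale = np.exp(x)
        p = _replace(params, weibull_shape=float(shape), weibull_scale=float(scale),
                     gamma=0.0, slope_reduction=0.0)
        s = marginal_survival(p, times, b=b)
        return s - goals

    x0 = np.log([params.weibull_shape, params.weibull_scale])
    sol = least_squares(residuals, x0, method="trf",
                        bounds=(np.log([0.2, 0.5]), np.log([15.0, 1000.0])),
                        xtol=1e-12, ftol=1e-14, gtol=1e-12, max_nfev=max_iter * 3)
    res = residuals(sol.x)
    if np.max(np.abs(res)) > tol:
        raise RuntimeError(
            f"Weibull calibration did not reach targets; residuals {res} at "
            f"shape/scale {np.exp(sol.x)}"
        )
    shape, scale = np.exp(sol.x)
    return float(shape), float(scale)
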