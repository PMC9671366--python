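"""Maximum-likelihood fitting of Poisson, CMP, ZIP and ZICMP regressions.

All four models share one likelihood machine.  Writing ``loglam = X @ beta``
(log link on the rate), ``nu = exp(S @ delta)`` (log link on dispersion,
fixed at 1 when the model has no dispersion part) and
``pi = expit(W @ gamma)`` (logit link on the structural-zero probability,
fixed at 0 when the model has no zero part), the per-observation
log-likelihood of the zero-inflated CMP is

    y  = 0:  log( pi + (1 - pi) / Z(lam, nu) )
    y  > 0:  log(1 - pi) + y*loglam - nu*log(y!) - log Z(lam, nu)

Poisson (nu = 1, pi = 0), CMP (pi = 0) and ZIP (nu = 1) are special cases.
Estimation is quasi-Newton (L-BFGS-B) on the unconstrained coefficient
scale with analytic gradients; standard errors come from the inverse of a
central-difference Hessian of the negative log-likelihood at the optimum.

Zero-part coefficients are bounded at +/-30 on the logit scale.  When the
data carry no excess zeros the likelihood is maximized as pi -> 0 and the
intercept drifts to the lower bound; such coefficients are flagged as
boundary estimates and their standard errors are unreliable (the classic
symptom is a hugely inflated SE on an insignificant zero-part intercept).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, gammaln, log_expit

from .design import DesignSet
from .distribution import DEFAULT_CONTROL, SeriesControl, series_stats

MODEL_KINDS = ("poisson", "cmp", "zip", "zicmp")

#: Hard bound for zero-part coefficients on the logit scale.
GAMMA_BOUND = 30.0
#: |gamma| beyond this is reported as a boundary estimate: the implied
#: structural-zero probability is below ~3e-7, indistinguishable from the
#: pi = 0 boundary at any realistic sample size.
BOUNDARY_FLAG_AT = 15.0


@dataclass
class FitOptions:
    """Optimizer policy: quasi-Newton with tight gradient/likelihood tolerances."""

    gtol: float = 1e-8
    ftol: float = 1e-13
    max_iter: int = 500


@dataclass
class FittedModel:
    """A fitted count regression: coefficients, SEs and fit statistics."""

    kind: str
    beta: np.ndarray
    delta: np.ndarray | None
    gamma: np.ndarray | None
    se_beta: np.ndarray
    se_delta: np.ndarray | None
    se_gamma: np.ndarray | None
    x_names: list[str]
    s_names: list[str]
    w_names: list[str]
    loglik: float
    aic: float
    n_params: int
    pearson: float
    converged: bool
    boundary_flags: dict = field(default_factory=dict)
    cov: np.ndarray | None = None
    message: str = ""

    @property
    def has_dispersion(self) -> bool:
        return self.delta is not None

    @property
    def has_zero_part(self) -> bool:
        return self.gamma is not None

    def coefficients(self) -> dict[str, dict[str, float]]:
        """Flat name -> estimate map, grouped by model part."""
        out = {"count": dict(zip(self.x_names, self.beta.tolist()))}
        if self.delta is not None:
            out["dispersion"] = dict(zip(self.s_names, self.delta.tolist()))
        if self.gamma is not None:
            out["zero"] = dict(zip(self.w_names, self.gamma.tolist()))
        return out


class RankDeficiencyError(ValueError):
    """A design matrix does not have full column rank."""


def _check_rank(mat: np.ndarray, names: list[str], part: str) -> None:
    if mat.shape[1] == 0:
        return
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # Identify offending columns via the smallest right singular vectors.
        _, s, vt = np.linalg.svd(mat, full_matrices=False)
        bad = vt[rank:]
        involved = sorted({names[j] for row in bad for j in np.flatnonzero(np.abs(row) > 1e-8)})
        raise RankDeficiencyError(
            f"{part} design matrix is rank deficient; collinear columns: {involved}"
        )


def _unique_stats(
    loglam: np.ndarray, nu: np.ndarray, control: SeriesControl
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(log Z, E[Y], E[log Y!]) per row, computed once per unique (lam, nu)."""
    key = np.column_stack([loglam, nu])
    uniq, inverse = np.unique(key, axis=0, return_inverse=True)
    log_z, ey, _, elf = series_stats(uniq[:, 0], uniq[:, 1], control)
    log_z = np.atleast_1d(log_z)
    ey = np.atleast_1d(ey)
    elf = np.atleast_1d(elf)
    return log_z[inverse], ey[inverse], elf[inverse]


def _make_objective(design: DesignSet, use_nu: bool, use_pi: bool, control: SeriesControl):
    y = design.y.astype(float)
    w = design.w
    lgy = gammaln(y + 1.0)
    X, S, W = design.X, design.S, design.W
    p = X.shape[1]
    q = S.shape[1] if use_nu else 0
    r = W.shape[1] if use_pi else 0
    zero = design.y == 0
    pos = ~zero

    def negloglik_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        beta = theta[:p]
        loglam = X @ beta
        if use_nu:
            delta = theta[p : p + q]
            nu = np.exp(S @ delta)
        else:
            nu = np.ones_like(loglam)
        log_z, ey, elf = _unique_stats(loglam, nu, control)
        ll = np.empty_like(loglam)
        g_loglam = np.empty_like(loglam)
        g_u = np.empty_like(loglam)  # derivative w.r.t. S @ delta
        # CMP body for positive counts (and for all counts when pi = 0)
        ll_cmp = y * loglam - nu * lgy - log_z
        g_loglam_cmp = y - ey
        g_u_cmp = nu * (elf - lgy)
        if use_pi:
            gamma = theta[p + q :]
            t = W @ gamma
            pi = expit(t)
            z_inv = np.exp(-log_z)
            # zero observations: L0 = pi + (1 - pi)/Z, stably on the log scale
            ll0 = np.logaddexp(log_expit(t), log_expit(-t) - log_z)
            l0 = pi + (1.0 - pi) * z_inv
            ll = np.where(zero, ll0, log_expit(-t) + ll_cmp)
            g_loglam = np.where(zero, -(1.0 - pi) * z_inv * ey / l0, g_loglam_cmp)
            g_u = np.where(zero, (1.0 - pi) * z_inv * elf * nu / l0, g_u_cmp)
            g_t = np.where(zero, (1.0 - z_inv) * pi * (1.0 - pi) / l0, -pi)
        else:
            ll = ll_cmp
            g_loglam = g_loglam_cmp
            g_u = g_u_cmp
        nll = -float(np.dot(w, ll))
        grads = [-(X.T @ (w * g_loglam))]
        if use_nu:
            grads.append(-(S.T @ (w * g_u)))
        if use_pi:
            grads.append(-(W.T @ (w * g_t)))
        return nll, np.concatenate(grads)

    return negloglik_grad, (p, q, r)


def _numerical_hessian(grad_fn, theta: np.ndarray) -> np.ndarray:
    """Central-difference Hessian of the negative log-likelihood."""
    k = len(theta)
    hess = np.empty((k, k))
    for j in range(k):
        h = 1e-5 * (1.0 + abs(theta[j]))
        up = theta.copy()
        dn = theta.copy()
        up[j] += h
        dn[j] -= h
        _, g_up = grad_fn(up)
        _, g_dn = grad_fn(dn)
        hess[:, j] = (g_up - g_dn) / (2.0 * h)
    return 0.5 * (hess + hess.T)


def _fit(
    kind: str,
    design: DesignSet,
    control: SeriesControl,
    options: FitOptions,
    start: dict | None = None,
) -> FittedModel:
    use_nu = kind in ("cmp", "zicmp")
    use_pi = kind in ("zip", "zicmp")
    _check_rank(design.X, design.x_names, "count")
    if use_nu:
        _check_rank(design.S, design.s_names, "dispersion")
    if use_pi:
        _check_rank(design.W, design.w_names, "zero")

    w = design.w
    ybar = float(np.dot(w, design.y)) / float(w.sum())
    if ybar <= 0.0:
        raise ValueError("all-zero outcome: the rate intercept log(mean) is undefined")
    if use_pi and not np.any(design.y == 0):
        pass  # no zeros: pi is driven to the boundary and flagged below
    if use_pi and np.all(design.y == 0):
        raise ValueError("all-zero outcome: zero-inflated models are unidentifiable")

    obj, (p, q, r) = _make_objective(design, use_nu, use_pi, control)

    # Initialization: beta from the Poisson fit, delta at 0, gamma at the
    # logit of the excess-zero fraction.
    if kind == "poisson":
        beta0 = np.zeros(p)
        beta0[0] = np.log(ybar)
    else:
        beta0 = fit_poisson(design, control=control, options=options).beta
    theta0 = [beta0]
    if use_nu:
        theta0.append(np.zeros(q))
    if use_pi:
        gamma0 = np.zeros(r)
        n0_frac = float(w[design.y == 0].sum()) / float(w.sum())
        p0_bar = float(np.dot(w, np.exp(-np.exp(design.X @ beta0)))) / float(w.sum())
        excess = max(n0_frac - p0_bar, 1e-3)
        gamma0[0] = np.log(excess / (1.0 - excess))
        theta0.append(gamma0)
    theta0 = np.concatenate(theta0)
    if start is not None:
        # User-supplied starting values override the defaults per part.
        if "beta" in start:
            theta0[:p] = np.asarray(start["beta"], dtype=float)
        if "delta" in start and use_nu:
            theta0[p : p + q] = np.asarray(start["delta"], dtype=float)
        if "gamma" in start and use_pi:
            theta0[p + q :] = np.asarray(start["gamma"], dtype=float)

    bounds = [(None, None)] * (p + q) + [(-GAMMA_BOUND, GAMMA_BOUND)] * r
    res = minimize(
        obj,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={
            "maxiter": options.max_iter,
            "ftol": options.ftol,
            "gtol": options.gtol,
            "maxfun": 50 * options.max_iter,
        },
    )
    theta = res.x
    converged = bool(res.success)
    if use_pi:
        # Deterministic boundary handling: once a zero-part coefficient has
        # drifted past the flag threshold the likelihood is flat in it, and
        # where L-BFGS-B stops depends on round-off.  Pin such components to
        # the bound exactly and re-optimize the remaining parameters.
        gamma_now = theta[p + q :]
        at_boundary = np.abs(gamma_now) >= BOUNDARY_FLAG_AT
        if np.any(at_boundary):
            trial = theta.copy()
            pinned = np.sign(gamma_now[at_boundary]) * GAMMA_BOUND
            trial[p + q :][at_boundary] = pinned
            refit_bounds = list(bounds)
            for idx, val in zip(np.flatnonzero(at_boundary), pinned):
                refit_bounds[p + q + idx] = (val, val)
            res_pin = minimize(
                obj, trial, jac=True, method="L-BFGS-B", bounds=refit_bounds,
                options={
                    "maxiter": options.max_iter,
                    "ftol": options.ftol,
                    "gtol": options.gtol,
                    "maxfun": 50 * options.max_iter,
                },
            )
            # Pinning is only valid when the likelihood really is flat in
            # the pinned direction(s); with several zero-part terms a large
            # coefficient can be offset by another, so keep the unpinned
            # optimum whenever pinning costs likelihood.
            if res_pin.fun <= res.fun + 1e-6:
                res = res_pin
                theta = res.x
                converged = converged and bool(res.success)
    loglik = -float(res.fun)

    hess = _numerical_hessian(obj, theta)
    cov = np.linalg.pinv(hess, hermitian=True)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    beta = theta[:p]
    delta = theta[p : p + q] if use_nu else None
    gamma = theta[p + q :] if use_pi else None
    boundary = {
        "beta": np.zeros(p, dtype=bool),
        "delta": np.zeros(q, dtype=bool) if use_nu else None,
        "gamma": (np.abs(gamma) >= BOUNDARY_FLAG_AT) if use_pi else None,
    }
    n_params = p + q + r
    fit = FittedModel(
        kind=kind,
        beta=beta,
        delta=delta,
        gamma=gamma,
        se_beta=se[:p],
        se_delta=se[p : p + q] if use_nu else None,
        se_gamma=se[p + q :] if use_pi else None,
        x_names=list(design.x_names),
        s_names=list(design.s_names) if use_nu else [],
        w_names=list(design.w_names) if use_pi else [],
        loglik=loglik,
        aic=-2.0 * loglik + 2.0 * n_params,
        n_params=n_params,
        pearson=float("nan"),
        converged=converged,
        boundary_flags=boundary,
        cov=cov,
        message=str(res.message),
    )
    mu = predict_mean(fit, design, control=control)
    fit.pearson = float(np.dot(w, (design.y - mu) ** 2 / mu))
    return fit


def fit_poisson(
    design: DesignSet,
    control: SeriesControl = DEFAULT_CONTROL,
    options: FitOptions | None = None,
    start: dict | None = None,
) -> FittedModel:
    """Poisson regression with log link; intercept-only reduces to log(mean)."""
    return _fit("poisson", design, control, options or FitOptions(), start)


def fit_cmp(
    design: DesignSet,
    control: SeriesControl = DEFAULT_CONTROL,
    options: FitOptions | None = None,
    start: dict | None = None,
) -> FittedModel:
    """CMP regression: joint ML over rate and dispersion coefficients."""
    return _fit("cmp", design, control, options or FitOptions(), start)


def fit_zip(
    design: DesignSet,
    control: SeriesControl = DEFAULT_CONTROL,
    options: FitOptions | None = None,
    start: dict | None = None,
) -> FittedModel:
    """Zero-inflated Poisson regression (logit zero part)."""
    return _fit("zip", design, control, options or FitOptions(), start)


def fit_zicmp(
    design: DesignSet,
    control: SeriesControl = DEFAULT_CONTROL,
    options: FitOptions | None = None,
    start: dict | None = None,
) -> FittedModel:
    """Zero-inflated CMP regression over (beta, delta, gamma)."""
    return _fit("zicmp", design, control, options or FitOptions(), start)


FITTERS = {
    "poisson": fit_poisson,
    "cmp": fit_cmp,
    "zip": fit_zip,
    "zicmp": fit_zicmp,
}


def predict_mean(
    fit: FittedModel,
    design: DesignSet,
    control: SeriesControl = DEFAULT_CONTROL,
) -> np.ndarray:
    """Per-row expected outcome under a fitted model.

    Poisson: ``exp(X beta)``; CMP and ZICMP use the exact series mean, the
    latter scaled by ``1 - pi``; ZIP is ``(1 - pi) * lam``.
    """
    if design.X.shape[1] != len(fit.beta):
        raise ValueError("count design does not match fitted coefficients")
    loglam = design.X @ fit.beta
    if fit.kind == "poisson":
        mean = np.exp(loglam)
    elif fit.kind in ("cmp", "zicmp"):
        if design.S.shape[1] != len(fit.delta):
            raise ValueError("dispersion design does not match fitted coefficients")
        nu = np.exp(design.S @ fit.delta)
        _, mean, _ = _unique_stats(loglam, nu, control)
    elif fit.kind == "zip":
        mean = np.exp(loglam)
    else:
        raise ValueError(f"unknown model kind {fit.kind!r}")
    if fit.kind in ("zip", "zicmp"):
        if design.W.shape[1] != len(fit.gamma):
            raise ValueError("zero design does not match fitted coefficients")
        mean = (1.0 - expit(design.W @ fit.gamma)) * mean
    return mean
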