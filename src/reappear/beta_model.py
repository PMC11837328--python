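"""Beta regression with logit link for burstiness.

Burstiness (maximum daily count over total count) lives in (0, 1]; the
beta law with mean mu and precision phi — shapes (mu*phi, (1-mu)*phi) —
is the standard likelihood for such proportions.  The mean is linked
through logit(mu_i) = eta_i with a fixed precision (no precision
covariates).  Observations exactly on the boundary (a single-day story
has burstiness 1.0) are handled by a configurable policy: reject, or
apply the usual (y*(n-1) + 0.5)/n shrinkage.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd
from scipy import special

from reappear.design import DesignSpec, build_design
from reappear.glm_base import (
    FitResult,
    fd_hessian,
    finish_wald,
    maximize,
    information_criteria,
    wald_from_information,
)

BOUNDARY_POLICIES = ("error", "shrink")


def apply_boundary_policy(y: np.ndarray, policy: str = "shrink") -> np.ndarray:
    """Map observations on {0, 1} strictly inside (0, 1), or reject them.

    The shrink transform y' = (y*(n-1) + 0.5)/n is applied to the whole
    vector only when boundary values actually occur.
    """
    y = np.asarray(y, dtype=float)
    if policy not in BOUNDARY_POLICIES:
        raise ValueError(f"unknown boundary policy {policy!r}")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("response outside [0, 1]")
    on_boundary = np.any((y == 0) | (y == 1))
    if not on_boundary:
        return y
    if policy == "error":
        raise ValueError("response on the boundary of (0, 1)")
    n = y.size
    return (y * (n - 1) + 0.5) / n


def beta_loglik(y, mu, phi: float) -> float:
    """Total beta log-likelihood at means ``mu`` and precision ``phi``."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("y must lie strictly inside (0, 1)")
    if np.any((mu <= 0) | (mu >= 1)):
        raise ValueError("mu must lie strictly inside (0, 1)")
    if not (np.isfinite(phi) and phi > 0):
        raise ValueError("phi must be finite and positive")
    a = mu * phi
    b = (1.0 - mu) * phi
    return float(np.sum(
        special.gammaln(phi) - special.gammaln(a) - special.gammaln(b)
        + (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y)
    ))


def _neg_ll_beta(params, X, y, logit_y, log1m_y):
    """Negative log-likelihood and gradient over (beta, log phi)."""
    beta, log_phi = params[:-1], params[-1]
    phi = math.exp(log_phi)
    eta = np.clip(X @ beta, -30.0, 30.0)
    mu = special.expit(eta)
    a = mu * phi
    b = (1.0 - mu) * phi
    log_y = logit_y + log1m_y  # log(y) = logit(y) + log(1-y)
    ll = np.sum(
        special.gammaln(phi) - special.gammaln(a) - special.gammaln(b)
        + (a - 1.0) * log_y + (b - 1.0) * log1m_y
    )
    # Ferrari & Cribari-Neto score equations
    ystar = logit_y
    mustar = special.digamma(a) - special.digamma(b)
    dmu = phi * (ystar - mustar)
    gbeta = X.T @ (dmu * mu * (1.0 - mu))
    dphi = np.sum(
        special.digamma(phi) - mu * special.digamma(a)
        - (1.0 - mu) * special.digamma(b)
        + mu * log_y + (1.0 - mu) * log1m_y
    )
    gphi = float(dphi) * phi
    grad = np.concatenate([gbeta, [gphi]])
    return -ll, -grad


def fit_beta(metrics: pd.DataFrame, design: DesignSpec,
             response: str = "burstiness",
             boundary_policy: str = "shrink",
             start: Optional[np.ndarray] = None) -> FitResult:
    """MLE beta regression of ``response`` on the rating design.

    Start values: logit-transformed least squares for the coefficients
    and a method-of-moments precision; optimization is quasi-Newton over
    (beta, log phi).
    """
    if metrics.shape[0] < design.k_design + 1:
        raise ValueError("not enough rows for this design")
    y = apply_boundary_policy(metrics[response].to_numpy(), boundary_policy)
    X, names = build_design(metrics[design.predictor].to_numpy(), design)
    logit_y = special.logit(y)
    log1m_y = np.log1p(-y)
    if start is None:
        coef, *_ = np.linalg.lstsq(X, logit_y, rcond=None)
        mu0 = special.expit(X @ coef)
        resid_var = float(np.var(y - mu0))
        mv = float(np.mean(mu0 * (1.0 - mu0)))
        phi0 = max(mv / max(resid_var, 1e-8) - 1.0, 0.5)
        x0 = np.concatenate([coef, [math.log(phi0)]])
    else:
        x0 = np.asarray(start, dtype=float)
    nll = lambda p: _neg_ll_beta(p, X, y, logit_y, log1m_y)
    bounds = [(None, None)] * (len(x0) - 1) + [(-10.0, 15.0)]
    sol, logL, conv = maximize(nll, x0, bounds=bounds)
    phi = math.exp(sol[-1])
    H = fd_hessian(lambda p: -nll(p)[1], sol)
    n = y.size
    aic, aicc, bic = information_criteria(logL, len(sol), n)
    se = wald_from_information(-H, len(sol) - 1)
    z, p = finish_wald(sol[:-1], se)
    return FitResult(
        model_family="beta", design=design, beta=sol[:-1], aux=phi,
        logL=logL, k=len(sol), n=n, aic=aic, aicc=aicc, bic=bic,
        se=se, z=z, p=p, converged=conv, coef_names=list(names),
        aux_name="phi",
    )
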