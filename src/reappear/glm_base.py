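"""Shared maximum-likelihood machinery for the regression families.

All families are estimated by quasi-Newton maximization of the exact
log-likelihood over an unconstrained parameterization (regression
coefficients plus the log of any positive auxiliary parameter).
Standard errors come from the inverse observed information, with the
Hessian obtained by central finite differences of the analytic
gradient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import optimize

#: gradient infinity-norm at which a solution counts as converged
GRAD_TOL = 1e-8

#: number of jittered restarts attempted when the first start fails
N_RESTARTS = 3


@dataclass
class FitResult:
    """A single fitted model: estimates, uncertainty and fit diagnostics."""

    model_family: str
    design: object
    beta: np.ndarray
    aux: Optional[float]            # dispersion theta / precision phi / None
    logL: float
    k: int                          # parameter count incl. auxiliary
    n: int
    aic: float
    aicc: float
    bic: float
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    converged: bool
    coef_names: list = field(default_factory=list)
    aux_name: Optional[str] = None
    extra: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"{self.model_family} fit ({getattr(self.design, 'structure', '?')}), "
            f"n={self.n}, k={self.k}, converged={self.converged}",
            f"logL={self.logL:.4f}  AIC={self.aic:.4f}  AICc={self.aicc:.4f}  "
            f"BIC={self.bic:.4f}",
            f"{'coef':<12}{'estimate':>12}{'se':>12}{'z':>10}{'p':>12}",
        ]
        for i, name in enumerate(self.coef_names):
            lines.append(
                f"{name:<12}{self.beta[i]:>12.4f}{self.se[i]:>12.4f}"
                f"{self.z[i]:>10.3f}{self.p[i]:>12.4g}"
            )
        if self.aux is not None:
            lines.append(f"{self.aux_name or 'aux':<12}{self.aux:>12.4f}")
        return "\n".join(lines)


def information_criteria(logL: float, k: int, n: int) -> tuple[float, float, float]:
    """(AIC, AICc, BIC) from a log-likelihood, parameter count and sample size."""
    aic = 2.0 * k - 2.0 * logL
    denom = n - k - 1
    aicc = aic + (2.0 * k * (k + 1) / denom) if denom > 0 else math.inf
    bic = k * math.log(n) - 2.0 * logL
    return aic, aicc, bic


def maximize(
    negloglik_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    x0: np.ndarray,
    bounds: Optional[list] = None,
    rng: Optional[np.random.Generator] = None,
    jitter: float = 0.3,
    maxiter: int = 500,
) -> tuple[np.ndarray, float, bool]:
    """Bounded quasi-Newton (L-BFGS-B) maximization with jittered restarts.

    ``negloglik_grad`` returns the negative log-likelihood and its
    gradient.  Returns (solution, logL, converged); converged means the
    (projected) gradient infinity-norm fell below a practical tolerance
    at the best solution.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    best = None
    starts = [np.asarray(x0, dtype=float)]
    for attempt, start in enumerate(starts):
        res = optimize.minimize(
            negloglik_grad, start, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"gtol": GRAD_TOL, "maxiter": maxiter, "ftol": 1e-14},
        )
        # restarting L-BFGS-B resets its Hessian memory and often
        # polishes the last digits after an ftol stop
        res2 = optimize.minimize(
            negloglik_grad, res.x, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"gtol": GRAD_TOL, "maxiter": maxiter, "ftol": 1e-16},
        )
        if res2.fun <= res.fun:
            res = res2
        _, g = negloglik_grad(res.x)
        if bounds is not None:
            # project the gradient at active bounds
            g = np.array(g, dtype=float)
            for j, b in enumerate(bounds):
                if b is None:
                    continue
                lo, hi = b
                if lo is not None and res.x[j] <= lo + 1e-12 and g[j] > 0:
                    g[j] = 0.0
                if hi is not None and res.x[j] >= hi - 1e-12 and g[j] < 0:
                    g[j] = 0.0
        # practical convergence: gradient small relative to the
        # log-likelihood scale
        ok = bool(np.max(np.abs(g)) < 1e-4 * max(1.0, abs(res.fun)))
        cand = (res.fun, res.x, ok)
        if best is None or cand[0] < best[0]:
            best = cand
        if best[2]:
            break
        if attempt < N_RESTARTS:
            starts.append(start + rng.normal(scale=jitter, size=start.shape))
    fun, x, conv = best
    return x, -fun, conv


def fd_hessian(grad: Callable[[np.ndarray], np.ndarray], x: np.ndarray,
               eps: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian from an analytic gradient; symmetrized."""
    x = np.asarray(x, dtype=float)
    p = x.size
    H = np.empty((p, p))
    for j in range(p):
        h = eps * max(1.0, abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        H[:, j] = (grad(xp) - grad(xm)) / (2.0 * h)
    return 0.5 * (H + H.T)


def wald_from_information(neg_hessian: np.ndarray, n_beta: int) -> np.ndarray:
    """Standard errors of the first ``n_beta`` parameters.

    ``neg_hessian`` is the observed information (negative Hessian of the
    log-likelihood over the full unconstrained parameter vector).
    Singular information yields NaN standard errors rather than a crash.
    """
    try:
        cov = np.linalg.inv(neg_hessian)
        var = np.diag(cov)[:n_beta].copy()
        var[var < 0] = np.nan
        se = np.sqrt(var)
    except np.linalg.LinAlgError:
        se = np.full(n_beta, np.nan)
    return se


def finish_wald(beta: np.ndarray, se: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """z statistics and two-sided normal p-values."""
    from scipy import stats

    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return z, p


def pseudo_r2(fit: FitResult, null_fit: FitResult) -> tuple[float, float]:
    """(Cox–Snell, McFadden) pseudo-R² of ``fit`` against the null model.

    Cox–Snell: 1 − exp(2(logL0 − logL)/n).  McFadden: 1 − logL/logL0.
    Both models must come from the same family fitted to the same rows.
    """
    if fit.model_family != null_fit.model_family:
        raise ValueError("pseudo_r2 requires fits from the same family")
    if fit.n != null_fit.n:
        raise ValueError(f"row-count mismatch: {fit.n} vs {null_fit.n}")
    cox_snell = 1.0 - math.exp(2.0 * (null_fit.logL - fit.logL) / fit.n)
    mcfadden = 1.0 - fit.logL / null_fit.logL
    return cox_snell, mcfadden
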