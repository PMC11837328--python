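"""AIC-based comparison of the rating-polynomial model family.

Four structures are compared per response family: null (intercept),
linear ("falsehood"), constrained quadratic ("ambiguity") and
unconstrained quadratic ("dual effect").  Evidence is summarized by
pairwise AIC differences, relative likelihoods and, for nested pairs,
likelihood-ratio tests; the winner is the lowest-AIC model, annotated
as unsupported when the runner-up sits within a delta-AIC of 2.

The relative likelihood RL(A, B) = exp((AIC_B - AIC_A)/2) states how
many times model A is as likely as model B given the data; RL > 1 iff
A has the lower AIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from reappear.beta_model import fit_beta
from reappear.count_models import fit_truncated_poisson, fit_ztnb
from reappear.design import DesignSpec
from reappear.glm_base import FitResult, pseudo_r2

#: the four structures of the main comparison, in table order
FAMILY_STRUCTURES = (
    ("null", "intercept"),
    ("falsehood", "linear"),
    ("ambiguity", "quadratic_constrained"),
    ("dual", "quadratic_unconstrained"),
)

AIC_NO_SUPPORT = 2.0

_FITTERS = {
    "ztnb": fit_ztnb,
    "poisson_truncated": fit_truncated_poisson,
    "beta": fit_beta,
}

_DEFAULT_RESPONSE = {
    "ztnb": "peak_frequency",
    "poisson_truncated": "peak_frequency",
    "beta": "burstiness",
}


def relative_likelihood(aic_a: float, aic_b: float) -> float:
    """How many times model A is as likely as model B, from their AICs."""
    return math.exp((aic_b - aic_a) / 2.0)


def lr_test(fit_restricted: FitResult, fit_full: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested pair: (chi2, df, p)."""
    if fit_restricted.model_family != fit_full.model_family:
        raise ValueError("LRT requires fits from the same family")
    if fit_restricted.n != fit_full.n:
        raise ValueError("LRT requires fits to the same rows")
    dr, df_ = fit_restricted.design, fit_full.design
    if not dr.is_nested_in(df_):
        raise ValueError(
            f"designs {dr.structure!r} and {df_.structure!r} are not nested; "
            "compare them by relative likelihood instead"
        )
    chi2 = max(0.0, 2.0 * (fit_full.logL - fit_restricted.logL))
    dof = fit_full.k - fit_restricted.k
    p = float(stats.chi2.sf(chi2, dof)) if dof > 0 else float(chi2 <= 0)
    return chi2, dof, p


@dataclass
class ComparisonTable:
    """Machine form of a four-model comparison for one response family."""

    family: str
    response: str
    fits: dict                      # model name -> FitResult
    pseudo_r2: dict                 # model name -> (cox_snell, mcfadden)
    delta_aic: pd.DataFrame         # AIC[row] - AIC[col]
    rl: pd.DataFrame                # RL of row model vs col model
    lrt: dict                       # (restricted, full) -> (chi2, df, p)
    best_model: str
    no_support: bool                # runner-up within AIC_NO_SUPPORT
    flagged: list = field(default_factory=list)  # non-converged members

    @property
    def model_names(self) -> list:
        return list(self.fits.keys())

    def to_frame(self) -> pd.DataFrame:
        """Flat per-model table (Tables-3/4 shape, full precision)."""
        rows = []
        for name, fit in self.fits.items():
            coefs = {c: v for c, v in zip(fit.coef_names, fit.beta)}
            ses = {f"se_{c}": v for c, v in zip(fit.coef_names, fit.se)}
            ps = {f"p_{c}": v for c, v in zip(fit.coef_names, fit.p)}
            cs, mcf = self.pseudo_r2[name]
            rows.append({
                "model": name, **coefs, **ses, **ps,
                "aux": fit.aux, "r2_cox_snell": cs, "r2_mcfadden": mcf,
                "logL": fit.logL, "AIC": fit.aic, "AICc": fit.aicc,
                "BIC": fit.bic, "converged": fit.converged,
                **{f"RL_vs_{other}": self.rl.loc[name, other]
                   for other in self.model_names if other != name},
            })
        return pd.DataFrame(rows)


def _fit_member(metrics: pd.DataFrame, family: str, structure: str,
                orthogonal: bool, response: str) -> FitResult:
    spec = DesignSpec(structure=structure, orthogonal=orthogonal)
    return _FITTERS[family](metrics, spec, response=response)


def compare_family(metrics: pd.DataFrame, family: str,
                   response: Optional[str] = None,
                   orthogonal: bool = False) -> ComparisonTable:
    """Fit the four model structures and fill all pairwise statistics."""
    if family not in _FITTERS:
        raise ValueError(f"unknown family {family!r}")
    if response is None:
        response = _DEFAULT_RESPONSE[family]

    fits: dict[str, FitResult] = {}
    flagged = []
    for name, structure in FAMILY_STRUCTURES:
        fit = _fit_member(metrics, family, structure, orthogonal, response)
        fits[name] = fit
        if not fit.converged:
            flagged.append(name)

    names = [n for n, _ in FAMILY_STRUCTURES]
    null_fit = fits["null"]
    r2 = {n: pseudo_r2(fits[n], null_fit) for n in names}

    aics = {n: fits[n].aic for n in names}
    delta = pd.DataFrame(
        [[aics[a] - aics[b] for b in names] for a in names],
        index=names, columns=names,
    )
    rl = pd.DataFrame(
        [[relative_likelihood(aics[a], aics[b]) for b in names] for a in names],
        index=names, columns=names,
    )
    lrt = {}
    for a in names:
        for b in names:
            if a == b:
                continue
            if fits[a].design.is_nested_in(fits[b].design):
                lrt[(a, b)] = lr_test(fits[a], fits[b])

    order = sorted(names, key=lambda n: aics[n])
    best = order[0]
    no_support = (aics[order[1]] - aics[best]) <= AIC_NO_SUPPORT
    return ComparisonTable(
        family=family, response=response, fits=fits, pseudo_r2=r2,
        delta_aic=delta, rl=rl, lrt=lrt, best_model=best,
        no_support=no_support, flagged=flagged,
    )


def dichotomous_effects(metrics: pd.DataFrame, family: str = "ztnb",
                        response: Optional[str] = None) -> dict:
    """Falsehood and ambiguity effects as binary contrasts.

    Falsehood: false stories (rating -2, -1) vs true (1, 2), excluding
    rating-0 stories.  Ambiguity: ambiguous (-1, 0, 1) vs unambiguous
    (-2, 2), all stories.  The effect estimate is exp(coefficient) of
    the binary indicator — a rate ratio for count families, an
    odds-scale ratio for the beta family — with delta-method SE.
    """
    if response is None:
        response = _DEFAULT_RESPONSE[family]
    out = {}
    contrasts = {
        "falsehood": (metrics["rating"] != 0,
                      metrics["rating"] < 0),
        "ambiguity": (pd.Series(True, index=metrics.index),
                      metrics["rating"].isin([-1, 0, 1])),
    }
    for name, (keep, indicator) in contrasts.items():
        sub = metrics.loc[keep].copy()
        flag = indicator.loc[keep].astype(int)
        if flag.nunique() < 2 or (flag == 1).sum() < 2 or (flag == 0).sum() < 2:
            raise ValueError(f"contrast {name!r} needs >= 2 stories per group")
        sub["rating"] = flag.to_numpy()  # reuse the linear design on 0/1
        spec = DesignSpec(structure="linear")
        fit = _FITTERS[family](sub, spec, response=response)
        coef, se = float(fit.beta[1]), float(fit.se[1])
        ratio = math.exp(coef)
        out[name] = {
            "ratio": ratio,
            "se_ratio": ratio * se,      # delta method
            "coef": coef, "se_coef": se,
            "p": float(fit.p[1]), "n": fit.n,
        }
    out["falsehood_ratio"] = out["falsehood"]["ratio"]
    out["ambiguity_ratio"] = out["ambiguity"]["ratio"]
    return out
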