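"""Robustness suite: orthogonal polynomials, permutation inference,
sensitivity grids and a temporal median-split check.

Permutation inference permutes the rating column uniformly at random
(responses fixed), refits the model, and compares the observed Wald z
of each coefficient against the permutation null of |z|; the p-value
uses the add-one convention (1 + #exceedances)/(B + 1).  Sensitivity
grids recompute the full metrics -> comparison pipeline per parameter
cell and summarize the stability of the linear and quadratic effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from reappear.beta_model import fit_beta
from reappear.count_models import fit_truncated_poisson, fit_ztnb
from reappear.design import DesignSpec, orthogonal_poly
from reappear.glm_base import FitResult
from reappear.ingest import DailySeries
from reappear.metrics import PeakParams, compute_metrics
from reappear.selection import ComparisonTable, compare_family

_FITTERS = {"ztnb": fit_ztnb, "poisson_truncated": fit_truncated_poisson,
            "beta": fit_beta}
_DEFAULT_RESPONSE = {"ztnb": "peak_frequency",
                     "poisson_truncated": "peak_frequency",
                     "beta": "burstiness"}

#: fraction of failed permutation refits that invalidates a run
MAX_REFIT_FAILURES = 0.05

#: grid cells need at least this many surviving stories to be fitted
MIN_STORIES_PER_CELL = 10


def orthogonalize(ratings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal linear and quadratic rating contrasts.

    Weighted Gram–Schmidt against the empirical rating distribution
    (QR of the Vandermonde matrix): both columns have zero mean, unit
    norm and zero dot product.  Needs >= 3 distinct rating values.
    """
    P = orthogonal_poly(np.asarray(ratings, dtype=float), 2)
    return P[:, 0], P[:, 1]


@dataclass
class PermutationResult:
    """Permutation null for one coefficient."""

    coefficient: str
    observed_z: float
    null_z: np.ndarray
    p_perm: float
    B: int
    seed: int
    n_failures: int = 0

    def __post_init__(self):
        expected = (1 + int(np.sum(np.abs(self.null_z) >= abs(self.observed_z)))) / (
            len(self.null_z) + 1
        )
        # keep the stored p consistent with its definition
        assert math.isclose(self.p_perm, expected), "inconsistent permutation p"


def permutation_test(metrics: pd.DataFrame, family: str, design: DesignSpec,
                     B: int = 10_000, seed: int = 0,
                     response: Optional[str] = None
                     ) -> dict[str, PermutationResult]:
    """Permutation test per coefficient: rating permuted B times,
    responses fixed, model refit each time; two-sided p from |z|
    exceedances.  Refit failures are counted; above 5% the run raises.
    """
    if B < 99:
        raise ValueError("B must be >= 99")
    if response is None:
        response = _DEFAULT_RESPONSE[family]
    fitter = _FITTERS[family]
    rng = np.random.default_rng(seed)

    observed = fitter(metrics, design, response=response)
    warm = np.concatenate([
        observed.beta,
        [] if observed.aux is None else [math.log(observed.aux)],
    ])
    names = observed.coef_names
    null_z = {c: [] for c in names}
    failures = {c: 0 for c in names}
    perm = metrics.copy()
    ratings = metrics[design.predictor].to_numpy()
    for _ in range(B):
        perm[design.predictor] = rng.permutation(ratings)
        try:
            fit = fitter(perm, design, response=response, start=warm)
        except Exception:
            for c in names:
                failures[c] += 1
            continue
        # a singular information matrix can void single coefficients
        for c, zval in zip(names, fit.z):
            if np.isfinite(zval):
                null_z[c].append(float(zval))
            else:
                failures[c] += 1
    bad = {c: f for c, f in failures.items() if f > MAX_REFIT_FAILURES * B}
    if bad:
        raise RuntimeError(
            f"permutation refit failures above {MAX_REFIT_FAILURES:.0%} "
            f"of B={B}: {bad}; run invalidated"
        )
    out = {}
    for i, c in enumerate(names):
        nz = np.asarray(null_z[c])
        p = (1 + int(np.sum(np.abs(nz) >= abs(observed.z[i])))) / (len(nz) + 1)
        out[c] = PermutationResult(
            coefficient=c, observed_z=float(observed.z[i]), null_z=nz,
            p_perm=p, B=B, seed=seed, n_failures=failures[c],
        )
    return out


@dataclass
class SensitivityGrid:
    """Per-cell comparison summaries over a parameter grid."""

    varied: list
    cells: pd.DataFrame             # one row per cell: params + summary
    summary: dict = field(default_factory=dict)


def sensitivity_sweep(corpus: Iterable[DailySeries], ratings: dict[str, int],
                      grid: dict[str, list], family: str = "ztnb",
                      response: Optional[str] = None,
                      base_params: Optional[PeakParams] = None,
                      min_tweets: int = 0) -> SensitivityGrid:
    """Recompute metrics and the four-model comparison over a grid.

    ``grid`` maps any of {min_height_frac, min_distance_days,
    min_tweets} to lists of values.  Cells with fewer than 10 surviving
    stories are marked unusable, not fitted.  The summary reports how
    often the linear and quadratic coefficients of the dual model are
    significant (p < 0.05) and sign-stable across usable cells.
    """
    corpus = list(corpus)
    if base_params is None:
        base_params = PeakParams()
    allowed = {"min_height_frac", "min_distance_days", "min_tweets"}
    unknown = set(grid) - allowed
    if unknown:
        raise ValueError(f"cannot sweep over {sorted(unknown)}")
    keys = sorted(grid)
    rows = []
    for values in product(*(grid[k] for k in keys)):
        cell = dict(zip(keys, values))
        params = PeakParams(
            min_height_frac=cell.get("min_height_frac", base_params.min_height_frac),
            min_distance_days=cell.get("min_distance_days",
                                       base_params.min_distance_days),
            neighbor_window=base_params.neighbor_window,
            mode=base_params.mode,
        )
        threshold = cell.get("min_tweets", min_tweets)
        kept = [s for s in corpus if s.n_tweets >= threshold]
        row = dict(cell)
        row["n_stories"] = len(kept)
        if len(kept) < MIN_STORIES_PER_CELL:
            row["usable"] = False
            rows.append(row)
            continue
        metrics = compute_metrics(kept, ratings, params)
        table = compare_family(metrics, family, response=response)
        dual = table.fits["dual"]
        idx = {n: i for i, n in enumerate(dual.coef_names)}
        row.update({
            "usable": True,
            "best_model": table.best_model,
            "no_support": table.no_support,
            "beta1": float(dual.beta[idx["beta1"]]),
            "p_beta1": float(dual.p[idx["beta1"]]),
            "beta2": float(dual.beta[idx["beta2"]]),
            "p_beta2": float(dual.p[idx["beta2"]]),
        })
        rows.append(row)
    cells = pd.DataFrame(rows)
    usable = cells[cells["usable"]] if "usable" in cells else cells
    summary = {}
    if len(usable):
        summary = {
            "n_cells": int(len(cells)),
            "n_usable": int(len(usable)),
            "frac_linear_sig": float((usable["p_beta1"] < 0.05).mean()),
            "frac_quadratic_sig": float((usable["p_beta2"] < 0.05).mean()),
            "linear_sign_stable": bool(
                (np.sign(usable["beta1"]) == np.sign(usable["beta1"].iloc[0])).all()
            ),
            "quadratic_sign_stable": bool(
                (np.sign(usable["beta2"]) == np.sign(usable["beta2"].iloc[0])).all()
            ),
        }
    return SensitivityGrid(varied=keys, cells=cells, summary=summary)


def temporal_split_check(metrics: pd.DataFrame,
                         families: tuple = (("ztnb", "peak_frequency"),
                                            ("beta", "burstiness"))) -> dict:
    """Median split on story onset; each response is modelled on a
    binary late-half indicator to screen for temporal drift.

    Degenerate splits (all onsets equal, or an empty half) return a
    warning instead of fits.
    """
    if "onset_day" not in metrics.columns:
        raise ValueError("metrics table lacks an onset_day column")
    onset = pd.to_datetime(metrics["onset_day"])
    median = onset.median()
    late = (onset > median).astype(int)
    report: dict = {"median_onset": str(median.date()),
                    "n_early": int((late == 0).sum()),
                    "n_late": int((late == 1).sum())}
    if late.nunique() < 2:
        report["warning"] = "degenerate split: all stories fall in one half"
        return report
    sub = metrics.copy()
    sub["rating"] = late.to_numpy()   # 0/1 indicator through the linear design
    spec = DesignSpec(structure="linear")
    for family, response in families:
        fit = _FITTERS[family](sub, spec, response=response)
        report[response] = {
            "coef_late": float(fit.beta[1]),
            "se": float(fit.se[1]),
            "z": float(fit.z[1]),
            "p": float(fit.p[1]),
            "family": family,
        }
    return report
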