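"""Synthetic story corpora with known falsehood/ambiguity effects.

Two levels of generation:

* **direct mode** draws the modelling rows themselves: peak frequency
  from a zero-truncated negative binomial whose log-mean is the rating
  polynomial beta0 + beta1*x + beta2*x^2, and burstiness from a beta
  law whose logit-mean is an analogous polynomial.  This is the
  generative inverse of the fitted models and drives the parameter-
  recovery checks.

* **timeseries mode** plants bursts in raw daily tweet-count series so
  the full pipeline (binning -> peak detection -> burstiness -> fits)
  can be exercised end to end.  The number of bursts per story is a
  ZTNB draw from the same rating polynomial; burst days respect a
  minimum separation of twice the detector's distance criterion, each
  burst is a discretized log-normal day profile whose peak height is at
  least 25% of the story's tallest burst, and background days are
  low-rate Poisson noise — so planted bursts are detectable by
  construction.

ZTNB sampling uses the exact inverse CDF of the truncated law (not
naive rejection), keeping tails correct at small means.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import special, stats

from reappear.ingest import DailySeries

#: rating split of the emulated corpus: 92 false, 9 mixed, 22 true
DEFAULT_COUNTS_PER_RATING = {-2: 92, -1: 0, 0: 9, 1: 0, 2: 22}

_EPOCH = _dt.date(1970, 1, 1)
#: onset window of the emulated corpus (early 2016 to mid 2022)
_ONSET_LO = (_dt.date(2016, 2, 1) - _EPOCH).days
_ONSET_HI = (_dt.date(2022, 8, 1) - _EPOCH).days


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a synthetic corpus."""

    counts_per_rating: dict = field(
        default_factory=lambda: dict(DEFAULT_COUNTS_PER_RATING))
    # defaults emulate the study corpus: marginal peak-frequency mean
    # near 3 with strong overdispersion, burstiness mean near 0.4
    beta_count: tuple = (math.log(2.8), -0.1, -0.1)  # log-link polynomial
    theta: float = 1.2                        # ZTNB dispersion
    beta_burst: tuple = (-0.5, 0.05, 0.05)    # logit-link polynomial
    phi: float = 4.0                          # beta precision
    mode: str = "direct"
    # timeseries-mode parameters
    duration_days: tuple = (60, 400)
    burst_separation: int = 14                # >= 2 x detector min distance
    kernel_sigma: float = 0.6                 # log-normal day-profile shape
    kernel_scale: float = 3.0                 # log-normal median, days
    kernel_support: int = 10                  # burst length, days
    background_rate: float = 2.0              # Poisson tweets/day off-burst
    height_range: tuple = (150.0, 600.0)      # tallest-burst peak height
    secondary_height_frac: float = 0.25       # others >= this frac of tallest
    seed: Optional[int] = None

    def validate(self) -> None:
        if any(c < 0 for c in self.counts_per_rating.values()):
            raise ValueError("story counts must be nonnegative")
        if sum(self.counts_per_rating.values()) == 0:
            raise ValueError("corpus is empty")
        if not set(self.counts_per_rating) <= {-2, -1, 0, 1, 2}:
            raise ValueError("ratings must lie on the five-level scale")
        if self.theta <= 0 or self.phi <= 0:
            raise ValueError("theta and phi must be positive")
        if self.mode not in ("direct", "timeseries"):
            raise ValueError("mode must be 'direct' or 'timeseries'")
        if self.burst_separation < 1 or self.kernel_support < 1:
            raise ValueError("separation and kernel support must be >= 1")
        if not 0 < self.secondary_height_frac <= 1:
            raise ValueError("secondary_height_frac must lie in (0, 1]")


def _ratings_vector(config: SyntheticConfig) -> np.ndarray:
    out = []
    for rating in sorted(config.counts_per_rating):
        out.extend([rating] * config.counts_per_rating[rating])
    return np.asarray(out, dtype=int)


def _poly(beta: tuple, x: np.ndarray) -> np.ndarray:
    b0, b1, b2 = beta
    return b0 + b1 * x + b2 * x * x


def ztnb_rvs(mu: np.ndarray, theta: float, rng: np.random.Generator) -> np.ndarray:
    """Exact inverse-CDF draws from the zero-truncated NB(mu, theta)."""
    mu = np.asarray(mu, dtype=float)
    p = theta / (theta + mu)
    p0 = p**theta
    u = rng.uniform(size=mu.shape)
    q = p0 + u * (1.0 - p0)          # uniform on (P(0), 1)
    y = stats.nbinom.ppf(q, theta, p)
    return np.maximum(y, 1.0).astype(int)


def _onsets(n: int, rng: np.random.Generator) -> list:
    days = rng.integers(_ONSET_LO, _ONSET_HI, size=n)
    return [_EPOCH + _dt.timedelta(days=int(d)) for d in days]


def draw_story_metrics(config: SyntheticConfig,
                       rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Direct-mode StoryMetrics table: one ZTNB count and one beta
    burstiness draw per story from the rating polynomials."""
    config.validate()
    if config.mode != "direct":
        raise ValueError("draw_story_metrics requires mode='direct'")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    x = _ratings_vector(config)
    n = x.size
    mu_c = np.exp(_poly(config.beta_count, x.astype(float)))
    y = ztnb_rvs(mu_c, config.theta, rng)
    mu_b = special.expit(_poly(config.beta_burst, x.astype(float)))
    b = rng.beta(mu_b * config.phi, (1.0 - mu_b) * config.phi)
    b = np.clip(b, 1e-12, 1.0 - 1e-12)   # guard exact float boundaries
    return pd.DataFrame({
        "story_id": [f"s{i:04d}" for i in range(n)],
        "rating": x,
        "peak_frequency": y,
        "burstiness": b,
        "onset_day": _onsets(n, rng),
    })


def _burst_kernel(config: SyntheticConfig) -> tuple[np.ndarray, int]:
    """Discretized unimodal log-normal day profile, peak weight 1.
    Returns (weights, index of the mode within the kernel)."""
    t = np.arange(1, config.kernel_support + 1, dtype=float)
    w = stats.lognorm.pdf(t, s=config.kernel_sigma, scale=config.kernel_scale)
    w = w / w.max()
    return w, int(np.argmax(w))


def _place_bursts(m: int, duration: int, lo: int, hi: int, sep: int,
                  rng: np.random.Generator) -> Optional[np.ndarray]:
    """m sorted burst-centre days in [lo, hi] with pairwise gaps >= sep,
    uniform over all feasible sets; None when infeasible."""
    span = hi - lo + 1 - (m - 1) * (sep - 1)
    if span < m:
        return None
    picks = np.sort(rng.choice(span, size=m, replace=False))
    return lo + picks + np.arange(m) * (sep - 1)


def draw_story_series(config: SyntheticConfig,
                      rng: Optional[np.random.Generator] = None,
                      max_retries: int = 20
                      ) -> tuple[list[DailySeries], pd.DataFrame]:
    """Timeseries-mode corpus: per-story daily series with planted
    bursts, plus the ground truth (planted burst count per story)."""
    config.validate()
    if config.mode != "timeseries":
        raise ValueError("draw_story_series requires mode='timeseries'")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    x = _ratings_vector(config)
    mu_c = np.exp(_poly(config.beta_count, x.astype(float)))
    m_planted = ztnb_rvs(mu_c, config.theta, rng)
    kernel, mode_idx = _burst_kernel(config)
    L = kernel.size
    onsets = _onsets(x.size, rng)

    series_list: list[DailySeries] = []
    truth_rows = []
    for i, (rating, m) in enumerate(zip(x, m_planted)):
        m = int(m)
        centres = None
        duration = None
        for _ in range(max_retries):
            duration = int(rng.integers(config.duration_days[0],
                                        config.duration_days[1] + 1))
            lo = mode_idx
            hi = duration - (L - mode_idx)
            if hi < lo:
                continue
            centres = _place_bursts(m, duration, lo, hi,
                                    config.burst_separation, rng)
            if centres is not None:
                break
        if centres is None:
            raise RuntimeError(
                f"cannot place {m} bursts separated by "
                f"{config.burst_separation} days within "
                f"{config.duration_days} days"
            )
        h_max = rng.uniform(*config.height_range)
        heights = rng.uniform(config.secondary_height_frac, 1.0, size=m) * h_max
        heights[rng.integers(m)] = h_max        # the tallest burst
        counts = rng.poisson(config.background_rate, size=duration).astype(float)
        for c, h in zip(centres, heights):
            start = c - mode_idx
            counts[start:start + L] += np.round(h * kernel)
        counts = counts.astype(int)
        nz = np.nonzero(counts)[0]
        counts = counts[nz[0]:nz[-1] + 1]
        series = DailySeries(story_id=f"s{i:04d}", onset_day=onsets[i],
                             counts=counts)
        series_list.append(series)
        truth_rows.append({
            "story_id": series.story_id, "rating": int(rating),
            "m_planted": m, "duration": duration,
            "n_tweets": series.n_tweets,
        })
    return series_list, pd.DataFrame(truth_rows)


def paper_shaped_corpus(seed: int = 0) -> pd.DataFrame:
    """Convenience preset: 123 stories split 92/9/22 across ratings
    -2/0/2 with parameters chosen so the marginal peak-frequency mean
    is about 3 and the marginal burstiness mean about 0.4 — a fixture
    for demos and golden-file tests, not a claim of equivalence to any
    real corpus."""
    return draw_story_metrics(SyntheticConfig(mode="direct", seed=seed))
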