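"""Response variables: peak frequency and burstiness of a daily series.

Peak frequency counts local maxima of the daily tweet-count series that
(i) reach at least 10% of the series maximum and (ii) lie at least 7
days from every other retained peak.  Burstiness is the maximum daily
count divided by the total count, in (0, 1]; 1 means all activity fell
on one day.  The two are strongly negatively correlated: many peaks
imply dispersed activity.

Two detection modes are provided.  ``greedy_prune`` (default) mirrors
the behaviour of general-purpose peak finders: candidate local maxima
(plateau midpoints; boundary maxima count, since an out-of-range
neighbour is treated as smaller) are height-filtered and then pruned
greedily in decreasing height order until all survivors respect the
minimum distance.  ``strict_dominance`` applies the literal
window-dominance rule: day i is a peak iff it strictly exceeds every
neighbour within the window on both sides (out-of-range comparisons
hold vacuously) and passes the height floor.  On series whose maxima
are far apart the two modes agree; they can differ when large peaks
crowd together.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from reappear.ingest import DailySeries

MODES = ("greedy_prune", "strict_dominance")


@dataclass(frozen=True)
class PeakParams:
    """Peak-detection criteria; the defaults are the study criteria
    (10% minimal height, 7-day minimum distance, 7-day window)."""

    min_height_frac: float = 0.1
    min_distance_days: int = 7
    neighbor_window: int = 7
    mode: str = "greedy_prune"

    def __post_init__(self):
        if not 0.0 < self.min_height_frac <= 1.0:
            raise ValueError("min_height_frac must lie in (0, 1]")
        if self.min_distance_days < 1 or self.neighbor_window < 1:
            raise ValueError("distance and window must be >= 1 day")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


@dataclass(frozen=True)
class PeakSet:
    """Sorted 0-based day offsets of the retained peaks."""

    indices: tuple
    params: PeakParams

    def __len__(self) -> int:
        return len(self.indices)


def _as_counts(series: Union[DailySeries, Sequence[int], np.ndarray]) -> np.ndarray:
    x = series.counts if isinstance(series, DailySeries) else np.asarray(series)
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("series must be a nonempty vector")
    if np.any(x < 0):
        raise ValueError("negative counts")
    if x.sum() <= 0:
        raise ValueError("all-zero series has no peaks")
    return x


def _plateau_candidates(x: np.ndarray) -> list[int]:
    """Strict local maxima with plateau handling: a run of equal values
    higher than both flanking values (out-of-range flanks treated as
    smaller) contributes one candidate at its midpoint (lower index on
    even-length plateaus)."""
    n = x.size
    cands = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        left_smaller = i == 0 or x[i - 1] < x[i]
        right_smaller = j == n - 1 or x[j + 1] < x[i]
        if left_smaller and right_smaller:
            cands.append((i + j) // 2)
        i = j + 1
    return cands


def _greedy_prune(x: np.ndarray, params: PeakParams) -> list[int]:
    floor = params.min_height_frac * x.max()
    cands = [i for i in _plateau_candidates(x) if x[i] >= floor]
    # decreasing height, ties broken toward the earlier index
    cands.sort(key=lambda i: (-x[i], i))
    kept: list[int] = []
    for i in cands:
        if all(abs(i - j) >= params.min_distance_days for j in kept):
            kept.append(i)
    return sorted(kept)


def _strict_dominance(x: np.ndarray, params: PeakParams) -> list[int]:
    n = x.size
    floor = params.min_height_frac * x.max()
    out = []
    for i in range(n):
        if x[i] < floor:
            continue
        ok = True
        for k in range(1, params.neighbor_window + 1):
            if i + k < n and not x[i] > x[i + k]:
                ok = False
                break
            if i - k >= 0 and not x[i] > x[i - k]:
                ok = False
                break
        if ok:
            out.append(i)
    return out


def detect_peaks(series, params: PeakParams | None = None) -> PeakSet:
    """Peak set of a daily series under the given criteria."""
    if params is None:
        params = PeakParams()
    x = _as_counts(series)
    if params.mode == "greedy_prune":
        idx = _greedy_prune(x, params)
    else:
        idx = _strict_dominance(x, params)
    return PeakSet(indices=tuple(idx), params=params)


def peak_frequency(series, params: PeakParams | None = None) -> int:
    """Number of retained peaks; >= 1 for any nonzero series in
    greedy_prune mode (the global maximum always survives)."""
    return len(detect_peaks(series, params))


def burstiness(series) -> float:
    """max(X) / sum(X), in (0, 1]."""
    x = _as_counts(series)
    return float(x.max() / x.sum())


def story_metrics(series: DailySeries, rating: int,
                  params: PeakParams | None = None) -> dict:
    """The modelling row for one story."""
    return {
        "story_id": series.story_id,
        "rating": int(rating),
        "peak_frequency": peak_frequency(series, params),
        "burstiness": burstiness(series),
        "n_days": series.n_days,
        "n_tweets": series.n_tweets,
        "onset_day": series.onset_day,
    }


def compute_metrics(corpus: Iterable[DailySeries], ratings: dict[str, int],
                    params: PeakParams | None = None) -> pd.DataFrame:
    """StoryMetrics table for a corpus of daily series.

    ``ratings`` maps story_id -> rating; stories without a rating raise.
    """
    rows = []
    for series in corpus:
        if series.story_id not in ratings:
            raise KeyError(f"no rating for story {series.story_id!r}")
        rows.append(story_metrics(series, ratings[series.story_id], params))
    df = pd.DataFrame(rows)
    return df.reset_index(drop=True)
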