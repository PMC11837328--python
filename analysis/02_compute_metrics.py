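#!/usr/bin/env python
"""Compute the response variables from the raw daily series.

Reads the timeseries corpus written by 01_simulate_corpus.py, applies
the peak detector (10% minimal height, 7-day minimum distance) and the
burstiness ratio, and writes the modelling table.  Also reports how
often the detector recovers the planted burst count and the rank
correlation between the two response variables.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from reappear.ingest import DailySeries
from reappear.metrics import PeakParams, compute_metrics
from reappear.simulate import SyntheticConfig, draw_story_series

CORPUS = Path("results/corpus")
RAW = Path("scratch/corpus/daily_series.csv")
OUT = Path("results")
SEED = 11


def main() -> None:
    truth = pd.read_csv(CORPUS / "ground_truth.csv")
    ratings = dict(zip(truth["story_id"].astype(str), truth["rating"]))

    if RAW.exists():
        df = pd.read_csv(RAW)
        corpus = []
        for sid, group in df.groupby("story_id"):
            counts = group.sort_values("day")["count"].to_numpy()
            nz = np.nonzero(counts)[0]
            corpus.append(DailySeries(str(sid),
                                      pd.Timestamp("1970-01-01").date(),
                                      counts[nz[0]:nz[-1] + 1]))
    else:  # regenerate deterministically from the seed
        cfg = SyntheticConfig(mode="timeseries", seed=SEED,
                              beta_count=(1.0, 0.0, -0.25))
        corpus, _ = draw_story_series(cfg)

    metrics = compute_metrics(corpus, ratings, PeakParams())
    metrics = metrics.merge(truth[["story_id", "m_planted"]], on="story_id")
    metrics.to_csv(OUT / "timeseries_metrics.csv", index=False)

    exact = (metrics["peak_frequency"] == metrics["m_planted"]).mean()
    rho = stats.spearmanr(metrics["peak_frequency"],
                          metrics["burstiness"]).statistic
    print(f"{len(metrics)} stories;")
    print(f"planted bursts recovered exactly for {exact:.1%} of stories")
    print(f"Spearman rho(peak frequency, burstiness) = {rho:.3f} "
          "(more peaks -> less concentrated activity)")


if __name__ == "__main__":
    main()
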