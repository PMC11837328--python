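"""Configured end-to-end runs: ingest -> metrics -> fits -> comparison
-> controls, with seeds, stage logging and report artifacts.

A run is a pure function of (inputs, RunConfig): the same config and
seed reproduce every numeric output.  Randomness is drawn from a single
global seed, with deterministic per-stage substreams.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from reappear.controls import permutation_test, temporal_split_check
from reappear.count_models import overdispersion_lrt
from reappear.design import DesignSpec
from reappear.ingest import (
    IngestConfig,
    apply_exclusions,
    build_daily_series,
    enforce_min_tweets,
    read_story_table,
    read_tweets,
    trim_tails,
)
from reappear.metrics import PeakParams, compute_metrics
from reappear.selection import ComparisonTable, compare_family
from reappear.simulate import SyntheticConfig, draw_story_metrics, draw_story_series

_STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """Conventional star coding: * p<0.05, ** p<0.01, *** p<0.001."""
    if not np.isfinite(p):
        return ""
    for level, stars in _STAR_LEVELS:
        if p < level:
            return stars
    return ""


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    out_dir: str = "results/run"
    seed: int = 0
    # input: either paths to real files or a synthetic generator config
    tweets_path: Optional[str] = None
    story_table_path: Optional[str] = None
    metrics_path: Optional[str] = None        # precomputed StoryMetrics CSV
    synthetic: Optional[dict] = None          # SyntheticConfig fields
    # stage parameters
    trim_fraction: float = 0.01
    min_tweets: int = 3000
    similarity_threshold: float = 0.7
    peak_min_height_frac: float = 0.1
    peak_min_distance_days: int = 7
    peak_mode: str = "greedy_prune"
    families: tuple = ("ztnb", "beta")
    orthogonal: bool = False
    permutation_B: int = 0                    # 0 disables the permutation stage
    run_controls: bool = True

    def validate(self) -> None:
        sources = [self.tweets_path, self.metrics_path, self.synthetic]
        if all(s is None for s in sources):
            raise ValueError(
                "config needs tweets_path, metrics_path or a synthetic block"
            )
        if self.tweets_path is not None and self.story_table_path is None:
            raise ValueError("tweets_path requires story_table_path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["families"] = list(self.families)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def render_comparison(table: ComparisonTable) -> tuple[str, pd.DataFrame]:
    """(Markdown, CSV frame) in the four-model table shape: coefficients
    with significance stars, pseudo-R², information criteria, and the
    pairwise relative-likelihood block (LRT stars on nested pairs)."""
    names = table.model_names
    md = [
        f"### {table.family} models for {table.response}",
        "",
        "| Model | " + " | ".join(
            ["β0", "β1", "β2", "R²CS", "R²McF", "logL", "AIC", "AICc", "BIC"]
            + [f"RL vs {n}" for n in names]) + " |",
        "|" + "---|" * (10 + len(names)),
    ]
    for name in names:
        fit = table.fits[name]
        coef = {c: (b, p) for c, b, p in zip(fit.coef_names, fit.beta, fit.p)}
        cells = []
        for label in ("beta0", "beta1", "beta2"):
            hit = next((k for k in coef if k.startswith(label)), None)
            if hit is None:
                cells.append("–")
            else:
                b, p = coef[hit]
                cells.append(f"{b:.2f}{significance_stars(p)}")
        cs, mcf = table.pseudo_r2[name]
        cells += [f"{cs:.3g}", f"{mcf:.3g}", f"{fit.logL:.2f}",
                  f"{fit.aic:.2f}", f"{fit.aicc:.2f}", f"{fit.bic:.2f}"]
        for other in names:
            if other == name:
                cells.append("–")
                continue
            rl = table.rl.loc[name, other]
            pair = (other, name) if (other, name) in table.lrt else (name, other)
            stars = ""
            if pair in table.lrt:
                stars = significance_stars(table.lrt[pair][2])
            cells.append(f"{rl:.2f}{stars}")
        md.append(f"| {name} | " + " | ".join(cells) + " |")
    best = table.best_model
    note = " (runner-up within ΔAIC ≤ 2: no decisive support)" if table.no_support else ""
    md += ["", f"Best model by AIC: **{best}**{note}.",
           "Stars on coefficients: Wald p; on relative likelihoods: "
           "likelihood-ratio test of the nested pair. Non-nested pairs "
           "(falsehood vs ambiguity) carry RL only."]
    return "\n".join(md), table.to_frame()


def read_comparison_csv(path: str | Path) -> pd.DataFrame:
    """Read a rendered comparison CSV, keeping the model name 'null' a
    string rather than a missing value."""
    return pd.read_csv(path, keep_default_na=False,
                       na_values=["NaN", "nan", ""])


def comparison_from_frame(frame: pd.DataFrame) -> dict:
    """Recover the per-model statistics of a rendered CSV comparison
    table (numeric round trip of ``ComparisonTable.to_frame``)."""
    out = {}
    for _, row in frame.iterrows():
        out[row["model"]] = {
            k: row[k] for k in frame.columns if k != "model"
        }
    return out


def _load_or_generate(config: RunConfig, log: list) -> tuple[pd.DataFrame, dict]:
    """Produce the StoryMetrics table from whichever input the config names."""
    artifacts: dict = {}
    peak_params = PeakParams(
        min_height_frac=config.peak_min_height_frac,
        min_distance_days=config.peak_min_distance_days,
        mode=config.peak_mode,
    )
    if config.metrics_path is not None:
        metrics = pd.read_csv(config.metrics_path)
        log.append(f"loaded {len(metrics)} precomputed story rows from "
                   f"{config.metrics_path}")
        return metrics, artifacts

    if config.synthetic is not None:
        syn = SyntheticConfig(**{**config.synthetic, "seed": config.seed})
        if syn.mode == "direct":
            metrics = draw_story_metrics(syn)
            log.append(f"generated {len(metrics)} direct-mode story rows")
        else:
            corpus, truth = draw_story_series(syn)
            ratings = dict(zip(truth["story_id"], truth["rating"]))
            metrics = compute_metrics(corpus, ratings, peak_params)
            artifacts["ground_truth"] = truth
            log.append(f"generated {len(metrics)} timeseries-mode stories")
        return metrics, artifacts

    tweets = read_tweets(config.tweets_path)
    stories = read_story_table(config.story_table_path)
    log.append(f"read {len(tweets)} tweets across "
               f"{tweets['story_id'].nunique()} stories")
    ingest_cfg = IngestConfig(
        similarity_threshold=config.similarity_threshold,
        trim_fraction=config.trim_fraction,
        min_tweets=config.min_tweets,
    )
    kept, audit = apply_exclusions(tweets, ingest_cfg)
    log.append(f"exclusion audit: {audit['rules']}; skipped {audit['skipped']}")
    series = {}
    for sid, group in kept.groupby("story_id"):
        if len(group) < 2:
            continue
        trimmed = trim_tails(group, config.trim_fraction)
        series[str(sid)] = build_daily_series(trimmed, str(sid))
    series, min_audit = enforce_min_tweets(series, config.min_tweets)
    log.append(f"{min_audit['n_kept']}/{min_audit['n_in']} stories above "
               f"{config.min_tweets} tweets")
    ratings = dict(zip(stories["story_id"], stories["rating"]))
    metrics = compute_metrics(series.values(), ratings, peak_params)
    artifacts["exclusion_audit"] = audit
    return metrics, artifacts


def run_pipeline(config: RunConfig) -> Path:
    """Execute a configured run; returns the run directory.

    Writes the StoryMetrics CSV, per-family comparison tables (Markdown
    + CSV), fit JSONs, control reports and a log with versions, seed
    and per-stage record counts.  Stage failures abort with the stage
    named; partial outputs are kept next to a FAILED marker.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from reappear import __version__

    log: list[str] = [f"reappear {__version__}  seed={config.seed}  "
                      f"started {_dt.datetime.now(_dt.timezone.utc).isoformat()}"]
    config.to_yaml(out / "config.yaml")
    stage = "ingest"
    try:
        metrics, artifacts = _load_or_generate(config, log)
        metrics.to_csv(out / "story_metrics.csv", index=False)
        if "ground_truth" in artifacts:
            artifacts["ground_truth"].to_csv(out / "ground_truth.csv", index=False)
        log.append(f"metrics table: {len(metrics)} rows")

        stage = "fits"
        for family in config.families:
            table = compare_family(metrics, family,
                                   orthogonal=config.orthogonal)
            md, frame = render_comparison(table)
            (out / f"comparison_{family}.md").write_text(md + "\n")
            frame.to_csv(out / f"comparison_{family}.csv", index=False)
            fit_json = {
                name: {
                    "coef": dict(zip(f.coef_names, map(float, f.beta))),
                    "se": dict(zip(f.coef_names, map(float, f.se))),
                    "p": dict(zip(f.coef_names, map(float, f.p))),
                    "aux": f.aux, "logL": f.logL, "k": f.k, "n": f.n,
                    "aic": f.aic, "aicc": f.aicc, "bic": f.bic,
                    "converged": f.converged,
                }
                for name, f in table.fits.items()
            }
            (out / f"fits_{family}.json").write_text(
                json.dumps(fit_json, indent=2))
            log.append(f"{family}: best={table.best_model} "
                       f"no_support={table.no_support} flagged={table.flagged}")

        stage = "controls"
        if config.run_controls:
            controls: dict = {}
            if "ztnb" in config.families:
                lrt = overdispersion_lrt(metrics,
                                         DesignSpec("quadratic_unconstrained"))
                controls["overdispersion"] = {
                    "chi2": lrt["chi2"], "df": lrt["df"], "p": lrt["p"]}
            if "onset_day" in metrics.columns:
                controls["temporal_split"] = temporal_split_check(metrics)
            if config.permutation_B >= 99:
                perm = permutation_test(
                    metrics, "ztnb", DesignSpec("quadratic_unconstrained"),
                    B=config.permutation_B, seed=config.seed,
                )
                controls["permutation_ztnb"] = {
                    c: {"observed_z": r.observed_z, "p_perm": r.p_perm,
                        "B": r.B}
                    for c, r in perm.items()
                }
            (out / "controls.json").write_text(
                json.dumps(controls, indent=2, default=str))
            log.append(f"controls: {sorted(controls)}")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        (out / "run.log").write_text("\n".join(log) + f"\nFAILED at {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    log.append("completed")
    (out / "run.log").write_text("\n".join(log) + "\n")
    return out
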