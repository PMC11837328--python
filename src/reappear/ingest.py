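"""Story and tweet ingestion: verdict mapping, cleaning and exclusion rules.

Fact-checking verdicts from Snopes and PolitiFact are mapped to a
five-level rating x in {-2, -1, 0, 1, 2} (false ... true).  Tweet
streams are cleaned (character whitelist, URL removal), filtered by a
sequence of exclusion rules (semantic-similarity threshold, doubt
words, fact-checker links, NLI contradiction labels), trimmed at the
timestamp tails, and binned into per-story daily count series.

Semantic-similarity and NLI scores are consumed as precomputed columns
(or any callable scorer plugged into the config); no language models
are shipped.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional

import numpy as np
import pandas as pd

SECONDS_PER_DAY = 86400

#: verdict -> rating per fact-checking source (matching is case-insensitive)
VERDICT_MAP: dict[str, dict[str, int]] = {
    "snopes": {
        "false": -2,
        "scam": -2,
        "mostly false": -1,
        "mixture": 0,
        "mostly true": 1,
        "true": 2,
    },
    "politifact": {
        "pants on fire": -2,
        "false": -2,
        "mostly false": -1,
        "half true": 0,
        "mostly true": 1,
        "true": 2,
    },
}

DEFAULT_DOUBT_WORDS = ("misinformation", "fact-check", "fake news")
DEFAULT_FACT_CHECK_DOMAINS = ("snopes.com", "politifact.com")

_URL_RE = re.compile(r"(?:https?://\S+|www\.\S+)", re.IGNORECASE)
_DISALLOWED_RE = re.compile(r"[^A-Za-z0-9?!.,'\s]")


class VerdictMappingError(KeyError):
    """Raised when a (source, verdict) pair is not in the rating table."""


@dataclass(frozen=True)
class StoryClaim:
    """One fact-checked story."""

    story_id: str
    source: str                     # "snopes" or "politifact"
    verdict_text: str
    rating: int
    claim_text: Optional[str] = None

    def __post_init__(self):
        if self.rating not in (-2, -1, 0, 1, 2):
            raise ValueError(f"rating {self.rating} outside the five-level scale")


@dataclass(frozen=True)
class TweetRecord:
    """One tweet attached to a story."""

    story_id: str
    timestamp: float                # seconds since epoch, UTC
    text: Optional[str] = None
    similarity: Optional[float] = None
    nli_label: Optional[str] = None

    def __post_init__(self):
        if not np.isfinite(self.timestamp):
            raise ValueError("timestamp must be finite")
        if self.similarity is not None and not -1.0 <= self.similarity <= 1.0:
            raise ValueError("similarity must lie in [-1, 1]")


@dataclass
class DailySeries:
    """Per-story daily tweet counts, trimmed to the first/last nonzero day."""

    story_id: str
    onset_day: _dt.date
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 1 or self.counts.size < 1:
            raise ValueError("counts must be a nonempty vector")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.counts.sum() == 0:
            raise ValueError("counts must sum to a positive total")
        if self.counts[0] == 0 or self.counts[-1] == 0:
            raise ValueError("series must be trimmed to its support")

    @property
    def n_days(self) -> int:
        return int(self.counts.size)

    @property
    def n_tweets(self) -> int:
        return int(self.counts.sum())


@dataclass
class IngestConfig:
    """Cleaning/exclusion parameters for a tweet stream."""

    doubt_words: tuple = DEFAULT_DOUBT_WORDS
    fact_check_domains: tuple = DEFAULT_FACT_CHECK_DOMAINS
    similarity_threshold: float = 0.7
    trim_fraction: float = 0.01
    min_tweets: int = 3000
    similarity_scorer: Optional[Callable] = None
    nli_scorer: Optional[Callable] = None


def map_verdict(source: str, verdict_text: str) -> int:
    """Rating in {-2..2} for a fact-checker verdict; unknown verdicts raise."""
    if not source or not verdict_text:
        raise ValueError("source and verdict_text must be non-empty")
    src = source.strip().lower()
    if src not in VERDICT_MAP:
        raise VerdictMappingError(f"unknown fact-checking source: {source!r}")
    verdict = verdict_text.strip().lower()
    table = VERDICT_MAP[src]
    if verdict not in table:
        raise VerdictMappingError(
            f"verdict {verdict_text!r} has no rating for source {source!r}"
        )
    return table[verdict]


def clean_text(raw: str) -> str:
    """Normalize tweet text: drop URLs, unhook @/# (keeping the word),
    keep only alphanumerics and [?!.,'] plus whitespace, lowercase."""
    if not raw:
        return ""
    s = _URL_RE.sub(" ", raw)
    s = s.replace("@", "").replace("#", "")
    s = _DISALLOWED_RE.sub("", s)
    s = re.sub(r"\s+", " ", s).strip()
    return s.lower()


def _has_doubt_word(cleaned: str, doubt_words: Iterable[str]) -> bool:
    return any(w.lower() in cleaned for w in doubt_words)


def _has_fact_check_link(raw: str, domains: Iterable[str]) -> bool:
    low = raw.lower()
    return any(d.lower() in low for d in domains)


def apply_exclusions(tweets: pd.DataFrame, config: Optional[IngestConfig] = None
                     ) -> tuple[pd.DataFrame, dict]:
    """Filter a tweet table by the exclusion rules, in order:
    similarity threshold -> doubt words -> fact-check links -> NLI
    contradiction.  Returns (kept, audit); the audit reports removal
    count and fraction per rule plus rules skipped for missing columns.
    """
    if config is None:
        config = IngestConfig()
    df = tweets.copy()
    n_in = len(df)
    audit: dict = {"n_in": n_in, "rules": {}, "skipped": []}

    def record(rule: str, mask_remove: pd.Series):
        removed = int(mask_remove.sum())
        audit["rules"][rule] = {
            "removed": removed,
            "fraction": removed / n_in if n_in else 0.0,
        }
        return df.loc[~mask_remove]

    # 1. similarity threshold
    if config.similarity_scorer is not None and "text" in df.columns:
        df = df.assign(similarity=[
            config.similarity_scorer(t) for t in df["text"]
        ])
    if "similarity" in df.columns and df["similarity"].notna().any():
        df = record("similarity", df["similarity"] < config.similarity_threshold)
    else:
        audit["skipped"].append("similarity")

    # 2. doubt words (substring, case-insensitive, on cleaned text)
    if "text" in df.columns:
        cleaned = df["text"].fillna("").map(clean_text)
        df = record("doubt_words",
                    cleaned.map(lambda s: _has_doubt_word(s, config.doubt_words)))
    else:
        audit["skipped"].append("doubt_words")

    # 3. links to the fact-checking sources (raw text: cleaning strips URLs)
    if "text" in df.columns:
        df = record("fact_check_links",
                    df["text"].fillna("").map(
                        lambda s: _has_fact_check_link(s, config.fact_check_domains)))
    else:
        audit["skipped"].append("fact_check_links")

    # 4. NLI contradiction
    if config.nli_scorer is not None and "text" in df.columns:
        df = df.assign(nli_label=[config.nli_scorer(t) for t in df["text"]])
    if "nli_label" in df.columns and df["nli_label"].notna().any():
        df = record("nli_contradiction", df["nli_label"] == "contradict")
    else:
        audit["skipped"].append("nli_contradiction")

    audit["n_kept"] = len(df)
    return df, audit


def trim_tails(tweets: pd.DataFrame, total_fraction: float = 0.01) -> pd.DataFrame:
    """Drop the earliest and latest ``total_fraction/2`` of one story's
    tweets by timestamp (floor count per side)."""
    if len(tweets) < 2:
        raise ValueError("need at least 2 tweets to trim")
    if not 0.0 <= total_fraction < 1.0:
        raise ValueError("total_fraction must lie in [0, 1)")
    df = tweets.sort_values("timestamp", kind="mergesort")
    k = int(np.floor(len(df) * total_fraction / 2.0))
    if k == 0:
        return df
    return df.iloc[k:len(df) - k]


def build_daily_series(tweets: pd.DataFrame, story_id: Optional[str] = None
                       ) -> DailySeries:
    """Bin one story's timestamps into UTC calendar days.

    The series spans the first to last nonempty day inclusive; interior
    zero days are retained.
    """
    if len(tweets) == 0:
        raise ValueError("cannot build a daily series from zero tweets")
    if story_id is None:
        ids = tweets["story_id"].unique()
        if len(ids) != 1:
            raise ValueError("tweet table mixes stories; pass story_id")
        story_id = str(ids[0])
    days = np.floor_divide(tweets["timestamp"].to_numpy(dtype=np.int64),
                           SECONDS_PER_DAY)
    first, last = int(days.min()), int(days.max())
    counts = np.bincount(days - first, minlength=last - first + 1)
    onset = _dt.date(1970, 1, 1) + _dt.timedelta(days=first)
    return DailySeries(story_id=story_id, onset_day=onset, counts=counts)


def enforce_min_tweets(stories: dict[str, DailySeries], threshold: int = 3000
                       ) -> tuple[dict[str, DailySeries], dict]:
    """Drop stories whose total kept-tweet count falls below ``threshold``."""
    kept, dropped = {}, {}
    for sid, series in stories.items():
        if series.n_tweets >= threshold:
            kept[sid] = series
        else:
            dropped[sid] = series.n_tweets
    audit = {"threshold": threshold, "n_in": len(stories),
             "n_kept": len(kept), "dropped": dropped}
    return kept, audit


# ---------------------------------------------------------------------------
# file readers

def _parse_timestamps(col: pd.Series) -> pd.Series:
    if np.issubdtype(col.dtype, np.number):
        return col.astype(float)
    ts = pd.to_datetime(col, utc=True, format="ISO8601")
    return ts.astype("int64") / 1e9


def read_tweets(path: str | Path) -> pd.DataFrame:
    """Read a tweet stream (CSV or JSONL) with columns story_id,
    timestamp (ISO-8601 or epoch seconds) and optional text, similarity,
    nli_label."""
    path = Path(path)
    if path.suffix.lower() in (".jsonl", ".ndjson"):
        rows = [json.loads(line) for line in path.read_text().splitlines() if line]
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path)
    if "story_id" not in df.columns or "timestamp" not in df.columns:
        raise ValueError("tweet stream needs story_id and timestamp columns")
    df["story_id"] = df["story_id"].astype(str)
    df["timestamp"] = _parse_timestamps(df["timestamp"])
    return df


def read_story_table(path: str | Path) -> pd.DataFrame:
    """Read the story table (CSV): story_id, source, verdict_text (or a
    precomputed rating column), optional claim_text.  Verdicts are
    mapped to ratings; unknown verdicts raise."""
    df = pd.read_csv(Path(path))
    if "story_id" not in df.columns:
        raise ValueError("story table needs a story_id column")
    df["story_id"] = df["story_id"].astype(str)
    if "rating" not in df.columns:
        if not {"source", "verdict_text"} <= set(df.columns):
            raise ValueError("story table needs rating or source+verdict_text")
        df["rating"] = [
            map_verdict(s, v) for s, v in zip(df["source"], df["verdict_text"])
        ]
    df["rating"] = df["rating"].astype(int)
    bad = ~df["rating"].isin([-2, -1, 0, 1, 2])
    if bad.any():
        raise ValueError(f"ratings outside the five-level scale: "
                         f"{df.loc[bad, 'rating'].tolist()}")
    return df
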