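"""Story/tweet ingestion: verdict mapping, cleaning, exclusions, binning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from reappear.ingest import (
    DailySeries,
    IngestConfig,
    VERDICT_MAP,
    VerdictMappingError,
    apply_exclusions,
    build_daily_series,
    clean_text,
    enforce_min_tweets,
    map_verdict,
    trim_tails,
)

SECONDS_PER_DAY = 86400


class TestMapVerdict:
    @pytest.mark.parametrize("source,verdict,expected", [
        ("Snopes", "False", -2),
        ("Snopes", "Scam", -2),
        ("Snopes", "Mostly False", -1),
        ("Snopes", "Mixture", 0),
        ("Snopes", "Mostly True", 1),
        ("Snopes", "True", 2),
        ("PolitiFact", "Pants on Fire", -2),
        ("PolitiFact", "False", -2),
        ("PolitiFact", "Mostly False", -1),
        ("PolitiFact", "Half True", 0),
        ("PolitiFact", "Mostly True", 1),
        ("PolitiFact", "True", 2),
    ])
    def test_rating_table(self, source, verdict, expected):
        assert map_verdict(source, verdict) == expected

    def test_case_insensitive(self):
        assert map_verdict("snopes", "mIxTuRe") == 0
        assert map_verdict("POLITIFACT", "PANTS ON FIRE") == -2

    @pytest.mark.parametrize("source,verdict", [
        ("Snopes", "Unproven"),
        ("Snopes", "Half True"),          # PolitiFact-only verdict
        ("PolitiFact", "Mixture"),        # Snopes-only verdict
        ("Reuters", "False"),             # unknown source
    ])
    def test_unknown_rejected_with_name(self, source, verdict):
        with pytest.raises((VerdictMappingError, ValueError)) as err:
            map_verdict(source, verdict)
        assert verdict in str(err.value) or source in str(err.value)

    def test_total_on_table(self):
        for source, table in VERDICT_MAP.items():
            for verdict in table:
                assert map_verdict(source, verdict) in (-2, -1, 0, 1, 2)


class TestCleanText:
    def test_mentions_hashtags_urls(self):
        raw = "Check @JoeSmith #Fake https://x.co/ab NOW!"
        assert clean_text(raw) == "check joesmith fake now!"

    def test_empty(self):
        assert clean_text("") == ""

    def test_allowed_charset_fixed_point(self):
        assert clean_text("abc123?!.,'") == "abc123?!.,'"

    def test_strips_irregular_characters(self):
        assert clean_text("héllo — wörld & $5") == "hllo wrld 5"


class TestApplyExclusions:
    def _frame(self, **cols):
        n = max(len(v) for v in cols.values())
        base = {"story_id": ["s"] * n, "timestamp": np.arange(n) * 3600.0}
        base.update(cols)
        return pd.DataFrame(base)

    def test_doubt_word_excluded(self):
        df = self._frame(text=["this is fake news folks", "plain tweet"])
        kept, audit = apply_exclusions(df)
        assert audit["rules"]["doubt_words"]["removed"] == 1
        assert list(kept["text"]) == ["plain tweet"]

    def test_similarity_threshold(self):
        df = self._frame(text=["a", "b"], similarity=[0.65, 0.9])
        kept, audit = apply_exclusions(df)
        assert audit["rules"]["similarity"]["removed"] == 1
        assert list(kept["similarity"]) == [0.9]

    def test_fact_check_link(self):
        df = self._frame(text=["see https://www.snopes.com/x", "ok"])
        kept, audit = apply_exclusions(df)
        assert audit["rules"]["fact_check_links"]["removed"] == 1

    def test_nli_contradiction(self):
        df = self._frame(text=["a", "b"], nli_label=["contradict", "entail"])
        kept, audit = apply_exclusions(df)
        assert audit["rules"]["nli_contradiction"]["removed"] == 1

    def test_missing_columns_noop_logged(self):
        df = self._frame(text=["no doubt here"])
        kept, audit = apply_exclusions(df)
        assert len(kept) == 1
        assert "similarity" in audit["skipped"]
        assert "nli_contradiction" in audit["skipped"]

    def test_conservation(self):
        df = self._frame(
            text=["fake news", "see politifact.com", "fine", "also fine"],
            similarity=[0.9, 0.9, 0.6, 0.95],
            nli_label=["neutral", "neutral", "neutral", "contradict"],
        )
        kept, audit = apply_exclusions(df)
        removed = sum(r["removed"] for r in audit["rules"].values())
        assert len(df) == len(kept) + removed


class TestTrimTails:
    def _tweets(self, n):
        return pd.DataFrame({"story_id": ["s"] * n,
                             "timestamp": np.arange(n, dtype=float)})

    def test_quantile_rule(self):
        out = trim_tails(self._tweets(1000), 0.01)
        assert len(out) == 990
        assert out["timestamp"].min() == 5 and out["timestamp"].max() == 994

    def test_floor_keeps_tiny_input(self):
        assert len(trim_tails(self._tweets(2), 0.01)) == 2

    def test_two_percent(self):
        assert len(trim_tails(self._tweets(200), 0.02)) == 196

    def test_zero_fraction_identity(self):
        out = trim_tails(self._tweets(57), 0.0)
        assert len(out) == 57

    @given(n=st.integers(2, 400), f1=st.floats(0, 0.3), f2=st.floats(0, 0.3))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_fraction(self, n, f1, f2):
        lo, hi = sorted([f1, f2])
        t = self._tweets(n)
        assert len(trim_tails(t, hi)) <= len(trim_tails(t, lo))


class TestBuildDailySeries:
    def test_single_day(self):
        df = pd.DataFrame({"story_id": ["s"] * 4,
                           "timestamp": [10.0, 20.0, 30.0, 40.0]})
        s = build_daily_series(df)
        assert list(s.counts) == [4]

    def test_interior_zero_days_retained(self):
        ts = [0.5 * SECONDS_PER_DAY] * 3 + [3.5 * SECONDS_PER_DAY] * 2
        df = pd.DataFrame({"story_id": ["s"] * 5, "timestamp": ts})
        s = build_daily_series(df)
        assert list(s.counts) == [3, 0, 0, 2]
        assert s.n_days == 4

    def test_conservation(self, rng):
        ts = rng.uniform(0, 30 * SECONDS_PER_DAY, size=500)
        df = pd.DataFrame({"story_id": ["s"] * 500, "timestamp": ts})
        s = build_daily_series(df)
        assert s.counts.sum() == 500
        assert s.counts[0] > 0 and s.counts[-1] > 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_daily_series(pd.DataFrame({"story_id": [], "timestamp": []}))


class TestEnforceMinTweets:
    def _series(self, total):
        return DailySeries("s", __import__("datetime").date(2020, 1, 1),
                           [total])

    def test_boundary(self):
        stories = {"a": self._series(2999), "b": self._series(3000)}
        kept, audit = enforce_min_tweets(stories, 3000)
        assert set(kept) == {"b"}
        assert audit["dropped"] == {"a": 2999}

    def test_zero_threshold_identity(self):
        stories = {"a": self._series(1), "b": self._series(10)}
        kept, _ = enforce_min_tweets(stories, 0)
        assert set(kept) == {"a", "b"}


def test_daily_series_invariants():
    import datetime

    with pytest.raises(ValueError):
        DailySeries("s", datetime.date(2020, 1, 1), [0, 3, 1])   # untrimmed
    with pytest.raises(ValueError):
        DailySeries("s", datetime.date(2020, 1, 1), [0])         # zero sum
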