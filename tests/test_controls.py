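"""Orthogonal polynomials, permutation inference, sensitivity sweeps,
temporal split."""

import math

import numpy as np
import pandas as pd
import pytest

from reappear.controls import (
    orthogonalize,
    permutation_test,
    sensitivity_sweep,
    temporal_split_check,
)
from reappear.count_models import fit_ztnb
from reappear.design import DesignSpec
from reappear.metrics import PeakParams, peak_frequency
from reappear.selection import compare_family
from reappear.simulate import SyntheticConfig, draw_story_metrics, draw_story_series

UNCONSTRAINED = DesignSpec("quadratic_unconstrained")


class TestOrthogonalize:
    def test_balanced_matches_classical_contrasts(self):
        ratings = np.repeat([-2, -1, 0, 1, 2], 10)
        lin, quad = orthogonalize(ratings)
        # classical orthogonal contrasts over 5 equally spaced levels
        lin_ref = np.repeat([-2, -1, 0, 1, 2], 10).astype(float)
        quad_ref = np.repeat([2, -1, -2, -1, 2], 10).astype(float)
        for col, ref in ((lin, lin_ref), (quad, quad_ref)):
            ref = ref / np.linalg.norm(ref)
            assert np.allclose(col, ref) or np.allclose(col, -ref)

    def test_zero_mean_unit_norm_orthogonal(self, rng):
        ratings = rng.choice([-2, -1, 0, 1, 2], size=123,
                             p=[0.5, 0.05, 0.1, 0.05, 0.3])
        lin, quad = orthogonalize(ratings)
        assert abs(lin.mean()) < 1e-12 and abs(quad.mean()) < 1e-12
        assert np.linalg.norm(lin) == pytest.approx(1.0)
        assert np.linalg.norm(quad) == pytest.approx(1.0)
        assert abs(lin @ quad) < 1e-12

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            orthogonalize(np.array([-2, -2, 2, 2]))

    def test_unconstrained_fit_invariant_under_orthogonalization(
            self, paper_corpus):
        raw = fit_ztnb(paper_corpus, DesignSpec("quadratic_unconstrained"))
        orth = fit_ztnb(paper_corpus,
                        DesignSpec("quadratic_unconstrained", orthogonal=True))
        assert orth.logL == pytest.approx(raw.logL, abs=1e-6)
        assert orth.aic == pytest.approx(raw.aic, abs=1e-6)


class TestPermutationTest:
    def test_same_seed_bit_identical(self, paper_corpus):
        r1 = permutation_test(paper_corpus, "ztnb", UNCONSTRAINED,
                              B=99, seed=5)
        r2 = permutation_test(paper_corpus, "ztnb", UNCONSTRAINED,
                              B=99, seed=5)
        for c in r1:
            assert r1[c].p_perm == r2[c].p_perm
            np.testing.assert_array_equal(r1[c].null_z, r2[c].null_z)

    def test_strong_quadratic_signal_detected(self):
        cfg = SyntheticConfig(
            counts_per_rating={r: 100 for r in (-2, -1, 0, 1, 2)},
            beta_count=(1.0, -0.3, -0.35), theta=1.5, mode="direct", seed=2)
        df = draw_story_metrics(cfg)
        res = permutation_test(df, "ztnb", UNCONSTRAINED, B=199, seed=1)
        assert res["beta2"].p_perm <= 0.01

    def test_add_one_p_definition(self, paper_corpus):
        res = permutation_test(paper_corpus, "beta", UNCONSTRAINED,
                               B=99, seed=3)
        for r in res.values():
            exceed = int(np.sum(np.abs(r.null_z) >= abs(r.observed_z)))
            assert r.p_perm == (1 + exceed) / (len(r.null_z) + 1)
            assert 0 < r.p_perm <= 1

    def test_small_b_rejected(self, paper_corpus):
        with pytest.raises(ValueError):
            permutation_test(paper_corpus, "ztnb", UNCONSTRAINED, B=50, seed=0)


@pytest.fixture(scope="module")
def corpus():
    cfg = SyntheticConfig(mode="timeseries",
                          beta_count=(1.0, 0.0, -0.25), seed=42)
    series, truth = draw_story_series(cfg)
    return series, dict(zip(truth["story_id"], truth["rating"]))


class TestSensitivitySweep:
    def test_degenerate_grid_equals_plain_comparison(self, corpus):
        series, ratings = corpus
        grid = sensitivity_sweep(series, ratings,
                                 {"min_height_frac": [0.1]}, family="ztnb")
        from reappear.metrics import compute_metrics

        metrics = compute_metrics(series, ratings, PeakParams())
        table = compare_family(metrics, "ztnb")
        row = grid.cells.iloc[0]
        assert row["best_model"] == table.best_model
        dual = table.fits["dual"]
        idx = dual.coef_names.index("beta2")
        assert row["beta2"] == pytest.approx(dual.beta[idx])

    def test_peak_frequency_monotone_in_distance(self, corpus):
        series, _ = corpus
        for s in series[:40]:
            freqs = [peak_frequency(s, PeakParams(min_distance_days=d))
                     for d in (3, 7, 14)]
            assert freqs == sorted(freqs, reverse=True)

    def test_ambiguity_effect_stable_across_cells(self, corpus):
        series, ratings = corpus
        grid = sensitivity_sweep(
            series, ratings,
            {"min_height_frac": [0.05, 0.1, 0.2],
             "min_distance_days": [3, 7, 14]},
            family="ztnb")
        assert grid.summary["n_usable"] == 9
        # quadratic (ambiguity) effect present, linear mostly absent
        assert grid.summary["frac_quadratic_sig"] >= 0.8
        assert grid.summary["frac_linear_sig"] <= 0.2

    def test_small_cells_marked_unusable(self, corpus):
        series, ratings = corpus
        grid = sensitivity_sweep(series, ratings,
                                 {"min_tweets": [10**9]}, family="ztnb")
        assert not grid.cells["usable"].iloc[0]

    def test_unknown_parameter_rejected(self, corpus):
        series, ratings = corpus
        with pytest.raises(ValueError):
            sensitivity_sweep(series, ratings, {"nope": [1]})


class TestTemporalSplit:
    def test_homogeneous_corpus_not_significant(self):
        rng = np.random.default_rng(6)
        hits = 0
        R = 40
        cfg = SyntheticConfig(mode="direct")
        for _ in range(R):
            df = draw_story_metrics(cfg, rng)
            rep = temporal_split_check(df)
            hits += rep["peak_frequency"]["p"] < 0.05
        assert hits / R <= 0.1

    def test_degenerate_split_warns(self, paper_corpus):
        df = paper_corpus.copy()
        df["onset_day"] = df["onset_day"].iloc[0]
        rep = temporal_split_check(df)
        assert "warning" in rep

    def test_planted_drift_detected(self):
        rng = np.random.default_rng(9)
        cfg = SyntheticConfig(counts_per_rating={0: 500}, mode="direct")
        detected = 0
        R = 20
        for _ in range(R):
            df = draw_story_metrics(cfg, rng)
            onset = pd.to_datetime(df["onset_day"])
            late = onset > onset.median()
            # late stories systematically burst more
            df.loc[late, "peak_frequency"] = (
                df.loc[late, "peak_frequency"] + 2)
            rep = temporal_split_check(df)
            detected += rep["peak_frequency"]["p"] < 0.05
        assert detected / R > 0.5

    def test_missing_onset_rejected(self):
        df = pd.DataFrame({"rating": [0, 1], "peak_frequency": [1, 2],
                           "burstiness": [0.5, 0.4]})
        with pytest.raises(ValueError):
            temporal_split_check(df)
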