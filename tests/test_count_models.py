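"""Zero-truncated count likelihoods and their MLE fits."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from reappear.count_models import (
    LOG_THETA_MAX,
    THETA_CAP,
    fit_oiztnb,
    fit_truncated_poisson,
    fit_ztnb,
    nb_logpmf,
    oiztnb_logpmf,
    one_inflation_lrt,
    overdispersion_lrt,
    truncated_poisson_logpmf,
    ztnb_logpmf,
    ztnb_loglik,
)
from reappear.design import DesignSpec
from reappear.simulate import SyntheticConfig, draw_story_metrics, ztnb_rvs

UNCONSTRAINED = DesignSpec("quadratic_unconstrained")
INTERCEPT = DesignSpec("intercept")


class TestZtnbPmf:
    @pytest.mark.parametrize("mu", [0.5, 1.0, 3.0, 5.0])
    @pytest.mark.parametrize("theta", [0.3, 1.0, 1.5, 5.0])
    def test_normalization(self, mu, theta):
        y = np.arange(1, 2001)
        total = np.exp(ztnb_logpmf(y, mu, theta)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_poisson_limit_closed_form(self):
        # theta -> inf: ZTNB(1; mu=1) -> Poisson(1;1)/(1-e^-1)
        expected = math.log(math.exp(-1.0) / (1.0 - math.exp(-1.0)))
        got = ztnb_loglik([1], np.array([1.0]), 1e6)
        assert got == pytest.approx(expected, abs=1e-6)

    def test_matches_direct_pmf_ratio_oracle(self):
        # brute force from scipy's NB pmf: P(y)/(1-P(0))
        for mu in (0.5, 1.0, 5.0):
            for theta in (0.3, 1.0, 5.0):
                p = theta / (theta + mu)
                for y in range(1, 11):
                    direct = math.log(
                        stats.nbinom.pmf(y, theta, p)
                        / (1.0 - stats.nbinom.pmf(0, theta, p))
                    )
                    assert ztnb_logpmf(y, mu, theta) == pytest.approx(
                        direct, abs=1e-10)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            ztnb_loglik([0, 1], np.array([1.0, 1.0]), 1.0)

    def test_truncated_poisson_normalization(self):
        y = np.arange(1, 400)
        for mu in (0.2, 1.0, 4.0):
            total = np.exp(truncated_poisson_logpmf(y, mu)).sum()
            assert total == pytest.approx(1.0, abs=1e-10)


class TestFitZtnb:
    def test_parameter_recovery_fixed_seed(self):
        cfg = SyntheticConfig(
            counts_per_rating={r: 100 for r in (-2, -1, 0, 1, 2)},
            beta_count=(1.0, -0.2, -0.2), theta=1.5, mode="direct", seed=5)
        df = draw_story_metrics(cfg)
        fit = fit_ztnb(df, UNCONSTRAINED)
        assert fit.converged
        for est, se, truth in zip(fit.beta, fit.se, (1.0, -0.2, -0.2)):
            assert abs(est - truth) < 3 * se

    def test_intercept_only_matches_grid_search(self, paper_corpus):
        fit = fit_ztnb(paper_corpus, INTERCEPT)
        y = paper_corpus["peak_frequency"].to_numpy()
        grid = np.arange(-1.0, 3.0, 1e-4)
        lls = [ztnb_loglik(y, np.full(y.size, math.exp(b0)), fit.aux)
               for b0 in grid]
        assert fit.beta[0] == pytest.approx(grid[int(np.argmax(lls))], abs=1e-4)

    def test_nesting_monotonicity(self, paper_corpus):
        fits = {s: fit_ztnb(paper_corpus, DesignSpec(s))
                for s in ("intercept", "linear", "quadratic_constrained",
                          "quadratic_unconstrained")}
        dual = fits["quadratic_unconstrained"].logL
        assert dual >= fits["linear"].logL - 1e-8
        assert dual >= fits["quadratic_constrained"].logL - 1e-8
        assert fits["linear"].logL >= fits["intercept"].logL - 1e-8
        assert fits["quadratic_constrained"].logL >= fits["intercept"].logL - 1e-8

    def test_matches_statsmodels(self, paper_corpus):
        from statsmodels.discrete.truncated_model import (
            TruncatedLFNegativeBinomialP,
        )

        from reappear.design import build_design

        X, _ = build_design(paper_corpus["rating"].to_numpy(), UNCONSTRAINED)
        ref = TruncatedLFNegativeBinomialP(
            paper_corpus["peak_frequency"].to_numpy(), X, truncation=0
        ).fit(disp=0, maxiter=300)
        fit = fit_ztnb(paper_corpus, UNCONSTRAINED)
        assert fit.logL == pytest.approx(ref.llf, abs=1e-6)
        np.testing.assert_allclose(fit.beta, ref.params[:-1], atol=1e-4)

    def test_local_optimality_under_perturbation(self, paper_corpus, rng):
        fit = fit_ztnb(paper_corpus, UNCONSTRAINED)
        y = paper_corpus["peak_frequency"].to_numpy()
        from reappear.design import build_design

        X, _ = build_design(paper_corpus["rating"].to_numpy(), UNCONSTRAINED)
        at_opt = ztnb_loglik(y, np.exp(X @ fit.beta), fit.aux)
        for _ in range(50):
            beta = fit.beta + rng.normal(scale=0.05, size=fit.beta.size)
            theta = fit.aux * math.exp(rng.normal(scale=0.05))
            assert ztnb_loglik(y, np.exp(X @ beta), theta) <= at_opt + 1e-9

    def test_aic_identities(self, paper_corpus):
        fit = fit_ztnb(paper_corpus, UNCONSTRAINED)
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.logL)
        assert fit.aicc == pytest.approx(
            fit.aic + 2 * fit.k * (fit.k + 1) / (fit.n - fit.k - 1))
        assert fit.bic == pytest.approx(fit.k * math.log(fit.n) - 2 * fit.logL)


class TestTruncatedPoisson:
    def test_overdispersed_data_rejected_strongly(self):
        cfg = SyntheticConfig(
            counts_per_rating={r: 100 for r in (-2, -1, 0, 1, 2)},
            beta_count=(1.0, -0.1, -0.1), theta=0.8, mode="direct", seed=9)
        df = draw_story_metrics(cfg)
        res = overdispersion_lrt(df, UNCONSTRAINED)
        assert res["p"] < 1e-3

    def test_size_under_truncated_poisson_truth(self):
        # equidispersed truth: boundary-corrected LRT rejects ~ alpha
        rng = np.random.default_rng(31)
        cfg = SyntheticConfig(beta_count=(1.0, 0.0, 0.0), theta=1e6,
                              mode="direct")
        rejections = 0
        R = 200
        for _ in range(R):
            df = draw_story_metrics(cfg, rng)
            res = overdispersion_lrt(df, INTERCEPT, boundary_corrected=True)
            rejections += res["p"] <= 0.05
        assert 0.005 <= rejections / R <= 0.10

    def test_theta_capped_on_equidispersed_data(self):
        cfg = SyntheticConfig(beta_count=(1.2, 0.0, 0.0), theta=1e6,
                              mode="direct", seed=3)
        df = draw_story_metrics(cfg)
        fit = fit_ztnb(df, INTERCEPT)
        assert fit.aux >= THETA_CAP or fit.extra["theta_capped"] \
            or fit.aux > 50.0  # no overdispersion signal


class TestOneInflation:
    def test_mixture_pmf_normalized(self):
        y = np.arange(1, 3001)
        total = np.exp(oiztnb_logpmf(y, 3.0, 1.2, 0.35)).sum()
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_pi_recovery(self):
        rng = np.random.default_rng(77)
        n = 800
        mu, theta, pi_true = 3.0, 1.5, 0.4
        base = ztnb_rvs(np.full(n, mu), theta, rng)
        ones = rng.uniform(size=n) < pi_true
        y = np.where(ones, 1, base)
        df = pd.DataFrame({"rating": np.zeros(n, dtype=int),
                           "peak_frequency": y})
        fit = fit_oiztnb(df, INTERCEPT)
        pi_hat = fit.extra["pi"]
        # binomial MC scale for pi at n=800
        assert abs(pi_hat - pi_true) < 3 * math.sqrt(pi_true * 0.6 / n) + 0.05

    def test_no_inflation_lrt_mostly_non_significant(self):
        rng = np.random.default_rng(13)
        cfg = SyntheticConfig(mode="direct")
        non_sig = 0
        R = 60
        for _ in range(R):
            df = draw_story_metrics(cfg, rng)
            res = one_inflation_lrt(df, INTERCEPT)
            non_sig += res["p"] > 0.05
        assert non_sig / R >= 0.9
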