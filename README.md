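# reappear

Statistical analysis of how **falsehood** and **ambiguity** predict the
*reappearance* of fact-checked stories on social media.

Fact-checking organisations (Snopes, PolitiFact) rate stories on an
ordinal credibility scale, mapped here to x ∈ {−2, −1, 0, 1, 2} from
false to true. For each story with a daily tweet-count series
X = (x₁, …, xₙ), two response variables summarize its long-term
dynamics:

* **Peak frequency** — the number of local maxima that reach at least
  10% of max(X) and lie at least 7 days apart. Each surviving peak
  marks one reappearance of the story.
* **Burstiness** — max(X) / Σxᵢ ∈ (0, 1]; a value of 1 means all
  activity fell on a single day.

Both are modelled as polynomial functions of the rating inside the GLM
framework:

* peak frequency ~ **zero-truncated negative binomial** (log link):
  log μᵢ = ηᵢ, with dispersion θ for overdispersed counts that are
  never zero;
* burstiness ~ **beta regression** (logit link): logit μᵢ = ηᵢ, with
  precision φ.

Four linear predictors are compared per response:

| model | ηᵢ | tests |
|---|---|---|
| null | β₀ | no effect |
| falsehood | β₀ + β₁xᵢ | linear credibility effect |
| ambiguity | β₀ + β₂xᵢ² | quadratic (mid-scale) effect |
| dual effect | β₀ + β₁xᵢ + β₂xᵢ² | both |

Model evidence is summarized by AIC (plus AICc/BIC), pairwise
**relative likelihoods** RL = exp(ΔAIC/2), and likelihood-ratio tests
on nested pairs; a ΔAIC ≤ 2 between winner and runner-up is reported
as "no decisive support". Robustness checks include truncated-Poisson
overdispersion LRTs, a one-inflated ZTNB mixture, orthogonal
polynomial refits, permutation tests of the Wald z statistics, and
sensitivity grids over detector parameters.

Because the underlying tweet corpus cannot be redistributed, the
package ships a first-class synthetic generator: it can draw modelling
rows directly from the generative inverse of the fitted models, or
plant detectable bursts in raw daily series so the whole pipeline
(binning → peak detection → burstiness → fits) runs end to end with a
known ground truth.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
corpora and write their tables under `results/`:

```sh
python analysis/01_simulate_corpus.py
python analysis/02_compute_metrics.py
python analysis/03_fit_models.py
python analysis/04_controls.py
```

Output of the run shipped in this repository:

```
direct-mode corpus: 123 stories, mean peak frequency 2.82, mean burstiness 0.42
timeseries-mode corpus: 123 stories, 242 planted bursts (per-story 1..9), quadratic effect beta2 = -0.25
planted bursts recovered exactly for 100.0% of stories
Spearman rho(peak frequency, burstiness) = -0.853 (more peaks -> less concentrated activity)
peak frequency: best model by AIC = ambiguity (runner-up within ΔAIC <= 2)
  dual-effect beta2: -0.338 (p = 0.0167)
burstiness: best model by AIC = ambiguity (runner-up within ΔAIC <= 2)
  dual-effect beta2: +0.131 (p = 0.00119)
permutation p-values (B = 999): beta0 = 0.227, beta1 = 0.847, beta2 = 0.005
sensitivity grid (9 usable cells): quadratic significant in 100%, linear in 0%
```

The timeseries corpus was generated with an ambiguity effect only
(β₂ = −0.25 on the count scale, β₁ = 0), and the analysis recovers
exactly that structure: the constrained-quadratic model wins for both
responses, the quadratic coefficient is negative for peak frequency
(inverted U — ambiguous stories resurface most) and positive for
burstiness (U — ambiguous stories are least concentrated), the linear
term is null everywhere, and the permutation and sensitivity controls
confirm the quadratic effect is the stable one.

The same machinery is available as a CLI
(`reappear simulate | metrics | fit | compare | controls | run`) and
as a one-shot configured pipeline (`reappear.run_pipeline`), which
also accepts real tweet streams (CSV/JSONL of story_id + timestamp)
and story tables (verdicts are mapped to ratings internally).

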