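# Methods

## Response variables

A story's daily tweet-count series X = (x₁, …, xₙ) is binned on UTC
calendar days and trimmed to its support (first and last nonzero day;
interior zero days retained).

**Peak frequency** counts local maxima passing two criteria: height at
least `min_height_frac` (default 0.1) of max(X), and pairwise distance
of at least `min_distance_days` (default 7). Two detection modes are
implemented because the two common formalizations disagree on some
inputs:

* `greedy_prune` (default) mirrors general-purpose peak finders:
  candidates are strict local maxima against their immediate
  neighbours, a flat plateau contributes one candidate at its midpoint
  (lower index on even-length plateaus), and out-of-range neighbours
  are treated as smaller so a maximal first or last day is a
  candidate. Height-passing candidates are then pruned greedily in
  decreasing height order (ties to the earlier index), discarding any
  candidate closer than the minimum distance to a kept one.
* `strict_dominance` applies the literal window rule: day i is a peak
  iff xᵢ strictly exceeds every neighbour within `neighbor_window`
  days on both sides (out-of-range comparisons vacuously true) and
  passes the height floor.

The modes agree whenever surviving maxima are at least twice the
window apart; they can differ when tall peaks crowd inside one window
(greedy pruning keeps the tallest of a crowded group, dominance may
keep none). Boundary and plateau policies are chosen so that every
nonzero series has at least one peak — the global maximum always
survives all three rules — which is what makes zero-truncated count
modelling the right likelihood downstream. The greedy order is *not*
a maximum-cardinality selection; it is the documented
tallest-first behaviour, verified in tests against a brute-force
enumeration (never larger than the optimum, always maximal).

**Burstiness** is max(X)/ΣX ∈ (0, 1]. It needs no tuning parameters
and anti-correlates strongly with peak frequency by construction.

## Ingestion rules

Verdict strings are mapped to the five-level rating exactly per the
per-source tables ("False"/"Scam" → −2 … "True" → 2 for Snopes;
"Pants on Fire"/"False" → −2 … for PolitiFact), case-insensitively;
unknown verdicts raise rather than coerce. Tweet cleaning removes
URLs, unhooks @/# (keeping the word), whitelists alphanumerics plus
`?!.,'`, and lowercases. Exclusion rules apply in a fixed order —
semantic-similarity threshold (default 0.7), doubt words (substring on
cleaned text), links to the fact-checking domains, NLI contradiction
label — each producing an audit entry; rules whose columns are absent
are logged as skipped, and similarity/NLI scores are consumed as
precomputed columns or pluggable callables (no language models are
shipped). Tail trimming removes `trim_fraction/2` (default 0.5% per
side, floor count) of a story's tweets at each timestamp extreme; the
total-1% reading was chosen over 1%-per-tail as the natural reading,
and the fraction is configurable. Stories below `min_tweets` (default
3000) are dropped with their counts logged.

## Count models

The zero-truncated negative binomial uses the (μ, θ) parameterization
(variance μ + μ²/θ), P(0) = (θ/(θ+μ))^θ, with the truncated pmf
NB(y)/(1 − P(0)) on y ≥ 1 and log link log μᵢ = ηᵢ. Likelihood,
analytic gradient and optimization all run on the log scale over
(β, log θ). Fits start from the truncated-Poisson coefficient solution
plus a moment-based dispersion guess; optimization is bounded
L-BFGS-B (log θ confined to a wide numerical box, the linear predictor
clipped at ±30) with a restart polish and up to three jittered
restarts; convergence is declared when the gradient infinity-norm is
small relative to the log-likelihood magnitude, and the flag is
reported honestly. Standard errors come from the inverse observed
information, with the Hessian built by central differences of the
analytic gradient. A dispersion estimate diverging past 10⁶ is capped
and flagged as the Poisson limit.

Two degenerate regimes are worth knowing about. When nearly all counts
equal 1, the truncated likelihood has a ridge towards (μ→0, θ→0)
(the logarithmic-series corner) on which β₀ and θ are weakly
identified; slope coefficients remain well behaved, and the
permutation machinery tolerates per-coefficient singular information.
The one-inflated ZTNB (structural probability π of a one, else ZTNB;
π on the logit scale) is prone to the same ridge, so it is fitted from
a small grid of starts including a moment start and an
empirical-excess-of-ones start for π; the LRT against π = 0 is a
boundary test, reported with the naive χ²(1) tail by default and the
½χ²(0)+½χ²(1) correction as an option — the same convention as the
overdispersion LRT of ZTNB against the truncated Poisson.

## Beta regression

Burstiness is modelled as Beta(μφ, (1−μ)φ) with logit link and fixed
precision (no precision covariates). Starts are logit-least-squares
for β and method-of-moments for φ. Exact boundary observations (a
single-day story has burstiness 1.0) are handled by a configurable
policy, default the usual (y(n−1)+0.5)/n shrinkage applied only when
boundary values occur; real corpora (observed range ≈ 0.03–0.92) never
trigger it.

## Model selection

Relative likelihood is implemented as RL(A, B) = exp((AIC_B −
AIC_A)/2): how many times model A is as likely as model B, > 1 exactly
when A has the lower AIC. (The source formula is sometimes printed
with the opposite sign convention; this orientation is the one
consistent with every worked comparison.) RL satisfies
RL(A,B)·RL(B,A) = 1 on every output. Likelihood-ratio tests are
offered only for genuinely nested pairs; the equal-parameter
falsehood-vs-ambiguity pair carries RL only. The winner is the
lowest-AIC model, annotated as not decisively supported when the
runner-up is within ΔAIC of 2. Both Cox–Snell
(1 − exp(2(logL₀ − logL)/n)) and McFadden (1 − logL/logL₀) pseudo-R²
are reported; published pseudo-R² values for truncated models are not
always reconstructible from printed log-likelihoods with either
formula, so no equivalence with any specific published cell is
claimed. Dichotomized effects refit each family on a binary contrast —
false (−2, −1) vs true (1, 2), mid-rating stories excluded; ambiguous
(−1, 0, 1) vs unambiguous (−2, 2) — and report exp(coefficient) (a
rate ratio for counts, an odds-scale ratio for burstiness) with
delta-method standard errors.

## Controls

Orthogonal polynomial contrasts are built by QR of the Vandermonde
matrix against the empirical rating distribution (zero mean, unit
norm, mutually orthogonal); they change the basis, not the span, so
the unconstrained-quadratic fit is invariant — asserted in tests —
while the constrained models become genuinely different (decorrelated)
hypotheses. Permutation tests permute the **rating** column (responses
fixed), the minimal scheme that breaks the rating–response link while
preserving both marginals; each refit warm-starts from the observed
fit, two-sided p-values use the add-one convention
(1 + #{|z_b| ≥ |z_obs|})/(B+1), and runs with more than 5% failed
refits are invalidated. Default B is 10,000 for production runs and
199 in tests. Sensitivity grids recompute metrics and the four-model
comparison per cell over detector or threshold parameters, marking
cells with fewer than 10 surviving stories unusable. The temporal
check is a median split on story onset with a binary late-half
indicator through each family model; smoother-based temporal analysis
is deliberately out of scope.

## Synthetic data

The generator's defaults are the emulated study conditions: 123
stories split 92/9/22 across ratings −2/0/2 (the three-way grouping is
the only published split; a flag can spread it), count polynomial
(log 2.8, −0.1, −0.1) with θ = 1.2 giving a marginal peak-frequency
mean near 3 with strong overdispersion and a right-skewed, mostly
small-count distribution, and burstiness polynomial (−0.5, 0.05, 0.05)
with φ = 4 giving mean ≈ 0.4, SD ≈ 0.22. ZTNB draws use the exact
inverse CDF of the truncated law (u rescaled to (P(0), 1), then the
untruncated quantile function), keeping tails correct at small means.

Timeseries mode plants m ~ ZTNB bursts per story: burst centres are
uniform over all feasible placements with pairwise separation ≥ 14
days (twice the detector distance), each burst is a discretized
log-normal day profile (shape 0.6, median 3 days, 10-day support)
scaled to a peak height ≥ 25% of the story's tallest burst (itself
uniform on 150–600), over Poisson(2) background days; durations are
uniform on 60–400 days and resampled a bounded number of times when m
separated bursts do not fit, then an error is raised. These margins
make planted bursts detectable by construction (recovery ≥ 95% at
default detector settings, empirically 100% on test corpora), which is
what the calibration tests verify.

What the generator does **not** emulate: textual content, user/bot
behaviour, network cascades, weekly seasonality, trend drift, or
correlated noise between stories. Passing tests therefore demonstrate
the correctness and calibration of the estimators and the pipeline
under the assumed generative models — not that real corpora satisfy
those models.

## Problem sizes and seeds

Simulation-based tests use the package's standard study conditions:
recovery and permutation calibration on corpora of n = 500 (balanced
ratings) and n = 123 (study split) respectively, 200 replicates each
with B = 199 permutations; model-selection frequency over 100
replicates. All randomness flows from explicit seeds; a pipeline run
is a pure function of (inputs, RunConfig), with per-stage substreams
derived from the single run seed, and reruns are byte-identical.

## Known limitations

* The exact argument set the original peak-frequency analysis passed
  to its peak finder (plateau policy, boundary handling) is not
  recoverable; both plausible semantics are implemented and the
  default is documented above.
* Intercept and dispersion of the ZTNB are weakly identified when
  almost all counts are 1; reported standard errors can be singular
  there (flagged, not hidden).
* The one-inflated mixture shares mass with low-(μ, θ) ZTNB shapes;
  its point estimate of π is noisy at realistic sample sizes even when
  the LRT is well calibrated.
* McFadden pseudo-R² is not meaningful when the null log-likelihood is
  positive (possible for beta regression); both definitions are
  reported and the caveat applies to the reader.
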