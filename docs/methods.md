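# Methods

This note documents the models, the synthetic-data design, the numerical
choices and the known limitations of `ldldur`. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Network model

A lexicon of word types is encoded twice. The cue matrix **C** is binary
(word × triphone): a word's transcription is padded with one boundary symbol
`#` on each side and decomposed into all overlapping three-symbol windows, so
an *n*-phone word contributes exactly *n* triphones; repeated triphones
within a word collapse to a single 1 (presence/absence coding). One symbol
per phone is assumed (DISC-style); multi-character phone symbols are not
supported. Cue columns are sorted lexicographically for stable serialization.

The semantic matrix **S** (word × D) is assembled from a lexome vector
store. Monomorphemic rows are always the word's own content vector. Derived
rows depend on the architecture: the *idiosyncratic* network uses the
derivative's content vector alone; the *morphology* network adds the
category's function vector to it; the *base* network adds the function
vector to the base's content vector instead. Derivatives whose bases are
themselves derived are rejected at load time — the additive construction is
undefined for them.

The comprehension and production mappings are the least-squares solutions
F = C⁺S and G = S⁺C, computed with the SVD-based pseudoinverse and numpy's
relative singular-value cutoff (machine precision × max dimension × largest
singular value). Recognition accuracy scores a word as correct only when its
own target attains the strictly maximal Pearson correlation among all target
rows; ties (within 1e-12) are counted and scored incorrect, which makes the
statistic deterministic. Zero-variance rows are excluded and logged.

## Measures

The *articulatory path* of a word is its own triphone sequence, with
supports read from the word's predicted form vector ĉ. (Production accuracy
in well-trained networks is near-perfect, so predicted and target paths
coincide almost always; graph-search synthesis of novel paths is out of
scope.) The support of a node is its clamped activation max(ĉ, 0) normalized
over all inventory cues sharing its two-symbol left context — a selection
probability bounded by 1, defined as 0 when no competitor has positive
activation. From this:

- *path sum* Σ supports; *mean word support* divides by path length. The
  node count is the default divisor, with a `divisor="transitions"` switch,
  because the two conventions differ for short words and the field's usage
  is not uniform; coefficients rescale but signs are unaffected.
- *path entropies* is the Shannon entropy (base 2) of the supports
  normalized to a distribution; a path with zero total support has no
  defined entropy and the measure is flagged missing (NaN) and logged.
- *semantic vector length* is the L1 norm of ŝ.
- *semantic density* is the mean correlation of ŝ with its k = 8 nearest
  neighbors, computed within the predicted matrix Ŝ by default
  (configurable to the target matrix S).
- *target correlation* is Pearson r between ŝ and s.

Group contrasts of measure distributions use the two-sided Wilcoxon
rank-sum test (exact for small tie-free samples, normal approximation with
tie correction otherwise).

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
English. Its defaults define the study conditions used by the analysis
scripts, the acceptance script and the recovery experiments:

- **Lexicon**: 160 monomorphemic bases (3–6 phones, uniform over a
  six-symbol inventory) plus five derivational categories × 48 types,
  mixing one prefix and four suffixes. The inventory is deliberately small
  so that a few hundred types nearly saturate the space of possible
  triphones and the cue matrix is not trivially full row rank — the regime
  of large natural lexicons, where predictions are genuinely smoothed.
- **Vectors** (D = 150): monomorphemic content vectors are i.i.d. standard
  normal per dimension with a per-word lognormal magnitude factor
  (sd 0.4 on the log scale). The magnitude heterogeneity emulates the broad
  word-to-word length variation of empirical lexome vectors; without it,
  vector length and neighborhood density are both monotone functions of the
  category shift alone and become unresolvably collinear, a regime the
  duration analysis excludes by design (VIF screening). Each category has
  an independent function vector with sd `shift_vector_scale` (0.7–1.5
  across the five categories, emulating differing semantic transparency),
  and a derivative's content vector is base + function + N(0, 0.5²·I)
  idiosyncratic noise.
- **Segments**: mean durations uniform on [40, 120] ms per phone.
- **Tokens**: per-type counts are zero-truncated geometric with mean 4
  (so ~25% of types are hapax, exercising the mixed-model repeated-type
  filter); speech rate is N(4, 1) syllables/s per token; durations follow
  intercept 60 ms + 1.0 × baseline + β·measures − 15 × speech rate + a
  type-level random intercept (sd 12 ms) + residual N(0, 30²), with
  non-positive draws rejected and redrawn (counted, and failing loudly if
  the configuration makes positivity implausible). Generating measure
  coefficients are +12 (mean word support), −6 (path entropies), −5
  (vector length) ms per SD, with semantic density and target correlation
  null — signs chosen to match the direction-of-effect pattern the
  pipeline is meant to detect (certainty lengthens, uncertainty and
  activation diversity shorten).

A single seed drives all stages through spawned substreams; identical
configurations give bit-identical output.

## Duration analysis

Baseline duration is the sum of mean segment durations. The response,
*duration difference*, is the residual of observed duration on baseline
duration (OLS with intercept over all tokens), making the response
orthogonal to segmental makeup in-sample.

**Predictor construction.** Because the response is baseline-residualized,
regressing it on raw measures leaks the word-length channel (path entropy in
particular correlates with length) and biases coefficients. The pipeline
therefore z-scores each measure across tokens and orthogonalizes it against
baseline duration (re-scaled to unit variance) before both token generation
and fitting; speech rate enters raw. This is an identifiability choice: it
keeps segmental makeup entirely in the response construction and makes the
two-step estimator exactly calibrated for the generating model. Raw
measures are used for all distributional and neighbor analyses. Measures
with near-zero variance (e.g. target correlation in an exactly
interpolating network) are dropped from the models with a log note.

**Fitting.** The standard model is OLS (adjusted R² reported). The mixed
model has a random intercept by word type, fit by REML via statsmodels
MixedLM, with types observed only once excluded beforehand (counts
recorded) and near-zero random-intercept variance flagged as singular.
Marginal and conditional R² follow the variance-components formulas
(fixed-effect variance share, and fixed-plus-random share, of
var(Xβ) + τ² + σ²). Fixed-effect p-values use the Wald normal
approximation; at the token counts used here (hundreds to thousands of
observations, hundreds of types) this is numerically indistinguishable from
finite-df corrections, and the fit is cross-checked against R's lme4 in the
test suite.

**Procedure order.** Backward stepwise elimination (drop the largest
p ≥ 0.05 among non-forced terms, refit, repeat; speech rate always
retained) runs on the untrimmed fit, and a single 2.5-SD standardized
residual trim with one refit is applied to the final model. Testing after
trimming would operate on a truncated residual distribution whose σ is
underestimated by ~4.5%, measurably inflating the type-I rate of the
selection step; simplification before trimming keeps the stepwise p-values
calibrated while still reporting one removal count per final model.
Trimming that would remove more than 20% of observations aborts (suspect
data). VIFs are computed for the full predictor set; the lmg decomposition
enumerates predictor subsets with combinatorial weights (exact for ≤ 10
predictors; shares sum to the model R² identically for OLS, and the mixed
variant decomposes the marginal R² analog by refitting per subset).

## Calibration experiments

Two experiment designs back the end-to-end claims, scaled to run in minutes:

- *Coefficient recovery*: 50 replicate studies under the default
  conditions; each refits the generating model (the three non-null measures
  plus speech rate) as a trimmed mixed model. Sign recovery is required in
  every replicate and 95% CI coverage pooled over coefficients and
  replicates must reach 90%. The recovery fit deliberately matches the
  generating specification — recovery of a known model is only defined for
  the model that generated the data; variable-selection behavior is tested
  separately.
- *Type-I control*: one study's measures held fixed, 200 token redraws with
  all measure coefficients zero and type-intercept sd 0 (the selection
  procedure is evaluated under its own exchangeable-error assumptions),
  stepwise retention of each null measure required to stay near the nominal
  α.

## What the synthetic data does and does not show

Passing tests demonstrate that the implementation is internally correct and
statistically calibrated: the mappings are exact least squares, the measures
match their definitions, category structure encoded only in the vector
geometry re-emerges in the measures, and the regression machinery recovers
known effects at nominal error rates. They do not show anything about
English: the generator has no phonotactics, no frequency structure, and its
additive vector construction is an idealization. Two known departures from
empirical behavior follow from that idealization: (i) because a derivative's
content vector literally contains base + function, the idiosyncratic and
morphology semantic spaces are always highly correlated at the target level
— the strong dissociation seen with corpus-trained vectors (where a
derivative's vector is largely unrelated to base + affix) cannot arise; the
category-information contrast appears instead as the two category-aware
networks agreeing with each other more than the category-blind network
agrees with the compositional one. (ii) Neighbor type diversity is lowest
in the morphology network (whose rows double the category vector), not in
the base network; the base network's degenerate neighborhoods in empirical
data rest on vector structure the generator does not model.

## Problem sizes

Default study: 400 word types, ~280 triphone cues, D = 150, ~1,600 tokens.
Acceptance experiments use 50 replicates (recovery) and 200 redraws
(type-I); unit tests use 40–80-type lexicons. These sizes were chosen so
every matrix operation is exact dense linear algebra and the full suite
runs in a couple of minutes on one CPU.
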