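# Methods

## Data model

Four tables drive the analysis. **Business listings** carry a unique id,
a region code (49 US states plus DC; New Jersey is absent from the
default outcome universe), 1–3 category labels, an optional ordinal
price tier (1–4 from the `$`…`$$$$` symbols), a half-step star rating in
[0.5, 5.0] and a non-negative review count. **Nutrition records** are
crowd-sourced calorie entries: a dish name, calories per stated serving,
a serving quantity, and a free-text serving unit in mixed dialects.
**Popular-dish tables** rank dishes per category. **Obesity tables** map
region codes to adult obesity prevalence in percent.

Dish names are lowercased and whitespace-collapsed before any join;
matching after normalization is exact — no fuzzy matching is attempted,
so crowd-sourced spelling variants of the same dish are treated as
distinct dishes. A category registry flags which listing categories are
food-related; non-food labels are stripped at ingest and businesses left
with no food category are dropped (and counted). On disk everything is
UTF-8 CSV, with the multi-valued `categories` column JSON-encoded.

## Availability, affordability, acceptability

Availability of category *c* in region *s* is `a_cs = N_cs / N_s`. A
business with *k* categories increments *k* numerators but the
denominator once, so `Σ_c a_cs ∈ [1, 3]`. A region with zero businesses
has no availability row at all rather than zeros — absence of evidence
is flagged, not imputed.

Between-region contrasts rank the net value `|a_cA − a_cB|` descending
(ties broken by category label) over categories present in either
region; a category absent from one side counts 0 there. Each category
gets a pooled two-proportion z-test,

    z = (p̂₁ − p̂₂) / sqrt(p̂(1−p̂)(1/n₁ + 1/n₂)),  p̂ = (x₁+x₂)/(n₁+n₂),

two-sided against the standard normal. The pooled variant was chosen
over the unpooled one because the null hypothesis being ranked is "same
availability". A degenerate pooled proportion (0 or 1) carries no
information and is reported as z = 0, p = 1. Raw p-values are the
default — the tiered annotation (≤.001, ≤.01, ≤.05) describes them — and
an optional Benjamini–Hochberg flag provides FDR adjustment for users
who want multiplicity control over the ~60–226 simultaneous category
tests.

Affordability is the mean numeric price tier of a category's businesses
in a region; businesses without a listed price are excluded from the
price mean only, not from rating/review means (dropping one field loses
less information than imputing an ordinal tier). Acceptability is the
mean star rating and the raw mean review count (no log transform; the
feature is defined as an average count).

## Caloric density and the weighted score

Calories-per-gram is only defined when the serving is a mass, so dish
density uses only records whose trimmed, lowercased unit is one of
`g`, `gr`, `gram`, `grams`. A dish's density is the mean of
calories/serving-grams over those records; a dish with none has no
density. A category's density is the unweighted mean over its *distinct*
popular dishes that have densities. No plausibility filter is applied to
raw records by default — crowd data is taken at face value — but a
configurable density cap can drop implausible entries.

The region score is the *normalized* availability-weighted mean

    W_s = Σ_c a_cs d_c / Σ_c a_cs,

over categories having both an availability > 0 and a density.
Normalization matters: availabilities do not sum to 1 (multi-category
businesses), and dividing by their sum makes `W_s` a convex combination
of category densities, guaranteeing `min_c d_c ≤ W_s ≤ max_c d_c` —
consistent with a realistic score range sitting inside the category
density range. The score is correlated with obesity prevalence by the
ordinary Pearson product-moment coefficient; constant inputs raise
rather than returning NaN.

The two-region caloric contrast needs a sampling unit, and businesses
are the only one available: each business is assigned the mean density
of its density-bearing categories, and the two per-business samples are
compared with an unpooled two-sample z statistic
`(m₁−m₂)/sqrt(s₁²/n₁ + s₂²/n₂)` with a normal two-sided p (sample sizes
are in the thousands, so a t reference would be indistinguishable).

## Feature assembly and zero-fill

The feature matrix has one row per region and, per category, four
columns (availability, mean price, mean rating, mean reviews), plus one
weighted-score column; columns are ordered by category label then
metric, so assembly is invariant to business row order. Category-region
combinations with no businesses are zero-filled across all four columns,
and the fraction of zero-filled per-category cells is tracked — it
measures the sparsity of category coverage (roughly a fifth to a quarter
of cells at realistic scales). Regions missing from the outcome table
are dropped with a warning rather than imputed.

## Prediction

Leave-one-out cross-validation fits N models, each on N−1 regions,
predicting the held-out one; the vector of held-out predictions is
scored by Pearson r against the actual rates. Four families: ordinary
least squares, random forest (100 trees), RBF support-vector regression,
and gradient-boosted trees (100 rounds), all otherwise at library
defaults — the defaults are exposed per family rather than tuned,
because with ~50 samples any within-fold tuning would be noise-chasing.
Linear and SVR pipelines standardize features with train-fold statistics
only (kernel methods are scale-sensitive; fold-local statistics prevent
leakage — for least squares standardization is a no-op on predictions).
Stochastic families are re-seeded per fold as `seed + fold_index`, so
results are reproducible and folds independent. The weighted-score-only
feature set is a single column, for which only the linear family is fit;
other families are marked not-applicable in the evaluation grid.

Two structural guards are tested: corrupting a held-out region's outcome
never changes that region's prediction, and on worlds with no planted
link the mean LOOCV r over 20 seeds is not significantly positive.

## Synthetic worlds

The generator emulates the structure of crowd-sourced listing and
nutrition data: businesses drawing 1–3 categories from a region-specific
mix, ordinal price tiers (default probabilities 0.50/0.38/0.09/0.03,
10% missing), half-step ratings (normal around 4.0, sd 0.75, clipped),
log-normal review counts (log-mean 3.6, log-sd 1.4 — mean ≈ 99 with a
heavy tail, matching summary statistics typical of review platforms),
mixed serving-unit dialects (25% non-gram by default) and multiplicative
per-record calorie noise (log-normal, coefficient of variation 0.15,
mean exactly 1 so densities are unbiased).

Region mixes are Dirichlet(2) draws tilted by
`exp(skew · t_s · w_c)` where `t_s ~ Uniform(−1, 1)` is a region's
latent leaning and `w_c` the category's obesogenic weight (the
standardized true density). Each region then drops its lowest-weight
22% of categories entirely, reproducing the sparsity that makes
zero-fill necessary in real listing data. The true environment score is
the mix-weighted mean of true densities, `E_s = Σ_c m_cs d_c`, and

    obesity_s = intercept + slope · E_s + ε_s,  ε_s ~ N(0, σ),

clamped to (5, 60)%. The defaults (intercept 4, slope 10, σ 0.8) were
calibrated once against the generator's own E_s distribution
(mean ≈ 2.7, sd ≈ 0.55 kcal/g under skew 1.2) so that rates span
roughly 20–42% — the observed range for US states — with a planted
signal-to-noise ratio `slope·sd(E)/σ ≈ 7`. A slope of zero gives a null
world; a degenerate configuration (signal below noise) warns rather
than fails. Everything is driven by one `numpy` Generator seed: equal
seeds give byte-identical worlds.

The study-scale default (50 regions, 62 categories, 2000 businesses per
region, 5 dishes per category, 8 records per dish) generates in about
two seconds and runs the full pipeline including a random-forest LOOCV
in well under a minute; tests use scaled-down worlds (8–20 regions,
tens of businesses each) chosen so the whole suite stays fast while
still exercising every stage at realistic sparsity.

What the generator does *not* emulate — geography and spatial
autocorrelation, chain businesses, menu-level heterogeneity within a
category, socioeconomic confounders, reporting bias in crowd-sourced
calories — bounds what passing tests show: they demonstrate that the
estimators recover a planted link of the assumed linear form under
realistic noise and sparsity, not that such a link has that form (or
that magnitude) in real data.

## Numerical choices and edge cases

- Noiseless limit: with calorie noise 0 and all-gram units, dish and
  category densities equal the planted truth to floating-point
  round-off, and region scores equal the same weighted mean computed
  from true densities (tested at 1e-9).
- The two-proportion z-test's p-value is validated against a permutation
  oracle. The permutation null is discrete: the observed difference
  carries tie mass, so the continuous normal p is required to lie
  between the strict-exceedance and inclusive-exceedance permutation
  probabilities (± 3 Monte-Carlo standard errors at 10⁵ shuffles), the
  sharpest statement that holds for a discrete null.
- Linear LOOCV is validated against the closed-form leave-one-out
  identity `ŷ₋ᵢ = yᵢ − rᵢ/(1−hᵢᵢ)`.
- Ties in net-value ranking break lexicographically; grid "best" flags
  the single maximal cell.
- Degenerate inputs raise early with the offending region, line or
  field named: empty business lists, zero-business regions, constant
  outcomes, zero-variance correlations, categories with no
  density-bearing dish.

## Known limitations

Ecological design: all associations are at region level and carry no
individual-level interpretation. Exact name matching understates
nutrition coverage. The density estimate inherits whatever biases
crowd-sourced calorie entries have. The synthetic obesity link is
linear by construction; model comparisons on synthetic worlds therefore
say little about which family would win on real data.
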