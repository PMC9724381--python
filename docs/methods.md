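# Methods

This note documents the statistical model behind `bpae`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate.

## The estimation problem

A seven-question instrument asks how often a participant performs dietary
behaviors that raise BPA exposure (canned food, microwaving in plastic,
polycarbonate bottles, hot drinks in hard plastic cups, stretch-wrap
microwaving, microwaveable meals, packaged food). The reference
measurement is a set of 24-hour dietary recalls in which every consumed
food carries a free-text description, a serving count, and a gram amount.
Validation asks: do questionnaire responses track the BPA-relevant food
consumption visible in the recalls?

## Recall-side exposure metrics

Food descriptions are searched case-insensitively for the substrings
`canned`, `packaged`, `microwave` (so "microwaveable" matches). Each item
receives exactly one category; when several keywords occur, precedence is
canned > microwave > packaged. Canned carries the highest weight, so this
precedence is conservative for the exposure metric; the rule is an
explicit argument of `classify_item` for sensitivity analyses.

Per participant-day:

* weighted servings = 1.0·(canned servings) + 0.25·(packaged servings)
  + 0.25·(microwave servings); the weights encode relative contamination
  potential of the packaging types;
* total grams = the unweighted gram sum over items in any of the three
  categories.

Both are averaged over the participant's *observed* recall days (default
design: three days). A day with recall rows but no classified item is a
valid zero-exposure observation; a day with no recall record at all is
missing data and is excluded from the mean rather than imputed as zero.
Participants with no recall days are flagged and excluded.

## The composite BPAe score

1. Answers are recoded to integers with 1 = lowest exposure frequency.
2. PCA runs on the correlation matrix (standardized recoded responses).
   The questions have different category counts, so correlation scaling
   stops any single question from dominating the decomposition.
3. The minimum number k of components with cumulative explained variance
   ≥ 90% is retained. Explained-variance proportions always use all
   components' eigenvalues as the denominator ("percentage of variation in
   the data" means total variance).
4. Each participant's weighted sum is Σⱼ scoreⱼ·wⱼ over the retained
   components, with wⱼ the raw variance proportions — deliberately *not*
   renormalized over the retained set, so three components at 75%/10%/5%
   with unit scores give 0.90, not 1.0.
5. BPAe is the quintile (1–5) of the weighted sum: empirical quantile
   breaks at 0.2/0.4/0.6/0.8, right-closed intervals (a value equal to a
   break goes to the lower quintile). Quintiles depend only on ranks, so
   BPAe is invariant to any increasing affine rescaling of the sums.

PCA component signs are arbitrary; each loading vector is flipped so its
coefficient sum is positive (first nonzero coefficient positive on an
exact tie). Without a sign convention the weighted sum — and therefore the
quintile assignment — would be ill-defined.

Degenerate inputs: a constant question column is dropped from the PCA with
a warning; if *every* response is identical the score is degenerate and
all participants receive quintile 1 with a warning, which the report
surfaces. By default BPAe is computed on complete cases; the imputation
machinery can alternatively score each completed dataset.

The score is validated by tabulating each question's mean recoded response
across BPAe levels and flagging non-decreasing patterns; in a
well-functioning instrument nearly all questions should be monotone.

## Missing data

"I don't know" answers are converted to the missing code and imputed
together with blank answers. Imputation is chained-equation predictive
mean matching on the integer recodes:

* per variable, a Bayesian linear regression on the other six questions
  (σ² drawn from the scaled inverse-chi-squared posterior, β from its
  normal posterior) produces predictions; each missing row is matched to
  the k = 5 observed rows with the nearest predictions and copies one
  randomly chosen donor's observed value. Donor copying guarantees every
  imputed value is a legal category code, and PMM stays stable in the
  sparse top categories where polytomous models can fail to converge.
* m = 5 completed datasets, 10 sweeps each, fixed left-to-right visit
  order. One master generator spawns a seed per dataset, so (input,
  config, seed) fully determines all outputs. Per-sweep mean imputed codes
  are recorded as a convergence trace.
* Optional fully observed `auxiliaries` columns can enter every
  conditional model without being imputed. Including the analysis outcome
  makes the imputation model congenial with the analysis model; leaving it
  out (the default, since only questionnaire data are imputed) attenuates
  regression coefficients on imputed predictors slightly. The test suite
  measures both behaviors.

## Inference

*Rank route.* Weighted servings and total grams are strongly right-skewed
(Poisson-lognormal item structure), so equality across the five BPAe
groups is tested with the tie-corrected Kruskal–Wallis H against a
chi-squared reference, followed (when significant) by Dunn's pairwise z
tests using the tie-corrected pooled rank variance. The Bonferroni family
is a declared input: all 10 BPAe pairs by default, and a 2-comparison
family (per-comparison α = 0.025) for the focused canned-food follow-up.

*Regression route.* Each question is binned to low (reference) / medium /
high — three levels avoid an ordinality assumption while keeping
interpretable contrasts — and each exposure outcome is regressed on all
seven binned questions (reference-cell dummy coding, 14 non-intercept
terms) within every imputed dataset via OLS. Participants without recall
data are excluded listwise; only questionnaire predictors are imputed.
Rank-deficient designs (an empty bin level in a small cohort) raise an
error naming the offending columns rather than silently dropping terms.

Pooling:

* coefficients by Rubin's rules — pooled estimate = mean, total variance
  T = W̄ + (1 + 1/m)B, Barnard–Rubin small-sample degrees of freedom,
  t-based p-values and 95% CIs;
* adjusted R² via the Fisher-z transform of √R̄²ⱼ (mean in transformed
  space, back-transformed and squared); negative adjusted R² is truncated
  at 0 with a warning; a simple-mean option exists for sensitivity;
* the overall F by the D2 procedure on the per-imputation Wald
  chi-squared statistics: with r = (1 + 1/m)·var(√dⱼ),
  F = (d̄/k − r(m+1)/(m−1)) / (1 + r) on (k, k^(−3/m)(m−1)(1+1/r)²)
  degrees of freedom.

A calibration caveat the test suite makes explicit: D2 is exactly nominal
only when between-imputation variability is negligible. An idealized
simulation (normal estimates, known within-covariance) shows the type-I
error at α = 0.05 falling from 0.052 with no missing information to
≈ 0.007 at a 15% missing-information fraction. With the default
missingness pattern (two questions at 26.2% and 19.8%), the pipeline's
null rejection rate for the pooled F is ≈ 0.015 — conservative, i.e. the
test under-rejects but never inflates type-I error. This is a property of
the D2 combination rule, not of this implementation.

## The synthetic cohort generator

One latent exposure factor per participant, log-normal with log-scale mean
0 and SD 1, drives everything:

* *Questionnaire*: for question q with loading λ_q, the latent (on the
  standardized log scale, z) plus independent Gaussian noise,
  u = λ_q z + √(1−λ_q²) ε, is thresholded onto the question's marginal
  category probabilities via normal quantiles. Default marginals are the
  instrument's observed baseline response distributions (e.g. canned:
  35.0% / 54.1% / 10.9%).
* *Recalls*: per day and packaging category, item counts are Poisson with
  log-rate = base + slope·z; servings per item are log-normal (log-SD
  0.5); grams per serving are log-normal with mean 26 g. Distractor
  (keyword-free) items arrive at 6 per day so classification is
  non-trivial. An optional day-level log-normal rate multiplier adds
  overdispersion; its default is off because day-to-day variability was a
  free choice, not a documented quantity.
* *Missingness*: per question, cells become blank or "I don't know"
  independently (MCAR) at the instrument's observed rates — 26.2% and
  19.8% on the two high-missingness questions, 6.4% on one, < 1%
  elsewhere — with small don't-know rates on the four questions whose
  wording offers that option.

Default effect sizes (all question loadings 0.8; item-rate slopes 0.8 /
0.5 / 0.5 for canned / packaged / microwave) were chosen once so the
planted structure yields the qualitative validation findings at n = 404 —
monotone quintile means in the vast majority of cohorts and positive
question–exposure concordance. Base rates (1.2 / 2.0 / 0.25 items per
day) and the 26 g grams-per-serving scale were calibrated once against
the published exposure medians (≈ 2 weighted servings, ≈ 98 g per day).
`effect_null=True` zeroes all loadings and slopes for calibration studies.

What the generator does *not* emulate: real questionnaires' weak and
heterogeneous question–recall concordance (the synthetic factor structure
is deliberately strong, so passing tests demonstrate that the pipeline
*detects* structure, not that real instruments possess it), informative
missingness, demographic covariates, longitudinal drift across study
visits, and the idiosyncrasies of a real food-coding database — the
built-in dictionary is a small synthetic stand-in whose descriptions
merely exercise the keyword rules.

## Problem sizes in the test suite

Monte-Carlo checks use 500 null cohorts at n = 100 (rank-test and
pooled-F calibration), 200 cohorts at n = 404 (CI coverage, planted-effect
recovery, quintile-mean monotonicity), and 100 imputation seeds for the
MCAR distribution check; these sizes give Monte-Carlo standard errors
comfortably below the tolerances being asserted while keeping the default
test run to a few minutes.

## Known limitations

* The keyword rule inherits the source database's blind spots: packaged
  foods are mostly desserts, very few microwave foods are labeled, and
  descriptions say nothing about packaging material.
* PMM with a shared donor pool can lightly shrink extreme-category
  frequencies when missingness is very high.
* The D2 overall F is conservative under substantial missing information
  (see above); pooled per-coefficient inference is unaffected.
* BPAe quintiles from complete cases discard participants missing any
  answer; with the default missingness pattern roughly 40% of rows drop
  out of the composite-score route (the regression route imputes instead).
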