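# bpae — dietary BPA exposure assessment and questionnaire validation

Bisphenol A (BPA) is an endocrine-disrupting chemical that migrates into
food from packaging — epoxy can linings, polycarbonate plastic, microwave
containers — making diet the dominant human exposure route. Measuring that
exposure with urinary biomarkers or interviewer-administered 24-hour
dietary recalls is accurate but expensive; a short exposure-risk
questionnaire is cheap but needs validation against the richer instrument.

`bpae` implements that validation pipeline for a seven-question dietary
BPA exposure risk questionnaire compared against 24-hour recall data, for
biostatisticians and exposure-assessment researchers. It provides:

* **Recall-side exposure quantification** — free-text food descriptions
  are keyword-classified (`canned` / `packaged` / `microwave`,
  case-insensitive substring match, precedence canned > microwave >
  packaged) and summarized per participant as

  * weighted servings: `Σ servingsᵢ · wᵢ` with `w = 1` (canned) and
    `w = 0.25` (packaged, microwave), reflecting relative contamination
    potential, and
  * total grams: the unweighted gram sum over classified items,

  both averaged over the participant's observed recall days.

* **The composite BPAe score** — questionnaire answers are recoded so
  higher codes mean more frequent exposure behavior, PCA is run on the
  standardized (correlation-matrix) responses, the minimum number of
  components explaining ≥ 90% of total variance is retained, and each
  participant's exposure index is the quintile (1–5) of
  `Σⱼ PCⱼ · λⱼ/Σλ`, the component scores weighted by their raw variance
  proportions. A monotonicity table of per-question mean responses across
  BPAe levels validates the score.

* **Statistical validation** — tie-corrected Kruskal–Wallis tests of the
  exposure metrics across the five BPAe groups (the metrics are heavily
  right-skewed) with Dunn's Bonferroni-adjusted pairwise follow-up;
  "I don't know" answers recoded to missing; chained-equation multiple
  imputation (predictive mean matching, m = 5); per-imputation OLS on the
  three-level binned questions pooled by Rubin's rules
  (`T = W̄ + (1 + 1/m)B`, Barnard–Rubin df), a pooled adjusted R², and a
  D2 (chi-squared-based) overall F.

* **A synthetic cohort generator** — a log-normal latent exposure factor
  drives both the ordinal questionnaire responses (Gaussian-noise
  thresholding onto realistic category marginals) and Poisson item counts
  per recall day in each packaging category, with configurable per-question
  missingness and "I don't know" rates, so every stage can be tested
  against known ground truth.

## Worked example

```sh
bpae simulate --seed 11 --outdir cohort
bpae analyze --questionnaire cohort/questionnaire.csv \
             --recall cohort/recall_items.csv --seed 11 --outdir report
```

prints

```
bpae analysis (seed=11, n=404 participants)
food lists: {'canned': 87, 'packaged': 40, 'microwave': 12}
exposure medians: weighted_servings=2.04 (IQR 2.03), total_grams=107.93 (IQR 103.85)
BPAe: 6 component(s) retained, variance proportions [0.522 0.101 0.093 0.082 0.078 0.064]
monotone questions: 7/7
Kruskal-Wallis weighted_servings: H=125.673, p=0.000
Kruskal-Wallis total_grams: H=120.654, p=0.000
pooled model weighted_servings: adj R2=0.5370, F(14, 12.9)=25.364, p=0.000
pooled model total_grams: adj R2=0.5361, F(14, 11.1)=24.572, p=0.000
```

Reading this: the simulated 404-person cohort eats a median of ~2 weighted
servings (~108 g) of BPA-relevant food per recall day; six principal
components are needed to reach 90% of the response variance, the first
carrying 52%; all seven question means rise monotonically across BPAe
quintiles, so the composite captures increasing exposure; and because this
synthetic cohort has a strong planted latent factor, both the rank tests
and the pooled regressions detect the questionnaire–recall association
emphatically (in real data these signals are far weaker). The report
directory holds every table as CSV (response frequencies, exposure
summaries, BPAe scores, monotonicity, rank tests, pooled coefficient
tables) plus a manifest with the seed and input hashes.

`bpae validate-example` re-derives the built-in arithmetic checks — e.g.
three retained components at 75%/10%/5% of variance with unit scores give
a weighted sum of `1·0.75 + 1·0.10 + 1·0.05 = 0.90` — and exits nonzero on
any mismatch.

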