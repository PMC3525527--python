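# infertrend

Survey-based estimation of infertility prevalence levels and trends,
1990–2010, with uncertainty quantification. The package implements a full
survey-to-estimate pipeline:

1. **`infertrend.simulate`** — synthetic DHS-like survey microdata with known
   ground truth: geographic hierarchies (country → subregion → region), true
   prevalence surfaces on the logit scale, schooling/population context
   tables, and woman-level records planted so that classification recovers
   the surface exactly in expectation. Planted bias archetypes (past
   contraceptive users, remarried women) reproduce the measurement biases of
   surveys that only collect current status.
2. **`infertrend.extraction`** — classification of each woman into four
   indicators (primary/secondary infertility prevalence among child-seeking
   women, exposure to primary/secondary infertility), survey screening
   (>15% missingness drop, ever-married age masking, the China rule for
   secondary infertility), and per-age-group observations with effective
   sample sizes.
3. **`infertrend.correction`** — log-linear regressions mapping biased
   estimates (current contraceptive status, first-union clock) to less-biased
   ones, with prediction uncertainty propagated to the analysis scale.
4. **`infertrend.model`** — Bayesian hierarchical space–time–age model per
   indicator: nested country/subregion/region/global intercepts, region time
   trends nested in a global trend, a schooling covariate, age-group offsets
   (with a High-Income-specific set for exposure to primary infertility), and
   separate extra-variance components for national vs subnational sources.
   Fitted by a blocked Gibbs sampler: exact joint multivariate-normal draws
   of all location parameters and collapsed (marginal-likelihood) slice
   updates for the variance components; 1,600 retained draws across 4 chains
   with split-R̂ convergence checks.
5. **`infertrend.aggregate`** — posterior-draw arithmetic: all-women
   percentages, population-weighted regional/global aggregates, mean +
   2.5th–97.5th percentile summaries, 1990→2010 trends with posterior
   probabilities (significance at pp > 0.975), and couples-affected counts.
6. **`infertrend.crossval`** — country-withholding cross-validation (five
   random 20% samples by default) reporting RMSE in percentage points,
   median relative error, and 95% predictive-interval coverage.

## CLI

```bash
infertrend simulate --regions 3 --subregions 2 --countries 3 \
    --surveys-per-country 2 --women-per-survey 5000 --seed 0 --out data/
infertrend extract  --data data/ --out obs.csv --log screening.csv
infertrend fit      --observations obs.csv --hierarchy data/hierarchy.yaml \
    --indicator primary_prev --seed 0 --out estimates.csv
infertrend crossval --observations obs.csv --hierarchy data/hierarchy.yaml \
    --indicator primary_prev --out cv.json
```

## Survey CSV column dictionary

One row per respondent: `age_years` (int, 15–49), `in_union` (bool),
`years_since_first_union`, `years_in_current_union` (float or empty),
`n_live_births` (int), `years_since_first_birth`, `years_since_last_birth`
(float or empty; empty when no births), `current_contraception`,
`contraception_last_5y` (bool or empty), `desire` (one of `wants_child`,
`undecided`, `declared_unable`, `wants_no_more`, or empty), `survey_weight`
(positive float). Undecided women and women who declare themselves unable
to become pregnant are counted as desiring a child.
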