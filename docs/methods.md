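# Methods

## Model and measures

Net benefit of a treat/don't-treat rule at risk threshold `r ∈ [0, 1)` is
`NB(r) = TP(r)/N − FP(r)/N · r/(1−r)`, in units of true positives per
subject; equivalently `NB(r) = P·se(r) − (1−P)(1−sp(r))·r/(1−r)` with
sensitivity `se`, specificity `sp` and prevalence `P`. A subject tests
positive when their predicted risk **strictly exceeds** `r`; a risk exactly
equal to the threshold is a negative test. Standardized net benefit is
`sNB = NB/P`, with maximum 1 (a perfect classifier at any threshold between
its two risk clusters). Treat All has `NB = P − (1−P)·r/(1−r)` (equal to `P`
at `r = 0`, zero at `r = P`); Treat None is identically 0. The threshold is
the equipoise point of the clinician's utilities: an exchange rate of `K`
false positives per true positive corresponds to `r = 1/(1+K)`.

A polytomous outcome `Y ∈ {0..K}` (0 least severe) is analysed through
binary splits. For ordinal outcomes the K cumulative splits `Y > j` are
generated, with per-subject risk `Σ_{c>j} p_ic`; the first and last are
one-vs-rest, interior ones some-vs-rest. Pooling an interior category with
the two extremes ("some vs severe-or-none") is refused in ordinal mode,
since that contrast is interpretable only for unordered outcomes; nominal
mode additionally offers one-vs-rest for every class and one-vs-one
(conditional risk `p_a/(p_a+p_b)` on the subjects in either class).

Per split, clinician threshold preferences are a distribution `f(r)` and the
utility summary is `wAUCsNB = ∫ sNB(r) f(r) dr`. Across splits, simplex
importance weights `w ~ f(w)` give the integrated summary
`IwAUCsNB = ∫∫ Σ_k sNB_k(r_k) w_k f(r) f(w) dr dw`, which under
independence of thresholds and weights equals `Σ_k E[w_k]·wAUCsNB_k`; that
factorization is used as the primary correctness oracle in the tests, never
as the implementation of the Monte Carlo estimator itself.

## Prediction from published coefficient tables

The cumulative-logit model is parameterized as
`logit P(Y ≤ j) = ζ_j − x'β` with strictly increasing cutpoints `ζ_j`, the
convention of `MASS::polr` and statsmodels' `OrderedModel`. Published tables
for the dehydration models sometimes display the algebra as
`logit P(Y > j) = α_j + x'β`, which would require intercepts *decreasing* in
severity; the printed intercept pairs (−3.38 < 0.66 for the full adult
model, 0.29 < 4.08 for the simplified one) increase, and the printed
coefficients are positive for signs of worse dehydration. The only
convention consistent with both is the ordered-cutpoint form above, with the
"any dehydration" intercept separating none from {some, severe} and the
"severe dehydration" intercept separating {none, some} from severe. This is
a documented interpretation, not something the tables state outright.

Continuous covariates enter on their printed scale ("per 10 mmHg" divides
systolic BP by 10; age per year is used raw), with no centering, since the
tables give no covariate means. Categorical covariates use the printed
reference level with coefficient 0; a level absent from the table and not
the stated reference is an error, never silently zeroed. The under-five
(DHAKA) table prints no intercepts, so its spec refuses prediction until
cutpoints are supplied explicitly — its exact predictions are not
reproducible from the published coefficients alone.

The WHO IMAI rules are two "at least 2 of {…}" clauses evaluated
severe-first (the sign sets overlap in sunken eyes, so precedence matters),
falling through to "no dehydration". Rule outputs enter DCA as indicator
rows of a degenerate risk matrix, making sensitivity and specificity
constant in `r` and the NB curve exactly linear in `r/(1−r)` — an assertable
consequence used in the tests. The under-five IMCI variant is not printed in
the sources used here; arbitrary rule sets in the same m-of-n schema can be
supplied instead.

## Numerical choices

- **Thresholds** live in `[0, 1)`; curve grids run over `[0, 1−grid_step]`
  (default step 0.001) because the odds weight diverges at 1.
- **Exact areas.** Between consecutive distinct predicted risks the
  confusion counts are constant, so `∫ NB(r) dr` is evaluated segment-wise
  with the closed form `∫ r/(1−r) dr = −r − log(1−r)` — no grid error. The
  uniform-`f(r)` weighted area is this integral divided by the range width.
- **Monte Carlo.** `wAUCsNB` and `IwAUCsNB` use inverse-CDF sampling
  (10,000 draws per split by default; at that size the MC standard error is
  well below the two decimals reported in summary tables). Normal threshold
  distributions are truncated to (0,1) and renormalized; a normal with at
  least half its mass outside (0,1) is rejected as a configuration error
  rather than concentrated at the boundary. Threshold draws across splits
  and weight draws are mutually independent by default; a comonotone option
  couples all splits' thresholds through one shared uniform for sensitivity
  analyses.
- **Bootstrap.** Nonparametric subject-level resampling (labels and risks
  jointly), percentile intervals, 1000 replicates by default. Monte Carlo
  sub-seeds are spawned deterministically from the master seed
  (`SeedSequence`), so identical inputs, configuration and seed reproduce
  the summary bit-for-bit. A resample on which a statistic is undefined
  (e.g. a split with no positive subjects) is redrawn and counted in the
  summary metadata; after 10× the requested replicates the run aborts.
- **Validation over repair.** Risk-matrix rows must sum to 1 within 1e-6 on
  read (reported by row, never renormalized silently); outcome categories
  must be contiguous from 0; text-labelled ordinal outcomes require an
  explicit level order — alphabetical inference is refused. Summary CSVs
  print probabilities with 12 significant digits so a write/read round trip
  is exact to below 1e-12.

## Synthetic cohorts

The generator emulates a three-category dehydration cohort: bedside signs
drawn from stated marginals, the published simplified adult model as the
data-generating truth, outcomes drawn from each subject's true probability
row (returned alongside the cohort). Sign prevalences are fixture choices
tuned so every outcome category carries ≥ 10% mass (roughly 22% none / 67%
some / 11% severe); the source studies do not report category prevalences,
so no claim of realism beyond plausibility is made. Extra boolean signs
(lethargy, inability to drink, eager drinking) are included so the WHO
rule-based classifier runs on the same table. The generator draws covariates
independently and adds no missingness or measurement error, so passing tests
demonstrate the correctness of the utility machinery under the stated model,
not robustness to the dependence structure of real bedside data. Percent
dehydration is `100·(stable − admission)/stable` (signed, unclamped), and
its categorization puts the boundaries 3% and 9% in "some" (the band is
3–9% inclusive, against strict <3% and >9%). The stable-weight measurement
protocol itself (averaging repeated post-rehydration weighings) is out of
scope.

## Verification strategy and problem sizes

The suite checks, at fixed seeds: the closed-form anchors above to 1e-12;
the count-form/sensitivity-form identity of NB on 1000 random confusion
tables; `sNB·P = NB`; exact linearity of the importance-weight sensitivity
profile; Monte Carlo weighted areas against exact quadrature within 3 MC
standard errors (100,000 draws, one 2000-subject cohort, for the model and
both references); parameter recovery of the generator's cumulative-logit
truth by statsmodels' `OrderedModel` (100 replicates of n = 2000; pooled
95%-CI coverage of the eight true coefficients required in [0.90, 0.99]);
generated category frequencies against mean true probabilities within 3
binomial standard errors at n = 50,000; and empirical coverage of the 95%
percentile bootstrap interval for the severe-split wAUCsNB in [0.90, 0.98]
over 200 cohorts of n = 500 (250 resamples each, against the population
value computed once on a 400,000-subject cohort). These replicate counts and
cohort sizes are chosen so each study's simulation error is small relative
to its acceptance band while the full suite stays desk-scale.

## Known limitations

- Published coefficient tables are reproduced to their printed (2 d.p.)
  precision; predictions inherit that rounding.
- The importance-weight and threshold distributions are inputs, not
  estimates; the package deliberately provides no elicitation machinery.
- Percentile bootstrap intervals can undercover for very small cohorts or
  very rare positive categories; the degenerate-resample counter in the
  summary metadata flags the latter.
- Only the logit link is implemented for ordinal prediction; probit and
  complementary log-log are natural extension points but out of scope.
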