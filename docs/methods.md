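# Methods

This note documents the models, conventions and design choices behind
`t2drisk`, and what its synthetic-data-based tests do and do not
demonstrate about real cohort data.

## Synthetic cohort model

The generator emulates the structure of a population-based T2D study with
a baseline examination and a partial ~7.5-year follow-up. It is a
*structural* emulation: distributions are plausible for the named
quantities (age ~ N(49, 16) years clipped to 18–90, BMI ~ N(27.8, 5.1)
kg/m², fasting glucose ~ N(94, 19.5) mg/dL, food-frequency items as
Poisson counts in mixed declared periods, …) but make no claim of
epidemiological realism beyond the documented composition counts.

**Latent risk and exact-count labels.** A latent risk score on the
log-odds scale is a linear combination of standardized driver features
plus N(0, 1) noise. The default drivers are fasting glucose (+1.6),
age (+0.9), BMI (+0.7), first-degree T2D relatives (+0.45) and sugared
soft drinks (+0.35) — a strong clinical marker, two strong and two weak
environmental markers. Labels are assigned by *exact-count thresholding*:
the configured number of positives is taken from the top of the latent
ordering (seed-stable tie break), not by Bernoulli draws, so the printed
composition is reproduced deterministically for every seed:

| quantity | default | note |
|---|---|---|
| individuals | 4617 | |
| known (pre-study) T2D | 417 | excluded from all tasks |
| newly diagnosed at baseline | 227 | 227/4200 = 5.405% → prints 5.4% |
| follow-up participants | 1850 | 1608 eligible + 100 known + 80 baseline + 62 incomplete |
| prognosis-eligible | 1608 | |
| incident T2D | 125 | 125/1608 = 7.77% → prints 7.8% |

The integer counts 227 and 125 were chosen because the study reports only
the rounded percentages; any count whose ratio rounds to the printed value
is admissible, and these are fixed once in the default configuration. A
per-individual follow-up time ~ N(7.48, 0.55) years is stored for
completeness but used by no downstream stage.

**Feature inventory.** The raw environmental layer has 242 columns that
collapse deterministically to 84 engineered ENV features with the
taxonomy breakdown 51 lifestyle/family-history + 8 anthropometric/age/sex
+ 11 diseases/treatments + 14 geospatial, plus 16 clinical features
(HEA = 100). Per-group source counts inside the food-frequency
questionnaire (e.g. 40 sugar-snack items, 24 carbohydrate items of which
8 whole-grain) are the package's own invention; only the totals are
externally constrained.

**Missingness.** Three mechanisms: (a) per-source MCAR (2% lifestyle and
anthropometric, 1% disease, 5% clinical); (b) individual-level block
wipes — a single indicator removes the whole food-frequency questionnaire
(12% of individuals) or the exercise block (10%), producing the monotone
multivariate patterns typical of questionnaire data; (c) geospatial
missingness as a deterministic function of municipality coverage: exactly
round(0.504·n) individuals are assigned to municipalities without a
pollution registry, and 20% of municipalities lack income records.

## Geospatial augmentation

Temporal aggregation (recency-weighted moving average, weights 1…n over
n(n+1)/2) is applied **before** spatial imputation, so IDW operates on one
scalar per metric per municipality; the two orders are equivalent under
linearity of both operators, and this order is simpler. The IDW pool is
covered municipalities only — a covered municipality always uses its own
aggregate, never a neighbour blend. β = 2 and k = 10 are defaults;
geometry is an abstract 100×100 planar square with Euclidean distance, so
no projection questions arise. An exact coordinate match returns the
matched value (the 1/d^β weight is singular there). Regions are contiguous
strips of municipalities along one coordinate (15 by default), giving
spatially coherent grouping units for leakage-safe splits.

## Feature engineering conventions

* Canonical frequency period is **month** with conversion constants
  30 d/month and 7 d/week (the engineered-feature names carry "/month").
  Both the period and constants are configuration.
* Pack-years = years smoked × cigarettes-per-day / 20 (standard 20-pack);
  "currently smokes" is kept as its own feature.
* A group value is missing iff **all** sources are missing; otherwise
  missing sources contribute 0. This propagates questionnaire block
  missingness to the group level without silently shrinking sums.
* Nested semantics (caffeinated beverages ⊇ coffee, alcohol ⊇ wine) are
  implemented as a sum over the subgroup's computed value plus the
  group's exclusive sources, so no raw item feeds two sum-groups.
* Threshold-derived flags are removed wherever the metadata tags a parent
  feature; the waist-to-hip ratio is added as a genuinely new feature
  (not recoverable by thresholding either measurement).
* The stage is idempotent: re-applying it to an engineered bundle is a
  no-op.

## Imputation quality assessment

For each incomplete feature (minimum 30 observed values), 20% of the
*observed* entries are masked (seeded), each applicable imputer is fitted
on the remainder and reconstructs the masked entries. μ is an R² score
clipped to [0, 1] for quantitative features and balanced accuracy for
nominal ones (no standard R² analogue exists for nominal data). The
discernibility gate is a two-sample Kolmogorov–Smirnov test
(quantitative) or χ² contingency test (nominal) between imputed and
held-out observed values at α = 0.05 — an imputer passes iff the test
does not reject. Typing follows the χ²-validity rule: nominal iff every
distinct observed level occurs ≥ 5 times and there are at most 15 levels.

Multivariate imputers see one-hot-encoded predictors capped at the 15
most complete columns, with predictor pre-fill statistics learned on the
training rows and reused verbatim on any later rows (no test-side
statistics are ever computed). The iterative imputer is sklearn's
IterativeImputer with a random-forest estimator, iteration cap 10,
seeded. When every imputer is rejected, QS falls back to γ alone; if the
feature is still retained (γ ≥ 0.7) the distribution-preserving random
imputer fills the holes, as the least distribution-distorting choice.

## Quasi-constancy index

The shift convention anchors the standardized vector's minimum at 1,
which bounds the ratios σ/xᵢ in (0, σ] and avoids division blow-ups near
zero; it is configurable. s = +1 when mean equals median (the sign
formula is 0/0 there; with σ = 0 the output is zero anyway, so only
symmetric non-constant inputs are affected). Gini is applied to absolute
values of the transform, since Gini is defined for nonnegative inputs
and negatively skewed features would otherwise be undefined. Gini uses
the sorted O(n log n) identity, verified against the O(n²)
pairwise-difference oracle in the tests. The 0.05 retention threshold is
taken as given.

## Feature selection

* CI of the mean importance: Student-t over the repetition values.
* Permutation is applied to the **test** partition only, post-fit — the
  standard reading that avoids refitting per permutation.
* SFS evaluates all candidates in a step on the same fixed battery of
  seeded splits, so comparisons are paired (variance reduction for the
  argmax); ties break lexicographically by feature name, and score ties
  between subset sizes prefer the smaller subset.
* Degenerate single-class splits are resampled with a fresh seed.
* Production repetition count is 100; the test suite runs at reduced
  reps (typically 10–30).

**Known limitation — within-cohort significance inflation.** The CI gate
tests whether a feature's mean AUROC drop across split repetitions of
*one realized cohort* is positive. Any finite cohort carries spurious
feature–label correlations of order 1/√n that generalize across its own
internal splits, so repetition drops are positively correlated and the
gate flags features at well above its nominal 2.5% rate when judged
against fresh-cohort nulls (empirically ~15–20% per feature, roughly
scale-invariant because effect size and CI width shrink together).
Significance here therefore means "reproducibly useful within this
cohort", not population-level association; the gate arithmetic itself is
calibrated, as the unit suite verifies on iid null drops. Users screening
many features should expect a corresponding number of cohort-specific
false positives.

## Modelling

* AUROC is computed by midranks (pairwise definition, ties half credit)
  and cross-checked exhaustively against a brute-force pair count.
* ROC curves are averaged vertically on a fixed 101-point FPR grid.
* CI of mean AUROC over folds: Student-t.
* Youden threshold scan covers all distinct score values; J ties resolve
  to the lowest threshold (the more sensitive operating point). Note that
  applying the F1 identity to fold-mean TPR/PPV only approximates the
  mean of per-fold F1 (Jensen gap) — fold means of each metric are
  reported separately for this reason.
* Evaluation folds are group-disjoint (StratifiedGroupKFold) by default,
  extending the region-grouping of the selection phase to evaluation;
  single-class folds trigger a reseeded refold.
* The TPE tuner is implemented in-package: after 10 random start-up
  trials, trials split into the top 25% ("good") and the rest, per-
  dimension densities are Gaussian KDEs (log-space for log-uniform
  dimensions, rounded for integers, smoothed frequencies for choices), 24
  candidates are drawn from the good density and the highest density
  ratio l(x)/g(x) is evaluated next. Trial 0 evaluates the space's
  declared default, so the tuned configuration never scores below the
  default on the same folds. Everything is seeded and deterministic.
* Partial dependence sweeps a feature over a grid (default: 50 points
  between the 5th and 95th percentiles) with all other columns at their
  observed values, averaging predicted positive probability; optional
  per-group curves (e.g. by diagnosed status).

## Pipeline

Stage order: simulate → geospatial augmentation → feature engineering →
imputation → quasi-constancy filter → per task/scenario: permutation
importance → backward SFS → tuning → 10-fold evaluation → partial
dependence. One master seed fans out to per-stage seeds via SHA-256 of
"seed:stage", so stages are independently reproducible. Imputation and
quasi-constancy filtering run once on the full modelling sample before
the selection phase's internal splits, matching the stage order of the
analysis this package operationalizes; the imputation module's
train/test API additionally supports strict per-split refitting for
users who want preprocessing nested inside every evaluation split (at
~100× the imputation cost when combined with the repetition battery).
Exclusion rules are logged with counts at each step.

## Problem sizes in the shipped tests

The test suite exercises the full default cohort (4617 individuals, 100
engineered features) for generation, augmentation, engineering and
composition checks, and scaled-down configurations elsewhere: a
300-person smoke cohort for the end-to-end pipeline; 10 seeds × 30
repetitions on a 12-feature panel (the five default drivers plus seven
non-drivers) for driver recovery; 10 seeds × 20 repetitions on a
4-feature panel for the null-signal control. Repetition counts below the
production 100 and reduced panels lower the cost of the multi-seed
suites while keeping each check's logic identical to production use.

## What passing tests do and do not show

Passing tests demonstrate that every stage implements its documented
contract, that the formulas (weighted moving average, IDW, QS,
L-transform/Gini, AUROC, Youden metrics) agree with independent oracles,
that splits never leak regions, and that the selection machinery recovers
planted signal and stays near chance on null signal under the stated
conditions. They do not demonstrate clinical validity: the synthetic
cohort has linear latent risk, independent noise features, Gaussian/
Poisson marginals and no confounding, none of which can be assumed of
real questionnaire or registry data.
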