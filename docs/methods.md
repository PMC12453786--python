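# Methods

This note records the models, conventions and design decisions behind
`rheumkit`, in the order data flows through the package.

## Synthetic cohort generator (`rheumkit.synth`)

**What it emulates.** A tabular clinical cohort of 12,085 patients across
seven diagnosis classes (RA 2,848; AS 2,127; SS 1,852; PA 1,783; N 1,604;
SLE 1,355; ReA 516) with 14 features: nine numeric (age; ESR in mm/hr;
CRP, C3, C4 in mg/dL; RF and anti-CCP in IU/mL) and five binary
autoantibody/genetic markers plus gender.  The shipped default
configuration (`data/default_cohort.yaml`) encodes the cohort's marginal
ranges, means/standard deviations, positivity splits and per-column
missing fractions (0% for age/gender up to 43% for anti-Sm).

**Numeric sampling.** Each numeric feature is drawn from a truncated
normal on its admissible range `[lo, hi]`.  The latent location is
*moment-matched*: it is solved (Brent root-finding on the truncated-normal
mean) so the post-truncation mean equals the configured target.  Without
this, features whose mean sits near a bound drift badly — the age
marginal (mean 29.905, sd 17.649, range [20, 80]) would come out ~8 years
high.  The latent scale is kept at the configured sd; truncation
therefore shrinks realized standard deviations (age realizes sd ≈ 8
rather than 17.6).  Matching both moments simultaneously would require a
two-parameter solve and is not needed by any downstream property, so the
single-parameter match was chosen.

**Class structure.** The cohort's published statistics are marginal only,
so the per-class structure is *invented* and clearly labeled as such in
the config: RF/anti-CCP elevated in RA; HLA-B27 positivity high in AS and
ReA; anti-Ro/anti-La positive in SS; anti-dsDNA/anti-Sm positive with
C3/C4 depressed in SLE; seronegative moderate inflammation in PA;
quiescent markers in N; ESR/CRP elevated in every disease class.  Numeric
shift profiles are re-centered to zero cohort-weighted mean at generation
time, so adding class structure never moves the configured marginal means
(the generator's marginal-recovery tests hold to well under 1% on the
default cohort).  Binary positivity overrides are taken as-is, so binary
marginals can drift from the configured split when overridden per class.

**Missingness** is MCAR, injected per column by an independent Bernoulli
mask at the configured rate after generation; age, gender and the label
are never masked.  What passing tests on this generator do *not* show:
real cohorts have correlated features beyond class structure, informative
(MAR/MNAR) missingness, and measurement artifacts; absolute benchmark
numbers on synthetic cohorts are therefore not comparable to clinical
results, which is why the package's published-value checks are confined
to the closed-form statistics and the FDOSM stage.

## Preprocessing (`rheumkit.preprocess`)

- **Imputation** fills numeric columns with the mean of observed values
  and categorical/binary columns with the mode (ties toward the smaller
  value).  Columns whose observed values lie in {0, 1} are treated as
  categorical by default (overridable).  The transformer is fitted on the
  full table by default, matching the preprocess-then-split order of the
  reference workflow; fitting on the training split only (leak-free) is
  available by using the `MeanModeImputer` transformer inside a pipeline.
- **Encoding**: two-level categoricals map to one 0/1 column using the
  clinical conventions (Negative=0/Positive=1, Female=0/Male=1; unknown
  level pairs fall back to sorted order); wider categoricals one-hot with
  exactly one 1 per row; binary encodings are invertible.
- **ADASYN** is implemented from its defining equations rather than taken
  from a resampling library, because the allocation rule is part of what
  the package tests: total synthetic count `G = (n_maj − n_min)·β`
  (default β = 1), neighbourhood majority ratio `η_i` over the k = 5
  nearest neighbours *of the whole dataset* (non-minority counted as
  majority in the multiclass case), normalized weights `r_i`, per-point
  counts `g_i = round(r_i·G)` rounded half-up and then adjusted on the
  largest-`r_i` points so they total exactly G (the source is silent on
  rounding; this keeps Σg_i = G exactly), and interpolation
  `x_i + δ(x_z − x_i)`, δ ~ U(0, 1), toward a random minority
  k-neighbour.  Distances use Euclidean metric on features min-max scaled
  to [0, 1]; interpolation happens in original units.  If every minority
  neighbourhood is majority-free (Ση = 0) the allocation falls back to
  uniform.  A β of 0 is accepted as an explicit no-op with a warning.
  Note the reference workflow reports a minority class growing 516 →
  2,946 although its majority class holds 2,848 — unreachable under the
  stated equation with β ≤ 1; the package implements the equation.
- **Split**: per class, `round(0.7·n)` rows to train (at least one row on
  each side), remainder to test, shuffled deterministically per seed.
  This derives counts from the fraction rather than hard-coding any
  published size table; published per-class splits that deviate slightly
  from exact 70% (e.g. 1,997 of 2,848 ≈ 70.1%) are reproduced in total
  but not in their off-by-a-few train counts.

## Metric suite (`rheumkit.metrics`)

Precision, recall and F-score are macro-averaged over classes (macro is
the only averaging consistent with published tables in which balanced-set
precision ≠ accuracy); per-class terms with empty denominators are
defined as 0 and the class is flagged.  Kappa is multiclass Cohen's kappa
`(p_o − p_e)/(1 − p_e)`; MCC is Gorodkin's multiclass coefficient.
Hamming loss is the per-sample misclassification fraction, so
HL + accuracy = 100 exactly for single-label prediction — this identity
is asserted on every benchmark run.  All metrics are stored at full
precision and rendered to 2–3 decimals.  The overfitting statistic is
`(train − validation)/train · 100`, rounded to 2 decimals, with status
Yes (≥ 10%), Mild (5–10%), No (< 5%).  The balanced-vs-unbalanced report
is AD = balanced − unbalanced and PD = AD/unbalanced·100 (undefined and
flagged at unbalanced = 0).  ROC AUC is one-vs-rest per class with a
macro mean.

## Benchmark (`rheumkit.bench`)

Model fitting is the one deliberately off-the-shelf stage: the twelve
panel members are the scikit-learn / xgboost / lightgbm estimators at the
reference hyperparameters (e.g. XGBoost: 100 estimators, depth 6,
learning rate 0.3; GBoost: 100 estimators, learning rate 0.1, depth 3;
AdaBoost: 50 estimators; NB: var_smoothing 1e-9).  Settings the reference
leaves unstated stay at library defaults.  Two mappings required
interpretation: the stated learning rate 0.2 for ANN/SGD maps to the
initial learning rate (`learning_rate_init` for the MLP; `eta0` with an
adaptive schedule for SGD, since its default schedule ignores an initial
rate), and "iter" limits map to `max_iter`.  An alternative
"regularized" spec set (stronger shrinkage, depth 4, 50% feature
subsampling, early stopping) is available but off by default since the
reference tables use the primary settings.  Cross-validation is
stratified K = 5 with shuffling; train/validation accuracy means feed the
overfitting report.  A failed model is recorded and the run continues.
The exported decision matrix uses the canonical criterion order
(precision, recall, F-score, kappa, Hamming loss, MCC, accuracy) with
Hamming loss as the single cost criterion.

## FDOSM (`rheumkit.fdosm`)

The scale, scoring and ranking are described in the README.  Two
conventions deserve a note because the method's published arithmetic is
reproducible only with them:

- **Aggregation across criteria.**  The walkthrough convention *sums*
  per-criterion defuzzified values; the group-ranking convention
  *averages* them.  Both are provided (`aggregation="sum" | "mean"`,
  default mean, which is what the headline group ranking uses).
- **Rounding.**  In sum mode the per-criterion values are rounded to 4
  decimals before summation (two D terms give 2 × 0.5167 = 1.0334, not
  3.1/3 ≈ 1.0333); in mean mode they are kept at full precision and only
  the per-expert score is rounded to 4 decimals (5×BD + 2×D over 7
  criteria gives 4.61667/7 → 0.6595, where pre-rounded values would give
  0.6596).  The group score is the mean of the *rounded* per-expert
  scores, again to 4 decimals.  All rounding is decimal half-up.  This is
  the unique combination that reproduces every published per-expert and
  final score simultaneously; it is fixture-fitted and documented as
  such.

Ties in the ideal solution report the first-listed alternative; scoring
is unaffected since tied cells carry identical opinions.  The *critical*
direction (ideal = value nearest a stated target) is implemented as
nearest-to-target; it is named but never exercised in the reference
workflow, so this is an interpretation.  Expert opinions are inputs;
`suggest_opinions` (relative-gap bucketing) exists only for demos and is
labeled invented.

## Explanations (`rheumkit.explain`)

Local explanations fit a kernel-weighted ridge regression of the target
class probability on standardized perturbations around the instance
(Gaussian noise scaled by background std for numeric features; flips with
probability 0.3 for binary ones; exponential kernel of width
0.75·√d on standardized distance).  This is the standard LIME recipe
restated as an explicit surrogate; weights are signed, deterministic
given the seed.  Global importance aggregates either the mean absolute
local weight over a label-stratified sample of instances (default,
n = 100) or sklearn permutation importance with negative drops clipped to
zero — the reference does not state how its global scores were derived
from local ones, so both readings are offered and labeled as
interpretations.  Published per-case weights/probabilities depend on the
real fitted model and are treated as a layout contract only, never as
numeric targets.

## Problem sizes and numerical choices

The test suite exercises the full pipeline at two scales chosen as the
package's own balance of coverage and runtime: the complete 12,085-row
default cohort for the single learnability check (a GBoost fit, the
pipeline's most expensive step) and a 10%-scale cohort for the remaining
pipeline properties; oracle equivalence checks (ADASYN, metric formulas)
run on dozens of small random instances where brute force is exact.
Degenerate inputs are defined rather than crashed wherever a convention
exists (empty metric denominators → 0 with a flag; single-observation
std → 0 with a flag); genuinely undefined quantities (mean of an
all-missing column, AUC of single-class truth, PD at unbalanced = 0)
raise or are flagged as undefined.

## Known limitations

- The generator models class structure only through per-feature shifts —
  no within-class correlations, no MAR/MNAR missingness, no longitudinal
  records.
- Absolute benchmark metrics on synthetic cohorts do not transfer to the
  clinical setting; only closed-form statistics, oracle equivalences and
  the FDOSM stage are checked against published values.
- The FDOSM rounding convention is fixture-fitted (see above); a source
  stating its arithmetic explicitly could invalidate the sum-mode choice
  without affecting mean-mode results.
- `Adasyn` oversamples one target class per call; balancing several
  minority classes requires repeated calls.
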