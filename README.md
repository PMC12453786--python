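# rheumkit

Benchmarking and fuzzy expert ranking of multiclass diagnostic classifiers
for rheumatic and autoimmune diseases.

Differential diagnosis across rheumatoid arthritis (RA), reactive
arthritis (ReA), ankylosing spondylitis (AS), Sjögren's syndrome (SS),
systemic lupus erythematosus (SLE), psoriatic arthritis (PA) and healthy
controls (N) is hard: the diseases share inflammatory markers and no
single biomarker separates them.  A common workflow trains a panel of
machine-learning classifiers on tabular clinical data (demographics,
inflammation markers, autoantibodies, complement levels) and must then
answer a second question: *which* model should the clinic deploy, given
that different models win on different metrics?  `rheumkit` implements
that full workflow for method developers and biostatisticians:

- **`rheumkit.synth`** — a synthetic cohort generator (14 typed clinical
  features, 7 diagnosis classes, configurable class sizes and per-column
  MCAR missingness) so every downstream stage is testable without any
  patient data;
- **`rheumkit.preprocess`** — mean/mode imputation, clinical encoding
  (Negative=0/Positive=1, Female=0/Male=1, one-hot for wider
  categoricals), an ADASYN oversampler written from its defining
  equations, and a per-class 70/30 split; the imputer/encoder are
  scikit-learn compatible transformers;
- **`rheumkit.bench`** — a 12-model panel (XGBoost, KNN, DT, RF, SVM,
  ANN, SGD, GBoost, LGBM, AdaBoost, NB, ET) with a seven-metric suite and
  5-fold cross-validation overfitting reports;
- **`rheumkit.metrics`** — macro precision/recall/F, multiclass Cohen's
  kappa, Hamming loss, Gorodkin's multiclass MCC, accuracy, one-vs-rest
  ROC AUC, the overfitting gap and balanced-vs-unbalanced difference
  statistics;
- **`rheumkit.fdosm`** — the fuzzy decision by opinion score method that
  turns the benchmark's decision matrix plus expert linguistic judgments
  into a single group ranking;
- **`rheumkit.explain`** — LIME-style local surrogate explanations and
  global feature importances.

## The core method: FDOSM

Given a decision matrix `v_ij` of m models by n criteria, each criterion
marked *benefit* or *cost* (here: all seven metrics are benefit criteria
except Hamming loss), FDOSM proceeds:

1. **Ideal solution** per criterion: `A* = max_i v_ij` for benefit,
   `min_i v_ij` for cost (a *critical* direction, nearest to a stated
   target, is also supported).
2. **Opinion matrices**: each expert compares every cell with its
   criterion's ideal and records one of five ordered linguistic terms —
   ND < SD < D < BD < HD (no / slight / - / big / huge difference).
3. **Fuzzy scoring**: terms map to triangular fuzzy numbers
   (ND = (0, 0.10, 0.30) … HD = (0.75, 0.90, 1.00)), defuzzified as
   `S = (V1 + V2 + V3) / 3` and aggregated across criteria (arithmetic
   mean by default; a sum mode is provided for compatibility with the
   method's walkthrough convention).
4. **Ranking**: `R_i = 1 + #{j : S_j < S_i}` — the lowest score (least
   difference from ideal everywhere) is the best model; per-expert scores
   are averaged into the group decision.

Expert opinions are *inputs*: the package validates and scores them but
never fabricates them (a clearly-labeled demo helper can suggest terms
from value gaps).

## Worked example

Rank the shipped 12-model decision matrix (from a balanced-cohort
benchmark run) using the three shipped expert opinion matrices:

```python
from rheumkit import datasets, fdosm

dm = datasets.load_diagnostic_dm(balanced=True)
report = fdosm.run_fdosm(dm, datasets.load_expert_opinions(dm=dm))
print(report.to_frame())
```

```
          Expert 1 score  Expert 1 rank  Expert 2 score  Expert 2 rank  Expert 3 score  Expert 3 rank  final score  final rank
Model
XGBoost           0.2286              4          0.1810              3          0.2048              4       0.2048           4
KNN               0.6595             10          0.5738             10          0.6881             11       0.6405          10
DT                0.3071              6          0.2524              6          0.2762              6       0.2786           6
RF                0.1571              2          0.1571              2          0.1571              2       0.1571           2
SVM               0.5429              9          0.4548              9          0.5119              9       0.5032           9
ANN               0.3357              7          0.2762              7          0.3071              7       0.3063           7
SGD               0.4857              8          0.3929              8          0.4238              8       0.4341           8
GBoost            0.1333              1          0.1333              1          0.1333              1       0.1333           1
LGBM              0.2048              3          0.2048              4          0.1810              3       0.1969           3
AdaBoost          0.8833             12          0.8833             12          0.8833             12       0.8833          12
NB                0.6881             11          0.6286             11          0.6595             10       0.6587          11
ET                0.2595              5          0.2286              5          0.2286              5       0.2389           5
```

GBoost scores 0.1333 — the all-ND floor, meaning every expert judged it
indistinguishable from the ideal on all seven criteria — and takes rank 1
unanimously; AdaBoost sits at the 0.8833 all-HD ceiling with rank 12.
The final score is the across-expert mean, so e.g. XGBoost's
(0.2286 + 0.1810 + 0.2048) / 3 = 0.2048, rank 4.

The same pipeline runs end to end on synthetic data from the shell:

```bash
rheumkit generate --seed 1 --out cohort.csv
rheumkit preprocess --in cohort.csv --adasyn-class ReA --seed 1 --out prep.csv
rheumkit bench --train prep.csv --test prep.csv --models GBoost,RF,NB --cv 0 --seed 1 --out bench_out
rheumkit fdosm --dm bench_out/decision_matrix.csv \
    --directions bench_out/decision_matrix_directions.json \
    --opinions expert1.csv --out ranking.csv
```

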