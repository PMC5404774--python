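# Methods

## Problem setting

Candidate-gene association studies measure a few hundred to a few
thousand SNPs in a few hundred individuals and ask which variants are
associated with a continuous trait (the motivating data: four platelet
activation responses in 462 individuals genotyped at 1430 candidate
SNPs).  With p > n, ordinary multiple regression is unavailable and
single-SNP testing is underpowered after multiplicity correction.
`snpconsensus` implements a consensus strategy: an iterative random
forest reduces p SNPs to a small working set, several regression methods
with different inductive biases then vote on the survivors, and a
cross-iteration confidence score flags which selections are stable.

## Model

All methods treat the genotype additively.  The genotype of sample i at
SNP j is coded x_ij ∈ {1, 2, 3} (major homozygous, heterozygous, minor
homozygous) and enters every model as a numeric predictor:

    Y = Xβ + ε,   ε ~ N(0, σ²I)

Phenotypes are assumed continuous and roughly standard normal and are
used as provided — the package never re-standardises them.  Numeric
covariates (e.g. age) are appended to X and ride through every stage as
extra predictors; they are reported separately and never enter the key
SNP list.

## Pipeline stages

### 1. Random-forest filter

For each iteration of the tree schedule (default 500, 1000, 2000, 3000
trees):

1. fit a bagged regression forest on all p SNPs;
2. rank predictors by raw (unscaled) out-of-bag permutation variable
   importance: the mean increase in a tree's OOB mean squared error when
   one predictor's OOB values are permuted, averaged over all trees with
   zero contribution from trees that never split on the predictor, ties
   broken by input order;
3. keep the top k SNPs (default k = 40; with p ≈ 1400–1430 this is
   approximately √p, the working-set size the protocol used);
4. refit on the top k and record percent variance explained,
   100·(1 − SS_res/SS_tot), computed from OOB predictions for both fits.

OOB evaluation is what makes the all-p figure land near zero and often
*below* zero on weak data: a forest fed mostly irrelevant predictors
predicts held-out samples worse than the phenotype mean.  The top-k
refit then typically explains 10–20 % — this gap, not the absolute
value, is the diagnostic pattern.

Each iteration restarts from all p SNPs; nothing is carried between
iterations except the significance tally used by the confidence score.
Convergence is not auto-detected: the fixed schedule runs to the end and
the last iteration is treated as the converged state.

The forest itself is built for this data shape.  Genotypes take only
three values, so trees grow on a binned (histogram) representation —
genotype columns get 3 bins, continuous covariates up to 32 quantile
bins — which makes split search a counting pass instead of a sort.
Split quality is variance reduction; each node samples
mtry = ⌊p/3⌋ predictors (the regression-forest convention);
terminal nodes hold at least 5 samples (the regression `nodesize`
convention).  Bootstrap membership is tracked per tree so OOB
predictions and OOB permutation importance are exact.  The hot loops are
numba-compiled; on the 460 × 1400 reference shape a full default
pipeline run takes on the order of 1–2 minutes on one CPU.  Unit tests
cross-check OOB variance explained against scikit-learn's
RandomForestRegressor on shared fixtures.

### 2. Regression ensemble (on the top-k set)

* **Forward stepwise.**  Starts from the null model; at each step the
  candidate with the largest RSS reduction enters if its partial-F entry
  p-value is ≤ 0.05 (the protocol names no entry threshold; 0.05 is this
  package's choice).  Reported per-SNP p-values are Wald t-tests on the
  final selected model — the protocol is ambiguous between entry-test
  and final-model p-values; final-model Wald was chosen.
* **Ridge.**  β̂ = (X′X + λI)⁻¹X′y with an unpenalised intercept
  (computed on centred predictors via SVD).  λ is chosen by minimising
  generalised cross-validation error over a logarithmic grid
  (10⁻³…10⁵, 161 points) — the original used an automatic selector
  whose internals are not reproducible from the text; GCV is
  deterministic and standard.  Per-SNP Wald p-values use the sandwich
  variance σ̂²(X′X+λI)⁻¹X′X(X′X+λI)⁻¹ with residual degrees of freedom
  n − tr(H).  At λ = 0 the fit reduces exactly to OLS; as λ → ∞ the
  prediction collapses to the phenotype mean.
* **Lasso.**  glmnet-convention fit: predictors standardised
  internally, penalty chosen as the 10-fold cross-validation-error
  minimiser (folds seeded and shuffled).  The nonzero-coefficient SNPs
  — the protocol's "relatively large coefficients", read as the least
  arbitrary interpretation: all of them — are then tested largest
  |standardised β̂| first, each by a partial F-test against the model of
  previously accepted SNPs; acceptance requires p ≤ 0.01.

Every method flags SNPs at p ≤ 0.01 (configurable).  These per-method
p-values are *not* corrected for the preceding forest selection; the
consensus and confidence layers are the protocol's false-positive
control (see Limitations).

### 3. Shadow-feature selection (Boruta)

Each run appends a permuted copy of every active predictor (at least 5
shadows, re-permuted each run), fits a 500-tree forest on the extended
design at mtry = √width (the reference implementation's convention for
this stage; the filter stage's p/3 would slow the loop ~5× without
changing decisions materially), and computes a Z-score per feature as
mean/sd of per-tree impurity importances.  A real SNP scores a hit when
its Z beats the best shadow Z.  After every run, two one-sided binomial
tests on the accumulated hit counts (Holm step-down over the undecided
features, family level α = 0.01) promote features to *confirmed* or
demote them to *rejected*; rejected features drop out of later runs.
The loop stops when nothing is undecided or after max_runs = 100.
Features still undecided are *tentative* and are **not** counted as
votes or confidence appearances — only confirmed features map to a
check mark.

### 4. Consensus and confidence

The final iteration's calls form a boolean vote matrix over the four
methods.  SNPs with ≥ 3 votes (configurable) are the consensus **key
SNPs**.  Independently, every significant/confirmed call in every
iteration counts one appearance (a method contributes at most one per
iteration), giving a frequency f ∈ [0, methods × iterations] — 16 under
the defaults — and a confidence score

    confidence = f / (n_methods × n_iterations)

Scores strictly above 0.5 mark likely true positives.  The key-SNP
report lists consensus SNPs annotated with their confidence; the
confidence table is emitted in full so that high-confidence non-consensus
SNPs (selected repeatedly but by fewer than 3 methods in the last
iteration) remain visible, since the protocol uses confidence as
verification rather than replacement.

## Synthetic data generator

The generator emulates the validation setting: n = 460 samples,
p = 1400 SNPs, phenotype standard normal.  Genotypes are drawn
independently per SNP under Hardy–Weinberg proportions with per-SNP
minor-allele frequency ~ Uniform(0.05, 0.5) (the original's exact
genotype frequencies live in supplementary code that is not part of this
package; this law gives realistic per-SNP class imbalance and is
configurable).  Planted-effect datasets add Σⱼ βⱼ·x_ij to N(0, σ²)
noise and return the causal set, so recovery can be measured;
`planted_spec_for_variance_fraction` calibrates β analytically so each
causal SNP explains a requested share of phenotype variance at a
reference MAF.

What the generator does **not** emulate: linkage disequilibrium between
SNPs (columns are independent), genotyping error, missingness patterns
beyond what tests inject, population structure, non-normal or
heteroscedastic traits, and dominance/epistatic effects.  Passing tests
therefore demonstrate the machinery's behaviour under the protocol's own
idealised conditions, not performance on structured real cohorts.

One seed drives everything: it is expanded through `SeedSequence`
substreams per stage, per iteration and per phenotype, so reruns are
bit-identical and stages are individually reproducible.

## Numerical and policy choices

* Missing genotypes are imputed to the SNP's modal code; modal ties
  break toward the smaller code (deterministic; usually the
  major-allele class).  A fully missing SNP column is an error.
* Importance ties and top-k boundary ties keep input order
  (stable sort).
* Percent variance explained is undefined for a constant observed
  vector and raises rather than returning a sentinel.
* The ridge GCV grid and the stepwise entry threshold are config keys;
  the λ grid spans far enough that the boundary is never selected on
  reasonable data.
* Histogram binning is exact for ≤ 32 distinct values per column (all
  genotype data); continuous covariates are approximated by quantile
  bins inside the forest only — the regression layer always sees raw
  values.
* Degenerate inputs: a constant phenotype yields no stepwise entries
  and an empty call list; k ≥ p keeps every SNP; an empty vote matrix
  produces header-only report tables.

## Test problem sizes

The test suite exercises the full protocol shape (460 × 1400, default
schedule) for the null-behaviour and recovery checks, two seeds each;
sweeps with more seeds reproduce the same picture.  Unit tests use
smaller shapes (n = 100–300, p = 12–60, schedules of 1–2 short
iterations) chosen so each statistical assertion still has clear margin
(effect sizes ≥ 3 standard errors from the decision boundary).

## Known limitations

* **Post-selection inflation on null data is inherent to the
  protocol.**  The top-k SNPs are chosen by the forest on the same data
  the ensemble then tests, so on pure-noise inputs each method still
  flags several of the 40 survivors at p ≤ 0.01, and a handful reach
  3-of-4 consensus with confidence > 0.5 (typically ~2–5 at the
  reference shape; the original validation run reported 8 confident
  null SNPs).  The confidence layer shrinks but does not eliminate
  this; treat key SNPs as candidates for follow-up, not discoveries.
* Shadow-feature selection shares this behaviour: a null feature whose
  spurious in-sample correlation is the largest of its cohort can be
  confirmed once its weaker peers are rejected.
* Wald p-values from ridge are approximate (sandwich variance at a
  data-chosen λ); partial-F p-values after lasso ignore the penalty's
  selection event.  No formal post-selection correction is attempted,
  matching the protocol.
* Forest results depend on the RNG stream; only the qualitative
  pattern (top-k ≫ all-p percent variance) is stable across seeds, so
  no test asserts specific percent-variance values.
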