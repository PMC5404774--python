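# snpconsensus

Consensus selection of key SNPs associated with continuous phenotypes
in high-dimensional (p > n) candidate-gene association data.

Genetic association panels often genotype ~10³ candidate SNPs in a few
hundred individuals and measure continuous traits (the motivating
setting: four platelet activation responses — P-selectin or fibrinogen
binding after ADP or CRP-XL stimulation — in 462 individuals with 1430
SNPs).  Single-SNP tests are underpowered after multiplicity
correction, and p > n rules out joint least squares.  `snpconsensus`
implements a consensus pipeline for this regime:

1. **Random-forest filter.**  For each tree count in a rising schedule
   (500, 1000, 2000, 3000), fit a bagged regression forest on all p
   SNPs (additive coding x ∈ {1,2,3}), rank SNPs by out-of-bag
   permutation variable importance, keep the top k = 40 ≈ √p, refit,
   and track % variance explained, 100·(1 − SS_res/SS_tot), on
   out-of-bag predictions.
2. **Regression ensemble** on each iteration's top-k set, under the
   additive linear model Y = Xβ + ε: forward stepwise OLS (partial-F
   entry, Wald reporting), ridge β̂ = (X′X + λI)⁻¹X′y at the
   GCV-optimal λ, and the lasso at the 10-fold cross-validation-optimal
   penalty with sequential partial-F screening of the nonzero set.
   Each method flags SNPs at p ≤ 0.01.
3. **Boruta shadow-feature selection**: real SNPs compete against
   freshly permuted copies of themselves over up to 100 forest runs;
   binomial tests on hit counts confirm or reject each SNP.
4. **Consensus + confidence.**  SNPs flagged by ≥ 3 of the 4 methods in
   the final iteration are *key SNPs*; every (method, iteration) call
   also counts toward a confidence score f/(4·4) ∈ [0, 1], with
   scores > 0.5 marking likely true positives.

A synthetic-data module generates null and planted-effect genotype
tables (Hardy–Weinberg genotypes, per-SNP MAF ~ U(0.05, 0.5), N(0,1)
phenotype) so the whole pipeline is testable end to end with no
external data.  See `docs/methods.md` for assumptions, parameter
semantics and limitations.

## Worked example

Simulate 460 samples × 1400 SNPs with 5 planted causal SNPs (additive
effect β = 0.5 per copy of the coded genotype), run the full default
protocol, and report:

```sh
snpconsensus simulate --n 460 --p 1400 --seed 7 --causal 5 --beta 0.5 \
    --out example.csv --truth-out truth.tsv
snpconsensus -v run --input example.csv --phenotype Y \
    --sample-id-column sample --seed 7 --out example_run
snpconsensus report example_run/Y
```

The run log shows the filter's characteristic pattern — the all-p
forest explains little variance while the top-k refit explains far
more:

```
iteration 1 (ntree=500):  %var all=11.19 top-k=28.46; votes stepwise=10 ridge=11 lasso=11 boruta=11
iteration 2 (ntree=1000): %var all=12.75 top-k=30.05; votes stepwise=13 ridge=16 lasso=15 boruta=11
iteration 3 (ntree=2000): %var all=12.27 top-k=30.16; votes stepwise=13 ridge=13 lasso=14 boruta=10
iteration 4 (ntree=3000): %var all=11.91 top-k=32.18; votes stepwise=16 ridge=16 lasso=16 boruta=12
```

(on a pure-noise dataset the all-p column sits near zero and is often
negative).  The key-SNP report lists the consensus SNPs with their
cross-iteration confidence:

```
  snp  n_votes  confidence  true_positive_candidate
X1400        4      1.0000                     True
   X1        4      1.0000                     True
X1050        4      1.0000                     True
 X700        4      1.0000                     True
 X350        3      0.7500                     True
X1316        3      0.5625                     True
 X226        4      0.7500                     True
 ...
 X839        3      0.1875                    False
```

All five planted SNPs (X1, X350, X700, X1050, X1400) are recovered
with confidence ≥ 0.75; the remaining rows are the false-positive load
this protocol carries on n = 460 data — chance associations that
survive the forest filter and reach consensus, mostly with lower
confidence.  This is why the confidence column, not consensus
membership alone, should guide follow-up (see "Known limitations" in
`docs/methods.md`).

Output tables (`iteration_metrics.tsv`, `method_calls.tsv`,
`vote_matrix.tsv`, `frequency*.tsv`, `confidence.tsv`, `key_snps.tsv`,
`manifest.json`) land under `example_run/Y/`.  Runs are fully
deterministic given `--seed`.  Real datasets are read the same way: a
CSV/TSV with a header naming phenotype, covariate and sample-id
columns; every other column is a SNP coded 1/2/3 (empty or `NA` cells
are imputed to the SNP's modal genotype).  Covariates such as age join
every stage as extra predictors and are reported separately
(`covariate_calls.tsv`), never as key SNPs.

The same machinery is importable as a library:

```python
from snpconsensus import PipelineConfig, analyse_phenotype, simulate_null

genotypes, phenotype = simulate_null(460, 1400, seed=1)
report = analyse_phenotype(genotypes, phenotype, config=PipelineConfig(seed=1))
print(report.key_snps)
```

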