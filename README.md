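# gwaswd

Case-control GWAS classification in Python: PLINK 1 binary IO, a
quality-control cascade, a per-SNP logistic association screen, one-hot
genotype encoding, hybrid PCA + Boruta feature selection with
neighbour-SNP expansion, and random-forest / wide / deep / wide-and-deep
neural-network classifiers with human-readable rule extraction.

## Who this is for

Statistical geneticists and ML practitioners who want to classify
disease status (e.g. dementia cases vs cognitively normal controls)
directly from genome-wide SNP genotypes, on cohorts of a few hundred
samples and 10⁵–10⁶ markers, with every stage — QC, screening,
selection, modelling, interpretation — reproducible from one seed.
Because real clinical GWAS cohorts are access-controlled, the package
ships a synthetic cohort generator (`gwaswd.simulate`) that emits
genuine PLINK triplets with planted causal SNPs and planted QC defects,
so the whole pipeline is testable end to end with known ground truth.

## The method

1. **QC cascade** (fixed order): SNP missingness > 0.02, sample
   missingness > 0.2, sex check on X-homozygosity (F > 0.8 male,
   F < 0.2 female), autosomes only, MAF ≥ 0.05, Hardy–Weinberg exact
   test in controls (p < 1e-6) then cases (p < 1e-10), relatedness
   (method-of-moments pi-hat > 0.2, lower-call-rate member removed),
   optional ethnicity filter.
2. **Association screen**: per-SNP additive logistic regression
   `logit P(case) = β₀ + β·g`, fitted by IRLS; Wald p-values with an
   LRT fallback under separation; genomic inflation
   `λ = median(χ²)/0.4559`; Manhattan/QQ tables; top-k SNPs by p-value
   (k = 1000).
3. **Encoding**: each SNP becomes three binary genotype indicators
   (`rs2075650_AA`, …); a missing call is the all-zero triple.
4. **Hybrid selection**: score features with PCA (sum of absolute
   component loadings up to 95% variance) and Boruta (shadow-feature
   random-forest hits with binomial confirm/reject); keep the top
   quartile of each ranking and intersect at the parent-SNP level.
5. **Models**: bagged random forest aggregated by explicit majority
   vote (ties → control); a wide network (one 256-unit hidden layer);
   a deep network (64-32-16); and a wide-and-deep network whose
   curated features join the last hidden representation directly
   before the sigmoid output, with the one-hot union of ±6
   neighbour-SNP windows as the deep input. Evaluation is a stratified
   70/30 split with 5-fold CV inside the training partition; metrics
   are accuracy, precision, recall, F1, ROC-AUC and PR-AUC with case
   as the positive class.
6. **Interpretation**: the forest's best-validation tree is unrolled
   into mutually exclusive, exhaustive genotype rules
   (`IF rs705904 = CC AND rs2075650 != AA THEN case [support, confidence]`).

The estimator-style classes (`BorutaSelector`, `PCAImportance`,
`GenotypeOneHotEncoder`, `RandomForestVoteClassifier`,
`WideNNClassifier`, `DeepNNClassifier`, `WideDeepNetClassifier`)
follow scikit-learn conventions (`fit`/`transform`/`predict`,
`get_params`, fitted attributes with trailing underscores) and compose
with sklearn model selection.

## Worked example

```python
import gwaswd as gw

cfg = gw.SimulationConfig(
    n_cases=100, n_controls=100,
    n_snps_per_chrom={c: 500 for c in (1, 2, 3, 4, 5)},
    causal_spec=[(i * 500 + 200, 3.0) for i in range(5)],  # 5 SNPs, OR 3
    seed=42,
)
G, truth = gw.simulate_cohort(cfg)

Gq, report = gw.run_qc(G)              # 2500 -> 2469 SNPs (8 high-missing, 23 low-MAF)
table = gw.run_association(Gq)
print(gw.genomic_lambda(table["P"]))   # 1.020  -- no inflation on a clean cohort
print(table.sort_values("P").head(3)[["SNP", "BETA", "P"]])
#     SNP      BETA            P
# rs4_200  1.320111 9.777074e-08      <- 3 planted SNPs lead the scan
# rs1_200  1.059411 3.083138e-06
# rs3_200  0.866503 1.665600e-04

res = gw.run_experiment(
    Gq, 1, top_k=500, seed=0, boruta_trees=100, boruta_iter=15,
    leakage="whole-dataset",          # whole-dataset selection, see docs/methods.md
)
for name, rep in res.reports.items():
    print(name, round(rep.metrics.accuracy, 2), round(rep.roc_auc, 2))
# rf  0.87 0.94
# wnn 0.95 0.99
# dnn 0.95 0.98
```

The association screen surfaces the planted SNPs (λ ≈ 1 confirms the
test is calibrated), the hybrid selection keeps 3 of the 5 causal SNPs
among 146 selected parents at this small scale, and the three
classifiers separate cases from controls on the 30% hold-out with
AUC 0.94–0.99. The `leakage` flag matters: `"fold-safe"` (the default)
selects features inside the training partition only and gives honest —
visibly lower — hold-out numbers; `"whole-dataset"` reproduces
whole-dataset selection for comparability with published results.
`docs/methods.md` quantifies the gap.

A shell interface wraps the same stages:

```bash
gwaswd simulate --config cfg.yaml --seed 1 --out runs/cohort
gwaswd qc    --in runs/cohort --out runs/clean
gwaswd assoc --in runs/clean --top-k 1000 --out runs/assoc
gwaswd train --exp 1 --in runs/clean --out runs/models
gwaswd rules --in runs/clean --out runs/rules.json
gwaswd pipeline --config cfg.yaml --out runs/full --seed 1
```

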