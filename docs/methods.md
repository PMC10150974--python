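# Methods

`gwaswd` implements an end-to-end case-control GWAS classification
pipeline: PLINK-format genotype IO, a quality-control cascade, a
per-SNP logistic association screen, one-hot genotype encoding, a
hybrid PCA + Boruta feature-selection stage, neighbour-SNP expansion,
and four classifier families (random forest, wide, deep, and
wide-and-deep neural networks) with decision-rule extraction.  A
synthetic cohort generator with planted ground truth provides the test
substrate, since real dementia GWAS cohorts are access-controlled.

## Genotype model and file semantics

Genotypes are diploid biallelic dosages counting copies of the .bim A1
allele (PLINK 1 convention: 2-bit code `00` = homozygous A1). Missing
calls are stored as −1. The .bed codec is bit-exact and round-trip
tested against an independent per-bit decoder; the file-size law
`3 + ceil(n/4)·m` is asserted. Only variant-major mode is supported —
modern PLINK emits nothing else. Chromosome labels X/Y/XY/MT normalise
to 23–26.

## Synthetic cohorts

Haplotypes run down each chromosome as a first-order Markov chain on a
latent uniform: site *j* reuses its left neighbour's uniform with
probability `ld_rho` (default 0.2, mild local LD) and redraws it
otherwise; the allele is the indicator `U < MAF_j`. Copying the latent
uniform rather than the allele keeps every site's marginal frequency
exactly at its drawn MAF — a naive allele-copy chain smooths each
site's frequency toward its neighbours', which breaks the generator's
frequency contract. `ld_rho = 0` recovers full independence.

Disease status follows a logistic liability `logit P(case) = α +
Σ β_j g_j`; the intercept is bisected so the *population* prevalence
matches `target_prevalence` (default 0.15, an elderly-cohort figure),
then exact case/control quotas (default 174/214, a realistic small
GWAS) are filled by rejection sampling, mirroring case-control
ascertainment. Odds ratios are invariant under this ascertainment, so
per-SNP slopes remain estimable.

Defaults chosen once, with the reasoning:

- MAF ~ U(0.05, 0.5): the post-QC spectrum of a genotyping array.
- Causal MAF ~ U(0.2, 0.5): at n ≈ 400, rare causal variants carry
  essentially no power, so planting them would make every recovery
  benchmark a coin flip; common causal variants are the standard
  simulation choice at this sample size.
- Planted effects: 10 SNPs, per-allele OR evenly spaced in [2, 3].
- Background missingness 0.005 MCAR — well under the 0.02 QC threshold,
  so background noise is not itself a planted defect.
- Defect injections for QC benchmarks: SNPs/samples with 10%/30%
  missingness; Hardy–Weinberg violators with inbreeding-style
  heterozygote excess F = −0.5 at MAF ≥ 0.35 (at ~200 controls the
  exact test only reaches p < 1e-6 for this F when the variant is
  common — rarer violators would be undetectable by construction);
  related pairs as genotype copies with 1% per-site redraw
  (concordance ≈ 0.99, pi-hat ≈ 1); sex-label flips against the
  X-genotype truth. Males carry one X haplotype stored as homozygous
  diploid codes, so the sex-check F statistic behaves as on real data.

What the generator does *not* emulate: population structure and
admixture, coalescent-realistic LD decay, genotyping batch effects,
imputation uncertainty. Tests passing on these cohorts show the
pipeline's statistical machinery is correct and calibrated; they do not
show that real cohorts are free of the confounders those features
create.

## QC cascade

Fixed order, matching standard practice: SNP missingness (> 0.02
removed), sample missingness (> 0.2), sex check, autosome restriction,
MAF < 0.05 (boundary retained, PLINK `--maf` semantics), Hardy–Weinberg
exact test (controls at 1e-6, then cases at 1e-10), relatedness,
optional ethnicity metadata filter. The report reconciles removal
counts against dimension changes by construction.

- The HWE test is the exact conditional test computed by the recurrence
  over heterozygote counts (no mid-p). A chi-square approximation is
  useless at the 1e-6/1e-10 tail with n ≈ 200, which is why the exact
  formulation is non-negotiable here. It is verified against full
  enumeration for every genotype table with n ≤ 50.
- The sex check computes per-sample X homozygosity
  `F = (obs_hom − exp_hom)/(n − exp_hom)` with pooled allele
  frequencies; F > 0.8 infers male, F < 0.2 female; discrepant samples
  are removed by default (configurable).
- Relatedness uses PLINK-style method-of-moments IBD on founder pairs:
  IBS 0/1/2 counts against allele-frequency expectations, clipped to
  the simplex, `pi-hat = P(IBD=1)/2 + P(IBD=2)`. No finite-sample
  allele-frequency correction and no LD pruning are applied; with
  fewer than ~2,000 informative SNPs the estimator is noisy enough
  that the 0.2 threshold will produce false positives — intended usage
  is genome-scale input. Of a flagged pair the lower-call-rate member
  is removed (ties: lexicographically larger id).

## Association screen

Each SNP gets an additive-coded (0/1/2) logistic regression fitted by
IRLS (log-likelihood tolerance 1e-8, 50 iterations max), two-sided Wald
p-values, per-SNP listwise deletion, no covariates (a hook exists).
A slope beyond ±15 flags (quasi-)separation — there the Wald statistic
degenerates, so the p-value falls back to the likelihood-ratio test.
The fit is verified against an iteratively refined grid-search MLE and
against statsmodels. Genomic inflation is
`λ = median(χ²)/0.455936`; the screen keeps the top-k SNPs by p-value
(k = 1000 by default; the 5e-8 genome-wide line is drawn on the
Manhattan output but is deliberately not a filter — at n ≈ 400 nothing
would survive it and the pipeline's selection is rank-based).

## Encoding and feature selection

One-hot encoding expands each SNP into three indicators named
`rsID_GT` with genotypes spelled from the .bim alleles (heterozygote as
A1A2). Missing genotypes encode as the all-zero triple: one-hot has no
fourth category, and absence-of-evidence is the conservative choice.

Two rankers score the encoded features:

- **PCA importance**: columns centred, SVD, components kept to 95%
  cumulative variance, feature score = unweighted sum of absolute
  loadings over retained components (variance weighting available).
  This is unsupervised — it ranks by variance/correlation structure,
  not by phenotype relevance.
- **Boruta**: per iteration, a shuffled shadow copy of every column is
  appended, a random forest fitted (default 300 trees), and a real
  feature scores a hit when its impurity importance beats the best
  shadow. Two-sided binomial tests on hit counts (Bonferroni over all
  features) confirm or reject; survivors at the iteration cap are
  tentative and treated as rejected downstream. The reported score is
  the mean importance across iterations. At GWAS scale (thousands of
  columns) the shadow-max bar is high and few features confirm —
  the *ranking* is what the quartile step consumes.

The hybrid selection takes the top quartile (ceil(0.25·m)) of each
ranking and intersects them **at parent-SNP level**: a SNP survives
when both rankers placed at least one of its indicators in their top
quartile, and all indicators either ranker promoted for that SNP are
kept, ordered by mean rank. This was a genuinely open design point,
and the feature-level alternative (kept as `level="feature"`) measured
decisively worse: because Boruta promotes the phenotype-informative
indicator while PCA promotes the high-variance indicator of the same
SNP, strict feature-level intersection discards most jointly-supported
SNPs (causal-parent coverage drops from ~80–90% to ~30–40% on planted
cohorts). Parent-level intersection also naturally yields selection
lists carrying several genotype spellings of one SNP, the shape such
hybrid selections report in practice.

Neighbour expansion takes, for each selected parent SNP, up to k = 6
map-adjacent SNPs on each side (bim row order, truncated at chromosome
ends), unions the windows, and one-hot encodes the union as the "deep"
feature space of the wide-and-deep model.

## Classifiers and evaluation

- **Random forest**: sklearn trees (bootstrap per tree, random feature
  subset per split) aggregated by explicit per-tree majority vote; the
  predicted probability is the vote fraction and an exact tie predicts
  control — the conservative call for a diagnostic.
- **Wide / deep / wide-and-deep networks**: one seeded numpy
  implementation (ReLU stacks, sigmoid output, binary cross-entropy,
  minibatch Adam at 1e-3, batch 32, epoch cap 200, early stopping on a
  10% stratified validation split with patience 20 and best-weight
  restore). The wide network has one hidden layer of 256 units; the
  deep network a 64-32-16 stack; the wide-and-deep model concatenates
  the curated wide block with the last hidden representation directly
  before the output unit. Fixed seed ⇒ bit-identical weights on one
  thread. These hyperparameters stand in for an unavailable published
  configuration table and are all exposed.

Evaluation: stratified 70/30 split; 5-fold cross-validation inside the
training partition (selection is *not* re-fit per fold; the hold-out
stays untouched); a single final fit; one hold-out evaluation. Case
(phenotype 2) is the positive class everywhere. Metrics are accuracy,
precision, recall, F1 (zero denominators report 0 with a flag), ROC
(trapezoidal AUC, verified against the Mann–Whitney U identity) and PR
(step-interpolated area).

### Selection leakage: fold-safe vs whole-dataset protocol

Two protocols are exposed. The default (`fold-safe`) fits the
association screen and feature selection on the training partition
only. `whole-dataset` performs selection on the full dataset before
splitting — the design many small-cohort GWAS classification studies
report, retained here for comparability with such results.

The planted-cohort benchmarks make the difference concrete: at n = 388
with 10 causal SNPs (OR 2–3) among 5,000, the oracle model on the true
causal features reaches hold-out AUC ≈ 0.86, the full pipeline under
`whole-dataset` reaches ≈ 0.92–0.97 (optimistic: the ~560 noise
features in the selected set were chosen partly on the evaluation
labels), while under `fold-safe` every model class plateaus near
0.55–0.60 — the honestly-selected noise features drown the signal at
this sample size. The acceptance benchmarks report the
`whole-dataset` figures, since they emulate experiments run under that
design; for real analyses, the fold-safe default is the sound choice and
larger feature-selection restraint (smaller k, confirmed-only Boruta)
is advisable.

## Experiments

EXP1 trains RF/WNN/DNN on the quartile intersection; EXP2 and EXP3 on
the Boruta and PCA quartiles alone; EXP4 trains the wide-and-deep model
with EXP1 features as the wide block and the neighbour-window union as
the deep block (a deep-only ablation is always trained alongside);
EXP5 ranks one-hot features by their parent SNP's association p-value
and takes the top quartile.

## Rule extraction

From a trained forest, the tree with the best validation accuracy
(ties: fewer leaves, then lower index — validation accuracy, not
training, so the most overfit tree is not rewarded) is unrolled into
one rule per root-to-leaf path. On binary indicators a split at 0.5
renders as a genotype statement (`rs705904 = CC`, `rs2075650 != AA`).
The rule set is a partition of the feature space by construction —
verified by exhaustive corner sweeps — so applying it reproduces the
source tree's predictions exactly. Support is the bootstrap-weighted
training count at the leaf; confidence its class purity.

## Numerical and benchmark-scale choices

- HWE recurrence normalised in linear space (overflow-safe for the
  cohort sizes involved); enumeration oracle uses log-gamma.
- IRLS weight floor 1e-12; grid-MLE oracle uses 5 zoom refinements.
- Boruta benchmarks in the test-suite and acceptance script use 150
  trees × 25 iterations (selection-stage runs) and 50 trees × 30
  iterations (confirm/reject benchmark) on cohorts of 388 samples ×
  5,000 SNPs — sizes chosen so the full suite runs on a single CPU
  desk machine in minutes while leaving every statistical conclusion
  unchanged at the default 300 × 100 settings.
- Tie-breaks are deterministic everywhere (feature name, chromosome
  and position, individual id), so fixed seeds give byte-identical
  artefacts, which the pipeline manifest hashes attest.

## Known limitations

- PLINK 1 triplets only; no PGEN/VCF/BGEN, no multi-allelic sites.
- No covariate adjustment or mixed-model association; population
  structure is neither simulated nor corrected for.
- pi-hat without LD pruning needs genome-scale marker counts.
- The wide-and-deep join is concatenation-before-output; the
  alternative reading (concatenation before the last hidden layer) is
  not implemented.
- Published-cohort figures (e.g. 99% accuracy on a specific clinical
  dataset) depend on access-controlled data and the optimistic
  selection protocol; this package reproduces the method, and its
  benchmarks quantify — rather than inherit — that optimism.
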