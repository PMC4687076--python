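# Methods

This note documents the statistical models and procedures implemented in
`aimsel`, the parameter choices that matter, what the synthetic benchmark
does and does not emulate, and the numerical conventions.

## Genotype coding

Genotypes are additive minor-allele counts, the coding PLINK's
`--recodeA` produces. The minor allele of each variant is the allele with
the lower total count over all non-missing calls **in the whole dataset**,
determined before any train/test split — a mild, conventional form of
information sharing that mirrors standard practice of recoding a complete
panel once. A frequency tie at exactly 0.5 is broken toward the
alphabetically first allele letter, so recoding is deterministic and
idempotent under write→read round trips. Monomorphic variants are coded
all-zero with a warning (they carry no association signal and receive
Cramer's V = 0 downstream); half-missing PED calls ("A 0") are treated as
malformed input rather than silently dropped.

## Association filter

For each SNP, the observed counts O_ij of genotype status j within
population i form a contingency table; Pearson's χ² with
E_ij = n_i·m_j/N gives Cramer's V = sqrt((χ²/N)/min(k−1, r−1)) ∈ [0, 1].
Conventions:

* Missing calls are excluded per SNP, so N varies across SNPs.
* k and r count the populations and statuses **observed** among
  non-missing calls (empty rows/columns are dropped). For common SNPs
  with all three genotype statuses present this equals the nominal r = 3;
  using observed counts avoids zero expected frequencies for absent
  classes. A SNP monomorphic among non-missing calls (r_eff = 1) gets
  V = 0, the only association-free value consistent with V's range.
* The filter keeps SNPs with V **strictly greater** than the threshold
  (default 0.6); a SNP at exactly the threshold is removed.
* In the pipeline the filter is fitted on training samples only.

The production scan is vectorised across SNPs; the test suite checks it
against a naive per-table double loop to 1e-10 on a thousand random
tables, and against scipy's `chi2_contingency` on single tables.

## Missing-data policy

Association tables simply exclude missing calls. The ranker and the
classifiers require complete vectors, so missing genotypes are imputed to
the per-SNP modal status computed on training samples (ties to the
smallest status, all-missing columns to 0). Modal imputation is the
minimal-assumption choice for categorical genotype data; at the default
0.2% missing rate its influence is negligible.

## mRMR ranking

Relevance of SNP f is the plug-in mutual information I(f, c) with the
population label c; redundancy with the already-selected set Ω_s of size
m is the mean (1/m) Σ I(f, f_i). Greedy selection maximises the
difference (the MID scheme): the first pick maximises relevance alone,
each later pick maximises relevance minus mean redundancy, ties going to
the lowest original column index. Notes:

* Genotypes and labels are already categorical, so the maximum-likelihood
  plug-in estimator is used directly — no binning, no small-sample bias
  correction. This matches how discrete mRMR is conventionally run.
* Reported relevance/redundancy values are in bits (log2); the selected
  **order** is invariant to the log base, which a property test verifies.
* Pairwise MI against the newly selected SNP is computed for all
  candidates at once via float64 one-hot inner products (nine
  matrix-vector products per step); float32 accumulation was measurably
  inexact (~1e-9) in values used to break ordering ties, so the wider
  type is deliberate.
* Complexity is O(K²) pairwise MI evaluations for K candidates; ranking
  ~300 candidates over ~1200 samples takes a few seconds.

## Classifiers

* **smo** (`PairwiseLinearSVM`) — a soft-margin linear SVM per unordered
  class pair with one-vs-one voting. Features are standardised to zero
  mean and unit variance using training statistics (mirroring Weka SMO's
  default input normalisation). The name denotes the model family; the
  per-pair quadratic programs are solved by libsvm via scikit-learn
  rather than a re-implementation of the SMO solver — the pipeline's
  contribution is the selection procedure, not the QP algorithm. Default
  C = 1.0.
* **ib1** (`OneNearestNeighbor`) — 1-NN under Euclidean distance with
  per-feature min-max normalisation from the training data; distance ties
  resolve to the earliest training index.
* **dagging** (`DaggingClassifier`) — the training set is shuffled and cut
  into k disjoint subsets of floor(N/k) samples (remainder unused), one
  base learner (default: the smo configuration) per subset, majority
  vote. k = 10 by default; k = 1 reduces exactly to the base learner.
* **random_forest** — scikit-learn's RandomForestClassifier with
  sqrt(M) features per split and 100 trees (the modern default; the
  older 10-tree convention is reachable through `n_trees`).

All vote ties break to the lexicographically smallest label, implemented
in the package's own voting step (library one-vs-one implementations
break ties by decision values, which would make tie behaviour
data-dependent). Randomised learners take explicit seeds; smo and ib1
are fully deterministic.

## Incremental feature selection

For prefix sizes i = step, 2·step, … the top-i ranked SNPs are evaluated
by stratified 10-fold cross-validation. The fold assignment is computed
once per curve and reused for every i, so prefix sizes are compared as
paired observations; a digest of the fold assignment is exposed
(`fold_hash`) and asserted equal across runs. Stratification is used
because several groups are small relative to a tenth of the panel.

Two optimal-prefix rules are provided:

* **max** — the smallest evaluated i achieving the curve's maximum.
* **plateau** (default) — the smallest i with total accuracy ≥ θ whose
  accuracy is not exceeded by more than δ at any later evaluated size.
  Defaults θ = 0.90, δ = 0.01. This replaces visual inspection of the
  curve ("the point where it flattens out above 90%") with a reproducible
  rule. With δ = ∞ it degenerates to the first crossing of θ. If no size
  qualifies, an explicit no-plateau result is returned (the pipeline then
  falls back to the max rule).

The `step` parameter is an efficiency knob: step = 1 evaluates every
prefix; the benchmark uses step = 10 up to 100 SNPs, which resolves the
plateau to within one step at a fraction of the cost.

## Train/test evaluation

The independent test set takes round-half-to-even(0.15 · n_g) samples
from each group g, computed in exact rational arithmetic so that e.g.
110 · 0.15 = 16.5 rounds to 16 rather than drifting on floating point.
Half-to-even is the only simple rounding rule consistent with all nine
published per-group train/test counts of the 1397-sample nine-group
HapMap panel (total test 209, training 1188), which the acceptance tests
verify. Accuracies follow Q_i = T_i/N_i per group and
Q = Σ T_i / Σ N_i in total, so Q·ΣN_i = ΣT_i holds as an integer
identity. `repeat_splits` re-runs the full pipeline over independently
seeded splits and reports mean and standard deviation (sd defined as 0
for a single repetition).

## Synthetic benchmark

The generator emulates a HapMap-like panel: nine groups at the published
training sizes (74–305 samples, 1188 total; the full 1397 with the test
column included), unlinked SNPs, ancestral minor-allele frequency
p ~ U(0.05, 0.5), per-lineage Balding–Nichols draws
Beta(p(1−F)/F, (1−p)(1−F)/F), admixed groups as weighted frequency
mixtures (ASW: 0.8 West African / 0.2 European; MEX: 0.50 European /
0.45 Amerindian / 0.05 West African — literature-typical admixture
proportions; the Amerindian lineage has no unadmixed population of its
own), Hardy–Weinberg genotype draws, and 0.2% missing calls (a typical
post-QC call-rate deficit).

AIM planting has two modes. The default draws AIMs from Balding–Nichols
at high F (`aim_divergence`, default 0.6, versus 0.01 for neutral SNPs);
this separates the Cramer's V distributions cleanly (the AIM median
exceeds the neutral 99th percentile) but leaves a substantial minority of
planted AIMs below V = 0.6, because independent per-lineage Beta draws
coincide by chance. The **cluster** mode instead assigns each lineage a
frequency near 0.05 or 0.95 per AIM (equiprobably, with small jitter),
reproducing the near-absent/near-fixed allele pattern that real
top-ranked AIMs show across continental groups; under it the V > 0.6
filter recovers ≈98–99% of planted AIMs with essentially no neutral
false positives. The benchmark used by the acceptance checks runs in
cluster mode for exactly this reason.

What the simulator does **not** emulate — and hence what passing tests do
not demonstrate about real data: linkage disequilibrium (SNPs are
independent, so redundancy among real neighbouring SNPs is understated
and real panels need more markers than the ~30 the benchmark selects),
genotyping error beyond MCAR missingness, within-group substructure and
relatedness, and realistic genome-wide frequency spectra. Absolute
accuracies on the benchmark (≈0.99) are accordingly optimistic relative
to real HapMap-scale analyses (≈0.90); the quantities the package is
tested on are the relative, structural ones — filter recall/specificity,
plateau behaviour, CV-versus-test agreement, and split variability.

## Problem sizes

The standard benchmark is 5000 SNPs × 1397 samples with 300 planted
AIMs — large enough that the filter's false-positive rate (≤1% of 4700
neutral SNPs) and recall (of 300 AIMs) are measured meaningfully, while a
full pipeline run (scan, ranking ~300 candidates, a 10-point IFS curve,
final evaluation) completes in well under a minute. The
repeated-split summary uses 5 repetitions with a fixed 50-SNP prefix.

## Known limitations

* Multi-allelic variants, phased data and binary PLINK files are out of
  scope; inputs are text PED/MAP or additive TSV matrices.
* The plateau rule's θ and δ are calibration constants, not estimates;
  on curves that never reach θ the pipeline falls back to the max rule.
* Cramer's V is used as a pure effect-size filter; no p-values or
  multiple-testing control are computed, by design.
* The mRMR estimator is the raw plug-in; with very small samples its
  positive bias inflates both relevance and redundancy, which partially
  cancels in the difference but is not corrected.
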