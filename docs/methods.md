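# Methods

`xplatnorm` benchmarks strategies for training machine-learning models on
mixed microarray / RNA-seq expression data. This note records the models,
the procedure, the numerical choices, and what the synthetic evaluation
does and does not establish.

## The benchmark design

The unit of analysis is a cohort of *matched samples*: each patient is
assayed on both platforms, so a training set can swap a patient's platform
without changing the underlying biology. One replicate proceeds as:

1. **Split.** Patients are partitioned 2/3 train, 1/3 holdout, stratified
   by subtype so per-class proportions differ by at most one patient
   between the parts. Any subtype with fewer than 3 patients aborts the
   split.
2. **Titrate.** For each level p in {0, 10, ..., 100}, round(p% x
   n_train) train patients (round-half-to-even) are represented by their
   RNA-seq sample, the rest by their microarray sample. The RNA-seq sets
   are *nested*: one seeded permutation of the train patients is drawn and
   level p uses its first k_p entries, so level p+10 always contains level
   p. Nesting reduces between-level variance; the manifest records it so
   non-nested replication is recognizable.
3. **Filter.** Genes constant (or all-missing, which ingestion maps to
   zero) within the RNA-seq holdout or within the RNA-seq titration
   portion of any level are removed from both platforms. Because the
   subsets depend on the random titration, the filter is re-applied per
   replicate. Subsets with fewer than two samples carry no variability
   information and are skipped.
4. **Normalize** each (method, level) cell (below), producing a training
   matrix whose columns are the train patients plus two platform-pure
   holdout matrices over the holdout patients.
5. **Evaluate** classifiers and PCA reconstruction on both holdouts.

Repeats derive their seed arithmetically from a master seed
(`seed_r = master_seed + r`) so replicates are independent but
individually reproducible from the manifest alone.

## Normalization schemes

All array data first passes through LOG: the (possibly negative)
log2-scale intensities are inverse-transformed and re-logged as
`log2(2^x + 1)`, making every value positive; this LOG matrix is the array
input to every downstream scheme. RNA-seq values enter rank-based and
scale-based schemes as `log2(x + 1)`; untransformed (UN) RNA-seq stays on
the raw count/FPKM scale.

Per-method training recipe at mixed levels (0 < p < 100); the holdout
column lists how the RNA-seq holdout is treated (the array holdout is
always normalized alone):

| method | train recipe | RNA-seq holdout |
|---|---|---|
| LOG | log both sides, gene 0-1 separately, join | alone |
| NPN | rank-inverse-normal per side, join, gene 0-1 | alone |
| QN | RNA-seq quantile-normalized to the array-train target; 0-1 separately; join | to the level's array-train target |
| QN (CN) | per-sample 0-1, CrossNorm joint QN, gene 0-1 | alone (rescale + self-QN) |
| QN-Z | self-QN + Z (array), QN-to-target + Z (RNA-seq); join; gene 0-1 | to the level's array-train target, then Z |
| TDM | RNA-seq TDM'd against array-train; 0-1 separately; join | against the level's array-train |
| Z | z-score per side, join, gene 0-1 | alone |
| UN | LOG array + raw RNA-seq, no 0-1 | alone, raw |

At p = 0 and p = 100 the training set is platform-pure and each scheme is
applied without a cross-platform reference, followed by gene-level 0-1
(except UN). CrossNorm needs both platforms, so its training cells at
0/100% do not exist; TDM needs an array reference, so it has no cell at
100% (at 0% its training set is the LOG array data, and the TDM-normalized
RNA-seq holdout is still evaluated against models trained on it). These
undefined cells are skipped with a logged reason, never silently.

Numerical choices:

- **Quantile normalization** maps each column's rank-r value to the r-th
  entry of a target vector (the mean of sorted columns of the reference,
  or of the matrix itself when self-referenced). Tied input values receive
  the mean of the target entries at their tied positions — the behavior
  users of the standard implementation expect.
- **TDM** pools *all* matrix values (not per gene) and uses
  linear-interpolation ("type 7") quantiles. The reference's IQR-to-tail
  factors set new bounds from the target's own quartiles; values are
  winsorized into those bounds, rescaled to [0, 1] by the winsorized
  min/max, and mapped onto the reference range — so output extremes equal
  the reference extremes unconditionally. RNA-seq enters TDM on the
  log2(x+1) scale so winsorization operates on the same scale as the LOG
  reference; transformed values are not rounded to integers.
- **NPN** is the plain rank-based inverse normal transform,
  `Phi^-1(r / (n + 1))` with average ranks; no shrinkage/truncation
  variant and no sd rescaling.
- **CrossNorm** enumerates all array x RNA-seq column pairings as stacked
  pseudo-samples (genes doubled) when their number is at most
  `max_stack` (default 10,000); above that a seeded random subset that
  still covers every column is used to bound memory.
- **Degenerate rows**: zero-variance genes map to all-zero under
  zero-to-one and z-scoring rather than erroring, because holdout subsets
  can contain constant genes that survived training-side filtering.

## Supervised evaluation

Three families, hyperparameters chosen by stratified fivefold
cross-validation maximizing total accuracy (fold count drops to the
rarest-class count when below five): L1-penalized multinomial logistic
regression (20 log-spaced penalties, C in 10^-3..10^2), linear SVM (cost
in {0.25, 0.5, 1, 2, 4}) and random forest (500 trees, max_features in
{sqrt(p)/2, sqrt(p), 2 sqrt(p)}). Grid ties resolve to the first entry.

Holdout agreement is Cohen's kappa, `(p0 - pe) / (1 - pe)` with pe the sum
over classes of the product of truth and prediction marginals; the
degenerate case pe = 1 returns kappa 0 with a warning (no information
beyond chance). One-vs-all AUC / sensitivity / specificity are
macro-averaged over classes present in the truth; AUC uses class
probabilities for the logistic and forest models and decision values for
the SVM. Replicates are summarized by the median with a
`1.58 * IQR / sqrt(n)` notch-style half-width.

For binary mutation tasks, delta-kappa subtracts the kappa of a *null
model* trained on mutation labels permuted within each subtype of the
training set. The permutation preserves every per-subtype prevalence, so
the null model retains exactly the signal that is a subtype proxy;
positive delta-kappa indicates mutation signal beyond the
mutation-subtype association. Singleton strata are fixed points of the
permutation; a permutation that leaves a single class cannot train a null
model and yields a missing delta. One null model is trained per replicate.

## Unsupervised evaluation

PCA (centering only, no variance scaling; UN data as-is) with 50
components, reduced to n_samples - 1 when the training set is smaller.
Holdout samples are centered with the *training* gene means — required for
a legitimate projection into the training PC space — then projected and
reconstructed. Per-gene error is the mean absolute scaled error, the mean
absolute reconstruction error divided by the gene's mean absolute
deviation about its own mean: scale-invariant, defined near zero, and
symmetric in over/under-estimation. Genes with constant holdout values
have undefined MASE; they are excluded from summaries but counted and
reported. Subtype models trained on the same cell are re-applied to the
reconstructed holdout to measure how much class signal the projection
keeps.

## Synthetic cohorts

The generator draws a latent per-patient log2-expression
`lambda = baseline_g + delta * 1[g in signature(subtype)] + mutation
effect`, shared across platforms. The microarray channel adds Gaussian
noise on the log2 scale (per-gene intensities approximately normal,
possibly negative). The RNA-seq channel draws negative-binomial counts
with mean `library_size * 2^lambda / sum_g 2^lambda` — a monotone
nonlinear map of the same latent signal — so the raw cross-platform
distributions differ strongly (pooled KS distance > 0.1 by construction)
while quantile normalization against the array demonstrably repairs the
mismatch (KS < 0.01). Subtype signatures are disjoint gene blocks;
mutation-signal genes are disjoint from them while mutation *prevalence*
still varies across subtypes, giving delta-kappa both a true-positive case
and a non-trivial null.

Defaults: 200 patients, 2,000 genes, 4 equal subtypes, 50 signature genes
per subtype at effect delta = 2 (log2 units), array noise sd 0.5,
negative-binomial size 10 (moderate overdispersion), library sizes uniform
in [5e5, 2e6], mutation prevalence 0.2-0.8 across subtypes with 30
mutation genes at effect 1. These sizes run the full 11-level x 8-method
sweep in minutes on one core.

What the generator does *not* emulate — deliberately, to stay a clean
null/signal instrument: probe affinity effects, GC and gene-length bias,
batch structure, and real cohort marginals. One consequence worth knowing
when extrapolating to real data: because both channels share the same
per-gene baseline, the gene-wise platform relationship is more consistent
than in real array/RNA-seq pairs, and direction-based linear classifiers
transfer across raw scales more readily than they would in practice.
Untransformed (UN) training still collapses where the design predicts —
on the RNA-seq holdout when training is mostly microarray (low titration)
and on the microarray holdout when training is mostly RNA-seq (high
titration), most visibly for the scale-sensitive random forest — but the
mid-level UN penalty is smaller on these cohorts than on real data.

## Evaluation problem sizes

The shipped checks use: exact identities on small random matrices and the
6-gene x 8-patient worked fixture; chance-level (delta = 0) behavior on
150-patient x 500-gene cohorts, 5 replicates, linear SVM; and the
signal-recovery/ranking comparison at the full default cohort (200 x
2,000, delta = 2) over titration levels 10-90% with the random-forest
family and 2 replicates. The ranking comparison asserts that quantile
normalization and TDM hold median holdout kappa at or above 0.8 on both
platforms at every level 10-90%, and that at some level and platform they
beat untransformed data by at least 0.3 — the level-resolved reading of
the supervised ordering, since UN's failure is concentrated at the
titration extremes here.

## Known limitations

- The nonparanormal variant and the QN tie rule follow the common
  defaults; other implementations differ in ties and in tail shrinkage.
- Nested titration sets are a variance-reduction choice; drawing levels
  independently is equally valid and is distinguishable via the manifest.
- Whether models other than the three linear/forest families behave the
  same is untested here; no nonlinear kernels or deep models are included.
- Real-data preprocessing (probe-level estimation, within-platform batch
  correction, expression quantification) is assumed done upstream.
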