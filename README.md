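# xplatnorm

Cross-platform expression normalization benchmarking: can a single
training set mix microarray and RNA-seq samples?

Large transcriptomic compendia are split across platforms — legacy
microarray studies with continuous log2 intensities, and RNA-seq with
overdispersed counts on a much wider dynamic range. Combining them in one
machine-learning training set requires cross-platform normalization, and
the right choice is not obvious. `xplatnorm` implements a matched-samples
titration benchmark for that question: patients assayed on *both*
platforms are split into training and platform-pure holdout sets, RNA-seq
samples are titrated into the training set in 10% increments (0–100%),
and eight normalization schemes are compared on supervised classification
and unsupervised dimensionality reduction. It is aimed at computational
biologists deciding how to pool array and RNA-seq cohorts, and ships a
synthetic matched-cohort generator so every stage is testable without
access to controlled tumor data.

## What it computes

**Normalization schemes** (genes x samples matrices): LOG
(`log2(2^x + 1)` re-transformed array / `log2(x + 1)` RNA-seq), quantile
normalization to a reference target (QN) and its CrossNorm variant that
quantile-normalizes stacked array+RNA-seq pseudo-samples jointly (QN
(CN)), QN followed by z-scores (QN-Z), Training Distribution Matching
(TDM) — which rescales the RNA-seq distribution so its IQR-to-tail
proportions and range match the array reference, winsorizing out-of-bound
values — the nonparanormal rank-based inverse normal transform (NPN,
`Phi^-1(r/(n+1))`), per-gene z-scores (Z), and untransformed data (UN).
Reference-based schemes use only the *microarray portion of the training
data* at each titration level, never holdout data.

**Supervised evaluation**: LASSO multinomial logistic regression, linear
SVM and random forest, tuned by stratified fivefold CV; holdout
performance scored with Cohen's kappa

    kappa = (p0 - pe) / (1 - pe)

(observed vs chance agreement from marginal products), plus one-vs-all
AUC/sensitivity/specificity and, for mutation tasks, delta-kappa against
a null model trained on mutation labels permuted within subtype.

**Unsupervised evaluation**: PCA (50 components) on each training set,
projection-reconstruction of the holdouts, per-gene mean absolute scaled
error

    MASE = mean_i( |y_i - yhat_i| ) / mean_i( |y_i - ybar| )

and re-prediction of subtypes on the reconstructed holdouts.

See `docs/methods.md` for the per-method training/holdout recipes, the
synthetic cohort model, and all numerical choices.

## Worked example

Run a small simulated experiment (three methods, three titration levels,
two replicates, random forest):

```python
import xplatnorm as xp

config = xp.RunConfig(
    methods=("qn", "tdm", "un"), levels=(10, 50, 90),
    classifiers=("rf",), tasks=("subtype",),
    n_repeats=2, master_seed=7, n_components=20,
    simulation=xp.SyntheticConfig(n_patients=120, n_genes=600,
                                  n_subtypes=3, n_signal_genes=30, seed=7))
result = xp.run_experiment(config)
print(result["summaries"][["method", "level", "holdout_platform",
                           "median", "ci_half_width"]]
      .to_string(index=False))
```

which prints (median holdout kappa per cell, +/- 1.58*IQR/sqrt(n)):

```
method  level holdout_platform   median  ci_half_width
    qn     10            array 1.000000       0.000000
    qn     10           rnaseq 1.000000       0.000000
    qn     50            array 1.000000       0.000000
    qn     50           rnaseq 1.000000       0.000000
    qn     90            array 1.000000       0.000000
    qn     90           rnaseq 1.000000       0.000000
   tdm     10            array 1.000000       0.000000
   tdm     10           rnaseq 1.000000       0.000000
   tdm     50            array 1.000000       0.000000
   tdm     50           rnaseq 1.000000       0.000000
   tdm     90            array 1.000000       0.000000
   tdm     90           rnaseq 1.000000       0.000000
    un     10            array 1.000000       0.000000
    un     10           rnaseq 0.596154       0.107426
    un     50            array 1.000000       0.000000
    un     50           rnaseq 0.903846       0.107426
    un     90            array 0.250000       0.279307
    un     90           rnaseq 1.000000       0.000000
```

Read it as a miniature of the full benchmark: quantile normalization and
TDM keep perfect subtype recovery on *both* platform-pure holdouts at
every titration level, while untransformed data collapses exactly where
platform transfer is required — on the RNA-seq holdout when training is
90% microarray (kappa 0.60), and above all on the microarray holdout when
training is 90% RNA-seq (kappa 0.25): the forest's split thresholds are
calibrated to count-scale features and carry nothing over to log2
intensities.

The same experiment is available from the shell:

```bash
xplatnorm simulate --seed 7 --out-dir sim/
xplatnorm titrate --array sim/array.tsv --rnaseq sim/rnaseq.tsv \
    --labels sim/labels.tsv --seed 7 --out-dir bundles/
xplatnorm evaluate --bundle-dir bundles/ --labels sim/labels.tsv \
    --classifiers svm --seed 7 --out metrics.tsv
xplatnorm reconstruct --bundle-dir bundles/ --components 50 --out recon.tsv
xplatnorm run --config run.yaml     # the full repeated pipeline
```

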