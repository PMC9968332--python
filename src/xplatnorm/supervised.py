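"""Supervised evaluation: classifiers, Cohen's kappa, delta-kappa, summaries.

Three classifier families are benchmarked on every normalized training
set: L1-penalized (LASSO) multinomial logistic regression, a linear-kernel
support vector classifier, and a random forest.  Hyperparameters are
chosen by stratified fivefold cross-validation maximizing total accuracy.

Holdout performance is scored with Cohen's kappa,

    kappa = (p0 - pe) / (1 - pe),

where p0 is the observed agreement between truth and prediction and pe the
chance agreement implied by the two marginal label distributions — a
chance-corrected statistic robust to the class imbalance typical of tumor
subtype panels.  For binary mutation tasks, where mutations concentrate in
particular subtypes, a null model is trained on mutation labels permuted
within each subtype; delta-kappa = kappa(true model) - kappa(null model)
isolates predictive signal beyond the mutation-subtype association.

One-vs-all AUC / sensitivity / specificity (macro-averaged) and the
median +/- 1.58*IQR/sqrt(n) notch-style interval summarize replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import LinearSVC

CLASSIFIERS = ("lasso", "svm", "rf")


# ---------------------------------------------------------------------------
# agreement statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KappaResult:
    p0: float   # observed agreement
    pe: float   # chance agreement from marginal products
    kappa: float


def cohen_kappa(truth: Sequence, predicted: Sequence) -> KappaResult:
    """Chance-corrected agreement between two label vectors.

    p0 is the agreeing fraction; pe sums, over the shared label universe,
    the product of each class's marginal frequency on the two sides.  The
    degenerate case pe = 1 (both vectors constant and identical) is
    returned as kappa = 0: such a prediction carries no information beyond
    chance.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape or truth.ndim != 1 or len(truth) == 0:
        raise ValueError("truth and predicted must be equal-length 1-D, n >= 1")
    n = len(truth)
    p0 = float(np.mean(truth == predicted))
    classes = np.union1d(truth, predicted)
    pe = 0.0
    for c in classes:
        pe += (np.mean(truth == c)) * (np.mean(predicted == c))
    pe = float(pe)
    if pe >= 1.0 - 1e-15:
        warnings.warn("pe = 1 (both label vectors constant); kappa set to 0")
        return KappaResult(p0=p0, pe=pe, kappa=0.0)
    return KappaResult(p0=p0, pe=pe, kappa=(p0 - pe) / (1.0 - pe))


def permute_within_strata(labels: Sequence, strata: Sequence,
                          seed: int) -> np.ndarray:
    """Permute ``labels`` independently within each stratum (per-stratum
    label prevalence is exactly preserved; singleton strata are fixed)."""
    labels = np.asarray(labels)
    strata = np.asarray(strata)
    if labels.shape != strata.shape:
        raise ValueError("labels and strata must align")
    rng = np.random.default_rng(seed)
    out = labels.copy()
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        out[idx] = labels[idx][rng.permutation(len(idx))]
    return out


# ---------------------------------------------------------------------------
# classifier training
# ---------------------------------------------------------------------------

def _cv(labels: np.ndarray, seed: int) -> StratifiedKFold:
    # stratified folds guarantee every fold sees every class whenever
    # class counts allow; with fewer than 5 members in the rarest class
    # the fold count is reduced accordingly
    _, counts = np.unique(labels, return_counts=True)
    n_splits = int(min(5, counts.min()))
    if n_splits < 2:
        raise ValueError("each class needs at least 2 members for CV")
    return StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)


def train_classifier(train: pd.DataFrame, labels: Sequence, family: str,
                     cv_seed: int = 0):
    """Fit one classifier family with 5-fold CV hyperparameter selection.

    ``train`` is genes x samples (columns are patients); it is transposed
    for fitting.  Grids: LASSO — 20 log-spaced penalties; linear SVM —
    cost in {0.25, 0.5, 1, 2, 4}; random forest — 500 trees with
    max_features in {sqrt(p)/2, sqrt(p), 2 sqrt(p)}.  Selection maximizes
    total accuracy; ties resolve to the first grid entry (deterministic).
    """
    X = train.to_numpy().T
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    cv = _cv(y, cv_seed)
    if family == "lasso":
        model = GridSearchCV(
            LogisticRegression(penalty="l1", solver="saga", max_iter=2000,
                               tol=1e-3, random_state=cv_seed),
            {"C": np.logspace(-3, 2, 20)},
            cv=cv, scoring="accuracy", n_jobs=1)
    elif family == "svm":
        model = GridSearchCV(
            LinearSVC(random_state=cv_seed, max_iter=20000),
            {"C": [0.25, 0.5, 1.0, 2.0, 4.0]},
            cv=cv, scoring="accuracy", n_jobs=1)
    elif family == "rf":
        p = X.shape[1]
        root = max(1, int(round(np.sqrt(p))))
        mtry = sorted({max(1, root // 2), root, min(p, 2 * root)})
        model = GridSearchCV(
            RandomForestClassifier(n_estimators=500, random_state=cv_seed),
            {"max_features": mtry},
            cv=cv, scoring="accuracy", n_jobs=1)
    else:
        raise ValueError(f"unknown classifier family {family!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return model


def predict_labels(model, holdout: pd.DataFrame) -> np.ndarray:
    return model.predict(holdout.to_numpy().T)


def predict_scores(model, holdout: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray]:
    """Per-class scores for AUC: probabilities for the penalized logistic
    and forest, decision values for the SVM.  Returns (classes, scores)."""
    X = holdout.to_numpy().T
    est = model.best_estimator_ if hasattr(model, "best_estimator_") else model
    classes = est.classes_
    if hasattr(est, "predict_proba"):
        return classes, est.predict_proba(X)
    scores = est.decision_function(X)
    if scores.ndim == 1:  # binary decision values -> two columns
        scores = np.column_stack([-scores, scores])
    return classes, scores


# ---------------------------------------------------------------------------
# one-vs-all composite metrics
# ---------------------------------------------------------------------------

def one_vs_all_metrics(truth: Sequence, classes: np.ndarray,
                       scores: np.ndarray,
                       predicted: Optional[Sequence] = None,
                       ) -> Tuple[float, float, float]:
    """Macro-averaged one-vs-all AUC, sensitivity and specificity.

    AUC uses the per-class score columns; sensitivity/specificity use the
    hard predictions (argmax of scores when ``predicted`` is omitted).
    Classes absent from the truth are excluded from the average.
    """
    truth = np.asarray(truth)
    if predicted is None:
        predicted = classes[np.argmax(scores, axis=1)]
    predicted = np.asarray(predicted)
    aucs, sens, spec = [], [], []
    for k, c in enumerate(classes):
        pos = truth == c
        if pos.all() or not pos.any():
            continue  # one-vs-all undefined without both outcomes
        aucs.append(roc_auc_score(pos.astype(int), scores[:, k]))
        pred_pos = predicted == c
        tp = np.sum(pos & pred_pos)
        fn = np.sum(pos & ~pred_pos)
        tn = np.sum(~pos & ~pred_pos)
        fp = np.sum(~pos & pred_pos)
        sens.append(tp / (tp + fn))
        spec.append(tn / (tn + fp))
    if not aucs:
        return float("nan"), float("nan"), float("nan")
    return float(np.mean(aucs)), float(np.mean(sens)), float(np.mean(spec))


# ---------------------------------------------------------------------------
# delta-kappa (mutation tasks)
# ---------------------------------------------------------------------------

def delta_kappa(train: pd.DataFrame, holdout: pd.DataFrame,
                truth_mut_train: Sequence, truth_mut_holdout: Sequence,
                subtype_of_train: Sequence, family: str,
                null_seed: int, cv_seed: int = 0,
                ) -> Tuple[float, float, float]:
    """Mutation-signal kappa beyond the mutation-subtype association.

    Trains one model on the true binary mutation labels and one null model
    on labels permuted within each subtype of the training set (the null
    preserves every per-subtype prevalence, hence all signal that is
    merely a subtype proxy).  Returns (delta, kappa_true, kappa_null) on
    the holdout.
    """
    model = train_classifier(train, truth_mut_train, family, cv_seed)
    k_true = cohen_kappa(truth_mut_holdout, predict_labels(model, holdout)).kappa
    null_labels = permute_within_strata(truth_mut_train, subtype_of_train,
                                        null_seed)
    if len(np.unique(null_labels)) < 2:  # a degenerate permutation cannot train
        return float("nan"), k_true, float("nan")
    null_model = train_classifier(train, null_labels, family, cv_seed)
    k_null = cohen_kappa(truth_mut_holdout,
                         predict_labels(null_model, holdout)).kappa
    return k_true - k_null, k_true, k_null


# ---------------------------------------------------------------------------
# records and summaries
# ---------------------------------------------------------------------------

@dataclass
class MetricsRecord:
    classifier: str
    method: str
    level: int
    holdout_platform: str  # "array" | "rnaseq"
    task: str              # "subtype" | "mutation"
    kappa: float
    auc: float
    sensitivity: float
    specificity: float
    repeat: int
    seed: int
    delta_kappa: float = float("nan")  # mutation tasks only

    def as_dict(self) -> dict:
        return dict(classifier=self.classifier, method=self.method,
                    level=self.level, holdout_platform=self.holdout_platform,
                    task=self.task, kappa=self.kappa,
                    delta_kappa=self.delta_kappa, auc=self.auc,
                    sensitivity=self.sensitivity,
                    specificity=self.specificity, repeat=self.repeat,
                    seed=self.seed)


@dataclass(frozen=True)
class MetricSummary:
    median: float
    ci_half_width: float  # 1.58 * IQR / sqrt(n)
    n: int


def summarize_values(values: Sequence[float]) -> MetricSummary:
    """Median with a notch-style 1.58*IQR/sqrt(n) half-width."""
    v = np.asarray([x for x in values if np.isfinite(x)], dtype=float)
    if len(v) == 0:
        raise ValueError("no finite values to summarize")
    q1, q3 = np.quantile(v, [0.25, 0.75])
    return MetricSummary(median=float(np.median(v)),
                         ci_half_width=float(1.58 * (q3 - q1) / np.sqrt(len(v))),
                         n=len(v))


def summarize(records: List[MetricsRecord], metric: str = "kappa",
              ) -> pd.DataFrame:
    """Per-(classifier, method, level, platform, task) median and CI."""
    df = pd.DataFrame([r.as_dict() for r in records])
    rows = []
    keys = ["classifier", "method", "level", "holdout_platform", "task"]
    for key, grp in df.groupby(keys):
        s = summarize_values(grp[metric].to_numpy())
        rows.append(dict(zip(keys, key), metric=metric, median=s.median,
                         ci_half_width=s.ci_half_width, n=s.n))
    return pd.DataFrame(rows)
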