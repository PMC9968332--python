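"""Train/holdout partitioning and RNA-seq titration.

The benchmark design: matched patients are split 2/3 train, 1/3 holdout
(stratified by subtype).  Training sets are then built at eleven titration
levels (0%, 10%, ..., 100% RNA-seq): at level p, round(p% * n_train) train
patients are represented by their RNA-seq sample and the rest by their
microarray sample, so patient identity is constant across levels and only
the platform varies.  Holdout sets stay platform-pure (one all-array, one
all-RNA-seq) and are normalized separately from training — the only
training-side information a holdout normalization may use is the level's
microarray training portion, which serves as the reference distribution
for QN, QN-Z and TDM on the RNA-seq holdout.

Per-method normalization recipes follow the benchmark protocol literally;
see :func:`assemble_training_set` / :func:`assemble_holdout_sets`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, LabelTable, MatchedPairSet
from . import normalize as nz

METHODS = ("log", "npn", "qn", "qn-cn", "qn-z", "tdm", "z", "un")
LEVELS = tuple(range(0, 101, 10))


class MethodUnavailable(ValueError):
    """A (method, level) cell that the protocol leaves undefined."""


def method_defined(method: str, level: int, *, training: bool) -> bool:
    """Whether a (method, level) cell exists.

    CrossNorm requires samples from both platforms, so there is no QN (CN)
    training data at 0% or 100% RNA-seq.  TDM requires a microarray
    reference, so there is no TDM at 100% RNA-seq (training or holdout);
    at 0% the TDM cell exists with a LOG-array training set.
    """
    if method == "qn-cn" and training and level in (0, 100):
        return False
    if method == "tdm" and level == 100:
        return False
    return True


# ---------------------------------------------------------------------------
# plan
# ---------------------------------------------------------------------------

@dataclass
class TitrationPlan:
    """Seeded train/holdout split plus nested per-level platform assignment."""

    seed: int
    train_patients: List[str]
    holdout_patients: List[str]
    rnaseq_order: List[str]  # permutation of train_patients; level p uses a prefix
    levels: tuple = LEVELS

    def n_rnaseq(self, level: int) -> int:
        if level not in self.levels:
            raise ValueError(f"level {level} not in plan")
        # round-half-to-even, matching the protocol's slight count variation
        return round(level / 100 * len(self.train_patients))

    def rnaseq_patients(self, level: int) -> List[str]:
        return self.rnaseq_order[: self.n_rnaseq(level)]

    def array_patients(self, level: int) -> List[str]:
        chosen = set(self.rnaseq_patients(level))
        return [p for p in self.train_patients if p not in chosen]

    def to_manifest(self) -> dict:
        return {
            "seed": self.seed,
            "train_patients": self.train_patients,
            "holdout_patients": self.holdout_patients,
            "rnaseq_order": self.rnaseq_order,
            "levels": list(self.levels),
            "nested": True,
        }


def make_plan(pair: MatchedPairSet, labels: LabelTable, seed: int,
              levels: Sequence[int] = LEVELS) -> TitrationPlan:
    """Stratified 2/3 train, 1/3 holdout split plus nested titration order.

    Stratification keeps per-subtype proportions in train and holdout
    within one patient of each other.  The titration sets are nested: the
    RNA-seq patient set at level p is a prefix of a single seeded
    permutation, so level p+10 always contains level p.
    """
    rng = np.random.default_rng(seed)
    missing = [p for p in pair.patient_ids if p not in labels.subtype]
    if missing:
        raise ValueError(f"unlabeled patients: {missing[:5]}")
    by_class: Dict[str, List[str]] = {}
    for p in pair.patient_ids:
        by_class.setdefault(labels.subtype[p], []).append(p)
    for cls, members in by_class.items():
        if len(members) < 3:
            raise ValueError(
                f"subtype {cls!r} has only {len(members)} patients; "
                "cannot stratify a 2/3-1/3 split"
            )
    train: List[str] = []
    holdout: List[str] = []
    for cls in sorted(by_class):
        members = list(by_class[cls])
        rng.shuffle(members)
        n_train = round(2 / 3 * len(members))
        n_train = min(max(n_train, 1), len(members) - 1)
        train.extend(members[:n_train])
        holdout.extend(members[n_train:])
    # keep original cohort order within the split for readability
    order = {p: i for i, p in enumerate(pair.patient_ids)}
    train.sort(key=order.get)
    holdout.sort(key=order.get)
    rnaseq_order = list(train)
    rng.shuffle(rnaseq_order)
    return TitrationPlan(seed=seed, train_patients=train,
                         holdout_patients=holdout,
                         rnaseq_order=rnaseq_order,
                         levels=tuple(levels))


def rnaseq_filter_subsets(pair: MatchedPairSet,
                          plan: TitrationPlan) -> List[List[str]]:
    """The RNA-seq sample groups whose constant genes must be filtered:
    the holdout set plus the titration portion at every level."""
    subsets = [pair.rnaseq_samples_for(plan.holdout_patients)]
    for level in plan.levels:
        subsets.append(pair.rnaseq_samples_for(plan.rnaseq_patients(level)))
    return subsets


# ---------------------------------------------------------------------------
# normalized bundles
# ---------------------------------------------------------------------------

@dataclass
class NormalizedBundle:
    """One normalized (method, level) cell of the experiment.

    ``train`` columns are patient ids (each train patient exactly once,
    sourced from whichever platform the plan assigns at this level); the
    holdout frames are platform-pure over the holdout patients.
    ``reference_samples`` records which array training samples served as
    the reference distribution for the RNA-seq holdout (empty when the
    method uses none) — the basis of the leakage audit.
    """

    method: str
    level: int
    train: pd.DataFrame
    array_holdout: pd.DataFrame
    rnaseq_holdout: Optional[pd.DataFrame]
    reference_samples: List[str] = field(default_factory=list)


def _em(values: np.ndarray, genes: Sequence[str], samples: Sequence[str],
        platform: str) -> ExpressionMatrix:
    return ExpressionMatrix(list(genes), list(samples), values, platform)


def _frame(matrix: ExpressionMatrix, columns: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame(matrix.values, index=matrix.genes, columns=list(columns))


def _single_platform_normalize(mat: ExpressionMatrix, method: str,
                               is_rnaseq: bool) -> ExpressionMatrix:
    """Normalize one platform-pure matrix with no external reference,
    then apply the gene-level zero-to-one rescale (except UN)."""
    base = nz.log2_seq(mat) if is_rnaseq else nz.log2_array(mat)
    if method == "un":
        return mat.with_values(mat.values.copy()) if is_rnaseq else base
    if method in ("log", "tdm"):
        out = base  # TDM leaves the array side as LOG data
    elif method == "npn":
        out = nz.npn(base)
    elif method == "qn":
        out = nz.quantile_normalize_self(base)
    elif method == "qn-z":
        out = nz.qn_z(base, None)
    elif method == "qn-cn":
        out = nz.quantile_normalize_self(nz.zero_to_one_columns(base))
    elif method == "z":
        out = nz.z_score(base)
    else:
        raise ValueError(f"unknown method {method!r}")
    return nz.zero_to_one(out)


def assemble_training_set(pair: MatchedPairSet, plan: TitrationPlan,
                          level: int, method: str, *,
                          seed: int = 0,
                          max_stack: int = nz.DEFAULT_MAX_STACK,
                          ) -> pd.DataFrame:
    """Build the normalized mixed-platform training matrix for one cell.

    Columns are patient ids; the microarray portion comes first, then the
    RNA-seq titration portion.  Raises :class:`MethodUnavailable` for the
    undefined cells (QN (CN) at 0/100%, TDM at 100%).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    if not method_defined(method, level, training=True):
        raise MethodUnavailable(f"no {method} training data at {level}% RNA-seq")
    arr_patients = plan.array_patients(level)
    seq_patients = plan.rnaseq_patients(level)

    if not seq_patients:  # 0% RNA-seq: single-platform array training set
        arr = pair.array_matrix.subset_samples(pair.array_samples_for(arr_patients))
        return _frame(_single_platform_normalize(arr, method, False), arr_patients)
    if not arr_patients:  # 100% RNA-seq
        seq = pair.rnaseq_matrix.subset_samples(pair.rnaseq_samples_for(seq_patients))
        return _frame(_single_platform_normalize(seq, method, True), seq_patients)

    arr = pair.array_matrix.subset_samples(pair.array_samples_for(arr_patients))
    seq = pair.rnaseq_matrix.subset_samples(pair.rnaseq_samples_for(seq_patients))
    arr_log = nz.log2_array(arr)
    seq_log = nz.log2_seq(seq)

    def join(a: ExpressionMatrix, s: ExpressionMatrix) -> pd.DataFrame:
        return pd.concat([_frame(a, arr_patients), _frame(s, seq_patients)],
                         axis=1)

    if method == "log":
        return join(nz.zero_to_one(arr_log), nz.zero_to_one(seq_log))
    if method == "npn":
        joined = join(nz.npn(arr_log), nz.npn(seq_log))
        return pd.DataFrame(nz.zero_to_one_rows(joined.to_numpy()),
                            index=joined.index, columns=joined.columns)
    if method == "qn":
        target = nz.target_quantiles(arr_log.values)
        seq_qn = nz.quantile_normalize_to_target(seq_log, target)
        return join(nz.zero_to_one(arr_log), nz.zero_to_one(seq_qn))
    if method == "qn-cn":
        a_out, s_out = nz.crossnorm_qn(arr_log, seq_log,
                                       max_stack=max_stack, seed=seed)
        joined = join(a_out, s_out)
        return pd.DataFrame(nz.zero_to_one_rows(joined.to_numpy()),
                            index=joined.index, columns=joined.columns)
    if method == "qn-z":
        target = nz.target_quantiles(arr_log.values)
        joined = join(nz.qn_z(arr_log, None), nz.qn_z(seq_log, target))
        return pd.DataFrame(nz.zero_to_one_rows(joined.to_numpy()),
                            index=joined.index, columns=joined.columns)
    if method == "tdm":
        ref = nz.tdm_fit(arr_log)
        seq_tdm = nz.tdm_transform(seq_log, ref)
        return join(nz.zero_to_one(arr_log), nz.zero_to_one(seq_tdm))
    if method == "z":
        joined = join(nz.z_score(arr_log), nz.z_score(seq_log))
        return pd.DataFrame(nz.zero_to_one_rows(joined.to_numpy()),
                            index=joined.index, columns=joined.columns)
    if method == "un":
        return join(arr_log, seq)
    raise ValueError(f"unknown method {method!r}")  # pragma: no cover


def assemble_holdout_sets(pair: MatchedPairSet, plan: TitrationPlan,
                          level: int, method: str,
                          ) -> NormalizedBundle:
    """Normalize the two platform-pure holdout sets for one cell.

    The microarray holdout is always normalized alone.  The RNA-seq
    holdout uses the level's microarray training portion as reference for
    QN, QN-Z and TDM (self-reference for QN/QN-Z at 100%; TDM absent
    there); every other method normalizes it without reference.  Holdout
    normalization never sees holdout labels, the training RNA-seq data, or
    the other holdout platform.

    Returns a bundle whose ``train`` frame is also assembled, so one call
    yields a complete, auditable cell.
    """
    train = assemble_training_set(pair, plan, level, method)

    hold = plan.holdout_patients
    arr_h = pair.array_matrix.subset_samples(pair.array_samples_for(hold))
    seq_h = pair.rnaseq_matrix.subset_samples(pair.rnaseq_samples_for(hold))

    array_holdout = _frame(_single_platform_normalize(arr_h, method, False), hold)

    reference_samples: List[str] = []
    rnaseq_holdout: Optional[pd.DataFrame]
    if method in ("qn", "qn-z", "tdm") and level < 100:
        ref_sample_ids = pair.array_samples_for(plan.array_patients(level))
        ref_log = nz.log2_array(pair.array_matrix.subset_samples(ref_sample_ids))
        seq_log = nz.log2_seq(seq_h)
        if method == "qn":
            out = nz.quantile_normalize_to_target(
                seq_log, nz.target_quantiles(ref_log.values))
        elif method == "qn-z":
            out = nz.qn_z(seq_log, nz.target_quantiles(ref_log.values))
        else:
            out = nz.tdm_transform(seq_log, nz.tdm_fit(ref_log))
        rnaseq_holdout = _frame(nz.zero_to_one(out), hold)
        reference_samples = ref_sample_ids
    elif method == "tdm":  # level == 100: no array reference exists
        rnaseq_holdout = None
    else:
        rnaseq_holdout = _frame(
            _single_platform_normalize(seq_h, method, True), hold)

    return NormalizedBundle(method=method, level=level, train=train,
                            array_holdout=array_holdout,
                            rnaseq_holdout=rnaseq_holdout,
                            reference_samples=reference_samples)


def make_bundle(pair: MatchedPairSet, plan: TitrationPlan, level: int,
                method: str) -> NormalizedBundle:
    """Assemble the full normalized cell (train + both holdouts)."""
    return assemble_holdout_sets(pair, plan, level, method)


# ---------------------------------------------------------------------------
# leakage audit
# ---------------------------------------------------------------------------

def audit_bundle(bundle: NormalizedBundle, pair: MatchedPairSet,
                 plan: TitrationPlan) -> None:
    """Provenance assertions against train/holdout contamination.

    Verifies that training columns are exactly the train patients, holdout
    columns exactly the holdout patients (disjoint from training), and
    that the only training-side data a holdout normalization consumed is
    the level's microarray training portion (QN/QN-Z/TDM reference), never
    a holdout sample.  Raises ``AssertionError`` on any violation.
    """
    train_cols = list(bundle.train.columns)
    assert sorted(train_cols) == sorted(plan.train_patients), \
        "training columns are not exactly the train patients"
    assert len(set(train_cols)) == len(train_cols), \
        "duplicated training column"
    assert not set(train_cols) & set(plan.holdout_patients), \
        "holdout patient appears in training matrix"
    assert list(bundle.array_holdout.columns) == plan.holdout_patients
    if bundle.rnaseq_holdout is not None:
        assert list(bundle.rnaseq_holdout.columns) == plan.holdout_patients
    expected_ref: List[str] = []
    if bundle.method in ("qn", "qn-z", "tdm") and bundle.level < 100 \
            and bundle.rnaseq_holdout is not None:
        expected_ref = pair.array_samples_for(plan.array_patients(bundle.level))
    assert bundle.reference_samples == expected_ref, \
        "RNA-seq holdout reference is not the level's array-train portion"
    holdout_array_samples = set(pair.array_samples_for(plan.holdout_patients))
    assert not set(bundle.reference_samples) & holdout_array_samples, \
        "holdout sample used as normalization reference"
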