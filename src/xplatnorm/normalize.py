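"""Cross-platform normalization procedures.

Eight schemes for putting microarray log2 intensities and RNA-seq counts on
a common footing before joint model training:

``log2_array`` / ``log2_seq``
    Platform-appropriate log transforms (the array data are already on a
    log2 scale but may be negative; they are inverse-transformed and
    re-logged with a +1 offset so all values are positive).
``quantile_normalize_self`` / ``quantile_normalize_to_target``
    Classic quantile normalization: every sample is forced onto a shared
    set of quantiles, either the mean-of-sorted of the matrix itself or an
    external reference (the microarray training portion).
``crossnorm_qn``
    CrossNorm-style joint normalization: array and RNA-seq columns are
    combinatorially stacked into pseudo-samples, quantile-normalized
    together, and unstacked by averaging, pulling both platforms toward one
    shared distribution.
``tdm_fit`` / ``tdm_transform``
    Training Distribution Matching: rescales the RNA-seq distribution so
    its IQR-to-tail proportions and range match the reference array
    distribution, winsorizing out-of-bound values.
``npn``
    Nonparanormal (rank-based inverse normal) transform per gene.
``z_score``
    Per-gene standardization (sample sd, n-1 denominator).
``zero_to_one``
    Per-gene linear rescaling to [0, 1].
``qn_z``
    Quantile normalization followed by z-scoring.

All operations preserve matrix shape, are deterministic given their inputs
(and seed, for the capped CrossNorm stacking), and commute with sample
reordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats

from .data import ExpressionMatrix

# cap on the number of stacked pseudo-samples enumerated by crossnorm_qn
# before falling back to seeded random pairings
DEFAULT_MAX_STACK = 10_000


# ---------------------------------------------------------------------------
# elementwise log transforms
# ---------------------------------------------------------------------------

def log2_array(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Re-log microarray data so all values are positive.

    Input is log2-scale intensity (possibly negative after lowess/SCAN
    preprocessing); output is ``log2(2**x + 1)``, a strictly monotone map
    with range (0, inf).
    """
    return matrix.with_values(np.log2(np.exp2(matrix.values) + 1.0))


def log2_seq(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """``log2(x + 1)`` for nonnegative RNA-seq counts/FPKM."""
    if (matrix.values < 0).any():
        raise ValueError("RNA-seq matrix contains negative values")
    return matrix.with_values(np.log2(matrix.values + 1.0))


# ---------------------------------------------------------------------------
# per-gene rescaling
# ---------------------------------------------------------------------------

def zero_to_one_rows(values: np.ndarray) -> np.ndarray:
    """Rescale each row linearly to [0, 1]; constant rows map to all-zero."""
    values = np.asarray(values, dtype=float)
    lo = values.min(axis=1, keepdims=True)
    hi = values.max(axis=1, keepdims=True)
    span = hi - lo
    out = np.zeros_like(values)
    nz = span[:, 0] > 0
    out[nz] = (values[nz] - lo[nz]) / span[nz]
    return out


def zero_to_one(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene zero-to-one transformation (idempotent)."""
    return matrix.with_values(zero_to_one_rows(matrix.values))


def zero_to_one_columns(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-sample (column) zero-to-one rescaling, used before CrossNorm."""
    return matrix.with_values(zero_to_one_rows(matrix.values.T).T)


def z_score_rows(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True) if values.shape[1] > 1 \
        else np.zeros_like(values[:, :1])
    out = np.zeros_like(values)
    nz = sd[:, 0] > 0
    out[nz] = (values[nz] - mu[nz]) / sd[nz]
    return out


def z_score(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z = (x - mu) / sigma with sample sd (n-1 denominator).

    Zero-variance genes map to all-zero rather than erroring, because
    holdout subsets can contain constant genes that survived training-side
    filtering.
    """
    return matrix.with_values(z_score_rows(matrix.values))


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def target_quantiles(values: np.ndarray) -> np.ndarray:
    """Build a target distribution from a reference matrix.

    Each column is sorted and the sorted columns are averaged, yielding a
    non-decreasing vector of length = gene count.
    """
    values = np.asarray(values, dtype=float)
    return np.sort(values, axis=0).mean(axis=1)


def _map_column_to_target(column: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Replace the value of rank r with target[r]; tied values all receive
    the mean of the target entries at their tied rank positions."""
    n = len(column)
    order = np.argsort(column, kind="mergesort")
    sorted_vals = column[order]
    starts = np.r_[0, np.flatnonzero(sorted_vals[1:] != sorted_vals[:-1]) + 1]
    lengths = np.diff(np.r_[starts, n])
    group_means = np.add.reduceat(target, starts) / lengths
    out = np.empty(n, dtype=float)
    out[order] = np.repeat(group_means, lengths)
    return out


def quantile_normalize_to_target(matrix: ExpressionMatrix,
                                 target: np.ndarray) -> ExpressionMatrix:
    """Force every column onto the quantiles of ``target``.

    ``target`` must be a sorted vector with one entry per gene; on tie-free
    columns, the sorted output column equals ``target`` exactly.
    """
    target = np.asarray(target, dtype=float)
    if target.ndim != 1 or len(target) != matrix.n_genes:
        raise ValueError(
            f"target length {target.shape} does not match gene count "
            f"{matrix.n_genes}"
        )
    if np.any(np.diff(target) < 0):
        raise ValueError("target quantiles must be non-decreasing")
    out = np.empty_like(matrix.values)
    for j in range(matrix.n_samples):
        out[:, j] = _map_column_to_target(matrix.values[:, j], target)
    return matrix.with_values(out)


def quantile_normalize_self(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize the columns of a single matrix against their own
    mean-of-sorted target (the no-reference case)."""
    if matrix.n_samples < 2:
        # QN of a single column against itself is the identity
        return matrix.with_values(matrix.values.copy())
    target = target_quantiles(matrix.values)
    return quantile_normalize_to_target(matrix, target)


def qn_z(matrix: ExpressionMatrix,
         target: Optional[np.ndarray] = None) -> ExpressionMatrix:
    """Quantile normalization (to ``target`` if given, else self) followed
    by per-gene z-scoring."""
    if target is None:
        qn = quantile_normalize_self(matrix)
    else:
        qn = quantile_normalize_to_target(matrix, target)
    return z_score(qn)


# ---------------------------------------------------------------------------
# CrossNorm: joint QN of stacked pseudo-samples
# ---------------------------------------------------------------------------

def _stack_pairs(n_array: int, n_rnaseq: int, max_stack: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Choose the (array column, rnaseq column) pairs to stack.

    Exhaustive enumeration when the product fits under ``max_stack``;
    otherwise a seeded random subset that still covers every column on both
    sides at least once.
    """
    total = n_array * n_rnaseq
    if total <= max_stack:
        return np.array([(i, j) for i in range(n_array)
                         for j in range(n_rnaseq)], dtype=int)
    # coverage first: cycle the longer side against a shuffled shorter side
    pairs = set()
    perm_a = rng.permutation(n_array)
    perm_s = rng.permutation(n_rnaseq)
    for k in range(max(n_array, n_rnaseq)):
        pairs.add((int(perm_a[k % n_array]), int(perm_s[k % n_rnaseq])))
    while len(pairs) < max_stack:
        need = max_stack - len(pairs)
        ii = rng.integers(0, n_array, size=need)
        jj = rng.integers(0, n_rnaseq, size=need)
        pairs.update(zip(ii.tolist(), jj.tolist()))
    return np.array(sorted(pairs), dtype=int)


def crossnorm_qn(array_matrix: ExpressionMatrix,
                 rnaseq_matrix: ExpressionMatrix,
                 max_stack: int = DEFAULT_MAX_STACK,
                 seed: int = 0,
                 ) -> Tuple[ExpressionMatrix, ExpressionMatrix]:
    """CrossNorm-style joint quantile normalization of two platforms.

    Each sample (column) on each side is first rescaled zero-to-one.
    Stacked pseudo-samples are then formed by concatenating one array
    column with one RNA-seq column (genes doubled), all pseudo-samples are
    quantile-normalized together, and each original column's normalized
    values are recovered by averaging its appearances across stacks.
    """
    if array_matrix.genes != rnaseq_matrix.genes:
        raise ValueError("CrossNorm requires an identical gene list")
    if array_matrix.n_samples == 0 or rnaseq_matrix.n_samples == 0:
        raise ValueError("CrossNorm requires samples on both platforms")
    g = array_matrix.n_genes
    a = zero_to_one_rows(array_matrix.values.T).T
    s = zero_to_one_rows(rnaseq_matrix.values.T).T
    rng = np.random.default_rng(seed)
    pairs = _stack_pairs(array_matrix.n_samples, rnaseq_matrix.n_samples,
                         max_stack, rng)
    stacked = np.empty((2 * g, len(pairs)))
    for k, (i, j) in enumerate(pairs):
        stacked[:g, k] = a[:, i]
        stacked[g:, k] = s[:, j]
    if len(pairs) >= 2:
        qn = quantile_normalize_to_target(
            ExpressionMatrix([f"r{t}" for t in range(2 * g)],
                             [f"c{t}" for t in range(len(pairs))],
                             stacked, "array"),
            target_quantiles(stacked)).values
    else:
        qn = stacked
    array_out = np.zeros_like(a)
    rnaseq_out = np.zeros_like(s)
    counts_a = np.zeros(array_matrix.n_samples)
    counts_s = np.zeros(rnaseq_matrix.n_samples)
    for k, (i, j) in enumerate(pairs):
        array_out[:, i] += qn[:g, k]
        rnaseq_out[:, j] += qn[g:, k]
        counts_a[i] += 1
        counts_s[j] += 1
    array_out /= counts_a
    rnaseq_out /= counts_s
    return array_matrix.with_values(array_out), rnaseq_matrix.with_values(rnaseq_out)


# ---------------------------------------------------------------------------
# Training Distribution Matching (TDM)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TdmReference:
    """Summary of a reference (array) distribution for TDM.

    ``upper_factor`` and ``lower_factor`` are how many reference IQRs fit
    into the reference's upper (max - Q3) and lower (Q1 - min) tails.
    """

    q1: float
    q3: float
    iqr: float
    ref_min: float
    ref_max: float
    upper_factor: float
    lower_factor: float


def tdm_fit(reference: ExpressionMatrix | np.ndarray) -> TdmReference:
    """Compute TDM reference statistics over all pooled reference values.

    Quantiles are linear-interpolation ("type 7") quantiles of the whole
    matrix, not per gene: TDM matches whole-distribution spread.
    """
    values = reference.values if isinstance(reference, ExpressionMatrix) \
        else np.asarray(reference, dtype=float)
    pooled = values.ravel()
    q1, q3 = np.quantile(pooled, [0.25, 0.75])
    iqr = q3 - q1
    if iqr <= 0:
        raise ValueError("reference IQR is zero; TDM undefined")
    ref_min, ref_max = float(pooled.min()), float(pooled.max())
    return TdmReference(q1=float(q1), q3=float(q3), iqr=float(iqr),
                        ref_min=ref_min, ref_max=ref_max,
                        upper_factor=float((ref_max - q3) / iqr),
                        lower_factor=float((q1 - ref_min) / iqr))


def tdm_transform(target_matrix: ExpressionMatrix,
                  ref: TdmReference) -> ExpressionMatrix:
    """Stretch/shrink a target (RNA-seq) distribution to match ``ref``.

    Steps: (1) set new bounds from the target's own quartiles scaled by the
    reference tail factors; (2) winsorize into those bounds; (3) rescale
    the winsorized values to [0, 1]; (4) map onto the reference range
    ``[ref_min, ref_max]``.  The result is monotone non-decreasing in the
    input and its extremes equal the reference extremes.
    """
    values = target_matrix.values
    pooled = values.ravel()
    if np.all(pooled == pooled[0]):
        raise ValueError("degenerate target: all values equal")
    q1t, q3t = np.quantile(pooled, [0.25, 0.75])
    iqrt = q3t - q1t
    new_upper = q3t + ref.upper_factor * iqrt
    new_lower = q1t - ref.lower_factor * iqrt
    wins = np.clip(values, new_lower, new_upper)
    lo, hi = wins.min(), wins.max()
    if hi == lo:
        raise ValueError("degenerate target after winsorization")
    unit = (wins - lo) / (hi - lo)
    return target_matrix.with_values(
        unit * (ref.ref_max - ref.ref_min) + ref.ref_min)


# ---------------------------------------------------------------------------
# Nonparanormal (rank-based inverse normal)
# ---------------------------------------------------------------------------

def npn(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene rank-based inverse normal transform.

    Each value is replaced by ``Phi^-1(r / (n + 1))`` where ``r`` is its
    average rank among the gene's ``n`` values — placing each observation
    where it would fall on a standard normal distribution.  Output depends
    only on within-gene ranks, so any strictly increasing transform of the
    input leaves the result unchanged.
    """
    if matrix.n_samples < 2:
        raise ValueError("NPN requires at least 2 samples")
    n = matrix.n_samples
    ranks = stats.rankdata(matrix.values, axis=1, method="average")
    return matrix.with_values(stats.norm.ppf(ranks / (n + 1)))
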