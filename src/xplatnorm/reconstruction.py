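"""PCA projection-reconstruction of holdout data and per-gene MASE.

Unsupervised evaluation: fit PCA (50 components, centering only) on each
normalized training set, project the holdout data onto the training PC
space, reconstruct it from those components, and score the distortion per
gene with the mean absolute scaled error

    MASE = mean_i( |y_i - yhat_i| / mean_j |y_j - ybar| ),

the mean absolute reconstruction error scaled by the gene's own mean
absolute deviation — scale-invariant, defined near zero, and weighting
over- and under-estimation equally.  Subtype classifiers trained on the
same bundle are then re-applied to the reconstructed holdout to check how
much class signal survives the low-dimensional projection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

DEFAULT_N_COMPONENTS = 50


@dataclass
class PcaModel:
    """Centering vector plus orthonormal loading matrix over genes."""

    gene_means: np.ndarray          # (n_genes,)
    components: np.ndarray          # (n_components, n_genes), orthonormal rows
    genes: list
    n_components: int
    explained_variance: np.ndarray


def fit_pca(train: pd.DataFrame,
            n_components: int = DEFAULT_N_COMPONENTS) -> PcaModel:
    """PCA on a genes x samples training frame (samples are observations).

    Genes are centered by their training means; no variance scaling (the
    inputs are already gene-wise zero-to-one for most normalization
    schemes, and untransformed data is analyzed as-is).  When the training
    set has fewer than ``n_components + 1`` samples, the component count
    is reduced to n_samples - 1.
    """
    n_samples = train.shape[1]
    if n_samples < 2:
        raise ValueError("PCA requires at least 2 training samples")
    k = int(min(n_components, n_samples - 1, train.shape[0]))
    X = train.to_numpy().T  # samples x genes
    pca = PCA(n_components=k, svd_solver="auto", random_state=0)
    pca.fit(X)
    return PcaModel(gene_means=pca.mean_, components=pca.components_,
                    genes=list(train.index), n_components=k,
                    explained_variance=pca.explained_variance_)


@dataclass
class ReconstructionResult:
    reconstructed: pd.DataFrame        # genes x samples, same shape as input
    mase: pd.Series                    # per gene; NaN where y is constant
    n_constant_genes: int              # MASE exclusions (reported, not hidden)


def project_reconstruct(holdout: pd.DataFrame,
                        model: PcaModel) -> ReconstructionResult:
    """Project holdout samples onto the training PC space and back.

    yhat = means + W^T (W (y - means)) with W the loading matrix; holdout
    samples are centered with the TRAINING gene means, as required for a
    projection into the training space.  The map is an orthogonal
    projector: idempotent and symmetric.
    """
    if list(holdout.index) != model.genes:
        raise ValueError("holdout gene list does not match the PCA model")
    Y = holdout.to_numpy().T - model.gene_means       # samples x genes
    recon = Y @ model.components.T @ model.components + model.gene_means
    recon_df = pd.DataFrame(recon.T, index=holdout.index,
                            columns=holdout.columns)
    mase_vals = mase_frame(holdout, recon_df)
    return ReconstructionResult(reconstructed=recon_df, mase=mase_vals,
                                n_constant_genes=int(mase_vals.isna().sum()))


def mase(y: Sequence[float], y_hat: Sequence[float]) -> float:
    """Mean absolute scaled error of one gene across samples.

    Undefined (NaN) when the observed values are constant — the scaling
    denominator, the gene's mean absolute deviation, is zero.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.ndim != 1 or len(y) < 2:
        raise ValueError("y and y_hat must be equal-length 1-D with n >= 2")
    denom = np.mean(np.abs(y - y.mean()))
    if denom == 0:
        return float("nan")
    return float(np.mean(np.abs(y - y_hat) / denom))


def mase_frame(y: pd.DataFrame, y_hat: pd.DataFrame) -> pd.Series:
    """Per-gene (row-wise) MASE between two genes x samples frames."""
    yv = y.to_numpy()
    hv = y_hat.to_numpy()
    denom = np.mean(np.abs(yv - yv.mean(axis=1, keepdims=True)), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.mean(np.abs(yv - hv), axis=1) / denom
    vals[denom == 0] = np.nan
    return pd.Series(vals, index=y.index, name="mase")


def repredict(reconstructed: pd.DataFrame, model,
              truth: Sequence) -> float:
    """Kappa of a previously trained subtype classifier on reconstructed
    holdout data (comparable side-by-side with the unreconstructed kappa)."""
    from .supervised import cohen_kappa, predict_labels
    return cohen_kappa(truth, predict_labels(model, reconstructed)).kappa
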