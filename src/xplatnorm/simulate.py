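"""Synthetic matched microarray / RNA-seq cohorts with planted structure.

Both platforms measure the same latent biology: per patient and gene a
latent log2-expression

    lambda_gp = baseline_g + delta * [g in signature(subtype_p)]
              + mut_effect * [g in mutation signature] * mutation_p

is shared across platforms.  The microarray channel adds Gaussian
measurement noise on the log2 scale (so per-gene intensities are
approximately normal and may be negative).  The RNA-seq channel draws
overdispersed negative-binomial counts whose mean is the patient's library
size times the relative abundance 2**lambda / sum_g 2**lambda — a monotone
nonlinear map of the same latent signal, so the raw value distributions of
the two platforms differ strongly (the cross-platform normalization
problem is non-trivial by construction).

Subtype signatures are disjoint gene blocks; mutation-signal genes are
disjoint from all subtype signatures, so mutation prediction has signal
that is not a subtype proxy, while mutation prevalence still varies by
subtype (the confounding the delta-kappa null is designed to remove).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .data import ARRAY, RNASEQ, ExpressionMatrix, LabelTable, MatchedPairSet


@dataclass
class SyntheticConfig:
    """Cohort-level parameters of the generator.

    Defaults describe a cohort large enough to run the full titration
    sweep quickly while keeping classifier behavior realistic: 200
    patients, 2000 genes, 4 subtypes with mildly unbalanced prevalence,
    a 2-log2-unit subtype effect on 50 genes per subtype, and mutation
    prevalence varying across subtypes.
    """

    n_patients: int = 200
    n_genes: int = 2000
    n_subtypes: int = 4
    subtype_proportions: Optional[Tuple[float, ...]] = None  # default uniform
    n_signal_genes: int = 50          # per subtype, disjoint blocks
    effect_size: float = 2.0          # delta, log2 units
    array_noise_sd: float = 0.5       # log2 intensity noise
    nb_dispersion: float = 10.0       # NB size; smaller = more overdispersed
    library_size_range: Tuple[float, float] = (5e5, 2e6)
    mutation_prevalence: Optional[Tuple[float, ...]] = None  # per subtype
    n_mutation_genes: int = 30        # disjoint from subtype signatures
    mutation_effect: float = 1.0      # log2 units
    baseline_mean: float = 6.0        # log2 baseline expression location
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2 or self.n_genes < 1 or self.n_subtypes < 1:
            raise ValueError("counts must be positive (>= 2 patients)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.subtype_proportions is None:
            self.subtype_proportions = tuple(
                [1.0 / self.n_subtypes] * self.n_subtypes)
        if len(self.subtype_proportions) != self.n_subtypes:
            raise ValueError("one proportion per subtype required")
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-8:
            raise ValueError("subtype proportions must sum to 1")
        if self.mutation_prevalence is None:
            # prevalence deliberately varies by subtype
            self.mutation_prevalence = tuple(
                0.2 + 0.6 * k / max(1, self.n_subtypes - 1)
                for k in range(self.n_subtypes))
        if len(self.mutation_prevalence) != self.n_subtypes:
            raise ValueError("one mutation prevalence per subtype required")
        needed = self.n_subtypes * self.n_signal_genes + self.n_mutation_genes
        if needed > self.n_genes:
            raise ValueError(
                f"{needed} signature genes exceed n_genes={self.n_genes}")


def generate(config: SyntheticConfig) -> Tuple[MatchedPairSet, LabelTable]:
    """Draw one matched cohort (array + RNA-seq + labels) from the model."""
    rng = np.random.default_rng(config.seed)
    G, P, K = config.n_genes, config.n_patients, config.n_subtypes

    genes = [f"G{i:05d}" for i in range(G)]
    patients = [f"P{i:04d}" for i in range(P)]

    # subtype assignment: deterministic proportions, then shuffled
    counts = np.floor(np.asarray(config.subtype_proportions) * P).astype(int)
    while counts.sum() < P:
        counts[int(np.argmax(np.asarray(config.subtype_proportions) * P
                             - counts))] += 1
    subtype_idx = np.repeat(np.arange(K), counts)
    rng.shuffle(subtype_idx)
    subtype_names = [f"S{k + 1}" for k in range(K)]

    mutation = (rng.random(P) <
                np.asarray(config.mutation_prevalence)[subtype_idx]).astype(int)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=G)
    # disjoint signature blocks: subtypes first, then mutation genes
    sig_of = [np.arange(k * config.n_signal_genes,
                        (k + 1) * config.n_signal_genes) for k in range(K)]
    mut_genes = np.arange(K * config.n_signal_genes,
                          K * config.n_signal_genes + config.n_mutation_genes)

    lam = np.tile(baseline[:, None], (1, P))
    for k in range(K):
        lam[np.ix_(sig_of[k], np.flatnonzero(subtype_idx == k))] += \
            config.effect_size
    if config.n_mutation_genes:
        lam[np.ix_(mut_genes, np.flatnonzero(mutation == 1))] += \
            config.mutation_effect

    array_values = lam + rng.normal(0.0, config.array_noise_sd, size=(G, P))

    lib = rng.uniform(*config.library_size_range, size=P)
    abundance = np.exp2(lam)
    mean_counts = lib * abundance / abundance.sum(axis=0, keepdims=True)
    size = config.nb_dispersion
    # NB(mean m, size r): p = r / (r + m)
    seq_values = rng.negative_binomial(
        size, size / (size + mean_counts)).astype(float)

    array_samples = [f"{p}.A" for p in patients]
    seq_samples = [f"{p}.R" for p in patients]
    pair = MatchedPairSet(
        array_matrix=ExpressionMatrix(genes, array_samples, array_values, ARRAY),
        rnaseq_matrix=ExpressionMatrix(genes, seq_samples, seq_values, RNASEQ),
        patient_ids=patients,
        mapping={p: (a, s) for p, a, s in
                 zip(patients, array_samples, seq_samples)})
    labels = LabelTable(
        patient_ids=patients,
        subtype={p: subtype_names[s] for p, s in zip(patients, subtype_idx)},
        mutation={"MUT1": {p: int(m) for p, m in zip(patients, mutation)}})
    return pair, labels


# ---------------------------------------------------------------------------
# tiny hand-checkable fixture
# ---------------------------------------------------------------------------

# 6 genes x 8 patients, 2 subtypes (P0-P3 = S1, P4-P7 = S2).  The array
# channel is on a small log2 scale (including negatives); the RNA-seq
# channel is counts whose maximum exceeds the array maximum by > 100x, so
# the platform mismatch is gross by construction.  Values are hard-coded so
# normalization traces can be followed by hand.
_FIXTURE_GENES = ["GA", "GB", "GC", "GD", "GE", "GF"]
_FIXTURE_PATIENTS = [f"P{i}" for i in range(8)]
_FIXTURE_ARRAY = np.array([
    [-1.0, -0.5,  0.0,  0.5,  3.0,  3.5,  4.0,  4.5],   # S2-high gene
    [ 4.0,  4.5,  5.0,  5.5,  1.0,  1.5,  2.0,  2.5],   # S1-high gene
    [ 2.0,  2.5,  1.5,  2.2,  2.1,  1.8,  2.4,  1.9],
    [ 0.0,  0.2, -0.2,  0.1,  0.3, -0.1,  0.2,  0.0],
    [ 6.0,  5.5,  6.5,  6.2,  5.8,  6.1,  6.3,  5.9],
    [ 3.0,  3.2,  2.8,  3.1,  2.9,  3.3,  3.0,  3.1],
])
_FIXTURE_RNASEQ = np.array([
    [   2.,    3.,    1.,    4.,  220.,  260.,  300.,  340.],
    [ 400.,  450.,  500.,  560.,   30.,   40.,   50.,   60.],
    [  90.,  110.,   70.,  100.,   95.,   80.,  120.,   85.],
    [   1.,    2.,    0.,    1.,    3.,    0.,    2.,    1.],
    [1500., 1200., 1800., 1600., 1300., 1550., 1700., 1400.],
    [ 200.,  230.,  180.,  210.,  190.,  240.,  205.,  215.],
])


def generate_worked_fixture() -> Tuple[MatchedPairSet, LabelTable]:
    """A versioned 6-gene x 8-patient matched cohort for hand traces."""
    array_samples = [f"{p}.A" for p in _FIXTURE_PATIENTS]
    seq_samples = [f"{p}.R" for p in _FIXTURE_PATIENTS]
    pair = MatchedPairSet(
        array_matrix=ExpressionMatrix(_FIXTURE_GENES, array_samples,
                                      _FIXTURE_ARRAY.copy(), ARRAY),
        rnaseq_matrix=ExpressionMatrix(_FIXTURE_GENES, seq_samples,
                                       _FIXTURE_RNASEQ.copy(), RNASEQ),
        patient_ids=list(_FIXTURE_PATIENTS),
        mapping={p: (a, s) for p, a, s in
                 zip(_FIXTURE_PATIENTS, array_samples, seq_samples)})
    labels = LabelTable(
        patient_ids=list(_FIXTURE_PATIENTS),
        subtype={p: ("S1" if i < 4 else "S2")
                 for i, p in enumerate(_FIXTURE_PATIENTS)},
        mutation={})
    return pair, labels
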