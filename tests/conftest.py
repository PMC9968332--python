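import numpy as np
import pytest

import xplatnorm as xp


@pytest.fixture(scope="session")
def worked_fixture():
    """Tiny hand-checkable matched cohort (6 genes x 8 patients, 2 subtypes)."""
    return xp.generate_worked_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    """A small but classifier-ready synthetic cohort (60 patients, 200 genes)."""
    cfg = xp.SyntheticConfig(n_patients=60, n_genes=200, n_subtypes=3,
                             n_signal_genes=20, n_mutation_genes=10, seed=11)
    return xp.generate(cfg)


@pytest.fixture(scope="session")
def small_plan(small_cohort):
    pair, labels = small_cohort
    return xp.make_plan(pair, labels, seed=11)


@pytest.fixture(scope="session")
def small_filtered(small_cohort, small_plan):
    pair, _ = small_cohort
    return xp.filter_degenerate_genes(
        pair, xp.rnaseq_filter_subsets(pair, small_plan))


def random_matrix(seed, n_genes=12, n_samples=7, platform="array"):
    rng = np.random.default_rng(seed)
    values = rng.normal(5, 2, size=(n_genes, n_samples))
    if platform == "rnaseq":
        values = np.abs(values) * 10
    return xp.ExpressionMatrix([f"g{i}" for i in range(n_genes)],
                               [f"s{j}" for j in range(n_samples)],
                               values, platform)
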