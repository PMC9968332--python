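"""Normalizer oracles and invariants.

Worked examples are checked against closed forms or brute-force oracles
that enumerate the definition directly; properties (rank invariance,
monotonicity, permutation equivariance) are checked on seeded random
matrices.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import xplatnorm as xp
from xplatnorm.normalize import zero_to_one_rows

from conftest import random_matrix


def em(values, platform="array"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return xp.ExpressionMatrix([f"g{i}" for i in range(values.shape[0])],
                               [f"s{j}" for j in range(values.shape[1])],
                               values, platform)


class TestLogTransforms:
    def test_log2_array_closed_forms(self):
        out = xp.log2_array(em([[0.0, -5.0]]))
        np.testing.assert_allclose(out.values[0, 0], 1.0)
        np.testing.assert_allclose(out.values[0, 1], 0.044394119358453436)

    def test_log2_array_positive_and_monotone(self):
        m = random_matrix(3)
        out = xp.log2_array(m).values
        assert (out > 0).all()
        order = np.argsort(m.values.ravel())
        assert (np.diff(out.ravel()[order]) >= 0).all()

    def test_log2_seq_values(self):
        out = xp.log2_seq(em([[0.0, 7.0, 1023.0]], "rnaseq"))
        np.testing.assert_allclose(out.values, [[0.0, 3.0, np.log2(1024.0)]])

    def test_log2_seq_rejects_negative(self):
        with pytest.raises(ValueError):
            xp.log2_seq(em([[-1.0, 2.0]], "rnaseq"))


class TestZeroToOne:
    def test_row_example(self):
        out = xp.zero_to_one(em([[2.0, 4.0, 6.0]]))
        np.testing.assert_allclose(out.values, [[0.0, 0.5, 1.0]])

    def test_constant_row_all_zero(self):
        out = xp.zero_to_one(em([[3.0, 3.0, 3.0]]))
        np.testing.assert_array_equal(out.values, [[0.0, 0.0, 0.0]])

    def test_idempotent(self):
        m = random_matrix(5)
        once = xp.zero_to_one(m)
        twice = xp.zero_to_one(once)
        np.testing.assert_allclose(once.values, twice.values)
        assert np.allclose(once.values.min(axis=1), 0)
        assert np.allclose(once.values.max(axis=1), 1)


class TestZScore:
    def test_row_example_n_minus_1(self):
        out = xp.z_score(em([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out.values, [[-1.0, 0.0, 1.0]])

    def test_constant_row_zero(self):
        out = xp.z_score(em([[4.0, 4.0, 4.0]]))
        np.testing.assert_array_equal(out.values, 0.0)

    def test_centering_and_unit_sd(self):
        m = random_matrix(7, n_genes=20, n_samples=9)
        out = xp.z_score(m).values
        assert np.abs(out.mean(axis=1)).max() < 1e-12
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0)


def qn_to_target_bruteforce(column, target):
    """Independent oracle: assign target values by rank; ties get the mean
    of the target entries at the positions the tie group occupies."""
    column = np.asarray(column, float)
    target = np.asarray(target, float)
    order = sorted(range(len(column)), key=lambda i: column[i])
    out = np.empty(len(column))
    pos = 0
    while pos < len(order):
        group = [order[pos]]
        while (pos + len(group) < len(order)
               and column[order[pos + len(group)]] == column[group[0]]):
            group.append(order[pos + len(group)])
        val = np.mean([target[pos + k] for k in range(len(group))])
        for g in group:
            out[g] = val
        pos += len(group)
    return out


class TestQuantileNormalization:
    def test_two_column_example(self):
        m = em([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]])
        out = xp.quantile_normalize_self(m).values
        np.testing.assert_allclose(out, [[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])

    def test_rank_mapping_forced(self):
        out = xp.quantile_normalize_to_target(
            em([[5.0], [1.0], [3.0]]), np.array([10.0, 20.0, 30.0]))
        np.testing.assert_allclose(out.values[:, 0], [30.0, 10.0, 20.0])

    def test_tie_rule(self):
        out = xp.quantile_normalize_to_target(
            em([[2.0], [2.0], [5.0]]), np.array([0.0, 10.0, 20.0]))
        np.testing.assert_allclose(out.values[:, 0], [5.0, 5.0, 20.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        col = rng.integers(0, 6, size=15).astype(float)  # guaranteed ties
        target = np.sort(rng.normal(size=15))
        out = xp.quantile_normalize_to_target(em(col[:, None]), target)
        np.testing.assert_allclose(out.values[:, 0],
                                   qn_to_target_bruteforce(col, target))

    def test_identical_columns_fixed_point(self):
        col = np.array([[3.0, 3.0], [1.0, 1.0], [7.0, 7.0]])
        out = xp.quantile_normalize_self(em(col)).values
        np.testing.assert_allclose(out, col)

    def test_tie_free_sorted_columns_equal_target(self):
        m = random_matrix(9, n_genes=30, n_samples=6)
        target = np.sort(np.random.default_rng(1).normal(size=30))
        out = xp.quantile_normalize_to_target(m, target).values
        for j in range(6):
            np.testing.assert_allclose(np.sort(out[:, j]), target)

    def test_multiset_conserved_for_permutation_of_target(self):
        target = np.array([1.0, 2.0, 5.0])
        out = xp.quantile_normalize_to_target(em([[5.0], [1.0], [2.0]]), target)
        assert sorted(out.values[:, 0]) == sorted(target)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            xp.quantile_normalize_to_target(em([[1.0], [2.0]]),
                                            np.array([1.0, 2.0, 3.0]))

    def test_single_gene_forced_to_row_mean(self):
        out = xp.quantile_normalize_self(em([[2.0, 4.0, 6.0]]))
        np.testing.assert_allclose(out.values, [[4.0, 4.0, 4.0]])


class TestQnZ:
    def test_composition_definition(self):
        m = random_matrix(11, n_genes=10, n_samples=5)
        target = np.sort(np.random.default_rng(2).normal(size=10))
        direct = xp.qn_z(m, target).values
        composed = xp.z_score(xp.quantile_normalize_to_target(m, target)).values
        np.testing.assert_array_equal(direct, composed)

    def test_output_rows_standardized(self):
        out = xp.qn_z(random_matrix(12, n_genes=10, n_samples=5)).values
        keep = out.std(axis=1) > 0
        assert np.abs(out[keep].mean(axis=1)).max() < 1e-12


class TestCrossNorm:
    def test_single_pair_is_per_sample_rescale(self):
        a = em([[1.0], [3.0], [2.0]])
        s = em([[100.0], [500.0], [300.0]], "rnaseq")
        a_out, s_out = xp.crossnorm_qn(a, s)
        np.testing.assert_allclose(a_out.values[:, 0], [0.0, 1.0, 0.5])
        np.testing.assert_allclose(s_out.values[:, 0], [0.0, 1.0, 0.5])

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(4)
        a = em(rng.normal(size=(2, 2)))
        s = em(np.abs(rng.normal(size=(2, 2))) * 50, "rnaseq")
        a_out, s_out = xp.crossnorm_qn(a, s)
        # independent oracle: enumerate all 4 stacks, QN by mean-of-sorted,
        # average each column's appearances
        av = zero_to_one_rows(a.values.T).T
        sv = zero_to_one_rows(s.values.T).T
        stacks = []
        for i, j in itertools.product(range(2), range(2)):
            stacks.append(np.concatenate([av[:, i], sv[:, j]]))
        stacked = np.column_stack(stacks)
        target = np.sort(stacked, axis=0).mean(axis=1)
        qn = np.column_stack([qn_to_target_bruteforce(stacked[:, k], target)
                              for k in range(4)])
        exp_a = np.zeros_like(av)
        exp_s = np.zeros_like(sv)
        for k, (i, j) in enumerate(itertools.product(range(2), range(2))):
            exp_a[:, i] += qn[:2, k] / 2
            exp_s[:, j] += qn[2:, k] / 2
        np.testing.assert_allclose(a_out.values, exp_a)
        np.testing.assert_allclose(s_out.values, exp_s)

    def test_pooled_distributions_pulled_together(self):
        # shapes comparable to pipeline inputs (both sides log-ish scale,
        # per-sample rescaled): the halves end up sharing quantiles closely
        a = random_matrix(6, n_genes=40, n_samples=5)
        s = random_matrix(7, n_genes=40, n_samples=6, platform="rnaseq")
        a_out, s_out = xp.crossnorm_qn(a, s)
        qa = np.quantile(a_out.values, [0.1, 0.25, 0.5, 0.75, 0.9])
        qs = np.quantile(s_out.values, [0.1, 0.25, 0.5, 0.75, 0.9])
        np.testing.assert_allclose(qa, qs, atol=0.1)

    def test_capped_stacking_deterministic_and_covering(self):
        a = random_matrix(8, n_genes=10, n_samples=6)
        s = random_matrix(9, n_genes=10, n_samples=7, platform="rnaseq")
        out1 = xp.crossnorm_qn(a, s, max_stack=10, seed=3)
        out2 = xp.crossnorm_qn(a, s, max_stack=10, seed=3)
        np.testing.assert_array_equal(out1[0].values, out2[0].values)
        np.testing.assert_array_equal(out1[1].values, out2[1].values)
        assert np.isfinite(out1[0].values).all()
        assert np.isfinite(out1[1].values).all()

    def test_empty_side_errors(self):
        a = random_matrix(6, n_genes=4, n_samples=3)
        s = xp.ExpressionMatrix([f"g{i}" for i in range(4)], [],
                                np.empty((4, 0)), "rnaseq")
        with pytest.raises(ValueError):
            xp.crossnorm_qn(a, s)


class TestTdm:
    def test_fit_on_0_to_100(self):
        ref = xp.tdm_fit(np.arange(101.0).reshape(1, -1))
        assert ref.q1 == 25.0 and ref.q3 == 75.0 and ref.iqr == 50.0
        assert ref.upper_factor == 0.5 and ref.lower_factor == 0.5

    def test_constant_reference_errors(self):
        with pytest.raises(ValueError):
            xp.tdm_fit(np.full((2, 3), 7.0))

    def test_normal_reference_symmetric_factors(self):
        vals = np.random.default_rng(0).normal(size=(100, 40))
        ref = xp.tdm_fit(vals)
        assert abs(ref.upper_factor - ref.lower_factor) \
            < 0.2 * max(ref.upper_factor, ref.lower_factor)

    def test_self_transform_preserves_bounds(self):
        m = random_matrix(13, n_genes=30, n_samples=8)
        ref = xp.tdm_fit(m)
        out = xp.tdm_transform(m, ref)
        np.testing.assert_allclose(out.values.min(), ref.ref_min)
        np.testing.assert_allclose(out.values.max(), ref.ref_max)

    def test_four_step_hand_trace(self):
        # target {0..100} against the reference fitted on {0..100}
        target = em(np.arange(101.0).reshape(1, -1), "rnaseq")
        ref = xp.tdm_fit(np.arange(101.0).reshape(1, -1))
        # step 1: target Q1=25, Q3=75, IQR=50 -> bounds 75+0.5*50=100,
        #         25-0.5*50=0; step 2: winsorize = identity;
        # step 3: rescale /100; step 4: *100+0 -> identity
        out = xp.tdm_transform(target, ref)
        np.testing.assert_allclose(out.values, target.values)

    def test_monotone_and_bounded(self):
        m = random_matrix(14, n_genes=25, n_samples=6, platform="rnaseq")
        ref = xp.tdm_fit(random_matrix(15, n_genes=25, n_samples=6))
        out = xp.tdm_transform(m, ref).values
        order = np.argsort(m.values.ravel())
        assert (np.diff(out.ravel()[order]) >= -1e-12).all()
        assert out.min() >= ref.ref_min - 1e-9
        assert out.max() <= ref.ref_max + 1e-9

    def test_degenerate_target_errors(self):
        ref = xp.tdm_fit(np.arange(101.0).reshape(1, -1))
        with pytest.raises(ValueError):
            xp.tdm_transform(em(np.full((2, 3), 1.0), "rnaseq"), ref)


class TestNpn:
    def test_three_distinct_values(self):
        out = xp.npn(em([[5.0, 1.0, 3.0]]))
        np.testing.assert_allclose(
            np.sort(out.values[0]),
            [-0.6744897501960817, 0.0, 0.6744897501960817], atol=1e-12)

    def test_rank_invariance_under_monotone_transform(self):
        m = random_matrix(16, n_genes=15, n_samples=9)
        out1 = xp.npn(m).values
        out2 = xp.npn(m.with_values(np.exp(m.values))).values
        np.testing.assert_allclose(out1, out2)

    def test_tie_free_rows_sum_to_zero(self):
        m = random_matrix(17, n_genes=15, n_samples=9)
        out = xp.npn(m).values
        np.testing.assert_allclose(out.sum(axis=1), 0.0, atol=1e-10)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000))
def test_normalizers_commute_with_sample_permutation(seed):
    """Permuting input columns permutes output columns identically."""
    rng = np.random.default_rng(seed)
    m = em(rng.normal(5, 2, size=(8, 6)))
    perm = rng.permutation(6)
    for fn in (xp.zero_to_one, xp.z_score, xp.npn,
               xp.quantile_normalize_self,
               lambda x: xp.tdm_transform(x, xp.tdm_fit(x))):
        out = fn(m).values
        permuted_in = xp.ExpressionMatrix(m.genes,
                                          [m.samples[j] for j in perm],
                                          m.values[:, perm], m.platform)
        out_of_permuted = fn(permuted_in).values
        np.testing.assert_allclose(out_of_permuted, out[:, perm], atol=1e-12)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000))
def test_shapes_preserved_by_every_normalizer(seed):
    rng = np.random.default_rng(seed)
    m = em(np.abs(rng.normal(5, 2, size=(7, 5))), "rnaseq")
    for fn in (xp.log2_seq, xp.zero_to_one, xp.z_score, xp.npn,
               xp.quantile_normalize_self,
               lambda x: xp.qn_z(x, None)):
        out = fn(m)
        assert out.values.shape == m.values.shape
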