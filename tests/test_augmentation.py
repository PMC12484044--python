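"""Unit and property tests for the ANAA augmentation core."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import convolve2d

from anaa.augmentation import (
    AttentionMatrix, AugmentationConfig, DegenerateInputError,
    augment_eval, augment_train, build_kernel, compute_noise_params,
    kernel_size, smooth, smooth_block,
)
from conftest import random_row_stochastic, two_point_matrix


def brute_force_convolve(M, kern, L):
    """Independent nested-sum oracle for the zero-padded kernel convolution
    over the centered offsets."""
    offs = kern.offsets
    out = np.zeros((L, L))
    for i in range(L):
        for j in range(L):
            acc = 0.0
            for a, u in enumerate(offs):
                for b, v in enumerate(offs):
                    ii, jj = i - u, j - v
                    if 0 <= ii < L and 0 <= jj < L:
                        acc += kern.weights[a, b] * M[ii, jj]
            out[i, j] = acc
    return out


class TestNoiseParams:
    def test_mu_is_inverse_length_for_row_stochastic(self, rng):
        # rows summing to 1 force total mass n, hence mean 1/n
        for n in (4, 8, 16):
            A = random_row_stochastic(n, rng)
            p = compute_noise_params(A, AugmentationConfig())
            assert p.mu == pytest.approx(1.0 / n, abs=1e-9)

    def test_identity_matrix_statistics(self):
        A = AttentionMatrix(np.eye(4), valid_len=4)
        p = compute_noise_params(A, AugmentationConfig())
        # sum of squared deviations: 4*(0.75)^2 + 12*(0.25)^2 = 3.0, /15 = 0.2
        assert p.mu == pytest.approx(0.25)
        assert p.sigma_gn == pytest.approx(math.sqrt(0.2), abs=1e-9)

    def test_as_printed_denominator(self):
        A = AttentionMatrix(np.eye(4), valid_len=4)
        cfg = AugmentationConfig(variance_denominator="as_printed")
        assert compute_noise_params(A, cfg).sigma_gn == pytest.approx(1.0)

    def test_uniform_matrix_has_zero_sigma(self):
        A = AttentionMatrix(np.full((6, 6), 1 / 6), valid_len=6)
        assert compute_noise_params(A, AugmentationConfig()).sigma_gn == 0.0

    def test_padding_excluded_from_statistics(self, rng):
        A = random_row_stochastic(10, rng, valid_len=6)
        p = compute_noise_params(A, AugmentationConfig())
        assert p.mu == pytest.approx(1 / 6, abs=1e-9)

    @pytest.mark.parametrize("L", [0, 1])
    def test_degenerate_valid_len_raises(self, L):
        A = AttentionMatrix(np.ones((2, 2)) * (L == 1), valid_len=L)
        with pytest.raises(DegenerateInputError):
            compute_noise_params(A, AugmentationConfig())

    @pytest.mark.parametrize("n", [4, 8, 16])
    @pytest.mark.parametrize("alpha_of", [lambda n: 1 / n, lambda n: 0.25,
                                          lambda n: 0.5])
    def test_two_point_law(self, n, alpha_of, rng):
        # on/off matrices: mu = alpha exactly, sigma^2 = a(1-a) m/(m-1)
        alpha = alpha_of(n)
        A = two_point_matrix(n, alpha, rng)
        p = compute_noise_params(A, AugmentationConfig())
        m = n * n
        assert p.mu == pytest.approx(alpha, abs=0)
        assert p.sigma_gn**2 == pytest.approx(alpha * (1 - alpha) * m / (m - 1),
                                              rel=1e-12)


class TestKernel:
    @pytest.mark.parametrize("sigma,k", [(1.0, 6), (0.33, 2), (0.1, 1),
                                         (0.5, 3), (1.11, 7)])
    def test_size_rule(self, sigma, k):
        assert kernel_size(sigma) == k
        assert build_kernel(sigma).size_k == k

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            build_kernel(0.0)
        with pytest.raises(ValueError):
            build_kernel(-1.0)

    def test_weights_positive_and_normalized(self):
        for sigma in (0.33, 0.5, 1.0):
            kern = build_kernel(sigma, normalized=True)
            assert (kern.weights > 0).all()
            assert kern.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_raw_weights_follow_gaussian_formula(self):
        kern = build_kernel(0.5, normalized=False)
        for a, u in enumerate(kern.offsets):
            for b, v in enumerate(kern.offsets):
                expect = math.exp(-0.5 * (u**2 + v**2) / 0.25) / (2 * math.pi * 0.25)
                assert kern.weights[a, b] == pytest.approx(expect, rel=1e-12)

    def test_odd_kernel_reflection_symmetric(self):
        kern = build_kernel(0.5)  # k = 3
        assert kern.size_k % 2 == 1
        np.testing.assert_allclose(kern.weights, kern.weights[::-1, ::-1])
        np.testing.assert_allclose(kern.weights, kern.weights.T)

    def test_single_point_kernel(self):
        kern = build_kernel(0.1, normalized=True)
        assert kern.size_k == 1
        np.testing.assert_array_equal(kern.weights, [[1.0]])

    def test_plain_text_export_round_trips(self, tmp_path):
        kern = build_kernel(1.0)
        kern.to_text(tmp_path / "kernel.txt")
        back = np.loadtxt(tmp_path / "kernel.txt")
        np.testing.assert_allclose(back, kern.weights, rtol=1e-12)


class TestSmooth:
    def test_delta_reproduces_kernel(self):
        kern = build_kernel(0.5)  # 3x3 normalized
        M = np.zeros((7, 7))
        M[3, 3] = 1.0
        out = smooth(M, kern, 7)
        np.testing.assert_allclose(out[2:5, 2:5], kern.weights, atol=1e-15)
        out[2:5, 2:5] = 0.0
        assert np.abs(out).max() == 0.0

    def test_identity_kernel(self, rng):
        M = rng.normal(size=(5, 5))
        np.testing.assert_array_equal(smooth(M, build_kernel(0.1), 5), M)

    def test_matches_brute_force_oracle(self, rng):
        worst = 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for _ in range(200):
                n = int(rng.integers(3, 13))
                sigma = float(rng.uniform(0.12, 1.11))  # k in 1..7
                kern = build_kernel(sigma, normalized=bool(rng.integers(0, 2)))
                M = rng.normal(size=(n, n))
                ref = brute_force_convolve(M, kern, n)
                worst = max(worst, np.abs(smooth(M, kern, n) - ref).max())
        assert worst < 1e-10

    def test_matches_scipy_for_odd_kernels(self, rng):
        # independent library cross-check (odd symmetric kernel, same-mode)
        kern = build_kernel(0.5)
        M = rng.normal(size=(9, 9))
        ref = convolve2d(M, kern.weights, mode="same", boundary="fill")
        np.testing.assert_allclose(smooth(M, kern, 9), ref, atol=1e-12)

    def test_constant_preserved_in_interior(self):
        kern = build_kernel(0.5)
        M = np.full((12, 12), 0.37)
        out = smooth(M, kern, 12)
        interior = out[3:-3, 3:-3]
        np.testing.assert_allclose(interior, 0.37, atol=1e-12)

    def test_low_pass_never_raises_second_differences(self, rng):
        # smoothing with a normalized kernel of size >= 3 acts as a low-pass
        # filter: max curvature along rows never increases
        for _ in range(25):
            n = int(rng.integers(6, 14))
            sigma = float(rng.uniform(0.4, 1.0))
            kern = build_kernel(sigma)
            if kern.size_k < 3:
                continue
            M = rng.normal(size=(n, n))
            out = smooth(M, kern, n)
            d2 = np.abs(np.diff(M, n=2, axis=1)).max()
            d2s = np.abs(np.diff(out, n=2, axis=1)).max()
            assert d2s <= d2 + 1e-12

    def test_padding_stays_zero(self, rng):
        M = np.zeros((10, 10))
        M[:6, :6] = rng.random((6, 6))
        out = smooth(M, build_kernel(1.0), 6)
        assert np.abs(out[6:, :]).max() == 0.0
        assert np.abs(out[:, 6:]).max() == 0.0

    def test_oversized_kernel_warns_but_runs(self, rng):
        M = rng.random((3, 3))
        with pytest.warns(RuntimeWarning, match="kernel size"):
            smooth(M, build_kernel(1.11), 3)  # k=7 > 2*3

    def test_adjoint_is_transpose_operator(self, rng):
        kern = build_kernel(1.0)
        x = rng.normal(size=(10, 10))
        y = rng.normal(size=(10, 10))
        lhs = (smooth_block(x, kern) * y).sum()
        rhs = (x * smooth_block(y, kern, adjoint=True)).sum()
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestAugmentPaths:
    def test_none_mode_is_identity(self, rng):
        A = random_row_stochastic(6, rng)
        cfg = AugmentationConfig(mode="none", training=True)
        np.testing.assert_array_equal(
            augment_train(A, cfg, np.random.default_rng(0)), A.scores)
        np.testing.assert_array_equal(
            augment_eval(A, AugmentationConfig(mode="none")), A.scores)

    def test_rna_with_zero_sigma_is_mu_shift(self):
        # uniform matrix: sigma=0, the degenerate normal collapses to mu
        A = AttentionMatrix(np.full((5, 5), 0.2), valid_len=5)
        cfg = AugmentationConfig(mode="RNA", training=True)
        out = augment_train(A, cfg, np.random.default_rng(0))
        np.testing.assert_allclose(out, 0.2 + 0.2, atol=1e-12)

    def test_anaa_train_seed_replay(self, rng):
        # an independent replay of the sampling procedure from the same seed
        # plus the convolution oracle must reproduce augment_train
        A = random_row_stochastic(7, rng)
        cfg = AugmentationConfig(mode="ANAA", sigma_eh=0.5, training=True)
        out = augment_train(A, cfg, np.random.default_rng(123))
        replay_rng = np.random.default_rng(123)
        p = compute_noise_params(A, cfg)
        G = replay_rng.normal(p.mu, p.sigma_gn, size=(7, 7))
        kern = build_kernel(0.5)
        ref = brute_force_convolve(A.scores + G, kern, 7)
        np.testing.assert_allclose(out, ref, atol=1e-10)

    def test_train_noise_redrawn_each_call(self, rng):
        A = random_row_stochastic(6, rng)
        cfg = AugmentationConfig(mode="RNA", training=True)
        stream = np.random.default_rng(5)
        assert not np.array_equal(augment_train(A, cfg, stream),
                                  augment_train(A, cfg, stream))

    def test_eval_path_deterministic(self, rng):
        A = random_row_stochastic(6, rng)
        cfg = AugmentationConfig(mode="ANAA", sigma_eh=1.0)
        np.testing.assert_array_equal(augment_eval(A, cfg),
                                      augment_eval(A, cfg))

    def test_eval_identity_kernel_reduces_to_mu_shift(self, rng):
        A = random_row_stochastic(4, rng)
        cfg = AugmentationConfig(mode="ANAA", sigma_eh=0.1)  # k = 1
        np.testing.assert_allclose(augment_eval(A, cfg), A.scores + 0.25,
                                   atol=1e-12)

    def test_eval_identity_matrix_composed_oracle(self):
        A = AttentionMatrix(np.eye(4), valid_len=4)
        cfg = AugmentationConfig(mode="ANAA", sigma_eh=0.33)
        kern = build_kernel(0.33)
        ref = brute_force_convolve(np.eye(4) + 0.25, kern, 4)
        np.testing.assert_allclose(augment_eval(A, cfg), ref, atol=1e-12)

    def test_anaa_size1_kernel_equals_rna_draws(self, rng):
        A = random_row_stochastic(5, rng)
        anaa = augment_train(A, AugmentationConfig(mode="ANAA", sigma_eh=0.1,
                                                   training=True),
                             np.random.default_rng(9))
        rna = augment_train(A, AugmentationConfig(mode="RNA", sigma_eh=0.1,
                                                  training=True),
                            np.random.default_rng(9))
        np.testing.assert_array_equal(anaa, rna)

    def test_noise_confined_to_valid_region(self, rng):
        A = random_row_stochastic(9, rng, valid_len=5)
        for cfg in (AugmentationConfig(mode="RNA", training=True),
                    AugmentationConfig(mode="ANAA", sigma_eh=1.0, training=True)):
            out = augment_train(A, cfg, np.random.default_rng(1))
            assert np.abs(out[5:, :]).max() == 0.0
            assert np.abs(out[:, 5:]).max() == 0.0


class TestAttentionMatrixInvariants:
    def test_validate_accepts_row_stochastic(self, rng):
        random_row_stochastic(8, rng, valid_len=5).validate()

    def test_validate_rejects_bad_rows(self):
        M = np.full((3, 3), 0.5)
        with pytest.raises(ValueError, match="sum to 1"):
            AttentionMatrix(M, valid_len=3).validate()

    def test_validate_rejects_dirty_padding(self, rng):
        A = random_row_stochastic(6, rng, valid_len=4)
        dirty = A.scores.copy()
        dirty[5, 5] = 1e-9
        with pytest.raises(ValueError, match="padded"):
            AttentionMatrix(dirty, valid_len=4).validate()

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            AttentionMatrix(np.zeros((3, 4)), valid_len=3)


@settings(max_examples=40, deadline=None)
@given(n=st.integers(3, 10), seed=st.integers(0, 10_000))
def test_mu_law_property(n, seed):
    """For every row-stochastic matrix, mu equals 1/valid_len."""
    A = random_row_stochastic(n, np.random.default_rng(seed))
    p = compute_noise_params(A, AugmentationConfig())
    assert abs(p.mu - 1.0 / n) < 1e-9


@settings(max_examples=25, deadline=None)
@given(sigma=st.floats(0.05, 2.0), seed=st.integers(0, 1000))
def test_normalized_kernel_mass_property(sigma, seed):
    kern = build_kernel(sigma, normalized=True)
    assert kern.size_k == max(1, round(2 * math.pi * sigma))
    assert abs(kern.weights.sum() - 1.0) < 1e-12
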