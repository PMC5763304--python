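"""Kernel constructions, PSD theory and the signed counterexample."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import array_shapes, arrays

import hksvm as hk
from hksvm.kernels import KernelSpec


def hadamard_oracle(x, y, alpha):
    """Independent per-coordinate loop: sum |x|^a |y|^a / (2(|x|^a+|y|^a))."""
    total = 0.0
    for xk, yk in zip(x, y):
        if xk == 0 or yk == 0:
            continue
        a, b = abs(xk) ** alpha, abs(yk) ** alpha
        total += a * b / (2.0 * (a + b))
    return total


class TestHadamardEntry:
    @pytest.mark.parametrize(
        "x, y, alpha, expected",
        [
            ([2], [2], 1.0, 0.5),
            ([0], [5], 1.0, 0.0),
            ([1, 2], [3, 4], 1.0, 3 / 8 + 8 / 12),
            ([1, 2], [3, 4], 2.0, 9 / 20 + 64 / 40),
        ],
    )
    def test_worked_values(self, x, y, alpha, expected):
        assert hk.hadamard_entry(x, y, alpha) == pytest.approx(expected, rel=1e-12)
        assert hadamard_oracle(x, y, alpha) == pytest.approx(expected, rel=1e-12)

    def test_symmetry_and_sign_invariance(self, rng):
        x, y = rng.normal(size=6), rng.normal(size=6)
        k = hk.hadamard_entry(x, y, 1.7)
        assert hk.hadamard_entry(y, x, 1.7) == pytest.approx(k)
        flip = np.where(rng.random(6) < 0.5, -1.0, 1.0)
        assert hk.hadamard_entry(x * flip, y * flip, 1.7) == pytest.approx(k)

    def test_negative_alpha_zero_convention(self):
        # a zero coordinate contributes 0 even when the exponent is negative
        assert hk.hadamard_entry([0.0, 2.0], [3.0, 2.0], -1.0) == pytest.approx(
            hadamard_oracle([0.0, 2.0], [3.0, 2.0], -1.0)
        )
        assert np.isfinite(hk.hadamard_entry([0.0], [1.0], -2.0))

    @pytest.mark.parametrize(
        "x, y, alpha, err",
        [
            ([1, 2], [1], 1.0, ValueError),
            ([1], [1], 0.0, ValueError),
            ([np.inf], [1], 1.0, ValueError),
            ([np.nan], [1], 1.0, ValueError),
        ],
    )
    def test_errors(self, x, y, alpha, err):
        with pytest.raises(err):
            hk.hadamard_entry(x, y, alpha)


class TestHadamardGram:
    def test_identical_and_sign_flipped_rows(self):
        same = hk.hadamard_gram(np.array([[2.0], [2.0]]), 1.0).values
        np.testing.assert_allclose(same, 0.5 * np.ones((2, 2)))
        flipped = hk.hadamard_gram(np.array([[-2.0], [2.0]]), 1.0).values
        np.testing.assert_allclose(flipped, 0.5 * np.ones((2, 2)))

    def test_small_matrix_matches_loop_oracle(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        K = hk.hadamard_gram(X, 1.0).values
        expected = np.array(
            [[hadamard_oracle(a, b, 1.0) for b in X] for a in X]
        )
        np.testing.assert_allclose(K, expected, rtol=1e-12)
        # frozen values from the defining formula (diagonal = sum |x_k|/4)
        np.testing.assert_allclose(K, [[0.75, 1.0416666666666665],
                                       [1.0416666666666665, 1.75]], rtol=1e-12)

    def test_matches_entry_on_random_data(self, signed_matrix):
        K = hk.hadamard_gram(signed_matrix, 0.5).values
        for i in (0, 3):
            for j in (1, 6):
                assert K[i, j] == pytest.approx(
                    hk.hadamard_entry(signed_matrix[i], signed_matrix[j], 0.5)
                )

    @pytest.mark.parametrize("alpha", [0.2, 0.5, 1.0, 2.0, 4.0])
    def test_psd_on_signed_data_with_zeros(self, signed_matrix, alpha):
        assert hk.is_psd(hk.hadamard_gram(signed_matrix, alpha), 1e-8)

    def test_feature_permutation_invariance(self, rng, positive_matrix):
        K = hk.hadamard_gram(positive_matrix, 1.3).values
        perm = rng.permutation(positive_matrix.shape[1])
        Kp = hk.hadamard_gram(positive_matrix[:, perm], 1.3).values
        np.testing.assert_allclose(K, Kp, rtol=1e-12)

    def test_symmetry_exact(self, signed_matrix):
        K = hk.hadamard_gram(signed_matrix, 2.5).values
        assert np.abs(K - K.T).max() == 0.0


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    X=arrays(
        np.float64,
        array_shapes(min_dims=2, max_dims=2, min_side=2, max_side=12),
        elements=st.floats(-100, 100, allow_nan=False),
    ),
    alpha=st.sampled_from([0.2, 0.5, 1.0, 2.0, 4.0]),
)
def test_hadamard_gram_always_psd(X, alpha):
    """The Hadamard kernel is PSD for every real matrix (signed, zeros, ...)."""
    assert hk.is_psd(hk.hadamard_gram(X, alpha), 1e-8)


class TestK0:
    def test_unit_rows(self):
        np.testing.assert_allclose(
            hk.k0_gram(np.array([[1.0], [1.0]])).values, 0.25 * np.ones((2, 2))
        )

    def test_equals_hadamard_alpha1_on_nonnegative(self, positive_matrix):
        np.testing.assert_allclose(
            hk.k0_gram(positive_matrix).values,
            hk.hadamard_gram(positive_matrix, 1.0).values,
            rtol=1e-12,
        )

    def test_signed_entry_by_formula(self):
        K = hk.k0_gram(np.array([[2.0], [-1.0]])).values
        assert K[0, 1] == pytest.approx((2.0 * -1.0) / (2.0 * (2.0 - 1.0)))

    def test_psd_on_nonnegative_with_zeros(self, rng):
        X = rng.uniform(0, 5, size=(10, 14))
        X[rng.random(X.shape) < 0.2] = 0.0
        assert hk.is_psd(hk.k0_gram(X), 1e-8)

    def test_cancelling_pair_raises_with_sample_names(self):
        X = hk.ExpressionMatrix(np.array([[2.0, 1.0], [-2.0, 1.0]]), ("a", "b"))
        with pytest.raises(ZeroDivisionError, match="a.*b|b.*a"):
            hk.k0_gram(X)


class TestHarmonicCounterexample:
    @pytest.mark.parametrize("n", [1, 4, 9])
    def test_printed_matrix_structure(self, n):
        """x1 = 1-vector, x2 = -(1/2)-vector gives [[n, -2n], [-2n, -n/2]]."""
        X = np.vstack([np.ones(n), -0.5 * np.ones(n)])
        K = hk.harmonic_example_gram(X).values
        np.testing.assert_allclose(K, [[n, -2 * n], [-2 * n, -n / 2]], rtol=1e-12)

    def test_quadratic_forms_show_indefiniteness(self):
        n = 4
        K = hk.harmonic_example_gram(np.vstack([np.ones(n), -0.5 * np.ones(n)])).values
        assert np.array([1, 1]) @ K @ np.array([1, 1]) == pytest.approx(-7 * n / 2)
        assert np.array([-1, 0]) @ K @ np.array([-1, 0]) == pytest.approx(n)
        assert hk.min_eigenvalue(K) < 0
        assert not hk.is_psd(K)

    def test_equals_four_times_k0(self, positive_matrix):
        np.testing.assert_allclose(
            hk.harmonic_example_gram(positive_matrix).values,
            4.0 * hk.k0_gram(positive_matrix).values,
            rtol=1e-12,
        )

    def test_harmonic_mean_of_equal_values(self):
        np.testing.assert_allclose(
            hk.harmonic_example_gram(np.array([[1.0], [1.0]])).values, np.ones((2, 2))
        )


class TestBaselineKernels:
    def test_linear_orthogonal_rows(self):
        K = hk.linear_gram(np.array([[1.0, 0.0], [0.0, 1.0]])).values
        np.testing.assert_allclose(K, np.eye(2))

    def test_quadratic_value(self):
        K = hk.polynomial_gram(np.array([[1.0], [1.0]]), degree=2).values
        assert K[0, 1] == pytest.approx(4.0)

    def test_rbf_values(self):
        K = hk.rbf_gram(np.array([[0.0], [1.0]]), sigma=1.0).values
        assert K[0, 1] == pytest.approx(np.exp(-1.0))
        np.testing.assert_allclose(np.diag(K), 1.0)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_rbf_rejects_nonpositive_sigma(self, bad):
        with pytest.raises(ValueError):
            hk.rbf_gram(np.eye(3), sigma=bad)

    def test_polynomial_rejects_degree_zero(self):
        with pytest.raises(ValueError):
            hk.polynomial_gram(np.eye(3), degree=0)

    def test_baselines_psd(self, rng):
        X = rng.normal(size=(9, 5))
        assert hk.is_psd(hk.linear_gram(X))
        assert hk.is_psd(hk.rbf_gram(X, 2.0))
        assert hk.is_psd(hk.polynomial_gram(np.abs(X), 2))


class TestCorrelationKernel:
    def test_identical_rows(self, rng):
        row = rng.normal(size=10)
        K = hk.correlation_base_gram(np.vstack([row, row])).values
        np.testing.assert_allclose(K, (1 - np.exp(-1)) * np.ones((2, 2)), rtol=1e-12)

    def test_anticorrelated_rows(self):
        K = hk.correlation_base_gram(np.array([[1.0, 2, 3], [3, 2, 1]])).values
        assert K[0, 1] == pytest.approx(1 - np.exp(1.0))
        assert K[0, 0] == pytest.approx(1 - np.exp(-1.0))

    def test_constant_row_raises_named(self):
        X = hk.ExpressionMatrix(np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]), ("flat", "ok"))
        with pytest.raises(ValueError, match="flat"):
            hk.correlation_base_gram(X)

    def test_denoised_is_psd(self, rng):
        X = rng.normal(size=(12, 20))
        assert hk.is_psd(hk.correlation_denoised_gram(X), 1e-10)


def eig_clip_oracle(K):
    """Independent denoising oracle: eigendecompose, clip, reconstruct."""
    S = (K + K.T) / 2.0
    w, V = np.linalg.eigh(S)
    return V @ np.diag(np.clip(w, 0, None)) @ V.T


class TestDenoise:
    @pytest.mark.parametrize(
        "K, expected",
        [
            ([[1.0, 2.0], [2.0, 1.0]], [[1.5, 1.5], [1.5, 1.5]]),
            (np.eye(3), np.eye(3)),
            ([[2.0, 0.0], [0.0, -3.0]], [[2.0, 0.0], [0.0, 0.0]]),
        ],
    )
    def test_worked_values(self, K, expected):
        D, clip = hk.denoise_to_psd(np.asarray(K))
        np.testing.assert_allclose(D.values, expected, atol=1e-12)
        np.testing.assert_array_equal(
            clip.eigenvalues_after, np.maximum(clip.eigenvalues_before, 0.0)
        )

    def test_matches_oracle_and_idempotent(self, rng):
        for _ in range(20):
            A = rng.normal(size=(8, 8))
            K = A + A.T
            D, _ = hk.denoise_to_psd(K)
            np.testing.assert_allclose(D.values, eig_clip_oracle(K), atol=1e-10)
            assert hk.is_psd(D, 1e-10)
            D2, _ = hk.denoise_to_psd(D)
            np.testing.assert_allclose(D2.values, D.values, atol=1e-10)

    def test_psd_input_unchanged(self, rng):
        A = rng.normal(size=(6, 4))
        K = A @ A.T
        D, _ = hk.denoise_to_psd(K)
        assert np.abs(D.values - K).max() <= 1e-10 * max(1, np.abs(K).max())

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="[Aa]symmetric"):
            hk.denoise_to_psd(np.array([[1.0, 5.0], [0.0, 1.0]]))


class TestCrossGram:
    @pytest.mark.parametrize(
        "spec",
        [
            KernelSpec("hadamard", alpha=1.5),
            KernelSpec("k0"),
            KernelSpec("linear"),
            KernelSpec("polynomial", degree=2),
            KernelSpec("rbf", sigma=3.0),
        ],
        ids=lambda s: s.family,
    )
    def test_self_consistency(self, positive_matrix, spec):
        full = hk.gram_matrix(spec, positive_matrix).values
        cross = hk.cross_gram(spec, positive_matrix, positive_matrix).values
        np.testing.assert_allclose(cross, full, rtol=1e-10)

    def test_rbf_single_test_sample(self, positive_matrix):
        test = positive_matrix[2:3]
        row = hk.cross_gram(KernelSpec("rbf", sigma=5.0), positive_matrix, test).values
        assert row.shape == (1, positive_matrix.shape[0])
        assert np.all((row > 0) & (row <= 1))
        assert row[0, 2] == pytest.approx(1.0)

    def test_correlation_slice_matches_concat_oracle(self, rng):
        train = rng.normal(size=(6, 15))
        test = rng.normal(size=(3, 15))
        sl = hk.cross_gram(KernelSpec("correlation_denoised"), train, test).values
        stacked = np.vstack([train, test])
        oracle = eig_clip_oracle(1 - np.exp(-np.corrcoef(stacked)))
        np.testing.assert_allclose(sl, oracle[6:, :6], atol=1e-10)

    def test_feature_mismatch(self, positive_matrix):
        with pytest.raises(ValueError, match="dimension"):
            hk.cross_gram(KernelSpec("linear"), positive_matrix, positive_matrix[:, :3])


class TestPSDTheoryPrimitives:
    def test_hadamard_inverse_values_and_involution(self, positive_matrix):
        A = np.array([[2.0, 4.0], [4.0, 2.0]])
        np.testing.assert_allclose(hk.hadamard_inverse(A), [[0.5, 0.25], [0.25, 0.5]])
        np.testing.assert_allclose(
            hk.hadamard_inverse(hk.hadamard_inverse(positive_matrix)), positive_matrix
        )

    def test_hadamard_inverse_zero_entry_position(self):
        with pytest.raises(ZeroDivisionError, match=r"\(1, 2\)"):
            hk.hadamard_inverse(np.array([[1.0, 0.0], [1.0, 1.0]]))

    def test_reciprocal_sum_unit(self):
        np.testing.assert_allclose(
            hk.reciprocal_sum_gram(np.array([[1.0], [1.0]])), 0.5 * np.ones((2, 2))
        )

    def test_proof_identity(self, positive_matrix):
        """K0 = (1/2) V_{X^(-1)} entrywise on positive data."""
        K0 = hk.k0_gram(positive_matrix).values
        V = hk.reciprocal_sum_gram(hk.hadamard_inverse(positive_matrix))
        np.testing.assert_allclose(K0, V / 2.0, rtol=1e-12)

    def test_columnwise_cauchy_decomposition(self, positive_matrix):
        """V_X is the sum over feature columns of PSD reciprocal terms."""
        V = hk.reciprocal_sum_gram(positive_matrix)
        terms = [hk.cauchy_gram(positive_matrix[:, r]) for r in range(positive_matrix.shape[1])]
        np.testing.assert_allclose(V, np.sum(terms, axis=0), rtol=1e-12)
        for term in terms:
            assert hk.is_psd(term, 1e-10)

    def test_cauchy_values_and_psd(self):
        V = hk.cauchy_gram(np.array([1.0, 2.0]))
        np.testing.assert_allclose(V, [[0.5, 1 / 3], [1 / 3, 0.25]])
        assert hk.min_eigenvalue(V) >= 0

    def test_reciprocal_sum_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            hk.reciprocal_sum_gram(np.array([[1.0], [-1.0]]))

    def test_min_eigenvalue_and_is_psd(self):
        assert hk.min_eigenvalue(np.eye(4)) == pytest.approx(1.0)
        assert hk.is_psd(np.eye(4))
        assert hk.min_eigenvalue(np.array([[1.0, 2.0], [2.0, 1.0]])) == pytest.approx(-1.0)
        assert not hk.is_psd(np.array([[1.0, 2.0], [2.0, 1.0]]))
        with pytest.raises(ValueError):
            hk.min_eigenvalue(np.ones((2, 3)))


class TestGramIO:
    def test_round_trip(self, tmp_path, positive_matrix):
        gram = hk.hadamard_gram(positive_matrix, 1.5)
        path = tmp_path / "gram.tsv"
        hk.write_gram(gram, path)
        back = hk.read_gram(path)
        assert back.spec == gram.spec
        assert back.sample_ids == gram.sample_ids
        np.testing.assert_allclose(back.values, gram.values, rtol=1e-14)

    def test_header_names_family_and_parameter(self, tmp_path):
        gram = hk.rbf_gram(np.eye(3), sigma=2.0)
        path = tmp_path / "g.tsv"
        hk.write_gram(gram, path)
        header = path.read_text().splitlines()[0]
        assert "family=rbf" in header and "sigma=2" in header


class TestKernelSpec:
    def test_rejects_alpha_zero(self):
        with pytest.raises(ValueError):
            KernelSpec("hadamard", alpha=0.0)

    def test_rejects_unknown_family(self):
        with pytest.raises(ValueError):
            KernelSpec("sigmoid")

    def test_irrelevant_parameters_dropped(self):
        spec = KernelSpec("linear", alpha=2.0, sigma=3.0, degree=5)
        assert spec.alpha is None and spec.sigma is None and spec.degree is None
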