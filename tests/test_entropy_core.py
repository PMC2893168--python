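import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uff.entropy_core import (
    ExpressionMatrix,
    SingularSpectrum,
    gram_eigendecomposition,
    gram_matrix,
    matrix_entropy,
    singular_spectrum,
    spectral_objective,
    svd_entropy,
)

from conftest import random_matrix


def spectrum_from_weights(weights, q=None):
    weights = np.asarray(weights, dtype=float)
    q = q or weights.size
    s = np.sqrt(np.sort(weights)[::-1])
    return SingularSpectrum(
        singular_values=s,
        weights=np.sort(weights)[::-1],
        q=q,
        norm_constant=math.log(q),
    )


class TestExpressionMatrix:
    def test_valid_construction(self):
        m = ExpressionMatrix([[1, 2], [3, 4]], ["a", "b"], ["x", "y"])
        assert m.shape == (2, 2)
        assert m.feature_ids == ("a", "b")

    @pytest.mark.parametrize(
        "values",
        [
            [[1, 2]],  # M < 2
            [[np.nan, 1], [2, 3]],
            [[np.inf, 1], [2, 3]],
            [[0, 0], [0, 0]],
        ],
    )
    def test_invalid_values(self, values):
        n = len(values[0])
        with pytest.raises(ValueError):
            ExpressionMatrix(
                values,
                [f"f{i}" for i in range(len(values))],
                [f"s{j}" for j in range(n)],
            )

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ExpressionMatrix([[1, 2], [3, 4]], ["a", "a"], ["x", "y"])

    def test_drop_feature(self):
        m = ExpressionMatrix(
            [[1, 2], [3, 4], [5, 6]], ["a", "b", "c"], ["x", "y"]
        )
        d = m.drop_feature(1)
        assert d.feature_ids == ("a", "c")
        np.testing.assert_array_equal(d.values, [[1, 2], [5, 6]])


class TestSingularSpectrum:
    def test_identity_2x2(self):
        m = ExpressionMatrix(np.eye(2), ["a", "b"], ["x", "y"])
        sp = singular_spectrum(m)
        np.testing.assert_allclose(sp.singular_values, [1, 1])
        np.testing.assert_allclose(sp.weights, [0.5, 0.5])

    def test_rank_one_outer_product(self, rng):
        u = rng.normal(size=5)
        v = rng.normal(size=4)
        m = ExpressionMatrix(
            np.outer(u, v),
            [f"f{i}" for i in range(5)],
            [f"s{j}" for j in range(4)],
        )
        sp = singular_spectrum(m)
        np.testing.assert_allclose(
            sp.weights, [1, 0, 0, 0], atol=1e-12
        )

    def test_known_weights(self):
        # singular values (sqrt(3), 1) -> weights (0.75, 0.25)
        m = ExpressionMatrix(
            np.diag([math.sqrt(3), 1.0]), ["a", "b"], ["x", "y"]
        )
        sp = singular_spectrum(m)
        np.testing.assert_allclose(sp.weights, [0.75, 0.25], atol=1e-12)

    def test_weights_sum_to_one(self, rng):
        sp = singular_spectrum(random_matrix(rng, 8, 5))
        assert sp.weights.sum() == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(
            sp.weights,
            sp.singular_values**2 / np.sum(sp.singular_values**2),
            atol=1e-10,
        )
        assert sp.q == 5
        assert sp.norm_constant == pytest.approx(math.log(5))


class TestSvdEntropy:
    def test_point_mass_is_zero(self):
        assert svd_entropy(spectrum_from_weights([1.0, 0.0])) == 0.0

    def test_uniform_is_one(self):
        for q in (2, 3, 7):
            sp = spectrum_from_weights(np.full(q, 1.0 / q))
            assert svd_entropy(sp) == pytest.approx(1.0, abs=1e-12)

    def test_binary_entropy_example(self):
        # H((0.75, 0.25)) / log 2 ~= 0.8113
        sp = spectrum_from_weights([0.75, 0.25])
        assert svd_entropy(sp) == pytest.approx(0.811278124459, abs=1e-9)

    def test_q_one_rejected(self):
        sp = SingularSpectrum(
            singular_values=np.array([2.0]),
            weights=np.array([1.0]),
            q=1,
            norm_constant=0.0,
        )
        with pytest.raises(ValueError, match="rank-bound 1"):
            svd_entropy(sp)

    def test_zero_iff_rank_one(self, rng):
        u = rng.normal(size=6)
        v = rng.normal(size=4)
        m = ExpressionMatrix(
            np.outer(u, v),
            [f"f{i}" for i in range(6)],
            [f"s{j}" for j in range(4)],
        )
        assert matrix_entropy(m) == pytest.approx(0.0, abs=1e-10)
        full = random_matrix(rng, 6, 4)
        assert matrix_entropy(full) > 0.0


class TestEntropyInvariances:
    def test_permutation_and_transpose_invariance(self, rng):
        m = random_matrix(rng, 7, 5)
        h = matrix_entropy(m)
        perm_rows = rng.permutation(7)
        perm_cols = rng.permutation(5)
        m2 = ExpressionMatrix(
            m.values[perm_rows][:, perm_cols],
            [m.feature_ids[i] for i in perm_rows],
            [m.instance_ids[j] for j in perm_cols],
        )
        assert matrix_entropy(m2) == pytest.approx(h, abs=1e-10)
        mt = ExpressionMatrix(m.values.T, m.instance_ids, m.feature_ids)
        assert matrix_entropy(mt) == pytest.approx(h, abs=1e-10)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           sign=st.sampled_from([-1.0, 1.0]),
           seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale, sign, seed):
        r = np.random.default_rng(seed)
        m = random_matrix(r, 6, 4)
        scaled = ExpressionMatrix(
            m.values * scale * sign, m.feature_ids, m.instance_ids
        )
        assert matrix_entropy(scaled) == pytest.approx(
            matrix_entropy(m), abs=1e-9
        )

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_entropy_in_unit_interval(self, seed):
        r = np.random.default_rng(seed)
        m = random_matrix(r, int(r.integers(2, 12)), int(r.integers(2, 12)))
        assert 0.0 <= matrix_entropy(m) <= 1.0


class TestGramMatrix:
    def test_identity(self):
        m = ExpressionMatrix(np.eye(2), ["a", "b"], ["x", "y"])
        np.testing.assert_allclose(gram_matrix(m), np.eye(2))

    def test_rank_one_from_single_dominant_row(self, rng):
        f = rng.normal(size=4)
        values = np.vstack([f, np.zeros(4) + 1e-30])
        # gram of a matrix with one effective row is the outer product
        c = values.T @ values
        np.testing.assert_allclose(c, np.outer(f, f), atol=1e-20)

    def test_eigenvalues_match_squared_singular_values(self, rng):
        m = random_matrix(rng, 5, 3)
        c, _ = gram_eigendecomposition(gram_matrix(m))
        s = np.linalg.svd(m.values, compute_uv=False)
        np.testing.assert_allclose(c, s**2, rtol=1e-8, atol=1e-10)

    def test_eigenvalues_match_on_larger_random(self, rng):
        for _ in range(5):
            m = random_matrix(rng, 50, 20)
            c, _ = gram_eigendecomposition(gram_matrix(m))
            s = np.linalg.svd(m.values, compute_uv=False)
            np.testing.assert_allclose(c, s**2, rtol=1e-8, atol=1e-8)


class TestGramEigendecomposition:
    def test_diagonal(self):
        c, v = gram_eigendecomposition(np.diag([4.0, 1.0]))
        np.testing.assert_allclose(c, [4.0, 1.0])
        np.testing.assert_allclose(np.abs(v), np.eye(2), atol=1e-12)

    def test_identity_matrix(self):
        c, _ = gram_eigendecomposition(np.eye(4))
        np.testing.assert_allclose(c, np.ones(4))

    def test_orthonormality_and_reconstruction(self, rng):
        a = rng.normal(size=(6, 6))
        gram = a @ a.T
        c, v = gram_eigendecomposition(gram)
        np.testing.assert_allclose(v.T @ v, np.eye(6), atol=1e-10)
        np.testing.assert_allclose(v @ np.diag(c) @ v.T, gram, atol=1e-8)
        assert np.all(np.diff(c) <= 1e-10)
        assert np.all(c >= 0)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            gram_eigendecomposition(np.array([[1.0, 2.0], [0.0, 1.0]]))


class TestSpectralObjective:
    def test_neg_sum_squares_point_mass(self):
        sp = spectrum_from_weights([1.0, 0.0])
        assert spectral_objective(sp, "neg_sum_squares") == -1.0

    @pytest.mark.parametrize("q", [2, 4, 8])
    def test_neg_sum_squares_uniform(self, q):
        sp = spectrum_from_weights(np.full(q, 1.0 / q))
        assert spectral_objective(sp, "neg_sum_squares") == pytest.approx(
            -1.0 / q
        )

    def test_geometric_mean_example(self):
        sp = spectrum_from_weights([0.75, 0.25])
        assert spectral_objective(sp, "geometric_mean") == pytest.approx(
            math.sqrt(0.75 * 0.25), abs=1e-12
        )

    def test_unknown_objective(self):
        sp = spectrum_from_weights([0.5, 0.5])
        with pytest.raises(ValueError, match="unknown objective"):
            spectral_objective(sp, "nope")

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=30, deadline=None)
    def test_objectives_extremal_at_uniform_and_point_mass(self, seed):
        r = np.random.default_rng(seed)
        q = int(r.integers(2, 8))
        w = r.dirichlet(np.ones(q))
        w = np.sort(w)[::-1]
        sp = spectrum_from_weights(w, q)
        uniform = spectrum_from_weights(np.full(q, 1.0 / q), q)
        point = spectrum_from_weights(
            np.r_[1.0, np.zeros(q - 1)], q
        )
        for obj in ("svd_entropy", "neg_sum_squares", "geometric_mean"):
            val = spectral_objective(sp, obj)
            assert val <= spectral_objective(uniform, obj) + 1e-9
            assert val >= spectral_objective(point, obj) - 1e-9
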