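"""PCE basis construction, least-squares fitting, evaluation and moments."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sonouq.pce import (
    basis_size,
    build_basis,
    design_matrix,
    evaluate_pce,
    fit_pce,
    hermite_norm,
    pce_moments,
)
from sonouq.tissuedb import SampleSet


def make_sample_set(z: np.ndarray, seed: int = 0) -> SampleSet:
    """Wrap standardized draws as a SampleSet with unit means/stds."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    u = z.shape[1]
    index = tuple((f"tissue{i}", "speed_of_sound") for i in range(u))
    return SampleSet(z.copy(), z.copy(), index, np.zeros(u), np.ones(u), seed)


class TestBasisSize:
    @pytest.mark.parametrize(
        "u, n, cross, expected",
        [
            (8, 2, False, 17),
            (16, 2, False, 33),
            (8, 2, True, 45),  # = 10!/(8!*2!) by direct factorial evaluation
            (3, 0, False, 1),
            (3, 0, True, 1),
            (1, 2, False, 3),
        ],
    )
    def test_examples(self, u, n, cross, expected):
        assert basis_size(u, n, cross) == expected

    def test_full_tensor_matches_factorial_formula(self):
        for u in (2, 5, 8):
            for n in (1, 2, 3):
                expected = math.factorial(u + n) // (
                    math.factorial(u) * math.factorial(n)
                )
                assert basis_size(u, n, True) == expected

    @settings(derandomize=True, max_examples=40)
    @given(u=st.integers(1, 20), n=st.integers(0, 4),
           cross=st.booleans())
    def test_count_always_matches_constructed_indices(self, u, n, cross):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # experimental n>2
            assert len(build_basis(u, n, cross).indices) == basis_size(u, n, cross)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            basis_size(0, 2)


class TestBasisFunctions:
    def test_u1_n2_closed_forms(self):
        basis = build_basis(1, 2)
        xi = np.array([[0.7]])
        phi = design_matrix(basis, xi)[0]
        assert phi[0] == 1.0
        assert phi[1] == pytest.approx(0.7)
        assert phi[2] == pytest.approx((0.7**2 - 1) / math.sqrt(2))

    def test_evaluation_at_zero(self):
        basis = build_basis(3, 2)
        phi = design_matrix(basis, np.zeros((1, 3)))[0]
        expected = [1.0, 0, 0, 0] + [-1 / math.sqrt(2)] * 3
        assert phi == pytest.approx(expected)

    def test_orthonormal_under_gauss_hermite_quadrature(self):
        # probabilists' weight: hermegauss nodes/weights, normalized by
        # sqrt(2*pi); 2D tensor quadrature integrates Psi_i Psi_j exactly.
        basis = build_basis(2, 2)
        x, w = np.polynomial.hermite_e.hermegauss(12)
        w = w / np.sqrt(2 * np.pi)
        xx, yy = np.meshgrid(x, x, indexing="ij")
        ww = np.outer(w, w).ravel()
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        phi = design_matrix(basis, pts)
        gram = (phi * ww[:, None]).T @ phi
        assert np.allclose(gram, np.eye(basis.M), atol=1e-10)

    def test_high_degree_hermite_normalisation(self):
        x, w = np.polynomial.hermite_e.hermegauss(30)
        w = w / np.sqrt(2 * np.pi)
        for d in (3, 5, 8):
            vals = hermite_norm(d, x)
            assert np.sum(w * vals * vals) == pytest.approx(1.0, abs=1e-9)

    def test_cross_free_indices_are_univariate(self):
        basis = build_basis(4, 2, cross_terms=False)
        for mi in basis.indices[1:]:
            assert sum(1 for d in mi if d > 0) == 1


class TestFit:
    def planted_response(self, z, coeffs, basis):
        return design_matrix(basis, z) @ coeffs

    def test_exact_recovery_in_interpolation_regime(self):
        rng = np.random.default_rng(42)
        basis = build_basis(3, 2)
        true = rng.normal(size=(basis.M, 4))
        z = rng.normal(size=(basis.M, 3))  # n_samples = M, distinct
        y = self.planted_response(z, true, basis)
        sur = fit_pce(make_sample_set(z), y, basis)
        assert np.allclose(sur.coeffs, true, rtol=1e-8, atol=1e-10)

    def test_constant_responses_give_constant_term_only(self):
        basis = build_basis(2, 2)
        z = np.random.default_rng(0).normal(size=(8, 2))
        y = np.full((8, 3), 7.5)
        sur = fit_pce(make_sample_set(z), y, basis)
        assert np.allclose(sur.coeffs[0], 7.5, atol=1e-10)
        assert np.allclose(sur.coeffs[1:], 0.0, atol=1e-9)

    def test_overdetermined_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        basis = build_basis(2, 2)
        z = rng.normal(size=(basis.M + 10, 2))
        y = rng.normal(size=(basis.M + 10, 5))
        sur = fit_pce(make_sample_set(z), y, basis)
        phi = design_matrix(basis, z)
        oracle = np.linalg.solve(phi.T @ phi, phi.T @ y)
        assert np.allclose(sur.coeffs, oracle, rtol=1e-8, atol=1e-10)

    def test_underdetermined_minimum_norm(self):
        rng = np.random.default_rng(4)
        basis = build_basis(8, 2)  # M = 17
        z = rng.normal(size=(5, 8))
        y = rng.normal(size=(5, 2))
        sur = fit_pce(make_sample_set(z), y, basis)
        # residual at training points is zero and the solution matches the
        # pseudo-inverse (minimum-norm) solve
        phi = design_matrix(basis, z)
        assert np.allclose(phi @ sur.coeffs, y, atol=1e-8)
        assert np.allclose(sur.coeffs, np.linalg.pinv(phi) @ y, atol=1e-8)

    def test_duplicated_points_warn(self):
        basis = build_basis(1, 2)
        z = np.zeros((5, 1))  # all identical
        y = np.ones((5, 1))
        with pytest.warns(UserWarning, match="rank-deficient"):
            fit_pce(make_sample_set(z), y, basis)

    def test_voxel_mask_restricts_fit(self):
        rng = np.random.default_rng(5)
        basis = build_basis(2, 2)
        z = rng.normal(size=(10, 2))
        y = rng.normal(size=(10, 4, 3))
        mask = np.zeros((4, 3), dtype=bool)
        mask[1, 1] = mask[2, 0] = True
        sur = fit_pce(make_sample_set(z), y, basis, voxel_mask=mask)
        assert sur.n_voxels == 2
        full = fit_pce(make_sample_set(z), y, basis)
        assert np.allclose(sur.coeffs[:, 0], full.coeffs[:, 1 * 3 + 1])

    def test_dimension_mismatch_rejected(self):
        basis = build_basis(3, 2)
        z = np.zeros((4, 2))
        with pytest.raises(ValueError):
            fit_pce(make_sample_set(z), np.zeros((4, 1)), basis)


class TestEvaluateAndMoments:
    def test_training_point_reproduction(self):
        rng = np.random.default_rng(6)
        basis = build_basis(3, 2)
        z = rng.normal(size=(basis.M, 3))
        y = rng.uniform(1.0, 2.0, size=(basis.M, 6))
        sur = fit_pce(make_sample_set(z), y, basis)
        pred = evaluate_pce(sur, z[4])
        assert np.allclose(pred, y[4], rtol=1e-6)

    def test_evaluation_at_zero_closed_form(self):
        rng = np.random.default_rng(7)
        basis = build_basis(2, 2)
        z = rng.normal(size=(basis.M, 2))
        y = rng.uniform(5.0, 6.0, size=(basis.M, 1))
        sur = fit_pce(make_sample_set(z), y, basis)
        deg2 = [i for i, mi in enumerate(basis.indices) if max(mi) == 2]
        expected = sur.coeffs[0, 0] - sum(
            sur.coeffs[i, 0] for i in deg2
        ) / math.sqrt(2)
        assert evaluate_pce(sur, np.zeros(2))[0] == pytest.approx(expected)

    def test_negative_predictions_clamped_with_counter(self):
        basis = build_basis(1, 1)
        sur_z = np.array([[-1.0], [1.0]])
        y = np.array([[0.0], [2.0]])  # linear: y = 1 + xi, negative at -3
        sur = fit_pce(make_sample_set(sur_z), y, basis)
        counter = []
        out = evaluate_pce(sur, np.array([[-3.0]]), clamp_counter=counter)
        assert out[0, 0] == 0.0
        assert counter == [1]

    def test_batch_evaluation_shape(self):
        basis = build_basis(2, 2)
        z = np.random.default_rng(8).normal(size=(10, 2))
        y = np.random.default_rng(9).uniform(1, 2, size=(10, 7))
        sur = fit_pce(make_sample_set(z), y, basis)
        out = evaluate_pce(sur, np.zeros((250, 2)))
        assert out.shape == (250, 7)

    def test_moments_from_known_coefficients(self):
        basis = build_basis(2, 2)
        z = np.random.default_rng(1).normal(size=(basis.M, 2))
        phi = design_matrix(basis, z)
        coeffs = np.zeros((basis.M, 1))
        coeffs[0, 0] = 5.0
        coeffs[1, 0] = 2.0
        y = phi @ coeffs
        sur = fit_pce(make_sample_set(z), y, basis)
        uq = pce_moments(sur)
        assert uq.mean.ravel()[0] == pytest.approx(5.0)
        assert uq.std.ravel()[0] == pytest.approx(2.0)

    def test_zero_nonconstant_coefficients_zero_std(self):
        basis = build_basis(2, 2)
        z = np.random.default_rng(2).normal(size=(10, 2))
        y = np.full((10, 3), 4.0)
        sur = fit_pce(make_sample_set(z), y, basis)
        assert np.allclose(pce_moments(sur).std, 0.0, atol=1e-9)

    def test_analytic_moments_match_resampling(self):
        rng = np.random.default_rng(11)
        basis = build_basis(3, 2)
        z = rng.normal(size=(30, 3))
        y = 10 + z[:, [0]] * 2 + 0.5 * z[:, [1]] ** 2 + rng.normal(
            scale=0.01, size=(30, 1)
        )
        sur = fit_pce(make_sample_set(z), y, basis)
        analytic = pce_moments(sur)
        n = 1_000_000
        draws = np.random.default_rng(12).standard_normal((n, 3))
        vals = design_matrix(basis, draws) @ sur.coeffs  # no clamping: raw
        mc_mean, mc_std = vals.mean(), vals.std(ddof=1)
        se_mean = mc_std / math.sqrt(n)
        assert abs(analytic.mean.ravel()[0] - mc_mean) < 4 * se_mean
        assert abs(analytic.std.ravel()[0] - mc_std) / mc_std < 0.01

    def test_standardize_uses_recorded_means_stds(self):
        basis = build_basis(2, 1)
        z = np.random.default_rng(13).normal(size=(5, 2))
        values = 100 + 10 * z
        index = (("a", "density"), ("b", "density"))
        samples = SampleSet(values, z, index, np.full(2, 100.0),
                            np.full(2, 10.0), 0)
        sur = fit_pce(samples, np.ones((5, 1)), basis)
        assert np.allclose(sur.standardize(values), z)
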