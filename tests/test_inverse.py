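"""Inverse-operator construction: closed forms, invariants, fixed points."""

import numpy as np
import pytest

import meginverse as mi
from meginverse.datatypes import Algorithm


def toy_leadfield(n_x=4, n_s=7, seed=0, scale=1.0):
    rng = np.random.default_rng(seed)
    return mi.Leadfield(scale * rng.standard_normal((n_x, n_s)))


class TestRegularizationFromSnr:
    def test_zero_db_definition(self):
        lf = toy_leadfield()
        noise = mi.NoiseModel(np.eye(4) * np.sum(lf.matrix**2) / 4)
        assert mi.regularization_from_snr(lf, noise, 0.0) == pytest.approx(1.0)

    def test_ten_db_is_ten_times_smaller(self):
        lf = toy_leadfield()
        noise = mi.NoiseModel.identity(4)
        assert mi.regularization_from_snr(lf, noise, 10.0) == pytest.approx(
            mi.regularization_from_snr(lf, noise, 0.0) / 10
        )

    def test_default_snr_value(self):
        lf = toy_leadfield()
        noise = mi.NoiseModel.identity(4)
        expected = np.sum(lf.matrix**2) / (4 * 10**0.25)
        assert mi.regularization_from_snr(lf, noise, 2.5) == pytest.approx(expected)

    def test_strictly_decreasing_over_sweep(self):
        lf = toy_leadfield()
        noise = mi.NoiseModel.identity(4)
        sweep = np.linspace(-10, 10, 21)
        vals = [mi.regularization_from_snr(lf, noise, s) for s in sweep]
        assert np.all(np.diff(vals) < 0)


class TestLsmnOperator:
    def test_orthonormal_square_leadfield_inverts(self):
        q, _ = np.linalg.qr(np.random.default_rng(1).standard_normal((5, 5)))
        lf = mi.Leadfield(q)
        op = mi.lsmn_operator(lf, mi.NoiseModel.identity(5), np.ones(5), 0.0)
        np.testing.assert_allclose(op.filters, q.T, atol=1e-12)
        np.testing.assert_allclose(op.filters @ q, np.eye(5), atol=1e-12)

    def test_infinite_regularization_kills_filters(self):
        lf = toy_leadfield()
        op = mi.lsmn_operator(lf, mi.NoiseModel.identity(4), np.ones(7), 1e12)
        assert np.abs(op.filters).max() < 1e-10

    def test_closed_form_small_matrix(self):
        l = np.array([[1.0, 0.0, 2.0], [0.0, 1.0, -1.0]])
        w = np.array([1.0, 2.0, 0.5])
        lam = 0.3
        c = np.eye(2)
        expected = np.diag(w) @ l.T @ np.linalg.inv(l @ np.diag(w) @ l.T + lam * c)
        op = mi.lsmn_operator(mi.Leadfield(l), mi.NoiseModel(c), w, lam)
        np.testing.assert_allclose(op.filters, expected, atol=1e-12)

    def test_lambda_zero_reproduces_pseudo_inverse(self):
        lf = toy_leadfield(4, 9, seed=3)
        op = mi.lsmn_operator(lf, mi.NoiseModel.identity(4), np.ones(9), 0.0)
        # independent SVD-based Moore-Penrose computation
        u, s, vt = np.linalg.svd(lf.matrix, full_matrices=False)
        pinv = vt.T @ np.diag(1 / s) @ u.T
        np.testing.assert_allclose(op.filters, pinv, atol=1e-10)

    def test_nonpositive_prior_rejected(self):
        lf = toy_leadfield()
        with pytest.raises(ValueError):
            mi.lsmn_operator(lf, mi.NoiseModel.identity(4), np.zeros(7), 0.1)


class TestPriorWeights:
    def test_mne_weights_all_ones(self):
        lf = toy_leadfield()
        np.testing.assert_array_equal(mi.mne_weights(lf), np.ones(7))

    def test_wmne_inverse_norm_rescaled(self):
        l = np.array([[1.0, 0.0], [0.0, 2.0]])
        w = mi.wmne_weights(mi.Leadfield(l), exponent=1.0)
        np.testing.assert_allclose(w, [4 / 3, 2 / 3])

    def test_wmne_exponent_zero_is_mne(self):
        lf = toy_leadfield()
        np.testing.assert_allclose(mi.wmne_weights(lf, exponent=0.0), mi.mne_weights(lf))

    def test_equal_norm_columns_give_identity_prior(self):
        q, _ = np.linalg.qr(np.random.default_rng(2).standard_normal((6, 6)))
        w = mi.wmne_weights(mi.Leadfield(q))
        np.testing.assert_allclose(w, np.ones(6), atol=1e-12)


class TestEloreta:
    def test_fixed_point_satisfied_at_convergence(self, small_leadfield, identity_noise):
        lam = mi.regularization_from_snr(small_leadfield, identity_noise, 2.5)
        w, iters, converged = mi.eloreta_weights(small_leadfield, identity_noise, lam, tol=1e-8)
        assert converged and iters < 100
        l = small_leadfield.matrix
        m = np.linalg.pinv((l * w) @ l.T + lam * identity_noise.covariance)
        w_check = np.einsum("ij,ij->j", l, m @ l) ** -0.5
        np.testing.assert_allclose(w, w_check, rtol=1e-6)

    def test_orthonormal_square_leadfield(self):
        q, _ = np.linalg.qr(np.random.default_rng(4).standard_normal((6, 6)))
        lf = mi.Leadfield(q)
        op = mi.eloreta_operator(lf, mi.NoiseModel.identity(6), 0.0)
        np.testing.assert_allclose(op.filters @ q, np.eye(6), atol=1e-8)

    def test_nonconvergence_warns_not_raises(self, small_leadfield, identity_noise):
        lam = mi.regularization_from_snr(small_leadfield, identity_noise, 2.5)
        with pytest.warns(RuntimeWarning):
            op = mi.eloreta_operator(small_leadfield, identity_noise, lam, tol=1e-15, max_iter=2)
        assert not op.converged


class TestSloreta:
    def test_resolution_diagonal_positive(self, small_leadfield, identity_noise):
        lam = mi.regularization_from_snr(small_leadfield, identity_noise, 2.5)
        op = mi.sloreta_operator(small_leadfield, identity_noise, lam)
        r = op.filters @ small_leadfield.matrix
        assert np.all(np.diag(r) > 0)

    def test_standardization_matches_hand_algebra(self):
        l = np.array([[1.0, 0.5, 0.0], [0.0, 1.0, 1.0]])
        lam = 0.2
        c = np.eye(2)
        phi_mne = l.T @ np.linalg.inv(l @ l.T + lam * c)
        var = np.diag(phi_mne @ (l @ l.T + lam * c) @ phi_mne.T)
        expected = phi_mne / np.sqrt(var)[:, None]
        op = mi.sloreta_operator(mi.Leadfield(l), mi.NoiseModel(c), lam)
        np.testing.assert_allclose(op.filters, expected, atol=1e-12)


class TestBeamformers:
    def test_lcmv_unit_gain_every_dipole(self, small_leadfield, small_recording):
        cov = mi.sample_covariance(small_recording)
        op = mi.lcmv_operator(small_leadfield, cov, gamma=10**-0.25)
        gains = np.einsum("ij,ji->i", op.filters, small_leadfield.matrix)
        np.testing.assert_allclose(gains, 1.0, atol=1e-8)

    def test_identity_covariance_closed_form(self):
        lf = toy_leadfield(5, 3, seed=6)
        op = mi.lcmv_operator(lf, np.eye(5), gamma=0.0)
        expected = (lf.matrix / np.sum(lf.matrix**2, axis=0)).T
        np.testing.assert_allclose(op.filters, expected, atol=1e-12)

    def test_two_source_analytic_output(self):
        # known mixing: two orthogonal unit leadfield columns, independent
        # unit-variance sources, noise-free covariance C = L L'
        l = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        cov = l @ l.T + 1e-9 * np.eye(3)
        op = mi.lcmv_operator(mi.Leadfield(l), cov, gamma=0.0)
        # with orthogonal columns the filter recovers each source exactly
        np.testing.assert_allclose(op.filters @ l, np.eye(2), atol=1e-6)

    def test_ungmv_rows_unit_norm(self, small_leadfield, small_recording):
        cov = mi.sample_covariance(small_recording)
        op = mi.ungmv_operator(small_leadfield, cov, gamma=10**-0.25)
        np.testing.assert_allclose(np.linalg.norm(op.filters, axis=1), 1.0, atol=1e-10)

    def test_ungmv_directions_match_lcmv(self, small_leadfield, small_recording):
        cov = mi.sample_covariance(small_recording)
        lcmv = mi.lcmv_operator(small_leadfield, cov, gamma=10**-0.25)
        ungmv = mi.ungmv_operator(small_leadfield, cov, gamma=10**-0.25)
        norms = np.linalg.norm(lcmv.filters, axis=1, keepdims=True)
        np.testing.assert_allclose(ungmv.filters, lcmv.filters / norms, atol=1e-12)

    def test_singular_covariance_without_loading_rejected(self):
        lf = toy_leadfield(4, 3, seed=8)
        rank1 = np.outer(np.ones(4), np.ones(4))
        with pytest.raises(np.linalg.LinAlgError):
            mi.lcmv_operator(lf, rank1, gamma=0.0)


class TestApplyInverse:
    def test_linearity(self, small_leadfield, identity_noise, small_config):
        lam = mi.regularization_from_snr(small_leadfield, identity_noise, 2.5)
        op = mi.lsmn_operator(small_leadfield, identity_noise, mi.mne_weights(small_leadfield), lam)
        rng = np.random.default_rng(9)
        x = mi.Recording(rng.standard_normal((40, 20)), fs=small_config.fs)
        y = mi.Recording(rng.standard_normal((40, 20)), fs=small_config.fs)
        combo = mi.Recording(1.5 * x.data - 0.5 * y.data, fs=small_config.fs)
        lhs = mi.apply_inverse(op, combo).data
        rhs = 1.5 * mi.apply_inverse(op, x).data - 0.5 * mi.apply_inverse(op, y).data
        np.testing.assert_allclose(lhs, rhs, atol=1e-12 * np.abs(rhs).max())

    def test_dimension_mismatch_raises(self, small_leadfield, identity_noise):
        op = mi.lsmn_operator(small_leadfield, identity_noise, mi.mne_weights(small_leadfield), 0.1)
        bad = mi.Recording(np.random.default_rng(0).standard_normal((7, 10)), fs=100.0)
        with pytest.raises(ValueError):
            mi.apply_inverse(op, bad)

    def test_normalized_units_flag(self, small_leadfield, small_recording):
        cov = mi.sample_covariance(small_recording)
        est = mi.apply_inverse(mi.ungmv_operator(small_leadfield, cov, 0.5), small_recording)
        assert est.units == "normalized"
        noise = mi.NoiseModel.identity(small_leadfield.n_sensors)
        op = mi.lsmn_operator(small_leadfield, noise, mi.mne_weights(small_leadfield), 0.1)
        assert mi.apply_inverse(op, small_recording).units == "current_density"


def test_build_operator_covers_all_six(small_leadfield, small_recording):
    cov = mi.sample_covariance(small_recording)
    for algo in mi.ALL_ALGORITHMS:
        dc = cov if algo in (Algorithm.LCMV, Algorithm.UNGMV) else None
        op = mi.build_operator(algo, small_leadfield, 2.5, data_cov=dc)
        assert op.filters.shape == (small_leadfield.n_dipoles, small_leadfield.n_sensors)
        assert np.all(np.isfinite(op.filters))
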