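"""LM Hessian, curvature spectra, participation ratios, surface projections."""

import numpy as np
import pytest

import netscape as ns
from netscape.landscape import (curvature_spectrum, finite_difference_hessian,
                                minima_landscape_summary, participation_ratio,
                                spectrum_at_minimum)


class TestResidualJacobian:
    def test_matches_finite_differences(self, suite):
        rng = np.random.default_rng(12)
        h = 1e-6
        for spec in suite[:2]:
            w = rng.uniform(-2, 2, spec.n_params)
            x = rng.uniform(-1, 1, 6)
            t = rng.uniform(0, 1, 6)
            J = ns.residual_jacobian(spec, w, (x, t))
            for j in range(spec.n_params):
                wp = w.copy(); wp[j] += h
                wm = w.copy(); wm[j] -= h
                fd = (ns.forward(spec, wp, x) - ns.forward(spec, wm, x)) / (2 * h)
                assert np.allclose(J[:, j], fd, atol=1e-6)

    def test_saturated_point_gives_near_zero_row(self, fan):
        """Where the output sigmoid saturates its derivative vanishes."""
        pv = ns.ParameterVector.zeros(fan)
        pv[("theta", 13)] = -50.0  # output pinned at 1
        J = ns.residual_jacobian(fan, pv, ([0.3], [0.0]))
        assert np.abs(J).max() < 1e-15

    def test_chain_rule_identity_with_gradient(self, fan, D_o):
        """grad E = 2 J^T r for E = sum r_i^2."""
        w = ns.initialize_weights(fan, 15).values
        J = ns.residual_jacobian(fan, w, D_o)
        r = ns.forward(fan, w, D_o.x) - D_o.t
        np.testing.assert_allclose(2 * J.T @ r, ns.error_gradient(fan, w, D_o),
                                   rtol=1e-12, atol=1e-14)


class TestLmHessian:
    def test_symmetric(self, fan, D_o):
        H = ns.lm_hessian(fan, ns.initialize_weights(fan, 2).values, D_o)
        assert np.abs(H - H.T).max() == 0.0

    def test_positive_semidefinite(self, stacked, D_o):
        H = ns.lm_hessian(stacked, ns.initialize_weights(stacked, 2).values, D_o)
        ev = np.linalg.eigvalsh(H)
        assert ev.min() >= -1e-10 * ev.max()

    def test_agrees_with_exact_hessian_at_zero_error(self, fan, D_o, fan_zero_fit):
        """With zero residuals the Gauss-Newton term is the whole Hessian."""
        H_lm = ns.lm_hessian(fan, fan_zero_fit.final_params, D_o)
        H_fd = finite_difference_hessian(fan, fan_zero_fit.final_params, D_o)
        top_lm = np.sort(np.linalg.eigvalsh(H_lm))[::-1][:5]
        top_fd = np.sort(np.linalg.eigvalsh(H_fd))[::-1][:5]
        assert np.all(np.abs(top_lm - top_fd) / top_fd < 1e-3)


class TestCurvatureSpectrum:
    def test_identity_matrix(self):
        cs = curvature_spectrum(np.eye(3))
        np.testing.assert_allclose(cs.eigenvalues, 1.0)
        assert cs.n_zero_modes == 0

    def test_rank_one_gram(self):
        u = np.array([1.0, 2.0, 0.5, -1.0, 3.0])
        cs = curvature_spectrum(np.outer(u, u))
        assert cs.eigenvalues[0] == pytest.approx(u @ u)
        assert cs.n_zero_modes == 4

    def test_zero_modes_at_fan_minimum(self, fan, D_o, fan_zero_fit):
        cs = spectrum_at_minimum(fan, fan_zero_fit.final_params, D_o)
        assert cs.n_zero_modes == fan.n_params - 6 == 31

    def test_eigenvectors_orthonormal(self, fan, D_o, fan_zero_fit):
        cs = spectrum_at_minimum(fan, fan_zero_fit.final_params, D_o)
        V = cs.eigenvectors
        np.testing.assert_allclose(V.T @ V, np.eye(fan.n_params), atol=1e-10)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            curvature_spectrum(np.array([[np.nan, 0], [0, 1.0]]))


class TestParticipationRatio:
    def test_uniform_vector_is_delocalized_bound(self):
        n = 16
        assert participation_ratio(np.full(n, 1 / np.sqrt(n))) == pytest.approx(1 / n)

    def test_basis_vector_is_localized_bound(self):
        v = np.zeros(9); v[4] = 1.0
        assert participation_ratio(v) == 1.0

    def test_half_localized(self):
        v = np.array([np.sqrt(0.5), np.sqrt(0.5), 0.0, 0.0])
        assert participation_ratio(v) == pytest.approx(0.5)

    def test_non_unit_rejected(self):
        with pytest.raises(ValueError):
            participation_ratio(np.array([1.0, 1.0]))

    def test_spectrum_ratios_within_bounds(self, fan, D_o, fan_zero_fit):
        cs = spectrum_at_minimum(fan, fan_zero_fit.final_params, D_o)
        assert np.all(cs.participation_ratios >= 1 / fan.n_params - 1e-12)
        assert np.all(cs.participation_ratios <= 1 + 1e-12)


class TestProjectErrorSurface:
    @pytest.fixture(scope="class")
    def slice_and_spectrum(self, fan, D_o, fan_zero_fit):
        cs = spectrum_at_minimum(fan, fan_zero_fit.final_params, D_o)
        sl = ns.project_error_surface(fan, fan_zero_fit.final_params, D_o,
                                      cs.eigenvectors[:, 0], cs.eigenvectors[:, 1],
                                      half_range=0.5, n_grid=10)
        return sl, cs

    def test_center_equals_sse(self, fan, D_o, fan_zero_fit, slice_and_spectrum):
        sl, _ = slice_and_spectrum
        center = sl.surface[10, 10]
        assert center == pytest.approx(
            ns.sse_error(fan, fan_zero_fit.final_params, D_o), abs=1e-15)

    def test_local_minimality_along_axes(self, slice_and_spectrum):
        sl, _ = slice_and_spectrum
        c = 10
        assert sl.surface[c - 1, c] >= sl.surface[c, c]
        assert sl.surface[c + 1, c] >= sl.surface[c, c]
        assert sl.surface[c, c - 1] >= sl.surface[c, c]

    def test_taylor_curvature_matches_eigenvalue(self, fan, D_o, fan_zero_fit):
        """E(w* + a v1) ~ E* + lambda1 a^2 / 2 for small a."""
        cs = spectrum_at_minimum(fan, fan_zero_fit.final_params, D_o)
        a = 1e-3
        v1 = cs.eigenvectors[:, 0]
        w = np.asarray(fan_zero_fit.final_params)
        E0 = ns.sse_error(fan, w, D_o)
        Ep = ns.sse_error(fan, w + a * v1, D_o)
        Em = ns.sse_error(fan, w - a * v1, D_o)
        curv = (Ep + Em - 2 * E0) / a ** 2
        assert curv == pytest.approx(cs.eigenvalues[0], rel=0.1)

    def test_axes_must_be_orthonormal(self, fan, D_o, fan_zero_fit):
        v = np.zeros(fan.n_params); v[0] = 1.0
        with pytest.raises(ValueError):
            ns.project_error_surface(fan, fan_zero_fit.final_params, D_o, v, v)


class TestMinimaSummary:
    def _fake_spectrum(self, n, lam1, lam2, p1, p2):
        cs = curvature_spectrum(np.eye(n))
        cs.eigenvalues = np.r_[lam1, lam2, np.zeros(n - 2)]
        cs.participation_ratios = np.r_[p1, p2, np.full(n - 2, 1 / n)]
        return cs

    def test_identical_minima_zero_covariance(self, fan):
        spectra = [self._fake_spectrum(fan.n_params, 3.0, 1.0, 0.2, 0.3)
                   for _ in range(4)]
        out = minima_landscape_summary([fan], [np.full(4, 0.5)], [spectra])
        cov = out["per_architecture"][fan.name]["cov_error_participation"]
        np.testing.assert_allclose(cov, 0.0, atol=1e-15)

    def test_two_points_degenerate_ellipse(self, fan):
        spectra = [self._fake_spectrum(fan.n_params, 3.0, 1.0, 0.2, 0.3),
                   self._fake_spectrum(fan.n_params, 5.0, 1.0, 0.4, 0.3)]
        out = minima_landscape_summary([fan], [np.array([0.1, 0.2])], [spectra])
        ell = out["per_architecture"][fan.name]["ellipse_error_participation"]
        assert ell["semiaxes"][1] == pytest.approx(0.0, abs=1e-12)
        # semimajor axis parallel to the difference vector (0.1, 0.2)
        d = np.array([0.1, 0.2]) / np.linalg.norm([0.1, 0.2])
        assert abs(abs(ell["axes"][:, 0] @ d) - 1.0) < 1e-10

    def test_recovers_known_bivariate_covariance(self, fan):
        rng = np.random.default_rng(0)
        true_cov = np.array([[0.04, 0.01], [0.01, 0.02]])
        n = 4000
        cloud = rng.multivariate_normal([0.5, 0.3], true_cov, size=n)
        spectra = [self._fake_spectrum(fan.n_params, 1.0, 0.5, p1, 0.3)
                   for p1 in cloud[:, 1]]
        out = minima_landscape_summary([fan], [np.abs(cloud[:, 0])], [spectra])
        # E was folded through abs(); check only the p1 variance entry
        cov = out["per_architecture"][fan.name]["cov_error_participation"]
        se = true_cov[1, 1] * np.sqrt(2 / (n - 1))
        assert abs(cov[1, 1] - true_cov[1, 1]) < 3 * se

    def test_single_minimum_rejected(self, fan):
        with pytest.raises(ValueError):
            minima_landscape_summary([fan], [np.array([0.1])],
                                     [[self._fake_spectrum(fan.n_params,
                                                           1, 1, 0.1, 0.1)]])
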