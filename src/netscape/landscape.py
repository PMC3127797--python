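"""Error-landscape curvature at training minima.

At a minimum w* of the batch SSE E(w) = sum_i r_i(w)^2, the Gauss-Newton
(Levenberg-Marquardt) Hessian H = 2 J^T J -- with J the residual Jacobian --
approximates the exact Hessian, is exact when the fit is perfect (all
residuals zero), and has exactly N_w - P zero eigenvalues when J has full row
rank: the landscape is flat in every direction the P data points do not
constrain.  Diagonalizing H yields stiff (large-eigenvalue) and sloppy
(small-eigenvalue) directions; the participation ratio of an eigenvector
measures how many individual network weights it engages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .arch import ArchitectureSpec
from .cgtrain import _param_values, _points_arrays, error_gradient, sse_error
from .network import compiled_graph

__all__ = ["CurvatureSpectrum", "LandscapeSlice", "residual_jacobian",
           "lm_hessian", "curvature_spectrum", "participation_ratio",
           "project_error_surface", "minima_landscape_summary",
           "spectrum_at_minimum", "finite_difference_hessian"]


@dataclass
class CurvatureSpectrum:
    """Eigen-structure of the LM Hessian at one minimum.

    Eigenvalues sorted descending; ``eigenvectors[:, k]`` belongs to
    ``eigenvalues[k]`` and each component maps to a specific network weight
    through the parameter vector's index map.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    participation_ratios: np.ndarray
    n_zero_modes: int
    at_params: np.ndarray
    at_error: float


@dataclass
class LandscapeSlice:
    """Error surface on the plane spanned by two eigenvector directions."""

    axis1: np.ndarray
    axis2: np.ndarray
    coeffs1: np.ndarray
    coeffs2: np.ndarray
    surface: np.ndarray  # surface[i, j] = E(w* + coeffs1[i] v1 + coeffs2[j] v2)

    def to_frame(self) -> pd.DataFrame:
        a, b = np.meshgrid(self.coeffs1, self.coeffs2, indexing="ij")
        return pd.DataFrame({"a": a.ravel(), "b": b.ravel(),
                             "E": self.surface.ravel()})


def residual_jacobian(spec: ArchitectureSpec, params, points) -> np.ndarray:
    """P x N_w matrix; row i is the parameter gradient of r_i = y(x_i) - t_i."""
    x, _ = _points_arrays(points)
    g = compiled_graph(spec)
    return _kernels.jacobian_kernel(_param_values(spec, params), x, *g.args())


def lm_hessian(spec: ArchitectureSpec, params, points) -> np.ndarray:
    """Gauss-Newton Hessian 2 J^T J of the batch SSE (symmetric PSD)."""
    J = residual_jacobian(spec, params, points)
    return 2.0 * (J.T @ J)


def curvature_spectrum(H: np.ndarray, n_params: int | None = None,
                       n_points: int | None = None,
                       zero_tol_rel: float = 1e-10,
                       at_params=None, at_error: float = np.nan
                       ) -> CurvatureSpectrum:
    """Full symmetric eigendecomposition of a Hessian, sorted descending,
    with per-eigenvector participation ratios and the count of numerically
    zero modes (eigenvalues below ``zero_tol_rel`` times the largest)."""
    H = np.asarray(H, dtype=float)
    if not np.all(np.isfinite(H)):
        raise ValueError("Hessian contains non-finite entries")
    if n_params is not None and H.shape != (n_params, n_params):
        raise ValueError(f"expected a {n_params}x{n_params} Hessian")
    evals, evecs = np.linalg.eigh(H)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    lam_max = max(evals[0], 0.0)
    n_zero = int(np.sum(evals < zero_tol_rel * lam_max)) if lam_max > 0 else H.shape[0]
    prs = np.array([participation_ratio(evecs[:, k]) for k in range(evecs.shape[1])])
    return CurvatureSpectrum(
        eigenvalues=evals, eigenvectors=evecs, participation_ratios=prs,
        n_zero_modes=n_zero,
        at_params=None if at_params is None else np.asarray(at_params, float),
        at_error=at_error)


def participation_ratio(v: np.ndarray, tol: float = 1e-8) -> float:
    """Localization of a unit vector: sum_j v_j^4, ranging from 1/N (fully
    delocalized, all components equal weight) to 1 (a single component
    carries unit weight)."""
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if abs(norm - 1.0) > tol:
        raise ValueError(f"participation ratio requires a unit vector (|v|={norm})")
    return float(np.sum(v ** 4))


def project_error_surface(spec: ArchitectureSpec, center_params, points,
                          v1: np.ndarray, v2: np.ndarray,
                          half_range: float = 1.0, n_grid: int = 60
                          ) -> LandscapeSlice:
    """Evaluate E on the (2 n_grid + 1)^2 lattice w* + a v1 + b v2 with
    a, b in [-half_range, half_range]; v1, v2 must be orthonormal."""
    v1 = np.asarray(v1, float)
    v2 = np.asarray(v2, float)
    for v in (v1, v2):
        if abs(np.linalg.norm(v) - 1.0) > 1e-8:
            raise ValueError("projection axes must be unit vectors")
    if abs(v1 @ v2) > 1e-8:
        raise ValueError("projection axes must be orthogonal")
    w = _param_values(spec, center_params)
    coeffs = np.linspace(-half_range, half_range, 2 * n_grid + 1)
    x, t = _points_arrays(points)
    g = compiled_graph(spec)
    surface = np.empty((coeffs.size, coeffs.size))
    for i, a in enumerate(coeffs):
        base = w + a * v1
        for j, b in enumerate(coeffs):
            surface[i, j] = _kernels.sse_kernel(base + b * v2, x, t, *g.args())
    return LandscapeSlice(axis1=v1, axis2=v2, coeffs1=coeffs.copy(),
                          coeffs2=coeffs.copy(), surface=surface)


def _cov_ellipse(cov: np.ndarray) -> dict:
    """Eigen-structure of a 2x2 covariance: semi-axes and orientation."""
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    return {"semiaxes": np.sqrt(evals), "axes": evecs,
            "angle_deg": float(np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0])))}


def minima_landscape_summary(specs, error_ensembles, spectra) -> dict:
    """Tabulate (E_o_star, lambda_1, lambda_2, p_1, p_2) per minimum and the
    per-architecture means and 2x2 covariance ellipses of (E, p1) and
    (lambda1, p1).

    Parameters are parallel sequences: one spec, one error vector and one
    list of CurvatureSpectrum per architecture.
    """
    rows = []
    per_arch = {}
    for spec, errors, specs_k in zip(specs, error_ensembles, spectra):
        errors = np.asarray(errors, float)
        if len(specs_k) != errors.size:
            raise ValueError("one spectrum per ensemble minimum required")
        if errors.size < 2:
            raise ValueError("need at least 2 minima per architecture for covariance")
        lam1 = np.array([s.eigenvalues[0] for s in specs_k])
        lam2 = np.array([s.eigenvalues[1] for s in specs_k])
        p1 = np.array([s.participation_ratios[0] for s in specs_k])
        p2 = np.array([s.participation_ratios[1] for s in specs_k])
        for i in range(errors.size):
            rows.append({"architecture": spec.name, "minimum": i,
                         "E_o_star": errors[i], "lambda1": lam1[i],
                         "lambda2": lam2[i], "p1": p1[i], "p2": p2[i]})
        cov_Ep = np.cov(np.vstack([errors, p1]))
        cov_lp = np.cov(np.vstack([lam1, p1]))
        per_arch[spec.name] = {
            "serialization": spec.serialization,
            "means": {"E_o_star": errors.mean(), "lambda1": lam1.mean(),
                      "lambda2": lam2.mean(), "p1": p1.mean(), "p2": p2.mean()},
            "cov_error_participation": cov_Ep,
            "cov_eigenvalue_participation": cov_lp,
            "ellipse_error_participation": _cov_ellipse(cov_Ep),
            "ellipse_eigenvalue_participation": _cov_ellipse(cov_lp),
        }
    return {"table": pd.DataFrame(rows), "per_architecture": per_arch}


def spectrum_at_minimum(spec: ArchitectureSpec, params, points,
                        zero_tol_rel: float = 1e-10) -> CurvatureSpectrum:
    """Convenience: LM Hessian spectrum of a network at a parameter vector.

    The LM Hessian of a P-point fit has N_w - P zero modes whenever the
    residual Jacobian has full row rank (generic position); at saturated
    minima the rank can drop and extra zero modes appear -- such departures
    are logged, not hidden.
    """
    H = lm_hessian(spec, params, points)
    x, _ = _points_arrays(points)
    cs = curvature_spectrum(H, spec.n_params, zero_tol_rel=zero_tol_rel,
                            at_params=_param_values(spec, params),
                            at_error=sse_error(spec, params, points))
    expected = spec.n_params - x.size
    if cs.n_zero_modes != expected:
        logging.getLogger("netscape").warning(
            "non-generic minimum of %s (E=%.3g): %d zero modes, expected "
            "N_w - P = %d", spec.name, cs.at_error, cs.n_zero_modes, expected)
    return cs


def finite_difference_hessian(spec: ArchitectureSpec, params, points,
                              step: float = 1e-5) -> np.ndarray:
    """Exact-Hessian oracle: central finite differences of the analytic
    gradient, symmetrized.  Test/validation use only."""
    w = _param_values(spec, params).copy()
    n = w.size
    H = np.empty((n, n))
    for i in range(n):
        w[i] += step
        gp = error_gradient(spec, w, points)
        w[i] -= 2 * step
        gm = error_gradient(spec, w, points)
        w[i] += step
        H[i] = (gp - gm) / (2 * step)
    return 0.5 * (H + H.T)
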