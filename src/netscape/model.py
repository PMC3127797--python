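"""Model/results interface for fitting a sigmoid network to points.

``SigmoidNetModel`` pairs an architecture with a training point set;
``fit()`` runs Polak-Ribière conjugate-gradient descent on the batch SSE and
returns a ``SigmoidNetFit`` results object carrying the fitted parameters,
the training trace, curvature diagnostics and a text ``summary()``.
"""

from __future__ import annotations

import numpy as np

from .arch import ArchitectureSpec, ParameterVector, build_architecture
from .cgtrain import OptimizerConfig, train_network
from .landscape import CurvatureSpectrum, project_error_surface, spectrum_at_minimum
from .network import NetworkFunction, evaluate_on_grid
from .protocol import initialize_weights
from .taskdata import PointSet

__all__ = ["SigmoidNetModel", "SigmoidNetFit"]


class SigmoidNetModel:
    """A feedforward sigmoid network to be fitted to (x, t) points.

    Parameters
    ----------
    x, t : array-like
        Training inputs and targets.
    spec : ArchitectureSpec, optional
        Wiring diagram; alternatively pass ``layers``/``nodes_per_layer``/
        ``wiring`` to build one.

    Examples
    --------
    >>> from netscape import SigmoidNetModel, generate_original_points
    >>> pts = generate_original_points()
    >>> fit = SigmoidNetModel.from_pointset(pts, layers=1,
    ...                                     nodes_per_layer=12).fit(seed=0)
    >>> fit.sse < 1e-6
    True
    """

    def __init__(self, x, t, spec: ArchitectureSpec | None = None, *,
                 layers: int = 1, nodes_per_layer: int = 12,
                 wiring: str = "full-adjacent"):
        self.x = np.asarray(x, dtype=float)
        self.t = np.asarray(t, dtype=float)
        if self.x.shape != self.t.shape or self.x.ndim != 1 or self.x.size == 0:
            raise ValueError("x and t must be non-empty 1-D arrays of equal length")
        self.spec = spec or build_architecture(layers, nodes_per_layer, wiring)

    @classmethod
    def from_pointset(cls, points: PointSet, spec: ArchitectureSpec | None = None,
                      **kwargs) -> "SigmoidNetModel":
        return cls(points.x, points.t, spec=spec, **kwargs)

    @property
    def nobs(self) -> int:
        return self.x.size

    def fit(self, start_params=None, seed: int | None = None,
            half_width: float = 1.0,
            config: OptimizerConfig | None = None) -> "SigmoidNetFit":
        """Minimize the batch SSE; random uniform start unless given."""
        if start_params is None:
            start_params = initialize_weights(self.spec, 0 if seed is None else seed,
                                              half_width)
        trace = train_network(self.spec, start_params, (self.x, self.t),
                              config or OptimizerConfig())
        return SigmoidNetFit(self, trace)


class SigmoidNetFit:
    """Results of one training run: estimates, diagnostics, summaries."""

    def __init__(self, model: SigmoidNetModel, trace):
        self.model = model
        self.trace = trace
        self.params = ParameterVector(model.spec, trace.final_params)
        self.network = NetworkFunction(model.spec, self.params)

    # ------------------------------------------------------------- quantities
    @property
    def sse(self) -> float:
        return self.trace.final_error

    @property
    def resid(self) -> np.ndarray:
        return self.predict(self.model.x) - self.model.t

    def predict(self, x) -> np.ndarray:
        return evaluate_on_grid(self.network, np.atleast_1d(x))

    def curvature(self, zero_tol_rel: float = 1e-10) -> CurvatureSpectrum:
        """LM-Hessian spectrum at the fitted parameters."""
        return spectrum_at_minimum(self.model.spec, self.params.values,
                                   (self.model.x, self.model.t),
                                   zero_tol_rel=zero_tol_rel)

    def landscape_slice(self, half_range: float = 1.0, n_grid: int = 60):
        """Error surface on the plane of the two stiffest eigen-directions."""
        spec = self.curvature()
        return project_error_surface(self.model.spec, self.params.values,
                                     (self.model.x, self.model.t),
                                     spec.eigenvectors[:, 0],
                                     spec.eigenvectors[:, 1],
                                     half_range=half_range, n_grid=n_grid)

    # ---------------------------------------------------------------- reports
    def summary(self) -> str:
        spec = self.model.spec
        cs = self.curvature()
        lines = [
            "Sigmoid network fit (Polak-Ribière CG)",
            "=" * 46,
            f"architecture:      {spec.name} ({spec.n_layers} layers x "
            f"{len(spec.hidden_layout[0])} nodes)",
            f"serialization L/N: {spec.serialization:.4g}",
            f"parameters N_w:    {spec.n_params} "
            f"({spec.n_connections} weights + {spec.n_hidden + 1} thresholds)",
            f"observations:      {self.model.nobs}",
            f"iterations:        {self.trace.n_iterations} "
            f"(stop: {self.trace.stop_reason})",
            f"final SSE:         {self.sse:.6g}",
            f"stiffest eigenvalues: {cs.eigenvalues[0]:.4g}, {cs.eigenvalues[1]:.4g}",
            f"participation p1, p2: {cs.participation_ratios[0]:.4g}, "
            f"{cs.participation_ratios[1]:.4g}",
            f"zero modes:        {cs.n_zero_modes} "
            f"(N_w - P = {spec.n_params - self.model.nobs})",
        ]
        return "\n".join(lines)

    def plot_fit(self, ax=None, grid_size: int = 201):
        """Fitted curve with the training points."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lo, hi = float(self.model.x.min()), float(self.model.x.max())
        grid = np.linspace(lo, hi, grid_size)
        ax.plot(grid, self.predict(grid), label="network function")
        ax.plot(self.model.x, self.model.t, "o", label="training points")
        ax.set_xlabel("x")
        ax.set_ylabel("y")
        ax.legend()
        return ax

    def plot_landscape(self, ax=None, half_range: float = 1.0, n_grid: int = 30):
        """Contour plot of the error surface along the two stiffest directions."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sl = self.landscape_slice(half_range=half_range, n_grid=n_grid)
        A, B = np.meshgrid(sl.coeffs1, sl.coeffs2, indexing="ij")
        c = ax.contourf(A, B, sl.surface, levels=30)
        ax.figure.colorbar(c, ax=ax, label="E")
        ax.set_xlabel("along stiffest eigenvector")
        ax.set_ylabel("along second-stiffest eigenvector")
        return ax
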