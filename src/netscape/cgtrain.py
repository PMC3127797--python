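"""Batch sum-of-squared-error objective and Polak-Ribière conjugate-gradient
minimization with an adaptive bracketing/parabolic line search.

The optimizer is generic: it accepts any (objective, gradient) pair over a
flat parameter vector.  ``sse_error`` / ``error_gradient`` supply the network
training objective E = sum_i (y(x_i) - t_i)^2, accumulated over the whole
batch of presented points, with the gradient computed by exact reverse-mode
backpropagation through the wiring graph.

Training stops at the iteration cap, when the error plateaus (change over a
trailing window below tolerance -- "unlimited" training in practice ends
here), or when no descent direction remains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .arch import ArchitectureSpec, ParameterVector
from .network import compiled_graph

__all__ = ["OptimizerConfig", "TrainingTrace", "LineSearchResult", "sse_error",
           "error_gradient", "line_search", "minimize_pr_cg", "train_network"]


@dataclass
class OptimizerConfig:
    """Tunables of the conjugate-gradient run.

    ``max_iterations`` caps the run (50 000 stands in for "unlimited" time;
    a limited-time session uses e.g. 500).  The plateau stop fires when the
    error decrease over the trailing ``plateau_window`` iterations falls
    below ``plateau_delta``; it can never fire before the window has elapsed.
    ``restart_period`` of None restarts the CG direction every N_w iterations.
    """

    max_iterations: int = 50_000
    plateau_window: int = 1000
    plateau_delta: float = 1e-8
    line_search_tol: float = 1e-4
    restart_period: int | None = None

    def __post_init__(self):
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")
        if self.plateau_window < 1:
            raise ValueError("plateau_window must be >= 1")
        if self.plateau_delta <= 0 or self.line_search_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.restart_period is not None and self.restart_period < 1:
            raise ValueError("restart_period must be >= 1")


@dataclass
class TrainingTrace:
    """Record of one minimization run.

    ``error_history[k]`` is the error after k accepted iterations (entry 0 is
    the starting error), hence non-increasing; ``final_error`` equals its last
    entry.
    """

    error_history: np.ndarray
    n_iterations: int
    stop_reason: str  # max_iterations | plateau | gradient_zero
    final_params: np.ndarray
    final_error: float
    n_evals: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"iteration": np.arange(len(self.error_history)),
                             "error": self.error_history})


# ------------------------------------------------------------------ objective

def _points_arrays(points):
    """Accept a PointSet or (x, t) arrays."""
    if hasattr(points, "x") and hasattr(points, "t"):
        return np.asarray(points.x, float), np.asarray(points.t, float)
    x, t = points
    return np.asarray(x, float), np.asarray(t, float)


def _param_values(spec, params):
    if isinstance(params, ParameterVector):
        return params.values
    v = np.asarray(params, float)
    if v.shape != (spec.n_params,):
        raise ValueError(f"expected {spec.n_params} parameters, got {v.shape}")
    return v


def sse_error(spec: ArchitectureSpec, params, points) -> float:
    """Batch sum of squared errors of the network over the point set."""
    x, t = _points_arrays(points)
    if x.size == 0:
        raise ValueError("point set is empty")
    g = compiled_graph(spec)
    return float(_kernels.sse_kernel(_param_values(spec, params), x, t, *g.args()))


def error_gradient(spec: ArchitectureSpec, params, points) -> np.ndarray:
    """Exact gradient of the batch SSE with respect to all N_w parameters."""
    x, t = _points_arrays(points)
    if x.size == 0:
        raise ValueError("point set is empty")
    g = compiled_graph(spec)
    _, grad = _kernels.sse_grad_kernel(_param_values(spec, params), x, t, *g.args())
    return grad


# ---------------------------------------------------------------- line search

@dataclass
class LineSearchResult:
    step: float
    f_step: float
    n_evals: int
    success: bool


def line_search(objective, slope: float, tol: float = 1e-4,
                initial_step: float = 1.0, max_halvings: int = 60,
                max_doublings: int = 60, max_refine: int = 30) -> LineSearchResult:
    """Adaptive 1-D minimization along a descent ray.

    Brackets a minimum by geometric step expansion/contraction from
    ``initial_step`` and refines it by parabolic interpolation (bisection
    fallback) until the bracket shrinks below ``tol`` relative to the step.
    Guarantees ``objective(step) <= objective(0)``; returns step 0 with
    ``success=False`` when no decrease is found, signalling a restart.
    """
    if not slope < 0:
        raise ValueError("line_search requires a descent direction (slope < 0)")
    f0 = objective(0.0)
    n_evals = 1
    s = float(initial_step)
    fs = objective(s)
    n_evals += 1
    if not fs < f0:
        # contract toward 0 until we dip below f0
        for _ in range(max_halvings):
            s *= 0.5
            fs = objective(s)
            n_evals += 1
            if fs < f0:
                break
        else:
            return LineSearchResult(0.0, f0, n_evals, False)
        lo, flo, mid, fmid = 0.0, f0, s, fs
        hi, fhi = 2 * s, objective(2 * s)
        n_evals += 1
    else:
        # expand until the objective turns upward
        lo, flo, mid, fmid = 0.0, f0, s, fs
        hi, fhi = 2 * s, objective(2 * s)
        n_evals += 1
        for _ in range(max_doublings):
            if fhi >= fmid:
                break
            lo, flo, mid, fmid = mid, fmid, hi, fhi
            hi = 2 * hi
            fhi = objective(hi)
            n_evals += 1
    # parabolic refinement on the bracket lo < mid < hi with fmid <= flo, fhi
    for _ in range(max_refine):
        if hi - lo <= tol * max(mid, 1e-300):
            break
        denom = (mid - lo) * (fmid - fhi) - (mid - hi) * (fmid - flo)
        if denom != 0.0:
            cand = mid - 0.5 * ((mid - lo) ** 2 * (fmid - fhi)
                                - (mid - hi) ** 2 * (fmid - flo)) / denom
        else:
            cand = mid
        if not (lo < cand < hi) or abs(cand - mid) < 1e-15 * max(1.0, mid):
            # bisect the larger half
            cand = 0.5 * (mid + (hi if hi - mid > mid - lo else lo))
        if cand == mid:
            break
        fc = objective(cand)
        n_evals += 1
        if fc < fmid:
            if cand < mid:
                hi, fhi = mid, fmid
            else:
                lo, flo = mid, fmid
            mid, fmid = cand, fc
        else:
            if cand < mid:
                lo, flo = cand, fc
            else:
                hi, fhi = cand, fc
    if fmid < f0:
        return LineSearchResult(mid, fmid, n_evals, True)
    return LineSearchResult(0.0, f0, n_evals, False)


# ------------------------------------------------------------------ optimizer

def minimize_pr_cg(objective, gradient, x0, config: OptimizerConfig | None = None
                   ) -> TrainingTrace:
    """Polak-Ribière conjugate-gradient descent with adaptive line search.

    ``d_k = -g_k + beta_k d_{k-1}`` with
    ``beta_k = g_k . (g_k - g_{k-1}) / (g_{k-1} . g_{k-1})``, reset to 0 when
    negative (PR+ safeguard) and every ``restart_period`` iterations.
    """
    cfg = config or OptimizerConfig()
    x = np.asarray(x0, dtype=float).copy()
    n = x.size
    restart_every = cfg.restart_period or n
    f = float(objective(x))
    if not np.isfinite(f):
        raise FloatingPointError("objective is not finite at the starting point")
    history = [f]
    n_evals = 1
    stop = "max_iterations"
    g = None
    d = None
    prev_step = 1.0
    k = 0
    while k < cfg.max_iterations:
        if g is None:
            g = np.asarray(gradient(x), dtype=float)
            if not np.all(np.isfinite(g)):
                raise FloatingPointError(f"non-finite gradient at iteration {k}")
        gnorm2 = float(g @ g)
        if gnorm2 == 0.0:
            stop = "gradient_zero"
            break
        if d is None or k % restart_every == 0:
            d = -g
        slope = float(g @ d)
        if slope >= 0:  # stale direction: steepest-descent restart
            d = -g
            slope = -gnorm2

        def phi(s, _x=x, _d=d):
            return float(objective(_x + s * _d))

        ls = line_search(phi, slope, tol=cfg.line_search_tol,
                         initial_step=prev_step)
        n_evals += ls.n_evals
        if not ls.success and not np.array_equal(d, -g):
            d = -g

            def phi(s, _x=x, _d=d):
                return float(objective(_x + s * _d))

            ls = line_search(phi, -gnorm2, tol=cfg.line_search_tol,
                             initial_step=prev_step)
            n_evals += ls.n_evals
        if not ls.success:
            # numerically stationary: no decrease even along steepest descent
            stop = "gradient_zero"
            break
        prev_step = ls.step
        x = x + ls.step * d
        f_new = ls.f_step
        if not np.isfinite(f_new):
            raise FloatingPointError(f"non-finite objective at iteration {k}")
        g_new = np.asarray(gradient(x), dtype=float)
        if not np.all(np.isfinite(g_new)):
            raise FloatingPointError(f"non-finite gradient at iteration {k + 1}")
        beta = float(g_new @ (g_new - g)) / gnorm2
        if beta < 0:
            beta = 0.0
        d = -g_new + beta * d
        g = g_new
        history.append(f_new)
        f = f_new
        k += 1
        if k >= cfg.plateau_window:
            if history[k - cfg.plateau_window] - history[k] < cfg.plateau_delta:
                stop = "plateau"
                break
    history = np.asarray(history)
    return TrainingTrace(error_history=history, n_iterations=k, stop_reason=stop,
                         final_params=x, final_error=float(history[-1]),
                         n_evals=n_evals)


def train_network(spec: ArchitectureSpec, params0, points,
                  config: OptimizerConfig | None = None) -> TrainingTrace:
    """Minimize the batch SSE of a network on a point set from ``params0``."""
    x, t = _points_arrays(points)
    g = compiled_graph(spec)
    args = g.args()

    def objective(w):
        return _kernels.sse_kernel(w, x, t, *args)

    def gradient(w):
        return _kernels.sse_grad_kernel(w, x, t, *args)[1]

    return minimize_pr_cg(objective, gradient, _param_values(spec, params0), config)
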