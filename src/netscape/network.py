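"""Network function evaluation: sigmoid nodes over a wiring graph.

Each node emits ``sigmoid(sum_j w_j s_j - theta)``; the threshold is folded
into the flat parameter vector as a weight on a constant bias input of -1, so
the whole network is a point in an N_w-dimensional weight space.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import expit

from . import _kernels
from .arch import ArchitectureSpec, ParameterVector

__all__ = ["sigmoid", "NetworkFunction", "forward", "evaluate_on_grid",
           "compiled_graph", "forward_reference"]

#: default scalar input interval
INPUT_INTERVAL = (-1.0, 1.0)
#: open output interval of the logistic transfer function
OUTPUT_INTERVAL = (0.0, 1.0)


def sigmoid(u):
    """Logistic transfer function 1/(1+exp(-u)), saturating gracefully."""
    return expit(u)


@dataclass(frozen=True)
class _Graph:
    """CSR arrays consumed by the evaluation kernels."""
    edge_src: np.ndarray
    edge_widx: np.ndarray
    indptr: np.ndarray
    theta_idx: np.ndarray

    def args(self):
        return self.edge_src, self.edge_widx, self.indptr, self.theta_idx


@lru_cache(maxsize=64)
def compiled_graph(spec: ArchitectureSpec) -> _Graph:
    """Flatten a spec's wiring into kernel-ready arrays (cached per spec)."""
    n_nodes = spec.n_hidden + 1  # hidden nodes plus the output node
    incoming = [[] for _ in range(n_nodes)]
    for widx, (s, t) in enumerate(spec.connections):
        incoming[t - 1].append((s, widx))
    edge_src, edge_widx, indptr = [], [], [0]
    for node_edges in incoming:
        for s, widx in node_edges:
            edge_src.append(s)
            edge_widx.append(widx)
        indptr.append(len(edge_src))
    theta_idx = np.arange(spec.n_connections, spec.n_connections + n_nodes,
                          dtype=np.int64)
    return _Graph(np.asarray(edge_src, dtype=np.int64),
                  np.asarray(edge_widx, dtype=np.int64),
                  np.asarray(indptr, dtype=np.int64),
                  theta_idx)


def _values(params, spec) -> np.ndarray:
    if isinstance(params, ParameterVector):
        if params.spec is not spec and params.spec != spec:
            raise ValueError("parameter vector belongs to a different architecture")
        return params.values
    v = np.asarray(params, dtype=float)
    if v.shape != (spec.n_params,):
        raise ValueError(f"expected {spec.n_params} parameters, got shape {v.shape}")
    return v


def forward(spec: ArchitectureSpec, params, x) -> float | np.ndarray:
    """Evaluate the network at scalar or vector input ``x``."""
    v = _values(params, spec)
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    g = compiled_graph(spec)
    A = _kernels.forward_kernel(v, xs, *g.args())
    out = A[spec.n_hidden + 1]
    return float(out[0]) if np.isscalar(x) or np.ndim(x) == 0 else out


def forward_reference(spec: ArchitectureSpec, params, x: float) -> float:
    """Slow dictionary-based evaluation used as an independent cross-check."""
    v = _values(params, spec)
    labels = {lab: i for i, lab in enumerate(spec.param_labels())}
    act = {0: float(x)}
    for node in [n for layer in spec.hidden_layout for n in layer] + [spec.output_node]:
        u = -v[labels[("theta", node)]]
        for s, t in spec.connections:
            if t == node:
                u += v[labels[("w", s, t)]] * act[s]
        act[node] = float(expit(u))
    return act[spec.output_node]


@dataclass
class NetworkFunction:
    """A trained (or arbitrary) network as a scalar function x -> y."""

    spec: ArchitectureSpec
    params: ParameterVector

    def __post_init__(self):
        if not isinstance(self.params, ParameterVector):
            self.params = ParameterVector(self.spec, self.params)

    def __call__(self, x):
        return forward(self.spec, self.params, x)

    def on_grid(self, grid) -> np.ndarray:
        return evaluate_on_grid(self, grid)


def evaluate_on_grid(fn: NetworkFunction, grid) -> np.ndarray:
    """Elementwise network evaluation; preserves length, empty in -> empty out."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        return np.empty(0)
    return forward(fn.spec, fn.params, grid)
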