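"""Loop-level evaluation kernels over compiled wiring arrays.

The wiring graph is flattened into CSR-style arrays (one incoming-edge block
per node, nodes in topological order) so the forward pass, the batch
sum-of-squared-error, its exact reverse-mode gradient, and the per-point
residual Jacobian are tight loops.  When numba is importable the kernels are
jit-compiled; otherwise the same source runs as plain Python (identical
results, just slower).
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=False)
def _sig(u):
    # overflow-safe logistic
    if u >= 0.0:
        return 1.0 / (1.0 + math.exp(-u))
    e = math.exp(u)
    return e / (1.0 + e)


@njit(cache=False)
def forward_kernel(params, xs, edge_src, edge_widx, indptr, theta_idx):
    """Activations of all nodes; row 0 is the input, row j+1 is node j+1."""
    n_nodes = theta_idx.shape[0]
    P = xs.shape[0]
    A = np.empty((n_nodes + 1, P))
    for p in range(P):
        A[0, p] = xs[p]
    for j in range(n_nodes):
        for p in range(P):
            u = -params[theta_idx[j]]
            for e in range(indptr[j], indptr[j + 1]):
                u += params[edge_widx[e]] * A[edge_src[e], p]
            A[j + 1, p] = _sig(u)
    return A


@njit(cache=False)
def sse_kernel(params, xs, ts, edge_src, edge_widx, indptr, theta_idx):
    A = forward_kernel(params, xs, edge_src, edge_widx, indptr, theta_idx)
    n_nodes = theta_idx.shape[0]
    E = 0.0
    for p in range(xs.shape[0]):
        r = A[n_nodes, p] - ts[p]
        E += r * r
    return E


@njit(cache=False)
def sse_grad_kernel(params, xs, ts, edge_src, edge_widx, indptr, theta_idx):
    """Batch SSE and its exact gradient by reverse-mode accumulation."""
    A = forward_kernel(params, xs, edge_src, edge_widx, indptr, theta_idx)
    n_nodes = theta_idx.shape[0]
    P = xs.shape[0]
    E = 0.0
    adj = np.zeros((n_nodes + 1, P))  # dE/d(activation)
    for p in range(P):
        r = A[n_nodes, p] - ts[p]
        E += r * r
        adj[n_nodes, p] = 2.0 * r
    grad = np.zeros(params.shape[0])
    for j in range(n_nodes - 1, -1, -1):  # reverse topological order
        row = j + 1
        for p in range(P):
            a = A[row, p]
            d = adj[row, p] * a * (1.0 - a)  # dE/d(pre-activation)
            grad[theta_idx[j]] -= d
            for e in range(indptr[j], indptr[j + 1]):
                src = edge_src[e]
                grad[edge_widx[e]] += d * A[src, p]
                if src >= 1:
                    adj[src, p] += d * params[edge_widx[e]]
    return E, grad


@njit(cache=False)
def jacobian_kernel(params, xs, edge_src, edge_widx, indptr, theta_idx):
    """Rows are d(output at x_i)/d(params): the residual Jacobian, since the
    residual y(x_i) - t_i has the same parameter derivative as y(x_i)."""
    n_nodes = theta_idx.shape[0]
    P = xs.shape[0]
    A = forward_kernel(params, xs, edge_src, edge_widx, indptr, theta_idx)
    J = np.zeros((P, params.shape[0]))
    adj = np.zeros(n_nodes + 1)
    for p in range(P):
        for j in range(n_nodes + 1):
            adj[j] = 0.0
        adj[n_nodes] = 1.0
        for j in range(n_nodes - 1, -1, -1):
            row = j + 1
            a = A[row, p]
            d = adj[row] * a * (1.0 - a)
            J[p, theta_idx[j]] -= d
            for e in range(indptr[j], indptr[j + 1]):
                src = edge_src[e]
                J[p, edge_widx[e]] += d * A[src, p]
                if src >= 1:
                    adj[src] += d * params[edge_widx[e]]
    return J
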