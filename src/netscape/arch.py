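"""Network architectures as explicit feedforward wiring graphs.

An architecture is a directed acyclic graph with a single scalar input, hidden
nodes arranged in ordered layers (optionally grouped into columns), and a
single output node.  Every adjustable quantity -- one weight per connection
plus one threshold per hidden node and one for the output node -- occupies a
slot in a flat parameter vector, which is the coordinate system in which the
error landscape lives.

Node identifiers: ``0`` is the network input, hidden nodes are ``1..n_hidden``
numbered layer by layer, and ``n_hidden + 1`` is the output node.  Identifiers
are topologically ordered: every connection goes from a lower to a higher id.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

INPUT_NODE = 0

__all__ = [
    "ArchitectureSpec",
    "ParameterVector",
    "build_architecture",
    "builtin_suite",
    "spec_to_json",
    "spec_from_json",
]


@dataclass(frozen=True)
class ArchitectureSpec:
    """Validated wiring diagram of a feedforward sigmoid network.

    Parameters
    ----------
    name : str
        Human-readable label, e.g. ``"fan-1x12"``.
    hidden_layout : tuple of tuple of int
        Hidden node ids grouped by layer, in evaluation order.
    connections : tuple of (int, int)
        Directed edges ``(source, target)`` over node ids; ordered, and the
        order defines the weight slots of the parameter vector.
    columns : tuple, optional
        Per-layer column grouping (tuples of node-id tuples); informational.
    """

    name: str
    hidden_layout: tuple
    connections: tuple
    columns: tuple = field(default=())

    def __post_init__(self):
        object.__setattr__(self, "hidden_layout",
                           tuple(tuple(layer) for layer in self.hidden_layout))
        object.__setattr__(self, "connections",
                           tuple((int(s), int(t)) for s, t in self.connections))
        self._validate()

    # ------------------------------------------------------------------ sizes
    @property
    def n_hidden(self) -> int:
        return sum(len(layer) for layer in self.hidden_layout)

    @property
    def n_layers(self) -> int:
        return len(self.hidden_layout)

    @property
    def output_node(self) -> int:
        return self.n_hidden + 1

    @property
    def n_connections(self) -> int:
        return len(self.connections)

    @property
    def n_params(self) -> int:
        """Total adjustable parameters N_w: weights plus all thresholds."""
        return self.n_connections + self.n_hidden + 1

    @property
    def serialization(self) -> float:
        """Geometric serialization ratio L/N (hidden layers over layer width)."""
        return self.n_layers / len(self.hidden_layout[0])

    # ------------------------------------------------------------- validation
    def _validate(self) -> None:
        if not self.hidden_layout or any(len(l) == 0 for l in self.hidden_layout):
            raise ValueError("hidden_layout must contain at least one non-empty layer")
        hidden = [n for layer in self.hidden_layout for n in layer]
        if sorted(hidden) != list(range(1, len(hidden) + 1)):
            raise ValueError("hidden node ids must be 1..n_hidden in layer order")
        out = self.output_node
        seen = set()
        for s, t in self.connections:
            if (s, t) in seen:
                raise ValueError(f"duplicate connection {(s, t)}")
            seen.add((s, t))
            if not (0 <= s <= self.n_hidden) or not (1 <= t <= out):
                raise ValueError(f"connection {(s, t)} uses unknown node ids")
            if s >= t:
                raise ValueError(
                    f"connection {(s, t)} violates feedforward (topological) order")
        # every hidden node must sit on an input -> output path
        fwd = {n: [] for n in range(out + 1)}
        rev = {n: [] for n in range(out + 1)}
        for s, t in self.connections:
            fwd[s].append(t)
            rev[t].append(s)
        from_input = _reachable(INPUT_NODE, fwd)
        to_output = _reachable(out, rev)
        for n in hidden:
            if n not in from_input or n not in to_output:
                raise ValueError(f"hidden node {n} is not on an input->output path")
        if out not in from_input:
            raise ValueError("output node is unreachable from the input")

    # ------------------------------------------------------------- parameters
    def param_labels(self) -> list:
        """Slot labels: weights in connection order, then thresholds."""
        labels = [("w", s, t) for s, t in self.connections]
        labels += [("theta", n) for n in range(1, self.n_hidden + 1)]
        labels.append(("theta", self.output_node))
        return labels

    def layer_of(self, node: int) -> int:
        """0 for the input, 1..L for hidden layers, L+1 for the output."""
        if node == INPUT_NODE:
            return 0
        if node == self.output_node:
            return self.n_layers + 1
        for i, layer in enumerate(self.hidden_layout, start=1):
            if node in layer:
                return i
        raise KeyError(node)


def _reachable(start, adj):
    seen = {start}
    stack = [start]
    while stack:
        for nxt in adj[stack.pop()]:
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return seen


@dataclass
class ParameterVector:
    """Flat vector of all connection weights and node thresholds.

    ``index_map`` is the bijection between vector slots and labelled
    parameters (``("w", src, dst)`` or ``("theta", node)``).
    """

    spec: ArchitectureSpec
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.n_params,):
            raise ValueError(
                f"expected {self.spec.n_params} parameters, got {self.values.shape}")

    @classmethod
    def zeros(cls, spec: ArchitectureSpec) -> "ParameterVector":
        return cls(spec, np.zeros(spec.n_params))

    @property
    def index_map(self) -> dict:
        return {label: i for i, label in enumerate(self.spec.param_labels())}

    def __getitem__(self, label):
        return self.values[self.index_map[label]]

    def __setitem__(self, label, v):
        self.values[self.index_map[label]] = v

    def copy(self) -> "ParameterVector":
        return ParameterVector(self.spec, self.values.copy())

    def __len__(self) -> int:
        return self.values.size


# --------------------------------------------------------------------- builders

def _full_adjacent_edges(layout):
    """Input to first layer, dense between adjacent layers, last layer to output."""
    out = sum(len(l) for l in layout) + 1
    edges = [(INPUT_NODE, n) for n in layout[0]]
    for a, b in zip(layout, layout[1:]):
        edges += [(s, t) for s in a for t in b]
    edges += [(n, out) for n in layout[-1]]
    return edges


def _columnar_edges(layout, column_width, cross_links):
    """Full-adjacent wiring inside width-``column_width`` columns, plus
    ``cross_links`` deterministic cross-column links per adjacent column pair
    at every layer interface (column c's top node -> column c+1's bottom node,
    then the next node pairs inward for additional links)."""
    n = len(layout[0])
    if n % column_width:
        raise ValueError(
            f"column width {column_width} does not divide layer width {n}")
    n_cols = n // column_width
    out = sum(len(l) for l in layout) + 1
    cols = [
        tuple(tuple(layer[c * column_width:(c + 1) * column_width])
              for c in range(n_cols))
        for layer in layout
    ]
    edges = [(INPUT_NODE, node) for node in layout[0]]
    for a, b in zip(cols, cols[1:]):
        for ca, cb in zip(a, b):          # within-column, full adjacent
            edges += [(s, t) for s in ca for t in cb]
        for c in range(n_cols - 1):       # deterministic cross links
            for k in range(cross_links):
                edges.append((a[c][-1 - (k % column_width)],
                              b[c + 1][k % column_width]))
    edges += [(node, out) for node in layout[-1]]
    # drop accidental duplicates from cross links while keeping order
    seen, unique = set(), []
    for e in edges:
        if e not in seen:
            seen.add(e)
            unique.append(e)
    return unique, cols


def build_architecture(layers: int, nodes_per_layer: int, wiring="full-adjacent",
                       *, column_width: int = 2, cross_links: int = 1,
                       name: str | None = None) -> ArchitectureSpec:
    """Construct an L-layer, N-nodes-per-layer architecture.

    ``wiring`` is ``"full-adjacent"`` (dense between adjacent layers) or
    ``"columnar"`` (adjacent columns of width ``column_width`` wired densely
    within themselves, plus ``cross_links`` deterministic cross-column links
    per layer interface).
    """
    if layers < 1 or nodes_per_layer < 1:
        raise ValueError("layers and nodes_per_layer must be >= 1")
    layout = []
    nid = 1
    for _ in range(layers):
        layout.append(tuple(range(nid, nid + nodes_per_layer)))
        nid += nodes_per_layer
    layout = tuple(layout)
    columns = ()
    if wiring == "full-adjacent":
        edges = _full_adjacent_edges(layout)
    elif wiring == "columnar":
        edges, columns = _columnar_edges(layout, column_width, cross_links)
    else:
        raise ValueError(f"unknown wiring rule {wiring!r}")
    if name is None:
        name = f"{wiring}-{layers}x{nodes_per_layer}"
    return ArchitectureSpec(name=name, hidden_layout=layout,
                            connections=tuple(edges), columns=tuple(columns))


def builtin_suite(total_hidden: int = 12) -> list:
    """The five-architecture suite ordered by increasing serialization L/N.

    For 12 hidden nodes: fan 1x12 and stacked 6x2 are full-adjacent (equal
    connection counts); intermediates 2x6, 3x4, 4x3 are columnar (width 2
    where it divides the layer, else width 1) with one cross link per adjacent
    column pair at each interface, keeping N_w within 15% of the fan's.
    For 18 hidden nodes the layouts are 1x18, 2x9, 3x6, 6x3, 9x2.
    """
    shapes = {12: [(1, 12), (2, 6), (3, 4), (4, 3), (6, 2)],
              18: [(1, 18), (2, 9), (3, 6), (6, 3), (9, 2)]}
    if total_hidden not in shapes:
        warnings.warn(f"no canonical suite for {total_hidden} hidden nodes; "
                      "deriving layouts by factorization", stacklevel=2)
        divs = [d for d in range(1, total_hidden + 1) if total_hidden % d == 0]
        pairs = sorted(((L, total_hidden // L) for L in divs
                        if L < total_hidden or L == 1),
                       key=lambda p: p[0] / p[1])
        # pick five spanning the serialization range
        idx = np.linspace(0, len(pairs) - 1, min(5, len(pairs))).round().astype(int)
        layout_list = [pairs[i] for i in idx]
    else:
        layout_list = shapes[total_hidden]
    specs = []
    for i, (L, N) in enumerate(layout_list):
        if i == 0:
            specs.append(build_architecture(L, N, "full-adjacent", name=f"fan-{L}x{N}"))
        elif i == len(layout_list) - 1:
            specs.append(build_architecture(L, N, "full-adjacent",
                                            name=f"stacked-{L}x{N}"))
        else:
            width = 2 if N % 2 == 0 else 1
            specs.append(build_architecture(L, N, "columnar", column_width=width,
                                            cross_links=1, name=f"inter-{L}x{N}"))
    specs.sort(key=lambda s: s.serialization)
    return specs


# ------------------------------------------------------------------------- io

def spec_to_json(spec: ArchitectureSpec) -> str:
    return json.dumps({
        "name": spec.name,
        "hidden_layout": [list(l) for l in spec.hidden_layout],
        "connections": [list(e) for e in spec.connections],
        "columns": [[list(c) for c in layer] for layer in spec.columns],
    }, indent=2)


def spec_from_json(text: str) -> ArchitectureSpec:
    d = json.loads(text)
    return ArchitectureSpec(
        name=d["name"],
        hidden_layout=tuple(tuple(l) for l in d["hidden_layout"]),
        connections=tuple(tuple(e) for e in d["connections"]),
        columns=tuple(tuple(tuple(c) for c in layer) for layer in d.get("columns", [])),
    )
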