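"""Synthetic point populations for the two-session function-approximation task.

Three populations feed the protocol:

* *original* points ``D_o`` -- inputs evenly spaced across the input interval,
  targets drawn once, uniformly over the sigmoid output interval, and then
  held fixed for the whole study (a documented study seed pins them down);
* *new* points ``D_n`` -- inputs and targets drawn independently and
  uniformly, fresh for every second-session trial;
* *buffer* points ``D_b`` -- inputs drawn uniformly, targets computed exactly
  from the network's own first-session function (pseudorehearsal: the network
  rehearses its representation of the old data, not the data itself).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .network import INPUT_INTERVAL, OUTPUT_INTERVAL, NetworkFunction

__all__ = ["PointSet", "STUDY_SEED", "generate_original_points",
           "generate_new_points", "sample_buffer_pool", "draw_buffer_subset"]

#: seed that fixes the canonical original targets for the whole study
STUDY_SEED = 1002063


@dataclass
class PointSet:
    """Ordered set of (input, target) pairs with a role and provenance."""

    x: np.ndarray
    t: np.ndarray
    role: str  # original | new | buffer
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if self.x.shape != self.t.shape or self.x.ndim != 1:
            raise ValueError("x and t must be 1-D arrays of equal length")
        if self.role not in ("original", "new", "buffer"):
            raise ValueError(f"unknown role {self.role!r}")

    def __len__(self):
        return self.x.size

    @property
    def points(self):
        return list(zip(self.x, self.t))

    def to_csv(self) -> str:
        buf = io.StringIO()
        prov = ",".join(f"{k}={v}" for k, v in sorted(self.provenance.items()))
        buf.write(f"# role={self.role} {prov}\n")
        buf.write("x,t\n")
        for xi, ti in zip(self.x, self.t):
            buf.write(f"{float(xi)!r},{float(ti)!r}\n")
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "PointSet":
        lines = text.strip().splitlines()
        header = lines[0].lstrip("# ").split()
        meta = dict(kv.split("=", 1) for item in header for kv in item.split(",") if "=" in kv)
        role = meta.pop("role")
        rows = [ln.split(",") for ln in lines[2:]]
        x = np.array([float(r[0]) for r in rows])
        t = np.array([float(r[1]) for r in rows])
        return cls(x=x, t=t, role=role, provenance=meta)


def generate_original_points(n_points: int = 6, seed: int = STUDY_SEED,
                             input_interval=INPUT_INTERVAL,
                             target_interval=OUTPUT_INTERVAL,
                             permute: bool = False) -> PointSet:
    """The fixed first-session training points: evenly spaced in x, uniform
    random in t.  The default study seed fixes one canonical set reused
    everywhere; ``permute=True`` keeps the x grid and shuffles the targets
    (the permuted-training-function study variant).
    """
    if n_points < 2:
        raise ValueError("need at least 2 original points")
    lo, hi = input_interval
    x = np.linspace(lo, hi, n_points)
    rng = np.random.default_rng(seed)
    a, b = target_interval
    t = rng.uniform(a, b, size=n_points)
    if permute:
        t = rng.permutation(t)
    return PointSet(x=x, t=t, role="original",
                    provenance={"seed": seed, "generator": "original",
                                "permuted": permute})


def generate_new_points(n_points: int = 6, seed: int | None = None,
                        input_interval=INPUT_INTERVAL,
                        target_interval=OUTPUT_INTERVAL) -> PointSet:
    """Second-session points: x and t independent uniform draws."""
    if n_points < 1:
        raise ValueError("need at least 1 new point")
    rng = np.random.default_rng(seed)
    x = rng.uniform(*input_interval, size=n_points)
    t = rng.uniform(*target_interval, size=n_points)
    return PointSet(x=x, t=t, role="new",
                    provenance={"seed": seed, "generator": "new"})


def sample_buffer_pool(fn: NetworkFunction, pool_size: int = 100,
                       seed: int | None = None,
                       input_interval=INPUT_INTERVAL) -> PointSet:
    """Pool of pseudorehearsal points lying exactly on the network's own
    first-session function: x uniform, t = fn(x)."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(*input_interval, size=pool_size)
    t = fn.on_grid(x)
    return PointSet(x=x, t=t, role="buffer",
                    provenance={"seed": seed, "generator": "buffer_pool"})


def draw_buffer_subset(pool: PointSet, n: int = 6,
                       seed: int | None = None) -> PointSet:
    """Uniform without-replacement subset of the buffer pool."""
    if pool.role != "buffer":
        raise ValueError("subset must be drawn from a buffer pool")
    if n > len(pool):
        raise ValueError(f"cannot draw {n} points from a pool of {len(pool)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return PointSet(x=pool.x[idx], t=pool.t[idx], role="buffer",
                    provenance=dict(pool.provenance, subset_seed=seed))
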