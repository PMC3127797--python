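"""Distributional statistics over error ensembles.

The study summarizes each ensemble of errors by its survival curve
S(e) = P[error > e] (the convention behind the published distribution plots),
its extrema and mean (best/worst/average performance), the across-trial
variance of the solution curves, and the signed deviation of a trial's memory
error from the first-session error it started from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ErrorEnsemble", "survival_cdf", "summarize", "solution_variance",
           "deviation_from_f_o"]


@dataclass
class ErrorEnsemble:
    """Vector of nonnegative errors with an identifying label."""

    values: np.ndarray
    label: tuple = ()  # (architecture, session, error kind, budget)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("ensemble values must be 1-D")
        if np.any(self.values < 0):
            raise ValueError("errors must be nonnegative")


def _values(ensemble) -> np.ndarray:
    v = ensemble.values if isinstance(ensemble, ErrorEnsemble) else np.asarray(
        ensemble, dtype=float)
    if v.size == 0:
        raise ValueError("empty ensemble")
    return v


def survival_cdf(ensemble):
    """Right-continuous survival step function S(e) = (# values > e) / n.

    Returns ``(thresholds, fractions)``: the sorted distinct values and the
    fraction of the ensemble strictly exceeding each.  S is 1 below the
    minimum and 0 at and above the maximum.
    """
    v = np.sort(_values(ensemble))
    thresholds = np.unique(v)
    n = v.size
    fractions = np.array([np.sum(v > e) / n for e in thresholds])
    return thresholds, fractions


def survival_at(ensemble, e: float) -> float:
    """S(e) for a single threshold."""
    v = _values(ensemble)
    return float(np.sum(v > e) / v.size)


def summarize(ensemble):
    """(min, max, mean): best, worst, and average performance."""
    v = _values(ensemble)
    return float(v.min()), float(v.max()), float(v.mean())


def solution_variance(trial_grids) -> float:
    """Average over grid points of the across-trial sample variance (ddof=1)
    of the solution curves; 0 iff all curves coincide."""
    G = np.asarray(trial_grids, dtype=float)
    if G.ndim != 2 or G.shape[0] < 2:
        raise ValueError("need >= 2 trials on a common grid")
    return float(np.mean(np.var(G, axis=0, ddof=1)))


def deviation_from_f_o(trial, E_o_star: float) -> float:
    """Signed interference measure E_o - E_o_star: how much re-training moved
    the network off its own original representation (negative if the second
    session incidentally improved the original fit)."""
    E_o = trial.E_o if hasattr(trial, "E_o") else float(trial)
    return float(E_o - E_o_star)


def survival_frame(ensemble) -> pd.DataFrame:
    """Sorted values with survival fractions, ready for CSV export."""
    thresholds, fractions = survival_cdf(ensemble)
    return pd.DataFrame({"error": thresholds, "survival": fractions})
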