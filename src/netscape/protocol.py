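"""Two-session pseudorehearsal protocol and its ensemble experiments.

Session one trains a randomly initialized network on the fixed original
points with an effectively unlimited iteration budget (plateau-stopped); the
resulting "sampled state" defines the network's own function f_o.  Session
two re-trains from the sampled state on the union of six fresh random new
points and six pseudorehearsal buffer points drawn from a pool sampled off
f_o, under a limited iteration budget, and measures the errors E_o (memory:
against the original points) and E_n (learning: against the new points) of
the re-trained function f_n.

Two ensembles repeat this: many second-session trials from one sampled state
(the distribution of solutions), and many random initializations of session
one under unlimited or limited budgets (the error-landscape census).

All randomness derives from a single master seed through
``numpy.random.SeedSequence`` sub-streams, so every trial is reproducible in
isolation and results are independent of scheduling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .arch import ArchitectureSpec, ParameterVector
from .cgtrain import OptimizerConfig, TrainingTrace, sse_error, train_network
from .network import INPUT_INTERVAL, NetworkFunction
from .taskdata import (PointSet, STUDY_SEED, draw_buffer_subset,
                       generate_new_points, sample_buffer_pool)

__all__ = ["ExperimentConfig", "SessionOneResult", "TrialRecord", "InitEnsemble",
           "derive_seed", "initialize_weights", "run_session_one",
           "run_session_two", "run_trial_ensemble", "run_initialization_ensemble"]

# sub-stream tags for seed derivation
_INIT, _NEW, _POOL, _SUBSET, _TRIAL = 1, 2, 3, 4, 5


def derive_seed(master_seed: int, *path: int) -> int:
    """Deterministic sub-seed for a work item, independent of scheduling."""
    return int(np.random.SeedSequence([int(master_seed), *map(int, path)])
               .generate_state(1)[0])


@dataclass
class ExperimentConfig:
    """Study conditions shared by the ensemble experiments."""

    n_trials: int = 1000              # M second-session repeats
    n_inits_unlimited: int = 500      # K for the unlimited-budget census
    n_inits_limited: int = 1000       # K for the limited-budget census
    limited_budget: int = 500         # T iterations per limited session
    pool_size: int = 100              # buffer pool B
    n_new: int = 6
    n_buffer: int = 6
    grid_size: int = 201
    half_width: float = 1.0           # uniform init range [-h, h]
    master_seed: int = STUDY_SEED
    unlimited: OptimizerConfig = field(default_factory=OptimizerConfig)

    def __post_init__(self):
        if min(self.n_trials, self.n_inits_unlimited, self.n_inits_limited,
               self.pool_size, self.n_new, self.n_buffer, self.grid_size) < 1:
            raise ValueError("all counts must be positive")
        if self.limited_budget < 0:  # T = 0 (no second-session training) is legal
            raise ValueError("limited_budget must be >= 0")
        if self.limited_budget >= self.unlimited.max_iterations:
            raise ValueError("limited_budget must be below the unlimited cap")

    @property
    def limited(self) -> OptimizerConfig:
        return replace(self.unlimited, max_iterations=self.limited_budget)

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(*INPUT_INTERVAL, self.grid_size)


@dataclass
class SessionOneResult:
    """The sampled state: end of the first training session."""

    spec: ArchitectureSpec
    sampled_params: ParameterVector
    f_o: NetworkFunction
    E_o_star: float
    trace: TrainingTrace


@dataclass
class TrialRecord:
    """One second-session outcome measured against both point sets."""

    trial_index: int
    f_n_grid: np.ndarray
    E_o: float
    E_n: float
    new_seed: int
    buffer_seed: int
    final_params: np.ndarray
    n_iterations: int


@dataclass
class InitEnsemble:
    """First-session error census over K random initializations.

    ``errors`` is the vector of first-session errors E_o^* (one per
    initialization); iteration counts, stop reasons and final parameter
    vectors ride along for landscape and speed/accuracy analyses.
    """

    spec: ArchitectureSpec
    budget: str
    errors: np.ndarray
    n_iterations: np.ndarray
    stop_reasons: list
    final_params: np.ndarray  # (K, N_w)
    init_seeds: np.ndarray

    def __len__(self):
        return self.errors.size


def representative_state(ensemble: "InitEnsemble", D_o: PointSet
                         ) -> SessionOneResult:
    """The sampled state whose first-session error is most representative of
    the initialization-ensemble average (the minimum with E_o* closest to the
    ensemble mean); trial ensembles start from such states so their
    statistics reflect typical, not extreme, first sessions."""
    k = int(np.argmin(np.abs(ensemble.errors - ensemble.errors.mean())))
    params = ParameterVector(ensemble.spec, ensemble.final_params[k].copy())
    # rebuild a SessionOneResult view of the stored minimum
    trace = TrainingTrace(error_history=np.array([ensemble.errors[k]]),
                          n_iterations=int(ensemble.n_iterations[k]),
                          stop_reason=ensemble.stop_reasons[k],
                          final_params=params.values,
                          final_error=float(ensemble.errors[k]))
    return SessionOneResult(spec=ensemble.spec, sampled_params=params,
                            f_o=NetworkFunction(ensemble.spec, params),
                            E_o_star=float(ensemble.errors[k]), trace=trace)


def initialize_weights(spec: ArchitectureSpec, seed: int,
                       half_width: float = 1.0) -> ParameterVector:
    """Uniform random start on [-half_width, half_width] per parameter."""
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    rng = np.random.default_rng(seed)
    return ParameterVector(spec, rng.uniform(-half_width, half_width,
                                             size=spec.n_params))


def run_session_one(spec: ArchitectureSpec, init_params, D_o: PointSet,
                    config: OptimizerConfig | None = None) -> SessionOneResult:
    """Train on the original points (unlimited budget, plateau-stopped)."""
    if D_o.role != "original":
        raise ValueError("first session trains on original points")
    trace = train_network(spec, init_params, D_o, config or OptimizerConfig())
    params = ParameterVector(spec, trace.final_params)
    return SessionOneResult(spec=spec, sampled_params=params,
                            f_o=NetworkFunction(spec, params),
                            E_o_star=trace.final_error, trace=trace)


def run_session_two(spec: ArchitectureSpec, sampled_params, D_o: PointSet,
                    pool: PointSet, trial_seed: int,
                    config: ExperimentConfig, trial_index: int = 0) -> TrialRecord:
    """Re-train from the sampled state on fresh new + buffer points for at
    most the limited budget, then score the result on D_o and D_n."""
    new_seed = derive_seed(trial_seed, _NEW)
    buffer_seed = derive_seed(trial_seed, _SUBSET)
    D_n = generate_new_points(config.n_new, seed=new_seed)
    D_b = draw_buffer_subset(pool, config.n_buffer, seed=buffer_seed)
    union = PointSet(x=np.concatenate([D_n.x, D_b.x]),
                     t=np.concatenate([D_n.t, D_b.t]), role="new",
                     provenance={"seed": trial_seed, "generator": "union"})
    trace = train_network(spec, sampled_params, union, config.limited)
    f_n = NetworkFunction(spec, ParameterVector(spec, trace.final_params))
    return TrialRecord(trial_index=trial_index,
                       f_n_grid=f_n.on_grid(config.grid),
                       E_o=sse_error(spec, trace.final_params, D_o),
                       E_n=sse_error(spec, trace.final_params, D_n),
                       new_seed=new_seed, buffer_seed=buffer_seed,
                       final_params=trace.final_params,
                       n_iterations=trace.n_iterations)


def run_trial_ensemble(spec: ArchitectureSpec, session_one: SessionOneResult,
                       D_o: PointSet, config: ExperimentConfig,
                       n_trials: int | None = None) -> list:
    """M independent second sessions, all from the same sampled state, each
    with fresh new/buffer draws; one pool is sampled once at the sampled
    state and subsets are drawn per trial."""
    M = config.n_trials if n_trials is None else n_trials
    pool_seed = derive_seed(config.master_seed, _POOL)
    pool = sample_buffer_pool(session_one.f_o, config.pool_size, seed=pool_seed)
    records = []
    for m in range(M):
        trial_seed = derive_seed(config.master_seed, _TRIAL, m)
        records.append(run_session_two(spec, session_one.sampled_params, D_o,
                                       pool, trial_seed, config, trial_index=m))
    return records


def run_initialization_ensemble(spec: ArchitectureSpec, D_o: PointSet,
                                K: int, budget: str = "unlimited",
                                master_seed: int | None = None,
                                config: ExperimentConfig | None = None
                                ) -> InitEnsemble:
    """First-session error distribution over K random initializations under
    the unlimited (plateau-stopped) or limited (T-iteration) budget."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if budget not in ("unlimited", "limited"):
        raise ValueError("budget must be 'unlimited' or 'limited'")
    cfg = config or ExperimentConfig()
    seed = cfg.master_seed if master_seed is None else master_seed
    opt = cfg.unlimited if budget == "unlimited" else cfg.limited
    errors = np.empty(K)
    iters = np.empty(K, dtype=int)
    reasons = []
    finals = np.empty((K, spec.n_params))
    seeds = np.empty(K, dtype=np.int64)
    for k in range(K):
        s = derive_seed(seed, _INIT, k)
        seeds[k] = s
        init = initialize_weights(spec, s, cfg.half_width)
        res = run_session_one(spec, init, D_o, opt)
        errors[k] = res.E_o_star
        iters[k] = res.trace.n_iterations
        reasons.append(res.trace.stop_reason)
        finals[k] = res.sampled_params.values
    return InitEnsemble(spec=spec, budget=budget, errors=errors,
                        n_iterations=iters, stop_reasons=reasons,
                        final_params=finals, init_seeds=seeds)
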