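"""Study orchestration: configuration, experiment sequencing, persistence.

``run_study`` executes the full pipeline at configured sizes -- first
sessions per architecture on the canonical original points, second-session
trial ensembles, initialization ensembles under both time budgets, curvature
spectra and participation summaries over converged minima, and one landscape
slice each for a fan and a stacked minimum -- writing flat CSV artifacts plus
a JSON manifest (config, seeds, versions) that makes the run reproducible
bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .arch import ArchitectureSpec, builtin_suite, spec_to_json
from .cgtrain import OptimizerConfig
from .landscape import minima_landscape_summary, project_error_surface, \
    spectrum_at_minimum
from .protocol import (ExperimentConfig, run_initialization_ensemble,
                       run_session_one, run_trial_ensemble, initialize_weights,
                       derive_seed)
from .stats import solution_variance, summarize, survival_frame, ErrorEnsemble
from .taskdata import STUDY_SEED, generate_original_points

__all__ = ["StudyConfig", "load_config", "save_config", "run_study"]

log = logging.getLogger("netscape")

_EXPERIMENTS = ("tradeoffs", "init-ensemble", "landscape")


@dataclass
class StudyConfig:
    """Everything a full study run needs, serializable to YAML/JSON."""

    study_seed: int = STUDY_SEED
    total_hidden: int = 12
    n_original: int = 6
    permute_targets: bool = False
    n_trials: int = 1000
    n_inits_unlimited: int = 500
    n_inits_limited: int = 1000
    limited_budget: int = 500
    pool_size: int = 100
    n_new: int = 6
    n_buffer: int = 6
    grid_size: int = 201
    half_width: float = 1.0
    max_iterations: int = 50_000
    plateau_window: int = 1000
    plateau_delta: float = 1e-8
    zero_tol_rel: float = 1e-10
    landscape_half_range: float = 1.0
    landscape_n_grid: int = 60
    n_spectra: int | None = None      # cap on minima analyzed per architecture
    experiments: list = field(default_factory=lambda: list(_EXPERIMENTS))
    out_dir: str = "results"
    log_level: str = "INFO"

    def __post_init__(self):
        unknown = set(self.experiments) - {*_EXPERIMENTS, "all"}
        if unknown:
            raise ValueError(f"unknown experiments: {sorted(unknown)}")
        if "all" in self.experiments:
            self.experiments = list(_EXPERIMENTS)
        if self.limited_budget >= self.max_iterations:
            raise ValueError("limited_budget must be below max_iterations")

    def experiment_config(self) -> ExperimentConfig:
        return ExperimentConfig(
            n_trials=self.n_trials, n_inits_unlimited=self.n_inits_unlimited,
            n_inits_limited=self.n_inits_limited,
            limited_budget=self.limited_budget, pool_size=self.pool_size,
            n_new=self.n_new, n_buffer=self.n_buffer, grid_size=self.grid_size,
            half_width=self.half_width, master_seed=self.study_seed,
            unlimited=OptimizerConfig(max_iterations=self.max_iterations,
                                      plateau_window=self.plateau_window,
                                      plateau_delta=self.plateau_delta))


def load_config(path) -> StudyConfig:
    """Load a YAML/JSON study config; empty file means all defaults;
    unknown keys are rejected with the offending names."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    valid = {f.name for f in fields(StudyConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return StudyConfig(**data)


def save_config(config: StudyConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=True))


def _config_hash(config: StudyConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()).hexdigest()[:16]


def run_study(config: StudyConfig) -> dict:
    """Execute the configured experiments and write all artifacts.

    Returns the manifest (also written to ``manifest.json``): config, seeds,
    versions, and every artifact path produced.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    cfg = config.experiment_config()
    suite = builtin_suite(config.total_hidden)
    D_o = generate_original_points(config.n_original, seed=config.study_seed,
                                   permute=config.permute_targets)
    artifacts = {}

    def write(name, frame):
        path = out / name
        frame.to_csv(path, index=False)
        artifacts[name] = str(path)

    (out / "original_points.csv").write_text(D_o.to_csv())
    artifacts["original_points.csv"] = str(out / "original_points.csv")
    for spec in suite:
        p = out / f"architecture_{spec.name}.json"
        p.write_text(spec_to_json(spec))
        artifacts[p.name] = str(p)

    # --- stage 1: canonical first sessions (always needed downstream)
    sessions = {}
    for spec in suite:
        init = initialize_weights(spec, derive_seed(config.study_seed, 0, 0),
                                  config.half_width)
        sessions[spec.name] = run_session_one(spec, init, D_o, cfg.unlimited)
        log.info("session one %s: E_o*=%.3g (%d iterations)", spec.name,
                 sessions[spec.name].E_o_star,
                 sessions[spec.name].trace.n_iterations)

    if "tradeoffs" in config.experiments:
        rows = []
        for spec in suite:
            records = run_trial_ensemble(spec, sessions[spec.name], D_o, cfg)
            for r in records:
                rows.append({"architecture": spec.name,
                             "serialization": spec.serialization,
                             "trial": r.trial_index, "E_o": r.E_o, "E_n": r.E_n})
            grids = np.array([r.f_n_grid for r in records])
            sv = solution_variance(grids)
            for kind in ("E_o", "E_n"):
                vals = np.array([getattr(r, kind) for r in records])
                mn, mx, mean = summarize(vals)
                write(f"survival_{spec.name}_{kind}.csv",
                      survival_frame(ErrorEnsemble(vals, (spec.name, 2, kind,
                                                          "limited"))))
                rows_sum = artifacts.setdefault("_summaries", [])
                rows_sum.append({"architecture": spec.name,
                                 "serialization": spec.serialization,
                                 "kind": kind, "min": mn, "max": mx,
                                 "mean": mean, "solution_variance": sv,
                                 "E_o_star": sessions[spec.name].E_o_star})
        write("trials.csv", pd.DataFrame(rows))
        write("trial_summaries.csv", pd.DataFrame(artifacts.pop("_summaries")))

    ensembles = {}
    if "init-ensemble" in config.experiments or "landscape" in config.experiments:
        rows = []
        for spec in suite:
            ens = run_initialization_ensemble(spec, D_o, cfg.n_inits_unlimited,
                                              "unlimited", config.study_seed, cfg)
            ensembles[spec.name] = ens
            rows += [{"architecture": spec.name, "budget": "unlimited",
                      "init": k, "E_o_star": ens.errors[k],
                      "n_iterations": int(ens.n_iterations[k]),
                      "stop_reason": ens.stop_reasons[k]}
                     for k in range(len(ens))]
        if "init-ensemble" in config.experiments:
            for spec in suite:
                ens = run_initialization_ensemble(spec, D_o, cfg.n_inits_limited,
                                                  "limited", config.study_seed, cfg)
                rows += [{"architecture": spec.name, "budget": "limited",
                          "init": k, "E_o_star": ens.errors[k],
                          "n_iterations": int(ens.n_iterations[k]),
                          "stop_reason": ens.stop_reasons[k]}
                         for k in range(len(ens))]
        write("init_ensembles.csv", pd.DataFrame(rows))

    if "landscape" in config.experiments:
        specs, err_vecs, spectra = [], [], []
        for spec in suite:
            ens = ensembles[spec.name]
            n = len(ens) if config.n_spectra is None else min(config.n_spectra,
                                                              len(ens))
            sp = [spectrum_at_minimum(spec, ens.final_params[k], D_o,
                                      config.zero_tol_rel) for k in range(n)]
            specs.append(spec)
            err_vecs.append(ens.errors[:n])
            spectra.append(sp)
        summary = minima_landscape_summary(specs, err_vecs, spectra)
        write("landscape_minima.csv", summary["table"])
        per_arch = {
            name: {"serialization": d["serialization"], "means": d["means"],
                   "cov_error_participation":
                       d["cov_error_participation"].tolist(),
                   "cov_eigenvalue_participation":
                       d["cov_eigenvalue_participation"].tolist()}
            for name, d in summary["per_architecture"].items()}
        p = out / "landscape_summary.json"
        p.write_text(json.dumps(per_arch, indent=2))
        artifacts[p.name] = str(p)
        # one slice per boundary architecture, centered on its best minimum
        for spec in (suite[0], suite[-1]):
            ens = ensembles[spec.name]
            best = int(np.argmin(ens.errors))
            cs = spectrum_at_minimum(spec, ens.final_params[best], D_o,
                                     config.zero_tol_rel)
            sl = project_error_surface(spec, ens.final_params[best], D_o,
                                       cs.eigenvectors[:, 0],
                                       cs.eigenvectors[:, 1],
                                       config.landscape_half_range,
                                       config.landscape_n_grid)
            write(f"landscape_slice_{spec.name}.csv", sl.to_frame())

    manifest = {
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "study_seed": config.study_seed,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
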