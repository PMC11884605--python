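"""End-to-end orchestration: simulate -> covariance -> Jacobian -> stats.

The whole run is a pure function of (config, seed): the global seed is
split into named substreams (simulation, bootstrap, cross-validation,
permutation) so any stage can be rerun independently with identical
results, and rerunning the full pipeline with the same config produces
byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import __version__
from .lyapunov import FluctuationSpec, bootstrap_jacobian, differential_jacobian
from .mvstats import fit_oplsda, permutation_validity, screen_metabolites
from .network import MetabolicNetwork, load_builtin, load_network
from .preprocess import condition_covariance, read_table
from .simulate import SimulationConfig, generate_study
from .table import MetaboliteTable

__all__ = ["RunConfig", "ConfigError", "PipelineError", "validate_config", "run_pipeline"]

log = logging.getLogger("metajac")

DEFAULT_COMPARISONS = [
    ("WT+SD", "AD+SD"),
    ("AD+SD", "AD+NMD"),
    ("AD+NMD", "AD+NMD+M"),
]


class ConfigError(ValueError):
    """Aggregates every schema violation found in a run configuration."""


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    network: str = "mannose_core"
    seed: int = 0
    outdir: str = "metajac_run"
    table_path: str | None = None  # mutually exclusive with simulation
    simulation: dict = field(default_factory=dict)
    comparisons: list[tuple[str, str]] = field(default_factory=lambda: list(DEFAULT_COMPARISONS))
    flu: str | list[float] = "identity"
    ridge: float = 0.0
    bootstrap_B: int = 200
    n_ortho: int = 1
    cv_folds: int = 7
    n_perm: int = 200
    fc_base: float = 2.0
    cov_scaling: str = "none"

    def load_net(self) -> MetabolicNetwork:
        p = Path(self.network)
        if p.suffix == ".tsv" or p.exists():
            return load_network(p)
        return load_builtin(self.network)

    def flu_spec(self, n: int) -> FluctuationSpec:
        if self.flu == "identity":
            return FluctuationSpec.identity()
        if self.flu == "simulation":
            noise_sd = float(self.simulation.get("noise_sd", 0.15))
            return FluctuationSpec.from_noise_sd(noise_sd, n)
        return FluctuationSpec.diagonal([float(v) for v in self.flu])

    def to_dict(self) -> dict:
        return {
            "network": self.network,
            "seed": self.seed,
            "table_path": self.table_path,
            "simulation": dict(self.simulation),
            "comparisons": [list(c) for c in self.comparisons],
            "flu": self.flu,
            "ridge": self.ridge,
            "bootstrap_B": self.bootstrap_B,
            "n_ortho": self.n_ortho,
            "cv_folds": self.cv_folds,
            "n_perm": self.n_perm,
            "fc_base": self.fc_base,
            "cov_scaling": self.cov_scaling,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(path: str | Path) -> RunConfig:
    """Parse a YAML run configuration, reporting *all* violations at once."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    errors: list[str] = []
    warnings_: list[str] = []
    cfg = RunConfig()
    known = set(cfg.to_dict()) | {"outdir"}
    for key in raw:
        if key not in known:
            errors.append(f"unknown key {key!r}")
    if "seed" not in raw:
        warnings_.append(f"no seed given; defaulting to {cfg.seed}")
    else:
        if not isinstance(raw["seed"], int):
            errors.append("seed must be an integer")
        else:
            cfg.seed = raw["seed"]
    cfg.network = str(raw.get("network", cfg.network))
    cfg.outdir = str(raw.get("outdir", cfg.outdir))
    cfg.table_path = raw.get("table_path")
    sim = raw.get("simulation") or {}
    if not isinstance(sim, dict):
        errors.append("simulation must be a mapping")
        sim = {}
    cfg.simulation = sim
    if cfg.table_path and sim:
        errors.append("give either table_path or simulation settings, not both")
    for key in ("ridge", "fc_base"):
        if key in raw:
            try:
                setattr(cfg, key, float(raw[key]))
            except (TypeError, ValueError):
                errors.append(f"{key} must be a number")
    for key in ("bootstrap_B", "n_ortho", "cv_folds", "n_perm"):
        if key in raw:
            if not isinstance(raw[key], int) or raw[key] < 1:
                errors.append(f"{key} must be a positive integer")
            else:
                setattr(cfg, key, raw[key])
    if "flu" in raw:
        cfg.flu = raw["flu"]
        if not (cfg.flu in ("identity", "simulation") or isinstance(cfg.flu, list)):
            errors.append("flu must be 'identity', 'simulation', or a list of values")
    if "cov_scaling" in raw:
        cfg.cov_scaling = str(raw["cov_scaling"])
    if "comparisons" in raw:
        comps = raw["comparisons"]
        if not isinstance(comps, list) or not all(
            isinstance(c, (list, tuple)) and len(c) == 2 for c in comps
        ):
            errors.append("comparisons must be a list of [condition_a, condition_b] pairs")
        else:
            cfg.comparisons = [tuple(map(str, c)) for c in comps]

    # cross-checks that need the network / condition universe
    try:
        cfg.load_net()
    except Exception as exc:
        errors.append(f"network {cfg.network!r}: {exc}")
    cond_universe = set(sim.get("conditions", {})) if sim.get("conditions") else None
    if cond_universe is not None:
        for a, b in cfg.comparisons:
            for label in (a, b):
                if label not in cond_universe:
                    errors.append(
                        f"comparison references unknown condition {label!r}; "
                        f"known: {sorted(cond_universe)}"
                    )
    if errors:
        raise ConfigError("; ".join(errors))
    for w in warnings_:
        log.warning(w)
    return cfg


def _build_sim_config(cfg: RunConfig, net: MetabolicNetwork) -> SimulationConfig:
    sim = dict(cfg.simulation)
    sim.setdefault("seed", cfg.seed)
    conditions = sim.pop("conditions", None)
    kwargs = {
        k: sim[k]
        for k in (
            "step",
            "burn_in",
            "sample_every",
            "n_replicates",
            "noise_sd",
            "measurement_cv",
            "seed",
        )
        if k in sim
    }
    if conditions is not None:
        kwargs["conditions"] = {k: dict(v or {}) for k, v in conditions.items()}
    return SimulationConfig(net=net, **kwargs)


def _stage(name: str):
    """Decorator-free stage wrapper: reraise with the stage name attached."""

    class _Ctx:
        def __init__(self) -> None:
            self.t0 = 0.0

        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.2fs", name, dt)
            return False

    return _Ctx()


def run_pipeline(cfg: RunConfig, outdir: str | Path | None = None) -> dict:
    """Run every stage and write all artifacts; returns the run report.

    Per compared condition pair this produces covariance CSVs, Jacobian
    edge-list TSVs, a differential-Jacobian JSON/TSV, an OPLS-DA summary
    JSON and a metabolite-screen TSV, plus one run-report JSON with the
    config hash and versions. Identical config + seed => byte-identical
    outputs.
    """
    outdir = Path(outdir if outdir is not None else cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "warnings": [],
        "stages": [],
        "comparisons": {},
    }
    root_ss = np.random.SeedSequence(cfg.seed)
    sim_ss, boot_ss, cv_ss, perm_ss = root_ss.spawn(4)

    with _stage("network"):
        net = cfg.load_net()
        flu = cfg.flu_spec(net.n)

    with _stage("data"):
        if cfg.table_path:
            table, imput = read_table(cfg.table_path)
            report["imputation"] = imput
        else:
            sim_cfg = _build_sim_config(cfg, net)
            table = generate_study(sim_cfg)
        table.check_invariants()
        table.to_csv(outdir / "study_table.csv")
    report["stages"].append("data")
    conditions = table.condition_labels()
    report["conditions"] = conditions

    with _stage("covariance"):
        for cond in conditions:
            cm = condition_covariance(table, cond, scaling=cfg.cov_scaling)
            cm.to_csv(outdir / f"covariance_{_slug(cond)}.csv")
    report["stages"].append("covariance")

    with _stage("reconstruction"):
        estimates = {}
        boot_seed = int(boot_ss.generate_state(1)[0] % (2**31))
        for k, cond in enumerate(conditions):
            est = bootstrap_jacobian(
                table,
                cond,
                net,
                flu,
                B=cfg.bootstrap_B,
                seed=boot_seed + k,
                ridge=cfg.ridge,
                scaling=cfg.cov_scaling,
            )
            est.to_tsv(outdir / f"jacobian_{_slug(cond)}.tsv")
            estimates[cond] = est
    report["stages"].append("reconstruction")

    cv_seed = int(cv_ss.generate_state(1)[0] % (2**31))
    perm_seed = int(perm_ss.generate_state(1)[0] % (2**31))
    for a, b in cfg.comparisons:
        pair_key = f"{a}_vs_{b}"
        entry: dict = {}
        with _stage(f"differential[{pair_key}]"):
            if a not in estimates or b not in estimates:
                raise KeyError(f"comparison ({a!r}, {b!r}) not among conditions {conditions}")
            diff = differential_jacobian(estimates[a], estimates[b], net)
            diff.to_json(outdir / f"differential_{_slug(pair_key)}.json")
            diff.to_tsv(outdir / f"differential_{_slug(pair_key)}.tsv")
            entry["pathway_scores"] = diff.pathway_scores
            entry["top_entry"] = list(diff.top_entry())
        with _stage(f"stats[{pair_key}]"):
            model = fit_oplsda(
                table,
                classes=(a, b),
                n_ortho=cfg.n_ortho,
                cv_folds=cfg.cv_folds,
                seed=cv_seed,
            )
            model.to_json(outdir / f"opls_{_slug(pair_key)}.json")
            perm = permutation_validity(
                table, (a, b), model, n_perm=cfg.n_perm, seed=perm_seed
            )
            screen = screen_metabolites(table, [a, b], model, fc_base=cfg.fc_base)
            screen.to_tsv(outdir / f"screen_{_slug(pair_key)}.tsv")
            entry["R2Y"] = model.r2y_cum
            entry["Q2"] = model.q2_cum
            entry["permutation_valid"] = perm.valid
            entry["selected_metabolites"] = screen.selected()
        report["comparisons"][pair_key] = entry
        report["stages"].append(pair_key)

    (outdir / "run_report.json").write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    return report


def _slug(text: str) -> str:
    return "".join(c if c.isalnum() or c in "-_" else "-" for c in text)
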