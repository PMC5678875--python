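"""Reproducible simulate -> qc -> smooth -> fanova -> report runs.

A run is described by one JSON config (schema-checked before any stage
executes) holding the simulation settings, the smoothing dimension or its
candidate grid, the design (covariates with reference levels), inference
settings and four named seeds (simulation, sampling, permutation,
bootstrap).  Every stage reads its inputs from and writes its artefacts to
the run's output directory, so stages can be re-run individually; numeric
CSV output uses 6 significant digits so digests are stable across
platforms.  A manifest records the config hash, per-stage artefact
digests and wall-clock times.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fanova as fa
from . import simulate as sim
from .epochs import parse_epoch_csv, qc_days, sample_one_profile_per_child
from .smoothing import (
    DEFAULT_K_GRID,
    QuasiGlmConfig,
    SmoothedDataset,
    build_basis,
    select_k,
    smooth_dataset,
)
from .timegrid import COMMON_END, COMMON_START, DEFAULT_WINDOWS, MINUTE_GRID, parse_window

REQUIRED_SEEDS = ("simulation", "sampling", "permutation", "bootstrap")
_FLOAT_FMT = "%.6g"


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    out_dir: Path
    simulation: sim.SimulationConfig
    refs: dict[str, str]
    k: int | None = None
    k_grid: tuple[int, ...] = DEFAULT_K_GRID
    nperm: int = 199
    n_bootstrap: int = 199
    level: float = 0.95
    windows: dict[str, tuple[int, int]] = field(default_factory=lambda: dict(DEFAULT_WINDOWS))
    seeds: dict[str, int] = field(default_factory=dict)
    statistic: str = "max"
    raw: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.raw, sort_keys=True).encode()).hexdigest()[:16]

    def design_spec(self) -> fa.DesignSpec:
        return fa.DesignSpec.from_refs(self.refs)


_KNOWN_KEYS = {"out_dir", "simulation", "smoothing", "design", "inference", "seeds"}
_KNOWN_SIM_KEYS = {"n_children", "dispersion", "days_per_child", "degrade_prob", "no_effects",
                   "equal_weights"}


def validate_config(path: str | Path) -> RunConfig:
    """Load, default-fill and cross-check a run config; errors name fields."""
    with open(path) as fh:
        raw = json.load(fh)
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")

    seeds = raw.get("seeds", {})
    for name in REQUIRED_SEEDS:
        if name not in seeds:
            raise ConfigError(f"missing seed: seeds.{name}")

    sim_raw = dict(raw.get("simulation", {}))
    unknown = set(sim_raw) - _KNOWN_SIM_KEYS
    if unknown:
        raise ConfigError(f"unknown simulation key(s): {sorted(unknown)}")
    no_effects = sim_raw.pop("no_effects", False)
    equal_weights = sim_raw.pop("equal_weights", False)
    if "days_per_child" in sim_raw:
        sim_raw["days_per_child"] = tuple(sim_raw["days_per_child"])
    sim_cfg = sim.SimulationConfig(seed=int(seeds["simulation"]), **sim_raw)
    if no_effects:
        sim_cfg.effects = ()
    if equal_weights:
        sim_cfg.propensity_offsets = {}
    sim_cfg.validate()

    design = raw.get("design", {})
    refs = design.get("refs")
    if not refs:
        raise ConfigError("design.refs must map every covariate to its reference level")
    for cov in sim_cfg.covariates:
        if cov not in refs:
            raise ConfigError(f"covariate {cov!r} has no declared reference level")

    smoothing = raw.get("smoothing", {})
    k = smoothing.get("k")
    k_grid = tuple(smoothing.get("grid", DEFAULT_K_GRID))

    inference = raw.get("inference", {})
    windows = {}
    for text in inference.get("windows", [f"{a}" for a in DEFAULT_WINDOWS]):
        if text in DEFAULT_WINDOWS:
            windows[text] = DEFAULT_WINDOWS[text]
            continue
        a, b = parse_window(text)
        if a < COMMON_START or b > COMMON_END:
            raise ConfigError(f"window {text!r} outside the 08:30-19:30 domain")
        windows[text] = (a, b)

    return RunConfig(
        out_dir=Path(raw.get("out_dir", "run_output")),
        simulation=sim_cfg,
        refs=dict(refs),
        k=int(k) if k is not None else None,
        k_grid=k_grid,
        nperm=int(inference.get("nperm", 199)),
        n_bootstrap=int(inference.get("bootstrap", 199)),
        level=float(inference.get("level", 0.95)),
        windows=windows,
        seeds={k_: int(v) for k_, v in seeds.items()},
        statistic=inference.get("statistic", "max"),
        raw=raw,
    )


@dataclass
class RunManifest:
    config_hash: str
    stages: list[dict] = field(default_factory=list)

    def add(self, name: str, outputs: list[Path], seconds: float) -> None:
        self.stages.append(
            {
                "stage": name,
                "seconds": round(seconds, 3),
                "outputs": {p.name: _digest(p) for p in outputs},
            }
        )

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump({"config_hash": self.config_hash, "stages": self.stages}, fh, indent=2)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def stage_simulate(cfg: RunConfig) -> list[Path]:
    epoch_path, cov_path, _ = sim.generate_dataset(cfg.simulation, cfg.out_dir)
    return [epoch_path, cov_path, cfg.out_dir / "ground_truth.json"]


def stage_qc(cfg: RunConfig) -> list[Path]:
    series = parse_epoch_csv(cfg.out_dir / "epochs.csv")
    profiles, report = qc_days(series)
    covariates = pd.read_csv(cfg.out_dir / "covariates.csv", dtype={"child_id": str})
    dataset = sample_one_profile_per_child(profiles, covariates, cfg.seeds["sampling"])
    report_path = cfg.out_dir / "qc_report.csv"
    report.to_csv(report_path, index=False)
    mat = pd.DataFrame(dataset.profiles, columns=[f"{int(t)}" for t in MINUTE_GRID])
    mat.insert(0, "child_id", dataset.child_ids)
    profile_path = cfg.out_dir / "profiles.csv"
    mat.to_csv(profile_path, index=False, float_format=_FLOAT_FMT)
    return [report_path, profile_path]


def _load_profiles(cfg: RunConfig) -> tuple[list[str], np.ndarray]:
    mat = pd.read_csv(cfg.out_dir / "profiles.csv", dtype={"child_id": str})
    return mat["child_id"].tolist(), mat.drop(columns=["child_id"]).to_numpy(dtype=float)


def stage_smooth(cfg: RunConfig) -> list[Path]:
    ids, Y = _load_profiles(cfg)
    outputs = []
    glm = QuasiGlmConfig()
    if cfg.k is None:
        k, table = select_k(Y, cfg.k_grid, glm)
        gcv_path = cfg.out_dir / "gcv_table.csv"
        table.to_csv(gcv_path, index=False, float_format=_FLOAT_FMT)
        outputs.append(gcv_path)
    else:
        k = cfg.k
    smoothed = smooth_dataset(Y, k, glm, child_ids=ids)
    coef = pd.DataFrame(smoothed.coefficients, columns=[f"c_{j + 1}" for j in range(k)])
    coef.insert(0, "child_id", ids)
    coef["dispersion"] = smoothed.dispersions
    coef["converged"] = smoothed.converged
    coef_path = cfg.out_dir / "coefficients.csv"
    coef.to_csv(coef_path, index=False, float_format=_FLOAT_FMT)
    basis_path = cfg.out_dir / "basis.json"
    with open(basis_path, "w") as fh:
        json.dump({"k": k, "order": smoothed.basis.order, "domain": list(smoothed.basis.domain),
                   "knots": smoothed.basis.knots.tolist()}, fh)
    return outputs + [coef_path, basis_path]


def _load_smoothed(cfg: RunConfig) -> tuple[SmoothedDataset, pd.DataFrame, np.ndarray]:
    with open(cfg.out_dir / "basis.json") as fh:
        meta = json.load(fh)
    basis = build_basis(meta["k"], tuple(meta["domain"]), meta["order"])
    coef = pd.read_csv(cfg.out_dir / "coefficients.csv", dtype={"child_id": str})
    ids = coef["child_id"].tolist()
    C = coef[[f"c_{j + 1}" for j in range(meta["k"])]].to_numpy(dtype=float)
    smoothed = SmoothedDataset(
        basis=basis,
        child_ids=ids,
        coefficients=C,
        dispersions=coef["dispersion"].to_numpy(dtype=float),
        converged=coef["converged"].to_numpy(dtype=bool),
    )
    covariates = pd.read_csv(cfg.out_dir / "covariates.csv", dtype={"child_id": str})
    covariates = covariates.set_index("child_id").loc[ids].reset_index()
    weights = covariates["weight"].to_numpy(dtype=float)
    return smoothed, covariates, weights


def stage_fanova(cfg: RunConfig) -> list[Path]:
    smoothed, covariates, weights = _load_smoothed(cfg)
    spec = cfg.design_spec()

    # univariable permutation screen, one test per covariate
    perms = {}
    for i, (cov, ref) in enumerate(cfg.refs.items()):
        single = fa.DesignSpec.from_refs({cov: ref})
        res = fa.permutation_F_test(
            smoothed, covariates, single, cfg.nperm, cfg.seeds["permutation"] + i,
            weights, cfg.statistic,
        )
        perms[cov] = {"statistic": res.observed, "p_value": res.p_value,
                      "nperm": res.n_permutations, "seed": res.seed,
                      "statistic_kind": res.statistic}
    perm_path = cfg.out_dir / "permutation.json"
    with open(perm_path, "w") as fh:
        json.dump(perms, fh, indent=2)

    # multivariable fit with bootstrap bands
    boot = fa.bootstrap_ci(smoothed, covariates, spec, cfg.n_bootstrap,
                           cfg.seeds["bootstrap"], weights, cfg.level)
    table, curves = fa.report_tables(boot.fit, boot, cfg.windows, spec, covariates)
    curves_path = cfg.out_dir / "contrast_curves.csv"
    curves.to_csv(curves_path, index=False, float_format=_FLOAT_FMT)

    rows = []
    full = (float(COMMON_START), float(COMMON_END))
    for label in boot.fit.contrast_labels():
        cov, level = label.split("=", 1)
        for name, win in {"full-day": full, **cfg.windows}.items():
            est, lo, hi = boot.window_ci(label, win)
            rows.append((cov, level, name, est, lo, hi))
    summary = pd.DataFrame(rows, columns=["covariate", "level", "window", "estimate", "lower", "upper"])
    summary_path = cfg.out_dir / "window_summary.csv"
    summary.to_csv(summary_path, index=False, float_format=_FLOAT_FMT)

    table_path = cfg.out_dir / "coefficient_table.csv"
    table.to_csv(table_path, index=False)
    return [perm_path, curves_path, summary_path, table_path]


def stage_report(cfg: RunConfig) -> list[Path]:
    smoothed, _, weights = _load_smoothed(cfg)
    mean_coef = fa.functional_mean(smoothed, weights)
    curve = smoothed.basis.evaluate(MINUTE_GRID) @ mean_coef
    mean_path = cfg.out_dir / "mean_curve.csv"
    pd.DataFrame({"minute": MINUTE_GRID.astype(int), "mean_counts_per_min": curve}).to_csv(
        mean_path, index=False, float_format=_FLOAT_FMT
    )
    return [mean_path]


STAGES = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "smooth": stage_smooth,
    "fanova": stage_fanova,
    "report": stage_report,
}


def run_pipeline(cfg: RunConfig, stages=tuple(STAGES)) -> RunManifest:
    """Execute the requested stages in order and write the run manifest."""
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=cfg.config_hash())
    for name in stages:
        start = time.perf_counter()
        outputs = STAGES[name](cfg)
        manifest.add(name, outputs, time.perf_counter() - start)
    manifest.write(cfg.out_dir / "manifest.json")
    return manifest
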