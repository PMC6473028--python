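"""End-to-end pipeline: config validation, stage orchestration, report bundle.

The pipeline runs, per group: partial-correlation matrix, sparsity sweep,
graph-metric curves and hub tables; per group pair: permutation comparison
and seed-correlation statistics; per group: hemispheric asymmetry.  All
intermediates are plain delimited text or JSON so every stage can be
re-derived and diffed independently.  A master seed propagates
deterministically to every stochastic stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .asymmetry import compare_ai_between_groups, within_group_test
from .compare import METRICS, permutation_test
from .metrics import hub_table, metric_curve
from .network import default_sparsity_grid, partial_correlation, sparsity_sweep
from .roi_io import AtlasDefinition, RoiSignalTable, default_atlas, load_atlas, read_roi_table
from .seed import DEFAULT_SEED_ROI, seed_comparison_table
from .synthetic import default_cohort_config, generate_cohort, write_cohort

__all__ = ["PipelineConfig", "validate_config", "load_config", "run_pipeline"]

log = logging.getLogger("metabnet")


@dataclass
class PipelineConfig:
    """Validated settings for a full run."""

    tables: dict[str, str]  # group label -> table path
    out_dir: str = "metabnet_out"
    atlas_path: str | None = None
    covariates: list[str] = field(default_factory=lambda: ["age", "sex"])
    sparsity_min: float = 0.06
    sparsity_max: float = 0.40
    sparsity_step: float = 0.01
    null_model_n: int = 100
    null_model_swaps: float = 10.0
    permutation_n: int = 1000
    permutation_metrics: list[str] = field(default_factory=lambda: ["C", "L", "Eglob", "Eloc"])
    permutation_null_model_n: int = 20
    alpha: float = 0.05
    seed_roi: str = DEFAULT_SEED_ROI
    fdr_q: float = 0.05
    hub_sparsity: float = 0.28
    asymmetry_sparsity: float = 0.28
    asymmetry_n_rep: int = 1000
    master_seed: int = 0
    include_small_world_curves: bool = True

    def grid(self) -> np.ndarray:
        return default_sparsity_grid(self.sparsity_min, self.sparsity_max, self.sparsity_step)


_FIELD_TYPES = {
    "out_dir": str, "atlas_path": (str, type(None)), "covariates": list,
    "sparsity_min": float, "sparsity_max": float, "sparsity_step": float,
    "null_model_n": int, "null_model_swaps": float, "permutation_n": int,
    "permutation_metrics": list, "permutation_null_model_n": int,
    "alpha": float, "seed_roi": str, "fdr_q": float, "hub_sparsity": float,
    "asymmetry_sparsity": float, "asymmetry_n_rep": int, "master_seed": int,
    "include_small_world_curves": bool,
}


def validate_config(raw: dict[str, Any]) -> tuple[PipelineConfig | None, list[str]]:
    """Validate a raw config mapping; all errors are collected, not first-failure."""
    errors: list[str] = []
    tables = raw.get("tables")
    if not isinstance(tables, dict) or not tables:
        errors.append("'tables' must map group labels to table paths")
        tables = {}
    for label, path in tables.items():
        if not Path(str(path)).exists():
            errors.append(f"table for group {label!r} not found: {path}")
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key == "tables":
            continue
        if key not in _FIELD_TYPES:
            errors.append(f"unknown config key {key!r}")
            continue
        want = _FIELD_TYPES[key]
        if want is float and isinstance(value, int):
            value = float(value)
        if not isinstance(value, want):
            errors.append(f"config key {key!r} has wrong type {type(value).__name__}")
            continue
        kwargs[key] = value
    cfg = PipelineConfig(tables={str(k): str(v) for k, v in tables.items()}, **kwargs)
    if cfg.sparsity_min > cfg.sparsity_max:
        errors.append(f"sparsity.min {cfg.sparsity_min} > sparsity.max {cfg.sparsity_max}")
    if not (0 < cfg.sparsity_step <= cfg.sparsity_max - cfg.sparsity_min + 1e-12):
        errors.append(f"invalid sparsity.step {cfg.sparsity_step}")
    if cfg.atlas_path is not None and not Path(cfg.atlas_path).exists():
        errors.append(f"atlas file not found: {cfg.atlas_path}")
    if not 0 < cfg.alpha < 1:
        errors.append(f"alpha must be in (0, 1), got {cfg.alpha}")
    if len(cfg.tables) < 1:
        errors.append("at least one group table is required")
    return (None, errors) if errors else (cfg, [])


def load_config(path: str | Path) -> tuple[PipelineConfig | None, list[str]]:
    """Parse a YAML/JSON config file and validate it."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        return None, [f"{path}: config must be a mapping"]
    return validate_config(raw)


def _write_matrix(values: np.ndarray, names: list[str], path: Path) -> None:
    pd.DataFrame(values, index=names, columns=names).to_csv(path)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.time()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.1fs", name, time.time() - t0)
            return out
        return inner
    return wrap


def simulate_stage(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Generate the bundled four-group synthetic cohort and write it out."""
    result = generate_cohort(default_cohort_config(seed=seed))
    write_cohort(result, out_dir)
    return {g: Path(out_dir) / f"cohort_{g}.csv" for g in result.tables}


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage; returns the manifest (also written to the output dir).

    Any stage failure aborts with the stage name in the exception message;
    the manifest written so far is flagged incomplete.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas = load_atlas(config.atlas_path) if config.atlas_path else default_atlas()
    grid = config.grid()
    seed_seq = np.random.SeedSequence(config.master_seed)
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ("curves", "permutation", "asymmetry"), seed_seq.spawn(3)
        )
    }
    manifest: dict[str, Any] = {
        "version": __version__,
        "master_seed": config.master_seed,
        "stage_seeds": stage_seeds,
        "config_hash": hashlib.sha256(
            json.dumps(config.__dict__, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "complete": False,
        "outputs": {},
    }

    tables: dict[str, RoiSignalTable] = _stage("load")(
        lambda: {g: read_roi_table(p, atlas) for g, p in config.tables.items()}
    )()
    groups = list(tables)

    @_stage("networks")
    def networks():
        matrices, stacks = {}, {}
        for g, tab in tables.items():
            pc = partial_correlation(tab, config.covariates, group_label=g)
            matrices[g] = pc
            stacks[g] = sparsity_sweep(pc, grid)
            _write_matrix(pc.values, pc.roi_names, out / f"pcorr_{g}.csv")
        return matrices, stacks

    matrices, stacks = networks()
    manifest["outputs"]["pcorr"] = [f"pcorr_{g}.csv" for g in groups]

    @_stage("curves")
    def curves():
        frames = []
        for k, g in enumerate(groups):
            frames.append(metric_curve(
                stacks[g], n_null=config.null_model_n,
                swaps_per_edge=config.null_model_swaps,
                seed=stage_seeds["curves"] + k,
                include_small_world=config.include_small_world_curves,
            ))
        df = pd.concat(frames, ignore_index=True)
        df.to_csv(out / "metric_curves.csv", index=False)
        return df

    curves()
    manifest["outputs"]["curves"] = "metric_curves.csv"

    @_stage("hubs")
    def hubs():
        frames = []
        for g in groups:
            adj = stacks[g][round(config.hub_sparsity, 10)] if round(
                config.hub_sparsity, 10
            ) in stacks[g].adjacency else None
            if adj is None:
                from .network import binarize_at_sparsity
                adj = binarize_at_sparsity(matrices[g], config.hub_sparsity)
            ht = hub_table(adj, atlas.abbreviations)
            ht.insert(0, "group", g)
            frames.append(ht)
        df = pd.concat(frames, ignore_index=True)
        df.to_csv(out / "hubs.csv", index=False)
        return df

    hub_df = hubs()
    manifest["outputs"]["hubs"] = "hubs.csv"
    manifest["hub_counts"] = {
        g: int(hub_df.loc[hub_df["group"] == g, "hub"].sum()) for g in groups
    }

    @_stage("permutation")
    def permutations():
        rows, ranges = [], {}
        for k, (ga, gb) in enumerate(combinations(groups, 2)):
            for j, metric in enumerate(config.permutation_metrics):
                if metric not in METRICS:
                    raise ValueError(f"unknown permutation metric {metric!r}")
                res = permutation_test(
                    tables[ga], tables[gb], metric=metric, grid=grid,
                    n_perm=config.permutation_n, alpha=config.alpha,
                    seed=stage_seeds["permutation"] + 97 * k + j,
                    covariates=config.covariates,
                    null_model_n=config.permutation_null_model_n,
                )
                df = res.to_frame()
                df.insert(0, "group_pair", f"{ga}_vs_{gb}")
                rows.append(df)
                ranges[f"{ga}_vs_{gb}:{metric}"] = res.significant_ranges
        pd.concat(rows, ignore_index=True).to_csv(out / "permutation.csv", index=False)
        (out / "significant_ranges.json").write_text(json.dumps(ranges, indent=1))
        return ranges

    if config.permutation_metrics and len(groups) > 1:
        manifest["significant_ranges"] = permutations()
        manifest["outputs"]["permutation"] = ["permutation.csv", "significant_ranges.json"]

    @_stage("seed_map")
    def seed_maps():
        frames = []
        for ga, gb in combinations(groups, 2):
            df = seed_comparison_table(
                tables[ga], tables[gb], seed_roi=config.seed_roi,
                q_level=config.fdr_q, group_labels=(ga, gb),
            )
            frames.append(df.reset_index())
        df = pd.concat(frames, ignore_index=True)
        df.to_csv(out / "seed_correlation.csv", index=False)
        return df

    if len(groups) > 1:
        seed_df = seed_maps()
        manifest["outputs"]["seed"] = "seed_correlation.csv"
        manifest["seed_roi"] = config.seed_roi
        manifest["seed_significant"] = {
            gp: int(sub["significant"].sum())
            for gp, sub in seed_df.groupby("group_pair")
        }

    @_stage("asymmetry")
    def asymmetry():
        results = {}
        frames = []
        for k, g in enumerate(groups):
            res = within_group_test(
                tables[g], atlas, config.covariates,
                sparsity=config.asymmetry_sparsity,
                n_rep=config.asymmetry_n_rep,
                seed=stage_seeds["asymmetry"] + k, alpha=config.alpha,
            )
            results[g] = res
            frames.append(res.to_frame())
            res.distributions["Eglob"].assign(metric="Eglob").to_csv(
                out / f"asymmetry_boot_{g}.csv", index=False
            )
        pd.concat(frames, ignore_index=True).to_csv(out / "asymmetry.csv", index=False)
        return results

    asym = asymmetry()
    manifest["outputs"]["asymmetry"] = "asymmetry.csv"
    manifest["asymmetry"] = {
        g: {
            "AI_global": asym[g].ai["Eglob"], "AI_local": asym[g].ai["Eloc"],
            "direction_global": asym[g].direction["Eglob"],
            "p_within_global": asym[g].p_within["Eglob"],
        }
        for g in groups
    }
    if "HC" in asym:
        ai_t = {}
        for g in groups:
            if g == "HC":
                continue
            t, p = compare_ai_between_groups(asym[g], asym["HC"])
            ai_t[f"{g}_vs_HC"] = {"t": t, "p": p}
        manifest["ai_vs_hc"] = ai_t

    manifest["complete"] = True
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=float))
    return manifest
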