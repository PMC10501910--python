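"""Pipeline orchestration: simulate -> extract -> fit -> report.

Stage outputs are plain CSV/JSON/NIfTI files under one output directory;
a run manifest records seeds, stage wall-clock and checksums of every
tabular output so reruns can be compared byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .extraction import (
    adjust_volumes,
    analysis_values,
    build_ratio_table,
    hemisphere_average,
    mask_set_for_region,
    read_masks,
    read_volume_dir,
)
from .models import (
    StudyDesign,
    build_cognitive_model,
    build_modality_factor_model,
    build_neurocognitive_model,
    run_reported_comparisons,
)
from .sem import ObservedDataset, fit_indices, fit_model
from .synthetic import SimulationConfig, simulate_cohort

log = logging.getLogger(__name__)

STAGES = ("simulate", "extract", "fit", "report")


class DependencyError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    outdir: Path
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        # one top-level seed derives every stage seed
        self.simulation.seed = self.seed

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        sim = SimulationConfig.from_dict(d.get("simulation", {}))
        cfg = cls(
            outdir=Path(d.get("outdir", "pipeline_out")),
            simulation=sim,
            stages=tuple(d.get("stages", STAGES)),
            seed=d.get("seed", sim.seed),
            log_level=d.get("log_level", "INFO"),
        )
        if seed is not None:
            cfg.seed = seed
            cfg.simulation.seed = seed
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# -- data wiring --------------------------------------------------------------


def wide_neural(ratio_table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the ratio table to participant x `<region>_<mod>_<hemi>_tp<k>`."""
    src = analysis_values(ratio_table).copy()
    src["column"] = (
        src["region"] + "_" + src["modality"] + "_" + src["hemisphere"]
        + "_tp" + src["timepoint"].astype(int).astype(str)
    )
    return src.pivot_table(
        index="participant", columns="column", values="value", aggfunc="first"
    )


def wide_neural_avg(ratio_table: pd.DataFrame) -> pd.DataFrame:
    """Hemisphere-averaged pivot: participant x `<region>_<mod>_tp<k>`."""
    avg = hemisphere_average(ratio_table)
    avg["column"] = (
        avg["region"] + "_" + avg["modality"]
        + "_tp" + avg["timepoint"].astype(int).astype(str)
    )
    return avg.pivot_table(
        index="participant", columns="column", values="value", aggfunc="first"
    )


def wide_cognitive(cognitive: pd.DataFrame) -> pd.DataFrame:
    """Pivot cognitive scores to participant x `<task>_tp<k>` (+ group, age)."""
    src = cognitive.copy()
    src["column"] = src["task"] + "_tp" + src["timepoint"].astype(int).astype(str)
    wide = src.pivot_table(
        index="participant", columns="column", values="score", aggfunc="first"
    )
    meta = src.groupby("participant")[["group", "age"]].first()
    return wide.join(meta)


def assemble_dataset(
    spec_observed: list[str],
    wide: pd.DataFrame,
    groups: list[str],
    group_col: str | None = "group",
) -> ObservedDataset:
    """Build an ObservedDataset for a model from a wide participant table."""
    cols = {}
    for v in spec_observed:
        cols[v] = wide[v] if v in wide.columns else np.nan
    frame = pd.DataFrame(cols, index=wide.index)
    if group_col and group_col in wide.columns and len(groups) > 1:
        labels = wide[group_col].to_numpy()
    else:
        labels = np.array([groups[0]] * len(wide))
    keep = np.isin(labels, groups)
    return ObservedDataset(
        frame.to_numpy()[keep], spec_observed, labels[keep], groups
    )


# -- stages -------------------------------------------------------------------


def stage_simulate(config: PipelineConfig) -> dict:
    cohort = simulate_cohort(config.simulation)
    cohort.to_directory(config.outdir / "data")
    return {
        "n_participants": config.simulation.n_total,
        "n_volumes": len(cohort.volumes),
    }


def stage_extract(config: PipelineConfig) -> dict:
    data_dir = config.outdir / "data"
    if not (data_dir / "volumes").exists():
        raise DependencyError("extract requires the simulate stage outputs")
    volumes = read_volume_dir(data_dir / "volumes")
    masks = read_masks(data_dir / "masks")
    mask_sets = {r: mask_set_for_region(masks, r) for r in ("lc", "snvta")}
    table = build_ratio_table(volumes, mask_sets)
    table.to_csv(config.outdir / "ratios.csv", index=False)
    avg = hemisphere_average(table)
    avg.to_csv(config.outdir / "ratios_hemiavg.csv", index=False)
    vols = pd.read_csv(data_dir / "roi_volumes.csv")
    adjust_volumes(vols).to_csv(config.outdir / "volumes_adjusted.csv", index=False)
    return {"n_rows": len(table)}


def stage_fit(config: PipelineConfig) -> dict:
    ratios_path = config.outdir / "ratios.csv"
    cog_path = config.outdir / "data" / "cognitive.csv"
    if not ratios_path.exists() or not cog_path.exists():
        raise DependencyError("fit requires the extract stage outputs")
    ratios = pd.read_csv(ratios_path)
    cognitive = pd.read_csv(cog_path)
    neural = wide_neural(ratios)
    cog_wide = wide_cognitive(cognitive)
    wide = cog_wide.join(neural, how="outer")
    design = StudyDesign()
    fits = {}
    fitdir = config.outdir / "fits"
    fitdir.mkdir(exist_ok=True)
    groups = list(design.groups)
    for region in design.regions:
        spec = build_modality_factor_model(region, 2, design, tuple(groups))
        ds = assemble_dataset(spec.observed, wide, groups)
        fits[f"modality_{region}"] = (spec, fit_model(spec, ds, seed=config.seed), ds)
    spec = build_cognitive_model(2, design, tuple(groups))
    ds = assemble_dataset(spec.observed, wide, groups)
    fits["cognitive"] = (spec, fit_model(spec, ds, seed=config.seed), ds)
    spec = build_neurocognitive_model("regression", 2, design, groups=("older",))
    ds = assemble_dataset(spec.observed, wide[wide["group"] == "older"], ["older"])
    fits["neurocognitive_regression"] = (
        spec, fit_model(spec, ds, seed=config.seed), ds
    )
    summary = {}
    for name, (spec, fit, ds) in fits.items():
        payload = fit.to_dict()
        if fit.converged:
            if min(ds.group_sizes().values()) > len(spec.observed):
                payload["fit_indices"] = fit_indices(fit, ds).to_dict()
            else:
                log.warning(
                    "fit %s: too few cases for a saturated model; "
                    "fit indices skipped", name,
                )
        else:
            log.warning("fit %s did not converge: %s", name, fit.message)
        with open(fitdir / f"{name}.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        spec.to_json(fitdir / f"{name}.spec.json")
        summary[name] = bool(fit.converged)
    # stash the dataset needed by the report stage
    wide.to_csv(config.outdir / "wide_dataset.csv")
    return {"converged": summary}


def stage_report(config: PipelineConfig) -> dict:
    fitdir = config.outdir / "fits"
    spec_path = fitdir / "neurocognitive_regression.spec.json"
    wide_path = config.outdir / "wide_dataset.csv"
    if not spec_path.exists() or not wide_path.exists():
        raise DependencyError("report requires the fit stage outputs")
    from .sem.model import ModelSpec

    spec = ModelSpec.from_json(spec_path)
    wide = pd.read_csv(wide_path, index_col=0)
    ds = assemble_dataset(
        spec.observed, wide[wide["group"] == "older"], list(spec.groups)
    )
    fit = fit_model(spec, ds, seed=config.seed)
    report = run_reported_comparisons(fit, ds, seed=config.seed)
    report.to_json(config.outdir / "report.json")
    (config.outdir / "report.txt").write_text(report.to_text() + "\n")
    return {"n_comparisons": len(report.rows)}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "extract": stage_extract,
    "fit": stage_fit,
    "report": stage_report,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages in order; returns the run manifest."""
    logging.basicConfig(level=config.log_level)
    config.outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {
            "seed": config.seed,
            "stages": list(config.stages),
            "simulation": config.simulation.to_dict(),
        },
        "stages": {},
        "checksums": {},
        "status": "ok",
    }
    try:
        for stage in config.stages:
            if stage not in _STAGE_FUNCS:
                raise ValueError(f"unknown stage {stage!r}")
            t0 = time.time()
            info = _STAGE_FUNCS[stage](config)
            manifest["stages"][stage] = {
                "wall_clock_s": round(time.time() - t0, 3),
                **info,
            }
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failure"] = {"stage": stage, "error": str(exc)}
        _write_manifest(config, manifest)
        raise
    for path in sorted(config.outdir.rglob("*")):
        if path.suffix in (".csv", ".json", ".txt") and path.name != "manifest.json":
            manifest["checksums"][str(path.relative_to(config.outdir))] = _sha256(path)
    _write_manifest(config, manifest)
    return manifest


def _write_manifest(config: PipelineConfig, manifest: dict) -> None:
    tmp = config.outdir / "manifest.json.tmp"
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    tmp.replace(config.outdir / "manifest.json")


def make_fixtures(size: str, outdir: Path, seed: int = 0) -> Path:
    """Write a small synthetic bundle through the standard writers."""
    if size == "tiny":
        sim = SimulationConfig(n_young=6, n_old=6, grid_shape=(16, 16, 16), seed=seed)
    elif size == "demo":
        sim = SimulationConfig(n_young=30, n_old=30, seed=seed)
    else:
        raise ValueError(f"unknown fixture size {size!r}")
    cohort = simulate_cohort(sim)
    outdir = Path(outdir)
    cohort.to_directory(outdir)
    return outdir
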