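"""Synthetic multimodal cohort with fully known latent ground truth.

Each participant owns named random substreams (keyed by the master seed
and their index), so enlarging the cohort never perturbs earlier
participants.  Nucleus voxels are rendered multiplicatively around the
reference mean, which makes the noiseless extracted ratio an exact
affine function of the latent integrity score:
``ratio = roi_offset + gain * latent``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..extraction.volumes import BrainVolume, MaskSet
from .config import (
    COGNITIVE,
    CONSTRUCTS,
    ConfigError,
    SimulationConfig,
)

VOLUME_KEYS = ("participant", "modality", "timepoint", "acquisition")


class GenerationError(ValueError):
    pass


def _participant_rng(seed: int, index: int, tag: int) -> np.random.Generator:
    return np.random.default_rng([seed, tag, index])


@dataclass
class GroundTruth:
    """Latent scores and true task scores per participant and timepoint."""

    latents: pd.DataFrame          # participant, group, age, <construct>_tp<k>
    task_scores: pd.DataFrame      # participant, task, timepoint, true_score
    config_echo: dict = field(default_factory=dict)

    def latent(self, participant: str, construct: str, timepoint: int) -> float:
        row = self.latents.loc[self.latents["participant"] == participant]
        return float(row[f"{construct}_tp{timepoint}"].iloc[0])


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    truth: GroundTruth
    volumes: dict[tuple[str, str, int, int], np.ndarray]
    masks: dict[str, np.ndarray]
    cognitive: pd.DataFrame
    roi_volumes: pd.DataFrame

    def brain_volumes(self) -> list[BrainVolume]:
        return [
            BrainVolume(arr, modality=mod, participant=pid, timepoint=tp,
                        acquisition=acq)
            for (pid, mod, tp, acq), arr in sorted(self.volumes.items())
        ]

    def mask_sets(self) -> dict[str, MaskSet]:
        vent = self.masks.get("ventricle")
        return {
            "lc": MaskSet(self.masks["lc_left"], self.masks["lc_right"],
                          self.masks["pons_ref"], vent, region="lc"),
            "snvta": MaskSet(self.masks["snvta_left"], self.masks["snvta_right"],
                             self.masks["crus_ref"], vent, region="snvta"),
        }

    def to_directory(self, path: Path) -> None:
        from ..extraction.io import save_volume

        path = Path(path)
        (path / "volumes").mkdir(parents=True, exist_ok=True)
        (path / "masks").mkdir(parents=True, exist_ok=True)
        for (pid, mod, tp, acq), arr in sorted(self.volumes.items()):
            name = f"sub-{pid}_tp-{tp}_mod-{mod}"
            if mod == "fse":
                name += f"_acq-{acq}"
            save_volume(path / "volumes" / f"{name}.nii.gz", arr)
        for name, mask in self.masks.items():
            save_volume(path / "masks" / f"{name}.nii.gz",
                        mask.astype(np.uint8))
        self.cognitive.to_csv(path / "cognitive.csv", index=False)
        self.roi_volumes.to_csv(path / "roi_volumes.csv", index=False)
        self.truth.latents.to_csv(path / "truth_latents.csv", index=False)
        self.truth.task_scores.to_csv(path / "truth_tasks.csv", index=False)
        import json

        with open(path / "config.json", "w") as fh:
            json.dump(self.config.to_dict(), fh, indent=2)


# -- ground truth -------------------------------------------------------------


def generate_ground_truth(config: SimulationConfig) -> GroundTruth:
    config.validate()
    rows = []
    groups = ["younger"] * config.n_young + ["older"] * config.n_old
    ranges = {
        "younger": config.age_range_young,
        "older": config.age_range_old,
    }
    for i, group in enumerate(groups):
        rng = _participant_rng(config.seed, i, tag=1)
        lo, hi = ranges[group]
        age = float(rng.uniform(lo, hi))
        gm = config.factor_moments[group]
        tp1 = rng.multivariate_normal(gm.means, gm.covariance,
                                      method="cholesky")
        row: dict = {
            "participant": f"p{i:04d}",
            "group": group,
            "age": age,
        }
        level = dict(zip(CONSTRUCTS, tp1))
        age_centre = 0.5 * (lo + hi)
        base_var = dict(zip(CONSTRUCTS, np.diag(gm.covariance)))
        base_mean = dict(zip(CONSTRUCTS, gm.means))
        for c in CONSTRUCTS:
            row[f"{c}_tp1"] = level[c]
        for tp in (2, 3):
            for c in CONSTRUCTS:
                ch = config.change_model[c]
                vb = max(base_var[c], 1e-12)
                slope = ch.cov_baseline / vb
                resid_var = max(ch.variance - ch.cov_baseline**2 / vb, 0.0)
                delta = (
                    ch.mean
                    + ch.age_slope * (age - age_centre)
                    + slope * (row[f"{c}_tp{tp-1}"] - base_mean[c])
                    + rng.normal(0.0, np.sqrt(resid_var))
                )
                row[f"{c}_tp{tp}"] = row[f"{c}_tp{tp-1}"] + delta
        rows.append(row)
    latents = pd.DataFrame(rows)
    task_rows = []
    for _, row in latents.iterrows():
        tps = (1, 2) if row["group"] == "younger" else (1, 2, 3)
        for task, (factor, loading, intercept, _sd) in config.cognitive_loadings.items():
            for tp in tps:
                task_rows.append(
                    {
                        "participant": row["participant"],
                        "task": task,
                        "timepoint": tp,
                        "true_score": intercept + loading * row[f"{factor}_tp{tp}"],
                    }
                )
    return GroundTruth(latents, pd.DataFrame(task_rows), config.to_dict())


# -- volume rendering ---------------------------------------------------------


def render_participant_volumes(
    truth_row: pd.Series,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> dict[tuple[str, int, int], np.ndarray]:
    """Noisy multimodal volumes for one participant.

    Returns a dict keyed (modality, timepoint, acquisition).  FSE exists
    at TP2 only, as two acquisitions sharing the truth but not the noise.
    """
    masks = config.masks()
    shape = tuple(config.grid_shape)
    out = {}
    cells = [("mtplus", 1, 1), ("mtminus", 1, 1), ("mtplus", 2, 1),
             ("mtminus", 2, 1), ("fse", 2, 1), ("fse", 2, 2)]
    for mod, tp, acq in cells:
        mp = config.modality_params[mod]
        noiseless = np.full(shape, config.background_level * mp.ref_mean)
        noiseless[masks["pons_ref"]] = mp.ref_mean
        noiseless[masks["crus_ref"]] = mp.ref_mean
        for region, roi_names in (
            ("lc", ("lc_left", "lc_right")),
            ("snvta", ("snvta_left", "snvta_right")),
        ):
            latent = float(truth_row[f"{region}_tp{tp}"])
            if not np.isfinite(latent):
                raise GenerationError(
                    f"non-finite latent {region!r} for participant "
                    f"{truth_row['participant']!r}"
                )
            level = mp.ref_mean * (1.0 + mp.roi_offset + mp.gain * latent)
            for name in roi_names:
                noiseless[masks[name]] = level
        if config.ventricle_enabled and mod in ("mtplus", "mtminus"):
            noiseless[masks["ventricle"]] = config.ventricle_brightness * mp.ref_mean
        noisy = noiseless + rng.normal(0.0, mp.noise_sd, size=shape)
        out[(mod, tp, acq)] = np.clip(noisy, 0.0, None)
    return out


# -- cognitive scores ---------------------------------------------------------


def generate_cognitive_scores(
    truth: GroundTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Observed task scores: intercept + loading x factor + residual.

    Younger adults contribute no TP3 rows (tested at TP1 and TP2 only).
    """
    for task, (factor, *_rest) in config.cognitive_loadings.items():
        if factor not in COGNITIVE:
            raise ConfigError(f"task {task!r} mapped to unknown factor {factor!r}")
    residual_sd = {t: v[3] for t, v in config.cognitive_loadings.items()}
    index_of = {pid: i for i, pid in enumerate(truth.latents["participant"])}
    table = truth.task_scores.sort_values(
        ["participant", "timepoint", "task"], ignore_index=True
    )
    # one named noise substream per participant, in participant order
    counts = table.groupby("participant", sort=False).size()
    noise = np.concatenate(
        [
            _participant_rng(config.seed, index_of[pid], tag=2).normal(0.0, 1.0, k)
            for pid, k in counts.items()
        ]
    )
    meta = truth.latents.set_index("participant")[["group", "age"]]
    out = table.merge(meta, left_on="participant", right_index=True)
    out["score"] = (
        out["true_score"] + out["task"].map(residual_sd).to_numpy() * noise
    )
    out["timepoint"] = out["timepoint"].astype(int)
    return out[["participant", "group", "age", "task", "timepoint", "score"]]


# -- regional volumes ---------------------------------------------------------

_VBM_BASE = {"hippocampus": 4.0, "parahippocampus": 2.5}


def generate_roi_volumes(truth: GroundTruth, config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for i, row in truth.latents.iterrows():
        rng = _participant_rng(config.seed, i, tag=3)
        tiv = max(float(rng.normal(1500.0, 80.0)), 500.0)
        for region, base in _VBM_BASE.items():
            for hemisphere in ("left", "right"):
                raw = base * (1.0 + 0.08 * row["mtl_tp1"]) + rng.normal(0.0, 0.12)
                rows.append(
                    {
                        "participant": row["participant"],
                        "region": region,
                        "hemisphere": hemisphere,
                        "raw_volume": max(raw, 0.05),
                        "tiv": tiv,
                    }
                )
    return pd.DataFrame(rows)


# -- missingness --------------------------------------------------------------


def inject_missingness(
    cohort: SyntheticCohort, config: SimulationConfig
) -> SyntheticCohort:
    """MCAR removal of volumes per (participant, modality, timepoint).

    Structural rules are untouched: FSE never appears at TP1 and the
    ground truth is never altered.
    """
    index_of = {
        pid: i for i, pid in enumerate(cohort.truth.latents["participant"])
    }
    keep: dict[tuple[str, str, int, int], np.ndarray] = {}
    decisions: dict[tuple[str, str, int], bool] = {}
    for (pid, mod, tp, acq), arr in cohort.volumes.items():
        cell = (pid, mod, tp)
        if cell not in decisions:
            p = config.availability.get((mod, tp), 1.0)
            if p >= 1.0:
                decisions[cell] = True
            elif p <= 0.0:
                decisions[cell] = False
            else:
                rng = _participant_rng(config.seed, index_of[pid], tag=4)
                # one uniform per (modality, timepoint) cell, ordered
                order = sorted(
                    {(m, t) for (_p, m, t, _a) in cohort.volumes if _p == pid}
                )
                draws = rng.random(len(order))
                for (m, t), u in zip(order, draws):
                    pp = config.availability.get((m, t), 1.0)
                    decisions[(pid, m, t)] = bool(u < pp)
        if decisions[cell]:
            keep[(pid, mod, tp, acq)] = arr
    return SyntheticCohort(
        config=cohort.config,
        truth=cohort.truth,
        volumes=keep,
        masks=cohort.masks,
        cognitive=cohort.cognitive,
        roi_volumes=cohort.roi_volumes,
    )


# -- top level ----------------------------------------------------------------


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Deterministic cohort generation from a validated configuration."""
    config.validate()
    truth = generate_ground_truth(config)
    volumes: dict[tuple[str, str, int, int], np.ndarray] = {}
    for i, (_, row) in enumerate(truth.latents.iterrows()):
        rng = _participant_rng(config.seed, i, tag=0)
        rendered = render_participant_volumes(row, config, rng)
        for (mod, tp, acq), arr in rendered.items():
            volumes[(row["participant"], mod, tp, acq)] = arr
    cohort = SyntheticCohort(
        config=config,
        truth=truth,
        volumes=volumes,
        masks=config.masks(),
        cognitive=generate_cognitive_scores(truth, config),
        roi_volumes=generate_roi_volumes(truth, config),
    )
    if any(p < 1.0 for p in config.availability.values()):
        cohort = inject_missingness(cohort, config)
    return cohort
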