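"""NIfTI readers/writers and cohort-level ratio-table assembly."""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable

import nibabel as nib
import numpy as np
import pandas as pd

from .tables import RATIO_COLUMNS, clean_and_scale
from .volumes import (
    BrainVolume,
    ExtractionError,
    MaskSet,
    apply_exclusion,
    average_fse_acquisitions,
    extract_peak_ratio,
)

log = logging.getLogger(__name__)

VOLUME_PATTERN = re.compile(
    r"sub-(?P<sub>[A-Za-z0-9]+)_tp-(?P<tp>\d+)_mod-(?P<mod>mtplus|mtminus|fse)"
    r"(?:_acq-(?P<acq>\d+))?\.nii(?:\.gz)?$"
)

MASK_FILES = {
    "lc_left", "lc_right", "snvta_left", "snvta_right",
    "pons_ref", "crus_ref", "ventricle",
}

REGION_MASKS = {
    "lc": ("lc_left", "lc_right", "pons_ref"),
    "snvta": ("snvta_left", "snvta_right", "crus_ref"),
}


def save_volume(path: Path, data: np.ndarray, affine: np.ndarray | None = None):
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32),
                          np.eye(4) if affine is None else affine)
    nib.save(img, str(path))


def load_array(path: Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata(), dtype=float)


def read_volume_dir(directory: Path) -> list[BrainVolume]:
    """Read every volume matching the cohort filename pattern."""
    volumes = []
    for path in sorted(Path(directory).iterdir()):
        m = VOLUME_PATTERN.match(path.name)
        if not m:
            continue
        volumes.append(
            BrainVolume(
                load_array(path),
                modality=m["mod"],
                participant=m["sub"],
                timepoint=int(m["tp"]),
                acquisition=int(m["acq"] or 1),
            )
        )
    return volumes


def read_masks(directory: Path) -> dict[str, np.ndarray]:
    directory = Path(directory)
    masks = {}
    for name in MASK_FILES:
        for suffix in (".nii.gz", ".nii"):
            path = directory / f"{name}{suffix}"
            if path.exists():
                masks[name] = load_array(path) > 0.5
                break
    return masks


def mask_set_for_region(masks: dict[str, np.ndarray], region: str) -> MaskSet:
    left, right, ref = REGION_MASKS[region]
    missing = [k for k in (left, right, ref) if k not in masks]
    if missing:
        raise ValueError(f"missing masks for region {region!r}: {missing}")
    return MaskSet(
        roi_left=masks[left],
        roi_right=masks[right],
        reference=masks[ref],
        exclusion=masks.get("ventricle"),
        region=region,
    )


def extract_ratio_table(
    volumes: Iterable[BrainVolume],
    masks: dict[str, MaskSet],
    use_exclusion: bool = True,
    reference_scope: str = "slice",
) -> pd.DataFrame:
    """Raw (unscaled) peak-ratio rows for a cohort of volumes.

    FSE acquisitions are averaged within participants; the ventricle
    exclusion is applied to MT scans before peak search.  SN-VTA is never
    extracted from FSE volumes (brainstem coverage only).
    """
    raw_rows = []
    for vol in sorted(
        volumes, key=lambda v: (v.participant, v.timepoint, v.modality, v.acquisition)
    ):
        for region, mask_set in sorted(masks.items()):
            if vol.modality == "fse" and region == "snvta":
                continue
            work = vol
            if use_exclusion and mask_set.exclusion is not None:
                work = apply_exclusion(vol, mask_set.exclusion)
            for hemisphere in ("left", "right"):
                try:
                    ratio, profile = extract_peak_ratio(
                        work, mask_set, hemisphere, reference_scope
                    )
                except ExtractionError as exc:
                    log.warning("skipping cell: %s", exc)
                    continue
                raw_rows.append(
                    {
                        "participant": vol.participant,
                        "region": region,
                        "modality": vol.modality,
                        "hemisphere": hemisphere,
                        "timepoint": vol.timepoint,
                        "acquisition": vol.acquisition,
                        "value": ratio,
                        "n_slices_used": int(profile["ratio"].notna().sum()),
                    }
                )
    raw = pd.DataFrame(
        raw_rows,
        columns=[
            "participant", "region", "modality", "hemisphere", "timepoint",
            "acquisition", "value", "n_slices_used",
        ],
    )
    if raw.empty:
        return raw.drop(columns=["acquisition"])
    keys = ["participant", "region", "modality", "hemisphere", "timepoint"]
    parts = []
    for cell, sub in raw.groupby(keys):
        if len(sub) > 1:  # two FSE acquisitions
            acq = sub.set_index("acquisition")["value"]
            a1 = acq.get(1, np.nan)
            a2 = acq.get(2, np.nan)
            avg, _ = average_fse_acquisitions(
                pd.Series([a1]), pd.Series([a2])
            )
            value = float(avg.iloc[0])
        else:
            value = float(sub["value"].iloc[0])
        parts.append(dict(zip(keys, cell), value=value,
                          n_slices_used=int(sub["n_slices_used"].max())))
    return pd.DataFrame(parts)


def build_ratio_table(
    volumes: Iterable[BrainVolume],
    masks: dict[str, MaskSet],
    use_exclusion: bool = True,
    sd_cutoff: float = 3.0,
    scale: float = 100.0,
    reference_scope: str = "slice",
) -> pd.DataFrame:
    """Full pipeline: extraction, FSE averaging, outlier screen, x100 scaling."""
    raw = extract_ratio_table(volumes, masks, use_exclusion, reference_scope)
    if raw.empty:
        return pd.DataFrame(columns=RATIO_COLUMNS)
    table = clean_and_scale(raw, k=sd_cutoff, factor=scale)
    return table[RATIO_COLUMNS]
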