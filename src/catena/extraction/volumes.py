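"""Slice-wise peak-intensity-ratio extraction from masked volumes.

For every axial slice (third grid axis) holding at least one usable
region-of-interest voxel and one usable reference voxel, the slice ratio
is ``(max(ROI) - max(Ref)) / max(Ref)``; the integrity indicator is the
maximum ratio over slices, per hemisphere.  Excluded voxels are marked
unusable rather than zeroed so they can never win (or distort) a peak
search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MODALITIES = ("mtplus", "mtminus", "fse")
MT_MODALITIES = ("mtplus", "mtminus")


class ShapeError(ValueError):
    pass


class ExtractionError(ValueError):
    pass


class DegenerateReferenceError(ValueError):
    pass


@dataclass
class BrainVolume:
    """One participant/modality/timepoint intensity grid in common space."""

    intensities: np.ndarray
    modality: str
    participant: str = ""
    timepoint: int = 1
    acquisition: int = 1
    usable: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ShapeError("volume must be a 3D grid")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("volume contains non-finite intensities")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.usable is None:
            self.usable = np.ones(self.intensities.shape, dtype=bool)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.intensities.shape


@dataclass
class MaskSet:
    """Binary masks for one region: left/right ROI, reference, exclusion."""

    roi_left: np.ndarray
    roi_right: np.ndarray
    reference: np.ndarray
    exclusion: np.ndarray | None = None
    region: str = "lc"

    def __post_init__(self) -> None:
        self.roi_left = _as_mask(self.roi_left)
        self.roi_right = _as_mask(self.roi_right)
        self.reference = _as_mask(self.reference)
        if self.exclusion is None:
            self.exclusion = np.zeros(self.roi_left.shape, dtype=bool)
        else:
            self.exclusion = _as_mask(self.exclusion)
        shapes = {
            m.shape
            for m in (self.roi_left, self.roi_right, self.reference, self.exclusion)
        }
        if len(shapes) != 1:
            raise ShapeError("mask grids differ in shape")
        for name, roi in (("left", self.roi_left), ("right", self.roi_right)):
            if not roi.any():
                raise ValueError(f"empty {name} ROI mask")
            if np.any(roi & self.reference):
                raise ValueError(f"{name} ROI overlaps the reference mask")

    def roi(self, hemisphere: str) -> np.ndarray:
        if hemisphere == "left":
            return self.roi_left
        if hemisphere == "right":
            return self.roi_right
        raise ValueError(f"unknown hemisphere {hemisphere!r}")


def _as_mask(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.dtype == bool:
        return arr
    # tolerate interpolated masks: values in (0.5, 1] count as inside
    return arr > 0.5


def apply_exclusion(volume: BrainVolume, exclusion: np.ndarray) -> BrainVolume:
    """Mark excluded voxels unusable for peak search (MT scans only).

    FSE volumes pass through unchanged: the exclusion mask targets the
    ventricle artifact present in the MT contrast.
    """
    if volume.modality == "fse":
        return volume
    exclusion = _as_mask(exclusion)
    if exclusion.shape != volume.shape:
        raise ShapeError(
            f"exclusion shape {exclusion.shape} != volume shape {volume.shape}"
        )
    return BrainVolume(
        volume.intensities,
        volume.modality,
        volume.participant,
        volume.timepoint,
        volume.acquisition,
        usable=volume.usable & ~exclusion,
    )


def slice_ratio(roi_peak: float, ref_peak: float) -> float:
    """``(max(ROI) - max(Ref)) / max(Ref)`` for one slice."""
    if ref_peak <= 0:
        raise DegenerateReferenceError(
            f"reference peak must be positive, got {ref_peak!r}"
        )
    return (roi_peak - ref_peak) / ref_peak


def extract_peak_ratio(
    volume: BrainVolume, masks: MaskSet, hemisphere: str,
    reference_scope: str = "slice",
) -> tuple[float, pd.DataFrame]:
    """Peak intensity ratio over axial slices plus the full slice profile.

    ``reference_scope`` selects whether the reference peak is taken per
    slice (default) or once over the whole reference region.
    """
    roi = masks.roi(hemisphere)
    if roi.shape != volume.shape:
        raise ShapeError("mask grid does not match volume grid")
    roi_ok = roi & volume.usable
    ref_ok = masks.reference & volume.usable
    intens = volume.intensities

    global_ref = None
    if reference_scope == "global":
        if not ref_ok.any():
            raise ExtractionError(
                f"no usable reference voxel "
                f"(participant={volume.participant!r}, modality={volume.modality!r})"
            )
        global_ref = float(intens[ref_ok].max())
    elif reference_scope != "slice":
        raise ValueError(f"unknown reference_scope {reference_scope!r}")

    rows = []
    n_slices = volume.shape[2]
    for z in range(n_slices):
        roi_z = roi_ok[:, :, z]
        ref_z = ref_ok[:, :, z]
        roi_peak = float(intens[:, :, z][roi_z].max()) if roi_z.any() else np.nan
        if reference_scope == "slice":
            ref_peak = float(intens[:, :, z][ref_z].max()) if ref_z.any() else np.nan
        else:
            ref_peak = global_ref if roi_z.any() else np.nan
        ratio = (
            slice_ratio(roi_peak, ref_peak)
            if np.isfinite(roi_peak) and np.isfinite(ref_peak)
            else np.nan
        )
        rows.append((z, roi_peak, ref_peak, ratio))
    profile = pd.DataFrame(
        rows, columns=["slice", "roi_peak", "ref_peak", "ratio"]
    )
    profile["hemisphere"] = hemisphere
    valid = profile["ratio"].dropna()
    if valid.empty:
        raise ExtractionError(
            f"no usable slice for peak-ratio extraction "
            f"(participant={volume.participant!r}, modality={volume.modality!r}, "
            f"hemisphere={hemisphere!r})"
        )
    return float(valid.max()), profile


def average_fse_acquisitions(ratios_acq1, ratios_acq2):
    """Elementwise mean of two acquisitions' ratios; one may be missing.

    Accepts scalars or aligned pandas Series; a missing side falls back
    to the other and is flagged.  Returns (averaged, single_acq_flag).
    """
    a = pd.Series(ratios_acq1, dtype=float) if not isinstance(
        ratios_acq1, pd.Series
    ) else ratios_acq1.astype(float)
    b = pd.Series(ratios_acq2, dtype=float) if not isinstance(
        ratios_acq2, pd.Series
    ) else ratios_acq2.astype(float)
    a, b = a.align(b)
    avg = pd.concat([a, b], axis=1).mean(axis=1, skipna=True)
    single = a.isna() ^ b.isna()
    return avg, single
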