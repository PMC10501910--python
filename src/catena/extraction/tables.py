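"""Tabular cleaning: outlier screening, scaling, hemisphere collapsing."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

RATIO_COLUMNS = [
    "participant", "region", "modality", "hemisphere", "timepoint",
    "value", "n_slices_used", "dropped",
]
DEFAULT_STRATA = ["region", "modality", "hemisphere", "timepoint"]


def clean_and_scale(
    table: pd.DataFrame,
    k: float = 3.0,
    factor: float = 100.0,
    strata: list[str] | None = None,
    value_col: str = "value",
) -> pd.DataFrame:
    """Single-pass ±k·s.d. outlier screen per stratum, then linear scaling.

    The stratum mean and s.d. are computed once, before any removal.
    Values beyond the cutoff are flagged ``dropped`` (value retained but
    excluded from analysis tables); survivors are multiplied by ``factor``.
    Strata with fewer than 3 values are scaled without screening.
    """
    if k <= 0:
        raise ValueError("s.d. multiplier k must be positive")
    strata = DEFAULT_STRATA if strata is None else strata
    strata = [c for c in strata if c in table.columns]
    out = table.copy()
    out["dropped"] = False
    groups = out.groupby(strata, dropna=False) if strata else [((), out)]
    for key, sub in groups:
        vals = sub[value_col].astype(float)
        ok = vals.notna()
        if ok.sum() < 3:
            log.warning(
                "stratum %s has %d values; outlier screening skipped", key, ok.sum()
            )
            continue
        mean = vals[ok].mean()
        sd = vals[ok].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            continue
        bad = ok & ((vals - mean).abs() > k * sd)
        if bad.any():
            for idx in sub.index[bad]:
                log.info("dropping outlier row %s (stratum %s)", idx, key)
        out.loc[sub.index[bad], "dropped"] = True
    out[value_col] = out[value_col].astype(float) * factor
    return out


def analysis_values(table: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Rows surviving the outlier screen."""
    if "dropped" not in table.columns:
        return table
    return table[~table["dropped"]]


def adjust_volumes(
    raw_volumes: pd.DataFrame,
    factor: float = 10000.0,
    k: float = 3.0,
    value_col: str = "raw_volume",
    tiv_col: str = "tiv",
) -> pd.DataFrame:
    """Gray-matter volume adjustment: screen, scale, divide by TIV.

    Outliers beyond ±k s.d. within region × hemisphere strata are flagged
    (single pass); survivors are multiplied by ``factor`` and divided by
    the participant's total intracranial volume.
    """
    if (raw_volumes[tiv_col] <= 0).any():
        bad = raw_volumes.loc[raw_volumes[tiv_col] <= 0, "participant"].tolist()
        raise ValueError(f"nonpositive total intracranial volume for {bad}")
    strata = [c for c in ("region", "hemisphere") if c in raw_volumes.columns]
    out = clean_and_scale(
        raw_volumes, k=k, factor=factor, strata=strata, value_col=value_col
    )
    out["adjusted_volume"] = out[value_col] / out[tiv_col]
    return out


def hemisphere_average(table: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Collapse left/right rows to their mean per participant cell.

    Missing hemispheres are skipped; a cell with both hemispheres
    missing stays missing.
    """
    keys = [
        c for c in ("participant", "region", "modality", "timepoint")
        if c in table.columns
    ]
    src = analysis_values(table, value_col)
    agg = (
        src.groupby(keys, dropna=False)[value_col]
        .mean()
        .reset_index()
    )
    agg["hemisphere"] = "both"
    return agg
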