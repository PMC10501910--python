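import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from catena.extraction import (
    BrainVolume,
    DegenerateReferenceError,
    ExtractionError,
    MaskSet,
    ShapeError,
    adjust_volumes,
    apply_exclusion,
    average_fse_acquisitions,
    clean_and_scale,
    extract_peak_ratio,
    extract_ratio_table,
    hemisphere_average,
    slice_ratio,
)


def brute_force_peak_ratio(intens, roi, ref, usable, scope="slice"):
    """Exhaustive loop over every slice and voxel; the independent oracle."""
    best = None
    global_ref = None
    if scope == "global":
        vals = [
            intens[x, y, z]
            for x in range(intens.shape[0])
            for y in range(intens.shape[1])
            for z in range(intens.shape[2])
            if ref[x, y, z] and usable[x, y, z]
        ]
        global_ref = max(vals) if vals else None
    for z in range(intens.shape[2]):
        roi_vals, ref_vals = [], []
        for x in range(intens.shape[0]):
            for y in range(intens.shape[1]):
                if usable[x, y, z]:
                    if roi[x, y, z]:
                        roi_vals.append(intens[x, y, z])
                    if ref[x, y, z]:
                        ref_vals.append(intens[x, y, z])
        ref_peak = global_ref if scope == "global" else (
            max(ref_vals) if ref_vals else None
        )
        if roi_vals and ref_peak is not None:
            r = (max(roi_vals) - ref_peak) / ref_peak
            best = r if best is None or r > best else best
    return best


def random_instance(rng, shape=(12, 12, 12)):
    intens = rng.uniform(1.0, 100.0, size=shape)
    roi_l = rng.random(shape) < 0.05
    roi_r = rng.random(shape) < 0.05
    ref = rng.random(shape) < 0.1
    roi_l &= ~ref
    roi_r &= ~ref
    roi_l.flat[0] = True  # guarantee non-empty masks
    roi_r.flat[1] = True
    ref.flat[2] = True
    ref.flat[0] = ref.flat[1] = False
    roi_l.flat[2] = roi_r.flat[2] = False
    excl = rng.random(shape) < 0.05
    return intens, roi_l, roi_r, ref, excl


# -- slice_ratio ---------------------------------------------------------------


@pytest.mark.parametrize(
    "roi,ref,expected", [(120, 100, 0.2), (100, 100, 0.0), (80, 100, -0.2)]
)
def test_slice_ratio_arithmetic(roi, ref, expected):
    assert slice_ratio(roi, ref) == pytest.approx(expected, abs=1e-15)


def test_slice_ratio_degenerate_reference():
    with pytest.raises(DegenerateReferenceError):
        slice_ratio(100, 0.0)
    with pytest.raises(DegenerateReferenceError):
        slice_ratio(100, -5.0)


# -- extract_peak_ratio --------------------------------------------------------


def single_slice_setup():
    intens = np.full((4, 4, 3), 10.0)
    roi = np.zeros((4, 4, 3), dtype=bool)
    ref = np.zeros((4, 4, 3), dtype=bool)
    roi[1, 1, 1] = True
    ref[2, 2, 1] = True
    intens[1, 1, 1] = 150.0
    intens[2, 2, 1] = 100.0
    masks = MaskSet(roi_left=roi, roi_right=roi.copy(), reference=ref)
    return BrainVolume(intens, "mtplus"), masks


def test_single_slice_constructed_peaks():
    vol, masks = single_slice_setup()
    ratio, profile = extract_peak_ratio(vol, masks, "left")
    assert ratio == pytest.approx(0.5)
    assert profile["ratio"].notna().sum() == 1


def test_matches_brute_force_on_random_instances(rng):
    for _ in range(100):
        intens, roi_l, roi_r, ref, _ = random_instance(rng)
        masks = MaskSet(roi_left=roi_l, roi_right=roi_r, reference=ref)
        vol = BrainVolume(intens, "mtplus")
        for hemi, roi in (("left", roi_l), ("right", roi_r)):
            expected = brute_force_peak_ratio(
                intens, roi, ref, np.ones_like(roi, dtype=bool)
            )
            if expected is None:
                with pytest.raises(ExtractionError):
                    extract_peak_ratio(vol, masks, hemi)
            else:
                got, _ = extract_peak_ratio(vol, masks, hemi)
                assert got == expected  # exact: same float operations


def test_global_reference_scope_matches_brute_force(rng):
    intens, roi_l, roi_r, ref, _ = random_instance(rng)
    masks = MaskSet(roi_left=roi_l, roi_right=roi_r, reference=ref)
    vol = BrainVolume(intens, "mtplus")
    got, _ = extract_peak_ratio(vol, masks, "left", reference_scope="global")
    expected = brute_force_peak_ratio(
        intens, roi_l, ref, np.ones_like(ref, dtype=bool), scope="global"
    )
    assert got == expected


@given(st.floats(min_value=1e-6, max_value=1e6))
@settings(max_examples=30, deadline=None)
def test_scale_invariance(scale):
    vol, masks = single_slice_setup()
    base, _ = extract_peak_ratio(vol, masks, "left")
    scaled = BrainVolume(vol.intensities * scale, "mtplus")
    got, _ = extract_peak_ratio(scaled, masks, "left")
    assert got == pytest.approx(base, abs=1e-12)


# -- apply_exclusion -----------------------------------------------------------


def test_empty_exclusion_is_identity(rng):
    intens, roi_l, roi_r, ref, _ = random_instance(rng)
    masks = MaskSet(roi_left=roi_l, roi_right=roi_r, reference=ref)
    vol = BrainVolume(intens, "mtplus")
    excluded = apply_exclusion(vol, np.zeros_like(roi_l))
    assert extract_peak_ratio(excluded, masks, "left")[0] == \
        extract_peak_ratio(vol, masks, "left")[0]


def test_exclusion_of_global_max_falls_back_to_next_voxel(rng):
    intens, roi_l, roi_r, ref, _ = random_instance(rng)
    masks = MaskSet(roi_left=roi_l, roi_right=roi_r, reference=ref)
    vol = BrainVolume(intens, "mtplus")
    # exclude the single brightest ROI voxel
    roi_vals = np.where(roi_l, intens, -np.inf)
    peak = np.unravel_index(np.argmax(roi_vals), intens.shape)
    excl = np.zeros_like(roi_l)
    excl[peak] = True
    excluded = apply_exclusion(vol, excl)
    got, _ = extract_peak_ratio(excluded, masks, "left")
    expected = brute_force_peak_ratio(intens, roi_l, ref, ~excl)
    assert got == expected


def test_exclusion_of_entire_roi_slice_drops_that_slice():
    vol, masks = single_slice_setup()
    excl = np.zeros(vol.shape, dtype=bool)
    excl[:, :, 1] = True  # the only informative slice
    excluded = apply_exclusion(vol, excl)
    with pytest.raises(ExtractionError, match="no usable slice"):
        extract_peak_ratio(excluded, masks, "left")


def test_fse_volumes_pass_through_exclusion():
    vol, masks = single_slice_setup()
    fse = BrainVolume(vol.intensities, "fse")
    excl = np.ones(vol.shape, dtype=bool)
    out = apply_exclusion(fse, excl)
    assert out.usable.all()


def test_exclusion_shape_mismatch():
    vol, _ = single_slice_setup()
    with pytest.raises(ShapeError):
        apply_exclusion(vol, np.zeros((2, 2, 2), dtype=bool))


def test_exclusion_monotonicity(rng):
    """Growing the exclusion mask never increases any slice peak."""
    intens, roi_l, roi_r, ref, excl = random_instance(rng)
    masks = MaskSet(roi_left=roi_l, roi_right=roi_r, reference=ref)
    vol = BrainVolume(intens, "mtplus")
    small = apply_exclusion(vol, excl)
    bigger = apply_exclusion(vol, excl | (rng.random(intens.shape) < 0.1))
    for v_small, v_big in ((small, bigger),):
        for z in range(intens.shape[2]):
            for mask in (roi_l, ref):
                m_small = mask[:, :, z] & v_small.usable[:, :, z]
                m_big = mask[:, :, z] & v_big.usable[:, :, z]
                if m_big.any():
                    assert m_small.any()
                    assert (
                        intens[:, :, z][m_big].max()
                        <= intens[:, :, z][m_small].max()
                    )


# -- FSE averaging -------------------------------------------------------------


def test_average_fse_acquisitions_mean_and_fallback():
    avg, single = average_fse_acquisitions(
        pd.Series([0.2, 0.2, np.nan]), pd.Series([0.4, np.nan, np.nan])
    )
    assert avg.iloc[0] == pytest.approx(0.3)
    assert avg.iloc[1] == pytest.approx(0.2)
    assert np.isnan(avg.iloc[2])
    assert list(single) == [False, True, False]


def test_average_fse_idempotent_on_equal_inputs():
    avg, single = average_fse_acquisitions(pd.Series([0.25]), pd.Series([0.25]))
    assert avg.iloc[0] == pytest.approx(0.25)
    assert not single.iloc[0]


# -- clean_and_scale -----------------------------------------------------------


def test_outlier_dropped_against_direct_stratum_oracle(rng):
    values = rng.normal(0.2, 0.01, size=100)
    values[17] = 0.2 + 0.055  # far beyond 3 s.d.
    table = pd.DataFrame({"region": "lc", "modality": "mtplus",
                          "hemisphere": "left", "timepoint": 1,
                          "value": values})
    out = clean_and_scale(table)
    mean, sd = values.mean(), values.std(ddof=1)
    expected = np.abs(values - mean) > 3 * sd
    assert expected[17]
    assert list(out["dropped"]) == list(expected)
    survivors = out[~out["dropped"]]
    assert survivors["value"].to_numpy() == pytest.approx(
        values[~expected] * 100.0
    )


def test_identical_values_never_dropped():
    table = pd.DataFrame({"value": [0.2] * 10})
    out = clean_and_scale(table, strata=[])
    assert not out["dropped"].any()
    assert (out["value"] == 20.0).all()


def test_small_stratum_skips_screening():
    table = pd.DataFrame({"value": [0.1, 99.0]})
    out = clean_and_scale(table, strata=[])
    assert not out["dropped"].any()
    assert out["value"].iloc[1] == pytest.approx(9900.0)


def test_scaling_factor_and_mean_sd_single_pass(rng):
    # two outliers on opposite sides: both flagged against the pre-removal
    # moments even though removing one would shift the other's z-score
    values = np.concatenate([rng.normal(0, 0.01, 60), [0.3, -0.3]])
    table = pd.DataFrame({"value": values})
    out = clean_and_scale(table, strata=[])
    assert out["dropped"].iloc[-2:].all()


def test_nonpositive_k_rejected():
    with pytest.raises(ValueError, match="positive"):
        clean_and_scale(pd.DataFrame({"value": [1.0]}), k=0)


# -- adjust_volumes ------------------------------------------------------------


def test_adjust_volumes_arithmetic():
    table = pd.DataFrame(
        {
            "participant": ["p1"] * 3 + ["p2"],
            "region": ["hippocampus"] * 4,
            "hemisphere": ["left", "right", "left", "right"],
            "raw_volume": [0.0004, 0.0004, 0.0004, 0.0004],
            "tiv": [2.0, 2.0, 2.0, 2.0],
        }
    )
    out = adjust_volumes(table)
    assert out["adjusted_volume"].iloc[0] == pytest.approx(2.0)
    assert not out["dropped"].any()  # all equal -> none dropped


def test_adjust_volumes_flags_4sd_outlier(rng):
    raw = rng.normal(4.0, 0.1, size=50)
    mean, sd = raw.mean(), raw.std(ddof=1)
    raw = np.append(raw, mean + 4 * sd)
    table = pd.DataFrame({"participant": [f"p{i}" for i in range(51)],
                          "region": "hippocampus", "hemisphere": "left",
                          "raw_volume": raw, "tiv": 1500.0})
    out = adjust_volumes(table)
    assert out["dropped"].iloc[-1]
    assert out["dropped"].sum() >= 1


def test_adjust_volumes_rejects_nonpositive_tiv():
    table = pd.DataFrame({"participant": ["p1"], "region": ["hippocampus"],
                          "hemisphere": ["left"], "raw_volume": [4.0],
                          "tiv": [0.0]})
    with pytest.raises(ValueError, match="intracranial"):
        adjust_volumes(table)


# -- hemisphere_average --------------------------------------------------------


def test_hemisphere_average_cases():
    table = pd.DataFrame(
        {
            "participant": ["p1", "p1", "p2", "p3"],
            "region": "lc",
            "modality": "mtplus",
            "timepoint": 1,
            "hemisphere": ["left", "right", "left", "left"],
            "value": [18.0, 22.0, 18.0, np.nan],
        }
    )
    out = hemisphere_average(table)
    byp = out.set_index("participant")["value"]
    assert byp["p1"] == pytest.approx(20.0)
    assert byp["p2"] == pytest.approx(18.0)
    assert np.isnan(byp["p3"])


# -- pipeline determinism ------------------------------------------------------


def test_extraction_independent_of_volume_ordering(rng):
    intens, roi_l, roi_r, ref, _ = random_instance(rng)
    masks = {"lc": MaskSet(roi_left=roi_l, roi_right=roi_r, reference=ref)}
    vols = [
        BrainVolume(intens * (i + 1), "mtplus", participant=f"p{i}", timepoint=1)
        for i in range(4)
    ]
    t1 = extract_ratio_table(vols, masks)
    t2 = extract_ratio_table(vols[::-1], masks)
    pd.testing.assert_frame_equal(t1, t2)
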