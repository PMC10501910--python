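import numpy as np
import pandas as pd
import pytest

from catena.extraction import build_ratio_table, extract_ratio_table
from catena.synthetic import (
    ConfigError,
    GenerationError,
    SimulationConfig,
    generate_cognitive_scores,
    generate_ground_truth,
    inject_missingness,
    render_participant_volumes,
    simulate_cohort,
)
from catena.synthetic.config import CONSTRUCTS, GroupMoments

from conftest import micro_config, tiny_config


def test_same_seed_gives_identical_cohorts():
    a = simulate_cohort(tiny_config())
    b = simulate_cohort(tiny_config())
    assert sorted(a.volumes) == sorted(b.volumes)
    for key in a.volumes:
        assert np.array_equal(a.volumes[key], b.volumes[key])
    pd.testing.assert_frame_equal(a.cognitive, b.cognitive)
    pd.testing.assert_frame_equal(a.roi_volumes, b.roi_volumes)
    pd.testing.assert_frame_equal(a.truth.latents, b.truth.latents)


def test_adding_participants_preserves_earlier_ones():
    small = simulate_cohort(tiny_config(n_young=3, n_old=3))
    large = simulate_cohort(tiny_config(n_young=3, n_old=5))
    for key, arr in small.volumes.items():
        if key in large.volumes:
            pid = key[0]
            if pid in set(small.truth.latents["participant"][:3]):
                assert np.array_equal(arr, large.volumes[key])


def test_cohort_structure():
    cohort = simulate_cohort(tiny_config())
    cfg = cohort.config
    assert len(cohort.truth.latents) == cfg.n_total
    assert set(cohort.cognitive["task"].unique()) == set(cfg.cognitive_loadings)
    # FSE only at TP2, two acquisitions
    fse = [(tp, acq) for (_p, m, tp, acq) in cohort.volumes if m == "fse"]
    assert fse and all(tp == 2 for tp, _ in fse)
    assert {acq for _, acq in fse} == {1, 2}
    # younger adults have no TP3 cognition
    young = cohort.cognitive[cohort.cognitive["group"] == "younger"]
    assert (young["timepoint"] != 3).all()
    old = cohort.cognitive[cohort.cognitive["group"] == "older"]
    assert (old["timepoint"] == 3).any()


def test_noiseless_ratio_is_affine_in_latent():
    cfg = micro_config(n_young=8, n_old=8)
    for mp in cfg.modality_params.values():
        mp.noise_sd = 0.0
    cohort = simulate_cohort(cfg)
    table = extract_ratio_table(cohort.brain_volumes(), cohort.mask_sets())
    latents = cohort.truth.latents.set_index("participant")
    for mod in ("mtplus", "mtminus", "fse"):
        mp = cfg.modality_params[mod]
        sub = table[(table.region == "lc") & (table.modality == mod)
                    & (table.timepoint == 2) & (table.hemisphere == "left")]
        lat = latents.loc[sub["participant"], "lc_tp2"].to_numpy()
        expected = mp.roi_offset + mp.gain * lat
        assert np.abs(sub["value"].to_numpy() - expected).max() < 1e-9
        # strictly increasing in the latent
        order = np.argsort(lat)
        assert (np.diff(sub["value"].to_numpy()[order]) > 0).all()


def test_zero_gain_gives_constant_ratio():
    cfg = micro_config(n_young=4, n_old=4)
    for mp in cfg.modality_params.values():
        mp.noise_sd = 0.0
        mp.gain = 0.0
    cohort = simulate_cohort(cfg)
    table = extract_ratio_table(cohort.brain_volumes(), cohort.mask_sets())
    for mod, sub in table[table.region == "lc"].groupby("modality"):
        assert sub["value"].to_numpy() == pytest.approx(
            cfg.modality_params[mod].roi_offset, abs=1e-12
        )


def test_ventricle_with_exclusion_matches_disabled_ventricle():
    cfg_on = micro_config(seed=11)
    cfg_off = micro_config(seed=11, ventricle_enabled=False)
    on = simulate_cohort(cfg_on)
    off = simulate_cohort(cfg_off)
    t_on = extract_ratio_table(on.brain_volumes(), on.mask_sets())
    t_off = extract_ratio_table(off.brain_volumes(), off.mask_sets())
    lc_on = t_on[t_on.region == "lc"].reset_index(drop=True)
    lc_off = t_off[t_off.region == "lc"].reset_index(drop=True)
    pd.testing.assert_frame_equal(lc_on, lc_off)


def test_ventricle_without_exclusion_inflates_lc_ratio():
    cfg = micro_config(seed=11)
    cohort = simulate_cohort(cfg)
    with_excl = extract_ratio_table(cohort.brain_volumes(), cohort.mask_sets())
    without = extract_ratio_table(
        cohort.brain_volumes(), cohort.mask_sets(), use_exclusion=False
    )
    key = ["participant", "region", "modality", "hemisphere", "timepoint"]
    merged = with_excl.merge(without, on=key, suffixes=("_ex", "_raw"))
    mt = merged[(merged.region == "lc") & (merged.modality != "fse")]
    assert (mt["value_raw"] >= mt["value_ex"] - 1e-12).all()
    assert (mt["value_raw"] > mt["value_ex"] + 0.1).any()


def test_fse_acquisitions_share_truth_but_not_noise():
    cohort = simulate_cohort(tiny_config())
    pid = cohort.truth.latents["participant"].iloc[0]
    a1 = cohort.volumes[(pid, "fse", 2, 1)]
    a2 = cohort.volumes[(pid, "fse", 2, 2)]
    assert not np.array_equal(a1, a2)
    # noiseless render is identical across acquisitions
    cfg = tiny_config()
    for mp in cfg.modality_params.values():
        mp.noise_sd = 0.0
    quiet = simulate_cohort(cfg)
    q1 = quiet.volumes[(pid, "fse", 2, 1)]
    q2 = quiet.volumes[(pid, "fse", 2, 2)]
    assert np.array_equal(q1, q2)


def test_non_finite_latent_raises():
    cfg = micro_config()
    truth = generate_ground_truth(cfg)
    row = truth.latents.iloc[0].copy()
    row["lc_tp1"] = np.nan
    with pytest.raises(GenerationError, match="non-finite"):
        render_participant_volumes(row, cfg, np.random.default_rng(0))


def test_cognitive_identity_when_residual_zero():
    cfg = micro_config()
    cfg.cognitive_loadings = {
        task: (factor, 1.0, 0.0, 0.0)
        for task, (factor, *_r) in cfg.cognitive_loadings.items()
    }
    truth = generate_ground_truth(cfg)
    cog = generate_cognitive_scores(truth, cfg)
    latents = truth.latents.set_index("participant")
    sub = cog[(cog.task == "scene") & (cog.timepoint == 1)]
    lat = latents.loc[sub["participant"], "em_tp1"].to_numpy()
    assert sub["score"].to_numpy() == pytest.approx(lat, abs=1e-12)


def test_group_mean_offset_propagates_through_loading():
    cfg = SimulationConfig(n_young=5000, n_old=5000, seed=2)
    idx = CONSTRUCTS.index("em")
    base = cfg.factor_moments["younger"]
    shifted_means = base.means.copy()
    shifted_means[idx] -= 2.0
    cfg.factor_moments["older"] = GroupMoments(shifted_means, base.covariance.copy())
    truth = generate_ground_truth(cfg)
    cog = generate_cognitive_scores(truth, cfg)
    sub = cog[(cog.task == "scene") & (cog.timepoint == 1)]
    young = sub[sub.group == "younger"]["score"].mean()
    old = sub[sub.group == "older"]["score"].mean()
    loading = cfg.cognitive_loadings["scene"][1]
    assert (young - old) == pytest.approx(2.0 * loading, abs=0.05)


def test_task_score_covariance_matches_lambda_psi_lambda(rng):
    """Oracle: empirical indicator covariance vs the independently computed
    matrix product Lambda Psi Lambda' + Theta at n = 10,000."""
    cfg = SimulationConfig(n_young=10000, n_old=0, seed=1)
    truth = generate_ground_truth(cfg)
    cog = generate_cognitive_scores(truth, cfg)
    tasks = list(cfg.cognitive_loadings)
    wide = (
        cog[cog.timepoint == 1]
        .pivot(index="participant", columns="task", values="score")[tasks]
    )
    factors = ("wm", "em", "gf")
    lam = np.zeros((10, 3))
    theta = np.zeros((10, 10))
    for i, t in enumerate(tasks):
        f, loading, _icpt, sd = cfg.cognitive_loadings[t]
        lam[i, factors.index(f)] = loading
        theta[i, i] = sd**2
    cog_idx = [CONSTRUCTS.index(f) for f in factors]
    psi = cfg.factor_moments["younger"].covariance[np.ix_(cog_idx, cog_idx)]
    implied = lam @ psi @ lam.T + theta
    emp = np.cov(wide.to_numpy().T)
    assert np.abs(emp - implied).max() < 0.02


def test_missingness_identity_when_probabilities_one():
    cohort = simulate_cohort(micro_config())
    out = inject_missingness(cohort, cohort.config)
    assert sorted(out.volumes) == sorted(cohort.volumes)


def test_missingness_rate_within_binomial_interval():
    cfg = micro_config(n_young=500, n_old=500, seed=9)
    cfg.availability[("mtplus", 1)] = 0.8
    cohort = simulate_cohort(cfg)
    n_obs = sum(1 for (_p, m, tp, _a) in cohort.volumes if m == "mtplus" and tp == 1)
    # binomial 99% interval for p=0.8, n=1000
    assert 0.76 <= n_obs / 1000 <= 0.84
    # ground truth untouched
    assert len(cohort.truth.latents) == 1000


def test_missingness_probability_zero_removes_modality():
    cfg = micro_config()
    cfg.availability[("mtminus", 1)] = 0.0
    cohort = simulate_cohort(cfg)
    assert not any(m == "mtminus" and tp == 1 for (_p, m, tp, _a) in cohort.volumes)
    assert any(m == "mtminus" and tp == 2 for (_p, m, tp, _a) in cohort.volumes)


def test_invalid_covariance_names_offending_block():
    cfg = micro_config()
    bad = np.eye(len(CONSTRUCTS))
    bad[0, 1] = bad[1, 0] = 2.0  # not PSD
    cfg.factor_moments["older"] = GroupMoments(np.zeros(len(CONSTRUCTS)), bad)
    with pytest.raises(ConfigError, match="older"):
        cfg.validate()


def test_unknown_cognitive_factor_rejected():
    cfg = micro_config()
    cfg.cognitive_loadings["scene"] = ("episodic", 1.0, 0.0, 0.5)
    with pytest.raises(ConfigError, match="unknown factor"):
        cfg.validate()


def test_fse_at_tp1_availability_rejected():
    cfg = micro_config()
    cfg.availability[("fse", 1)] = 1.0
    with pytest.raises(ConfigError, match="TP2 only"):
        cfg.validate()


def test_latent_change_is_exact_difference():
    truth = generate_ground_truth(micro_config())
    for c in CONSTRUCTS:
        delta = truth.latents[f"{c}_tp2"] - truth.latents[f"{c}_tp1"]
        assert np.all(np.isfinite(delta))


def test_config_yaml_round_trip(tmp_path):
    cfg = tiny_config()
    path = tmp_path / "sim.yaml"
    cfg.to_yaml(path)
    loaded = SimulationConfig.from_yaml(path, seed=99)
    assert loaded.seed == 99
    assert loaded.n_young == cfg.n_young
    assert loaded.grid_shape == cfg.grid_shape
    assert loaded.availability == cfg.availability
    a = loaded.modality_params["mtplus"]
    b = cfg.modality_params["mtplus"]
    assert (a.gain, a.roi_offset, a.ref_mean, a.noise_sd) == (
        b.gain, b.roi_offset, b.ref_mean, b.noise_sd
    )
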