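"""Phantom generator: ground-truth consistency, determinism, signal model."""

import numpy as np
import pytest

from octachoroid.phantom import (
    EyeRecord,
    PhantomConfig,
    generate_cohort,
    generate_phantom_eye,
    generate_slab_masks,
    generate_slab_pair,
    make_qc_roster,
)


@pytest.mark.parametrize(
    "kwargs, field",
    [
        ({"sct": -10.0}, "sct"),
        ({"axial_step": 0.0}, "axial_step"),
        ({"grid_nx": 8}, "grid_nx"),
        ({"lumen_fraction_by_depth": {100.0: 1.4}}, "lumen_fraction_by_depth"),
        ({"noise_sd": -1.0}, "noise_sd"),
        ({"pixel_size_xy": 0.0}, "pixel_size_xy"),
    ],
)
def test_invalid_config_rejected_naming_field(kwargs, field):
    cfg = PhantomConfig(**kwargs)
    with pytest.raises(ValueError, match=field):
        cfg.validate()


def test_same_seed_gives_bit_identical_volumes(small_cfg):
    pair1, truth1 = generate_phantom_eye(small_cfg)
    pair2, truth2 = generate_phantom_eye(small_cfg)
    assert np.array_equal(pair1.oct_volume, pair2.oct_volume)
    assert np.array_equal(pair1.octa_volume, pair2.octa_volume)
    assert np.array_equal(truth1.lumen_mask_volume, truth2.lumen_mask_volume)

    other = PhantomConfig(**{**small_cfg.__dict__, "seed": 2})
    pair3, _ = generate_phantom_eye(other)
    assert not np.array_equal(pair1.octa_volume, pair3.octa_volume)


@pytest.mark.parametrize("target", [0.2, 0.55, 0.8])
def test_ground_truth_fraction_within_tolerance(target):
    cfg = PhantomConfig(
        sct=300.0,
        grid_nx=96,
        grid_ny=96,
        lumen_fraction_by_depth={98.8: target, 200.2: 0.4},
        seed=7,
    )
    _, truth = generate_phantom_eye(cfg)
    assert abs(truth.lumen_fraction(98.8) - target) <= 0.05
    assert abs(truth.lumen_fraction(200.2) - 0.4) <= 0.05


def test_no_vessel_noiseless_slab_is_uniform_bright():
    cfg = PhantomConfig(
        sct=300.0,
        grid_nx=64,
        grid_ny=64,
        lumen_fraction_by_depth={98.8: 0.0},
        noise_sd=0.0,
        seed=3,
    )
    octa, oct_ = generate_slab_pair(cfg, 98.8)
    assert np.ptp(octa) == 0 and np.ptp(oct_) == 0
    assert octa.mean() > cfg.noise_floor + 20  # bright stroma, not floor


def test_slabs_below_sct_sit_at_noise_floor(small_cfg):
    pair, _ = generate_phantom_eye(small_cfg)
    deep_page = int((small_cfg.sct + 20) / small_cfg.axial_step)
    mean = pair.octa_volume[deep_page].mean()
    assert mean <= small_cfg.noise_floor + 3 * small_cfg.noise_sd


def test_stroma_attenuation_monotone_with_depth(small_cfg):
    pair, truth = generate_phantom_eye(small_cfg)
    step = small_cfg.axial_step
    depths = np.arange(int(small_cfg.choriocap_thickness / step) + 1,
                       int(small_cfg.sct / step))
    means = []
    for k in depths:
        stroma = ~truth.lumen_mask_volume[k]
        means.append(pair.oct_volume[k][stroma].mean())
    diffs = np.diff(means)
    assert (diffs <= small_cfg.noise_sd).all()


def test_single_slab_path_matches_full_volume_mask(small_cfg):
    """The fast slab renderer shares its tube geometry with the volume path."""
    masks = generate_slab_masks(small_cfg)
    _, truth = generate_phantom_eye(small_cfg)
    k = int(round(98.8 / small_cfg.axial_step))
    assert np.array_equal(masks[98.8], truth.lumen_mask_volume[k])


def test_tilted_bm_shifts_anatomy_down():
    flat = PhantomConfig(sct=200.0, grid_nx=32, grid_ny=32, noise_sd=0.0,
                         lumen_fraction_by_depth={98.8: 0.4}, seed=9)
    tilted = PhantomConfig(**{**flat.__dict__, "bm_tilt": 2.6})
    pf, _ = generate_phantom_eye(flat)
    pt, _ = generate_phantom_eye(tilted)
    assert pt.bm_depth_map.max() == pytest.approx(2.6)
    # last column of the tilted volume equals the flat volume one page up
    col = pt.oct_volume[39, :, -1]
    assert np.array_equal(col, pf.oct_volume[38, :, -1])


def test_cohort_deterministic_and_null_case():
    a = generate_cohort(5, 0, effect=0.0, slope=0.0, seed=7, cvd_noise_sd=0.0)
    b = generate_cohort(5, 0, effect=0.0, slope=0.0, seed=7, cvd_noise_sd=0.0)
    assert [r.eye_id for r, _ in a] == [r.eye_id for r, _ in b]
    assert [c.sct for _, c in a] == [c.sct for _, c in b]
    fracs = [list(c.lumen_fraction_by_depth.values())[0] for _, c in a]
    assert len(set(fracs)) == 1  # null slope + null effect + no noise
    assert all(r.group == "healthy" for r, _ in a)


def test_cohort_group_effect_at_equal_sct():
    """With the SCT confound removed, the generator-side CVD offset between
    CSC and healthy eyes equals the injected effect (8.2 points)."""
    cohort = generate_cohort(200, 200, effect=8.2, slope=3.9, seed=11,
                             match_sct=True)
    adj = {"healthy": [], "csc": []}
    for rec, cfg in cohort:
        frac = 100 * list(cfg.lumen_fraction_by_depth.values())[0]
        adj["csc" if rec.is_csc else "healthy"].append(
            frac - 3.9 * (rec.sct - 333.0) / 100.0
        )
    diff = np.mean(adj["csc"]) - np.mean(adj["healthy"])
    assert diff == pytest.approx(8.2, abs=2.5)


def test_cohort_sct_distributions_follow_groups():
    cohort = generate_cohort(300, 300, seed=13)
    h = [r.sct for r, _ in cohort if not r.is_csc]
    c = [r.sct for r, _ in cohort if r.is_csc]
    assert min(h) > 150 and min(c) > 200
    assert np.mean(h) == pytest.approx(333, abs=25)
    assert np.mean(c) == pytest.approx(547, abs=30)


def test_qc_roster_categories_are_disjoint_and_counted():
    roster = make_qc_roster(n_total=50, n_blink=1, n_banding=2, n_low_score=3,
                            n_wide_motion=4, seed=1)
    assert len(roster) == 50
    assert sum("blink" in r.artefact_flags for r in roster) == 1
    assert sum("banding" in r.artefact_flags for r in roster) == 2
    assert sum(r.image_score < 50 for r in roster) == 3
    assert sum(r.wide_motion_artefact_count >= 2 for r in roster) == 4


def test_eye_record_validation():
    with pytest.raises(ValueError, match="sct"):
        EyeRecord("e", 40, "F", 23.5, -1.0, "healthy")
    with pytest.raises(ValueError, match="artefact"):
        EyeRecord("e", 40, "F", 23.5, 300.0, "healthy",
                  artefact_flags={"sparkle"})
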