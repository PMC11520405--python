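"""Tests for the synthetic nanowell simulator."""

import numpy as np
import pytest
from scipy import stats

from postfocus import metrics, synth
from postfocus.synth import (DatasetValidationError, DefocusModel, FramePair,
                             PlacementError, SceneSpec, VideoSpec)


# ---------------------------------------------------------------------------
# specs


def test_scene_spec_validation():
    with pytest.raises(ValueError):
        SceneSpec(image_size_px=100, pixel_pitch_um=0.325)   # well larger than image
    with pytest.raises(ValueError):
        SceneSpec(radius_um_range=(6.0, 4.0))
    with pytest.raises(ValueError):
        SceneSpec(intensity_fg=1.5)
    with pytest.raises(ValueError):
        SceneSpec(object_kind="triangle")


def test_video_spec_validation():
    with pytest.raises(ValueError):
        VideoSpec(oof_event_rate=1.5)
    with pytest.raises(ValueError):
        VideoSpec(oof_burst_len_frames=(0, 3))
    with pytest.raises(ValueError):
        VideoSpec(n_frames=0)


def test_defocus_model_validation():
    with pytest.raises(ValueError):
        DefocusModel(sigma_per_um=0.0)
    with pytest.raises(ValueError):
        DefocusModel(psf_family="bessel")


# ---------------------------------------------------------------------------
# render_scene


def test_empty_scene(small_scene):
    spec = SceneSpec(image_size_px=64, pixel_pitch_um=0.83, n_cells=0)
    img, masks = synth.render_scene(spec, 3)
    assert masks.shape == (0, 64, 64)
    assert img.min() >= 0 and img.max() <= 1
    # well border is visible: darker wall pixels exist
    assert (img < spec.intensity_bg - 0.15).any()


def test_render_determinism(small_scene):
    a, _ = synth.render_scene(small_scene, 42)
    b, _ = synth.render_scene(small_scene, 42)
    assert np.array_equal(a, b)
    c, _ = synth.render_scene(small_scene, 43)
    assert not np.array_equal(a, c)


def test_mask_areas_match_disc_oracle():
    spec = SceneSpec(n_cells=3, radius_um_range=(4.0, 6.0), pixel_pitch_um=0.325)
    _, masks = synth.render_scene(spec, 7)
    assert masks.shape[0] == 3
    lo = np.pi * (4.0 / 0.325) ** 2 * 0.9
    hi = np.pi * (6.0 / 0.325) ** 2 * 1.1
    for m in masks:
        assert lo <= m.sum() <= hi
    # disjoint
    assert (masks.sum(axis=0) <= 1).all()


def test_placement_error_when_overcrowded():
    spec = SceneSpec(image_size_px=64, pixel_pitch_um=0.83, n_cells=30)
    with pytest.raises(PlacementError):
        synth.render_scene(spec, 0)


# ---------------------------------------------------------------------------
# defocus


def test_defocus_sigma_contract(small_model):
    m = DefocusModel(sigma_per_um=0.8)
    assert synth.defocus_sigma(0, m) == 0.0
    assert synth.defocus_sigma(-10, m) == pytest.approx(8.0)
    assert synth.defocus_sigma(-10, m) == synth.defocus_sigma(10, m)
    assert synth.defocus_sigma(5, m) == pytest.approx(synth.defocus_sigma(10, m) / 2)


def test_apply_defocus_identity(small_scene, small_model):
    img, _ = synth.render_scene(small_scene, 5)
    out = synth.apply_defocus(img, 0.0, small_model, seed=1, noise_sigma=0.0)
    assert np.array_equal(out, img)


def test_apply_defocus_blurs(small_scene, small_model):
    img, _ = synth.render_scene(small_scene, 5)
    out = synth.apply_defocus(img, 10.0, small_model, seed=1, noise_sigma=0.0)
    assert metrics.tenengrad(out) < metrics.tenengrad(img)


def test_defocus_monotone_in_offset(small_scene, small_model):
    img, _ = synth.render_scene(small_scene, 9)
    scores = [metrics.tenengrad(synth.apply_defocus(img, dz, small_model))
              for dz in (0, 5, 10)]
    assert scores[0] > scores[1] > scores[2]


def test_defocus_kernel_too_large():
    tiny = np.full((8, 8), 0.5)
    with pytest.raises(ValueError):
        synth.apply_defocus(tiny, 10.0, DefocusModel(sigma_per_um=2.0))


def test_disk_psf_runs(small_scene):
    img, _ = synth.render_scene(small_scene, 5)
    m = DefocusModel(sigma_per_um=0.35, psf_family="disk")
    out = synth.apply_defocus(img, 10.0, m)
    assert metrics.tenengrad(out) < metrics.tenengrad(img)


def test_contrast_floor():
    m = DefocusModel(sigma_per_um=0.1, contrast_decay_per_um=0.5)
    img = np.zeros((32, 32))
    img[8:24, 8:24] = 1.0
    out = synth.apply_defocus(img, 10.0, m)   # decay 5.0 -> clamps at 0.2
    assert out.std() > 0.1 * img.std()


# ---------------------------------------------------------------------------
# paired datasets


def test_identity_pair_count(small_scene, small_model):
    ds = synth.make_pair_dataset(small_scene, small_model, n_pairs=100,
                                 identity_fraction=0.25, seed=0)
    n_id = sum(r.is_identity for r in ds.records)
    assert n_id == 25
    for rec, pair in zip(ds.records, ds.pairs):
        if rec.is_identity:
            assert rec.focus_label == "in_focus"
            assert np.array_equal(pair.in_focus, pair.oof)
        else:
            assert rec.focus_label == "oof"
            assert abs(rec.delta_z_um) > 0


def test_zero_identity_fraction(small_scene, small_model):
    ds = synth.make_pair_dataset(small_scene, small_model, n_pairs=20,
                                 identity_fraction=0.0, seed=1)
    assert all(abs(r.delta_z_um) > 0 for r in ds.records)


def test_offset_sign_distribution(small_scene, small_model):
    # binomial oracle on the +/- split at 99% over a fixed seed
    ds = synth.make_pair_dataset(small_scene, small_model, n_pairs=40,
                                 identity_fraction=0.25, offsets_um=(10.0,),
                                 seed=5)
    signs = [r.delta_z_um for r in ds.records if not r.is_identity]
    assert len(signs) == 30
    n_pos = sum(1 for s in signs if s > 0)
    lo, hi = stats.binom.interval(0.99, 30, 0.5)
    assert lo <= n_pos <= hi


def test_split_ratio(small_scene, small_model):
    ds = synth.make_pair_dataset(small_scene, small_model, n_pairs=40, seed=2)
    n_train = sum(r.split == "train" for r in ds.records)
    assert n_train == 32   # 4:1


def test_make_pair_dataset_errors(small_scene, small_model):
    with pytest.raises(ValueError):
        synth.make_pair_dataset(small_scene, small_model, n_pairs=0)
    with pytest.raises(ValueError):
        synth.make_pair_dataset(small_scene, small_model, n_pairs=10,
                                identity_fraction=1.0)
    with pytest.raises(ValueError):
        synth.make_pair_dataset(small_scene, small_model, n_pairs=10,
                                offsets_um=())


def test_frame_pair_invariant_enforced(small_scene):
    img = np.random.default_rng(0).random((8, 8))
    with pytest.raises(ValueError):
        FramePair(in_focus=img, oof=img + 0.1, delta_z_um=0.0,
                  is_identity=True, masks=np.zeros((0, 8, 8), bool))


def test_classifier_frames_ratio(small_pair_dataset):
    frames, labels = synth.classifier_frames(small_pair_dataset, seed=3)
    n_oof = int(labels.sum())
    n_if = len(labels) - n_oof
    # requested 21:20; within rounding of the available pool
    assert abs(n_if - round(n_oof * 20 / 21)) <= 1


# ---------------------------------------------------------------------------
# videos


def test_video_no_events(small_scene, small_model):
    vspec = VideoSpec(n_frames=6, oof_event_rate=0.0)
    sim = synth.simulate_video(small_scene, vspec, small_model, seed=4)
    assert np.all(sim.z_trace == 0)
    assert len(sim.in_focus_frames) == 6
    # observed equals in-focus up to acquisition noise
    diff = np.abs(sim.observed_frames - sim.in_focus_frames)
    assert diff.max() < 8 * small_scene.noise_sigma


def test_video_saturated_events(small_scene, small_model):
    vspec = VideoSpec(n_frames=5, oof_event_rate=1.0,
                      oof_burst_len_frames=(5, 5))
    sim = synth.simulate_video(small_scene, vspec, small_model, seed=4)
    assert np.all(np.abs(sim.z_trace) > 0)


def test_video_oof_fraction_matches_markov_oracle(small_model):
    # brute-force Markov chain oracle over many short traces
    rate, burst = 0.05, 3
    vspec = VideoSpec(n_frames=50, oof_event_rate=rate,
                      oof_burst_len_frames=(burst, burst))
    scene = SceneSpec(image_size_px=32, pixel_pitch_um=1.6, n_cells=0)
    fracs = []
    for s in range(60):
        sim = synth.simulate_video(scene, vspec, small_model, seed=s)
        fracs.append((np.abs(sim.z_trace) > 0).mean())
    observed = float(np.mean(fracs))

    rng = np.random.default_rng(999)
    oracle_fracs = []
    for _ in range(600):
        n_oof = 0
        remaining = 0
        for _i in range(vspec.n_frames):
            if remaining == 0 and rng.random() < rate:
                remaining = burst
            if remaining > 0:
                n_oof += 1
                remaining -= 1
        oracle_fracs.append(n_oof / vspec.n_frames)
    expected = float(np.mean(oracle_fracs))
    se = float(np.std(oracle_fracs) / np.sqrt(600) +
               np.std(fracs) / np.sqrt(60))
    assert abs(observed - expected) < 3 * se + 1e-9


def test_video_mask_motion_bounded(small_scene, small_model):
    vspec = VideoSpec(n_frames=8, motion_step_px=1.5, oof_event_rate=0.0)
    sim = synth.simulate_video(small_scene, vspec, small_model, seed=6)
    for t in range(1, len(sim.masks_per_frame)):
        for k in range(small_scene.n_cells):
            prev = np.argwhere(sim.masks_per_frame[t - 1][k]).mean(axis=0)
            cur = np.argwhere(sim.masks_per_frame[t][k]).mean(axis=0)
            # per-axis steps clipped at 3*step; allow sqrt(2) for the diagonal
            assert np.linalg.norm(cur - prev) <= 3 * 1.5 * np.sqrt(2) + 1e-6


def test_video_z_values_from_configured_set(small_scene, small_model):
    vspec = VideoSpec(n_frames=40, oof_event_rate=0.3,
                      burst_delta_z_um=(5.0, 10.0))
    sim = synth.simulate_video(small_scene, vspec, small_model, seed=8)
    nz = np.abs(sim.z_trace[sim.z_trace != 0])
    assert set(np.unique(nz)) <= {5.0, 10.0}


# ---------------------------------------------------------------------------
# disk round trip


def test_write_read_roundtrip(tmp_path, small_scene, small_model):
    ds = synth.make_pair_dataset(small_scene, small_model, n_pairs=10, seed=3)
    synth.write_dataset(ds, tmp_path)
    back = synth.read_dataset(tmp_path)
    assert len(back) == 10
    for a, b in zip(ds.pairs, back.pairs):
        assert np.array_equal(synth.quantize16(a.in_focus),
                              synth.quantize16(b.in_focus))
        assert np.array_equal(synth.quantize16(a.oof), synth.quantize16(b.oof))
        assert np.array_equal(a.masks, b.masks)
    for ra, rb in zip(ds.records, back.records):
        assert ra.pair_id == rb.pair_id
        assert ra.delta_z_um == rb.delta_z_um
        assert ra.split == rb.split


def test_write_empty_dataset(tmp_path):
    synth.write_dataset(synth.PairDataset(records=[], pairs=[]), tmp_path)
    back = synth.read_dataset(tmp_path)
    assert len(back) == 0


def test_read_detects_label_corruption(tmp_path, small_scene, small_model):
    import pandas as pd
    ds = synth.make_pair_dataset(small_scene, small_model, n_pairs=6, seed=3)
    synth.write_dataset(ds, tmp_path)
    manifest = tmp_path / "manifest.csv"
    df = pd.read_csv(manifest)
    oof_rows = df.index[df["focus_label"] == "oof"]
    df.loc[oof_rows[0], "focus_label"] = "in_focus"
    df.to_csv(manifest, index=False)
    with pytest.raises(DatasetValidationError) as exc:
        synth.read_dataset(tmp_path)
    assert df.loc[oof_rows[0], "pair_id"] in str(exc.value)


def test_read_detects_missing_file(tmp_path, small_scene, small_model):
    ds = synth.make_pair_dataset(small_scene, small_model, n_pairs=3, seed=3)
    synth.write_dataset(ds, tmp_path)
    (tmp_path / ds.records[1].oof_path).unlink()
    with pytest.raises(DatasetValidationError):
        synth.read_dataset(tmp_path)
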