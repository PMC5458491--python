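"""Synthetic scenes, MRC I/O, and the desk-scale stage primitives."""

import numpy as np
import pytest

from emflow.errors import ValidationError
from emflow.synthetic import (SyntheticScene, block_mean_downscale,
                              classify_2d, estimate_shifts, extract_particles,
                              gaussian_pick, gaussian_template, make_movie,
                              motion_correct, random_scene, read_ledger,
                              read_mrc, write_mrc)


def test_mrc_round_trip_and_determinism(tmp_path):
    rng = np.random.default_rng(0)
    arr = rng.normal(size=(3, 16, 16)).astype(np.float32)
    write_mrc(tmp_path / "a.mrc", arr)
    write_mrc(tmp_path / "b.mrc", arr)
    assert np.array_equal(read_mrc(tmp_path / "a.mrc"), arr)
    assert (tmp_path / "a.mrc").read_bytes() == (tmp_path / "b.mrc").read_bytes()


def test_noise_free_single_frame_is_analytic(tmp_path):
    """Zero noise, zero drift, one frame: maxima sit exactly on the planted
    centres with the template's unit peak value."""
    scene = SyntheticScene(image_size=64, particle_diameter=11,
                           coords=[(20, 30), (45, 15)], drift=(0, 0),
                           noise_sigma=0.0, seed=0)
    make_movie(scene, 1, tmp_path / "m.mrcs", tmp_path / "t.star")
    frame = read_mrc(tmp_path / "m.mrcs")[0]
    for x, y in scene.coords:
        assert frame[y, x] == pytest.approx(1.0, abs=1e-5)
        # local maximum
        patch = frame[y - 2:y + 3, x - 2:x + 3]
        assert patch.max() == frame[y, x]
    assert read_ledger(tmp_path / "t.star") == scene.coords


def test_drift_shifts_later_frames(tmp_path):
    scene = SyntheticScene(image_size=64, particle_diameter=9,
                           coords=[(30, 30)], drift=(1.0, 0.0),
                           noise_sigma=0.0, seed=0)
    make_movie(scene, 16, tmp_path / "m.mrcs")
    mov = read_mrc(tmp_path / "m.mrcs")
    y15, x15 = np.unravel_index(mov[15].argmax(), mov[15].shape)
    assert (x15, y15) == (45, 30)  # 15 frames of +1 px drift in x


def test_movie_reproducible_under_fixed_seed(tmp_path):
    scene = random_scene(seed=9, image_size=96, n_particles=3,
                         particle_diameter=13)
    make_movie(scene, 3, tmp_path / "a.mrcs")
    make_movie(scene, 3, tmp_path / "b.mrcs")
    assert (tmp_path / "a.mrcs").read_bytes() == (tmp_path / "b.mrcs").read_bytes()


def test_margin_violation_rejected(tmp_path):
    scene = SyntheticScene(image_size=64, particle_diameter=15,
                           coords=[(3, 3)], noise_sigma=0.0)
    with pytest.raises(ValidationError):
        make_movie(scene, 1, tmp_path / "m.mrcs")


def test_known_linear_drift_recovered_exactly():
    scene = SyntheticScene(image_size=96, particle_diameter=13,
                           coords=[(30, 40), (70, 60)], drift=(2.0, 1.0),
                           noise_sigma=0.01, seed=4)
    scene.validate()
    import tempfile, pathlib

    with tempfile.TemporaryDirectory() as d:
        make_movie(scene, 4, pathlib.Path(d) / "m.mrcs")
        mov = read_mrc(pathlib.Path(d) / "m.mrcs")
    shifts = estimate_shifts(mov)
    assert shifts.tolist() == [[0, 0], [2, 1], [4, 2], [6, 3]]


def test_zero_drift_movie_gives_zero_shifts(tmp_path):
    scene = SyntheticScene(image_size=64, particle_diameter=9,
                           coords=[(32, 32)], drift=(0, 0),
                           noise_sigma=0.05, seed=2)
    make_movie(scene, 5, tmp_path / "m.mrcs")
    assert not estimate_shifts(read_mrc(tmp_path / "m.mrcs")).any()


def test_frame_averaging_reduces_noise_sqrt_n(tmp_path):
    """Averaging N identical frames shrinks the noise sigma by √N (within
    10%), measured on blank regions."""
    n_frames = 16
    scene = SyntheticScene(image_size=128, particle_diameter=9,
                           coords=[(20, 20)], drift=(0, 0),
                           noise_sigma=0.2, seed=7)
    make_movie(scene, n_frames, tmp_path / "m.mrcs")
    mov = read_mrc(tmp_path / "m.mrcs")
    mic, _ = motion_correct(mov)
    blank = mic[64:, 64:]  # far from the single particle
    expected = 0.2 / np.sqrt(n_frames)
    assert abs(blank.std() - expected) / expected < 0.10


def test_gaussian_template_unit_peak_and_symmetry():
    t = gaussian_template(13)
    assert t.max() == pytest.approx(1.0)
    assert t.shape == (13, 13)
    assert np.allclose(t, t.T)
    assert np.allclose(t, t[::-1, ::-1])


def test_picker_blank_image_no_picks():
    assert gaussian_pick(np.zeros((128, 128), np.float32), 15, 0.3) == []


def test_picker_parameter_validation():
    img = np.zeros((64, 64), np.float32)
    with pytest.raises(ValidationError):
        gaussian_pick(img, 15, 1.01)
    with pytest.raises(ValidationError):
        gaussian_pick(img, 15, 0.0)
    with pytest.raises(ValidationError):
        gaussian_pick(img, 100, 0.3)  # wider than the image


def test_picker_finds_planted_blobs_within_2px(tmp_path):
    """Five well-separated planted blobs at the standard threshold 0.3:
    every pick lands within 2 px of a distinct true centre."""
    scene = random_scene(seed=11, image_size=512, n_particles=5,
                         particle_diameter=27, noise_sigma=0.1)
    make_movie(scene, 3, tmp_path / "m.mrcs")
    mic, _ = motion_correct(read_mrc(tmp_path / "m.mrcs"))
    picks = gaussian_pick(mic, 27, 0.3)
    assert len(picks) == 5
    remaining = list(scene.coords)
    for x, y, score in picks:
        dists = [np.hypot(x - u, y - v) for u, v in remaining]
        assert min(dists) <= 2.0
        remaining.pop(int(np.argmin(dists)))
        assert score >= 0.3


def test_picker_monotone_in_threshold(tmp_path):
    scene = random_scene(seed=13, image_size=256, n_particles=4,
                         particle_diameter=21, noise_sigma=0.3)
    make_movie(scene, 1, tmp_path / "m.mrcs")
    img = read_mrc(tmp_path / "m.mrcs")[0]
    counts = [len(gaussian_pick(img, 21, h))
              for h in (0.05, 0.1, 0.2, 0.3, 0.5, 0.7, 0.9)]
    assert counts == sorted(counts, reverse=True)


def test_extraction_box_arithmetic():
    img = np.arange(400 * 400, dtype=np.float32).reshape(400, 400)
    stack, kept, skipped = extract_particles(img, [(200, 200)], 360, 3)
    assert stack.shape == (1, 120, 120)
    assert (kept, skipped) == ([0], 0)


def test_extraction_identity_crop():
    rng = np.random.default_rng(3)
    img = rng.normal(size=(64, 64)).astype(np.float32)
    stack, _, _ = extract_particles(img, [(32, 32)], 16, 1)
    assert np.array_equal(stack[0], img[24:40, 24:40])


def test_extraction_skips_edge_windows():
    img = np.zeros((100, 100), np.float32)
    stack, kept, skipped = extract_particles(img, [(10, 50), (50, 50)], 64, 1)
    assert skipped == 1
    assert kept == [1]
    assert stack.shape == (1, 64, 64)


def test_extraction_rejects_indivisible_box():
    with pytest.raises(ValidationError):
        extract_particles(np.zeros((64, 64), np.float32), [(32, 32)], 50, 3)


def test_block_mean_constant_blocks_invertible():
    """Block-mean of a block-constant image is exactly the block values."""
    vals = np.arange(16, dtype=np.float32).reshape(4, 4)
    img = np.kron(vals, np.ones((3, 3), np.float32))
    assert np.array_equal(block_mean_downscale(img, 3), vals)


def test_classify_k1_mean_and_checkpoints(tmp_path):
    rng = np.random.default_rng(5)
    particles = rng.normal(size=(10, 8, 8)).astype(np.float32)
    classify_2d(particles, k=1, seed=0, iterations=10, job_dir=tmp_path)
    classes = read_mrc(tmp_path / "run_it010_classes.mrcs")
    assert np.allclose(classes[0], particles.mean(axis=0), atol=1e-5)
    for it in range(1, 11):
        assert (tmp_path / f"run_it{it:03d}_optimiser.star").exists()


def test_classify_two_shapes_pure_assignment(tmp_path):
    """Two well-separated planted shapes, K=2: assignment purity is 100%."""
    rng = np.random.default_rng(6)
    blob = gaussian_template(9)
    a = np.zeros((12, 12), np.float32)
    a[:9, :9] = blob  # corner blob
    b = np.zeros((12, 12), np.float32)
    b[3:, 3:] = blob  # opposite corner
    labels = np.array([0, 1] * 8)
    particles = np.stack([(a if l == 0 else b)
                          + rng.normal(0, 0.05, (12, 12)).astype(np.float32)
                          for l in labels])
    assign = classify_2d(particles, k=2, seed=3, iterations=5,
                         job_dir=tmp_path)
    # purity: each true label maps to exactly one cluster
    m = {}
    for l, c in zip(labels, assign):
        m.setdefault(l, set()).add(int(c))
    assert all(len(s) == 1 for s in m.values())
    assert m[0] != m[1]
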