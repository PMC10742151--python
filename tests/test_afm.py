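"""AFM statistics: flattening, detection, counts, rho(h), complex calls."""

import numpy as np
import pytest

import aptaprobe as ap
from aptaprobe.errors import (
    InsufficientDataError,
    InvalidParameterError,
    UndefinedFractionError,
)


def frame_from(heights, pixel_size=19.53125):
    return ap.TopographyImage(np.asarray(heights, dtype=float), pixel_size)


class TestFlatten:
    def test_removes_exact_tilted_plane(self):
        rows, cols = np.indices((64, 64))
        tilted = frame_from(0.01 * rows - 0.02 * cols + 3.0)
        flat = ap.flatten_background(tilted)
        assert np.max(np.abs(flat.heights)) < 1e-9

    def test_idempotent_on_flat_frame(self):
        rng = np.random.default_rng(0)
        frame = frame_from(rng.normal(0.0, 0.1, (64, 64)))
        once = ap.flatten_background(frame)
        twice = ap.flatten_background(once)
        assert np.allclose(once.heights, twice.heights, atol=1e-9)

    def test_bump_height_preserved(self):
        cfg = ap.GeneratorConfig(seed=0, roughness_rms=0.0)
        spec = ap.ObjectSpec((128.0, 128.0), 1.5, 100.0)
        frame = ap.simulate_topography([spec], cfg, tilt=(0.4, -0.3))
        flat = ap.flatten_background(frame)
        assert flat.heights.max() == pytest.approx(1.5, rel=0.01)

    def test_constant_frame_becomes_zero(self):
        flat = ap.flatten_background(frame_from(np.full((8, 8), 4.2)))
        assert np.all(flat.heights == 0.0)


class TestDetection:
    def test_pure_roughness_frame_is_empty(self):
        for seed in range(5):
            cfg = ap.GeneratorConfig(seed=seed, roughness_rms=0.1)
            frame = ap.simulate_topography([], cfg)
            assert ap.detect_objects(ap.flatten_background(frame)) == []

    def test_five_bumps_recovered_with_heights(self):
        cfg = ap.GeneratorConfig(seed=11, roughness_rms=0.1)
        scene = ap.grid_scene(np.full(5, 1.2), cfg, lateral_sigma=100.0, seed=3)
        frame = ap.simulate_topography(scene, cfg, tilt=(0.3, -0.3))
        objects = ap.detect_objects(ap.flatten_background(frame))
        assert len(objects) == 5
        for obj in objects:
            assert 1.1 <= obj.height <= 1.3
            assert obj.morphology == "compact"

    def test_broad_plateau_classified_layered(self):
        cfg = ap.GeneratorConfig(seed=5, roughness_rms=0.1)
        n_px = cfg.frame_pixels
        plateau = ap.ObjectSpec((n_px / 2, n_px / 2), 1.2,
                                0.31 * n_px * cfg.pixel_size, kind="layered")
        frame = ap.simulate_topography([plateau], cfg)
        objects = ap.detect_objects(ap.flatten_background(frame))
        assert len(objects) == 1
        assert objects[0].morphology == "layered"
        assert objects[0].height == pytest.approx(1.2, abs=0.15)

    def test_exact_scene_recovery_when_heights_dominate_roughness(self):
        rng = np.random.default_rng(1)
        for seed in range(4):
            cfg = ap.GeneratorConfig(seed=300 + seed, roughness_rms=0.1,
                                     frame_edge=10.0)
            heights = rng.uniform(0.5, 3.0, 30)
            scene = ap.grid_scene(heights, cfg, lateral_sigma=80.0, seed=seed)
            frame = ap.simulate_topography(scene, cfg, tilt=(0.2, -0.1))
            objects = ap.detect_objects(ap.flatten_background(frame))
            assert len(objects) == 30


class TestCounts:
    def test_normalization_cases(self):
        assert ap.normalize_count(0, 16, 25.0).n400 == 0.0
        # n x S_fr = 400 -> N400 equals the raw count
        assert ap.normalize_count(19, 16, 25.0).n400 == pytest.approx(19.0)
        assert ap.normalize_count(16, 8, 25.0).n400 == pytest.approx(32.0)

    def test_linearity(self):
        base = ap.normalize_count(10, 4, 25.0).n400
        assert ap.normalize_count(30, 4, 25.0).n400 == pytest.approx(3 * base)
        assert ap.normalize_count(10, 8, 25.0).n400 == pytest.approx(base / 2)
        assert ap.normalize_count(10, 4, 50.0).n400 == pytest.approx(base / 2)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidParameterError):
            ap.normalize_count(5, 0, 25.0)
        with pytest.raises(InvalidParameterError):
            ap.normalize_count(5, 4, 0.0)


def make_objects(heights):
    return [ap.DetectedObject(np.array([[0, 0]]), float(h), 400.0, "compact")
            for h in heights]


class TestHeightDistribution:
    def test_single_height_single_bin(self):
        dist = ap.height_distribution(make_objects([1.3, 1.3, 1.3]))
        assert dist.total_count == 3
        assert dist.rho.max() == pytest.approx(100.0)
        assert np.count_nonzero(dist.rho) == 1

    def test_always_sums_to_hundred(self):
        rng = np.random.default_rng(2)
        for n in (1, 7, 200):
            dist = ap.height_distribution(make_objects(rng.uniform(0.2, 5.0, n)))
            assert dist.rho.sum() == pytest.approx(100.0, abs=1e-9)

    def test_empty_list_flagged(self):
        dist = ap.height_distribution([])
        assert dist.total_count == 0
        assert np.all(dist.rho == 0.0)

    def test_bimodal_modes_recovered(self):
        rng = np.random.default_rng(4)
        cfg = ap.GeneratorConfig(seed=2, roughness_rms=0.1, frame_edge=10.0)
        heights = np.clip(np.concatenate([rng.normal(1.0, 0.1, 60),
                                          rng.normal(1.8, 0.1, 60)]), 0.6, None)
        scene = ap.grid_scene(heights, cfg, lateral_sigma=80.0, seed=5)
        frame = ap.simulate_topography(scene, cfg, tilt=(0.2, 0.1))
        dist = ap.height_distribution(
            ap.detect_objects(ap.flatten_background(frame)), bin_width=0.2)
        centers = dist.bin_edges[:-1] + dist.bin_width / 2
        rho = dist.rho
        modes = [centers[i] for i in range(1, rho.size - 1)
                 if rho[i] >= rho[i - 1] and rho[i] >= rho[i + 1] and rho[i] > 5.0]
        assert any(abs(m - 1.0) <= 0.2 for m in modes)
        assert any(abs(m - 1.8) <= 0.2 for m in modes)


class TestFractionAbove:
    def test_boundary_thresholds(self):
        dist = ap.height_distribution(make_objects([1.0, 2.0, 3.0]))
        assert ap.fraction_above(dist, 0.1) == 100.0
        assert ap.fraction_above(dist, 5.0) == 0.0

    def test_uses_raw_heights_not_bins(self):
        # both heights fall in the same 0.2-wide bin; raw values still split
        dist = ap.height_distribution(make_objects([1.41, 1.39]))
        assert ap.fraction_above(dist, 1.40) == pytest.approx(50.0)

    def test_generated_fraction_exact(self):
        heights = np.concatenate([np.linspace(1.6, 3.0, 88),
                                  np.linspace(0.6, 1.2, 12)])
        dist = ap.height_distribution(make_objects(heights))
        assert ap.fraction_above(dist, 1.4) == pytest.approx(88.0)

    def test_empty_distribution_rejected(self):
        with pytest.raises(UndefinedFractionError):
            ap.fraction_above(ap.height_distribution([]), 1.0)


class TestComplexFormation:
    def test_identical_distributions_no_shift(self):
        dist = ap.height_distribution(make_objects([1.2] * 10))
        call = ap.call_complex_formation(dist, dist, threshold=1.4)
        assert call.verdict == "no-shift"

    def test_clear_shift_called(self):
        before = ap.height_distribution(make_objects(
            np.random.default_rng(0).normal(1.2, 0.1, 100)))
        after = ap.height_distribution(make_objects(
            np.random.default_rng(1).normal(2.0, 0.1, 100)))
        call = ap.call_complex_formation(before, after, threshold=1.4)
        assert call.verdict == "complex-formed"
        assert call.fraction_above_before < 5.0
        assert call.fraction_above_after > 95.0

    def test_sub_threshold_shift_not_called(self):
        before = ap.height_distribution(make_objects([1.0] * 90 + [2.0] * 10))
        after = ap.height_distribution(make_objects([1.0] * 75 + [2.0] * 25))
        call = ap.call_complex_formation(before, after, threshold=1.4,
                                         min_shift_fraction=20.0)
        assert call.verdict == "no-shift"
        # one more percentage point of shift crosses the decision line
        after2 = ap.height_distribution(make_objects([1.0] * 70 + [2.0] * 30))
        assert ap.call_complex_formation(before, after2, 1.4).verdict == \
            "complex-formed"

    def test_empty_inputs_rejected(self):
        good = ap.height_distribution(make_objects([1.0]))
        with pytest.raises(InsufficientDataError):
            ap.call_complex_formation(good, ap.height_distribution([]), 1.4)
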