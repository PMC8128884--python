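import numpy as np
import pytest

from colonyflow import (
    ChanVeseParams,
    DegenerateImageWarning,
    SimulationSpec,
    chan_vese_segment,
    edge_magnitude,
    growth_fraction,
    growth_series,
    iou,
    segment_sequence,
    simulate_sequence,
    smooth_frame,
)
from colonyflow.segmentation import chan_vese_energy, gaussian_kernel_3x3


def _conv3x3_reflect(img, kernel):
    """Brute-force 3×3 correlation with reflected borders (test oracle)."""
    padded = np.pad(img, 1, mode="symmetric")
    out = np.zeros_like(img, dtype=float)
    for di in range(3):
        for dj in range(3):
            out += kernel[di, dj] * padded[
                di : di + img.shape[0], dj : dj + img.shape[1]
            ]
    return out


class TestSmoothing:
    def test_constant_preserved(self):
        img = np.full((16, 16), 0.7)
        np.testing.assert_allclose(smooth_frame(img), img)

    def test_kernel_normalization_single_pixel(self):
        img = np.zeros((15, 15))
        img[7, 7] = 5.0
        out = smooth_frame(img)
        assert out.sum() == pytest.approx(5.0)
        assert np.count_nonzero(out) == 9  # 3×3 support

    def test_matches_explicit_convolution_and_reduces_variance(self):
        rng = np.random.default_rng(0)
        img = (np.indices((20, 20)).sum(axis=0) % 2).astype(float)
        img += 0.05 * rng.standard_normal(img.shape)
        out = smooth_frame(img, sigma=0.8)
        oracle = _conv3x3_reflect(img, gaussian_kernel_3x3(0.8))
        np.testing.assert_allclose(out, oracle, atol=1e-12)
        assert out.var() < img.var()

    def test_rejects_non_2d(self):
        with pytest.raises(ValueError):
            smooth_frame(np.zeros((3, 3, 3)))


class TestEdgeMagnitude:
    def test_constant_gives_zero(self):
        assert edge_magnitude(np.full((10, 10), 0.3)).max() == 0

    def test_vertical_step_response_is_4h(self):
        # hand-convolution of the ±1/±2 Sobel kernel across a step of
        # height h gives |Gx| = 4h on the two columns adjacent to the edge
        h = 0.25
        img = np.zeros((12, 12))
        img[:, 6:] = h
        mag = edge_magnitude(img)
        np.testing.assert_allclose(mag[:, 5], 4 * h)
        np.testing.assert_allclose(mag[:, 6], 4 * h)
        np.testing.assert_allclose(mag[:, :5], 0, atol=1e-12)

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(1)
        img = rng.random((18, 25))
        np.testing.assert_allclose(
            edge_magnitude(img.T), edge_magnitude(img).T, atol=1e-12
        )


def _textured_disk(shape=(160, 160), center=(80, 80), radius=45, seed=0):
    """Disk of high-variance texture on a flat background, with truth mask."""
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    mask = ((yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2).astype(
        np.uint8
    )
    img = np.full(shape, 0.3)
    img[mask == 1] = 0.5 + 0.2 * rng.standard_normal(int(mask.sum()))
    return np.clip(img, 0, 1), mask


class TestChanVese:
    def test_textured_disk_recovered(self):
        # colony-scale disk: the segmentation halo (the ~2-px ring where
        # the smoothed Sobel support extends past the object) is small
        # relative to the object, as at native microscope resolution
        img, truth = _textured_disk(shape=(256, 256), center=(128, 128),
                                    radius=90)
        edge = edge_magnitude(smooth_frame(img))
        mask = chan_vese_segment(edge)
        assert iou(mask, truth) >= 0.95

    def test_constant_edge_image_degenerate(self):
        with pytest.warns(DegenerateImageWarning):
            res = chan_vese_segment(np.zeros((32, 32)), return_result=True)
        assert res.degenerate
        assert res.mask.sum() == 0

    def test_two_level_image_exact_recovery_is_energy_minimizer(self):
        # large piecewise-constant regions: brute-force the energies of all
        # four region labelings; the true split must be the minimizer and
        # the algorithm must return it exactly
        img = np.zeros((48, 48))
        img[12:36, 8:40] = 1.0
        truth = (img == 1).astype(np.uint8)
        params = ChanVeseParams()

        def binary_energy(m):
            phi = np.where(m > 0, 5.0, -5.0)
            return chan_vese_energy(img, phi, params)

        labelings = {
            "truth": truth,
            "inverted": 1 - truth,
            "all_in": np.ones_like(truth),
            "all_out": np.zeros_like(truth),
        }
        energies = {k: binary_energy(m) for k, m in labelings.items()}
        assert min(energies, key=energies.get) == "truth"

        mask = chan_vese_segment(img, params)
        np.testing.assert_array_equal(mask, truth)

    def test_energy_trace_non_increasing(self):
        img, _ = _textured_disk(seed=3)
        edge = edge_magnitude(smooth_frame(img))
        res = chan_vese_segment(edge, return_result=True)
        diffs = np.diff(res.energies)
        assert np.all(diffs <= 1e-9 * np.abs(res.energies[:-1]) + 1e-9)

    def test_idempotent_on_rebinarized_mask(self):
        img, _ = _textured_disk(seed=4)
        edge = edge_magnitude(smooth_frame(img))
        mask = chan_vese_segment(edge)
        again = chan_vese_segment(mask.astype(float))
        np.testing.assert_array_equal(again, mask)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            ChanVeseParams(lambda1=0)
        with pytest.raises(ValueError):
            ChanVeseParams(max_iterations=0)
        with pytest.raises(ValueError):
            ChanVeseParams(init="bogus")


class TestSegmentSequence:
    def test_one_mask_per_frame(self, small_capture):
        seq, _ = small_capture
        masks = segment_sequence(seq)
        assert len(masks) == seq.frame_count
        assert all(m.shape == (seq.height, seq.width) for m in masks)

    def test_identical_frames_identical_masks(self):
        img, _ = _textured_disk(shape=(64, 64), center=(32, 32), radius=20)
        frames = np.stack([img, img, img])
        masks = segment_sequence(frames)
        np.testing.assert_array_equal(masks[0], masks[1])
        np.testing.assert_array_equal(masks[1], masks[2])

    def test_growing_colony_areas_nondecreasing(self):
        spec = SimulationSpec(
            height=128, width=128, n_frames=6, initial_confluency=30,
            confluency_drift=10.0, speed_um_per_h=0.0, seed=5,
        )
        seq, truth = simulate_sequence(spec)
        masks = segment_sequence(seq)
        areas = np.array([m.sum() for m in masks])
        # allow small boundary jitter: any decrease must be < 1% of area
        drops = np.diff(areas)
        assert np.all(drops > -0.01 * areas[:-1])

    def test_decimation_returns_full_size(self, small_capture):
        seq, _ = small_capture
        masks = segment_sequence(seq.frames[:2], decimation=2)
        assert masks[0].shape == (seq.height, seq.width)


class TestGrowthFraction:
    def test_all_and_half(self):
        assert growth_fraction(np.ones((10, 10))) == 100.0
        half = np.zeros((10, 10))
        half[:5] = 1
        assert growth_fraction(half) == 50.0

    def test_full_resolution_arithmetic(self):
        # 1,382,400 cell pixels on a 1920×1440 sensor is exactly half
        mask = np.zeros((1440, 1920), dtype=np.uint8)
        mask.ravel()[:1_382_400] = 1
        assert growth_fraction(mask) == 50.0

    def test_rotation_and_flip_invariance(self):
        rng = np.random.default_rng(6)
        mask = (rng.random((33, 47)) > 0.6).astype(np.uint8)
        ref = growth_fraction(mask)
        for m in (np.rot90(mask), np.rot90(mask, 2), mask[::-1], mask[:, ::-1]):
            assert growth_fraction(m) == ref

    def test_empty_array_error(self):
        with pytest.raises(ValueError):
            growth_fraction(np.zeros((0, 0)))


class TestGrowthSeries:
    def test_constant_masks_constant_series(self):
        mask = np.ones((8, 8))
        assert growth_series([mask] * 4 ) == [100.0] * 4

    def test_length_preserved(self, small_capture):
        _, truth = small_capture
        assert len(growth_series(truth.masks)) == truth.masks.shape[0]

    def test_confluency_ramp_recovered_within_two_points(self):
        spec = SimulationSpec(
            height=128, width=128, n_frames=6, initial_confluency=30,
            confluency_drift=5.0, speed_um_per_h=20.0, seed=4,
        )
        seq, truth = simulate_sequence(spec)
        est = np.array(growth_series(segment_sequence(seq)))
        np.testing.assert_allclose(est, truth.true_growth_series, atol=2.0)

    def test_empty_list_error(self):
        with pytest.raises(ValueError):
            growth_series([])
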