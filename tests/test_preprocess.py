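"""Orientation detection, rotation and collimator removal."""

import numpy as np
import pytest
from scipy import ndimage

from collesmetrics import PhantomParams, Radiograph, generate_phantom, preprocess
from collesmetrics._geometry import rotate_image, transform_points
from collesmetrics.preprocess import (
    detect_collimator_mask,
    detect_orientation,
    extract_central_region,
    rotate_to_vertical,
)


def _band_image(angle_deg: float, shape=(400, 400)) -> np.ndarray:
    """Two bright near-parallel bands rotated by angle_deg from vertical."""
    img = np.full(shape, 20.0)
    img[:, 150:180] = 200.0
    img[:, 220:250] = 200.0
    return rotate_image(img, angle_deg)


class TestCentralRegion:
    @pytest.mark.parametrize(
        "shape, sub_shape, offset",
        [((900, 600), (300, 200), (300, 200)), ((64, 64), (22, 22), (21, 21))],
    )
    def test_thirds_arithmetic(self, shape, sub_shape, offset):
        rad = Radiograph(np.ones(shape), 0.2)
        sub, off = extract_central_region(rad)
        assert sub.shape == sub_shape
        assert off == offset

    def test_subimage_always_within_parent(self, rng):
        for _ in range(50):
            shape = tuple(rng.integers(64, 500, size=2))
            rad = Radiograph(np.ones(shape), 0.2)
            sub, (r0, c0) = extract_central_region(rad)
            assert r0 >= 0 and c0 >= 0
            assert r0 + sub.shape[0] <= shape[0]
            assert c0 + sub.shape[1] <= shape[1]


class TestDetectOrientation:
    def test_bands_at_ten_degrees(self):
        assert detect_orientation(_band_image(10.0)) == pytest.approx(10.0, abs=1.0)

    def test_vertical_bands(self):
        assert detect_orientation(_band_image(0.0)) == pytest.approx(0.0, abs=0.5)

    def test_flat_image_falls_back_to_zero(self, caplog):
        with caplog.at_level("WARNING"):
            angle = detect_orientation(np.full((200, 200), 37.0))
        assert angle == 0.0
        assert "no Hough line" in caplog.text


class TestRotateToVertical:
    def test_zero_angle_is_identity(self, rng):
        rad = Radiograph(rng.uniform(1, 100, (80, 90)), 0.2)
        out = rotate_to_vertical(rad, 0.0)
        np.testing.assert_array_equal(out.pixels, rad.pixels)

    def test_roundtrip_within_interpolation_tolerance(self, rng):
        smooth = ndimage.gaussian_filter(rng.uniform(0, 100, (200, 200)), 5)
        rad = Radiograph(smooth + 10, 0.2)
        fwd = rotate_to_vertical(rad, 17.0)
        back = rotate_to_vertical(fwd, -17.0)
        # compare on the central region of the original, which survives both
        # canvas enlargements unclipped
        r0 = (back.shape[0] - 200) // 2
        c0 = (back.shape[1] - 200) // 2
        core = back.pixels[r0 + 60 : r0 + 140, c0 + 60 : c0 + 140]
        orig = rad.pixels[60:140, 60:140]
        dyn = np.ptp(rad.pixels)
        assert np.mean(np.abs(core - orig)) < 0.02 * dyn

    def test_correction_makes_bands_vertical(self):
        img = _band_image(10.0)
        rad = Radiograph(img, 0.2)
        out = rotate_to_vertical(rad, detect_orientation(img))
        assert abs(detect_orientation(out.pixels)) < 1.0

    def test_out_of_range_angle_rejected(self, rng):
        rad = Radiograph(rng.uniform(1, 10, (64, 64)), 0.2)
        with pytest.raises(ValueError):
            rotate_to_vertical(rad, 135.0)

    def test_landmarks_follow_the_image(self):
        img = np.full((300, 300), 20.0)
        img[140:160, 140:160] = 200.0  # block centred at (149.5, 149.5)
        pts = transform_points(np.array([[149.5, 149.5]]), img.shape, 25.0)
        rot = rotate_image(img, 25.0)
        r, c = np.round(pts[0]).astype(int)
        assert rot[r, c] > 150  # transformed point still on the block


class TestCollimatorMask:
    def test_zero_frame_detected_and_dilated(self):
        img = np.full((100, 100), 50.0)
        img[:10, :] = img[-10:, :] = img[:, :10] = img[:, -10:] = 0.0
        mask = detect_collimator_mask(Radiograph(img, 0.2))
        assert mask[:10, :].all() and mask[:, :10].all()
        assert mask[14, 50] and not mask[16, 50]  # 5 px dilation margin

    def test_positive_image_gives_empty_mask(self):
        mask = detect_collimator_mask(Radiograph(np.full((80, 80), 3.0), 0.2))
        assert not mask.any()

    def test_interior_zero_blob_excluded(self):
        img = np.full((100, 100), 50.0)
        img[:8, :] = 0.0                  # border-touching
        img[40:50, 40:50] = 0.0           # interior annotation blob
        mask = detect_collimator_mask(Radiograph(img, 0.2))
        # oracle: flood fill the zero set from the border
        zeros = img == 0
        lbl, _ = ndimage.label(zeros, structure=np.ones((3, 3)))
        border = set(lbl[0, :]) | set(lbl[-1, :]) | set(lbl[:, 0]) | set(lbl[:, -1])
        expected = np.isin(lbl, [b for b in border if b != 0])
        expected = ndimage.binary_dilation(expected, iterations=5)
        assert not mask[40:50, 40:50].any()
        assert mask[zeros & expected].all()


class TestPreprocessPipeline:
    def test_recovers_phantom_rotation_and_removes_frame(self):
        radiograph, truth = generate_phantom(PhantomParams(rotation_deg=15.0, seed=21))
        result = preprocess(radiograph)
        assert result.rotation_deg == pytest.approx(15.0, abs=1.0)
        assert result.collimator_mask.any()
        # all masked pixels zeroed after rotation: corners of output are 0
        assert result.image.pixels[0, 0] == 0.0

    def test_vertical_frameless_phantom_is_left_alone(self):
        radiograph, _ = generate_phantom(
            PhantomParams(rotation_deg=0.0, collimator_border_px=0, seed=8)
        )
        result = preprocess(radiograph)
        assert abs(result.rotation_deg) < 0.5
        assert not result.collimator_mask.any()

    def test_collimator_mask_disjoint_from_forearm(self, flat_phantom):
        radiograph, truth = flat_phantom
        mask = detect_collimator_mask(radiograph)
        assert not (mask & truth.masks["forearm"]).any()

    def test_idempotent_within_tolerance(self, default_phantom):
        radiograph, _ = default_phantom
        first = preprocess(radiograph)
        second = preprocess(first.image)
        assert abs(second.rotation_deg) < 1.0

    def test_orientation_recovery_spot_check(self, rng):
        errors = []
        for _ in range(5):
            angle = float(rng.uniform(-25, 25))
            radiograph, _ = generate_phantom(
                PhantomParams(rotation_deg=angle, seed=int(rng.integers(1 << 30)))
            )
            errors.append(abs(preprocess(radiograph).rotation_deg - angle))
        assert np.mean(errors) <= 1.0

    def test_large_image_preprocesses_quickly(self):
        import time

        radiograph, _ = generate_phantom(
            PhantomParams(shape=(2000, 1500), spacing_mm=0.1, seed=4)
        )
        start = time.perf_counter()
        preprocess(radiograph)
        assert time.perf_counter() - start < 5.0
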