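import numpy as np
import pytest

from pavasc.core import Volume3D
from pavasc.vessels import (
    VesselMap,
    enhance_vessels,
    frangi_direction,
    jerman_vesselness,
    mip_2d,
    normalize01,
    suppress_vertical,
)


def tube_image(n=128, sigma=2.0, pos=None, orientation="horizontal", amplitude=1.0):
    """Gaussian tube; 'horizontal' = extended along X (axis 0)."""
    pos = n // 2 if pos is None else pos
    x = np.arange(n, dtype=float)
    prof = amplitude * np.exp(-((x - pos) ** 2) / (2 * sigma**2))
    if orientation == "horizontal":
        return np.tile(prof[None, :], (n, 1))
    return np.tile(prof[:, None], (1, n))


class TestMip:
    def test_single_bright_voxel(self):
        values = np.zeros((6, 7, 8))
        values[2, 3, 4] = 5.0
        v = Volume3D(values, (0.1,) * 3, "PA", 532)
        out = mip_2d(v, np.ones(values.shape, bool))
        assert out[2, 3] == 5.0
        assert out.sum() == 5.0

    def test_constant_masked_volume(self):
        v = Volume3D(np.full((4, 4, 4), 2.5), (0.1,) * 3, "PA", 532)
        mask = np.zeros((4, 4, 4), bool)
        mask[:, :, 1:3] = True
        np.testing.assert_array_equal(mip_2d(v, mask), 2.5)

    def test_brighter_of_two_depths_wins(self):
        values = np.zeros((4, 4, 8))
        values[1, 1, 2] = 1.0
        values[1, 1, 6] = 3.0
        v = Volume3D(values, (0.1,) * 3, "PA", 532)
        assert mip_2d(v, np.ones(values.shape, bool))[1, 1] == 3.0

    def test_empty_masked_column_is_zero(self):
        values = np.ones((3, 3, 4))
        mask = np.ones((3, 3, 4), bool)
        mask[0, 0, :] = False
        assert mip_2d(Volume3D(values, (0.1,) * 3, "US"), mask)[0, 0] == 0.0

    def test_empty_mask_rejected(self):
        v = Volume3D(np.ones((3, 3, 3)), (0.1,) * 3, "US")
        with pytest.raises(ValueError, match="empty"):
            mip_2d(v, np.zeros((3, 3, 3), bool))


class TestNormalize01:
    def test_range_mapped(self):
        out = normalize01(np.array([[2.0, 6.0], [4.0, 2.0]]))
        assert out.min() == 0.0 and out.max() == 1.0

    def test_constant_map_warns_and_zeros(self):
        with pytest.warns(UserWarning, match="constant"):
            out = normalize01(np.full((3, 3), 4.2))
        assert np.all(out == 0)

    def test_order_preserved(self, rng):
        m = rng.random((10, 10))
        out = normalize01(m)
        assert np.array_equal(np.argsort(m, axis=None), np.argsort(out, axis=None))


class TestJerman:
    def test_uniform_image_zero(self):
        assert np.all(jerman_vesselness(np.full((32, 32), 0.5), 4.0) == 0)

    def test_tube_centerline_vs_background(self):
        img = tube_image(sigma=2.0)
        v = jerman_vesselness(img, 4.0)
        assert v[64, 64] > 0.5
        assert v[10, 10] < 0.05 and v[110, 20] < 0.05

    def test_blob_penalized_vs_tube(self):
        img = tube_image(sigma=2.0, pos=40)
        xx, yy = np.meshgrid(np.arange(128), np.arange(128), indexing="ij")
        img = img + np.exp(-((xx - 64) ** 2 + (yy - 90) ** 2) / (2 * 1.0**2))
        v = jerman_vesselness(img, 4.0)
        assert v[64, 90] < v[64, 40]

    def test_scale_tuning_peaks_near_radius_4(self):
        # four tubes of radius 1/2/4/8 px plus a strong reference tube that
        # sets the frame max, keeping the test tubes out of saturation
        n = 256
        x = np.arange(n, dtype=float)
        img = np.zeros((n, n))
        centers = {1: 40, 2: 90, 4: 150, 8: 210}
        for r, c in centers.items():
            img += np.exp(-((x - c) ** 2) / (2 * (r / 2) ** 2))[None, :]
        img += 10 * np.exp(-((x - 15) ** 2) / (2 * 2.83**2))[None, :]
        v = jerman_vesselness(img, 4.0)
        resp = {r: v[n // 2, c] for r, c in centers.items()}
        assert max(resp, key=resp.get) == 4

    def test_non_positive_scale_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            jerman_vesselness(np.ones((8, 8)), 0.0)

    def test_output_in_unit_interval(self, rng):
        v = jerman_vesselness(rng.random((48, 48)), 4.0)
        assert v.min() >= 0 and v.max() <= 1


class TestDirection:
    def test_vertical_tube_angle_zero(self):
        th = frangi_direction(tube_image(orientation="vertical"), 4.0)
        assert abs(th[64, 64]) < 1e-6

    def test_horizontal_tube_angle_pi_half(self):
        th = frangi_direction(tube_image(orientation="horizontal"), 4.0)
        assert abs(abs(th[64, 64]) - np.pi / 2) < 1e-6

    def test_45_degree_tube(self):
        n = 128
        xx, yy = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        img = np.exp(-(((xx - yy) / np.sqrt(2)) ** 2) / (2 * 2.0**2))
        th = frangi_direction(img, 4.0)
        assert abs(abs(th[64, 64]) - np.pi / 4) < 0.05

    def test_range(self, rng):
        th = frangi_direction(rng.random((32, 32)), 4.0)
        assert np.all(th > -np.pi / 2) and np.all(th <= np.pi / 2)


def two_structure_image(n=128):
    """Horizontal tube at y=40 plus a vertical ridge segment at x=90."""
    x = np.arange(n, dtype=float)
    img = np.tile(np.exp(-((x - 40) ** 2) / (2 * 2.0**2))[None, :], (n, 1))
    ridge = np.exp(-((x - 90) ** 2) / (2 * 2.0**2))[:, None]
    img = img + ridge * (x >= 60)[None, :]
    tube_region = np.zeros((n, n), bool)
    tube_region[:, 28:53] = True
    ridge_region = np.zeros((n, n), bool)
    ridge_region[78:103, 60:] = True
    ridge_region &= ~tube_region
    return img, tube_region, ridge_region


class TestSuppression:
    def test_selectivity(self):
        img, tube, ridge = two_structure_image()
        e = jerman_vesselness(img, 4.0)
        s = suppress_vertical(e, frangi_direction(img, 4.0))
        assert s[tube].sum() / e[tube].sum() >= 0.9
        assert 1 - s[ridge].sum() / e[ridge].sum() >= 0.9

    def test_rotation_swaps_outcome(self):
        img, tube, ridge = two_structure_image()
        rot = np.rot90(img)
        e = jerman_vesselness(rot, 4.0)
        s = suppress_vertical(e, frangi_direction(rot, 4.0))
        tube_r, ridge_r = np.rot90(tube), np.rot90(ridge)
        assert 1 - s[tube_r].sum() / e[tube_r].sum() >= 0.9  # now vertical
        assert s[ridge_r].sum() / e[ridge_r].sum() >= 0.9  # now horizontal

    def test_zero_map_stays_zero(self):
        out = suppress_vertical(np.zeros((8, 8)), np.zeros((8, 8)))
        assert np.all(out == 0)

    def test_empty_band_is_identity(self, rng):
        e = rng.random((8, 8))
        th = rng.uniform(-1.5, 1.5, (8, 8))
        np.testing.assert_array_equal(suppress_vertical(e, th, band=(-0.0, 0.0)), e)

    def test_inverted_band_rejected(self):
        with pytest.raises(ValueError, match="inverted"):
            suppress_vertical(np.ones((4, 4)), np.zeros((4, 4)), band=(0.5, -0.5))

    def test_suppressed_bounded_by_enhanced(self, rng):
        e = rng.random((16, 16))
        th = rng.uniform(-np.pi / 2, np.pi / 2, (16, 16))
        s = suppress_vertical(e, th)
        assert np.all(s <= e)


class TestVesselMapAndPipeline:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="suppressed"):
            VesselMap(
                mip=np.ones((2, 2)),
                enhanced=np.zeros((2, 2)),
                direction=np.zeros((2, 2)),
                suppressed=np.ones((2, 2)),
            )

    def test_enhance_vessels_end_to_end(self, flat_phantom):
        from pavasc import synthetic as syn
        from pavasc.segmentation import segment_session

        us = syn.generate_us_volume(flat_phantom, seed=0)
        seg = segment_session(us)
        stack = syn.generate_pa_stack(flat_phantom, seed=0)
        vm = enhance_vessels(stack[532], seg.skin_mask)
        assert vm.enhanced.min() >= 0 and vm.enhanced.max() <= 1
        assert np.all(vm.suppressed <= vm.enhanced + 1e-12)
        # the phantom's vessels are horizontal: suppression keeps them
        assert vm.suppressed.sum() > 0.5 * vm.enhanced.sum()
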