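"""View geometry and the surface-anchored MIP."""

from dataclasses import replace

import numpy as np
import pytest

from ctoam.errors import ConfigError, GeometryError, InputError
from ctoam.experiments import random_test_volume
from ctoam.projection import (
    default_views,
    dorsal_view,
    make_view,
    project_mip,
    proximal_view,
)
from ctoam.reference import mip_bruteforce
from ctoam.synthetic import generate_volume
from ctoam.volume import BoneMask, CtVolume


class TestMakeView:
    def test_zero_tilt_is_proximal(self):
        v = make_view("base", 0.0)
        np.testing.assert_allclose(v.projection_axis, [0, 0, -1], atol=1e-12)

    def test_ninety_degree_tilt_gives_dorsal_axis(self):
        v = make_view("dorsal", 90.0)
        np.testing.assert_allclose(v.projection_axis, [0, 1, 0], atol=1e-12)
        e0, e1 = v.in_plane_basis
        np.testing.assert_allclose(e0, [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(e1, [0, 0, 1], atol=1e-12)

    def test_double_tilt_is_antiparallel(self):
        v = make_view("flipped", 180.0)
        np.testing.assert_allclose(v.projection_axis, [0, 0, 1], atol=1e-12)

    def test_degenerate_axis_rejected(self):
        with pytest.raises(GeometryError):
            make_view("bad", 0.0, base_axis=(0, 0, 0))


def _box_volume(c=700.0, shape=(12, 12, 12)):
    vol = np.full(shape, 0.0)
    mask = np.zeros(shape, dtype=bool)
    mask[3:9, 3:9, 3:9] = True
    vol[mask] = c
    return CtVolume(vol, (1.0, 1.0, 1.0)), BoneMask(mask)


class TestProjectMip:
    def test_constant_bone_projects_constant(self):
        vol, mask = _box_volume(c=700.0)
        for view in default_views():
            dg = project_mip(vol, mask, view)
            assert dg.surface_mask.any()
            np.testing.assert_allclose(dg.values_hu[dg.surface_mask], 700.0)
            # values defined exactly on the surface mask
            assert np.all(np.isnan(dg.values_hu[~dg.surface_mask]))

    def test_shell_dominates_when_depth_covers_shell(self, quiet_spec):
        """High-density shell over low interior: every surface pixel reports
        shell-level HU when the MIP depth reaches through the shell."""
        spec = replace(quiet_spec, hotspots=())
        vol, mask, _ = generate_volume(spec)
        shell_hu = (spec.shell_base_density - spec.true_calibration[1]) / spec.true_calibration[0]
        dg = project_mip(vol, mask, proximal_view(mip_depth=2.5))
        vals = dg.values_hu[dg.surface_mask]
        np.testing.assert_allclose(vals, shell_hu, atol=1e-6)

    def test_matches_bruteforce_reference(self, rng):
        for _ in range(3):
            vol, mask = random_test_volume(rng, max_side=16)
            view = make_view("tilt", float(rng.uniform(0, 90)), mip_depth=2.0)
            fast = project_mip(vol, mask, view)
            slow = mip_bruteforce(vol, mask, view)
            assert np.array_equal(fast.surface_mask, slow.surface_mask)
            np.testing.assert_allclose(
                fast.values_hu[fast.surface_mask],
                slow.values_hu[slow.surface_mask],
                atol=1.0,
            )

    def test_translation_leaves_densitogram_unchanged(self, rng):
        """The pixel grid is anchored to the bone's bounding box, so a whole
        -voxel translation of volume + mask reproduces the same densitogram."""
        shape = (16, 16, 16)
        vol = rng.normal(500, 200, size=shape)
        mask = np.zeros(shape, dtype=bool)
        mask[4:9, 5:10, 4:9] = True
        v1 = CtVolume(vol, (1.0, 1.0, 1.0))
        shift = (2, 1, 3)
        v2 = CtVolume(np.roll(vol, shift, axis=(0, 1, 2)), (1.0, 1.0, 1.0))
        m2 = np.roll(mask, shift, axis=(0, 1, 2))
        for view in default_views():
            d1 = project_mip(v1, BoneMask(mask), view)
            d2 = project_mip(v2, BoneMask(m2), view)
            assert np.array_equal(d1.surface_mask, d2.surface_mask)
            np.testing.assert_allclose(
                d1.values_hu[d1.surface_mask], d2.values_hu[d2.surface_mask], atol=1e-9
            )

    def test_monotone_in_hu(self, rng):
        vol, mask = random_test_volume(rng, max_side=14)
        view = proximal_view()
        base = project_mip(vol, mask, view)
        bumped = CtVolume(vol.voxels + np.abs(rng.normal(0, 50, vol.shape)), vol.spacing)
        up = project_mip(bumped, mask, view)
        s = base.surface_mask
        assert np.all(up.values_hu[s] >= base.values_hu[s] - 1e-9)

    def test_monotone_in_depth(self, rng):
        vol, mask = random_test_volume(rng, max_side=14)
        shallow = project_mip(vol, mask, proximal_view(mip_depth=1.0))
        deep = project_mip(vol, mask, proximal_view(mip_depth=3.0))
        s = shallow.surface_mask
        assert np.array_equal(s, deep.surface_mask)
        assert np.all(deep.values_hu[s] >= shallow.values_hu[s] - 1e-9)

    def test_exterior_voxels_never_contribute(self, rng):
        """Poisoning every out-of-mask voxel with +1e6 HU must not change a
        single surface value."""
        vol, mask = random_test_volume(rng, max_side=14)
        poisoned = vol.voxels.copy()
        poisoned[~mask.data] = 1e6
        for view in default_views():
            d1 = project_mip(vol, mask, view)
            d2 = project_mip(CtVolume(poisoned, vol.spacing), mask, view)
            np.testing.assert_allclose(
                d1.values_hu[d1.surface_mask], d2.values_hu[d2.surface_mask], atol=1e-9
            )

    def test_empty_mask_rejected(self):
        with pytest.raises(InputError):
            BoneMask(np.zeros((4, 4, 4), dtype=bool))

    def test_depth_below_step_rejected(self):
        vol, mask = _box_volume()
        with pytest.raises(ConfigError):
            project_mip(vol, mask, proximal_view(mip_depth=0.2), step=0.5)


class TestDensitogramFrame:
    def test_plane_to_pixel_roundtrip(self):
        vol, mask = _box_volume()
        dg = project_mip(vol, mask, dorsal_view())
        r, c = dg.plane_to_pixel(dg.u0, dg.v0)
        assert (r, c) == pytest.approx((0.0, 0.0))
        u = dg.u0 + 3 * dg.pixel_size
        assert dg.plane_to_pixel(u, dg.v0)[1] == pytest.approx(3.0)
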