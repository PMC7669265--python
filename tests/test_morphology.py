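import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import organquant as oq
from organquant.errors import AlignmentStateError, SegmentationError
from organquant.morphology import OrganMask, voxelize_mesh
from conftest import rasterize_ellipse, rasterize_rectangle


class TestSliceGeometryClosedForms:
    def test_disc(self):
        r = 10.0
        g = oq.slice_geometry(rasterize_ellipse(r, r), (1.0, 1.0))
        assert g.area_um2 == pytest.approx(np.pi * r**2, rel=0.03)
        assert g.circularity == pytest.approx(1.0, rel=0.03)
        assert g.i_max_um4 == pytest.approx(np.pi * r**4 / 4, rel=0.05)
        assert g.i_min_um4 == pytest.approx(np.pi * r**4 / 4, rel=0.05)

    def test_axis_aligned_ellipse(self):
        g = oq.slice_geometry(rasterize_ellipse(20.0, 10.0), (1.0, 1.0))
        assert g.chord_major_um == pytest.approx(40.0, rel=0.03)
        assert g.chord_minor_um == pytest.approx(20.0, rel=0.03)
        assert g.circularity == pytest.approx(0.5, rel=0.03)

    def test_ellipse_rotation_invariance(self):
        vals = [
            oq.slice_geometry(rasterize_ellipse(20.0, 10.0, angle_deg=a), (1.0, 1.0)).circularity
            for a in range(0, 91, 15)
        ]
        assert (max(vals) - min(vals)) / np.mean(vals) < 0.02

    def test_rectangle_second_moments(self):
        w, h = 30.0, 10.0
        g = oq.slice_geometry(rasterize_rectangle(w, h), (1.0, 1.0))
        assert g.area_um2 == pytest.approx(w * h, rel=0.03)
        assert g.i_max_um4 == pytest.approx(h * w**3 / 12, rel=0.03)
        assert g.i_min_um4 == pytest.approx(w * h**3 / 12, rel=0.03)

    def test_error_shrinks_with_resolution(self):
        errs = []
        for d in (2.0, 1.0, 0.5):
            g = oq.slice_geometry(rasterize_ellipse(10.0, 10.0, spacing=(d, d)), (d, d))
            errs.append(abs(g.area_um2 - np.pi * 100) / (np.pi * 100))
        assert errs[0] > errs[1] > errs[2]

    def test_circularity_scale_invariant_exactly(self):
        base = rasterize_ellipse(20.0, 10.0, angle_deg=30.0)
        g1 = oq.slice_geometry(base, (1.0, 1.0))
        g2 = oq.slice_geometry(base, (3.0, 3.0))  # same raster, scaled pixels
        assert g2.circularity == pytest.approx(g1.circularity, abs=1e-12)

    def test_empty_and_single_pixel_slices(self):
        g = oq.slice_geometry(np.zeros((5, 5), bool), (1.0, 1.0))
        assert g.area_um2 == 0.0 and np.isnan(g.circularity)
        single = np.zeros((5, 5), bool)
        single[2, 2] = True
        assert np.isnan(oq.slice_geometry(single, (1.0, 1.0)).circularity)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            oq.slice_geometry(np.arange(9).reshape(3, 3), (1.0, 1.0))


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    arr=arrays(bool, st.tuples(st.integers(2, 14), st.integers(2, 14))),
    d0=st.floats(0.5, 3.0),
    d1=st.floats(0.5, 3.0),
)
def test_slice_geometry_invariants(arr, d0, d1):
    """Area/moment/chord invariants hold on arbitrary binary sections."""
    g = oq.slice_geometry(arr, (d0, d1))
    n = int(arr.sum())
    assert g.area_um2 == pytest.approx(n * d0 * d1)
    assert g.i_max_um4 >= g.i_min_um4 >= 0.0
    assert g.chord_major_um >= g.chord_minor_um >= 0.0
    if n > 1:
        assert 0.0 < g.circularity <= 1.0 + 1e-12


class TestSegmentOrgan:
    def test_phantom_volume_within_5_percent(self, snr5_phantom):
        organ, _, _, spec = snr5_phantom
        mask = oq.segment_organ(organ)
        assert mask.volume_um3 == pytest.approx(spec.analytic_volume_um3(), rel=0.05)

    def test_single_component_no_holes(self, snr5_phantom):
        organ, _, _, _ = snr5_phantom
        mask = oq.segment_organ(organ)
        assert mask.n_components() == 1
        assert mask.n_interior_holes() == 0

    def test_all_zero_stack_raises(self):
        stack = oq.VolumeStack(np.zeros((10, 10, 10), np.uint8), (1, 1, 1))
        with pytest.raises(SegmentationError, match="threshold"):
            oq.segment_organ(stack, threshold=10.0)


class TestMaskChannel:
    def test_full_mask_is_identity(self):
        data = np.random.default_rng(0).integers(0, 99, size=(6, 7, 8)).astype(np.uint16)
        stack = oq.VolumeStack(data, (1, 1, 1))
        mask = OrganMask(np.ones_like(data, bool), (1, 1, 1))
        np.testing.assert_array_equal(oq.mask_channel(stack, mask).data, data)

    def test_empty_mask_zeroes_everything(self):
        stack = oq.VolumeStack(np.ones((4, 4, 4), np.uint8), (1, 1, 1))
        mask = OrganMask(np.zeros((4, 4, 4), bool), (1, 1, 1))
        assert oq.mask_channel(stack, mask).data.max() == 0

    def test_foreground_sum_conserved(self):
        data = np.random.default_rng(1).integers(0, 99, size=(5, 5, 5)).astype(np.int64)
        m = np.random.default_rng(2).random((5, 5, 5)) > 0.5
        stack = oq.VolumeStack(data, (1, 1, 1))
        out = oq.mask_channel(stack, OrganMask(m, (1, 1, 1)))
        assert int(out.data.sum()) == int(data[m].sum())

    def test_shape_mismatch_rejected(self):
        stack = oq.VolumeStack(np.ones((4, 4, 4)), (1, 1, 1))
        with pytest.raises(ValueError, match="mismatch"):
            oq.mask_channel(stack, OrganMask(np.ones((4, 4, 5), bool), (1, 1, 1)))


class TestGeometryProfile:
    def test_uniform_cylinder_constant_interior_area(self):
        zz, yy, xx = np.meshgrid(*(np.arange(s) for s in (40, 40, 80)), indexing="ij")
        cyl = ((zz - 19.5) ** 2 + (yy - 19.5) ** 2 <= 144) & (xx >= 5) & (xx < 75)
        prof = oq.geometry_profile(OrganMask(cyl, (1, 1, 1), axis_aligned=True))
        interior = [s.area_um2 for s in prof.slices[10:70]]
        assert max(interior) == pytest.approx(min(interior), rel=0.05)

    def test_tapered_phantom_tracks_analytic_area(self, snr5_phantom):
        organ, _, _, spec = snr5_phantom
        mask = oq.segment_organ(organ)
        mask.axis_aligned = True  # generated unrotated
        prof = oq.geometry_profile(mask)
        dx = spec.spacing[2]
        x0 = spec.grid_center_um[2] - spec.length_um / 2
        for frac in (0.2, 0.4, 0.6, 0.8):
            k = int(round((x0 + frac * spec.length_um) / dx))
            a, b = spec.semi_axes_at(frac)
            assert prof.slices[k].area_um2 == pytest.approx(np.pi * a * b, rel=0.05)

    def test_total_volume_equals_voxel_volume_exactly(self):
        m = np.random.default_rng(3).random((10, 12, 14)) > 0.6
        mask = OrganMask(m, (2.0, 1.5, 1.0), axis_aligned=True)
        prof = oq.geometry_profile(mask)
        assert prof.total_volume_um3 == pytest.approx(mask.volume_um3, rel=1e-12)

    def test_unaligned_mask_rejected(self):
        with pytest.raises(AlignmentStateError):
            oq.geometry_profile(OrganMask(np.ones((4, 4, 4), bool), (1, 1, 1), axis_aligned=False))


class TestExportMesh:
    def test_voxel_cube_volume(self, tmp_path):
        m = np.zeros((26, 26, 26), bool)
        m[3:23, 3:23, 3:23] = True
        mesh = oq.export_mesh(OrganMask(m, (1, 1, 1)), tmp_path / "cube.stl")
        assert mesh.is_watertight
        assert mesh.volume == pytest.approx(8000.0, rel=0.10)
        assert (tmp_path / "cube.stl").stat().st_size > 0

    def test_cylinder_watertight_and_dice(self):
        zz, yy, xx = np.meshgrid(*(np.arange(s) for s in (30, 30, 60)), indexing="ij")
        cyl = ((zz - 14.5) ** 2 + (yy - 14.5) ** 2 <= 100) & (xx >= 5) & (xx < 55)
        mask = OrganMask(cyl, (1, 1, 1))
        mesh = oq.export_mesh(mask)
        assert mesh.is_watertight
        vox = voxelize_mesh(mesh, cyl.shape, mask.spacing)
        dice = 2 * np.logical_and(vox, cyl).sum() / (vox.sum() + cyl.sum())
        assert dice > 0.95

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            oq.export_mesh(OrganMask(np.zeros((4, 4, 4), bool), (1, 1, 1)))
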