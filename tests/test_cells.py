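import numpy as np
import pytest

import organquant as oq
from organquant.cells import objects_to_dataframe
from organquant.errors import AlignmentStateError
from organquant.metrics import match_centroids
from organquant.morphology import OrganMask


class TestEnhanceCells:
    def test_constant_stack_flattens_to_near_zero(self):
        stack = oq.VolumeStack(np.full((20, 20, 20), 50.0), (1, 1, 1))
        out = oq.enhance_cells(stack)
        assert out.data.max() <= 1.0

    def test_blob_peak_location_preserved(self):
        data = np.zeros((30, 30, 30), np.float64)
        zz, yy, xx = np.meshgrid(*(np.arange(30),) * 3, indexing="ij")
        r2 = (zz - 15) ** 2 + (yy - 15) ** 2 + (xx - 15) ** 2
        data += 100 * np.exp(-r2 / (2 * 3.0**2))
        out = oq.enhance_cells(oq.VolumeStack(data, (1, 1, 1)))
        peak = np.unravel_index(np.argmax(out.data), out.data.shape)
        assert np.abs(np.array(peak) - 15).max() <= 1

    def test_linear_ramp_background_removed(self):
        """Post-filter background falls near zero while the blob keeps >=50% height."""
        shape = (24, 24, 60)
        zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
        ramp = 20.0 + 0.5 * xx
        blob = 120 * np.exp(-(((zz - 12) ** 2 + (yy - 12) ** 2 + (xx - 30) ** 2) / (2 * 3.0**2)))
        out = oq.enhance_cells(oq.VolumeStack(ramp + blob, (1, 1, 1)))
        corner = out.data[2:6, 2:6, 45:55].mean()
        assert corner < 0.05 * 120
        assert out.data[12, 12, 30] >= 0.5 * 120 * 0.35  # blur spreads the peak

    def test_invalid_parameters_rejected(self):
        stack = oq.VolumeStack(np.ones((5, 5, 5)), (1, 1, 1))
        with pytest.raises(ValueError):
            oq.enhance_cells(stack, background_radius_um=0)
        with pytest.raises(ValueError):
            oq.enhance_cells(stack, blur_sigma_um=-1)


class TestSegmentAndCount:
    def test_detection_precision_recall(self, detected_snr5):
        _, objects, truth, spec = detected_snr5
        detected = np.array([o.centroid_um for o in objects])
        m = match_centroids(truth.cell_centroids_um(), detected, radius_um=spec.cell_radius_um)
        assert m["precision"] >= 0.95
        assert m["recall"] >= 0.95

    def test_doublet_splits_only_with_watershed(self, doublet_phantom):
        _, cell, truth, _ = doublet_phantom
        enhanced = oq.enhance_cells(cell)
        assert oq.segment_cells(enhanced, split=True).max() == 2
        assert oq.segment_cells(enhanced, split=False).max() == 1

    def test_singlets_never_oversplit(self, detected_snr5):
        labels, objects, truth, _ = detected_snr5
        assert labels.max() == len(truth.cells)

    def test_detection_degrades_gracefully_with_snr(self):
        from organquant.phantom import detection_scenario_spec

        recalls = []
        for snr in (2.0, 5.0):
            spec = detection_scenario_spec(seed=13, n_cells=30, snr=snr)
            _, cell, truth = oq.generate_phantom(spec)
            labels = oq.segment_cells(oq.enhance_cells(cell))
            det = np.array([o.centroid_um for o in oq.count_objects(labels, cell.spacing, cell.data)])
            recalls.append(match_centroids(truth.cell_centroids_um(), det, spec.cell_radius_um)["recall"])
        assert recalls[0] <= recalls[1] + 1e-9
        assert recalls[1] >= 0.95

    def test_empty_enhanced_stack_gives_no_labels(self):
        stack = oq.VolumeStack(np.zeros((10, 10, 10), np.float32), (1, 1, 1))
        labels = oq.segment_cells(stack)
        assert labels.max() == 0
        assert oq.count_objects(labels, (1, 1, 1), stack.data) == []

    def test_invalid_volume_bounds_rejected(self):
        stack = oq.VolumeStack(np.ones((5, 5, 5), np.float32), (1, 1, 1))
        with pytest.raises(ValueError, match="min_volume"):
            oq.segment_cells(stack, min_volume_um3=100, max_volume_um3=10)

    def test_cube_object_closed_form(self):
        labels = np.zeros((10, 10, 10), np.int32)
        labels[2:5, 3:6, 4:7] = 1
        objs = oq.count_objects(labels, (1, 1, 1), np.full((10, 10, 10), 7.0))
        (obj,) = objs
        assert obj.voxel_count == 27
        assert obj.volume_um3 == 27.0
        assert obj.mean_intensity == 7.0
        np.testing.assert_allclose(obj.centroid_um, [3.0, 4.0, 5.0])

    def test_voxel_count_conservation_and_volume_law(self, detected_snr5):
        labels, objects, _, spec = detected_snr5
        assert sum(o.voxel_count for o in objects) == int(np.count_nonzero(labels))
        voxvol = np.prod(spec.spacing)
        for o in objects:
            assert o.volume_um3 == pytest.approx(o.voxel_count * voxvol, rel=1e-12)

    def test_object_volume_matches_analytic_threshold_sphere(self):
        """Thresholding an ideal Gaussian blob yields the closed-form sphere volume."""
        spec = oq.PhantomSpec(
            shape=(48, 84, 200), spacing=(2.0, 1.0, 1.0), length_um=160.0,
            proximal_semi_axes_um=(34.0, 30.0), distal_semi_axes_um=(34.0, 30.0),
            n_cells=4, cell_radius_um=8.0, cell_radius_sd_um=0.0,
            cell_peak_intensity=100.0, cell_peak_sd=0.0, background=0.0,
            min_cell_separation_um=25.0, noise_sd=0.0, rng_seed=21,
        )
        _, _, truth = oq.generate_phantom(spec)
        thr = 50.0
        enhanced = oq.VolumeStack(truth.cell_noise_free.astype(np.float32), spec.spacing)
        labels = oq.segment_cells(enhanced, threshold=thr, split=False)
        objs = oq.count_objects(labels, spec.spacing, truth.cell_noise_free)
        sigma = spec.cell_radius_um / 2
        r_star = sigma * np.sqrt(2 * np.log(spec.cell_peak_intensity / thr))
        analytic = 4 / 3 * np.pi * r_star**3
        assert len(objs) == 4
        for o in objs:
            assert o.volume_um3 == pytest.approx(analytic, rel=0.15)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            oq.count_objects(np.zeros((3, 3, 3), np.int32), (1, 1, 1), np.zeros((3, 3, 4)))

    def test_object_table_columns(self, detected_snr5):
        _, objects, _, _ = detected_snr5
        df = objects_to_dataframe(objects)
        assert list(df.columns) == [
            "label", "x_um", "y_um", "z_um", "voxel_count", "volume_um3", "mean_intensity",
        ]
        assert len(df) == len(objects)


def _cell_at(x_um, y_um=10.0, z_um=10.0):
    return oq.CellObject(
        label=1, centroid_um=np.array([z_um, y_um, x_um]), voxel_count=1,
        volume_um3=1.0, mean_intensity=1.0,
        bbox_min_um=np.zeros(3), bbox_max_um=np.zeros(3),
    )


class TestDensityProfile:
    def _mask(self, nx=120, dx=1.0):
        m = np.zeros((20, 20, nx), bool)
        m[5:15, 5:15, :] = True
        return OrganMask(m, (1.0, 1.0, dx), axis_aligned=True)

    def test_no_cells_all_zero(self):
        prof = oq.density_profile([], self._mask())
        assert prof.counts.sum() == 0
        assert np.all(prof.density_per_mm3 == 0)

    def test_boundary_centroid_half_open_rule(self):
        prof = oq.density_profile([_cell_at(50.0)], self._mask())
        assert prof.counts[1] == 1  # belongs to [50, 100), not [0, 50)
        assert prof.counts[0] == 0

    def test_count_conservation_exact(self, detected_snr5, snr5_phantom):
        organ, _, _, spec = snr5_phantom
        _, objects, _, _ = detected_snr5
        mask = oq.segment_organ(organ)
        mask.axis_aligned = True
        prof = oq.density_profile(objects, mask)
        assert prof.counts.sum() + prof.n_outside == len(objects)

    def test_uniform_density_recovered(self, density_phantom):
        """Slab counts of a uniform-λ phantom stay within Poisson bounds."""
        organ, cell, truth, spec = density_phantom
        mask = oq.segment_organ(organ)
        mask.axis_aligned = True
        # enhance before masking: the mask edge must not enter the high-pass
        labels = oq.segment_cells(oq.mask_channel(oq.enhance_cells(cell), mask))
        objects = oq.count_objects(labels, cell.spacing, cell.data)
        prof = oq.density_profile(objects, mask)
        lam = spec.cell_density_per_mm3 / 1e9  # cells / µm³
        expected = lam * prof.slab_volumes_um3
        ok = np.abs(prof.counts - expected) <= 3 * np.sqrt(np.maximum(expected, 1))
        assert ok.mean() >= 0.8

    def test_invalid_slab_thickness(self):
        with pytest.raises(ValueError, match="thickness"):
            oq.density_profile([], self._mask(), slab_um=0)

    def test_unaligned_mask_rejected(self):
        mask = self._mask()
        mask.axis_aligned = False
        with pytest.raises(AlignmentStateError):
            oq.density_profile([], mask)

    def test_density_units(self):
        """One cell in a slab of known volume gives count/volume in cells/mm³."""
        mask = self._mask(nx=50)
        prof = oq.density_profile([_cell_at(25.0)], mask)
        slab_vol_um3 = 10 * 10 * 50  # 5000 µm³
        assert prof.slab_volumes_um3[0] == pytest.approx(slab_vol_um3)
        assert prof.density_per_mm3[0] == pytest.approx(1 / slab_vol_um3 * 1e9)
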