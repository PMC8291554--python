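import numpy as np
import pytest

from visor.geometry import AcquisitionGeometry
from visor.phantom import (CellSpec, NoiseSpec, PhantomSpec,
                           cut_and_deform_slices, evaluate_deformation,
                           invert_deformation, make_fst_cohort, mea_preset,
                           pvn_preset, render_phantom, simulate_acquisition,
                           REGIONS_14)


class TestRenderPhantom:
    def test_empty_spec_is_constant_background(self):
        spec = PhantomSpec(volume_shape_um=(20, 20, 10), background_level=42.0,
                           noise=NoiseSpec(poisson=False, read_sigma=0.0))
        vols, gt = render_phantom(spec)
        for vol in vols.values():
            assert np.all(vol == 42)
        assert len(gt.cells) == 0

    def test_single_cell_argmax_at_center(self, single_soma_phantom):
        spec, vols, gt = single_soma_phantom
        dz, dy, dx = spec.spacing_um[2], spec.spacing_um[1], spec.spacing_um[0]
        k, r, c = np.unravel_index(np.argmax(vols["red"]), vols["red"].shape)
        assert abs(c * dx - 40.0) <= dx
        assert abs(r * dy - 36.0) <= dy
        assert abs(k * dz - 30.0) <= dz

    def test_ground_truth_bookkeeping(self):
        rng = np.random.default_rng(1)
        cells = [CellSpec(tuple(rng.uniform(10, 50, 3)), (5.0,) * 3, 1000.0,
                          channel="red" if i % 2 else "green")
                 for i in range(50)]
        spec = PhantomSpec(volume_shape_um=(60, 60, 60), cells=cells)
        _, gt = render_phantom(spec)
        assert len(gt.cells) == 50
        counts = gt.region_counts.set_index("channel")["count"]
        assert counts["red"] + counts["green"] == 50

    def test_seed_reproducibility(self):
        spec = pvn_preset(seed=3)
        v1, _ = render_phantom(spec)
        v2, _ = render_phantom(pvn_preset(seed=3))
        assert all(np.array_equal(v1[ch], v2[ch]) for ch in v1)

    def test_out_of_volume_cell_rejected(self):
        spec = PhantomSpec(volume_shape_um=(20, 20, 20),
                           cells=[CellSpec((30.0, 5.0, 5.0), (3.0,) * 3, 100.0)])
        with pytest.raises(ValueError):
            render_phantom(spec)


class TestDualChannelPresets:
    def test_pvn_class_counts(self):
        spec = pvn_preset(seed=0)
        red = [c for c in spec.cells if c.channel == "red"]
        green = [c for c in spec.cells if c.channel == "green"]
        doubles = [c for c in green if c.colabel_partner is not None]
        assert len(red) == 834
        assert len(doubles) == 430
        assert len(green) == 455

    def test_mea_class_counts(self):
        spec = mea_preset(seed=0)
        red = [c for c in spec.cells if c.channel == "red"]
        green = [c for c in spec.cells if c.channel == "green"]
        doubles = [c for c in green if c.colabel_partner is not None]
        assert len(red) == 1018
        assert len(green) == 569
        assert len(doubles) == 104

    def test_double_positive_cells_are_cocentred(self):
        spec = pvn_preset(seed=1)
        for c in spec.cells:
            if c.channel == "green" and c.colabel_partner is not None:
                partner = spec.cells[c.colabel_partner]
                assert partner.channel == "red"
                assert partner.center_um == c.center_um


class TestSimulateAcquisition:
    def test_zero_speed_gives_identical_frames(self):
        g = AcquisitionGeometry(objective_mag=10.0, tube_focal_mm=180.0,
                                camera_pixel_um=5.0, stage_speed_um_s=1e-9,
                                frame_shape=(40, 40))
        vol = np.random.default_rng(0).uniform(0, 1000, (30, 30, 30))
        cols = simulate_acquisition(vol, g, overlap=0.0, n_frames=3)
        frames = cols[0].frames
        assert np.array_equal(frames[0], frames[1])

    def test_synchronized_roundtrip_psnr(self):
        from scipy import ndimage
        from visor.stitching import stack_column
        # 2.5 µm frame step so band-limited (σ = 6 µm) somata are well
        # sampled along the scan axis
        g = AcquisitionGeometry(objective_mag=10.0, tube_focal_mm=180.0,
                                camera_pixel_um=5.0, scan_rate_hz=200.0,
                                stage_speed_um_s=500.0, frame_shape=(100, 80))
        spec = PhantomSpec(volume_shape_um=(120, 40, 30),
                           spacing_um=(1.0, 1.0, 1.0),
                           cells=[CellSpec((60.0, 20.0, 15.0), (12.0,) * 3, 3000.0),
                                  CellSpec((30.0, 15.0, 14.0), (12.0,) * 3, 2000.0)],
                           background_level=0.0,
                           noise=NoiseSpec(poisson=False, read_sigma=0.0))
        vols, _ = render_phantom(spec)
        truth = vols["red"].astype(float)
        cols = simulate_acquisition(truth, g, spacing_um=(1, 1, 1), overlap=0.0)
        deskewed, (dx, dy, dz) = stack_column(cols[0], z_step_um=1.0)
        zz, yy, xx = np.meshgrid(np.arange(30), np.arange(40), np.arange(120),
                                 indexing="ij")
        coords = np.stack([zz / dz - 0.5, yy / dy, xx / dx])
        recon = ndimage.map_coordinates(deskewed, coords, order=1)
        mask = truth > 0
        mse = np.mean((recon[mask] - truth[mask]) ** 2)
        psnr = 10 * np.log10(truth.max() ** 2 / mse)
        assert psnr > 40.0

    def test_unsynchronized_blur_width(self):
        # 0.5 mm/s at 100 Hz → 5 µm box smear along x; a box of length L
        # adds L²/12 to the variance of any profile along x
        g = AcquisitionGeometry(objective_mag=10.0, tube_focal_mm=180.0,
                                camera_pixel_um=5.0, scan_rate_hz=100.0,
                                stage_speed_um_s=500.0, frame_shape=(40, 60),
                                tilt_angle_deg=45.0)
        zz, yy, xx = np.meshgrid(np.arange(20), np.arange(30), np.arange(60),
                                 indexing="ij")
        vol = 1000.0 * np.exp(-0.5 * ((xx - 30) / 3.0) ** 2)  # σ=3 µm slab
        kw = dict(spacing_um=(1, 1, 1), overlap=0.0, n_blur_samples=25)
        sync = simulate_acquisition(vol, g, mode="synchronized", **kw)
        unsync = simulate_acquisition(vol, g, mode="unsynchronized", **kw)

        def x_variance(cols):
            prof = cols[0].frames.astype(float).sum(axis=(1, 2))
            x = np.arange(len(prof)) * 5.0  # frame step, µm
            w = prof / prof.sum()
            mu = (x * w).sum()
            return ((x - mu) ** 2 * w).sum(), mu

        v_sync, mu_sync = x_variance(sync)
        v_unsync, mu_unsync = x_variance(unsync)
        added = v_unsync - v_sync
        assert added == pytest.approx(5.0 ** 2 / 12.0, rel=0.35)
        # exposure ahead of the nominal frame position advances the
        # centroid by half the box length
        assert mu_unsync - mu_sync == pytest.approx(-2.5, abs=0.8)

    def test_columns_overlap_fraction(self, unit_pixel_geometry):
        vol = np.zeros((20, 80, 40))
        cols = simulate_acquisition(vol, unit_pixel_geometry,
                                    spacing_um=(1, 1, 1), overlap=0.10)
        assert len(cols) >= 2
        width = unit_pixel_geometry.frame_shape[1] * 0.5
        stride = cols[1].nominal_origin_um[1] - cols[0].nominal_origin_um[1]
        assert stride == pytest.approx(width * 0.9, rel=1e-6)


class TestCutAndDeform:
    def test_zero_amplitude_concatenates_exactly(self, rng):
        vol = rng.uniform(0, 1000, (30, 20, 20))
        slices, params = cut_and_deform_slices(vol, (1, 1, 1),
                                               slice_thickness_um=10,
                                               deform_amplitude_um=0.0)
        assert len(slices) == 3
        assert np.allclose(np.concatenate(slices, axis=0), vol)

    def test_slice_count(self):
        vol = np.zeros((150, 10, 10))
        slices, _ = cut_and_deform_slices(vol, (1, 1, 10.0),
                                          slice_thickness_um=300.0)
        assert len(slices) == 5  # 1500 µm / 300 µm

    def test_thickness_above_depth_gives_single_slice(self):
        vol = np.zeros((10, 5, 5))
        slices, _ = cut_and_deform_slices(vol, (1, 1, 1), slice_thickness_um=100)
        assert len(slices) == 1

    def test_expansion_scales_about_slice_center(self):
        vol = np.zeros((4, 101, 101))
        vol[:, 50, 80] = 1000.0  # bead 30 px right of centre
        slices, params = cut_and_deform_slices(vol, (1, 1, 1), 4,
                                               expansion_factor=1.1)
        assert params[0]["expansion"] == 1.1
        c = slices[0][0, 50, :].argmax()
        assert abs((c - 50) - 1.1 * 30) <= 1.0

    def test_recorded_warp_inverts(self, rng):
        vol = np.zeros((10, 64, 64))
        _, params = cut_and_deform_slices(vol, (1, 1, 1), 10,
                                          deform_amplitude_um=4.0, rng_seed=5)
        x, y = rng.uniform(10, 54, (2, 100))
        d = evaluate_deformation(params[0], x, y)
        fx, fy = x + d[0], y + d[1]  # forward-mapped positions
        sx, sy = invert_deformation(params[0], fx, fy)
        resid = np.hypot(sx - x, sy - y)
        assert resid.max() < 0.5


class TestPhotonConservation:
    def test_noiseless_flux_preserved_through_resampling(self, unit_pixel_geometry):
        from visor.stitching import stack_column
        spec = PhantomSpec(volume_shape_um=(80, 40, 18), spacing_um=(1, 1, 1),
                           cells=[CellSpec((40.0, 20.0, 9.0), (6.0,) * 3, 2000.0)],
                           background_level=0.0,
                           noise=NoiseSpec(poisson=False, read_sigma=0.0))
        vols, _ = render_phantom(spec)
        truth = vols["red"].astype(float)
        cols = simulate_acquisition(truth, unit_pixel_geometry,
                                    spacing_um=(1, 1, 1), overlap=0.0)
        deskewed, (dx, dy, dz) = stack_column(cols[0], z_step_um=1.0)
        flux_in = truth.sum()  # 1 µm³ voxels
        flux_out = deskewed.sum() * dx * dy * dz
        assert flux_out == pytest.approx(flux_in, rel=0.01)


class TestFstCohort:
    def test_shape_and_groups(self):
        table = make_fst_cohort(seed=0)
        assert set(table.group) == {"FST", "control"}
        assert table.animal_id.nunique() == 16
        assert set(table.region) == set(REGIONS_14)
        assert (table["count"] >= 0).all()

    def test_null_mode_removes_effect(self):
        table = make_fst_cohort(seed=0, null=True)
        wide = table.pivot_table(index=["animal_id", "group"], columns="region",
                                 values="count")
        fst = wide.xs("FST", level="group")["BMA"]
        ctrl = wide.xs("control", level="group")["BMA"]
        # same distribution: means within a few control SDs of each other
        assert abs(fst.mean() - ctrl.mean()) < 3 * ctrl.std()
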