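import numpy as np
import pytest
from scipy import ndimage

from visor import alignment as al
from visor.phantom import (cortex_block_preset, cut_and_deform_slices,
                           evaluate_deformation, render_phantom)


@pytest.fixture(scope="module")
def textured_face(rng=None):
    rng = np.random.default_rng(2)
    return ndimage.gaussian_filter(rng.uniform(0, 1, (220, 220)), 3) * 1000


@pytest.fixture(scope="module")
def block_volume():
    vols, _ = render_phantom(cortex_block_preset())
    return vols["red"].astype(float)


class TestSurfaceFit:
    def _tilted_slab(self, a, b, nz=40, n=64, dz=1.0):
        # anti-aliased slab edges so threshold crossings are well defined
        yy, xx = np.meshgrid(np.arange(n, dtype=float),
                             np.arange(n, dtype=float), indexing="ij")
        top = 5.0 + a * xx + b * yy
        zz = np.arange(nz)[:, None, None] * dz
        vol = 1000.0 * np.clip(zz - top[None], 0, 1) \
            * np.clip(top[None] + 25.0 - zz, 0, 1)
        return vol

    def test_known_tilt_recovered(self):
        vol = self._tilted_slab(0.01, -0.02)
        model = al.fit_surface(vol, (1, 1, 1))
        assert model.top[0] == pytest.approx(0.01, abs=1e-3)
        assert model.top[1] == pytest.approx(-0.02, abs=1e-3)

    def test_flat_slab_zero_coefficients(self):
        vol = self._tilted_slab(0.0, 0.0)
        model = al.fit_surface(vol, (1, 1, 1))
        assert abs(model.top[0]) < 1e-6
        assert abs(model.top[1]) < 1e-6
        assert model.top[2] == pytest.approx(5.0, abs=1.0)

    def test_masked_hole_does_not_change_fit(self):
        vol = self._tilted_slab(0.01, -0.02)
        mask = np.zeros(vol.shape[1:], bool)
        mask[24:40, 24:40] = True  # ventricle-like exclusion
        m1 = al.fit_surface(vol, (1, 1, 1))
        m2 = al.fit_surface(vol, (1, 1, 1), mask=mask)
        assert np.allclose(m1.top[:2], m2.top[:2], atol=1e-3)  # tilt unchanged
        assert abs(m1.top[2] - m2.top[2]) < 0.05  # level within noise

    def test_too_few_support_points(self):
        vol = self._tilted_slab(0.0, 0.0, n=8)
        mask = np.ones(vol.shape[1:], bool)
        mask[0, 0] = False
        with pytest.raises(ValueError):
            al.fit_surface(vol, (1, 1, 1), mask=mask)


class TestFlatten:
    def test_flat_input_is_identity(self):
        rng = np.random.default_rng(0)
        vol = np.zeros((30, 32, 32))
        vol[5:25] = rng.uniform(500, 1500, (20, 32, 32))
        model = al.fit_surface(vol, (1, 1, 1))
        flat = al.flatten_slice(vol, model, (1, 1, 1))
        assert np.allclose(flat[8:22], vol[8:22], rtol=0.05, atol=20)

    def test_tilted_beads_land_on_constant_z(self):
        # beads embedded at fixed depth below a tilted surface
        n = 96
        a = 0.05
        yy, xx = np.meshgrid(np.arange(n, dtype=float),
                             np.arange(n, dtype=float), indexing="ij")
        top = 4.0 + a * xx
        vol = np.zeros((40, n, n))
        zz = np.arange(40)[:, None, None]
        vol[(zz >= top[None]) & (zz <= top[None] + 28)] = 300.0
        bead_depth = 10.0
        for cx in (20, 48, 76):
            zc = top[48, cx] + bead_depth
            for k in range(40):
                vol[k] += 3000.0 * np.exp(-0.5 * (((xx - cx) / 2.5) ** 2 +
                                                  ((yy - 48) / 2.5) ** 2 +
                                                  ((k - zc) / 2.5) ** 2))
        model = al.fit_surface(vol, (1, 1, 1))
        flat = al.flatten_slice(vol, model, (1, 1, 1))
        zs = []
        for cx in (20, 48, 76):
            prof = flat[:, 44:53, cx - 3:cx + 4].sum(axis=(1, 2))
            zs.append(np.argmax(prof))
        assert max(zs) - min(zs) <= 1

    def test_mass_conserved(self):
        vol = np.zeros((30, 48, 48))
        yy, xx = np.meshgrid(np.arange(48.), np.arange(48.), indexing="ij")
        top = 3.0 + 0.04 * xx
        zz = np.arange(30)[:, None, None]
        vol[(zz >= top[None]) & (zz <= top[None] + 20)] = 700.0
        model = al.fit_surface(vol, (1, 1, 1))
        flat = al.flatten_slice(vol, model, (1, 1, 1))
        assert flat.sum() == pytest.approx(vol.sum(), rel=0.01)


class TestCorrespondences:
    def test_identical_faces_zero_flow(self, textured_face):
        cs = al.extract_correspondences(textured_face, textured_face, (1, 1))
        assert len(cs) > 20
        assert np.abs(cs.displacements).max() < 0.2

    def test_pure_translation_recovered(self, textured_face):
        shifted = ndimage.shift(textured_face, (0, -4), order=1, mode="nearest")
        cs = al.extract_correspondences(textured_face, shifted, (1, 1))
        med = np.median(cs.displacements, axis=0)
        assert med[0] == pytest.approx(4.0, abs=0.5)
        assert med[1] == pytest.approx(0.0, abs=0.5)

    def test_smooth_warp_endpoint_error(self, textured_face):
        n = textured_face.shape[0]
        yy, xx = np.meshgrid(np.arange(n, dtype=float),
                             np.arange(n, dtype=float), indexing="ij")
        amp = 5.0
        dxf = amp * np.sin(2 * np.pi * xx / n) * np.cos(2 * np.pi * yy / n)
        dyf = amp * np.cos(2 * np.pi * xx / n) * np.sin(2 * np.pi * yy / n)
        warped = ndimage.map_coordinates(textured_face, [yy - dyf, xx - dxf],
                                         order=1, mode="nearest")
        cs = al.extract_correspondences(textured_face, warped, (1, 1))
        # content moved by +d, so the a→b displacement (pa − pb) is −d
        true = -np.column_stack([
            dxf[cs.points_a[:, 1].astype(int), cs.points_a[:, 0].astype(int)],
            dyf[cs.points_a[:, 1].astype(int), cs.points_a[:, 0].astype(int)]])
        err = np.linalg.norm(cs.displacements - true, axis=1)
        assert np.median(err) < 0.2 * amp

    def test_textureless_faces_warn_and_empty(self):
        flat = np.full((80, 80), 100.0)
        cs = al.extract_correspondences(flat, flat, (1, 1))
        assert len(cs) == 0


class TestAdjust:
    def _grid_set(self, disp, pair_id=0):
        pts = np.array([(x, y) for x in range(0, 100, 10)
                        for y in range(0, 100, 10)], float)
        d = np.broadcast_to(disp, pts.shape).copy()
        return al.CorrespondenceSet(pair_id, pts, pts - d, np.ones(len(pts)))

    def test_zero_displacements_stay_zero(self):
        adj = al.adjust_correspondences([self._grid_set((0.0, 0.0))])
        assert np.allclose(adj[0].displacements, 0.0)

    def test_outlier_shrunk_toward_neighbors(self):
        cs = self._grid_set((1.0, 0.0))
        d = cs.displacements.copy()
        d[42] = (8.0, 0.0)  # one outlier
        cs = al.CorrespondenceSet(0, cs.points_a, cs.points_a - d,
                                  np.ones(len(d)))
        adj = al.adjust_correspondences([cs], lambda_smooth=1.0,
                                        lambda_small=0.0)
        assert adj[0].displacements[42, 0] < 6.0
        # consistent points barely move
        others = np.delete(adj[0].displacements[:, 0], 42)
        assert np.abs(others - 1.0).max() < 0.5

    def test_large_small_penalty_kills_displacements(self):
        cs = self._grid_set((2.0, -1.0))
        adj = al.adjust_correspondences([cs], lambda_smooth=0.0,
                                        lambda_small=1e6)
        assert np.abs(adj[0].displacements).max() < 1e-3

    def test_smoothing_is_tv_contractive(self, rng):
        pts = np.array([(x, y) for x in range(0, 60, 6)
                        for y in range(0, 60, 6)], float)
        d = rng.normal(0, 2, pts.shape)
        cs = al.CorrespondenceSet(0, pts, pts - d, np.ones(len(pts)))
        adj = al.adjust_correspondences([cs], lambda_smooth=1.0,
                                        lambda_small=0.0)

        def tv(disp):
            from scipy.spatial import cKDTree
            _, idx = cKDTree(pts).query(pts, k=2)
            return np.linalg.norm(disp - disp[idx[:, 1]], axis=1).sum()

        assert tv(adj[0].displacements) <= tv(d) + 1e-9


class TestMLS:
    def test_zero_displacement_identity_image(self, rng):
        img = rng.uniform(0, 100, (48, 48))
        out = al.mls_warp(img, np.array([[10.0, 12.0]]), np.array([[0.0, 0.0]]))
        assert np.array_equal(out, img)

    def test_single_control_point_translates_globally(self, rng):
        v = rng.uniform(0, 100, (40, 2))
        out = al.mls_transform(v, np.array([[50.0, 50.0]]),
                               np.array([[53.0, 48.0]]))
        assert np.allclose(out, v + [3.0, -2.0])

    def test_similarity_transform_reproduced_exactly(self, rng):
        p = rng.uniform(0, 100, (6, 2))
        s, th, t = 1.3, 0.7, np.array([4.0, -2.0])
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        q = s * p @ R.T + t
        v = rng.uniform(-20, 120, (200, 2))
        out = al.mls_transform(v, p, q)
        assert np.abs(out - (s * v @ R.T + t)).max() < 0.1

    def test_controls_interpolated_exactly(self, rng):
        p = rng.uniform(0, 100, (8, 2))
        q = p + rng.normal(0, 3, p.shape)
        assert np.allclose(al.mls_transform(p, p, q), q)

    def test_conflicting_coincident_controls_rejected(self):
        p = np.array([[10.0, 10.0], [10.0, 10.0]])
        q = np.array([[11.0, 10.0], [9.0, 10.0]])
        with pytest.raises(ValueError):
            al.mls_transform(np.array([[0.0, 0.0]]), p, q)


class TestReconstruct:
    def test_undeformed_slices_concatenate(self, block_volume):
        slices, _ = cut_and_deform_slices(block_volume, (1, 1, 2), 32,
                                          deform_amplitude_um=0.0)
        res = al.reconstruct_brain(slices, (1, 1, 2), flatten=False)
        assert np.allclose(res["volume"], block_volume, atol=1e-6)
        assert all(r["after_um"] < 0.5 for r in res["residuals"])

    def test_mismatch_reduced_on_deformed_phantom(self, block_volume):
        slices, params = cut_and_deform_slices(block_volume, (1, 1, 2), 32,
                                               deform_amplitude_um=5.0,
                                               rng_seed=4)
        res = al.reconstruct_brain(slices, (1, 1, 2), flatten=False)
        rng = np.random.default_rng(0)
        pts = rng.uniform(25, 175, (200, 2))
        for k in range(len(slices) - 1):
            Dk = np.array(evaluate_deformation(params[k], pts[:, 0], pts[:, 1])).T
            Dk1 = np.array(evaluate_deformation(params[k + 1], pts[:, 0], pts[:, 1])).T
            before = np.linalg.norm(Dk - Dk1, axis=1)

            def final(widx, D):
                pos = pts + D
                p, d = res["warps"][widx]
                if not len(p):
                    return pos
                return al._mls_transform_grid(pos, p, p + d, alpha=2.0)

            after = np.linalg.norm(final(k, Dk) - final(k + 1, Dk1), axis=1)
            assert np.median(before) / np.median(after) >= 5.0
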