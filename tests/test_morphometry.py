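"""Structural-parameter oracles: analytic fixtures and brute-force censuses."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trabstiff import morphometry as mm
from trabstiff import phantoms
from trabstiff.image_io import BinaryROI, DensityStack


# ---------------------------------------------------------------------------
# independent oracles


def euler_census(mask):
    """Brute-force cubical-complex census: enumerate the distinct vertices,
    edges, faces and cells contributed by every foreground voxel."""
    vertices, edges, faces, cells = set(), set(), set(), set()
    for z, y, x in zip(*np.nonzero(mask)):
        corners = [(z + dz, y + dy, x + dx)
                   for dz in (0, 1) for dy in (0, 1) for dx in (0, 1)]
        vertices.update(corners)
        cells.add((z, y, x))
        for a in corners:
            for b in corners:
                diff = sum(abs(u - v) for u, v in zip(a, b))
                if a < b and diff == 1:
                    edges.add((a, b))
        # the six faces, keyed by their 4 corners
        for axis in range(3):
            for side in (0, 1):
                quad = tuple(sorted(c for c in corners if c[axis] == (z, y, x)[axis] + side))
                faces.add(quad)
    return len(vertices) - len(edges) + len(faces) - len(cells)


def exposed_face_census(mask):
    """Count voxel faces adjacent to background or the border, by looping."""
    count = 0
    shape = mask.shape
    for z, y, x in zip(*np.nonzero(mask)):
        for dz, dy, dx in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)]:
            nz, ny, nx = z + dz, y + dy, x + dx
            if not (0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]):
                count += 1
            elif not mask[nz, ny, nx]:
                count += 1
    return count


def two_handle_pretzel():
    """Voxel frame with two holes (genus-2 handlebody): chi = -1, Conn = 2."""
    m = np.zeros((3, 5, 9), dtype=bool)
    m[1, :, :5] = True
    m[1, 1:4, 1:4] = False
    m[1, :, 4:] = True
    m[1, 1:4, 5:8] = False
    return m


# ---------------------------------------------------------------------------
# volume fraction and density


class TestBvTv:
    def test_solid_and_empty(self):
        solid = phantoms.solid_cylinder(10, 5)
        assert mm.bv_tv(solid) == 100.0
        empty = BinaryROI(np.zeros_like(solid.mask), solid.voxel_size,
                          solid.cylinder, solid.region)
        assert mm.bv_tv(empty) == 0.0

    def test_direct_count(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask.ravel()[:123] = True
        assert mm.bv_tv(BinaryROI(mask, 1.0)) == pytest.approx(12.3)


class TestMeanBmd:
    def test_uniform_and_mixture(self):
        roi = BinaryROI(np.ones((2, 4, 4), bool), 1.0)
        assert mm.mean_bmd(DensityStack(np.full((2, 4, 4), 0.3), 1.0), roi) == pytest.approx(0.3)
        half = np.zeros((2, 4, 4)); half[0] = 0.5
        assert mm.mean_bmd(DensityStack(half, 1.0), roi) == pytest.approx(0.25)

    def test_matches_loop(self):
        rng = np.random.default_rng(0)
        dens = rng.random((4, 6, 6))
        region = rng.random((4, 6, 6)) < 0.6
        roi = BinaryROI(np.zeros_like(region), 1.0, region=region)
        total, n = 0.0, 0
        for idx in np.ndindex(region.shape):
            if region[idx]:
                total += dens[idx]; n += 1
        assert mm.mean_bmd(DensityStack(dens, 1.0), roi) == pytest.approx(total / n)


# ---------------------------------------------------------------------------
# thickness / separation


class TestLocalThickness:
    def test_slab_thickness(self, voxel_size):
        roi = BinaryROI(phantoms.slab(5, 32), voxel_size)
        # 5-voxel plate: 0.090 mm, within half a voxel
        assert mm.local_thickness(roi) == pytest.approx(0.090, abs=voxel_size / 2)

    def test_ball_is_its_own_maximal_sphere(self, ball_roi, voxel_size):
        expect = 16 * voxel_size
        assert mm.local_thickness(ball_roi) == pytest.approx(expect, rel=0.10)

    def test_empty_phase_rejected(self):
        roi = BinaryROI(np.zeros((4, 4, 4), bool), 1.0)
        with pytest.raises(ValueError, match="empty"):
            mm.local_thickness(roi, "foreground")

    def test_separation_equals_complement_thickness(self):
        rng = np.random.default_rng(1)
        mask = rng.random((10, 12, 12)) < 0.5
        roi = BinaryROI(mask, 0.018)
        complement = BinaryROI(~mask, 0.018)
        assert mm.local_thickness(roi, "background") == pytest.approx(
            mm.local_thickness(complement, "foreground"))


# ---------------------------------------------------------------------------
# fractal dimension


class TestFractalDimension:
    def test_space_filling_cube(self):
        assert mm.fractal_dimension(np.ones((64,) * 3, bool)) == pytest.approx(3.0, abs=0.05)

    def test_plane_in_volume(self):
        m = np.zeros((64,) * 3, bool)
        m[32] = True
        assert mm.fractal_dimension(m) == pytest.approx(2.0, abs=0.05)

    def test_menger_sponge_similarity_dimension(self):
        expect = np.log(20) / np.log(3)
        assert mm.fractal_dimension(phantoms.menger(4)) == pytest.approx(expect, abs=0.1)

    def test_small_structure_rejected(self):
        with pytest.raises(ValueError):
            mm.fractal_dimension(np.ones((4, 4, 4), bool))


# ---------------------------------------------------------------------------
# pattern factor


class TestTbPf:
    def test_ball_positive_and_matches_census(self, voxel_size):
        from scipy import ndimage as ndi
        mask = phantoms.ball(6)
        roi = BinaryROI(mask, voxel_size)
        got = mm.tb_pf(roi)
        dil = ndi.binary_dilation(mask, ndi.generate_binary_structure(3, 1))
        a = voxel_size
        s1, s2 = exposed_face_census(mask) * a**2, exposed_face_census(dil) * a**2
        v1, v2 = mask.sum() * a**3, dil.sum() * a**3
        assert got > 0
        assert got == pytest.approx((s1 - s2) / (v1 - v2))

    def test_enclosed_cavity_negative(self, voxel_size):
        g = np.ones((15, 15, 15), bool)
        z, y, x = np.indices(g.shape)
        g[(z - 7) ** 2 + (y - 7) ** 2 + (x - 7) ** 2 <= 16] = False
        roi = BinaryROI(g, voxel_size)
        got = mm.tb_pf(roi)
        from scipy import ndimage as ndi
        dil = ndi.binary_dilation(g, ndi.generate_binary_structure(3, 1))
        a = voxel_size
        s1, s2 = exposed_face_census(g) * a**2, exposed_face_census(dil) * a**2
        v1, v2 = g.sum() * a**3, dil.sum() * a**3
        assert got < 0
        assert got == pytest.approx((s1 - s2) / (v1 - v2))

    def test_grid_filling_mask_rejected(self):
        roi = BinaryROI(np.ones((5, 5, 5), bool), 1.0)
        with pytest.raises(ValueError, match="dilation changes no voxels"):
            mm.tb_pf(roi)


# ---------------------------------------------------------------------------
# anisotropy


class TestDegreeOfAnisotropy:
    def test_isotropic_porous_ball(self):
        rng = np.random.default_rng(0)
        b = phantoms.ball(14)
        iso = b & ~(rng.random(b.shape) < 0.3)
        assert mm.degree_of_anisotropy(BinaryROI(iso, 0.018), seed=0) < 0.15

    def test_parallel_axial_rods(self):
        rods = phantoms.rod_lattice(3, 6, 40, 60)
        assert mm.degree_of_anisotropy(rods, seed=0) > 0.6

    def test_solid_mask_rejected(self):
        with pytest.raises(ValueError):
            mm.degree_of_anisotropy(BinaryROI(np.ones((8, 8, 8), bool), 1.0))

    def test_in_bounds(self, trabecular_phantom):
        da = mm.degree_of_anisotropy(trabecular_phantom.roi, seed=0)
        assert 0.0 <= da < 1.0


# ---------------------------------------------------------------------------
# connectivity


class TestConnectivity:
    def test_ball_chi_one(self):
        assert mm.euler_characteristic(phantoms.ball(6)) == 1
        roi = BinaryROI(phantoms.ball(6), 0.018)
        assert mm.connectivity_density(roi) == pytest.approx(0.0)

    def test_torus_conn_dn(self, torus_roi):
        assert mm.euler_characteristic(torus_roi.mask) == 0
        assert mm.connectivity_density(torus_roi) == pytest.approx(0.125)

    def test_pretzel_two_handles(self):
        m = two_handle_pretzel()
        chi = mm.euler_characteristic(m)
        assert chi == euler_census(m)
        assert 1 - chi == 2

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(seed=st.integers(0, 10_000), fill=st.floats(0.2, 0.8))
    def test_matches_census_on_random_masks(self, seed, fill):
        rng = np.random.default_rng(seed)
        m = rng.random((6, 6, 6)) < fill
        assert mm.euler_characteristic(m) == euler_census(m)

    def test_matches_skimage_euler_number(self):
        """Independent cross-check against the integral-geometry estimator."""
        from skimage.measure import euler_number
        for seed in range(5):
            rng = np.random.default_rng(seed)
            m = rng.random((7, 7, 7)) < 0.4
            assert mm.euler_characteristic(m) == euler_number(m, connectivity=3)


# ---------------------------------------------------------------------------
# composite panels


class TestAnalyze3D:
    def test_composition_equals_parts(self, trabecular_phantom):
        import warnings
        roi = trabecular_phantom.roi
        dens = DensityStack(roi.mask.astype(float) * 0.6, roi.voxel_size)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # multi-component Conn warning
            rec = mm.analyze_3d(roi, dens, da_seed=0)
        assert rec.bv_tv == mm.bv_tv(roi)
        assert rec.tb_th == mm.local_thickness(roi, "foreground")
        assert rec.tb_sp == mm.local_thickness(roi, "background")
        assert rec.fd == mm.fractal_dimension(roi.mask)
        assert rec.tb_pf == mm.tb_pf(roi)
        assert rec.da == mm.degree_of_anisotropy(roi, seed=0)
        assert rec.tv == pytest.approx(roi.tv_mm3)

    def test_solid_cylinder_degenerate_values(self):
        roi = phantoms.solid_cylinder(16, 12)
        assert mm.bv_tv(roi) == 100.0
        assert mm.connectivity_density(roi) == pytest.approx(0.0)


class TestAnalyzeSlices:
    def test_axially_uniform_phantom_constant_curves(self):
        roi = phantoms.rod_lattice(3, 6, 24, 10)
        slices = mm.analyze_slices(roi, da_seed=0)
        for attr in ("bv_tv", "tb_th", "tb_sp", "fd", "tb_pf", "da"):
            vals = [getattr(s, attr) for s in slices]
            assert np.allclose(vals, vals[0]), attr

    def test_empty_middle_slice(self):
        roi = phantoms.solid_cylinder(12, 7)
        mask = roi.mask.copy()
        mask[3] = False
        roi2 = BinaryROI(mask, roi.voxel_size, roi.cylinder, roi.region)
        slices = mm.analyze_slices(roi2)
        assert slices[3].bv_tv == 0.0
        assert slices[0].bv_tv == 100.0

    def test_normalized_height_endpoints(self, trabecular_phantom):
        slices = mm.analyze_slices(trabecular_phantom.roi, da_seed=0)
        assert slices[0].normalized_height == 0.0
        assert slices[-1].normalized_height == 1.0

    def test_slice_values_match_single_slice_recompute(self, trabecular_phantom):
        roi = trabecular_phantom.roi
        k = 10
        slices = mm.analyze_slices(roi, da_seed=0)
        m2, r2 = roi.mask[k], roi.region[k]
        assert slices[k].bv_tv == pytest.approx(100.0 * m2.sum() / r2.sum())
        th = mm.local_thickness_map(m2)
        assert slices[k].tb_th == pytest.approx(th[m2].mean() * roi.voxel_size)
        assert slices[k].fd == pytest.approx(mm.fractal_dimension(m2))


class TestScaleEquivariance:
    def test_voxel_size_scaling(self):
        rng = np.random.default_rng(3)
        from scipy import ndimage as ndi
        mask = ndi.gaussian_filter(rng.standard_normal((24, 24, 24)), 2) > 0
        r1 = BinaryROI(mask, 0.018)
        r2 = BinaryROI(mask, 0.036)
        assert mm.local_thickness(r2) == pytest.approx(2 * mm.local_thickness(r1))
        assert mm.local_thickness(r2, "background") == pytest.approx(
            2 * mm.local_thickness(r1, "background"))
        assert mm.tb_pf(r2) == pytest.approx(mm.tb_pf(r1) / 2)
        assert mm.connectivity_density(r2) == pytest.approx(
            mm.connectivity_density(r1) / 8)
        assert mm.bv_tv(r2) == mm.bv_tv(r1)
        assert mm.fractal_dimension(r2.mask) == mm.fractal_dimension(r1.mask)
        assert mm.degree_of_anisotropy(r2, seed=0) == pytest.approx(
            mm.degree_of_anisotropy(r1, seed=0))


class TestBmdBvTvCoupling:
    def test_affine_coupling_on_uniform_grays(self, trabecular_phantom):
        """With uniform bone gray and constant marrow gray, the slice BMD
        curve is an affine image of the BV/TV curve."""
        from trabstiff.image_io import apply_calibration, fit_density_calibration
        from trabstiff.phantoms import gray_from_roi
        roi = trabecular_phantom.roi
        gray = gray_from_roi(roi, noise_sd=0.0)
        calib = fit_density_calibration([(60, 0.25), (220, 0.75)])
        dens = apply_calibration(gray, calib)
        slices = mm.analyze_slices(roi, dens, da_seed=0)
        bv = np.array([s.bv_tv for s in slices])
        bmd = np.array([s.bmd for s in slices])
        r = np.corrcoef(bv, bmd)[0, 1]
        assert r > 0.999
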