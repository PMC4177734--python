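"""Surface extraction, boundary segmentation, spline fitting, thickness maps."""

import numpy as np
import pytest

from octguide.enhance import compensate_attenuation
from octguide.phantom import PhantomParams, ScanGeometry, make_phantom, render_oct
from octguide.surfaces import (
    BoundaryCandidates,
    InsufficientSupportError,
    SurfaceModel,
    detect_bone_surface,
    fallback_virtual_structure,
    fit_boundary_surface,
    make_channel_mask,
    make_stop_surface,
    segment_critical_boundary,
    thickness_map,
)


def _segment(vol, threshold=0.5):
    surf = detect_bone_surface(vol, threshold, fill_invalid=True)
    enh = compensate_attenuation(vol)
    return surf, segment_critical_boundary(enh, surf, localization_volume=vol)


class TestDetectBoneSurface:
    def test_flat_surface_recovered_within_half_voxel(self):
        p = make_phantom(PhantomParams(boundary_apex_depth=800.0,
                                       curvature_radius=np.inf,
                                       extent=(2000.0, 2000.0), surface_depth=300.0))
        geom = ScanGeometry(fov=(800.0, 800.0), origin=(600.0, 600.0),
                            z_range=(100.0, 900.0), noise_floor=0.0, speckle=False)
        vol = render_oct(p, geom, seed=0)
        surf = detect_bone_surface(vol, 0.5)
        X, Y = np.meshgrid(vol.x, vol.y, indexing="ij")
        z = surf.evaluate(X, Y)
        assert np.nanmax(np.abs(z - 300.0)) <= geom.spacing[2] / 2.0

    def test_tilted_plane_recovered_within_02_degrees(self):
        slope = np.tan(np.deg2rad(2.0))
        p = make_phantom(PhantomParams(boundary_apex_depth=900.0,
                                       curvature_radius=np.inf,
                                       extent=(2000.0, 2000.0),
                                       surface_depth=100.0,
                                       surface_tilt=(slope, 0.0)))
        geom = ScanGeometry(fov=(800.0, 800.0), origin=(600.0, 600.0),
                            z_range=(0.0, 600.0), noise_floor=0.0, speckle=False)
        vol = render_oct(p, geom, seed=0)
        surf = detect_bone_surface(vol, 0.5)
        X, Y = np.meshgrid(vol.x, vol.y, indexing="ij")
        z = surf.evaluate(X, Y)
        A = np.column_stack([X.ravel(), Y.ravel(), np.ones(X.size)])
        coef, *_ = np.linalg.lstsq(A, z.ravel(), rcond=None)
        fitted_angle = np.rad2deg(np.arctan(coef[0]))
        assert abs(fitted_angle - 2.0) <= 0.2

    def test_speckled_render_rms_below_axial_resolution(self, flat_volume):
        surf = detect_bone_surface(flat_volume, 0.5)
        X, Y = np.meshgrid(flat_volume.x, flat_volume.y, indexing="ij")
        err = surf.evaluate(X, Y) - 0.0
        assert np.sqrt(np.nanmean(err**2)) <= 18.0

    def test_empty_volume_raises(self):
        from octguide.volume import OctVolume

        vol = OctVolume(data=np.zeros((6, 6, 30)), spacing=[20, 20, 6])
        with pytest.raises(ValueError):
            detect_bone_surface(vol, 0.5)


class TestSegmentBoundary:
    def test_noise_free_candidates_within_one_voxel(self, flat_phantom,
                                                    small_geom_clean):
        vol = render_oct(flat_phantom, small_geom_clean, seed=0)
        _, cand = _segment(vol)
        assert len(cand.points) > 0
        err = cand.points[:, 2] - 400.0
        assert np.mean(np.abs(err) <= small_geom_clean.spacing[2]) >= 0.95

    def test_deep_boundary_reports_low_confidence(self, deep_phantom, small_geom):
        vol = render_oct(deep_phantom, small_geom, seed=21)
        _, cand = _segment(vol)
        assert cand.confidence < 0.2

    def test_partially_visible_boundary_flagged_for_fallback(self):
        """Boundary inside imaging range only near the channel centre:
        confidence lands between 'invisible' and the trust threshold."""
        p = make_phantom(PhantomParams(boundary_apex_depth=500.0,
                                       curvature_radius=450.0,
                                       extent=(2000.0, 2000.0)))
        geom = ScanGeometry(fov=(1000.0, 1000.0), origin=(500.0, 500.0),
                            z_range=(-60.0, 900.0), noise_floor=0.0, speckle=False)
        vol = render_oct(p, geom, seed=0)
        surf = detect_bone_surface(vol, 0.5, fill_invalid=True)
        enh = compensate_attenuation(vol)
        mask = make_channel_mask((1000.0, 1000.0), 1000.0, vol.x, vol.y).mask
        cand = segment_critical_boundary(enh, surf, channel_mask=mask,
                                         localization_volume=vol)
        assert 0.2 <= cand.confidence < 0.5
        with pytest.raises(InsufficientSupportError):
            fit_boundary_surface(cand)

    def test_candidates_lie_below_bone_surface(self, flat_volume):
        surf, cand = _segment(flat_volume)
        X = cand.points[:, 0]
        Y = cand.points[:, 1]
        sz = surf.evaluate(X, Y)
        assert np.all(cand.points[:, 2] > sz)


def _candidates_from_points(points):
    n = len(points)
    return BoundaryCandidates(points=np.asarray(points, float),
                              grad=np.ones(n), frame=np.zeros(n, dtype=int),
                              linked=np.ones((1, 1), dtype=bool), confidence=1.0)


class TestFitBoundarySurface:
    def test_reproduces_representable_bicubic_field(self):
        x = np.arange(500.0, 1500.0, 20.0)
        y = np.arange(500.0, 1500.0, 25.0)
        X, Y = np.meshgrid(x, y, indexing="ij")
        u, v = (X - 1000) / 500, (Y - 1000) / 500
        Z = 400 + 30 * u + 20 * v - 15 * u * v + 10 * u**3 - 8 * v**3 + 5 * u**2 * v
        cand = _candidates_from_points(np.column_stack([X.ravel(), Y.ravel(), Z.ravel()]))
        fit = fit_boundary_surface(cand)
        resid = fit.evaluate(X, Y) - Z
        assert np.sqrt(np.mean(resid**2)) < 1e-6

    def test_robust_to_jitter_and_outliers(self):
        rng = np.random.default_rng(12)
        x = np.arange(500.0, 1500.0, 20.0)
        y = np.arange(500.0, 1500.0, 20.0)
        X, Y = np.meshgrid(x, y, indexing="ij")
        R = 1500.0
        r2 = (X - 1000) ** 2 + (Y - 1000) ** 2
        Z = 1200.0 + R - np.sqrt(R * R - r2)
        noisy = Z + rng.normal(0, 10.0, Z.shape)
        outliers = rng.random(Z.shape) < 0.10
        noisy[outliers] += 200.0
        cand = _candidates_from_points(
            np.column_stack([X.ravel(), Y.ravel(), noisy.ravel()]))
        fit = fit_boundary_surface(cand)
        err = fit.evaluate(X, Y) - Z
        assert np.sqrt(np.mean(err**2)) <= 10.0

    def test_fitted_surface_is_c2_smooth(self):
        x = np.arange(500.0, 1500.0, 20.0)
        X, Y = np.meshgrid(x, x, indexing="ij")
        Z = 400 + 0.0002 * (X - 1000) ** 2 + 0.0001 * (Y - 1000) ** 2
        cand = _candidates_from_points(np.column_stack([X.ravel(), Y.ravel(), Z.ravel()]))
        fit = fit_boundary_surface(cand)
        xs = np.linspace(600.0, 1400.0, 161)
        Xs, Ys = np.meshgrid(xs, xs, indexing="ij")
        zs = fit.evaluate(Xs, Ys)
        h = xs[1] - xs[0]
        d2 = np.diff(zs, n=2, axis=0) / h**2
        assert np.max(np.abs(d2)) < 0.01  # bounded curvature, no kinks

    def test_low_confidence_rejected(self):
        cand = _candidates_from_points(np.random.default_rng(0).uniform(0, 100, (50, 3)))
        cand.confidence = 0.2
        with pytest.raises(InsufficientSupportError):
            fit_boundary_surface(cand)


class TestStopSurfaceAndThickness:
    def _grid_surface(self, value, x=None, y=None):
        x = x if x is not None else np.arange(0.0, 1000.0, 20.0)
        y = y if y is not None else np.arange(0.0, 1000.0, 20.0)
        z = np.full((x.size, y.size), float(value))
        return SurfaceModel(kind="grid", x=x, y=y, z=z), x, y

    def test_offset_shifts_surface_exactly(self):
        boundary, x, y = self._grid_surface(500.0)
        stop = make_stop_surface(boundary, 100.0)
        rng = np.random.default_rng(4)
        X = rng.uniform(x[0], x[-1], 10_000)
        Y = rng.uniform(y[0], y[-1], 10_000)
        direct = boundary.evaluate(X, Y) - 100.0
        assert np.nanmax(np.abs(stop.evaluate(X, Y) - direct)) < 1e-9

    def test_zero_offset_is_identity(self):
        boundary, x, y = self._grid_surface(321.0)
        stop = make_stop_surface(boundary, 0.0)
        X, Y = np.meshgrid(x, y, indexing="ij")
        assert np.array_equal(stop.evaluate(X, Y), boundary.evaluate(X, Y))

    def test_negative_offset_rejected(self):
        boundary, *_ = self._grid_surface(100.0)
        with pytest.raises(ValueError):
            make_stop_surface(boundary, -5.0)

    def test_thickness_and_penetration_trivial_cases(self):
        bottom, x, y = self._grid_surface(200.0)
        stop, *_ = self._grid_surface(500.0)
        mask = make_channel_mask((500.0, 500.0), 600.0, x, y)
        t = thickness_map(bottom, stop, mask)
        assert np.allclose(t.thickness[mask.mask], 300.0)
        assert np.allclose(t.penetration[mask.mask], 0.0)

        deep_bottom, *_ = self._grid_surface(510.0)
        t2 = thickness_map(deep_bottom, stop, mask)
        assert np.allclose(t2.thickness[mask.mask], 0.0)
        assert np.allclose(t2.penetration[mask.mask], 10.0)

    def test_thickness_penetration_decompose_signed_difference(self):
        rng = np.random.default_rng(8)
        x = np.arange(0.0, 1000.0, 20.0)
        zb = rng.uniform(100, 600, (x.size, x.size))
        zs = rng.uniform(100, 600, (x.size, x.size))
        bottom = SurfaceModel(kind="grid", x=x, y=x, z=zb)
        stop = SurfaceModel(kind="grid", x=x, y=x, z=zs)
        mask = make_channel_mask((500.0, 500.0), 800.0, x, x)
        t = thickness_map(bottom, stop, mask)
        m = mask.mask
        assert np.allclose((t.thickness - t.penetration)[m], (zs - zb)[m], atol=1e-9)
        assert np.all(t.thickness * t.penetration == 0.0)

    def test_invalid_surface_inside_mask_rejected(self):
        bottom, x, y = self._grid_surface(200.0)
        stop, *_ = self._grid_surface(500.0)
        bottom.valid = bottom.valid.copy()
        bottom.valid[25, 25] = False  # inside the channel disc
        mask = make_channel_mask((500.0, 500.0), 600.0, x, y)
        with pytest.raises(ValueError):
            thickness_map(bottom, stop, mask)

    def test_curved_phantom_thickness_matches_ground_truth(self):
        """End-to-end noise-free check: detected thickness map equals
        z_e − offset − z_b within one axial voxel RMS."""
        p = make_phantom(PhantomParams(boundary_apex_depth=400.0,
                                       curvature_radius=1500.0,
                                       extent=(2000.0, 2000.0)))
        geom = ScanGeometry(fov=(1000.0, 1000.0), origin=(500.0, 500.0),
                            z_range=(-60.0, 900.0), noise_floor=0.0, speckle=False)
        vol = render_oct(p, geom, seed=0)
        surf, cand = _segment(vol)
        fit = fit_boundary_surface(cand)
        stop = make_stop_surface(fit, 100.0)
        mask = make_channel_mask((1000.0, 1000.0), 800.0, vol.x, vol.y)
        t = thickness_map(surf, stop, mask)
        X, Y = mask.meshgrid()
        truth = p.boundary_height(X, Y) - 100.0 - p.bone_height(X, Y)
        err = (t.thickness - np.maximum(truth, 0.0))[mask.mask]
        assert np.sqrt(np.mean(err**2)) <= geom.spacing[2]


class TestFallback:
    def test_virtual_structure_is_parallel_shift(self):
        x = np.arange(0.0, 1000.0, 20.0)
        rng = np.random.default_rng(1)
        z = rng.uniform(0, 50, (x.size, x.size))
        surf = SurfaceModel(kind="grid", x=x, y=x, z=z)
        virt = fallback_virtual_structure(surf, 250.0)
        X, Y = np.meshgrid(x, x, indexing="ij")
        assert np.allclose(virt.evaluate(X, Y), surf.evaluate(X, Y) + 250.0)

    def test_huge_nominal_depth_keeps_relative_shape(self):
        x = np.arange(0.0, 1000.0, 20.0)
        z = 10.0 + 0.02 * np.arange(x.size)[:, None] * np.ones(x.size)[None, :]
        surf = SurfaceModel(kind="grid", x=x, y=x, z=z)
        virt = fallback_virtual_structure(surf, 1.0e6)
        X, Y = np.meshgrid(x, x, indexing="ij")
        rel = virt.evaluate(X, Y) - surf.evaluate(X, Y)
        assert np.allclose(rel, 1.0e6, atol=1e-6)
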