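"""Phantom geometry, ablation model and OCT renderer physics."""

import numpy as np
import pytest

from octguide.phantom import (
    GeometryError,
    Phantom,
    PhantomParams,
    ScanGeometry,
    TissueOptics,
    apply_displacement,
    apply_pulse,
    crater_profile,
    default_optics,
    make_phantom,
    render_oct,
    speckle_field,
    SPOT_RADIUS_UM,
)
from octguide.transforms import RigidTransform


class TestMakePhantom:
    def test_spherical_cap_apex_thickness_by_construction(self):
        p = make_phantom(PhantomParams(boundary_apex_depth=1200.0,
                                       curvature_radius=1500.0,
                                       endosteum_thickness=40.0))
        cx = p.params.extent[0] / 2
        assert p.boundary_height(np.array(cx), np.array(cx)) == pytest.approx(1200.0, abs=1e-9)
        # convex towards the surface: apex is the shallowest point
        assert p.z_e.min() == pytest.approx(1200.0, abs=1e-9)
        assert p.z_e.max() > 1200.0

    def test_infinite_radius_gives_constant_thickness(self):
        p = make_phantom(PhantomParams(boundary_apex_depth=800.0,
                                       curvature_radius=np.inf))
        assert np.allclose(p.bone_thickness(), 800.0)

    def test_geometry_independent_of_seed(self):
        p1 = make_phantom(PhantomParams(), seed=1)
        p2 = make_phantom(PhantomParams(), seed=99)
        assert np.array_equal(p1.z_b, p2.z_b)
        assert np.array_equal(p1.z_e, p2.z_e)

    @pytest.mark.parametrize("bad", [
        dict(boundary_apex_depth=-10.0),
        dict(boundary_apex_depth=0.0),
        dict(endosteum_thickness=60.0),
        dict(endosteum_thickness=0.0),
        dict(curvature_radius=-5.0),
        dict(grid_spacing=-1.0),
    ])
    def test_inconsistent_geometry_rejected(self, bad):
        with pytest.raises(GeometryError):
            make_phantom(PhantomParams(**bad))


class TestApplyPulse:
    def test_duration_endpoints_map_to_crater_depths(self, deep_phantom):
        for dur in (20.0, 100.0):
            out = apply_pulse(deep_phantom, (1000.0, 1000.0), dur)
            added = out.z_b - deep_phantom.z_b
            assert added.max() == pytest.approx(dur, rel=1e-6)

    def test_overlapping_craters_add(self, deep_phantom):
        once = apply_pulse(deep_phantom, (1000.0, 1000.0), 60.0)
        twice = apply_pulse(once, (1000.0, 1000.0), 60.0)
        assert (twice.z_b - deep_phantom.z_b).max() == pytest.approx(120.0, rel=1e-6)

    def test_duration_out_of_range_rejected(self, deep_phantom):
        for dur in (10.0, 150.0):
            with pytest.raises(ValueError):
                apply_pulse(deep_phantom, (1000.0, 1000.0), dur)

    def test_ablation_monotone_under_random_pulse_sequence(self, deep_phantom):
        rng = np.random.default_rng(3)
        cur = deep_phantom
        for _ in range(15):
            prev = cur
            pos = tuple(rng.uniform(600, 1400, 2))
            cur = apply_pulse(cur, pos, float(rng.uniform(20, 100)))
            assert np.all(cur.z_b >= prev.z_b - 1e-12)

    def test_removed_volume_matches_crater_integral(self, deep_phantom):
        out = apply_pulse(deep_phantom, (1000.0, 1000.0), 80.0)
        dx = deep_phantom.x[1] - deep_phantom.x[0]
        removed = (out.z_b - deep_phantom.z_b).sum() * dx * dx
        analytic = 80.0 * np.pi * SPOT_RADIUS_UM**2 / 2.0  # Gaussian volume
        assert removed == pytest.approx(analytic, rel=0.01)

    def test_crater_through_boundary_sets_hit_flag_and_clips(self, flat_phantom):
        cur = flat_phantom  # boundary at 400 µm
        for _ in range(3):
            cur = apply_pulse(cur, (1000.0, 1000.0), 100.0)
        assert not cur.critical_hit
        for _ in range(2):
            cur = apply_pulse(cur, (1000.0, 1000.0), 100.0)
        assert cur.critical_hit
        assert np.all(cur.z_b <= cur.z_e + cur.t_e + 1e-9)


class TestApplyDisplacement:
    def test_identity_preserves_rendered_geometry(self, flat_phantom):
        moved = apply_displacement(flat_phantom, RigidTransform.identity())
        assert np.allclose(moved.pose.translation, flat_phantom.pose.translation)

    def test_translation_shifts_surface_in_world_frame(self, deep_phantom):
        marked = apply_pulse(deep_phantom, (1000.0, 1000.0), 100.0)
        moved = apply_displacement(marked, RigidTransform(translation=[50.0, -30.0, 0.0]))
        X = np.array([1050.0]); Y = np.array([970.0])
        zb_moved, _ = moved.world_surface_heights(X, Y)
        zb_orig, _ = marked.world_surface_heights(np.array([1000.0]), np.array([1000.0]))
        assert zb_moved == pytest.approx(zb_orig, abs=1e-6)

    def test_composition_with_inverse_restores_pose(self, flat_phantom):
        t = RigidTransform(translation=[40.0, 10.0, 5.0], angles=[0.01, 0.0, -0.005])
        back = apply_displacement(apply_displacement(flat_phantom, t), t.inverse())
        assert np.allclose(back.pose.translation, 0.0, atol=1e-9)
        assert np.allclose(back.pose.angles, 0.0, atol=1e-9)


class TestRender:
    def test_log_intensity_slope_matches_beer_lambert(self):
        """Homogeneous bone, no speckle/noise: slope = 2× attenuation coefficient."""
        p = make_phantom(PhantomParams(boundary_apex_depth=5000.0,
                                       curvature_radius=np.inf, extent=(2000.0, 2000.0)))
        geom = ScanGeometry(fov=(600.0, 600.0), origin=(700.0, 700.0),
                            z_range=(-60.0, 1200.0), noise_floor=0.0,
                            speckle=False, specular_amplitude=0.0)
        vol = render_oct(p, geom, seed=1)
        prof = vol.data.mean(axis=(0, 1)).astype(float)
        sel = (vol.z > 100) & (vol.z < 400)
        slope = np.polyfit(vol.z[sel], np.log(prof[sel]), 1)[0]
        mu = default_optics()["bone"].attenuation
        assert slope == pytest.approx(-2.0 * mu, rel=0.02)

    def test_bone_signal_meets_noise_floor_near_half_millimetre(self):
        p = make_phantom(PhantomParams(boundary_apex_depth=5000.0,
                                       curvature_radius=np.inf, extent=(2000.0, 2000.0)))
        geom = ScanGeometry(fov=(600.0, 600.0), origin=(700.0, 700.0),
                            z_range=(-60.0, 1200.0))
        vol = render_oct(p, geom, seed=2)
        prof = vol.data.mean(axis=(0, 1)).astype(float)
        # depth at which mean signal has decayed to the (additive) noise level
        idx = np.nonzero((vol.z > 50) & (prof <= 2.0 * geom.noise_floor))[0]
        assert 430.0 <= vol.z[idx[0]] <= 570.0

    def test_point_reflector_psf_fwhm(self):
        transparent = {k: TissueOptics(0.0, 0.0, False) for k in default_optics()}
        p = make_phantom(PhantomParams(boundary_apex_depth=5000.0,
                                       curvature_radius=np.inf, extent=(2000.0, 2000.0),
                                       optics=transparent))
        p.reflectors = np.array([[1000.0, 1000.0, 300.0, 50.0]])
        geom = ScanGeometry(fov=(600.0, 600.0), origin=(700.0, 700.0),
                            z_range=(-60.0, 600.0), spacing=(5.0, 5.0, 3.0),
                            noise_floor=0.0, speckle=False, specular_amplitude=0.0,
                            dynamic_range=100.0)
        vol = render_oct(p, geom, seed=0)
        iu, iv, iw = np.unravel_index(np.argmax(vol.data), vol.shape)

        def fwhm(profile, step):
            prof = profile.astype(float)
            half = prof.max() / 2.0
            above = np.nonzero(prof >= half)[0]
            return (above[-1] - above[0] + 1) * step

        axial = fwhm(vol.data[iu, iv, :], geom.spacing[2])
        lateral = fwhm(vol.data[:, iv, iw], geom.spacing[0])
        assert abs(axial - 18.0) <= geom.spacing[2]
        assert abs(lateral - 35.0) <= geom.spacing[0]

    def test_render_deterministic_for_fixed_seed(self, flat_phantom, small_geom):
        v1 = render_oct(flat_phantom, small_geom, seed=7)
        v2 = render_oct(flat_phantom, small_geom, seed=7)
        assert np.array_equal(v1.data, v2.data)
        v3 = render_oct(flat_phantom, small_geom, seed=8)
        assert not np.array_equal(v1.data, v3.data)

    def test_fov_outside_phantom_rejected(self, flat_phantom):
        geom = ScanGeometry(fov=(1000.0, 1000.0), origin=(1800.0, 1800.0))
        with pytest.raises(GeometryError):
            render_oct(flat_phantom, geom, seed=0)

    @pytest.mark.parametrize("contrast", [0.5, 1.0])
    def test_speckle_contrast_matches_configuration(self, contrast):
        rng = np.random.default_rng(5)
        field = speckle_field((200, 200, 4), contrast, rng)  # 1.6e5 samples
        cov = field.std() / field.mean()
        assert cov == pytest.approx(contrast, rel=0.05)
        assert field.mean() == pytest.approx(1.0, rel=0.02)


def test_nyquist_violation_rejected():
    with pytest.raises(ValueError):
        ScanGeometry(spacing=(20.0, 20.0, 12.0))  # > half the 18 µm axial PSF


def test_crater_profile_shape():
    r = np.array([0.0, SPOT_RADIUS_UM])
    d = crater_profile(r, 100.0)
    assert d[0] == pytest.approx(100.0)
    assert d[1] == pytest.approx(100.0 * np.exp(-2.0), rel=1e-9)
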