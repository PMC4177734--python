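"""Digital cochlea phantom: ground-truth geometry, OCT-like rendering, ablation.

The phantom stands in for the ex vivo specimen and the imaging/ablation
hardware. It carries two analytic height maps sampled on a fine lateral
grid — the air–bone surface ``z_b(x, y)`` and the outer boundary of the
endosteum ``z_e(x, y)`` (depth increases with ``z``, zero at the undisturbed
bone surface plane) — plus the thin endosteal layer of thickness ``t_e``
with perilymph beneath. The cochlear shell is convex towards the outside,
so the boundary is modelled as a spherical cap whose apex (shallowest
point) sits at the channel centre and which deepens towards the rim.

Rendering follows a single-scattering picture: per A-scan the backscatter
profile of the tissue stack is attenuated by a cumulative Beer–Lambert
factor ``exp(-2 τ)`` (round trip), multiplied by unit-mean multiplicative
speckle, given a strong specular reflex at the air–bone interface,
convolved with the anisotropic Gaussian point-spread function of the
scanner (18 µm axial / 35 µm lateral FWHM by default), and summed with an
additive noise floor. With the default bone attenuation the bone signal
meets the noise floor at ≈0.5 mm depth, the penetration the system achieves
in compact bone.

Ablation pulses carve Gaussian craters (1/e² radius = the 100 µm spot
radius of the 200 µm TEM00 beam) whose centre depth maps linearly from the
pulse duration, 20 µs → 20 µm up to 100 µs → 100 µm. Craters add; the bone
surface can only deepen. A crater reaching past ``z_e`` marks the phantom
with a critical-structure hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter

from .transforms import RigidTransform
from .volume import OctVolume

__all__ = [
    "TissueOptics",
    "PhantomParams",
    "Phantom",
    "ScanGeometry",
    "make_phantom",
    "render_oct",
    "apply_pulse",
    "apply_displacement",
    "speckle_field",
    "PULSE_DURATION_RANGE_US",
    "DEPTH_PER_US",
    "SPOT_RADIUS_UM",
]

# Printed system constants: pulse durations 20–100 µs ablate 20–100 µm
# (linear map), spot diameter 200 µm.
PULSE_DURATION_RANGE_US = (20.0, 100.0)
DEPTH_PER_US = 1.0  # µm ablated per µs of pulse duration
SPOT_RADIUS_UM = 100.0

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class GeometryError(ValueError):
    """Raised for inconsistent phantom geometry."""


@dataclass(frozen=True)
class TissueOptics:
    """Optical behaviour of one tissue class.

    attenuation : 1/µm, single-pass intensity attenuation coefficient
    backscatter : arbitrary units, local backscatter level
    speckle : whether the class carries fully developed speckle
    refractive_index : scales geometric to optical (apparent) depth
    """

    attenuation: float
    backscatter: float
    speckle: bool = True
    refractive_index: float = 1.0


def default_optics() -> dict[str, TissueOptics]:
    # Bone attenuation is set so the round-trip signal decays to the noise
    # floor (factor 100 below the bone backscatter level) at 500 µm depth:
    # exp(-2 µ 500) = 1e-2  =>  µ = ln(100)/1000 ≈ 0.0046 /µm.
    return {
        "air": TissueOptics(attenuation=0.0, backscatter=0.0, speckle=False),
        "bone": TissueOptics(attenuation=np.log(100.0) / 1000.0, backscatter=0.5),
        "endosteum": TissueOptics(attenuation=0.003, backscatter=0.9),
        "perilymph": TissueOptics(attenuation=2e-4, backscatter=0.02),
    }


@dataclass
class PhantomParams:
    """Geometry + optics descriptor for :func:`make_phantom` (µm throughout)."""

    extent: tuple[float, float] = (3000.0, 3000.0)
    grid_spacing: float = 10.0
    surface_depth: float = 0.0
    surface_tilt: tuple[float, float] = (0.0, 0.0)  # dz/dx, dz/dy slopes
    boundary_apex_depth: float = 1200.0
    curvature_radius: float = 1500.0
    boundary_center: tuple[float, float] | None = None  # default: extent centre
    endosteum_thickness: float = 40.0
    surface_roughness: float = 0.0  # RMS µm of smooth seeded bumps on z_b
    roughness_scale: float = 150.0  # lateral correlation length of the bumps
    optics: dict[str, TissueOptics] = field(default_factory=default_optics)


@dataclass
class Phantom:
    """Ground-truth tissue model; all lengths in µm, depth positive down."""

    x: np.ndarray  # (nx,) lateral sample positions
    y: np.ndarray  # (ny,)
    z_b: np.ndarray  # (nx, ny) air–bone surface depth
    z_e: np.ndarray  # (nx, ny) bone–endosteum boundary depth
    t_e: float  # endosteum thickness
    optics: dict[str, TissueOptics]
    pose: RigidTransform = field(default_factory=RigidTransform.identity)
    critical_hit: bool = False
    params: PhantomParams | None = None
    reflectors: np.ndarray | None = None  # (N, 4): x, y, z, amplitude — isolated
    # point scatterers (e.g. a resolution target); rendered as sub-voxel deltas

    def __post_init__(self) -> None:
        if self.z_b.shape != (self.x.size, self.y.size) or self.z_e.shape != self.z_b.shape:
            raise GeometryError("height-map shapes do not match the lateral grid")
        # note: z_e > z_b is validated at construction (make_phantom); after a
        # critical-structure hit the ablated surface may legitimately reach z_e
        if not 0 < self.t_e < 50.0:
            raise GeometryError(f"endosteum thickness {self.t_e} µm outside (0, 50) µm")

    # -- geometry queries ---------------------------------------------------
    def _interp(self, grid: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
        f = RegularGridInterpolator(
            (self.x, self.y), grid, bounds_error=False, fill_value=None
        )
        return lambda pts: f(pts)

    def bone_height(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        """Phantom-frame surface depth at lateral points (linear interpolation)."""
        return self._interp(self.z_b)(np.stack([X, Y], axis=-1))

    def boundary_height(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        return self._interp(self.z_e)(np.stack([X, Y], axis=-1))

    def bone_thickness(self) -> np.ndarray:
        """Residual bone thickness z_e − z_b on the phantom grid."""
        return self.z_e - self.z_b

    def world_surface_heights(self, X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Surface and boundary depths seen from the world frame.

        Solves the small-angle pose correspondence by two fixed-point
        iterations; exact for pure translations.
        """
        if self.pose.is_identity():
            return self.bone_height(X, Y), self.boundary_height(X, Y)
        out = []
        for interp_grid in (self.z_b, self.z_e):
            f = self._interp(interp_grid)
            z_w = np.full(np.shape(X), self.pose.translation[2] + float(interp_grid.mean()))
            inv = self.pose.inverse()
            for _ in range(3):
                q = inv.apply(np.stack([X, Y, z_w], axis=-1))
                zq = f(np.stack([q[..., 0], q[..., 1]], axis=-1))
                z_w = self.pose.apply(
                    np.stack([q[..., 0], q[..., 1], zq], axis=-1)
                )[..., 2]
            out.append(z_w)
        return out[0], out[1]

    def copy(self) -> "Phantom":
        return replace(self, z_b=self.z_b.copy(), z_e=self.z_e.copy())

    def export_height_maps(self) -> tuple[np.ndarray, np.ndarray]:
        """Two (N, 3) tables ``(x, y, z_b)`` and ``(x, y, z_e)`` for CSV export."""
        X, Y = np.meshgrid(self.x, self.y, indexing="ij")
        a = np.column_stack([X.ravel(), Y.ravel(), self.z_b.ravel()])
        b = np.column_stack([X.ravel(), Y.ravel(), self.z_e.ravel()])
        return a, b


def make_phantom(params: PhantomParams, seed: int = 0) -> Phantom:
    """Build the layered bone/endosteum/perilymph phantom.

    The bone top is a (possibly tilted, optionally rough) plane; the
    endosteum boundary is a spherical cap of the given curvature radius with
    its apex — the shallowest point, the cochlea being convex towards the
    outside — at ``boundary_apex_depth`` under the boundary centre.
    Geometry is deterministic given ``seed``; with zero roughness it is
    seed-independent.
    """
    p = params
    if p.grid_spacing <= 0 or p.extent[0] <= 0 or p.extent[1] <= 0:
        raise GeometryError("extent and grid spacing must be positive")
    if p.boundary_apex_depth <= p.surface_depth:
        raise GeometryError("boundary apex must lie beneath the bone surface")
    if p.curvature_radius <= 0:
        raise GeometryError("curvature radius must be positive (np.inf for a plane)")
    if not 0 < p.endosteum_thickness < 50.0:
        raise GeometryError("endosteum thickness must be in (0, 50) µm")

    x = np.arange(0.0, p.extent[0] + 0.5 * p.grid_spacing, p.grid_spacing)
    y = np.arange(0.0, p.extent[1] + 0.5 * p.grid_spacing, p.grid_spacing)
    X, Y = np.meshgrid(x, y, indexing="ij")

    z_b = p.surface_depth + p.surface_tilt[0] * X + p.surface_tilt[1] * Y
    if p.surface_roughness > 0:
        rng = np.random.default_rng(seed)
        bumps = gaussian_filter(
            rng.standard_normal(X.shape), p.roughness_scale / p.grid_spacing
        )
        std = bumps.std()
        if std > 0:
            z_b = z_b + bumps * (p.surface_roughness / std)

    cx, cy = p.boundary_center if p.boundary_center is not None else (
        p.extent[0] / 2.0,
        p.extent[1] / 2.0,
    )
    if np.isinf(p.curvature_radius):
        # infinite radius: boundary parallel to the (un-roughened) surface plane
        z_e = p.boundary_apex_depth + p.surface_tilt[0] * X + p.surface_tilt[1] * Y
    else:
        r2 = (X - cx) ** 2 + (Y - cy) ** 2
        R = p.curvature_radius
        sag = R - np.sqrt(np.maximum(R * R - np.minimum(r2, R * R), 0.0))
        z_e = p.boundary_apex_depth + sag

    if not np.all(z_e > z_b):
        raise GeometryError(
            "inconsistent geometry: boundary not strictly beneath the surface everywhere"
        )
    return Phantom(x=x, y=y, z_b=z_b, z_e=z_e, t_e=p.endosteum_thickness,
                   optics=dict(p.optics), params=p)


# ---------------------------------------------------------------------------
# Scan geometry and rendering
# ---------------------------------------------------------------------------

@dataclass
class ScanGeometry:
    """Field of view and optical response of the simulated OCT scanner."""

    fov: tuple[float, float] = (1400.0, 1400.0)  # lateral extent, µm
    origin: tuple[float, float] = (800.0, 800.0)  # world position of voxel (0, 0)
    spacing: tuple[float, float, float] = (20.0, 20.0, 6.0)  # (du, dv, dw) µm
    z_range: tuple[float, float] = (-60.0, 1560.0)  # axial window, µm depth
    axial_fwhm: float = 18.0
    lateral_fwhm: float = 35.0
    noise_floor: float = 0.005
    speckle: bool = True
    speckle_contrast: float = 1.0
    specular_amplitude: float = 3.0
    dynamic_range: float = 1.0

    def __post_init__(self) -> None:
        if self.axial_fwhm <= 0 or self.lateral_fwhm <= 0:
            raise ValueError("PSF FWHMs must be positive")
        if min(self.spacing) <= 0:
            raise ValueError("voxel spacing must be positive")
        if self.spacing[2] > self.axial_fwhm / 2.0:
            raise ValueError(
                f"axial spacing {self.spacing[2]} µm violates Nyquist for a "
                f"{self.axial_fwhm} µm axial PSF"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        nu = int(np.floor(self.fov[0] / self.spacing[0])) + 1
        nv = int(np.floor(self.fov[1] / self.spacing[1])) + 1
        nw = int(np.floor((self.z_range[1] - self.z_range[0]) / self.spacing[2])) + 1
        return nu, nv, nw

    def lateral_grids(self) -> tuple[np.ndarray, np.ndarray]:
        nu, nv, _ = self.shape
        xs = self.origin[0] + np.arange(nu) * self.spacing[0]
        ys = self.origin[1] + np.arange(nv) * self.spacing[1]
        return xs, ys


def speckle_field(
    shape: tuple[int, ...], contrast: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-mean multiplicative speckle with the given intensity contrast.

    Fully developed speckle has exponentially distributed intensity
    (contrast 1); intermediate contrasts ``c`` use a Gamma distribution
    with shape ``1/c²``, the classical ``N``-look model.
    """
    if contrast <= 0:
        return np.ones(shape)
    k = 1.0 / (contrast * contrast)
    return rng.gamma(shape=k, scale=1.0 / k, size=shape)


def render_oct(phantom: Phantom, geom: ScanGeometry, seed: int = 0) -> OctVolume:
    """Render an OCT-like volume of the phantom in its current pose.

    Deterministic given ``(phantom, geom, seed)``.
    """
    xs, ys = geom.lateral_grids()
    if (
        xs[0] < phantom.x[0] - 1e-6
        or xs[-1] > phantom.x[-1] + 1e-6
        or ys[0] < phantom.y[0] - 1e-6
        or ys[-1] > phantom.y[-1] + 1e-6
    ):
        raise GeometryError("scan field of view exceeds the phantom extent")

    nu, nv, nw = geom.shape
    dw = geom.spacing[2]
    z = geom.z_range[0] + np.arange(nw) * dw  # depth samples

    X, Y = np.meshgrid(xs, ys, indexing="ij")
    zb_w, ze_w = phantom.world_surface_heights(X, Y)

    opt = phantom.optics
    n_bone = opt["bone"].refractive_index
    n_end = opt["endosteum"].refractive_index
    # apparent (optical) depths of the subsurface interfaces
    c0 = zb_w[..., None]
    c1 = (zb_w + n_bone * (ze_w - zb_w))[..., None]
    c2 = c1 + n_end * phantom.t_e

    Z = z[None, None, :]
    in_bone = (Z >= c0) & (Z < c1)
    in_end = (Z >= c1) & (Z < c2)
    in_peri = Z >= c2

    mu = np.zeros((nu, nv, nw))
    back = np.zeros((nu, nv, nw))
    spk = np.zeros((nu, nv, nw), dtype=bool)
    for mask, cls in ((in_bone, "bone"), (in_end, "endosteum"), (in_peri, "perilymph")):
        mu[mask] = opt[cls].attenuation
        back[mask] = opt[cls].backscatter
        spk[mask] = opt[cls].speckle
    # air voxels keep µ = 0, backscatter = 0

    tau = np.cumsum(mu, axis=2) * dw - 0.5 * mu * dw  # optical depth at voxel centres
    intensity = back * np.exp(-2.0 * tau)

    rng = np.random.default_rng(seed)
    if geom.speckle:
        mult = speckle_field(intensity.shape, geom.speckle_contrast, rng)
        intensity = np.where(spk, intensity * mult, intensity)

    # strong specular reflex at the air–bone interface, placed with
    # sub-voxel weighting so its blurred peak is centred on the true surface
    fidx = (zb_w - geom.z_range[0]) / dw
    k0 = np.floor(fidx).astype(int)
    frac = fidx - k0
    iu, iv = np.meshgrid(np.arange(nu), np.arange(nv), indexing="ij")
    ok0 = (k0 >= 0) & (k0 < nw)
    ok1 = (k0 + 1 >= 0) & (k0 + 1 < nw)
    amp = geom.specular_amplitude
    intensity[iu[ok0], iv[ok0], k0[ok0]] += amp * (1.0 - frac[ok0])
    intensity[iu[ok1], iv[ok1], k0[ok1] + 1] += amp * frac[ok1]

    if phantom.reflectors is not None:
        for rx, ry, rz, ramp in np.atleast_2d(phantom.reflectors):
            p_w = phantom.pose.apply(np.array([rx, ry, rz]))
            fu = (p_w[0] - geom.origin[0]) / geom.spacing[0]
            fv = (p_w[1] - geom.origin[1]) / geom.spacing[1]
            fw = (p_w[2] - geom.z_range[0]) / dw
            iu0, iv0, iw0 = int(np.floor(fu)), int(np.floor(fv)), int(np.floor(fw))
            for du_ in (0, 1):
                for dv_ in (0, 1):
                    for dw_ in (0, 1):
                        ku, kv, kw = iu0 + du_, iv0 + dv_, iw0 + dw_
                        if 0 <= ku < nu and 0 <= kv < nv and 0 <= kw < nw:
                            wgt = (
                                (1 - abs(fu - ku)) * (1 - abs(fv - kv)) * (1 - abs(fw - kw))
                            )
                            intensity[ku, kv, kw] += ramp * wgt

    sig_lat = geom.lateral_fwhm * FWHM_TO_SIGMA
    sigmas = (
        sig_lat / geom.spacing[0],
        sig_lat / geom.spacing[1],
        geom.axial_fwhm * FWHM_TO_SIGMA / geom.spacing[2],
    )
    intensity = gaussian_filter(intensity, sigma=sigmas, mode="nearest")

    if geom.noise_floor > 0:
        intensity = intensity + geom.noise_floor * rng.exponential(size=intensity.shape)

    np.clip(intensity, 0.0, geom.dynamic_range, out=intensity)
    return OctVolume(
        data=intensity.astype(np.float32),
        spacing=np.asarray(geom.spacing),
        origin=np.array([geom.origin[0], geom.origin[1], geom.z_range[0]]),
        dynamic_range=geom.dynamic_range,
    )


# ---------------------------------------------------------------------------
# Ablation and motion
# ---------------------------------------------------------------------------

def crater_profile(r: np.ndarray, duration_us: float) -> np.ndarray:
    """Gaussian crater depth d(r) = d0 exp(-2 r²/w0²) for one pulse."""
    d0 = duration_us * DEPTH_PER_US
    return d0 * np.exp(-2.0 * (r / SPOT_RADIUS_UM) ** 2)


def apply_pulse(
    phantom: Phantom, position: tuple[float, float], duration_us: float
) -> Phantom:
    """Ablate one pulse at a lateral world position; returns a new Phantom.

    The crater adds onto any existing relief. Ablation past the endosteum
    outer boundary sets the critical-structure hit flag; the bone surface is
    clipped at the perilymph interface (``z_e + t_e``).
    """
    lo, hi = PULSE_DURATION_RANGE_US
    if not lo <= duration_us <= hi:
        raise ValueError(f"pulse duration {duration_us} µs outside [{lo}, {hi}] µs")
    # map the commanded (world/laser frame) position into the phantom frame
    p0 = phantom.pose.inverse().apply(np.array([position[0], position[1], 0.0]))
    px, py = float(p0[0]), float(p0[1])
    if not (phantom.x[0] <= px <= phantom.x[-1] and phantom.y[0] <= py <= phantom.y[-1]):
        raise GeometryError(f"pulse position {position} outside the phantom field")

    out = phantom.copy()
    cut = 3.0 * SPOT_RADIUS_UM
    ix = np.nonzero(np.abs(out.x - px) <= cut)[0]
    iy = np.nonzero(np.abs(out.y - py) <= cut)[0]
    if ix.size and iy.size:
        Xl, Yl = np.meshgrid(out.x[ix], out.y[iy], indexing="ij")
        r = np.hypot(Xl - px, Yl - py)
        sub = np.ix_(ix, iy)
        new_zb = out.z_b[sub] + crater_profile(r, duration_us)
        if np.any(new_zb > out.z_e[sub]):
            out.critical_hit = True
        out.z_b[sub] = np.minimum(new_zb, out.z_e[sub] + out.t_e)
    return out


def apply_displacement(phantom: Phantom, transform: RigidTransform) -> Phantom:
    """Compose a rigid displacement onto the phantom pose (new Phantom)."""
    out = phantom.copy()
    out.pose = transform.compose(phantom.pose)
    return out
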