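"""Surface extraction and residual-thickness computation.

The channel bottom (air–bone surface) is bright and specular, so it is
found by simple per-A-scan thresholding with sub-voxel peak refinement and
cleaned by grey-morphological smoothing of the height map. The
bone–endosteum–perilymph boundary is faint: it is segmented per B-scan
frame as axial-gradient extrema below the detected surface, linked into
chains under a continuity model, and a robust bicubic B-spline is fitted
to all linked candidates of the volume at once, so frames with sparse
evidence borrow support from their neighbours.

Depths are micrometres, increasing downward. A *stop surface* is the
segmented boundary shifted towards the surface by the chosen standoff; the
residual-thickness map (per lateral position: stop depth minus channel
bottom depth, clamped at zero, with the complementary penetration map) is
what drives pulse planning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import LSQBivariateSpline, RegularGridInterpolator
from scipy.ndimage import binary_dilation, gaussian_filter1d, grey_closing, grey_opening

from .volume import OctVolume

__all__ = [
    "SurfaceModel",
    "BoundaryCandidates",
    "ThicknessMap",
    "ChannelMask",
    "SegmentationParams",
    "BoundaryFitParams",
    "InsufficientSupportError",
    "detect_bone_surface",
    "segment_critical_boundary",
    "fit_boundary_surface",
    "make_stop_surface",
    "thickness_map",
    "fallback_virtual_structure",
    "make_channel_mask",
    "support_mask",
]


class InsufficientSupportError(RuntimeError):
    """The boundary fit cannot be trusted; the caller should fall back."""


@dataclass
class SurfaceModel:
    """A lateral surface ``z = s(x, y)``, as a grid height map or bicubic spline.

    ``z_offset`` is added at evaluation time; shifting a surface to build a
    parallel stop surface is therefore exact, not resampled.
    """

    kind: str  # "grid" | "spline"
    x: np.ndarray | None = None
    y: np.ndarray | None = None
    z: np.ndarray | None = None  # (nx, ny) for kind == "grid"
    valid: np.ndarray | None = None
    spline: LSQBivariateSpline | None = None
    bbox: tuple[float, float, float, float] | None = None  # x0, x1, y0, y1
    z_offset: float = 0.0
    clip_to_bbox: bool = False  # if True, NaN outside bbox instead of extrapolating

    def __post_init__(self) -> None:
        if self.kind == "grid":
            if self.z is None or self.x is None or self.y is None:
                raise ValueError("grid surface needs x, y and z samples")
            if self.valid is None:
                self.valid = np.isfinite(self.z)
        elif self.kind == "spline":
            if self.spline is None:
                raise ValueError("spline surface needs a fitted spline")
            assert self.spline.degrees == (3, 3), "boundary surface must be bicubic"
        else:
            raise ValueError(f"unknown surface kind {self.kind!r}")

    def evaluate(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        """Surface depth at lateral points; NaN outside the valid region."""
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if self.kind == "grid":
            zm = np.where(self.valid, self.z, np.nan)
            f = RegularGridInterpolator(
                (self.x, self.y), zm, bounds_error=False, fill_value=np.nan
            )
            out = f(np.stack([X, Y], axis=-1))
        else:
            out = self.spline.ev(X.ravel(), Y.ravel()).reshape(X.shape)
            if self.clip_to_bbox and self.bbox is not None:
                x0, x1, y0, y1 = self.bbox
                outside = (X < x0) | (X > x1) | (Y < y0) | (Y > y1)
                out = np.where(outside, np.nan, out)
        return out + self.z_offset

    def shifted(self, dz: float) -> "SurfaceModel":
        """The same surface translated axially by ``dz`` (positive = deeper)."""
        return replace(self, z_offset=self.z_offset + dz)

    def fraction_valid(self) -> float:
        if self.kind == "grid":
            return float(np.mean(self.valid))
        return 1.0


@dataclass
class ChannelMask:
    """Lateral planning grid with the cochleostomy channel footprint."""

    x: np.ndarray
    y: np.ndarray
    mask: np.ndarray  # (nx, ny) bool

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x, self.y, indexing="ij")


def make_channel_mask(
    center: tuple[float, float], diameter: float, x: np.ndarray, y: np.ndarray
) -> ChannelMask:
    X, Y = np.meshgrid(x, y, indexing="ij")
    mask = np.hypot(X - center[0], Y - center[1]) <= diameter / 2.0
    return ChannelMask(x=np.asarray(x, float), y=np.asarray(y, float), mask=mask)


@dataclass
class BoundaryCandidates:
    """Gradient-edge candidates for the subsurface boundary.

    ``points`` is (N, 3) world coordinates (x, y, z µm); ``grad`` the
    per-point axial gradient magnitude; ``frame`` the B-scan index each
    point came from. ``linked`` marks lateral grid positions belonging to a
    chain that satisfied the continuity model; ``confidence`` is the
    fraction of channel A-scans with a linked candidate.
    """

    points: np.ndarray
    grad: np.ndarray
    frame: np.ndarray
    linked: np.ndarray
    confidence: float
    polylines: list[np.ndarray] = field(default_factory=list)


@dataclass
class ThicknessMap:
    """Residual bone thickness above the stop surface, per lateral position."""

    x: np.ndarray
    y: np.ndarray
    thickness: np.ndarray  # µm, >= 0
    penetration: np.ndarray  # µm, >= 0, complementary to thickness
    mask: np.ndarray  # channel footprint

    def masked_thickness(self) -> np.ndarray:
        return self.thickness[self.mask]


# ---------------------------------------------------------------------------
# Surface detection
# ---------------------------------------------------------------------------

def _parabolic_refine(a: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Sub-voxel offset of local extrema by quadratic interpolation."""
    n = a.shape[-1]
    i0 = np.clip(idx, 1, n - 2)
    am = np.take_along_axis(a, (i0 - 1)[..., None], axis=-1)[..., 0]
    a0 = np.take_along_axis(a, i0[..., None], axis=-1)[..., 0]
    ap = np.take_along_axis(a, (i0 + 1)[..., None], axis=-1)[..., 0]
    denom = am - 2.0 * a0 + ap
    safe = np.where(np.abs(denom) > 1e-12, denom, 1.0)
    delta = np.where(np.abs(denom) > 1e-12, 0.5 * (am - ap) / safe, 0.0)
    return i0 + np.clip(delta, -1.0, 1.0)


def detect_bone_surface(
    vol: OctVolume,
    threshold: float,
    peak_window: int = 5,
    smooth_size: int = 3,
    fill_invalid: bool = False,
    dominance: float = 0.8,
) -> SurfaceModel:
    """Extract the air–bone surface height map from a volume.

    Per A-scan: first suprathreshold sample, refined to the sub-voxel
    centre of the local specular peak; then grey closing and opening with a
    ``smooth_size`` square on the height map remove outlier spikes. A-scans
    with no suprathreshold sample are marked invalid; with
    ``fill_invalid`` isolated misses are instead inpainted by the
    morphological smoothing and the surface reported valid everywhere.

    At a steep relief step (the channel wall, a deep crater) the lateral
    PSF leaks the *shallow* side's specular into the neighbouring column,
    and the first crossing would report the shallow rim instead of the
    column's own surface. A crossing whose peak is weaker than
    ``dominance`` times the column maximum is therefore re-seeded at the
    dominant specular of the A-scan.
    """
    if not 0 < threshold <= vol.dynamic_range:
        raise ValueError("threshold must lie within the volume dynamic range")
    data = vol.data.astype(float)
    above = data >= threshold
    has = np.any(above, axis=2)
    if not np.any(has):
        raise ValueError("empty volume: no suprathreshold surface found anywhere")
    w0 = np.argmax(above, axis=2)
    # climb to the local peak of the specular reflex within a short window
    nw = data.shape[2]
    offs = np.arange(peak_window)

    def climb(seed):
        idx = np.minimum(seed[..., None] + offs, nw - 1)
        seg = np.take_along_axis(data, idx, axis=2)
        return np.take_along_axis(idx, np.argmax(seg, axis=2)[..., None], axis=2)[..., 0]

    peak = climb(w0)
    peak_val = np.take_along_axis(data, peak[..., None], axis=2)[..., 0]
    col_max = data.max(axis=2)
    weak = peak_val < dominance * col_max
    if np.any(weak):
        reseed = np.argmax(data, axis=2)
        start = np.maximum(reseed - peak_window // 2, 0)
        peak = np.where(weak, climb(start), peak)
    wref = _parabolic_refine(data, peak)
    height = vol.origin[2] + wref * vol.spacing[2]

    fill = float(np.nanmax(np.where(has, height, -np.inf)))
    hmap = np.where(has, height, fill)
    size = (smooth_size, smooth_size)
    hmap = grey_opening(grey_closing(hmap, size=size), size=size)
    valid = np.ones_like(has) if fill_invalid else has
    return SurfaceModel(kind="grid", x=vol.x, y=vol.y, z=hmap, valid=valid)


# ---------------------------------------------------------------------------
# Boundary segmentation
# ---------------------------------------------------------------------------

@dataclass
class SegmentationParams:
    """Tunables of the gradient edge detector and the linking model."""

    min_offset: float = 80.0  # µm below the detected surface before searching
    max_offset: float = 600.0  # µm search depth; bounded by the ~0.5 mm penetration
    axial_smooth_sigma: float = 1.5  # voxels, pre-gradient smoothing
    lateral_smooth_sigma: float = 2.0  # voxels along u, within-frame speckle averaging
    max_jump: int = 2  # axial voxels allowed between adjacent A-scans
    min_chain: int = 10  # A-scans, minimum accepted chain length
    guard_voxels: int = 6  # deepest samples excluded from the search
    refine_window: int = 5  # voxels searched in the localization volume
    surface_consistency: bool = True  # robust low-order prefit rejects stray chains
    consistency_floor: float = 25.0  # µm, minimum inlier band around the prefit
    consistency_cap: float = 60.0  # µm, maximum inlier band


def _smoothed_axial_gradient(
    data: np.ndarray, dw: float, p: "SegmentationParams"
) -> np.ndarray:
    s = gaussian_filter1d(data, p.axial_smooth_sigma, axis=2, mode="nearest")
    if p.lateral_smooth_sigma > 0:
        s = gaussian_filter1d(s, p.lateral_smooth_sigma, axis=0, mode="nearest")
    return np.gradient(s, dw, axis=2)


def segment_critical_boundary(
    vol: OctVolume,
    bone_surface: SurfaceModel,
    params: SegmentationParams | None = None,
    channel_mask: np.ndarray | None = None,
    localization_volume: OctVolume | None = None,
) -> BoundaryCandidates:
    """Per-frame gradient edge detection plus continuity-model linking.

    In each B-scan frame the candidate edge of every A-scan is the largest
    positive axial gradient in a window below the bone surface (the
    boundary appears as a rise into the brighter endosteum). Candidates of
    adjacent A-scans whose axial positions differ by at most ``max_jump``
    voxels are linked; only chains of at least ``min_chain`` A-scans are
    kept. Confidence is the fraction of channel A-scans carrying a linked
    candidate — near zero when the boundary is deeper than the imaging
    range, because argmax positions are then speckle-random and do not
    chain.

    The attenuation-compensated volume is the right place to *detect* the
    faint boundary, but its depth-monotone gain skews the gradient peak a
    little deeper than the true edge. When ``localization_volume`` (the
    pre-compensation compound) is given, each detected candidate is
    re-localised on that volume's gradient within ``refine_window`` voxels,
    removing the skew.
    """
    p = params or SegmentationParams()
    data = vol.data.astype(float)
    nu, nv, nw = data.shape
    dw = vol.spacing[2]
    grad = _smoothed_axial_gradient(data, dw, p)

    X, Y = np.meshgrid(vol.x, vol.y, indexing="ij")
    surf = bone_surface.evaluate(X, Y)
    surf_ok = np.isfinite(surf)

    z = vol.z
    lo = np.searchsorted(z, np.where(surf_ok, surf + p.min_offset, np.inf))
    hi = np.searchsorted(z, np.where(surf_ok, surf + p.max_offset, -np.inf))
    hi = np.minimum(hi, nw - p.guard_voxels)
    window_ok = surf_ok & (hi > lo + 2)

    wgrid = np.arange(nw)
    in_win = (wgrid[None, None, :] >= lo[..., None]) & (wgrid[None, None, :] < hi[..., None])
    gmask = np.where(in_win, grad, -np.inf)
    cand = np.argmax(gmask, axis=2)
    gval = np.take_along_axis(grad, cand[..., None], axis=2)[..., 0]
    cand_ok = window_ok & np.isfinite(gval) & (gval > 0)
    # an argmax pinned to the window edge is censoring, not an edge: the
    # candidate must be a local gradient maximum strictly inside the window
    cand_ok &= (cand > lo) & (cand < hi - 1)
    g_prev = np.take_along_axis(grad, np.maximum(cand - 1, 0)[..., None], axis=2)[..., 0]
    g_next = np.take_along_axis(grad, np.minimum(cand + 1, nw - 1)[..., None], axis=2)[..., 0]
    cand_ok &= (gval >= g_prev) & (gval >= g_next)

    if localization_volume is not None:
        if not vol.same_grid(localization_volume):
            raise ValueError("localization volume grid does not match")
        loc_grad = _smoothed_axial_gradient(
            localization_volume.data.astype(float), dw, p
        )
        r = p.refine_window
        offs = np.arange(-r, r + 1)
        idx = np.clip(cand[..., None] + offs, 1, nw - 2)
        seg = np.take_along_axis(loc_grad, idx, axis=2)
        cand = np.take_along_axis(idx, np.argmax(seg, axis=2)[..., None], axis=2)[..., 0]
        cand_f = _parabolic_refine(loc_grad, cand)
    else:
        cand_f = _parabolic_refine(grad, cand)

    # continuity-model linking along u within each frame v
    linked = np.zeros((nu, nv), dtype=bool)
    polylines: list[np.ndarray] = []
    for iv in range(nv):
        ok = cand_ok[:, iv]
        w = cand[:, iv]
        start = 0
        for iu in range(1, nu + 1):
            boundary_break = (
                iu == nu
                or not ok[iu]
                or not ok[iu - 1]
                or abs(int(w[iu]) - int(w[iu - 1])) > p.max_jump
            )
            if boundary_break:
                if ok[start] and iu - start >= p.min_chain:
                    linked[start:iu, iv] = True
                    zs = vol.origin[2] + cand_f[start:iu, iv] * dw
                    polylines.append(
                        np.column_stack([vol.x[start:iu], np.full(iu - start, vol.y[iv]), zs])
                    )
                start = iu
    zs = vol.origin[2] + cand_f * dw

    # global surface-consistency filter: the anatomical boundary is smooth
    # (a near-spherical shell), so linked candidates must cohere with one
    # low-order surface; chains formed by correlated speckle or deep
    # amplified noise scatter hundreds of µm around it and are rejected
    if p.surface_consistency and np.count_nonzero(linked) >= 32:
        lx, ly, lz = X[linked], Y[linked], zs[linked]
        sx, sy = lx - lx.mean(), ly - ly.mean()
        scale = max(sx.std(), sy.std(), 1.0)
        sx, sy = sx / scale, sy / scale
        A = np.column_stack([np.ones_like(sx), sx, sy, sx * sx, sx * sy, sy * sy])
        w = np.ones_like(lz)
        resid = np.zeros_like(lz)
        mad = np.inf
        for _ in range(10):
            coef, *_ = np.linalg.lstsq(A * w[:, None], lz * w, rcond=None)
            resid = lz - A @ coef
            med = np.median(resid)
            mad = np.median(np.abs(resid - med))
            c = 3.0 * max(mad, 10.0)
            rr = np.clip(np.abs(resid - med) / c, 0.0, 1.0)
            w = (1.0 - rr * rr) ** 2 + 1e-6
        band = float(np.clip(3.5 * mad, p.consistency_floor, p.consistency_cap))
        keep = np.abs(resid - np.median(resid)) <= band
        drop_idx = np.nonzero(linked)
        linked = linked.copy()
        linked[drop_idx[0][~keep], drop_idx[1][~keep]] = False

    sel = linked
    points = np.column_stack([X[sel], Y[sel], zs[sel]])
    frames = np.nonzero(sel)[1]

    cm = channel_mask if channel_mask is not None else surf_ok
    denom = int(np.count_nonzero(cm))
    confidence = float(np.count_nonzero(linked & cm)) / denom if denom else 0.0
    return BoundaryCandidates(
        points=points,
        grad=gval[sel],
        frame=frames,
        linked=linked,
        confidence=confidence,
        polylines=polylines,
    )


# ---------------------------------------------------------------------------
# Robust bicubic boundary fit
# ---------------------------------------------------------------------------

@dataclass
class BoundaryFitParams:
    knot_spacing: float = 150.0  # µm between interior knots, both lateral axes
    n_iter: int = 5  # reweighting iterations
    tukey_factor: float = 3.0  # cut at this multiple of the median abs residual
    min_confidence: float = 0.5  # visibility gate; below it, fall back


def _interior_knots(vals: np.ndarray, spacing: float) -> np.ndarray:
    lo, hi = float(vals.min()), float(vals.max())
    # keep interior knots strictly inside and leave breathing room at the rim
    knots = np.arange(lo + spacing, hi - 0.5 * spacing, spacing)
    return knots


def fit_boundary_surface(
    candidates: BoundaryCandidates, params: BoundaryFitParams | None = None
) -> SurfaceModel:
    """Robust bicubic B-spline fit to all candidate edge points of a volume.

    Iteratively reweighted least squares with Tukey biweight down-weighting
    at ``tukey_factor`` times the median absolute residual, so isolated
    mis-detections do not bend the surface. Raises
    :class:`InsufficientSupportError` when confidence is below the
    visibility gate or the control lattice is not supported by the points.
    """
    p = params or BoundaryFitParams()
    if candidates.confidence < p.min_confidence:
        raise InsufficientSupportError(
            f"boundary confidence {candidates.confidence:.2f} below "
            f"{p.min_confidence:.2f}: use fallback"
        )
    pts = candidates.points
    if pts.shape[0] < 16:
        raise InsufficientSupportError("too few candidate points for a bicubic lattice")
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    tx = _interior_knots(x, p.knot_spacing)
    ty = _interior_knots(y, p.knot_spacing)
    w = np.ones_like(z)
    spline = None
    for _ in range(max(1, p.n_iter)):
        try:
            with warnings.catch_warnings():
                # partial lateral coverage leaves rim knot cells unsupported;
                # the minimal-norm solution is fine inside the supported
                # region, which is the only region the caller may trust
                warnings.simplefilter("ignore", UserWarning)
                spline = LSQBivariateSpline(x, y, z, tx, ty, w=w, kx=3, ky=3)
        except Exception as exc:  # dfitpack errors on unsupported lattices
            raise InsufficientSupportError(
                f"insufficient lateral support for the control lattice: {exc}"
            ) from exc
        resid = z - spline.ev(x, y)
        mad = np.median(np.abs(resid))
        if mad <= 1e-9:
            break
        c = p.tukey_factor * mad
        r = np.clip(np.abs(resid) / c, 0.0, 1.0)
        w = (1.0 - r * r) ** 2 + 1e-6
    bbox = (float(x.min()), float(x.max()), float(y.min()), float(y.max()))
    return SurfaceModel(kind="spline", spline=spline, bbox=bbox)


def quadratic_model_surface(points: np.ndarray):
    """Least-squares quadratic surface through boundary points.

    Returns ``evaluate(X, Y) -> Z``. Used as the smooth global model the
    bicubic refinement is not allowed to stray far from: the anatomical
    boundary is a near-spherical shell, which a quadratic captures to a
    few µm over a millimetre-scale channel.
    """
    x, y, z = points[:, 0], points[:, 1], points[:, 2]
    mx, my = x.mean(), y.mean()
    scale = max(x.std(), y.std(), 1.0)
    sx, sy = (x - mx) / scale, (y - my) / scale
    A = np.column_stack([np.ones_like(sx), sx, sy, sx * sx, sx * sy, sy * sy])
    coef, *_ = np.linalg.lstsq(A, z, rcond=None)

    def evaluate(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        u = (np.asarray(X, float) - mx) / scale
        v = (np.asarray(Y, float) - my) / scale
        return (
            coef[0] + coef[1] * u + coef[2] * v
            + coef[3] * u * u + coef[4] * u * v + coef[5] * v * v
        )

    return evaluate


def support_mask(
    candidates: BoundaryCandidates,
    lateral_spacing: tuple[float, float],
    radius: float = 150.0,
) -> np.ndarray:
    """Lateral positions where the fitted boundary can be trusted.

    The linked-candidate footprint dilated by ``radius`` (one knot
    interval by default): inside it the spline is constrained by data,
    outside it is pure extrapolation and must not drive planning.
    """
    rx = max(1, int(np.ceil(radius / lateral_spacing[0])))
    ry = max(1, int(np.ceil(radius / lateral_spacing[1])))
    yy, xx = np.meshgrid(np.arange(-ry, ry + 1), np.arange(-rx, rx + 1))
    disc = (xx / rx) ** 2 + (yy / ry) ** 2 <= 1.0
    return binary_dilation(candidates.linked, structure=disc)


# ---------------------------------------------------------------------------
# Stop surface, thickness map, fallback
# ---------------------------------------------------------------------------

def make_stop_surface(boundary: SurfaceModel, offset: float) -> SurfaceModel:
    """Stop surface: the boundary shifted ``offset`` µm towards the surface."""
    if offset < 0:
        raise ValueError("stop-surface offset must be non-negative")
    return boundary.shifted(-offset)


def fallback_virtual_structure(
    original_surface: SurfaceModel, nominal_depth: float
) -> SurfaceModel:
    """A virtual critical structure parallel to the round-0 bone surface.

    Used while the real boundary is still out of imaging range: planning
    against it produces a channel bottom parallel to the original surface.
    The nominal depth is a finite stand-in for "at infinity"; the loop caps
    per-round ablation depth instead.
    """
    return original_surface.shifted(nominal_depth)


def thickness_map(
    bottom: SurfaceModel, stop: SurfaceModel, channel_mask: ChannelMask
) -> ThicknessMap:
    """Residual thickness and penetration between channel bottom and stop.

    ``thickness = max(stop − bottom, 0)`` and ``penetration =
    max(bottom − stop, 0)`` along the optical axis, evaluated on the
    channel-mask lateral grid; the two decompose the signed difference
    exactly. Surfaces must be valid everywhere inside the mask.
    """
    X, Y = channel_mask.meshgrid()
    zb = bottom.evaluate(X, Y)
    zs = stop.evaluate(X, Y)
    diff = zs - zb
    if np.any(~np.isfinite(diff[channel_mask.mask])):
        raise ValueError("surface undefined inside the channel mask")
    thickness = np.where(channel_mask.mask, np.maximum(diff, 0.0), 0.0)
    penetration = np.where(channel_mask.mask, np.maximum(-diff, 0.0), 0.0)
    return ThicknessMap(
        x=channel_mask.x,
        y=channel_mask.y,
        thickness=thickness,
        penetration=penetration,
        mask=channel_mask.mask,
    )
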