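"""OCT-landmark tracking: the imaging system as its own motion tracker.

Small craters ablated on a ring around the planned cochleostomy serve as
artificial landmarks. Each new volume is reduced to a surface height map;
every landmark is localised to sub-voxel precision as the depth-weighted
centroid of its crater within a search window around its expected
position, and the rigid displacement of the target area relative to the
working space follows from closed-form least-squares point-set
registration of detected versus reference landmark positions. Because the
cochleostomy sits near the centroid of the landmark layout, rotational
estimation errors are not amplified at the channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np

from .phantom import SPOT_RADIUS_UM, Phantom, apply_pulse
from .planning import Pulse, PulsePlan
from .surfaces import SurfaceModel, detect_bone_surface
from .transforms import RigidTransform
from .volume import OctVolume

__all__ = [
    "LandmarkSet",
    "TrackingLostError",
    "plan_landmarks",
    "ablate_landmarks",
    "localize_landmarks",
    "estimate_displacement",
    "apply_correction",
]

log = logging.getLogger(__name__)


class TrackingLostError(RuntimeError):
    """Fewer than three valid landmark correspondences; halt ablation."""


@dataclass
class LandmarkSet:
    """Reference landmark layout and the latest detections."""

    reference: np.ndarray  # (n, 3) positions at ablation time (µm)
    ring_radius: float
    channel_center: tuple[float, float]
    detected: np.ndarray | None = None  # (n, 3) latest localisation
    valid: np.ndarray | None = None  # (n,) detection validity flags

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference, dtype=float)
        if ref.shape[0] < 3:
            raise ValueError("need at least three landmarks")
        lateral = ref[:, :2] - ref[:, :2].mean(axis=0)
        if np.linalg.matrix_rank(lateral, tol=1e-6) < 2:
            raise ValueError("landmarks must be non-collinear")
        self.reference = ref

    @property
    def centroid(self) -> np.ndarray:
        return self.reference.mean(axis=0)


def plan_landmarks(
    channel_center: tuple[float, float],
    ring_radius: float,
    count: int = 4,
    channel_radius: float = 500.0,
    surface_depth: float = 0.0,
) -> LandmarkSet:
    """Equally spaced landmarks on a ring around the channel.

    The ring must clear the channel by at least one spot radius so the
    landmark craters never intersect the cochleostomy.
    """
    if count < 3:
        raise ValueError("need at least three landmarks")
    if ring_radius <= channel_radius + SPOT_RADIUS_UM:
        raise ValueError(
            f"ring radius {ring_radius} µm overlaps the channel "
            f"(needs > {channel_radius + SPOT_RADIUS_UM} µm)"
        )
    ang = 2.0 * np.pi * np.arange(count) / count
    pts = np.column_stack(
        [
            channel_center[0] + ring_radius * np.cos(ang),
            channel_center[1] + ring_radius * np.sin(ang),
            np.full(count, surface_depth),
        ]
    )
    return LandmarkSet(reference=pts, ring_radius=ring_radius, channel_center=channel_center)


def ablate_landmarks(
    phantom: Phantom, landmarks: LandmarkSet, duration_us: float = 100.0, n_pulses: int = 2
) -> Phantom:
    """Burn the landmark craters onto the phantom (stacked pulses per site)."""
    out = phantom
    for p in landmarks.reference:
        for _ in range(n_pulses):
            out = apply_pulse(out, (p[0], p[1]), duration_us)
    return out


def localize_landmarks(
    vol: OctVolume,
    expected: LandmarkSet,
    surface: SurfaceModel | None = None,
    surface_threshold: float = 0.5,
    window_factor: float = 3.0,
    min_depth: float = 10.0,
    exclude_center_radius: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sub-voxel crater centres from the surface height map.

    For each landmark a square search window of ``window_factor`` spot
    diameters around the expected lateral position is cut from the height
    map; the crater centre is the centroid of the local extra depth
    (height minus the window median, clipped at zero) and its axial
    coordinate the local undisturbed surface level. A landmark is flagged
    invalid when the window leaves the scan field or contains no crater
    deeper than ``min_depth`` µm.

    ``exclude_center_radius`` masks out a disc around the channel centre:
    once the cochleostomy has been ablated, its pit would otherwise leak
    into windows of landmarks ringed closely around it and drag the
    centroid off the crater.
    """
    if surface is None:
        surface = detect_bone_surface(vol, surface_threshold)
    x, y = surface.x, surface.y
    h = np.where(surface.valid, surface.z, np.nan)
    half = window_factor * SPOT_RADIUS_UM
    n = expected.reference.shape[0]
    start = expected.detected if expected.detected is not None else expected.reference
    detected = np.full((n, 3), np.nan)
    valid = np.zeros(n, dtype=bool)
    for i in range(n):
        ex, ey = start[i, 0], start[i, 1]
        ix = np.nonzero(np.abs(x - ex) <= half)[0]
        iy = np.nonzero(np.abs(y - ey) <= half)[0]
        if ix.size < 3 or iy.size < 3:
            continue  # window (mostly) outside the field of view
        sub = h[np.ix_(ix, iy)]
        finite = np.isfinite(sub)
        Xs, Ys = np.meshgrid(x[ix], y[iy], indexing="ij")
        if exclude_center_radius is not None:
            cx, cy = expected.channel_center
            finite &= np.hypot(Xs - cx, Ys - cy) > exclude_center_radius
        if np.mean(finite) < 0.5:
            continue
        baseline = np.nanmedian(np.where(finite, sub, np.nan))
        wgt = np.where(finite, np.maximum(sub - baseline, 0.0), 0.0)
        if wgt.max() < min_depth:
            continue
        s = wgt.sum()
        detected[i] = (
            float((wgt * Xs).sum() / s),
            float((wgt * Ys).sum() / s),
            float(baseline),
        )
        valid[i] = True
    expected.detected = detected
    expected.valid = valid
    return detected, valid


def estimate_displacement(
    reference: np.ndarray, detected: np.ndarray, valid: np.ndarray | None = None
) -> tuple[RigidTransform, np.ndarray]:
    """Closed-form least-squares rigid alignment reference → detected.

    Standard SVD point-set registration (no scale). Raises
    :class:`TrackingLostError` with fewer than three valid, non-collinear
    correspondences. Returns the transform and per-landmark residuals.
    """
    ref = np.asarray(reference, dtype=float)
    det = np.asarray(detected, dtype=float)
    if valid is None:
        valid = np.all(np.isfinite(det), axis=1)
    ref, det = ref[valid], det[valid]
    if ref.shape[0] < 3:
        raise TrackingLostError(
            f"only {ref.shape[0]} valid landmarks; tracking lost — halt ablation"
        )
    rc, dc = ref.mean(axis=0), det.mean(axis=0)
    H = (ref - rc).T @ (det - dc)
    if np.linalg.matrix_rank((ref - rc)[:, :2], tol=1e-6) < 2:
        raise TrackingLostError("valid landmarks are collinear; tracking lost")
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = dc - R @ rc
    transform = RigidTransform.from_matrix(R, t)
    residuals = np.linalg.norm(transform.apply(ref) - det, axis=1)
    return transform, residuals


def apply_correction(
    plan: PulsePlan,
    transform: RigidTransform,
    working_space: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> PulsePlan:
    """Map every planned pulse position through the estimated displacement.

    Durations are untouched. Pulses whose corrected position leaves the
    working space are dropped and logged rather than fired blind.
    """
    corrected: list[Pulse] = []
    for p in plan.pulses:
        q = transform.apply(np.array([p.x, p.y, 0.0]))
        if working_space is not None:
            (x0, x1), (y0, y1) = working_space
            if not (x0 <= q[0] <= x1 and y0 <= q[1] <= y1):
                log.warning(
                    "dropping pulse at (%.1f, %.1f): corrected position "
                    "(%.1f, %.1f) leaves the working space",
                    p.x, p.y, q[0], q[1],
                )
                continue
        corrected.append(
            Pulse(x=float(q[0]), y=float(q[1]), duration_us=p.duration_us,
                  duration_class=p.duration_class, energy_mj=p.energy_mj)
        )
    return PulsePlan(pulses=corrected, round_index=plan.round_index)
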