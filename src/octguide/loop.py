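"""The closed control loop: scan → enhance → segment → plan → correct → ablate.

Each round renders a volume of the phantom in its current pose, estimates
any rigid displacement from the landmark ring (when tracking is enabled),
brings the volume into the stable reference frame, compounds it with the
usable history, compensates attenuation, extracts the channel bottom and —
once the bone–endosteum–perilymph boundary is confidently visible — fits
the boundary and derives the stop surface at the configured standoff.
While the boundary is still out of imaging range the round plans against a
virtual critical structure parallel to the original bone surface, which
yields a channel bottom parallel to it. Pulses are planned greedily on the
residual-thickness map, mapped through the estimated displacement, and
applied to the phantom. The loop stops when the stop surface is reached
everywhere on the channel (converged), on a critical-structure hit, on
lost tracking, on a hard depth-safety stop, or when rounds run out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .enhance import (
    compensate_attenuation,
    register_to_current,
    rescaled_history_compound,
)
from .phantom import (
    SPOT_RADIUS_UM,
    Phantom,
    ScanGeometry,
    apply_displacement,
    apply_pulse,
    crater_profile,
    render_oct,
)
from .planning import PlanningConstraints, PulsePlan, is_terminated, plan_ablation
from .surfaces import (
    BoundaryFitParams,
    ChannelMask,
    InsufficientSupportError,
    SegmentationParams,
    SurfaceModel,
    detect_bone_surface,
    fallback_virtual_structure,
    fit_boundary_surface,
    make_channel_mask,
    make_stop_surface,
    quadratic_model_surface,
    segment_critical_boundary,
    support_mask,
    thickness_map,
)
from .tracking import (
    LandmarkSet,
    TrackingLostError,
    ablate_landmarks,
    apply_correction,
    estimate_displacement,
    localize_landmarks,
    plan_landmarks,
)
from .transforms import RigidTransform

__all__ = ["LoopConfig", "RoundRecord", "LoopResult", "EvaluationReport", "run_loop", "evaluate_result"]


@dataclass
class LoopConfig:
    """All tunables of one closed-loop run (lengths in µm)."""

    target_thickness: float = 100.0  # standoff of the stop surface above the boundary
    tolerance: float = 10.0  # termination: thickness ≤ tolerance everywhere
    max_rounds: int = 40
    channel_diameter: float = 1000.0
    channel_center: tuple[float, float] | None = None  # default: scan-field centre
    wall_margin: float = 100.0  # one spot radius: the sloped wall annulus is
    # not part of the "channel bottom" that termination and evaluation see
    surface_threshold: float = 0.5
    history_length: int = 8
    fallback_nominal_depth: float = 1.0e6  # "virtual structure at infinity"
    safety_max_depth: float = 1600.0  # hard stop on detected channel depth
    bone_attenuation: float = 0.004605  # 1/µm, for history rescaling (≈ ln(100)/1 mm)
    tracking_enabled: bool = False
    landmark_count: int = 4
    landmark_ring_radius: float = 800.0
    displacement_jitter_sigma: float = 0.0  # per-round lateral jitter (µm), tests only
    keep_snapshots: bool = False  # retain per-round ground-truth bottoms
    seed: int = 0
    scan: ScanGeometry = field(default_factory=ScanGeometry)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    boundary_fit: BoundaryFitParams = field(default_factory=BoundaryFitParams)
    planning: PlanningConstraints = field(default_factory=PlanningConstraints)

    def __post_init__(self) -> None:
        if self.target_thickness < 0:
            raise ValueError("target thickness must be non-negative")
        if self.max_rounds < 1:
            raise ValueError("need at least one round")


@dataclass
class RoundRecord:
    round_index: int
    confidence: float
    used_fallback: bool
    coverage: float  # fraction of the channel with a trusted boundary fit
    n_pulses: int
    plan: PulsePlan
    transform: RigidTransform
    thickness_mean: float
    thickness_max: float
    detected_depth_max: float
    gt_bottom: np.ndarray | None = None


@dataclass
class LoopResult:
    rounds: list[RoundRecord]
    termination: str  # converged | max_rounds | tracking_lost | critical_hit | safety_stop
    phantom: Phantom
    stop_surface: SurfaceModel | None
    channel_mask: ChannelMask  # full channel footprint (planning)
    bottom_mask: ChannelMask  # channel bottom, wall annulus excluded (evaluation)
    original_surface: SurfaceModel | None
    first_visible_round: int | None  # first round with a trusted boundary fit

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)


@dataclass
class EvaluationReport:
    """Ground-truth channel bottom versus the stop surface, over the mask."""

    mean_abs_error: float
    std_error: float
    max_penetration: float
    critical_hit: bool
    error_map: np.ndarray  # signed, bottom − stop (µm); NaN outside the mask
    mean_signed_error: float

    def __post_init__(self) -> None:
        assert self.max_penetration >= 0


def _round_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def run_loop(config: LoopConfig, phantom: Phantom) -> LoopResult:
    """Run the closed loop against a phantom until a termination condition.

    Fully reproducible: all randomness (render speckle and noise, optional
    displacement jitter) derives from ``config.seed``.
    """
    geom = config.scan
    xs, ys = geom.lateral_grids()
    center = config.channel_center or (
        geom.origin[0] + geom.fov[0] / 2.0,
        geom.origin[1] + geom.fov[1] / 2.0,
    )
    channel = make_channel_mask(center, config.channel_diameter, xs, ys)
    bottom = make_channel_mask(
        center, config.channel_diameter - 2.0 * config.wall_margin, xs, ys
    )
    render_seeds = _round_seeds(config.seed, config.max_rounds + 1)
    jitter_rng = np.random.default_rng(int(render_seeds[-1]))

    landmarks: LandmarkSet | None = None
    reference_detection: np.ndarray | None = None
    if config.tracking_enabled:
        landmarks = plan_landmarks(
            center,
            config.landmark_ring_radius,
            config.landmark_count,
            channel_radius=config.channel_diameter / 2.0,
        )
        phantom = ablate_landmarks(phantom, landmarks)
        # reference layout is measured right after ablating the landmarks,
        # before any displacement can occur
        ref_vol = render_oct(phantom, geom, seed=int(render_seeds[-1]))
        reference_detection, ref_valid = localize_landmarks(
            ref_vol,
            LandmarkSet(landmarks.reference.copy(), landmarks.ring_radius, center),
            exclude_center_radius=config.channel_diameter / 2.0 + SPOT_RADIUS_UM,
        )
        if not ref_valid.all():
            raise TrackingLostError("reference landmark detection incomplete")

    history_vols: list = []
    history_surfs: list = []
    # best-known stop surface per lateral position (reference frame): the
    # boundary is static, so once a position has had a trusted fit its
    # estimate is kept when later rounds lose visibility there — firing
    # "infinite-depth" fallback pulses into a thin residual layer because
    # one round's confidence dipped would destroy the endosteum
    known_stop: np.ndarray | None = None
    # cumulative commanded crater depth per lateral position (reference
    # frame): a dead-reckoning bound on the channel depth. At steep relief
    # (the channel wall, deep pits) the optical surface reading saturates
    # on the shallow side of the step and would let the planner fire into
    # the same spot indefinitely; the commanded ablation budget cannot be
    # fooled that way, so the effective bottom is the deeper of the two.
    commanded_depth: np.ndarray | None = None
    rounds: list[RoundRecord] = []
    original_surface: SurfaceModel | None = None
    stop: SurfaceModel | None = None
    first_visible: int | None = None
    termination = "max_rounds"

    for r in range(config.max_rounds):
        if config.displacement_jitter_sigma > 0:
            jitter = RigidTransform(
                translation=np.r_[
                    jitter_rng.normal(0, config.displacement_jitter_sigma, 2), 0.0
                ]
            )
            phantom = apply_displacement(phantom, jitter)

        vol = render_oct(phantom, geom, seed=int(render_seeds[r]))
        vol.acquisition_index = r

        transform = RigidTransform.identity()
        if config.tracking_enabled and landmarks is not None:
            try:
                det, val = localize_landmarks(
                    vol,
                    LandmarkSet(landmarks.reference.copy(), landmarks.ring_radius, center),
                    exclude_center_radius=config.channel_diameter / 2.0 + SPOT_RADIUS_UM,
                )
                transform, _ = estimate_displacement(reference_detection, det, val)
            except TrackingLostError:
                termination = "tracking_lost"
                break
        # bring the acquisition into the reference frame for processing
        vol_ref = register_to_current(vol, transform.inverse())

        surface = detect_bone_surface(vol_ref, config.surface_threshold, fill_invalid=True)
        if original_surface is None:
            original_surface = surface
        Xv, Yv = np.meshgrid(xs, ys, indexing="ij")
        surf_map = surface.evaluate(Xv, Yv)
        compound = rescaled_history_compound(
            vol_ref, history_vols, surf_map, history_surfs, config.bone_attenuation
        )
        enhanced = compensate_attenuation(compound)
        candidates = segment_critical_boundary(
            enhanced,
            surface,
            config.segmentation,
            channel_mask=channel.mask,
            localization_volume=compound,
        )
        # stop surface: fitted boundary minus standoff where the fit has
        # lateral candidate support; the fallback virtual structure
        # (parallel to the round-0 surface, effectively at infinity)
        # everywhere else — extrapolated spline values must not drive
        # planning, and termination cannot trigger while any channel
        # position is still unsupported
        X, Y = channel.meshgrid()
        fallback = fallback_virtual_structure(
            original_surface, config.fallback_nominal_depth
        )
        used_fallback = True
        coverage = 0.0
        try:
            boundary = fit_boundary_surface(candidates, config.boundary_fit)
            support = support_mask(
                candidates,
                (geom.spacing[0], geom.spacing[1]),
                radius=config.boundary_fit.knot_spacing,
            )
            coverage = float(np.mean(support[channel.mask]))
            guided_stop = make_stop_surface(boundary, config.target_thickness)
            # the bicubic refinement must stay within the consistency band
            # of the smooth global model; sparsely supported spline cells
            # can oscillate by hundreds of µm and would otherwise steer
            # pulses through the boundary
            quad = quadratic_model_surface(candidates.points)
            qz = quad(X, Y) - config.target_thickness
            band = config.segmentation.consistency_cap
            guided_z = np.clip(guided_stop.evaluate(X, Y), qz - band, qz + band)
            if known_stop is None:
                known_stop = np.full(X.shape, np.nan)
            known_stop = np.where(support, guided_z, known_stop)
            used_fallback = False
            if first_visible is None:
                first_visible = r
        except InsufficientSupportError:
            pass
        if known_stop is not None:
            stop_z = np.where(np.isfinite(known_stop), known_stop,
                              fallback.evaluate(X, Y))
            stop = SurfaceModel(kind="grid", x=channel.x, y=channel.y, z=stop_z)
        else:
            stop = fallback

        detected_z = surface.evaluate(X, Y)
        if commanded_depth is None:
            commanded_depth = np.zeros(X.shape)
            original_z = detected_z.copy()
        bottom_eff = SurfaceModel(
            kind="grid", x=channel.x, y=channel.y,
            z=np.maximum(detected_z, original_z + commanded_depth),
        )
        tmap = thickness_map(bottom_eff, stop, channel)
        tmap_bottom = thickness_map(bottom_eff, stop, bottom)
        depth_max = float(np.nanmax(np.where(channel.mask, detected_z, np.nan)))

        guided_vals = tmap.masked_thickness()
        guided_vals = guided_vals[guided_vals < config.fallback_nominal_depth / 2.0]
        t_mean = float(guided_vals.mean()) if guided_vals.size else np.nan
        t_max = float(guided_vals.max()) if guided_vals.size else np.nan

        if not used_fallback and is_terminated(tmap_bottom, config.tolerance):
            termination = "converged"
            rounds.append(RoundRecord(
                round_index=r, confidence=candidates.confidence, used_fallback=False,
                coverage=coverage, n_pulses=0, plan=PulsePlan(round_index=r),
                transform=transform, thickness_mean=t_mean, thickness_max=t_max,
                detected_depth_max=depth_max,
                gt_bottom=phantom.z_b.copy() if config.keep_snapshots else None,
            ))
            break
        if depth_max >= config.safety_max_depth:
            termination = "safety_stop"
            break

        constraints = config.planning
        plan = plan_ablation(tmap, constraints, round_index=r)
        corrected = apply_correction(
            plan, transform,
            working_space=((xs[0], xs[-1]), (ys[0], ys[-1])),
        )
        hit = False
        for pulse in corrected.pulses:
            phantom = apply_pulse(phantom, (pulse.x, pulse.y), pulse.duration_us)
            # book the commanded crater into the dead-reckoning budget at
            # its reference-frame (tissue) position
            ref_pos = transform.inverse().apply(np.array([pulse.x, pulse.y, 0.0]))
            rr = np.hypot(X - ref_pos[0], Y - ref_pos[1])
            commanded_depth += crater_profile(rr, pulse.duration_us)
            if phantom.critical_hit:
                hit = True
                break

        history_vols.append(vol_ref)
        history_surfs.append(surf_map)
        if len(history_vols) > config.history_length:
            history_vols.pop(0)
            history_surfs.pop(0)

        rounds.append(RoundRecord(
            round_index=r, confidence=candidates.confidence, used_fallback=used_fallback,
            coverage=coverage, n_pulses=len(corrected), plan=corrected, transform=transform,
            thickness_mean=t_mean, thickness_max=t_max,
            detected_depth_max=depth_max,
            gt_bottom=phantom.z_b.copy() if config.keep_snapshots else None,
        ))
        if hit:
            termination = "critical_hit"
            break

    return LoopResult(
        rounds=rounds,
        termination=termination,
        phantom=phantom,
        stop_surface=stop,
        channel_mask=channel,
        bottom_mask=bottom,
        original_surface=original_surface,
        first_visible_round=first_visible,
    )


def evaluate_result(
    phantom_final: Phantom, stop: SurfaceModel, mask: ChannelMask
) -> EvaluationReport:
    """Strict accuracy evaluation against ground truth.

    The signed per-position error is the ground-truth channel bottom depth
    minus the stop-surface depth, on the channel mask; positive values are
    penetrations past the stop surface.
    """
    X, Y = mask.meshgrid()
    bottom, _ = phantom_final.world_surface_heights(X, Y)
    stop_z = stop.evaluate(X, Y)
    if np.any(~np.isfinite(stop_z[mask.mask])):
        raise ValueError("stop surface undefined inside the channel mask")
    signed = np.where(mask.mask, bottom - stop_z, np.nan)
    vals = signed[mask.mask]
    return EvaluationReport(
        mean_abs_error=float(np.abs(vals).mean()),
        std_error=float(np.abs(vals).std()),
        max_penetration=float(np.maximum(vals, 0.0).max()),
        critical_hit=phantom_final.critical_hit,
        error_map=signed,
        mean_signed_error=float(vals.mean()),
    )
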