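"""Pulse planning: thickness map in, next round's ablation pattern out.

The strategy is greedy: repeatedly place the next pulse at the not-yet-
claimed channel position of maximal residual thickness, claim a disc of
the minimum pulse spacing around it, and stop when no eligible position
remains. The pulse duration is quasi-proportional to the local excess
thickness — clamped to the tunable 20–100 µs range (20–100 µm nominal
depth under the linear duration→depth map) and quantised to the three
classes short / middle / long. Pulse energy follows the same linear map,
20 µs → 4.2 mJ through 100 µs → 28.5 mJ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import DEPTH_PER_US, PULSE_DURATION_RANGE_US
from .surfaces import ThicknessMap

__all__ = [
    "Pulse",
    "PulsePlan",
    "PlanningConstraints",
    "plan_ablation",
    "duration_for_thickness",
    "energy_for_duration",
    "is_terminated",
]

ENERGY_RANGE_MJ = (4.2, 28.5)

_CLASS_DURATIONS = {"short": 20.0, "middle": 60.0, "long": 100.0}


def energy_for_duration(duration_us: float) -> float:
    """Pulse energy in mJ, linear in duration (20 µs → 4.2 mJ, 100 µs → 28.5 mJ)."""
    lo, hi = PULSE_DURATION_RANGE_US
    e_lo, e_hi = ENERGY_RANGE_MJ
    return e_lo + (duration_us - lo) * (e_hi - e_lo) / (hi - lo)


@dataclass(frozen=True)
class Pulse:
    x: float
    y: float
    duration_us: float
    duration_class: str
    energy_mj: float


@dataclass
class PulsePlan:
    pulses: list[Pulse] = field(default_factory=list)
    round_index: int = 0

    def __len__(self) -> int:
        return len(self.pulses)

    def positions(self) -> np.ndarray:
        if not self.pulses:
            return np.zeros((0, 2))
        return np.array([[p.x, p.y] for p in self.pulses])

    def min_pairwise_distance(self) -> float:
        pos = self.positions()
        if len(pos) < 2:
            return np.inf
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        return float(d[~np.eye(len(pos), dtype=bool)].min())


@dataclass
class PlanningConstraints:
    """Spacing and target for the greedy planner.

    ``target`` is the residual thickness (µm, measured to the stop surface)
    to leave standing; with a thickness map already referenced to the stop
    surface it is zero. Pulses are only planned where the thickness exceeds
    ``target + margin``.
    """

    min_spacing: float = 150.0  # µm between pulse centres
    target: float = 0.0
    margin: float = 10.0
    class_thresholds: tuple[float, float] = (100.0, 300.0)  # excess µm: short|middle|long
    quantize: bool = True


def duration_for_thickness(
    thickness: float,
    target: float = 0.0,
    class_thresholds: tuple[float, float] = (100.0, 300.0),
    quantize: bool = True,
) -> tuple[float, str]:
    """Pulse duration (µs) and class for a local excess thickness.

    Excess = thickness − target. The continuous law clamps the excess into
    the 20–100 µs range (1 µm nominal depth per µs); quantisation snaps to
    short (20 µs), middle (60 µs) or long (100 µs) by the excess
    thresholds. The nominal depth never exceeds the excess by more than the
    short-pulse depth of 20 µm.
    """
    excess = thickness - target
    if excess <= 0:
        raise ValueError(f"thickness {thickness} µm does not exceed target {target} µm")
    lo, hi = PULSE_DURATION_RANGE_US
    duration = float(np.clip(excess / DEPTH_PER_US, lo, hi))
    t_mid, t_long = class_thresholds
    if excess >= t_long:
        cls = "long"
    elif excess >= t_mid:
        cls = "middle"
    else:
        cls = "short"
    if quantize:
        duration = min(_CLASS_DURATIONS[cls], duration)
    nominal_depth = duration * DEPTH_PER_US
    assert nominal_depth <= excess + _CLASS_DURATIONS["short"] * DEPTH_PER_US
    return duration, cls


def plan_ablation(
    t: ThicknessMap, constraints: PlanningConstraints | None = None, round_index: int = 0
) -> PulsePlan:
    """Greedy maximal-thickness pulse placement under the spacing rule.

    Each iteration picks the unclaimed in-mask position of maximal
    thickness strictly above ``target + margin`` (ties broken
    lexicographically by (y, x)), appends a pulse there and claims the
    spacing disc around it. An empty plan is valid output: it means the
    round has nothing left to ablate.
    """
    c = constraints or PlanningConstraints()
    X, Y = np.meshgrid(t.x, t.y, indexing="ij")
    eligible = t.mask.copy()
    thick = t.thickness
    cutoff = c.target + c.margin
    pulses: list[Pulse] = []
    while True:
        avail = np.where(eligible & (thick > cutoff), thick, -np.inf)
        # lexicographic (y, x) tie-break: scan the transposed (y-major) array
        flat = np.argmax(avail.T)
        iy, ix = np.unravel_index(flat, avail.T.shape)
        if not np.isfinite(avail[ix, iy]):
            break
        px, py = float(t.x[ix]), float(t.y[iy])
        duration, cls = duration_for_thickness(
            float(thick[ix, iy]), c.target, c.class_thresholds, c.quantize
        )
        pulses.append(
            Pulse(x=px, y=py, duration_us=duration, duration_class=cls,
                  energy_mj=energy_for_duration(duration))
        )
        eligible &= (X - px) ** 2 + (Y - py) ** 2 >= c.min_spacing**2
    return PulsePlan(pulses=pulses, round_index=round_index)


def is_terminated(t: ThicknessMap, tolerance: float) -> bool:
    """True iff thickness ≤ tolerance at every channel-mask position."""
    vals = t.masked_thickness()
    if vals.size == 0:
        raise ValueError("thickness map has an empty channel mask")
    return bool(np.all(vals <= tolerance))
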