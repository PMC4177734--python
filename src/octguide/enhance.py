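"""Image-quality chain applied before segmentation.

Two stages, in the order the control loop uses them:

1. **History compounding** — speckle averaging across loop rounds. Each
   acquired volume is kept (co-registered to the current pose) together
   with a lateral change mask recording where ablation has altered the
   tissue since that round. The compound image averages, per voxel, the
   current volume with those history volumes whose column is unchanged;
   decorrelated speckle averages down as 1/sqrt(N) while the anatomy,
   static wherever the mask is clear, is preserved.

2. **Attenuation compensation** — a per-A-scan energy-remaining
   normalisation: each sample is divided by (twice) the signal energy
   remaining beneath it, with a contrast exponent ``n``,

       out(w) = I(w)^n / (2 Σ_{w' > w} I(w')^n + floor).

   Structures whose raw signal has been attenuated into the noise gain
   contrast because the denominator has decayed with them. The deepest
   samples of each A-scan have no tail left to normalise by; a small guard
   band at the bottom of the scan is zeroed, and the result is rescaled to
   the input dynamic range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import shift as nd_shift

from .transforms import RigidTransform
from .volume import OctVolume

__all__ = [
    "VolumeHistory",
    "history_compound",
    "rescaled_history_compound",
    "compensate_attenuation",
    "register_to_current",
]

log = logging.getLogger(__name__)


@dataclass
class VolumeHistory:
    """Prior-round volumes co-registered to the current pose.

    ``change_masks[i]`` is a lateral boolean grid, true where ablation has
    changed the tissue since round ``i`` was acquired; those columns are
    excluded from the average. Masks are monotone: once a column is marked
    changed it stays changed in every older round's mask.
    """

    volumes: list[OctVolume] = field(default_factory=list)
    change_masks: list[np.ndarray] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.volumes)

    def append(self, vol: OctVolume) -> None:
        """Add the newest round with an all-clear change mask."""
        self.volumes.append(vol)
        self.change_masks.append(np.zeros(vol.shape[:2], dtype=bool))

    def mark_changed(self, mask: np.ndarray) -> None:
        """Propagate newly ablated lateral positions into every round's mask."""
        for m in self.change_masks:
            m |= mask

    def trim(self, max_len: int) -> None:
        while len(self.volumes) > max_len:
            self.volumes.pop(0)
            self.change_masks.pop(0)


def register_to_current(vol: OctVolume, transform: RigidTransform) -> OctVolume:
    """Resample a history volume into the current pose.

    ``transform`` maps the old acquisition frame onto the current one; the
    dominant motion in this application is translational, so the volume is
    shifted by the translation in voxel units (linear interpolation,
    nearest-edge padding). Identity transforms return the input unchanged.
    """
    if transform.is_identity(atol=1e-9):
        return vol
    shift_vox = transform.translation / vol.spacing
    out = vol.copy()
    out.data = nd_shift(vol.data.astype(float), shift_vox, order=1, mode="nearest")
    out.data = np.clip(out.data, 0.0, vol.dynamic_range).astype(vol.data.dtype)
    return out


def history_compound(current: OctVolume, history: VolumeHistory) -> OctVolume:
    """Masked temporal average of the current volume with usable history.

    At each voxel the output is the mean of the current intensity and the
    intensities of those history volumes whose change mask is false at that
    lateral position. Columns with no usable history pass through
    unchanged. Spacing, origin and dynamic range are preserved.
    """
    if len(history) == 0:
        return current.copy()
    acc = current.data.astype(np.float64).copy()
    count = np.ones(current.shape[:2], dtype=np.float64)
    for vol, mask in zip(history.volumes, history.change_masks):
        if not current.same_grid(vol):
            raise ValueError("history volume grid does not match the current volume")
        usable = ~mask
        acc[usable] += vol.data[usable]
        count[usable] += 1.0
    out = current.copy()
    out.data = (acc / count[..., None]).astype(np.float32)
    return out


def rescaled_history_compound(
    current: OctVolume,
    history_volumes: list[OctVolume],
    current_surface: np.ndarray,
    history_surfaces: list[np.ndarray],
    bone_attenuation: float,
    min_weight: float = 1e-3,
) -> OctVolume:
    """Speckle averaging across ablation rounds with attenuation rescaling.

    Ablation moves the bone surface down by a known, per-column amount; the
    subsurface anatomy — in particular the bone–endosteum–perilymph
    boundary — stays where it is, only its signal grows brighter as the
    overlying bone thins (round-trip Beer–Lambert factor
    ``exp(2 µ_bone Δd)`` for a column deepened by ``Δd``). Multiplying each
    history column by that factor aligns its subsurface signal with the
    current round, so even re-ablated columns can be averaged. Because the
    rescaling amplifies the history's detector noise by the same factor,
    rounds are blended with inverse-variance weights ``exp(−4 µ_bone Δd)``:
    recent, lightly ablated history contributes strongly, old deep history
    fades out.

    ``current_surface``/``history_surfaces`` are detected surface depth
    maps (µm) on the volume's lateral grid. The shallow band between the
    old and new surface position is stale in the history (it was bone, now
    air); consumers search for the boundary well below the current
    surface, where the compound is valid.
    """
    acc = current.data.astype(np.float64).copy()
    wsum = np.ones(current.shape[:2])
    for vol, surf in zip(history_volumes, history_surfaces):
        if not current.same_grid(vol):
            raise ValueError("history volume grid does not match the current volume")
        dd = np.clip(current_surface - surf, 0.0, None)
        fac = np.exp(2.0 * bone_attenuation * dd)
        w = 1.0 / (fac * fac)
        w[w < min_weight] = 0.0
        rescaled = np.clip(
            vol.data.astype(np.float64) * fac[..., None], 0.0, current.dynamic_range
        )
        acc += rescaled * w[..., None]
        wsum += w
    out = current.copy()
    out.data = np.clip(acc / wsum[..., None], 0.0, current.dynamic_range).astype(np.float32)
    return out


def compensate_attenuation(
    vol: OctVolume,
    exponent: float = 2.0,
    floor: float | None = None,
    guard_voxels: int = 8,
    subtract_noise: bool = True,
    tail_window_um: float = 500.0,
) -> OctVolume:
    """Energy-remaining attenuation compensation, per A-scan.

    Parameters
    ----------
    exponent : contrast exponent ``n`` applied before normalisation.
    floor : additive denominator guard; defaults to 1e-6 of the dynamic
        range (per-voxel energy scale).
    guard_voxels : number of deepest samples zeroed before rescaling — the
        energy-remaining denominator is meaningless where almost no tail
        remains.
    subtract_noise : estimate the additive noise floor from the deepest
        decile of the scan and subtract it (clipped at zero) before
        normalising, so the compensation amplifies signal, not detector
        noise.
    tail_window_um : depth extent of the energy-remaining integral. No
        signal exists beyond the light-penetration range (~0.5 mm in
        bone), so integrating the tail further only accumulates residual
        noise energy into the denominator; ``0`` or ``inf`` integrates to
        the bottom of the scan.
    """
    if exponent <= 0:
        raise ValueError("contrast exponent must be positive")
    if floor is None:
        floor = 1e-6 * vol.dynamic_range
    data = vol.data.astype(np.float64)
    if subtract_noise and data.shape[2] >= 10:
        noise_est = float(np.mean(data[..., -max(2, data.shape[2] // 10):]))
        data = np.maximum(data - noise_est, 0.0)
    if not np.any(data > 0):
        log.warning("attenuation compensation of an all-zero volume")
        out = vol.copy()
        out.data = np.zeros_like(vol.data)
        return out
    powered = data**exponent
    # tail sum strictly below each sample: reversed cumulative sum shifted by one
    rev_cum = np.flip(np.cumsum(np.flip(powered, axis=2), axis=2), axis=2)
    tail = rev_cum - powered
    if tail_window_um and np.isfinite(tail_window_um):
        k = int(round(tail_window_um / vol.spacing[2]))
        if 0 < k < data.shape[2]:
            # subtract the portion of the tail deeper than the window
            beyond = np.zeros_like(rev_cum)
            beyond[..., : data.shape[2] - k] = rev_cum[..., k:]
            tail = tail - beyond
    comp = powered / (2.0 * tail + floor)
    if guard_voxels > 0:
        comp[..., -guard_voxels:] = 0.0
    zero_scans = ~np.any(data > 0, axis=2)
    if np.any(zero_scans):
        log.warning("%d all-zero A-scans in attenuation compensation", int(zero_scans.sum()))
    peak = comp.max()
    if peak > 0:
        comp *= vol.dynamic_range / peak
    out = vol.copy()
    out.data = comp.astype(np.float32)
    return out
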