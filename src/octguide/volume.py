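"""The in-memory OCT volume container and its on-disk representation.

A volume is a non-negative intensity grid indexed ``(u, v, w)`` with ``w``
the axial (depth) direction, together with the voxel spacing in micrometres
and the acquisition round it belongs to. Files are written as multi-page
TIFF (pages along the axial axis) with a JSON sidecar carrying the spacing
and acquisition metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["OctVolume", "save_volume", "load_volume"]


@dataclass
class OctVolume:
    """3-D OCT intensity grid.

    Attributes
    ----------
    data : ndarray, shape (nu, nv, nw)
        Intensities in ``[0, dynamic_range]``; ``w`` (last axis) is depth.
    spacing : ndarray of 3 floats
        Voxel spacing ``(du, dv, dw)`` in micrometres.
    origin : ndarray of 3 floats
        World coordinate (µm) of voxel ``(0, 0, 0)``; ``origin[2]`` is the
        depth of the first axial sample (z increases with depth, z = 0 at
        the undisturbed bone surface plane).
    acquisition_index : int
        Loop round at which the volume was acquired.
    dynamic_range : float
        Upper bound of the intensity scale.
    axis_direction : ndarray of 3 floats
        Optical axis direction; ``(0, 0, 1)`` for downward-looking scans.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    acquisition_index: int = 0
    dynamic_range: float = 1.0
    axis_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D (u, v, w)")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError(f"voxel spacing must be strictly positive, got {self.spacing}")
        if self.dynamic_range <= 0:
            raise ValueError("dynamic range must be positive")
        dmin = float(self.data.min()) if self.data.size else 0.0
        dmax = float(self.data.max()) if self.data.size else 0.0
        if dmin < 0 or dmax > self.dynamic_range * (1 + 1e-6):
            raise ValueError(
                f"intensities [{dmin}, {dmax}] outside [0, {self.dynamic_range}]"
            )

    # -- coordinate helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def x(self) -> np.ndarray:
        """Lateral world coordinates of the u axis (µm)."""
        return self.origin[0] + np.arange(self.shape[0]) * self.spacing[0]

    @property
    def y(self) -> np.ndarray:
        """Lateral world coordinates of the v axis (µm)."""
        return self.origin[1] + np.arange(self.shape[1]) * self.spacing[1]

    @property
    def z(self) -> np.ndarray:
        """Axial depth coordinates of the w axis (µm)."""
        return self.origin[2] + np.arange(self.shape[2]) * self.spacing[2]

    def copy(self) -> "OctVolume":
        return replace(self, data=self.data.copy())

    def same_grid(self, other: "OctVolume", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


def save_volume(vol: OctVolume, path: str | Path) -> Path:
    """Write ``vol`` as multi-page TIFF plus a ``.json`` spacing sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # pages along the axial axis so standard viewers show B-scan-like slices
    tifffile.imwrite(path, np.moveaxis(vol.data, 2, 0).astype(np.float32))
    meta = {
        "spacing_um": vol.spacing.tolist(),
        "origin_um": vol.origin.tolist(),
        "acquisition_index": int(vol.acquisition_index),
        "dynamic_range": float(vol.dynamic_range),
        "axis_direction": vol.axis_direction.tolist(),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
    return path


def load_volume(path: str | Path) -> OctVolume:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing spacing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("spacing_um", "origin_um", "acquisition_index", "dynamic_range"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar} is missing required field '{key}'")
    spacing = np.asarray(meta["spacing_um"], dtype=float)
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise ValueError(f"sidecar field 'spacing_um' is malformed: {meta['spacing_um']}")
    data = np.moveaxis(tifffile.imread(path), 0, 2)
    return OctVolume(
        data=data,
        spacing=spacing,
        origin=np.asarray(meta["origin_um"], dtype=float),
        acquisition_index=int(meta["acquisition_index"]),
        dynamic_range=float(meta["dynamic_range"]),
        axis_direction=np.asarray(meta.get("axis_direction", [0, 0, 1]), dtype=float),
    )
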