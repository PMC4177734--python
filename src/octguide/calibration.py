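"""Cross-scanner calibration: tricubic mapping from imaging to ablation frame.

The imaging scanner and the ablation scanner have separate optics sharing
one working space. A planar point pattern defined in the ablation (laser)
frame is ablated and re-detected in 3-D scans of the imaging frame at
several equidistant axial positions, giving corresponding point pairs. A
tricubic B-spline field ``(x, y, z) = f(u, v, w)`` is then least-squares
fitted to the pairs, absorbing the smooth geometric distortion between the
two scan geometries. Accuracy is reported as the mapping error
``|(x, y, z) − f(u, v, w)|``, evaluated both at the calibration points and
at an evaluation pattern — the 45°-rotated cell centres on the axial
midplanes — which sits maximally far from every calibration point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import NdBSpline

__all__ = [
    "WorkingSpace",
    "Mapping3D",
    "make_patterns",
    "fit_mapping",
    "mapping_error",
    "harmonic_distortion",
    "simulate_detection",
    "save_pairs",
    "load_pairs",
]


@dataclass(frozen=True)
class WorkingSpace:
    """Axis-aligned calibrated volume in the laser frame (µm)."""

    lateral_extent: tuple[float, float] = (4000.0, 4000.0)
    axial_extent: float = 2000.0

    def __post_init__(self) -> None:
        if min(self.lateral_extent) <= 0 or self.axial_extent <= 0:
            raise ValueError("degenerate working space")


def make_patterns(
    space: WorkingSpace, n_planes: int = 5, n_cells: int = 7
) -> tuple[np.ndarray, np.ndarray]:
    """Calibration and evaluation point clouds in the laser frame.

    The calibration pattern is the (n_cells+1)² lattice of square corners,
    replicated at ``n_planes`` equidistant axial planes. The evaluation
    pattern consists of the n_cells² cell centres (the 45°-rotated square
    pattern) placed on the ``n_planes − 1`` axial midplanes, i.e. the
    points farthermost from any calibration point.
    """
    if n_planes < 2:
        raise ValueError("need at least two axial calibration planes")
    if n_cells < 1:
        raise ValueError("need at least one pattern cell")
    Lx, Ly = space.lateral_extent
    cx = np.linspace(0.0, Lx, n_cells + 1)
    cy = np.linspace(0.0, Ly, n_cells + 1)
    cz = np.linspace(0.0, space.axial_extent, n_planes)
    CX, CY, CZ = np.meshgrid(cx, cy, cz, indexing="ij")
    cal = np.column_stack([CX.ravel(), CY.ravel(), CZ.ravel()])

    ex = 0.5 * (cx[:-1] + cx[1:])
    ey = 0.5 * (cy[:-1] + cy[1:])
    ez = 0.5 * (cz[:-1] + cz[1:])
    EX, EY, EZ = np.meshgrid(ex, ey, ez, indexing="ij")
    ev = np.column_stack([EX.ravel(), EY.ravel(), EZ.ravel()])
    return cal, ev


def harmonic_distortion(
    amplitude: float = 50.0, seed: int = 0, space: WorkingSpace | None = None
):
    """A smooth ground-truth distortion field laser → imaging frame.

    One low-order harmonic per output axis with seeded phases, peak
    amplitude bounded by ``amplitude`` µm — the scale of residual scan-field
    distortion after coaxial alignment.
    """
    sp = space or WorkingSpace()
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0, 2 * np.pi, size=(3, 3))
    Lx, Ly = sp.lateral_extent
    Lz = sp.axial_extent
    scales = np.array([Lx, Ly, Lz])

    def f(points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        out = p.copy()
        for axis in range(3):
            wave = (
                np.sin(np.pi * p[..., 0] / scales[0] + phases[axis, 0])
                * np.cos(np.pi * p[..., 1] / scales[1] + phases[axis, 1])
                * np.cos(np.pi * p[..., 2] / scales[2] + phases[axis, 2])
            )
            out[..., axis] = p[..., axis] + amplitude * wave
        return out

    return f


def simulate_detection(
    laser_points: np.ndarray,
    distortion,
    sigma: float = 10.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Imaging-frame detections of ablated points: distortion + isotropic noise.

    ``sigma`` models the ablate-and-detect localisation noise (between the
    2–3 µm optics accuracy and the 18/35 µm imaging resolution).
    """
    rng = rng or np.random.default_rng(0)
    detected = distortion(laser_points)
    if sigma > 0:
        detected = detected + rng.normal(0.0, sigma, size=detected.shape)
    return detected


@dataclass
class Mapping3D:
    """Tricubic B-spline field imaging frame → laser frame."""

    knots: tuple[np.ndarray, np.ndarray, np.ndarray]
    coefficients: np.ndarray  # (n1, n2, n3, 3)
    bbox: np.ndarray  # (3, 2) domain bounds in the imaging frame
    residual_rms: float = np.nan

    def __post_init__(self) -> None:
        assert all(len(t) == n + 4 for t, n in zip(self.knots, self.coefficients.shape))

    def _spline(self) -> NdBSpline:
        return NdBSpline(self.knots, self.coefficients, k=3)

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        lo, hi = self.bbox[:, 0], self.bbox[:, 1]
        tol = 1e-9 * (hi - lo)
        bad = np.nonzero(np.any((p < lo - tol) | (p > hi + tol), axis=1))[0]
        if bad.size:
            raise ValueError(f"point index {int(bad[0])} outside the calibrated domain")
        return self._spline()(p)

    def to_json(self, path: str | Path) -> None:
        rec = {
            "degree": 3,
            "knots": [t.tolist() for t in self.knots],
            "coefficients": self.coefficients.tolist(),
            "bbox": self.bbox.tolist(),
            "residual_rms": None if np.isnan(self.residual_rms) else self.residual_rms,
        }
        Path(path).write_text(json.dumps(rec))

    @classmethod
    def from_json(cls, path: str | Path) -> "Mapping3D":
        rec = json.loads(Path(path).read_text())
        return cls(
            knots=tuple(np.asarray(t) for t in rec["knots"]),
            coefficients=np.asarray(rec["coefficients"]),
            bbox=np.asarray(rec["bbox"]),
            residual_rms=rec["residual_rms"] if rec["residual_rms"] is not None else np.nan,
        )


def _clamped_knots(vals: np.ndarray, n_intervals: int) -> np.ndarray:
    lo, hi = float(vals.min()), float(vals.max())
    inner = np.linspace(lo, hi, n_intervals + 1)[1:-1]
    return np.r_[[lo] * 4, inner, [hi] * 4]


def fit_mapping(
    imaging_points: np.ndarray,
    laser_points: np.ndarray,
    knot_intervals: tuple[int, int, int] | None = None,
    ridge: float = 0.0,
) -> Mapping3D:
    """Least-squares tricubic B-spline fit of the frame mapping.

    The default control lattice uses, per axis, as many knot intervals as
    the distinct sample positions support (``n_distinct − 3``), which keeps
    the normal equations full rank on gridded patterns while reproducing
    any polynomial distortion exactly. A ridge term is available for sparse
    or scattered coverage.
    """
    P = np.asarray(imaging_points, dtype=float)
    Q = np.asarray(laser_points, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point arrays must both be (N, 3)")
    if P.shape[0] < 4**3:
        raise ValueError("need at least 4³ well-distributed point pairs")
    if knot_intervals is None:
        # per axis, the rank of a gridded design is bounded by the number of
        # resolvable sample planes; cluster with a 5%-of-span tolerance so
        # distortion and detection noise do not inflate the count
        def n_clusters(vals: np.ndarray) -> int:
            v = np.sort(vals)
            tol = 0.05 * max(v[-1] - v[0], 1e-9)
            return int(1 + np.count_nonzero(np.diff(v) > tol))

        knot_intervals = tuple(max(1, n_clusters(P[:, a]) - 3) for a in range(3))
    knots = tuple(
        _clamped_knots(P[:, a], knot_intervals[a]) for a in range(3)
    )
    A = NdBSpline.design_matrix(P, knots, k=[3, 3, 3]).toarray()
    n_coef = A.shape[1]
    if ridge > 0:
        AtA = A.T @ A + ridge * np.eye(n_coef)
        coef = np.linalg.solve(AtA, A.T @ Q)
        rank = n_coef
    else:
        coef, _, rank, _ = np.linalg.lstsq(A, Q, rcond=None)
        if rank < n_coef:
            raise ValueError(
                f"control lattice under-determined: rank {rank} < {n_coef} "
                "coefficients; pattern does not cover the lattice (reduce "
                "knot_intervals or add a ridge term)"
            )
    shape = tuple(len(t) - 4 for t in knots)
    resid = Q - A @ coef
    mapping = Mapping3D(
        knots=knots,
        coefficients=coef.reshape(*shape, 3),
        bbox=np.column_stack([P.min(axis=0), P.max(axis=0)]),
        residual_rms=float(np.sqrt(np.mean(np.sum(resid**2, axis=1)))),
    )
    return mapping


def mapping_error(
    f: Mapping3D,
    imaging_points: np.ndarray,
    laser_points: np.ndarray,
    roles: np.ndarray | None = None,
) -> dict:
    """Per-pair Euclidean mapping errors plus summary statistics."""
    pred = f.evaluate(imaging_points)
    err = np.linalg.norm(np.asarray(laser_points, dtype=float) - pred, axis=1)
    out = {
        "per_pair": err,
        "mean_abs": float(err.mean()),
        "std": float(err.std()),
        "max": float(err.max()),
        "rms": float(np.sqrt(np.mean(err**2))),
    }
    if roles is not None:
        roles = np.asarray(roles)
        for role in np.unique(roles):
            sel = roles == role
            out[f"mean_abs_{role}"] = float(err[sel].mean())
    return out


# -- CSV round trip ----------------------------------------------------------

def save_pairs(
    path: str | Path,
    laser_points: np.ndarray,
    imaging_points: np.ndarray,
    roles: np.ndarray,
    planes: np.ndarray | None = None,
) -> None:
    df = pd.DataFrame(
        np.column_stack([laser_points, imaging_points]),
        columns=["x", "y", "z", "u", "v", "w"],
    )
    df["role"] = roles
    df["plane"] = planes if planes is not None else -1
    df.to_csv(path, index=False)


def load_pairs(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    required = ["x", "y", "z", "u", "v", "w", "role"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"point-pair table {path} is missing columns {missing}")
    return (
        df[["x", "y", "z"]].to_numpy(float),
        df[["u", "v", "w"]].to_numpy(float),
        df["role"].to_numpy(),
        df["plane"].to_numpy() if "plane" in df.columns else np.full(len(df), -1),
    )
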