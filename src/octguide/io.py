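"""On-disk formats for every loop artifact.

Volumes go through :mod:`octguide.volume` (multi-page TIFF + JSON
sidecar). Everything tabular — surfaces, pulse plans, landmark layouts,
point pairs — is plain CSV via pandas; configs are YAML; reports and
transforms are JSON. Round trips are bit-exact for integers and to 1e-9
relative for reals; malformed files are rejected with the offending field
named.
"""

from __future__ import annotations

import json
from dataclasses import asdict, fields, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .phantom import Phantom, ScanGeometry, TissueOptics
from .planning import Pulse, PulsePlan, PlanningConstraints
from .surfaces import BoundaryFitParams, SegmentationParams, SurfaceModel
from .transforms import RigidTransform

__all__ = [
    "save_surface_csv",
    "load_surface_csv",
    "save_plan_csv",
    "load_plan_csv",
    "save_report_json",
    "save_transform_json",
    "load_transform_json",
    "save_phantom_truth",
    "config_to_yaml",
    "config_from_yaml",
]


def save_surface_csv(surface: SurfaceModel, path: str | Path,
                     x: np.ndarray | None = None, y: np.ndarray | None = None) -> None:
    """Height-map export ``(x_um, y_um, z_um, valid)``.

    Spline surfaces are sampled on the grid the caller provides.
    """
    if surface.kind == "grid":
        gx, gy = surface.x, surface.y
        Z = surface.z + surface.z_offset
        V = surface.valid
    else:
        if x is None or y is None:
            raise ValueError("spline surface export needs an explicit lateral grid")
        gx, gy = np.asarray(x, float), np.asarray(y, float)
        X, Y = np.meshgrid(gx, gy, indexing="ij")
        Z = surface.evaluate(X, Y)
        V = np.isfinite(Z)
    X, Y = np.meshgrid(gx, gy, indexing="ij")
    pd.DataFrame({
        "x_um": X.ravel(), "y_um": Y.ravel(),
        "z_um": Z.ravel(), "valid": V.ravel().astype(int),
    }).to_csv(path, index=False)


def load_surface_csv(path: str | Path) -> SurfaceModel:
    df = pd.read_csv(path)
    for col in ("x_um", "y_um", "z_um", "valid"):
        if col not in df.columns:
            raise ValueError(f"surface table {path} is missing column '{col}'")
    x = np.unique(df["x_um"].to_numpy())
    y = np.unique(df["y_um"].to_numpy())
    if len(df) != x.size * y.size:
        raise ValueError(f"surface table {path} is not a complete lateral grid")
    z = df["z_um"].to_numpy(float).reshape(x.size, y.size)
    valid = df["valid"].to_numpy().astype(bool).reshape(x.size, y.size)
    return SurfaceModel(kind="grid", x=x, y=y, z=z, valid=valid)


def save_plan_csv(plan: PulsePlan, path: str | Path) -> None:
    pd.DataFrame({
        "x_um": [p.x for p in plan.pulses],
        "y_um": [p.y for p in plan.pulses],
        "duration_us": [p.duration_us for p in plan.pulses],
        "class": [p.duration_class for p in plan.pulses],
        "energy_mJ": [p.energy_mj for p in plan.pulses],
        "order": np.arange(len(plan)),
        "round": plan.round_index,
    }).to_csv(path, index=False)


def load_plan_csv(path: str | Path) -> PulsePlan:
    df = pd.read_csv(path)
    for col in ("x_um", "y_um", "duration_us", "class", "energy_mJ", "order"):
        if col not in df.columns:
            raise ValueError(f"plan table {path} is missing column '{col}'")
    df = df.sort_values("order")
    pulses = [
        Pulse(x=float(row["x_um"]), y=float(row["y_um"]),
              duration_us=float(row["duration_us"]),
              duration_class=str(row["class"]), energy_mj=float(row["energy_mJ"]))
        for _, row in df.iterrows()
    ]
    rnd = int(df["round"].iloc[0]) if "round" in df.columns and len(df) else 0
    return PulsePlan(pulses=pulses, round_index=rnd)


def save_report_json(report, path: str | Path) -> None:
    """Serialise an evaluation report (numpy arrays become lists)."""
    rec = {}
    for k, v in asdict(report).items():
        rec[k] = v.tolist() if isinstance(v, np.ndarray) else v
    Path(path).write_text(json.dumps(rec))


def save_transform_json(t: RigidTransform, path: str | Path) -> None:
    Path(path).write_text(json.dumps({
        "translation_um": t.translation.tolist(),
        "angles_rad": t.angles.tolist(),
    }))


def load_transform_json(path: str | Path) -> RigidTransform:
    rec = json.loads(Path(path).read_text())
    for key in ("translation_um", "angles_rad"):
        if key not in rec:
            raise ValueError(f"transform file {path} is missing field '{key}'")
    return RigidTransform(translation=rec["translation_um"], angles=rec["angles_rad"])


def save_phantom_truth(phantom: Phantom, outdir: str | Path) -> None:
    """Ground-truth export: two CSV height maps plus a JSON parameter record."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    surf, bnd = phantom.export_height_maps()
    pd.DataFrame(surf, columns=["x_um", "y_um", "z_um"]).to_csv(
        outdir / "bone_surface.csv", index=False)
    pd.DataFrame(bnd, columns=["x_um", "y_um", "z_um"]).to_csv(
        outdir / "endosteum_boundary.csv", index=False)
    rec = {
        "endosteum_thickness_um": phantom.t_e,
        "critical_hit": bool(phantom.critical_hit),
        "pose_translation_um": phantom.pose.translation.tolist(),
        "pose_angles_rad": phantom.pose.angles.tolist(),
        "optics": {k: asdict(v) for k, v in phantom.optics.items()},
    }
    if phantom.params is not None:
        p = asdict(phantom.params)
        p["optics"] = {k: asdict(v) if is_dataclass(v) else v
                       for k, v in phantom.params.optics.items()}
        rec["params"] = p
    (outdir / "phantom.json").write_text(json.dumps(rec, default=float))


# -- config round trip -------------------------------------------------------

_NESTED = {
    "scan": ScanGeometry,
    "segmentation": SegmentationParams,
    "boundary_fit": BoundaryFitParams,
    "planning": PlanningConstraints,
    "optics": None,  # special-cased
}


def _coerce(cls, data: dict):
    """Rebuild a (possibly nested) dataclass from YAML primitives."""
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def config_to_yaml(config, path: str | Path) -> None:
    """Write a LoopConfig (or PhantomParams) as YAML."""
    rec = asdict(config)

    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    Path(path).write_text(yaml.safe_dump(clean(rec), sort_keys=False))


def config_from_yaml(path: str | Path, cls):
    """Read a YAML config back into dataclass ``cls`` (nested blocks included)."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    kwargs = {}
    valid = {f.name: f for f in fields(cls)}
    for key, value in data.items():
        if key not in valid:
            raise ValueError(f"config file {path}: unknown field '{key}'")
        if key in _NESTED and isinstance(value, dict):
            if key == "optics":
                kwargs[key] = {k: _coerce(TissueOptics, v) for k, v in value.items()}
            else:
                kwargs[key] = _coerce(_NESTED[key], value)
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)
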