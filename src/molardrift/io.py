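"""File formats: NIfTI volumes, binary STL meshes with label sidecars,
landmark CSVs, transform/frame JSON, and run manifests.

STL carries no vertex attributes, so per-vertex region labels travel in a
CSV sidecar (``<mesh>.labels.csv``) indexed by vertex order — a documented
dialect decision.  Landmark CSVs use the shared schema
``tooth_id, timepoint, label, x_mm, y_mm, z_mm``; the target tooth's rows
use ``tooth_id="target"`` and quadrant (neighbor) cusp tips use
``tooth_id="quadrant"``.  Floats are written with fixed 6-decimal
formatting so identical runs produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import LandmarkSet, RigidTransform, SurfaceModel, ToothFrame, VoxelVolume

__all__ = [
    "save_volume",
    "load_volume",
    "save_mesh",
    "load_mesh",
    "save_landmarks",
    "load_landmarks",
    "save_transform",
    "load_transform",
    "save_frame",
    "load_frame",
    "write_manifest",
]

_FLOAT_FMT = "%.6f"


def save_volume(vol: VoxelVolume, path) -> Path:
    """Write a volume as NIfTI; spacing/origin go into the affine."""
    path = Path(path)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(vol.spacing_mm)
    affine[:3, 3] = vol.origin_mm
    nib.save(nib.Nifti1Image(vol.intensities.astype(np.float32), affine), path)
    return path


def load_volume(path) -> VoxelVolume:
    img = nib.load(str(path))
    affine = img.affine
    return VoxelVolume(
        np.asarray(img.dataobj, dtype=np.float32),
        spacing_mm=np.abs(np.diag(affine)[:3]),
        origin_mm=affine[:3, 3],
    )


def _labels_path(mesh_path: Path) -> Path:
    return mesh_path.with_suffix(mesh_path.suffix + ".labels.csv")


def save_mesh(model: SurfaceModel, path) -> Path:
    """Binary STL plus a per-vertex label sidecar CSV.

    STL is a triangle soup without stable vertex indexing, so the sidecar
    stores each labeled vertex's coordinates; loading re-associates labels
    by nearest neighbor after duplicate-vertex welding.
    """
    path = Path(path)
    model.as_trimesh().export(path, file_type="stl")
    pd.DataFrame(
        {
            "x_mm": model.vertices[:, 0],
            "y_mm": model.vertices[:, 1],
            "z_mm": model.vertices[:, 2],
            "tissue": model.tissue.astype(int),
            "is_target": model.is_target.astype(int),
            "crest_zone": model.crest_zone.astype(int),
            "window_zone": model.window_zone.astype(int),
        }
    ).to_csv(_labels_path(path), index=False, float_format=_FLOAT_FMT)
    return path


def load_mesh(path) -> SurfaceModel:
    import trimesh
    from scipy.spatial import cKDTree

    path = Path(path)
    tm = trimesh.load(path, file_type="stl", process=True)
    labels = pd.read_csv(_labels_path(path))
    ref = labels[["x_mm", "y_mm", "z_mm"]].to_numpy(float)
    dist, idx = cKDTree(ref).query(np.asarray(tm.vertices))
    if dist.max() > 1e-3:
        raise ValueError(
            "label sidecar does not match mesh vertices "
            f"(max association distance {dist.max():.4g} mm)"
        )
    return SurfaceModel(
        np.asarray(tm.vertices),
        np.asarray(tm.faces),
        labels["tissue"].to_numpy(np.uint8)[idx],
        labels["is_target"].to_numpy(bool)[idx],
        labels["crest_zone"].to_numpy(bool)[idx],
        labels["window_zone"].to_numpy(bool)[idx],
    )


def landmarks_to_frame_rows(lm: LandmarkSet, timepoint: str) -> pd.DataFrame:
    rows = []

    def add(tooth_id, label, p):
        rows.append(
            {
                "tooth_id": tooth_id,
                "timepoint": timepoint,
                "label": label,
                "x_mm": p[0],
                "y_mm": p[1],
                "z_mm": p[2],
            }
        )

    for label in lm.cusp_labels():
        add("target", label, lm.cusp_tips[label])
    for i, p in enumerate(lm.apexes, start=1):
        add("target", f"apex_{i}", p)
    add("target", "Mm", lm.mesial_crest)
    add("target", "Md", lm.distal_crest)
    for i, p in enumerate(lm.quadrant_cusp_tips, start=1):
        add("quadrant", f"tip_{i}", p)
    return pd.DataFrame(rows)


def save_landmarks(landmark_sets: dict, path) -> Path:
    """``landmark_sets`` maps timepoint name (e.g. 'To', 'Tn') -> LandmarkSet."""
    path = Path(path)
    df = pd.concat(
        [landmarks_to_frame_rows(lm, tp) for tp, lm in landmark_sets.items()],
        ignore_index=True,
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def load_landmarks(path, timepoint: str) -> LandmarkSet:
    df = pd.read_csv(path)
    df = df[df["timepoint"] == timepoint]
    if df.empty:
        raise ValueError(f"no landmarks for timepoint {timepoint!r}")
    pts = {
        (r.tooth_id, r.label): np.array([r.x_mm, r.y_mm, r.z_mm])
        for r in df.itertuples()
    }
    cusp_tips = {
        label: p
        for (tooth, label), p in pts.items()
        if tooth == "target" and not label.startswith("apex_") and label not in ("Mm", "Md")
    }
    apexes = [
        p for (tooth, label), p in sorted(pts.items())
        if tooth == "target" and label.startswith("apex_")
    ]
    quadrant = [p for (tooth, _), p in sorted(pts.items()) if tooth == "quadrant"]
    return LandmarkSet(
        cusp_tips=cusp_tips,
        apexes=np.array(apexes),
        mesial_crest=pts[("target", "Mm")],
        distal_crest=pts[("target", "Md")],
        quadrant_cusp_tips=np.array(quadrant),
    )


def save_transform(t: RigidTransform, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(t.to_dict(), indent=2) + "\n")
    return path


def load_transform(path) -> RigidTransform:
    return RigidTransform.from_dict(json.loads(Path(path).read_text()))


def save_frame(f: ToothFrame, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(f.to_dict(), indent=2) + "\n")
    return path


def load_frame(path) -> ToothFrame:
    return ToothFrame.from_dict(json.loads(Path(path).read_text()))


def write_manifest(path, config: dict, seed: int | None = None, inputs=()) -> Path:
    """Run manifest: configuration, its hash, seed and package version."""
    from . import __version__

    cfg_json = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "package": "molardrift",
        "version": __version__,
        "seed": seed,
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "inputs": [str(p) for p in inputs],
    }
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
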