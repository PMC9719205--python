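"""Threshold segmentation and surface-model building.

Mirrors the clinical model-building workflow: per-tissue intensity
thresholding into "Crown", "Root" and "Alveolar bone" masks, a spherical
window opened in the bone mask around the target tooth's apical region
(so the root surface is exposed in the final model), Boolean union of the
masks, and isosurface extraction to a triangle mesh in mm coordinates.

Thresholds are explicit configuration: clinical "experience thresholds"
are scanner-specific, so the phantom defaults place each cut at the
midpoint between adjacent tissue-class mean intensities.  Intervals are
half-open [lo, hi) so adjacent classes partition the intensity axis
exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .core import SurfaceModel, Tissue, VoxelVolume

__all__ = [
    "ThresholdConfig",
    "default_thresholds",
    "threshold_mask",
    "union_masks",
    "open_apical_window",
    "extract_mesh",
    "build_model_mesh",
]


@dataclass(frozen=True)
class ThresholdConfig:
    """Intensity ranges per tissue plus the apical-window geometry."""

    crown_range: tuple
    root_range: tuple
    bone_range: tuple
    window_center_mm: tuple = (0.0, 0.0, 0.0)
    window_radius_mm: float = 0.0

    def __post_init__(self):
        for name in ("crown_range", "root_range", "bone_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: require lo < hi, got ({lo}, {hi})")
        if self.window_radius_mm < 0:
            raise ValueError("window_radius_mm must be non-negative")


def default_thresholds(spec, window_center_mm=(0.0, 0.0, 0.0)) -> ThresholdConfig:
    """Midpoint thresholds for a phantom's tissue-class intensity means."""
    m = spec.intensity_means
    bone_lo = 0.5 * (m["background"] + m["bone"])
    root_lo = 0.5 * (m["bone"] + m["root"])
    crown_lo = 0.5 * (m["root"] + m["crown"])
    return ThresholdConfig(
        crown_range=(crown_lo, np.inf),
        root_range=(root_lo, crown_lo),
        bone_range=(bone_lo, root_lo),
        window_center_mm=tuple(np.asarray(window_center_mm, dtype=float)),
        window_radius_mm=spec.window_radius_mm,
    )


def threshold_mask(vol: VoxelVolume, intensity_range) -> np.ndarray:
    """Binary mask of voxels with lo <= intensity < hi (half-open)."""
    lo, hi = intensity_range
    if not lo < hi:
        raise ValueError(f"require lo < hi, got ({lo}, {hi})")
    mask = (vol.intensities >= lo) & (vol.intensities < hi)
    if not mask.any():
        warnings.warn(
            f"threshold range ({lo}, {hi}) selected no voxels", stacklevel=2
        )
    return mask


def union_masks(masks) -> np.ndarray:
    """Voxelwise Boolean union of same-shape binary masks."""
    masks = list(masks)
    if not masks:
        raise ValueError("need at least one mask")
    shape = masks[0].shape
    for m in masks[1:]:
        if m.shape != shape:
            raise ValueError(f"mask shape mismatch: {m.shape} vs {shape}")
    return np.logical_or.reduce([np.asarray(m, dtype=bool) for m in masks])


def open_apical_window(
    mask: np.ndarray, vol: VoxelVolume, center_mm, radius_mm: float
) -> np.ndarray:
    """Clear mask voxels within a sphere around the apical region.

    Applied to the *bone* mask before union so the target root is exposed
    in the assembled model; root/crown masks are never windowed.  A window
    that misses the volume (or the mask) is a no-op with a warning.
    """
    if radius_mm < 0:
        raise ValueError("radius_mm must be non-negative")
    if radius_mm == 0:
        return mask.copy()
    center = np.asarray(center_mm, dtype=float)
    out = np.asarray(mask, dtype=bool).copy()

    # restrict to the window's bounding box of voxel indices
    lo_idx = np.floor((center - radius_mm - vol.origin_mm) / vol.spacing_mm).astype(int)
    hi_idx = np.ceil((center + radius_mm - vol.origin_mm) / vol.spacing_mm).astype(int)
    lo_idx = np.clip(lo_idx, 0, np.array(vol.shape) - 1)
    hi_idx = np.clip(hi_idx, 0, np.array(vol.shape) - 1)
    if np.any(lo_idx > hi_idx):
        warnings.warn("apical window lies outside the volume; mask unchanged")
        return out

    sl = tuple(slice(l, h + 1) for l, h in zip(lo_idx, hi_idx))
    axes = [
        vol.origin_mm[d] + vol.spacing_mm[d] * np.arange(sl[d].start, sl[d].stop)
        for d in range(3)
    ]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    inside = (
        (gx - center[0]) ** 2 + (gy - center[1]) ** 2 + (gz - center[2]) ** 2
        <= radius_mm**2
    )
    cleared = int(np.count_nonzero(out[sl] & inside))
    if cleared == 0:
        warnings.warn("apical window cleared no voxels")
    out[sl] &= ~inside
    return out


def extract_mesh(mask: np.ndarray, vol: VoxelVolume, annotator=None) -> SurfaceModel:
    """Marching-cubes isosurface (level 0.5) of a binary mask, in mm.

    ``annotator`` is a caller-supplied function mapping vertex coordinates
    to (tissue, is_target, crest_zone, window_zone) per-vertex arrays —
    the caller knows which tooth is the target; the mask does not.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot extract a mesh from an empty mask")
    verts, faces, _, _ = measure.marching_cubes(
        mask.astype(np.float32), level=0.5, spacing=tuple(vol.spacing_mm)
    )
    model = _mesh_from_arrays(verts + vol.origin_mm, faces, annotator)
    if not model.as_trimesh().is_watertight:
        warnings.warn("extracted mesh is not watertight")
    return model


def _mesh_from_arrays(verts, faces, annotator):
    import trimesh

    tm = trimesh.Trimesh(verts, faces, process=True)
    if tm.is_watertight and tm.volume < 0:
        tm.invert()
    verts = np.asarray(tm.vertices, dtype=float)
    faces = np.asarray(tm.faces, dtype=np.int64)
    n = len(verts)
    if annotator is None:
        ann = (
            np.zeros(n, dtype=np.uint8),
            np.zeros(n, dtype=bool),
            np.zeros(n, dtype=bool),
            np.zeros(n, dtype=bool),
        )
    else:
        ann = annotator(verts)
    return SurfaceModel(verts, faces, *ann)


def extract_intensity_mesh(
    vol: VoxelVolume, iso: float, annotator=None
) -> SurfaceModel:
    """Isosurface of the intensity field itself at the threshold value.

    Marching cubes interpolates the intensity between voxel centers, so on
    partial-volume data the surface is positioned with sub-voxel accuracy
    — the behavior of clinical threshold-based model building, and what
    registration-grade surfaces require.
    """
    verts, faces, _, _ = measure.marching_cubes(
        vol.intensities.astype(np.float32), level=iso, spacing=tuple(vol.spacing_mm)
    )
    return _mesh_from_arrays(verts + vol.origin_mm, faces, annotator)


def build_model_mesh(
    vol: VoxelVolume,
    cfg: ThresholdConfig,
    annotator=None,
    surface: str = "intensity",
) -> SurfaceModel:
    """Full model-building chain: threshold, window, unite, mesh.

    ``surface="intensity"`` (default) meshes the intensity field at the
    outer tissue/background threshold after blanking the windowed bone
    voxels, giving sub-voxel surface placement on partial-volume data;
    ``surface="mask"`` meshes the binary united mask at iso-level 0.5.
    """
    crown = threshold_mask(vol, cfg.crown_range)
    root = threshold_mask(vol, cfg.root_range)
    bone = threshold_mask(vol, cfg.bone_range)
    if cfg.window_radius_mm > 0:
        windowed = open_apical_window(
            bone, vol, cfg.window_center_mm, cfg.window_radius_mm
        )
    else:
        windowed = bone

    if surface == "mask":
        united = union_masks([crown, root, windowed])
        return extract_mesh(united, vol, annotator)
    if surface != "intensity":
        raise ValueError(f"unknown surface mode {surface!r}")
    iso = cfg.bone_range[0]  # outer tissue/background boundary
    intens = vol.intensities.copy()
    removed = bone & ~windowed
    intens[removed] = iso - 1.0  # blank the apical window
    blanked = VoxelVolume(intens, vol.spacing_mm, vol.origin_mm)
    return extract_intensity_mesh(blanked, iso, annotator)
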