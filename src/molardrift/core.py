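"""Core containers shared across the measurement pipeline.

Coordinates are millimetres throughout.  Volumes follow an (i, j, k) ->
(x, y, z) axis convention: world position of voxel center = origin +
index * spacing.  Tooth-local axes follow the dental convention used by
the measurement method: +x mesial, +y lingual, +z occlusal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "RigidTransform",
    "VoxelVolume",
    "SurfaceModel",
    "LandmarkSet",
    "ToothFrame",
    "DriftResult",
    "Tissue",
    "CUSP_LABEL_ORDER",
    "BUCCAL_LABELS",
    "LINGUAL_LABELS",
]

#: fixed cusp-label order used for deterministic tie-breaking
CUSP_LABEL_ORDER = ("MB", "DB", "ML", "DL", "B", "L", "M", "D")

BUCCAL_LABELS = frozenset({"MB", "DB", "B"})
LINGUAL_LABELS = frozenset({"ML", "DL", "L"})


class Tissue:
    """Integer tissue codes attached to mesh vertices."""

    BACKGROUND = 0
    CROWN = 1
    ROOT = 2
    BONE = 3


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    return a


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform p -> R @ p + t.

    The rotation must be proper orthogonal (R^T R = I, det R = +1) to
    within 1e-9; improper (reflecting) transforms are rejected.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = _as_point(self.translation)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthogonal within 1e-9")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation is not proper (det != +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- constructors -----------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(cls, axis, angle_deg: float, center=None) -> "RigidTransform":
        """Rotation by ``angle_deg`` about ``axis`` through ``center``."""
        axis = _as_point(axis)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("zero rotation axis")
        ux, uy, uz = axis / n
        th = np.deg2rad(angle_deg)
        c, s = np.cos(th), np.sin(th)
        C = 1.0 - c
        R = np.array(
            [
                [c + ux * ux * C, ux * uy * C - uz * s, ux * uz * C + uy * s],
                [uy * ux * C + uz * s, c + uy * uy * C, uy * uz * C - ux * s],
                [uz * ux * C - uy * s, uz * uy * C + ux * s, c + uz * uz * C],
            ]
        )
        if center is None:
            t = np.zeros(3)
        else:
            center = _as_point(center)
            t = center - R @ center
        return cls(R, t)

    @classmethod
    def from_translation(cls, t) -> "RigidTransform":
        return cls(np.eye(3), _as_point(t))

    # -- algebra ----------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self o other: (self.compose(other))(p) == self(other(p))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RigidTransform":
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation"]))


@dataclass
class VoxelVolume:
    """3D intensity array with voxel spacing and world origin (mm)."""

    intensities: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3 or self.intensities.size == 0:
            raise ValueError("intensities must be a non-empty 3D array")
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float).reshape(3)
        if np.any(self.spacing_mm <= 0):
            raise ValueError("voxel spacing must be strictly positive")
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(3)

    @property
    def shape(self):
        return self.intensities.shape

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape (*grid, 3)."""
        axes = [
            self.origin_mm[d] + self.spacing_mm[d] * np.arange(self.shape[d])
            for d in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)


@dataclass
class SurfaceModel:
    """Triangle mesh (mm) with per-vertex region annotations.

    ``tissue`` carries :class:`Tissue` codes; ``is_target`` flags vertices
    belonging to the moving (target) tooth; ``crest_zone`` / ``window_zone``
    flag bone vertices near the alveolar crest or the opened apical window,
    which are excluded from the registration alignment area.
    """

    vertices: np.ndarray
    faces: np.ndarray
    tissue: np.ndarray
    is_target: np.ndarray
    crest_zone: np.ndarray
    window_zone: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        n = len(self.vertices)
        for name in ("tissue", "is_target", "crest_zone", "window_zone"):
            a = np.asarray(getattr(self, name)).reshape(-1)
            if len(a) != n:
                raise ValueError(f"{name} must have one entry per vertex")
            setattr(self, name, a)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def as_trimesh(self):
        import trimesh

        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def transformed(self, t: RigidTransform) -> "SurfaceModel":
        return replace(self, vertices=t.apply(self.vertices))


@dataclass
class LandmarkSet:
    """Labeled landmarks for one target tooth at one timepoint.

    cusp_tips map standard cusp labels (MB, DB, ML, DL, B, L, D, ...) to
    3D points; ``apexes`` are root-apex points; ``mesial_crest`` /
    ``distal_crest`` are the marginal-crest midpoints Mm / Md;
    ``quadrant_cusp_tips`` are cusp tips of the *other* posterior teeth in
    the quadrant, used together with the target's own tips to fit the
    occlusal plane.
    """

    cusp_tips: dict
    apexes: np.ndarray
    mesial_crest: np.ndarray
    distal_crest: np.ndarray
    quadrant_cusp_tips: np.ndarray

    def __post_init__(self):
        self.cusp_tips = {k: _as_point(v) for k, v in self.cusp_tips.items()}
        self.apexes = np.asarray(self.apexes, dtype=float).reshape(-1, 3)
        self.mesial_crest = _as_point(self.mesial_crest)
        self.distal_crest = _as_point(self.distal_crest)
        self.quadrant_cusp_tips = np.asarray(
            self.quadrant_cusp_tips, dtype=float
        ).reshape(-1, 3)
        self.validate()

    def validate(self):
        labels = set(self.cusp_tips)
        if len(labels) < 2:
            raise ValueError("need at least two labeled cusp tips")
        if not labels & BUCCAL_LABELS or not labels & LINGUAL_LABELS:
            raise ValueError("need at least one buccal and one lingual cusp")
        if len(self.apexes) < 1:
            raise ValueError("need at least one root apex")
        if np.allclose(self.mesial_crest, self.distal_crest):
            raise ValueError("mesial and distal crest midpoints coincide")

    # -- derived ----------------------------------------------------------
    def cusp_labels(self) -> tuple:
        """Labels in the fixed deterministic order, unknown labels last."""
        known = [l for l in CUSP_LABEL_ORDER if l in self.cusp_tips]
        extra = sorted(set(self.cusp_tips) - set(known))
        return tuple(known + extra)

    def cusp_array(self) -> np.ndarray:
        return np.array([self.cusp_tips[l] for l in self.cusp_labels()])

    def occlusal_fit_points(self, include_target: bool = True) -> np.ndarray:
        pts = [self.quadrant_cusp_tips]
        if include_target:
            pts.append(self.cusp_array())
        return np.vstack(pts)

    def all_points(self) -> np.ndarray:
        return np.vstack(
            [
                self.cusp_array(),
                self.apexes,
                self.mesial_crest[None],
                self.distal_crest[None],
                self.quadrant_cusp_tips,
            ]
        )

    def transformed(self, t: RigidTransform) -> "LandmarkSet":
        return LandmarkSet(
            cusp_tips={k: t.apply(v) for k, v in self.cusp_tips.items()},
            apexes=t.apply(self.apexes),
            mesial_crest=t.apply(self.mesial_crest),
            distal_crest=t.apply(self.distal_crest),
            quadrant_cusp_tips=t.apply(self.quadrant_cusp_tips),
        )


@dataclass(frozen=True)
class ToothFrame:
    """Tooth-local coordinate frame: origin plus orthonormal axes.

    +x mesial, +y lingual, +z occlusal.  The three reference planes all
    pass through the origin: the occlusal plane (normal z), the
    mesio-distal plane (normal y, contains the z axis and Md) and the
    bucco-lingual plane (normal x).
    """

    origin: np.ndarray
    x_hat: np.ndarray
    y_hat: np.ndarray
    z_hat: np.ndarray

    def __post_init__(self):
        for name in ("origin", "x_hat", "y_hat", "z_hat"):
            object.__setattr__(self, name, _as_point(getattr(self, name)))
        for a in (self.x_hat, self.y_hat, self.z_hat):
            if not np.isclose(np.linalg.norm(a), 1.0, atol=1e-9):
                raise ValueError("frame axes must be unit vectors")
        for a, b in ((self.x_hat, self.y_hat), (self.x_hat, self.z_hat), (self.y_hat, self.z_hat)):
            if abs(float(a @ b)) > 1e-9:
                raise ValueError("frame axes must be pairwise orthogonal")

    @property
    def occlusal_plane(self):
        return self.origin, self.z_hat

    @property
    def md_plane(self):
        return self.origin, self.y_hat

    @property
    def bl_plane(self):
        return self.origin, self.x_hat

    @property
    def handedness(self) -> int:
        """+1 if (x, y, z) is right-handed, -1 if left-handed."""
        return int(np.sign(np.cross(self.x_hat, self.y_hat) @ self.z_hat))

    def to_coords(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float) - self.origin
        return p @ np.stack([self.x_hat, self.y_hat, self.z_hat], axis=1)

    def from_coords(self, coords: np.ndarray) -> np.ndarray:
        c = np.asarray(coords, dtype=float)
        basis = np.stack([self.x_hat, self.y_hat, self.z_hat], axis=0)
        return c @ basis + self.origin

    def to_dict(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "x_hat": self.x_hat.tolist(),
            "y_hat": self.y_hat.tolist(),
            "z_hat": self.z_hat.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ToothFrame":
        return cls(
            np.asarray(d["origin"]),
            np.asarray(d["x_hat"]),
            np.asarray(d["y_hat"]),
            np.asarray(d["z_hat"]),
        )


@dataclass
class DriftResult:
    """Positional-change outcome parameters for one tooth.

    Signs follow the frame convention: positive OE is occlusal movement,
    positive cBLT is tipping toward lingual (negative = buccal), positive
    cMDT toward mesial (negative = distal).
    """

    OE_mean_mm: float
    OE_max_mm: float
    OE_max_cusp_label: str
    BLT_To_deg: float
    BLT_Tn_deg: float
    MDT_To_deg: float
    MDT_Tn_deg: float
    cBLT_deg: float
    cMDT_deg: float
    per_cusp_dz_mm: dict = field(default_factory=dict)
    registration_rms_mm: float | None = None

    def to_dict(self) -> dict:
        d = {
            "OE_mean_mm": self.OE_mean_mm,
            "OE_max_mm": self.OE_max_mm,
            "OE_max_cusp_label": self.OE_max_cusp_label,
            "BLT_To_deg": self.BLT_To_deg,
            "BLT_Tn_deg": self.BLT_Tn_deg,
            "MDT_To_deg": self.MDT_To_deg,
            "MDT_Tn_deg": self.MDT_Tn_deg,
            "cBLT_deg": self.cBLT_deg,
            "cMDT_deg": self.cMDT_deg,
            "per_cusp_dz_mm": dict(self.per_cusp_dz_mm),
        }
        if self.registration_rms_mm is not None:
            d["registration_rms_mm"] = self.registration_rms_mm
        return d
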