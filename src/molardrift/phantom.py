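"""Synthetic two-timepoint molar phantoms with known ground-truth motion.

The phantom emulates the situation the measurement method addresses: an
unopposed molar (the *target* tooth) embedded in an arch segment of
alveolar bone with stable neighbor crowns, imaged at a baseline timepoint
To and a follow-up timepoint Tn.  Between timepoints the target tooth
drifts — it erupts along the occlusal axis and tips by small rotations
about axes through the root-apex centroid — while the whole jaw may also
move rigidly (patient repositioning between scans).

Geometry is fully analytic: the crown is a superellipsoid carrying
spherical-cap cusps (so true cusp tips are known in closed form), roots
are tapered cones (true apexes in closed form), and bone is a rectangular
block with periodontal clearance around every root.  Voxel volumes are
rasterized by evaluating tissue membership at voxel centers, which keeps
the two timepoints exactly congruent up to the ground-truth motion.

Jaw-local coordinates: +x mesial, +y lingual, +z occlusal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    CUSP_LABEL_ORDER,
    LandmarkSet,
    RigidTransform,
    SurfaceModel,
    Tissue,
    ToothFrame,
    VoxelVolume,
)

__all__ = [
    "PhantomSpec",
    "GroundTruthMotion",
    "TimepointData",
    "ArchPhantom",
    "generate_phantom",
    "jitter_landmarks",
    "jitter_sd_for_method_error",
]

QUADRANTS = ("upper-left", "upper-right", "lower-left", "lower-right")

#: cusp tips protrude this far above the crown-body top (mm)
CUSP_PROTRUSION_MM = 0.8
#: periodontal clearance carved out of bone around each tooth solid (mm)
BONE_GAP_MM = 0.4

# lateral cusp-center layout per cusp count: label -> (x, y) offset; buccal
# cusps sit at y < 0, lingual at y > 0, mesial at x > 0
_CUSP_LAYOUTS = {
    2: {"B": (0.0, -2.6), "L": (0.0, 2.6)},
    3: {"MB": (2.4, -2.6), "DB": (-2.4, -2.6), "L": (0.0, 2.6)},
    4: {"MB": (2.4, -2.6), "DB": (-2.4, -2.6), "ML": (2.4, 2.6), "DL": (-2.4, 2.6)},
    5: {
        "MB": (2.4, -2.6),
        "DB": (-2.4, -2.6),
        "ML": (2.4, 2.6),
        "DL": (-2.4, 2.6),
        "D": (-3.2, 0.0),
    },
}

# root layout per root count: (x, y) center and cervical radius; the
# 3-root layout mimics an upper molar (two buccal roots, one palatal)
_ROOT_LAYOUTS = {
    1: [((0.0, 0.0), 2.4)],
    2: [((2.0, 0.0), 1.8), ((-2.0, 0.0), 1.8)],
    3: [((2.0, -1.8), 1.5), ((-2.0, -1.8), 1.5), ((0.0, 2.0), 1.6)],
}


@dataclass(frozen=True)
class PhantomSpec:
    """Construction parameters of the arch phantom.

    ``intensity_means`` must be strictly ordered background < bone < root
    < crown so that single thresholds separate adjacent tissue classes.
    """

    quadrant: str = "lower-left"
    n_cusps: int = 4
    n_roots: int = 2
    cusp_radius_mm: float = 1.2
    crown_height_mm: float = 7.0
    root_length_mm: float = 13.0
    voxel_spacing_mm: tuple = (0.25, 0.25, 0.25)
    intensity_means: dict = field(
        default_factory=lambda: {
            "background": 0.0,
            "bone": 400.0,
            "root": 800.0,
            "crown": 1200.0,
        }
    )
    noise_sd: float = 20.0
    seed: int = 0
    #: supersample class-boundary voxels (3x3x3) to emulate the
    #: partial-volume averaging of real CT; False = pure center sampling
    partial_volume: bool = True
    # arch-segment geometry
    crown_halfwidth_md_mm: float = 5.0
    crown_halfwidth_bl_mm: float = 5.0
    tooth_pitch_mm: float = 11.0
    bone_top_mm: float = 1.0
    window_radius_mm: float = 3.5
    crest_margin_mm: float = 2.5

    def __post_init__(self):
        if self.quadrant not in QUADRANTS:
            raise ValueError(f"unknown quadrant {self.quadrant!r}")
        if self.n_cusps not in _CUSP_LAYOUTS:
            raise ValueError("n_cusps must be between 2 and 5")
        if self.n_roots not in _ROOT_LAYOUTS:
            raise ValueError("n_roots must be between 1 and 3")
        for name in ("cusp_radius_mm", "crown_height_mm", "root_length_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if np.any(np.asarray(self.voxel_spacing_mm, dtype=float) <= 0):
            raise ValueError("voxel spacing must be positive")
        m = self.intensity_means
        order = [m["background"], m["bone"], m["root"], m["crown"]]
        if not all(a < b for a, b in zip(order, order[1:])):
            raise ValueError(
                "intensity means must be strictly ordered "
                "background < bone < root < crown"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class GroundTruthMotion:
    """Ground-truth positional change of the target tooth.

    ``eruption_mm`` translates along the true occlusal axis; ``bl_tip_deg``
    rotates about the mesio-distal axis through the apex centroid CA
    (positive tips the crown toward lingual); ``md_tip_deg`` rotates about
    the bucco-lingual axis through CA (positive toward mesial);
    ``jaw_transform`` is the whole-jaw rigid motion between scans.

    Composition order is fixed: tooth-local rotation about CA, then
    eruption translation, then the jaw transform.
    """

    eruption_mm: float = 0.0
    bl_tip_deg: float = 0.0
    md_tip_deg: float = 0.0
    jaw_transform: RigidTransform = field(default_factory=RigidTransform.identity)

    @classmethod
    def zero(cls) -> "GroundTruthMotion":
        return cls()


# ---------------------------------------------------------------------------
# analytic solids
# ---------------------------------------------------------------------------


class _Superellipsoid:
    """|x/a|^n + |y/b|^n + |(z-zc)/c|^n <= 1 around (x0, y0, zc)."""

    def __init__(self, center, a, b, c, exponent=4.0):
        self.center = np.asarray(center, dtype=float)
        self.a, self.b, self.c = float(a), float(b), float(c)
        self.n = float(exponent)

    def contains(self, pts, dilate=0.0):
        d = np.asarray(pts, dtype=float) - self.center
        v = (
            np.abs(d[..., 0] / (self.a + dilate)) ** self.n
            + np.abs(d[..., 1] / (self.b + dilate)) ** self.n
            + np.abs(d[..., 2] / (self.c + dilate)) ** self.n
        )
        return v <= 1.0

    def bbox(self):
        half = np.array([self.a, self.b, self.c])
        return self.center - half, self.center + half


class _Sphere:
    def __init__(self, center, radius):
        self.center = np.asarray(center, dtype=float)
        self.radius = float(radius)

    def contains(self, pts, dilate=0.0):
        d = np.asarray(pts, dtype=float) - self.center
        return np.einsum("...i,...i->...", d, d) <= (self.radius + dilate) ** 2

    def bbox(self):
        r = self.radius
        return self.center - r, self.center + r


class _RootCone:
    """Vertical tapered cone: radius r0 at z=0 shrinking to 0 at z=-length."""

    def __init__(self, center_xy, r0, length):
        self.cx, self.cy = float(center_xy[0]), float(center_xy[1])
        self.r0 = float(r0)
        self.length = float(length)

    @property
    def apex(self):
        return np.array([self.cx, self.cy, -self.length])

    def contains(self, pts, dilate=0.0):
        p = np.asarray(pts, dtype=float)
        z = p[..., 2]
        inside_z = (z <= dilate) & (z >= -self.length - dilate)
        frac = np.clip(1.0 + z / self.length, 0.0, 1.0)
        r = self.r0 * frac + dilate
        dx = p[..., 0] - self.cx
        dy = p[..., 1] - self.cy
        return inside_z & (dx * dx + dy * dy <= r * r)

    def bbox(self):
        lo = np.array([self.cx - self.r0, self.cy - self.r0, -self.length])
        hi = np.array([self.cx + self.r0, self.cy + self.r0, 0.0])
        return lo, hi


class _Box:
    def __init__(self, lo, hi):
        self.lo = np.asarray(lo, dtype=float)
        self.hi = np.asarray(hi, dtype=float)

    def contains(self, pts, dilate=0.0):
        p = np.asarray(pts, dtype=float)
        return np.all((p >= self.lo - dilate) & (p <= self.hi + dilate), axis=-1)

    def bbox(self):
        return self.lo, self.hi


class _ToothSolid:
    """Crown superellipsoid + cusp spheres (+ optional root cones)."""

    def __init__(self, center_x, spec: PhantomSpec, cusp_layout, roots):
        h = spec.crown_height_mm
        self.crown = _Superellipsoid(
            (center_x, 0.0, h / 2.0),
            spec.crown_halfwidth_md_mm,
            spec.crown_halfwidth_bl_mm,
            h / 2.0,
        )
        r = spec.cusp_radius_mm
        cz = h + CUSP_PROTRUSION_MM - r
        self.cusps = {
            label: _Sphere((center_x + dx, dy, cz), r)
            for label, (dx, dy) in cusp_layout.items()
        }
        self.tip_z = h + CUSP_PROTRUSION_MM
        self.center_x = center_x
        self.roots = roots

    def cusp_tips(self):
        return {
            label: np.array([s.center[0], s.center[1], self.tip_z])
            for label, s in self.cusps.items()
        }

    def crown_contains(self, pts, dilate=0.0):
        out = self.crown.contains(pts, dilate)
        for s in self.cusps.values():
            out |= s.contains(pts, dilate)
        return out

    def root_contains(self, pts, dilate=0.0):
        if not self.roots:
            return np.zeros(np.asarray(pts).shape[:-1], dtype=bool)
        out = self.roots[0].contains(pts, dilate)
        for c in self.roots[1:]:
            out |= c.contains(pts, dilate)
        return out

    def contains(self, pts, dilate=0.0):
        return self.crown_contains(pts, dilate) | self.root_contains(pts, dilate)


# ---------------------------------------------------------------------------
# the arch phantom
# ---------------------------------------------------------------------------


@dataclass
class TimepointData:
    """Everything the phantom produces for one timepoint."""

    volume: VoxelVolume
    landmarks: LandmarkSet
    mesh: SurfaceModel | None = None


class ArchPhantom:
    """Analytic arch segment: target molar, two stable neighbor crowns, bone."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        layout = _CUSP_LAYOUTS[spec.n_cusps]
        roots = [
            _RootCone(c, r0, spec.root_length_mm) for c, r0 in _ROOT_LAYOUTS[spec.n_roots]
        ]
        self.target = _ToothSolid(0.0, spec, layout, roots)
        pitch = spec.tooth_pitch_mm
        neighbor_layout = _CUSP_LAYOUTS[4]
        self.neighbors = [
            _ToothSolid(pitch, spec, neighbor_layout, []),
            _ToothSolid(-pitch, spec, neighbor_layout, []),
        ]
        a = spec.crown_halfwidth_md_mm
        b = spec.crown_halfwidth_bl_mm
        self.bone = _Box(
            lo=(-pitch - a - 0.5, -b - 1.5, -spec.root_length_mm - 1.5),
            hi=(pitch + a + 0.5, b + 1.5, spec.bone_top_mm),
        )

    # -- ground-truth landmarks and frame ---------------------------------
    @property
    def apexes(self) -> np.ndarray:
        return np.array([c.apex for c in self.target.roots])

    @property
    def apex_centroid(self) -> np.ndarray:
        return self.apexes.mean(axis=0)

    @property
    def occlusal_axis(self) -> np.ndarray:
        """The phantom's true occlusal direction (a constructor constant)."""
        return np.array([0.0, 0.0, 1.0])

    def landmarks(self) -> LandmarkSet:
        a = self.spec.crown_halfwidth_md_mm
        crest_z = self.spec.crown_height_mm - 0.9
        quadrant = np.vstack(
            [np.array(list(n.cusp_tips().values())) for n in self.neighbors]
        )
        return LandmarkSet(
            cusp_tips=self.target.cusp_tips(),
            apexes=self.apexes,
            mesial_crest=np.array([a - 1.1, 0.0, crest_z]),
            distal_crest=np.array([-(a - 1.1), 0.0, crest_z]),
            quadrant_cusp_tips=quadrant,
        )

    def true_frame(self) -> ToothFrame:
        return ToothFrame(
            origin=np.array([0.0, 0.0, self.target.tip_z]),
            x_hat=np.array([1.0, 0.0, 0.0]),
            y_hat=np.array([0.0, 1.0, 0.0]),
            z_hat=np.array([0.0, 0.0, 1.0]),
        )

    # -- motion -----------------------------------------------------------
    def local_tooth_transform(self, motion: GroundTruthMotion) -> RigidTransform:
        """Target-tooth drift in jaw coordinates (no jaw motion)."""
        ca = self.apex_centroid
        # +bl tips the crown lingually (+y): rotation about -x moves +z toward +y
        rot_bl = RigidTransform.from_axis_angle([-1, 0, 0], motion.bl_tip_deg, center=ca)
        rot_md = RigidTransform.from_axis_angle([0, 1, 0], motion.md_tip_deg, center=ca)
        erupt = RigidTransform.from_translation(motion.eruption_mm * self.occlusal_axis)
        return erupt.compose(rot_md.compose(rot_bl))

    def tooth_transform(self, motion: GroundTruthMotion) -> RigidTransform:
        """Full target-tooth transform including the jaw motion."""
        return motion.jaw_transform.compose(self.local_tooth_transform(motion))

    def followup_landmarks(self, motion: GroundTruthMotion) -> LandmarkSet:
        lm = self.landmarks()
        t_tooth = self.tooth_transform(motion)
        jaw = motion.jaw_transform
        return LandmarkSet(
            cusp_tips={k: t_tooth.apply(v) for k, v in lm.cusp_tips.items()},
            apexes=t_tooth.apply(lm.apexes),
            mesial_crest=t_tooth.apply(lm.mesial_crest),
            distal_crest=t_tooth.apply(lm.distal_crest),
            quadrant_cusp_tips=jaw.apply(lm.quadrant_cusp_tips),
        )

    # -- tissue classification --------------------------------------------
    def tissue_at(
        self,
        pts,
        motion: GroundTruthMotion | None = None,
        timepoint: str = "To",
        dilate: float = 0.0,
    ):
        """Tissue code at world points of the phantom at one timepoint.

        The target tooth is evaluated at its pose for ``timepoint``; bone
        is the alveolar block minus a periodontal socket carved around the
        *union* of the tooth's baseline and follow-up poses (in jaw
        coordinates), so bone is exactly congruent across timepoints up to
        the jaw transform.  Priority: crown > root > bone.
        """
        pts = np.asarray(pts, dtype=float)
        motion = motion if motion is not None else GroundTruthMotion.zero()
        local = self.local_tooth_transform(motion)
        if timepoint == "To":
            p_jaw = pts
        elif timepoint == "Tn":
            p_jaw = motion.jaw_transform.inverse().apply(pts)
        else:
            raise ValueError(f"unknown timepoint {timepoint!r}")
        # target pose in jaw coordinates at this timepoint
        p_tooth = local.inverse().apply(p_jaw) if timepoint == "Tn" else p_jaw

        out = np.zeros(pts.shape[:-1], dtype=np.uint8)
        bone = self.bone.contains(p_jaw, dilate=dilate)
        bone &= ~self.target.contains(p_jaw, dilate=BONE_GAP_MM)
        bone &= ~self.target.contains(local.inverse().apply(p_jaw), dilate=BONE_GAP_MM)
        for n in self.neighbors:
            bone &= ~n.contains(p_jaw, dilate=BONE_GAP_MM)
        out[bone] = Tissue.BONE
        root = self.target.root_contains(p_tooth, dilate=dilate)
        out[root] = Tissue.ROOT
        crown = self.target.crown_contains(p_tooth, dilate=dilate)
        for n in self.neighbors:
            crown |= n.crown_contains(p_jaw, dilate=dilate)
        out[crown] = Tissue.CROWN
        return out

    def is_target_at(
        self,
        pts,
        motion: GroundTruthMotion | None = None,
        timepoint: str = "To",
        dilate: float = 0.0,
    ):
        pts = np.asarray(pts, dtype=float)
        if motion is not None and timepoint == "Tn":
            pts = self.tooth_transform(motion).inverse().apply(pts)
        return self.target.contains(pts, dilate=dilate)

    def surface_annotator(self, motion: GroundTruthMotion | None = None, timepoint: str = "To"):
        """Vertex classifier for meshes extracted at one timepoint.

        Surface vertices sit on tissue boundaries, so membership is tested
        with a small dilation.  Returns (tissue, is_target, crest_zone,
        window_zone) arrays for the registration alignment-area rule; the
        window flag covers the apical window at either tooth pose so its
        rim never enters the alignment area.
        """
        spec = self.spec
        motion = motion if motion is not None else GroundTruthMotion.zero()
        tol = 0.75 * float(np.linalg.norm(spec.voxel_spacing_mm))
        jaw_inv = (
            motion.jaw_transform.inverse() if timepoint == "Tn" else RigidTransform.identity()
        )
        ca = self.apex_centroid
        window_centers = [ca, self.local_tooth_transform(motion).apply(ca)]
        window_r = spec.window_radius_mm + 1.0 + tol

        def annotate(verts):
            tissue = self.tissue_at(verts, motion=motion, timepoint=timepoint, dilate=tol)
            is_target = self.is_target_at(verts, motion=motion, timepoint=timepoint, dilate=tol)
            is_target &= tissue != Tissue.BONE
            p_jaw = jaw_inv.apply(verts)
            crest = (tissue == Tissue.BONE) & (
                p_jaw[:, 2] > spec.bone_top_mm - spec.crest_margin_mm - tol
            )
            window = np.zeros(len(verts), dtype=bool)
            for c in window_centers:
                d = p_jaw - c
                window |= np.einsum("ij,ij->i", d, d) <= window_r**2
            window &= tissue == Tissue.BONE
            return tissue, is_target, crest, window

        return annotate

    # -- rasterization ------------------------------------------------------
    def grid_bounds(self, motion: GroundTruthMotion, pad_mm: float = 1.0):
        """Shared voxel-grid bounds covering both timepoints."""
        lo = np.array(self.bone.lo)
        hi = np.array(self.bone.hi)
        hi[2] = self.target.tip_z  # cusp tips are the topmost structures
        corners = np.array(
            [[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])]
        )
        moved = np.vstack(
            [
                corners,
                motion.jaw_transform.apply(corners),
                self.tooth_transform(motion).apply(corners),
            ]
        )
        return moved.min(axis=0) - pad_mm, moved.max(axis=0) + pad_mm

    def rasterize(
        self,
        motion: GroundTruthMotion | None,
        timepoint: str,
        origin,
        shape,
        rng: np.random.Generator,
    ) -> VoxelVolume:
        """Render one timepoint's intensity volume.

        With ``spec.partial_volume`` (the default) voxels whose
        face-neighborhood crosses a tissue boundary are supersampled
        3x3x3 and given the mean class intensity, emulating CT
        partial-volume averaging; this is what gives threshold
        isosurfaces their sub-voxel accuracy.
        """
        spec = self.spec
        spacing = np.asarray(spec.voxel_spacing_mm, dtype=float)
        origin = np.asarray(origin, dtype=float)
        vol = VoxelVolume(np.zeros(shape, dtype=np.float32), spacing, origin)
        pts = vol.voxel_centers().reshape(-1, 3)
        tissue = self.tissue_at(pts, motion=motion, timepoint=timepoint).reshape(shape)
        means = spec.intensity_means
        lut = np.array(
            [means["background"], means["crown"], means["root"], means["bone"]],
            dtype=np.float32,
        )
        intens = lut[tissue]

        if spec.partial_volume:
            boundary = np.zeros(shape, dtype=bool)
            for ax in range(3):
                step = np.diff(tissue, axis=ax) != 0
                lo_sl = [slice(None)] * 3
                hi_sl = [slice(None)] * 3
                lo_sl[ax] = slice(0, -1)
                hi_sl[ax] = slice(1, None)
                boundary[tuple(lo_sl)] |= step
                boundary[tuple(hi_sl)] |= step
            idx = np.argwhere(boundary)
            if len(idx):
                k = 3
                offsets = (
                    np.stack(np.meshgrid(*[np.arange(k)] * 3, indexing="ij"), -1)
                    .reshape(-1, 3)
                    + 0.5
                ) / k - 0.5
                centers = origin + idx * spacing
                sub = (centers[:, None, :] + offsets[None, :, :] * spacing).reshape(-1, 3)
                t_sub = self.tissue_at(sub, motion=motion, timepoint=timepoint)
                intens[tuple(idx.T)] = (
                    lut[t_sub].reshape(len(idx), -1).mean(axis=1)
                )

        if spec.noise_sd > 0:
            intens = intens + rng.normal(0.0, spec.noise_sd, size=shape).astype(
                np.float32
            )
        vol.intensities = intens.astype(np.float32)
        return vol


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def generate_phantom(
    spec: PhantomSpec,
    motion: GroundTruthMotion,
    build_meshes: bool = True,
):
    """Generate baseline and follow-up phantom data plus the ground truth.

    Returns ``(baseline, followup, truth)`` where each timepoint carries a
    voxel volume, an exact landmark set, and (if ``build_meshes``) a
    labeled surface mesh produced by the segmentation workflow with
    thresholds at the tissue-class mean midpoints.
    """
    if abs(motion.eruption_mm) > 5:
        raise ValueError("|eruption_mm| must be <= 5")
    if abs(motion.bl_tip_deg) > 15 or abs(motion.md_tip_deg) > 15:
        raise ValueError("tip angles must be within +/-15 degrees")

    phantom = ArchPhantom(spec)
    lo, hi = phantom.grid_bounds(motion)
    spacing = np.asarray(spec.voxel_spacing_mm, dtype=float)
    shape = tuple(np.ceil((hi - lo) / spacing).astype(int) + 1)

    seeds = np.random.SeedSequence(spec.seed).spawn(2)
    vol_to = phantom.rasterize(motion, "To", lo, shape, np.random.default_rng(seeds[0]))
    vol_tn = phantom.rasterize(motion, "Tn", lo, shape, np.random.default_rng(seeds[1]))

    lm_to = phantom.landmarks()
    lm_tn = phantom.followup_landmarks(motion)

    mesh_to = mesh_tn = None
    if build_meshes:
        from .segmentation import build_model_mesh, default_thresholds

        cfg_to = default_thresholds(spec, window_center_mm=phantom.apex_centroid)
        ca_tn = phantom.tooth_transform(motion).apply(phantom.apex_centroid)
        cfg_tn = replace(cfg_to, window_center_mm=tuple(ca_tn))
        mesh_to = build_model_mesh(vol_to, cfg_to, phantom.surface_annotator(motion, "To"))
        mesh_tn = build_model_mesh(vol_tn, cfg_tn, phantom.surface_annotator(motion, "Tn"))

    return (
        TimepointData(vol_to, lm_to, mesh_to),
        TimepointData(vol_tn, lm_tn, mesh_tn),
        motion,
    )


def jitter_landmarks(lm: LandmarkSet, sd_mm: float, seed: int) -> LandmarkSet:
    """Gaussian per-coordinate perturbation of every landmark.

    Emulates operator digitization error for repeatability studies; labels
    are preserved and ``sd_mm == 0`` returns an identical copy.
    """
    if sd_mm < 0:
        raise ValueError("sd_mm must be non-negative")
    if sd_mm == 0:
        return LandmarkSet(
            cusp_tips=dict(lm.cusp_tips),
            apexes=lm.apexes.copy(),
            mesial_crest=lm.mesial_crest.copy(),
            distal_crest=lm.distal_crest.copy(),
            quadrant_cusp_tips=lm.quadrant_cusp_tips.copy(),
        )
    rng = np.random.default_rng(seed)
    labels = lm.cusp_labels()
    cusp_noise = rng.normal(0.0, sd_mm, size=(len(labels), 3))
    return LandmarkSet(
        cusp_tips={
            l: lm.cusp_tips[l] + cusp_noise[i] for i, l in enumerate(labels)
        },
        apexes=lm.apexes + rng.normal(0.0, sd_mm, size=lm.apexes.shape),
        mesial_crest=lm.mesial_crest + rng.normal(0.0, sd_mm, size=3),
        distal_crest=lm.distal_crest + rng.normal(0.0, sd_mm, size=3),
        quadrant_cusp_tips=lm.quadrant_cusp_tips
        + rng.normal(0.0, sd_mm, size=lm.quadrant_cusp_tips.shape),
    )


def jitter_sd_for_method_error(target_me_mm: float, n_cusps: int) -> float:
    """Per-coordinate landmark jitter sd giving a target Dahlberg error.

    The mean-overeruption measurement averages n cusp-tip z coordinates at
    each of two timepoints, so its error variance is 2*sd^2/n and the
    Dahlberg error of duplicate sessions estimates sd*sqrt(2/n); invert
    that to calibrate the jitter.
    """
    return target_me_mm * np.sqrt(n_cusps / 2.0)
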