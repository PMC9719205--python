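# Methods

`molardrift` implements a 3D measurement pipeline for the positional
change of unopposed molars between two CBCT-style scans, together with a
fully synthetic phantom that provides ground truth for every stage.  This
note records the model, the numerical choices, and what the synthetic
validation does and does not demonstrate.

## The measurement model

A molar that loses its antagonist drifts: it erupts along the occlusal
direction and tips about axes through its root apexes.  The pipeline
quantifies this from two scans, a baseline To and a follow-up Tn, in five
stages.

**1. Segmentation.** Each scan is thresholded into three tissue masks —
crown (enamel), root (dentin) and alveolar bone — using half-open
intensity intervals `[lo, hi)` so adjacent classes partition the
intensity axis exactly.  A spherical *apical window* is cleared from the
bone mask around the target tooth's apex region so the root surface is
exposed in the assembled model.  The masks are united by Boolean OR and
the model surface is extracted by marching cubes.

**2. Superimposition.** The follow-up model is rigidly aligned onto the
baseline model by iterative closest point (ICP) surface best fit.  The
alignment area deliberately excludes everything that may genuinely move
or remodel between timepoints: the target tooth itself, the
alveolar-crest zone, and the opened window area.  Only non-target crowns
and stable bone drive the fit.

**3. Tooth coordinate frame** (built on To only, reused for Tn).  The
occlusal plane is the total-least-squares plane through all posterior
cusp tips of the quadrant (SVD of the centered point matrix; the fit
criterion is orthogonal distance, chosen for determinism).  The z-axis is
the plane normal through M0, the midpoint of the segment joining the
mesial and distal marginal-crest midpoints Mm and Md; the origin is where
this axis meets the occlusal plane.  The mesio-distal plane contains the
z-axis and Md; the bucco-lingual plane is perpendicular to both.  Signs:
+x mesial, +y lingual, +z occlusal.  The z sign comes from the
root-to-crown direction (apex centroid toward cusp-tip centroid) and the
y sign from the lingual-minus-buccal cusp-centroid indicator, which works
in all four quadrants without jaw metadata; the frame may therefore be
left- or right-handed.

**4. Outcome parameters.**  With CC the cusp-tip centroid, CA the apex
centroid and the tooth axis the CA→CC unit vector:

* `OE_mean` — z-displacement of CC between Tn and To (equals the mean of
  per-cusp z-displacements);
* `OE_max` — the *signed* maximum per-cusp z-displacement, with the
  attaining cusp reported (ties broken by the fixed label order MB, DB,
  ML, DL, B, L);
* `BLT` = arcsin(axis · ŷ), the signed angle between the tooth axis and
  the mesio-distal plane (positive lingual); `MDT` = arcsin(axis · x̂),
  positive mesial; both in [−90°, 90°];
* `cBLT`, `cMDT` — differences of these angles between timepoints, both
  evaluated in the baseline frame.  Negative cBLT is buccal tipping,
  negative cMDT distal.

The signed conventions are forced by the frame axes; a purely "angle
between" reading would lose the direction of tipping that the cohort
statistics need.

**5. Statistics.**  One-sample t-tests of each outcome against zero,
one-way ANOVA across molar types (α = 0.05), descriptive
count/percentage tables (percentages rounded half-up to 2 decimals),
Dahlberg's combined method error `sqrt(Σd²/2n)` for duplicate
measurement sessions, and the two-way mixed, single-measure,
*consistency* intraclass correlation ICC(3,1).  The consistency form was
chosen over absolute agreement because a constant between-session offset
is an occasion effect, not disagreement; the offset-invariance unit test
documents this choice.

## The phantom

`ArchPhantom` builds an analytic arch segment in jaw-local coordinates
(+x mesial, +y lingual, +z occlusal): a target molar with a
superellipsoid crown (exponent 4, half-widths 5 mm, height 7 mm)
carrying 2–5 spherical-cap cusps (radius 1.2 mm, tips protruding 0.8 mm
above the crown body, all at one height so the true occlusal plane is
exact), 1–3 tapered-cone roots (length 13 mm, a typical molar
dimension), two stable neighbor crowns at ±11 mm, and an alveolar bone
block with a 0.4 mm periodontal gap around every tooth.  All landmark
ground truth (cusp tips, apexes, crest midpoints) is available in closed
form, and the true occlusal axis is a constructor constant rather than a
derived quantity, so ground truth is unambiguous.

Ground-truth motion composes in a fixed, documented order: tooth-local
rotation about CA (bucco-lingual tip about −x̂, then mesio-distal tip
about ŷ), then eruption translation along the true occlusal axis, then
the whole-jaw rigid transform.  Tests depend on this order.

Two timepoints are rasterized on one shared grid sized to cover both
poses.  Tissue-class intensities default to background 0, bone 400,
dentin 800, enamel 1200 with Gaussian noise sd 20, giving >6σ separation
at the midpoint thresholds.  Rasterization is *partial-volume aware*:
voxels whose face-neighborhood crosses a class boundary are supersampled
3×3×3 and assigned the mean class intensity, emulating the
partial-volume averaging of real CT.  This matters: a point-sampled
binary rasterization carries no sub-voxel information, and isosurfaces
of such grids are biased against each other by up to half a voxel in an
orientation-dependent way, which caps registration accuracy far below
what clinical threshold workflows achieve.  A `partial_volume=False`
switch retains pure center-point sampling for voxel-count oracles.

The bone socket is carved around the *union* of the target tooth's
baseline and follow-up poses, in both timepoints, so that "stable bone"
is exactly congruent across timepoints up to the jaw transform — the
property the masked registration relies on.  (Biologically the socket
remodels as the tooth moves; emulating that would only enlarge the
excluded unstable zone.)

Geometric ground truth stays exact: intensity noise lives in voxel space
only, and operator digitization error is modeled separately by
`jitter_landmarks` (i.i.d. Gaussian per coordinate, labels preserved).

## Registration numerics

Point-to-point ICP with k-d-tree nearest-vertex correspondences and the
closed-form Kabsch/SVD step; identity initialization by default with an
optional centroid pre-alignment flag; convergence when the RMS change
drops below 1e-6 mm (max 200 iterations, non-convergence flagged rather
than raised); optional distance-quantile trimming, off by default.

Point-to-point correspondences between two independently sampled meshes
of the same surface have an RMS floor of roughly half the vertex
spacing, dominated by the *in-plane* component of the nearest-vertex
offset; around that floor the cost basin is shallow and terraced
marching-cubes artifacts can hold the minimum a few tenths of a degree
from truth.  `icp_align` therefore accepts per-vertex normals of the
fixed surface and, after the point-to-point stage converges, runs a
linearized point-to-plane Gauss–Newton refinement that scores only the
normal component of each residual.  On the phantom at 0.25 mm voxels
this sharpens jaw-transform recovery by roughly an order of magnitude.
Correspondence remains vertex-to-vertex (not point-to-surface), a
documented limitation.

## Problem sizes and defaults

Analysis-grade phantom runs use 0.25 mm isotropic voxels (grids around
150×90×120 after motion padding); the CLI `demo` defaults to 0.4 mm so
it completes in seconds.  The landmark-recovery study uses 200 random
motions with |eruption| ≤ 2 mm and |tips| ≤ 10°; the full-pipeline study
uses 20 random seeds with jaw motion up to 5°/3 mm and landmark jitter
sd 0.05 mm; the in-silico repeatability protocol measures 10 phantom
subjects spanning eruptions −0.4 to 1.9 mm twice, with jitter calibrated
analytically (sd = target·sqrt(n_cusps/2)) to a target Dahlberg error of
0.074 mm for OE_mean.

## Degenerate inputs and tie-breaks

Collinear occlusal-fit points, a distal crest that projects onto the
frame origin, coincident buccal/lingual cusp centroids, coincident
CA/CC, zero-variance t-tests, all-identical ANOVA groups and
zero-between-subject-variance ICCs raise `ValueError` with a message
naming the degeneracy.  Empty threshold masks and no-op apical windows
warn instead of raising.  The OE_max cusp tie-break is the fixed label
order above.

## What the phantom validation does not show

The phantom has flat-topped coplanar cusp tips, a straight arch, boxy
bone, no enamel/dentin texture gradients, no beam hardening or metal
artifacts, no scanner-specific point-spread function, and its landmark
error model is i.i.d. Gaussian rather than operator-specific bias.
Passing ground-truth recovery here shows the *geometry and algebra* of
the pipeline are correct at clinical voxel sizes and noise levels; it
does not certify accuracy on real CBCT, where threshold selection and
landmark digitization dominate the error budget.  The bundled cohort
summary statistics are used only to recompute derived quantities
(percentages, t statistics); patient-level replication is not possible
from summaries.
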