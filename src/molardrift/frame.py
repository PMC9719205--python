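"""Tooth-local coordinate frame from labeled landmarks.

The frame is built on the baseline model only and reused for follow-up
measurements.  Construction: the occlusal plane is the total-least-squares
fit through all posterior cusp tips of the quadrant; the z-axis is the
plane normal through M0, the midpoint of the segment joining the mesial
and distal marginal-crest midpoints (Mm, Md); the origin is where that
axis meets the occlusal plane; the mesio-distal plane contains the z-axis
and Md; the bucco-lingual plane is perpendicular to both.  Axis signs:
+x mesial, +y lingual, +z occlusal.
"""

from __future__ import annotations

import numpy as np

from .core import BUCCAL_LABELS, LINGUAL_LABELS, LandmarkSet, ToothFrame

__all__ = ["fit_occlusal_plane", "build_frame", "to_tooth_coords"]


def fit_occlusal_plane(points: np.ndarray):
    """Orthogonal least-squares plane through >= 3 non-collinear points.

    Returns ``(centroid, unit_normal)``; the normal is the right singular
    vector of the centered point matrix with the smallest singular value
    (sign unresolved — callers orient it with a hint).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 3:
        raise ValueError("need at least 3 points to fit a plane")
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("points are collinear; occlusal plane is undefined")
    return centroid, vt[2]


def build_frame(lm: LandmarkSet, occlusal_hint=None, include_target_cusps=True) -> ToothFrame:
    """Construct the tooth frame from one timepoint's landmarks.

    ``occlusal_hint`` is a rough occlusal direction used only to sign the
    z-axis; by default the root-to-crown direction (apex centroid toward
    cusp-tip centroid) is used, which works for either jaw.
    """
    fit_pts = lm.occlusal_fit_points(include_target=include_target_cusps)
    plane_point, normal = fit_occlusal_plane(fit_pts)

    if occlusal_hint is None:
        occlusal_hint = lm.cusp_array().mean(axis=0) - lm.apexes.mean(axis=0)
    occlusal_hint = np.asarray(occlusal_hint, dtype=float)
    if np.linalg.norm(occlusal_hint) < 1e-12:
        raise ValueError("occlusal hint is a zero vector")
    z_hat = normal if float(normal @ occlusal_hint) > 0 else -normal
    z_hat = z_hat / np.linalg.norm(z_hat)

    m0 = 0.5 * (lm.mesial_crest + lm.distal_crest)
    origin = m0 + (float((plane_point - m0) @ z_hat)) * z_hat

    d = lm.distal_crest - origin
    d_in_plane = d - float(d @ z_hat) * z_hat
    n = np.linalg.norm(d_in_plane)
    if n < 1e-9:
        raise ValueError(
            "distal crest midpoint projects onto the origin; "
            "mesio-distal direction is undefined"
        )
    x_hat = -d_in_plane / n  # +x mesial (away from the distal crest)

    y_hat = np.cross(z_hat, x_hat)
    buccal = [p for l, p in lm.cusp_tips.items() if l in BUCCAL_LABELS]
    lingual = [p for l, p in lm.cusp_tips.items() if l in LINGUAL_LABELS]
    indicator = np.mean(lingual, axis=0) - np.mean(buccal, axis=0)
    side = float(indicator @ y_hat)
    if abs(side) < 1e-9:
        raise ValueError(
            "lingual and buccal cusp centroids coincide; y-axis sign is ambiguous"
        )
    if side < 0:
        y_hat = -y_hat
    return ToothFrame(origin=origin, x_hat=x_hat, y_hat=y_hat / np.linalg.norm(y_hat), z_hat=z_hat)


def to_tooth_coords(points, frame: ToothFrame) -> np.ndarray:
    """World point(s) -> (x, y, z) mm in the tooth frame."""
    return frame.to_coords(points)
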