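"""Outcome parameters: overeruption (OE_mean, OE_max) and tipping change.

All quantities are evaluated in the baseline tooth frame after the
follow-up landmarks have been superimposed into the baseline global
coordinates.  The cusp-tip centroid is CC, the root-apex centroid is CA,
and the CA->CC unit vector is the tooth axis.

Sign conventions (forced by the frame axes): positive OE is occlusal
movement; BLT = arcsin(axis . y_hat), positive toward lingual; MDT =
arcsin(axis . x_hat), positive toward mesial.  Their between-timepoint
differences cBLT and cMDT are therefore negative for buccal / distal
tipping.  OE_max is the *signed* maximum of per-cusp occlusal
displacements (a tooth moving apically yields a negative OE_max).
"""

from __future__ import annotations

import numpy as np

from .core import CUSP_LABEL_ORDER, DriftResult, LandmarkSet, ToothFrame

__all__ = [
    "centroid",
    "tooth_axis",
    "overeruption",
    "tipping_angles",
    "tipping_change",
    "compute_drift",
]


def centroid(points: np.ndarray) -> np.ndarray:
    """Arithmetic mean per coordinate."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        raise ValueError("centroid of an empty point set")
    return pts.mean(axis=0)


def tooth_axis(ca: np.ndarray, cc: np.ndarray) -> np.ndarray:
    """Unit vector from the apex centroid CA to the cusp-tip centroid CC."""
    v = np.asarray(cc, dtype=float) - np.asarray(ca, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("CA and CC coincide; tooth axis is undefined")
    return v / n


def _check_labels(lm_to: LandmarkSet, lm_tn: LandmarkSet):
    if set(lm_to.cusp_tips) != set(lm_tn.cusp_tips):
        raise ValueError(
            "cusp label mismatch between timepoints: "
            f"{sorted(lm_to.cusp_tips)} vs {sorted(lm_tn.cusp_tips)}"
        )


def overeruption(lm_to: LandmarkSet, lm_tn: LandmarkSet, frame: ToothFrame):
    """Per-cusp occlusal displacement and its mean / signed maximum.

    Returns ``(OE_mean, OE_max, OE_max_cusp_label, per_cusp_dz)``.
    OE_mean equals the z-displacement of the cusp-tip centroid, which is
    the mean of the per-cusp displacements; ties for the maximum are
    broken by the fixed label order MB, DB, ML, DL, B, L.
    """
    _check_labels(lm_to, lm_tn)
    labels = lm_to.cusp_labels()
    dz = {
        l: float(
            frame.to_coords(lm_tn.cusp_tips[l])[2]
            - frame.to_coords(lm_to.cusp_tips[l])[2]
        )
        for l in labels
    }
    oe_mean = float(np.mean(list(dz.values())))
    oe_max = max(dz.values())
    max_label = next(l for l in labels if dz[l] == oe_max)
    return oe_mean, float(oe_max), max_label, dz


def tipping_angles(axis: np.ndarray, frame: ToothFrame):
    """Signed line-plane angles (degrees) of the tooth axis.

    BLT: angle to the mesio-distal plane (normal y), positive lingual.
    MDT: angle to the bucco-lingual plane (normal x), positive mesial.
    Both lie in [-90, +90].
    """
    a = np.asarray(axis, dtype=float)
    blt = float(np.degrees(np.arcsin(np.clip(a @ frame.y_hat, -1.0, 1.0))))
    mdt = float(np.degrees(np.arcsin(np.clip(a @ frame.x_hat, -1.0, 1.0))))
    return blt, mdt


def tipping_change(lm_to: LandmarkSet, lm_tn: LandmarkSet, frame: ToothFrame):
    """(cBLT, cMDT) in degrees, both angles evaluated in the baseline frame."""
    _check_labels(lm_to, lm_tn)
    axis_to = tooth_axis(centroid(lm_to.apexes), centroid(lm_to.cusp_array()))
    axis_tn = tooth_axis(centroid(lm_tn.apexes), centroid(lm_tn.cusp_array()))
    blt_to, mdt_to = tipping_angles(axis_to, frame)
    blt_tn, mdt_tn = tipping_angles(axis_tn, frame)
    return blt_tn - blt_to, mdt_tn - mdt_to


def compute_drift(
    lm_to: LandmarkSet,
    lm_tn: LandmarkSet,
    frame: ToothFrame,
    registration_rms_mm: float | None = None,
) -> DriftResult:
    """Full outcome set for one tooth (follow-up already superimposed)."""
    oe_mean, oe_max, max_label, dz = overeruption(lm_to, lm_tn, frame)
    axis_to = tooth_axis(centroid(lm_to.apexes), centroid(lm_to.cusp_array()))
    axis_tn = tooth_axis(centroid(lm_tn.apexes), centroid(lm_tn.cusp_array()))
    blt_to, mdt_to = tipping_angles(axis_to, frame)
    blt_tn, mdt_tn = tipping_angles(axis_tn, frame)
    return DriftResult(
        OE_mean_mm=oe_mean,
        OE_max_mm=oe_max,
        OE_max_cusp_label=max_label,
        BLT_To_deg=blt_to,
        BLT_Tn_deg=blt_tn,
        MDT_To_deg=mdt_to,
        MDT_Tn_deg=mdt_tn,
        cBLT_deg=blt_tn - blt_to,
        cMDT_deg=mdt_tn - mdt_to,
        per_cusp_dz_mm=dz,
        registration_rms_mm=registration_rms_mm,
    )
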