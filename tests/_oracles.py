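"""Independent reference implementations used only as test oracles.

Everything here is deliberately written from scratch (or delegates to a
third-party library the package itself does not use for that step) so
the oracle never shares code with the implementation path it checks.
"""

import numpy as np


def rot_x(deg):
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def rot_y(deg):
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def rot_z(deg):
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def tooth_motion_matrix(bl_tip_deg, md_tip_deg, eruption_mm, ca):
    """Ground-truth tooth motion as an explicit (R, t) pair.

    Composition mirrors the documented order — rotation about CA (bl then
    md; +bl lingual is a rotation about -x), then occlusal translation —
    but is assembled from hand-rolled axis rotations.
    """
    R = rot_y(md_tip_deg) @ rot_x(-bl_tip_deg)
    ca = np.asarray(ca, dtype=float)
    t = ca - R @ ca + np.array([0.0, 0.0, eruption_mm])
    return R, t


def expected_drift_canonical(lm, bl_tip_deg, md_tip_deg, eruption_mm):
    """Expected outcomes for the canonical phantom (frame = identity axes).

    Works directly in jaw-local coordinates where the true frame axes are
    the unit vectors, so no frame construction code is exercised.
    """
    ca = lm.apexes.mean(axis=0)
    R, t = tooth_motion_matrix(bl_tip_deg, md_tip_deg, eruption_mm, ca)
    labels = lm.cusp_labels()
    tips_to = np.array([lm.cusp_tips[l] for l in labels])
    tips_tn = tips_to @ R.T + t
    dz = dict(zip(labels, (tips_tn[:, 2] - tips_to[:, 2]).tolist()))
    oe_mean = float(np.mean(list(dz.values())))
    oe_max = float(max(dz.values()))
    max_label = next(l for l in labels if dz[l] == oe_max)

    def angles(axis):
        a = axis / np.linalg.norm(axis)
        return np.degrees(np.arcsin(a[1])), np.degrees(np.arcsin(a[0]))

    axis_to = tips_to.mean(axis=0) - ca
    axis_tn = (tips_tn.mean(axis=0)) - (lm.apexes @ R.T + t).mean(axis=0)
    blt_o, mdt_o = angles(axis_to)
    blt_n, mdt_n = angles(axis_tn)
    return {
        "OE_mean": oe_mean,
        "OE_max": oe_max,
        "OE_max_cusp": max_label,
        "per_cusp_dz": dz,
        "cBLT": blt_n - blt_o,
        "cMDT": mdt_n - mdt_o,
    }


def brute_force_plane_rms(points, n_theta=180, n_phi=90):
    """Best orthogonal-residual RMS over a dense grid of plane normals."""
    pts = np.asarray(points, dtype=float)
    c = pts.mean(axis=0)
    d = pts - c
    best = np.inf
    for theta in np.linspace(0, np.pi, n_theta):
        for phi in np.linspace(0, np.pi, n_phi):
            n = np.array(
                [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
            )
            rms = np.sqrt(np.mean((d @ n) ** 2))
            best = min(best, rms)
    return best


def count_voxel_centers_inside(vol, inside_fn):
    """Voxel centers of ``vol`` satisfying a boolean predicate."""
    pts = vol.voxel_centers().reshape(-1, 3)
    return int(np.count_nonzero(inside_fn(pts)))
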