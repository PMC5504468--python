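"""Independent closed-form oracles used by the test suite.

The spherical montage oracle reproduces the scalp-positioning construction
analytically on a true sphere: every curve is a circle (sphere cut by the
plane through three points), and arc-length fractions along a circle are
angle fractions about its axis.  No meshes, sections or polylines are used,
so it is independent of the implementation it checks.
"""

import numpy as np

from scalpmap.montage import MONTAGE_DEFINITIONS


def _circle_frame(p1, p2, p3):
    p1, p2, p3 = (np.asarray(p, float) for p in (p1, p2, p3))
    n = np.cross(p2 - p1, p3 - p1)
    n = n / np.linalg.norm(n)
    # circumcenter via barycentric weights
    l1, l2, l3 = np.dot(p2 - p3, p2 - p3), np.dot(p1 - p3, p1 - p3), np.dot(p1 - p2, p1 - p2)
    w1 = l1 * np.dot(p1 - p2, p1 - p3)
    w2 = l2 * np.dot(p2 - p1, p2 - p3)
    w3 = l3 * np.dot(p3 - p1, p3 - p2)
    center = (w1 * p1 + w2 * p2 + w3 * p3) / (w1 + w2 + w3)
    radius = np.linalg.norm(p1 - center)
    u, v = _circle_basis(p1, center, n)

    def angle_of(p):
        d = np.asarray(p, float) - center
        return np.arctan2(np.dot(d, v), np.dot(d, u))

    return center, n, radius, angle_of


def _circle_basis(p_ref, center, axis):
    u = np.asarray(p_ref, float) - center
    u = u / np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


def _arc_point(start, end, via, frac):
    """Point at fraction ``frac`` of the circular arc start -> end passing
    through ``via`` (the sub-arc containing ``via``)."""
    center, axis, radius, angle_of = _circle_frame(start, via, end)
    a_s, a_v, a_e = angle_of(start), angle_of(via), angle_of(end)
    span = (a_e - a_s) % (2 * np.pi)
    via_rel = (a_v - a_s) % (2 * np.pi)
    if via_rel > span:  # the short unwrap misses via; go the other way
        span = span - 2 * np.pi
    ang = a_s + frac * span
    u, v = _circle_basis(start, center, axis)
    return center + radius * (np.cos(ang) * u + np.sin(ang) * v)


def spherical_montage(radius, fiducials, system="10-10"):
    """Closed-form montage positions on a true sphere centered at the origin
    with the four fiducials on it."""
    defs = MONTAGE_DEFINITIONS[system]
    nz, iz = fiducials["Nz"], fiducials["Iz"]
    al, ar = fiducials["AL"], fiducials["AR"]
    cz = np.array([0.0, 0.0, radius])  # by symmetry of the fixture fiducials
    pos = {"Nz": nz, "Iz": iz, "AL": al, "AR": ar}
    for label, f in defs["midline"].items():
        pos[label] = _arc_point(nz, iz, cz, f)
    cz = pos["Cz"]
    for label, f in defs["coronal"].items():
        pos[label] = _arc_point(al, ar, cz, f)
    fpz, oz = pos["Fpz"], pos["Oz"]
    for ring_key, t_label in (("ring_left", "T3"), ("ring_right", "T4")):
        t = pos[t_label]
        for label, f in defs[ring_key]["q1"].items():
            pos[label] = _quarter_point(fpz, oz, t, "q1", f)
        for label, f in defs[ring_key]["q2"].items():
            pos[label] = _quarter_point(fpz, oz, t, "q2", f)
    for row in defs["rows"]:
        left, mid, right = pos[row["left"]], pos[row["mid"]], pos[row["right"]]
        for label, f in row["left_points"].items():
            pos[label] = _half_point(left, mid, right, "left", f)
        for label, f in row["right_points"].items():
            pos[label] = _half_point(left, mid, right, "right", f)
    return pos


def _quarter_point(fpz, oz, t, quarter, frac):
    """Point on the half-ring circle through Fpz, T, Oz: q1 spans Fpz->T,
    q2 spans T->Oz, fractions by angle within the quarter."""
    center, axis, radius, angle_of = _circle_frame(fpz, t, oz)
    a_f, a_t, a_o = angle_of(fpz), angle_of(t), angle_of(oz)
    span_ft = (a_t - a_f) % (2 * np.pi)
    span_fo = (a_o - a_f) % (2 * np.pi)
    if span_ft > span_fo:  # orient so T lies between Fpz and Oz
        span_ft -= 2 * np.pi
        span_fo -= 2 * np.pi
    if quarter == "q1":
        ang = a_f + frac * span_ft
    else:
        ang = a_f + span_ft + frac * (span_fo - span_ft)
    u, v = _circle_basis(fpz, center, axis)
    return center + radius * (np.cos(ang) * u + np.sin(ang) * v)


def _half_point(left, mid, right, side, frac):
    """Point on the circle through a transverse row, fractions measured per
    half (left->mid or mid->right) by angle."""
    center, axis, radius, angle_of = _circle_frame(left, mid, right)
    a_l, a_m, a_r = angle_of(left), angle_of(mid), angle_of(right)
    span_lm = (a_m - a_l) % (2 * np.pi)
    span_lr = (a_r - a_l) % (2 * np.pi)
    if span_lm > span_lr:
        span_lm -= 2 * np.pi
        span_lr -= 2 * np.pi
    if side == "left":
        ang = a_l + frac * span_lm
    else:
        ang = a_l + span_lm + frac * (span_lr - span_lm)
    u, v = _circle_basis(left, center, axis)
    return center + radius * (np.cos(ang) * u + np.sin(ang) * v)


def random_rotation(rng):
    """Uniform random proper rotation from a normalized quaternion."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
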