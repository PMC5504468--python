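"""Transfer of cortical landmarks to a template scalp via 10-10 positions.

A cortical point CP in a subject's head is written as a combination of the
three vectors running from M (the midpoint of the AL-AR segment) to the
three neighboring 10-10 positions L1, L2, L3:

    CP - M = a1 (L1 - M) + a2 (L2 - M) + a3 (L3 - M)

The coefficients (a1, a2, a3) are carried to a template head, where the same
combination of the template's M and 10-10 positions reconstructs the point,
which is then back-projected onto the template scalp by extending the ray
M -> CP to its outermost scalp crossing (equivalently, scaling all three
coefficients by one common factor).  Cross-subject scatter of the projected
points per landmark is summarized with Tukey box-and-whisker statistics and
compared against the pitch (nearest-neighbor distance) of the 10-10 montage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import LandmarkSet, RayMissError, TriangleMesh, ray_surface_intersection
from .montage import TenTenMontage, nearest_neighbor_distances

logger = logging.getLogger("scalpmap")

#: montage labels never used as L1/L2/L3 (reference fiducials, not 10-10 sites)
_EXCLUDED_NEIGHBOR_LABELS = frozenset({"Nz", "Iz", "AL", "AR"})


class NeighborSelectionError(RuntimeError):
    """Raised when no linearly independent neighbor triple exists."""


@dataclass
class VectorCoefficients:
    a1: float
    a2: float
    a3: float
    labels: tuple
    midpoint: np.ndarray
    subject_id: str = ""
    landmark: tuple | None = None

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.a1, self.a2, self.a3])


def pre_auricular_midpoint(fiducials: dict) -> np.ndarray:
    return 0.5 * (np.asarray(fiducials["AL"], float) + np.asarray(fiducials["AR"], float))


def choose_neighbors(
    cp,
    montage: TenTenMontage,
    midpoint,
    cond_max: float = 1e6,
) -> tuple:
    """The three nearest montage positions forming an independent vector triple.

    Candidates are ranked by Euclidean distance to ``cp`` (ties broken by
    label order).  If the vectors {Li - M} are ill-conditioned the farthest
    member of the triple is replaced by the next-nearest candidate until the
    condition number drops below ``cond_max``.
    """
    cp = np.asarray(cp, dtype=float)
    m = np.asarray(midpoint, dtype=float)
    labels = [l for l in montage.labels() if l not in _EXCLUDED_NEIGHBOR_LABELS]
    if len(labels) < 3:
        raise ValueError("montage needs at least three candidate positions")
    pts = montage.array(labels)
    d = np.linalg.norm(pts - cp, axis=1)
    order = sorted(range(len(labels)), key=lambda i: (d[i], labels[i]))
    chosen = order[:3]
    queue = order[3:]
    while True:
        basis = np.column_stack([pts[i] - m for i in chosen])
        if np.linalg.cond(basis) < cond_max:
            break
        if not queue:
            raise NeighborSelectionError("no linearly independent neighbor triple found")
        # drop the farthest member of the current triple, pull the next candidate
        farthest = max(chosen, key=lambda i: (d[i], labels[i]))
        chosen.remove(farthest)
        chosen.append(queue.pop(0))
        chosen.sort(key=lambda i: (d[i], labels[i]))
    chosen.sort(key=lambda i: (d[i], labels[i]))
    return tuple(labels[i] for i in chosen)


def decompose(cp, midpoint, l1, l2, l3, subject_id: str = "", landmark=None) -> VectorCoefficients:
    """Unique coefficients expressing CP - M in the {Li - M} basis."""
    cp = np.asarray(cp, float)
    m = np.asarray(midpoint, float)
    basis = np.column_stack([np.asarray(l, float) - m for l in (l1, l2, l3)])
    if np.linalg.cond(basis) > 1e12:
        raise np.linalg.LinAlgError("neighbor vectors are linearly dependent")
    a = np.linalg.solve(basis, cp - m)
    residual = np.linalg.norm(basis @ a - (cp - m))
    if residual > 1e-9 * max(1.0, np.linalg.norm(cp - m)):
        raise np.linalg.LinAlgError(f"decomposition residual {residual:.2e} mm")
    return VectorCoefficients(
        float(a[0]), float(a[1]), float(a[2]), labels=(), midpoint=m,
        subject_id=subject_id, landmark=landmark,
    )


def recompose(coeffs: VectorCoefficients, midpoint, l1, l2, l3) -> np.ndarray:
    """Evaluate the coefficient combination with template-space points."""
    m = np.asarray(midpoint, float)
    out = m.copy()
    for a, l in zip(coeffs.as_array, (l1, l2, l3)):
        out = out + a * (np.asarray(l, float) - m)
    return out


def backproject_to_scalp(cp_t, midpoint, scalp: TriangleMesh):
    """Outermost scalp crossing of the ray M -> CP_t; returns (point, scale).

    The scale is the single common factor by which all three coefficients
    are enlarged to land on the scalp.
    """
    cp_t = np.asarray(cp_t, float)
    m = np.asarray(midpoint, float)
    offset = cp_t - m
    d0 = np.linalg.norm(offset)
    if d0 < 1e-9:
        raise ValueError("cortical point coincides with the pre-auricular midpoint")
    point = ray_surface_intersection(scalp, m, offset)
    s = float(np.linalg.norm(point - m) / d0)
    return point, s


@dataclass
class TransferResult:
    """Per-landmark transferred scalp points and per-row records."""

    points: dict                 # (label, hemi) -> (n_used, 3) array
    records: pd.DataFrame        # subject x landmark coefficient bookkeeping
    excluded: list               # (subject_id, reason)
    template_id: str


def transfer_cohort(
    cohort,
    template,
    montages: dict,
    labels=None,
) -> TransferResult:
    """Transfer every subject's cortical landmarks to the template scalp.

    ``montages`` maps subject id to its 10-10 montage; subjects without a
    valid montage are excluded with a logged reason.  Neighbor ranking uses
    each landmark's own scalp projection (ray M -> CP extended to the
    subject scalp) so that deep landmarks select lateral, not vertex,
    neighbors; the decomposition itself uses the raw cortical point.
    """
    t_ls = template.landmarks if hasattr(template, "landmarks") else template
    template_id = t_ls.subject_id
    if template_id not in montages:
        raise ValueError("template montage is required")
    t_montage = montages[template_id]
    t_m = pre_auricular_midpoint(t_ls.fiducials)
    t_scalp = template.scalp
    clouds: dict = {}
    records = []
    excluded = []
    for subject in cohort:
        ls = subject.landmarks if hasattr(subject, "landmarks") else subject
        sid = ls.subject_id
        if sid not in montages:
            logger.warning("subject %s excluded: no valid montage", sid)
            excluded.append((sid, "no valid montage"))
            continue
        s_montage = montages[sid]
        s_m = pre_auricular_midpoint(ls.fiducials)
        s_scalp = subject.scalp if hasattr(subject, "scalp") else None
        keys = labels if labels is not None else sorted(ls.points.keys())
        for key in keys:
            cp = ls.points[key]
            query = cp
            if s_scalp is not None:
                try:
                    query, _ = backproject_to_scalp(cp, s_m, s_scalp)
                except (RayMissError, ValueError):
                    logger.warning("%s %s: scalp projection missed; ranking by raw point", sid, key)
            triple = choose_neighbors(query, s_montage, s_m)
            l1s, l2s, l3s = (s_montage.positions[l] for l in triple)
            coeffs = decompose(cp, s_m, l1s, l2s, l3s, subject_id=sid, landmark=key)
            coeffs.labels = triple
            l1t, l2t, l3t = (t_montage.positions[l] for l in triple)
            cp_t = recompose(coeffs, t_m, l1t, l2t, l3t)
            point, scale = backproject_to_scalp(cp_t, t_m, t_scalp)
            clouds.setdefault(key, []).append(point)
            records.append(
                {
                    "subject_id": sid,
                    "label": key[0],
                    "hemisphere": key[1],
                    "L1": triple[0],
                    "L2": triple[1],
                    "L3": triple[2],
                    "a1": coeffs.a1,
                    "a2": coeffs.a2,
                    "a3": coeffs.a3,
                    "scale": scale,
                    "x_mm": point[0],
                    "y_mm": point[1],
                    "z_mm": point[2],
                }
            )
    points = {k: np.array(v) for k, v in clouds.items()}
    return TransferResult(points, pd.DataFrame(records), excluded, template_id)


def dispersion(points_by_landmark: dict) -> pd.DataFrame:
    """Tukey box-and-whisker statistics of distances from per-landmark centroids.

    Quartiles use the linear-interpolation convention; whiskers are the most
    extreme distances within 1.5 interquartile ranges of the quartiles.
    """
    rows = []
    for key in sorted(points_by_landmark.keys()):
        pts = np.asarray(points_by_landmark[key], dtype=float)
        if len(pts) < 2:
            raise ValueError(f"landmark {key}: need at least two points")
        centroid = pts.mean(axis=0)
        d = np.linalg.norm(pts - centroid, axis=1)
        q1, med, q3 = np.percentile(d, [25, 50, 75])
        iqr = q3 - q1
        hi = d[d <= q3 + 1.5 * iqr].max()
        lo = d[d >= q1 - 1.5 * iqr].min()
        label, hemi = key if isinstance(key, tuple) else (key, "")
        rows.append(
            {
                "label": label,
                "hemisphere": hemi,
                "n": len(pts),
                "centroid_x": centroid[0],
                "centroid_y": centroid[1],
                "centroid_z": centroid[2],
                "median_mm": med,
                "q1_mm": q1,
                "q3_mm": q3,
                "whisker_lo_mm": lo,
                "whisker_hi_mm": hi,
            }
        )
    return pd.DataFrame(rows)


def montage_pitch_summary(montage: TenTenMontage) -> dict:
    """Median and quartiles of the montage nearest-neighbor distances."""
    d = np.array(list(nearest_neighbor_distances(montage).values()))
    q1, med, q3 = np.percentile(d, [25, 50, 75])
    return {"median_mm": float(med), "q1_mm": float(q1), "q3_mm": float(q3), "n": int(d.size)}


def plot_dispersion(stats: pd.DataFrame, pitch: dict | None = None, path=None):
    """Box-and-whisker plot of per-landmark dispersion (optionally with the
    montage nearest-neighbor pitch as a rightmost reference box)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    boxes = []
    for _, row in stats.iterrows():
        boxes.append(
            {
                "label": f"{row['label']}{row['hemisphere']}",
                "med": row["median_mm"],
                "q1": row["q1_mm"],
                "q3": row["q3_mm"],
                "whislo": row["whisker_lo_mm"],
                "whishi": row["whisker_hi_mm"],
                "fliers": [],
            }
        )
    fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(boxes)), 4))
    ax.bxp(boxes, showfliers=False)
    if pitch is not None:
        ax.axhline(pitch["median_mm"], color="gray", ls="--", lw=1,
                   label=f"10-10 pitch median ({pitch['median_mm']:.0f} mm)")
        ax.legend(loc="upper right", fontsize=8)
    ax.set_ylabel("distance from centroid (mm)")
    ax.tick_params(axis="x", rotation=90, labelsize=6)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
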