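"""Virtual 10-20 / 10-10 scalp positioning from the four cranial fiducials.

Given a closed scalp mesh and the fiducials Nz (nasion), Iz (inion), AL and
AR (pre-auricular points), the vertex position Cz is found as the fixed
point of an alternating midpoint construction, after which the standard
scalp curves (midline, central coronal, circumferential ring and transverse
rows) are cut as plane sections and subdivided at the standard fractions.

The label/fraction tables live in ``data/montage_definitions.json`` and are
editable without code changes.  The classic 10-20 names T3/T4/T5/T6 are used
for the modern T7/T8/P7/P8.  Under the per-half subdivision convention used
here the 25-point 10-20 set (19 electrodes + Fpz + Oz + the four fiducials)
is an exact subset of the 10-10 montage.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .geometry import SurfaceArc, TriangleMesh, plane_section_arc

logger = logging.getLogger("scalpmap")


def _load_definitions() -> dict:
    with resources.files("scalpmap.data").joinpath("montage_definitions.json").open() as fh:
        return json.load(fh)


MONTAGE_DEFINITIONS = _load_definitions()

#: the 25 10-20 positions entering the head shape analysis
HEAD_1020_LABELS = (
    "Nz", "Iz", "AL", "AR",
    "Fpz", "Fp1", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "Oz", "O2",
)


class ConvergenceError(RuntimeError):
    """Raised when the Cz fixed-point iteration fails to converge."""


@dataclass
class TenTenMontage:
    """Labeled scalp positions with per-label curve/fraction provenance."""

    positions: dict  # label -> (3,) ndarray
    provenance: dict  # label -> (curve id, fraction along curve)
    fiducials: dict
    system: str

    def __len__(self):
        return len(self.positions)

    def labels(self):
        return sorted(self.positions.keys())

    def array(self, labels=None) -> np.ndarray:
        labels = list(labels) if labels is not None else self.labels()
        return np.array([self.positions[l] for l in labels])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label in self.labels():
            p = self.positions[label]
            curve, frac = self.provenance[label]
            rows.append((label, p[0], p[1], p[2], curve, frac))
        return pd.DataFrame(rows, columns=["label", "x_mm", "y_mm", "z_mm", "curve", "fraction"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, system: str = "10-10") -> "TenTenMontage":
        positions, provenance = {}, {}
        for _, row in df.iterrows():
            label = str(row["label"])
            positions[label] = np.array([row["x_mm"], row["y_mm"], row["z_mm"]], dtype=float)
            provenance[label] = (str(row["curve"]), float(row["fraction"]))
        fiducials = {k: positions[k] for k in ("Nz", "Iz", "AL", "AR") if k in positions}
        return cls(positions, provenance, fiducials, system)


def place_cz(
    mesh: TriangleMesh,
    nz,
    iz,
    al,
    ar,
    tol: float = 0.1,
    max_iter: int = 50,
    initial=None,
) -> np.ndarray:
    """Fixed point of the alternating midpoint construction for Cz.

    Cz is simultaneously the 50% point of the Nz->Cz->Iz arc and of the
    AL->Cz->AR arc; the iteration alternates the two midpoint updates until
    Cz moves less than ``tol`` mm.
    """
    nz, iz = np.asarray(nz, dtype=float), np.asarray(iz, dtype=float)
    al, ar = np.asarray(al, dtype=float), np.asarray(ar, dtype=float)
    if initial is None:
        cz = mesh.vertices[int(np.argmax(mesh.vertices[:, 2]))].copy()
    else:
        cz = np.asarray(initial, dtype=float)
    for it in range(1, max_iter + 1):
        sagittal = plane_section_arc(mesh, nz, iz, cz)
        cz_mid = sagittal.point_at_fraction(0.5)
        coronal = plane_section_arc(mesh, al, ar, cz_mid)
        cz_new = coronal.point_at_fraction(0.5)
        delta = float(np.linalg.norm(cz_new - cz))
        cz = cz_new
        if delta < tol:
            logger.info("Cz converged after %d iterations (moved %.4f mm)", it, delta)
            return cz
    raise ConvergenceError(f"Cz did not converge within {max_iter} iterations")


def _place_on_arc(arc: SurfaceArc, fractions: dict, curve: str, positions, provenance):
    for label, f in fractions.items():
        positions[label] = arc.point_at_fraction(float(f))
        provenance[label] = (curve, float(f))


def _place_on_span(arc, s_lo, s_hi, fractions, curve, positions, provenance):
    """Place labels at fractions of the [s_lo, s_hi] arc-length span."""
    for label, f in fractions.items():
        s = s_lo + float(f) * (s_hi - s_lo)
        positions[label] = arc.point_at_length(s)
        provenance[label] = (curve, s / arc.length)


def place_montage(
    mesh: TriangleMesh,
    fiducials: dict,
    system: str = "10-10",
    cz_tol: float = 0.1,
    max_iter: int = 50,
) -> TenTenMontage:
    """Place a full virtual montage on a scalp mesh from the four fiducials."""
    if system not in MONTAGE_DEFINITIONS:
        raise ValueError(f"unknown montage system {system!r}")
    defs = MONTAGE_DEFINITIONS[system]
    nz, iz = fiducials["Nz"], fiducials["Iz"]
    al, ar = fiducials["AL"], fiducials["AR"]
    positions = {"Nz": np.asarray(nz, float), "Iz": np.asarray(iz, float),
                 "AL": np.asarray(al, float), "AR": np.asarray(ar, float)}
    provenance = {k: ("fiducial", 0.0) for k in positions}

    cz = place_cz(mesh, nz, iz, al, ar, tol=cz_tol, max_iter=max_iter)
    midline = plane_section_arc(mesh, nz, iz, cz)
    _place_on_arc(midline, defs["midline"], "midline", positions, provenance)
    cz = positions["Cz"]

    coronal = plane_section_arc(mesh, al, ar, cz)
    _place_on_arc(coronal, defs["coronal"], "coronal", positions, provenance)

    fpz, oz = positions["Fpz"], positions["Oz"]
    for side, ring_key in (("left", "ring_left"), ("right", "ring_right")):
        t_label = "T3" if side == "left" else "T4"
        ring = plane_section_arc(mesh, fpz, oz, positions[t_label])
        s_t = ring.locate(positions[t_label])
        curve = ring_key
        _place_on_span(ring, 0.0, s_t, defs[ring_key]["q1"], curve, positions, provenance)
        _place_on_span(ring, s_t, ring.length, defs[ring_key]["q2"], curve, positions, provenance)

    for row in defs["rows"]:
        left, mid, right = positions[row["left"]], positions[row["mid"]], positions[row["right"]]
        arc = plane_section_arc(mesh, left, right, mid)
        s_m = arc.locate(mid)
        curve = f"row_{row['left']}_{row['right']}"
        _place_on_span(arc, 0.0, s_m, row["left_points"], curve, positions, provenance)
        _place_on_span(arc, s_m, arc.length, row["right_points"], curve, positions, provenance)

    fid = {k: positions[k] for k in ("Nz", "Iz", "AL", "AR")}
    montage = TenTenMontage(positions, provenance, fid, system)
    logger.info("placed %d %s positions", len(montage), system)
    return montage


def nearest_neighbor_distances(montage: TenTenMontage) -> dict:
    """Euclidean distance from each montage position to its nearest neighbor."""
    labels = montage.labels()
    if len(labels) < 2:
        raise ValueError("need at least two positions")
    pts = montage.array(labels)
    d = cdist(pts, pts)
    np.fill_diagonal(d, np.inf)
    return {label: float(d[i].min()) for i, label in enumerate(labels)}


def mirror_label(label: str) -> str:
    """Label of the left-right mirrored position (odd <-> even suffix)."""
    if label == "AL":
        return "AR"
    if label == "AR":
        return "AL"
    m = re.match(r"^([A-Za-z]+?)(\d+)$", label)
    if not m:
        return label  # z-line labels and Nz/Iz are their own mirrors
    stem, num = m.group(1), int(m.group(2))
    return f"{stem}{num + 1 if num % 2 == 1 else num - 1}"
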