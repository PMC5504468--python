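"""Topological-relationship statistics between cortical landmarks.

For selected triples (a, b, c) of landmarks the dimensionless ratio
d(a,b)/d(b,c) of Euclidean distances is computed -- either directly in 3-D,
or after projection onto the sagittal (x := 0) or coronal (y := 0) plane --
and correlated with age across a cohort.  A declining anterior-share ratio
(frontal pole ... occipital pole) means the middle landmark shifts
anteriorly; a declining vertex ... base ratio means a dorsal shift.

Junction landmarks picked on slice images tend to sit beneath the lateral
cortical surface, so before measuring they are adjusted laterally (along
+/-x) to the outermost brain-surface crossing, which removes variability in
the depth direction while preserving y and z.

The ratio table ships as ``data/table1_specs.tsv`` and is editable without
code changes; rows are keyed by their definition strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import (
    LandmarkSet,
    RayMissError,
    TriangleMesh,
    project,
    ray_surface_intersection,
)

logger = logging.getLogger("scalpmap")

#: landmarks adjusted to the cortical surface before ratio computation
#: (the sulcus/fissure junctions and roots picked on slice images)
ADJUSTED_LANDMARKS = (8, 9, 10, 11, 12, 20)

#: slice-dependent landmarks whose y coordinate is tied to landmark 11
SLICE_DEPENDENT_LANDMARKS = (16, 17, 18, 19)

_MODES = ("direct", "sagittal", "coronal")


class ZeroVarianceError(ValueError):
    """Raised when a correlation is requested for a constant sample."""


class UndefinedRatioError(ValueError):
    """Raised when the denominator distance of a ratio is zero."""


@dataclass(frozen=True)
class RatioSpec:
    """Distance-ratio d(a,b)/d(b,c) in one of the three measurement modes."""

    a: int
    b: int
    c: int
    mode: str = "direct"
    landmark_id: int | None = None
    definition: str | None = None
    decline_means: str = ""

    def __post_init__(self):
        if len({self.a, self.b, self.c}) != 3:
            raise ValueError("ratio landmarks must be distinct")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")

    @property
    def key(self) -> str:
        return self.definition or f"({self.a}-{self.b})/({self.b}-{self.c})"


@dataclass
class CorrelationResult:
    r: float
    n: int
    t: float
    p: float
    spec: RatioSpec | None = None

    def p_printed(self) -> float:
        """p to 3 decimals, round-half-even (table display convention)."""
        return float(np.round(self.p, 3))


def _load_table1_specs() -> list[RatioSpec]:
    with resources.files("scalpmap.data").joinpath("table1_specs.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return [
        RatioSpec(
            a=int(r["a"]), b=int(r["b"]), c=int(r["c"]), mode=str(r["mode"]),
            landmark_id=int(r["landmark_id"]), definition=str(r["definition"]),
            decline_means=str(r["decline_means"]),
        )
        for _, r in df.iterrows()
    ]


TABLE1_SPECS = _load_table1_specs()


# ---------------------------------------------------------------------------
# surface adjustment
# ---------------------------------------------------------------------------

def adjust_to_surface(point, brain: TriangleMesh, hemisphere: str) -> np.ndarray:
    """Move a landmark laterally to the outermost brain-surface crossing.

    The ray runs along +x for the right hemisphere and -x for the left,
    cast from the midline at the landmark's (y, z); y and z are unchanged.
    If the ray misses (landmark beyond the surface silhouette), the nearest
    surface vertex is used as a logged fallback.
    """
    p = np.asarray(point, dtype=float)
    direction = np.array([1.0, 0.0, 0.0]) if hemisphere == "R" else np.array([-1.0, 0.0, 0.0])
    origin = np.array([0.0, p[1], p[2]])
    try:
        return ray_surface_intersection(brain, origin, direction)
    except RayMissError:
        fallback = brain.nearest_vertex(p)
        logger.warning(
            "surface adjustment ray missed at (y=%.1f, z=%.1f); using nearest vertex", p[1], p[2]
        )
        return fallback


def impose_slice_dependents(ls: LandmarkSet, brain: TriangleMesh) -> LandmarkSet:
    """Re-impose the CS-tip coronal-slice constraint on landmarks 16-19.

    Their defining slice is the y coordinate of landmark 11, so y := y(11)
    and the point is re-projected laterally onto the brain surface (z kept).
    """
    out = ls.copy()
    for hemi in ("L", "R"):
        if (11, hemi) not in out.points:
            continue
        y11 = out.points[(11, hemi)][1]
        for lid in SLICE_DEPENDENT_LANDMARKS:
            if (lid, hemi) not in out.points:
                continue
            p = out.points[(lid, hemi)].copy()
            p[1] = y11
            out.points[(lid, hemi)] = adjust_to_surface(p, brain, hemi)
    return out


# ---------------------------------------------------------------------------
# ratios and correlations
# ---------------------------------------------------------------------------

def ratio(ls: LandmarkSet, spec: RatioSpec, hemisphere: str) -> float:
    """d(a,b)/d(b,c) after applying the spec's projection mode to all points."""
    pts = [ls.get(lid, hemisphere) for lid in (spec.a, spec.b, spec.c)]
    if spec.mode != "direct":
        plane = "sagittal" if spec.mode == "sagittal" else "coronal"
        pts = [project(p, plane) for p in pts]
    d_ab = float(np.linalg.norm(pts[0] - pts[1]))
    d_bc = float(np.linalg.norm(pts[1] - pts[2]))
    if d_bc < 1e-12:
        raise UndefinedRatioError(f"zero denominator distance for {spec.key}")
    return d_ab / d_bc


def pearson_with_p(xs, ys, spec: RatioSpec | None = None) -> CorrelationResult:
    """Pearson r with the exact two-tailed p from the t transform (n-2 df)."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    n = len(xs)
    if n != len(ys):
        raise ValueError("paired samples must have equal length")
    if n < 3:
        raise ValueError("need at least three pairs")
    sx, sy = xs.std(), ys.std()
    if sx < 1e-15 or sy < 1e-15:
        raise ZeroVarianceError("zero variance in one of the samples")
    r = float(np.clip(np.corrcoef(xs, ys)[0, 1], -1.0, 1.0))
    if abs(r) >= 1.0 - 1e-15:
        return CorrelationResult(r=r, n=n, t=np.inf * np.sign(r), p=0.0, spec=spec)
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return CorrelationResult(r=r, n=n, t=float(t), p=float(p), spec=spec)


def _prepare_set(ls: LandmarkSet, brain: TriangleMesh | None) -> LandmarkSet:
    if brain is None:
        return ls
    out = impose_slice_dependents(ls, brain)
    for (lid, hemi) in list(out.points):
        if lid in ADJUSTED_LANDMARKS:
            out.points[(lid, hemi)] = adjust_to_surface(out.points[(lid, hemi)], brain, hemi)
    return out


#: relative-variance threshold below which a ratio series is treated as
#: constant (r := 0, p := 1): the degenerate no-signal case of a
#: shape-preserving cohort
_CONST_RTOL = 1e-10


def table1_analysis(
    landmark_sets,
    brains: dict | None = None,
    specs=None,
    adjust: bool = True,
) -> pd.DataFrame:
    """Ratio/age Pearson correlations, one row per ratio spec and hemisphere.

    ``landmark_sets`` may be LandmarkSet objects or synthetic subjects (their
    ``.landmarks``/``.brain`` attributes are used).  ``brains`` optionally
    maps subject id to a brain mesh for surface adjustment.
    """
    sets, meshes = [], {}
    for item in landmark_sets:
        if hasattr(item, "landmarks"):
            sets.append(item.landmarks)
            if getattr(item, "brain", None) is not None:
                meshes[item.landmarks.subject_id] = item.brain
        else:
            sets.append(item)
    if brains:
        meshes.update(brains)
    if len(sets) < 3:
        raise ValueError("need at least three subjects")
    if specs is None:
        specs = TABLE1_SPECS
    if adjust and meshes:
        sets = [_prepare_set(ls, meshes.get(ls.subject_id)) for ls in sets]
    ages = np.array([ls.age_months for ls in sets], dtype=float)
    rows = []
    for spec in specs:
        for hemi in ("L", "R"):
            try:
                values = np.array([ratio(ls, spec, hemi) for ls in sets])
            except KeyError:
                logger.warning("missing landmark for %s %s; row skipped", spec.key, hemi)
                continue
            if values.std() <= _CONST_RTOL * (abs(values.mean()) + 1.0):
                res = CorrelationResult(r=0.0, n=len(values), t=0.0, p=1.0, spec=spec)
            else:
                res = pearson_with_p(ages, values, spec=spec)
            rows.append(
                {
                    "definition": spec.key,
                    "landmark_id": spec.landmark_id,
                    "hemisphere": hemi,
                    "mode": spec.mode,
                    "n": res.n,
                    "r": res.r,
                    "t": res.t,
                    "p": res.p,
                    "p_printed": res.p_printed(),
                    "decline_means": spec.decline_means,
                }
            )
    return pd.DataFrame(rows)


def axis_length_correlations(landmark_sets) -> pd.DataFrame:
    """Descriptive brain-size trends: length (2-5), height (1-4), width (|x| of 6)
    per hemisphere vs age, via the same Pearson machinery."""
    sets = [item.landmarks if hasattr(item, "landmarks") else item for item in landmark_sets]
    ages = np.array([ls.age_months for ls in sets], dtype=float)
    rows = []
    for hemi in ("L", "R"):
        measures = {
            "length": [np.linalg.norm(ls.get(2, hemi) - ls.get(5, hemi)) for ls in sets],
            "height": [np.linalg.norm(ls.get(1, hemi) - ls.get(4, hemi)) for ls in sets],
            "width": [abs(ls.get(6, hemi)[0]) for ls in sets],
        }
        for name, vals in measures.items():
            res = pearson_with_p(ages, np.array(vals))
            rows.append({"measure": name, "hemisphere": hemi, "n": res.n, "r": res.r, "p": res.p})
    return pd.DataFrame(rows)
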