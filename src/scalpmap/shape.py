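"""Generalized Procrustes analysis, shape-space PCA and age regression.

Configurations of homologous landmarks are translated to a common centroid,
scaled to unit centroid size (partial Procrustes) and rotated by proper
rotations to a consensus, iterating until the consensus is stable.  A PCA of
the flattened Procrustes coordinates then describes the main modes of shape
variation, and per-subject component scores are regressed on age to detect
developmental trends.

Two configuration sets are conventional here: the "cortex" set (the ten
sulcal/fissural landmarks 7-15 and 20 on each hemisphere, k = 20) and the
"head" set (the 25-point virtual 10-20 montage, k = 25).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import LandmarkSet
from .metrics import CorrelationResult, pearson_with_p
from .montage import HEAD_1020_LABELS, TenTenMontage

logger = logging.getLogger("scalpmap")

#: cortical landmark ids entering the shape analysis (per hemisphere)
CORTEX_LANDMARK_IDS = (7, 8, 9, 10, 11, 12, 13, 14, 15, 20)
CORTEX_LABELS = tuple((lid, hemi) for hemi in ("L", "R") for lid in CORTEX_LANDMARK_IDS)


class DegenerateConfigurationError(ValueError):
    """Raised when a configuration has rank < 3 (alignment is undefined)."""


class GPAConvergenceError(RuntimeError):
    pass


@dataclass
class Configuration:
    """One subject's ordered landmark configuration (k x 3, mm)."""

    subject_id: str
    age_months: float
    labels: tuple
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.labels), 3):
            raise ValueError("coords must be (k, 3) matching labels")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")


def configuration_from_landmarks(
    ls: LandmarkSet, labels=CORTEX_LABELS
) -> Configuration:
    coords = np.array([ls.get(lid, hemi) for lid, hemi in labels])
    return Configuration(ls.subject_id, ls.age_months, tuple(labels), coords)


def configuration_from_montage(
    montage: TenTenMontage, subject_id: str, age_months: float, labels=HEAD_1020_LABELS
) -> Configuration:
    coords = montage.array(labels)
    return Configuration(subject_id, age_months, tuple(labels), coords)


@dataclass
class ShapeSpace:
    """Procrustes-aligned configurations with optional PCA results."""

    labels: tuple
    subject_ids: list
    ages: np.ndarray
    consensus: np.ndarray          # (k, 3), centroid 0, unit centroid size
    aligned: np.ndarray            # (n, k, 3)
    centroid_sizes: np.ndarray     # (n,), mm
    n_iterations: int
    loadings: np.ndarray | None = field(default=None)
    scores: np.ndarray | None = field(default=None)
    variance_fractions: np.ndarray | None = field(default=None)


def centroid_size(config) -> float:
    """Square root of the summed squared landmark distances from the centroid."""
    coords = config.coords if isinstance(config, Configuration) else np.asarray(config, float)
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt(np.sum(centered**2)))


def _proper_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimizing ||a @ R - b||_F.  Reflections forbidden."""
    u, _, vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


def _canonical_rotation(consensus: np.ndarray) -> np.ndarray:
    """Deterministic orientation: consensus principal axes onto x, y, z.

    Makes the aligned coordinates invariant to rigid pre-transforms of the
    inputs and to input ordering (up to convergence tolerance).
    """
    u, _, vt = np.linalg.svd(consensus, full_matrices=False)
    # sign-fix via the left singular vectors (per-landmark weights), which do
    # not depend on the ambient coordinate basis
    for i in range(2):
        j = int(np.argmax(np.abs(u[:, i])))
        if u[j, i] < 0:
            vt[i] = -vt[i]
    v1, v2 = vt[0], vt[1]
    v3 = np.cross(v1, v2)
    return np.column_stack([v1, v2, v3])


def gpa(configs, tol: float = 1e-8, max_iter: int = 100) -> ShapeSpace:
    """Generalized (partial) Procrustes alignment to a consensus.

    Each configuration is centered, scaled to unit centroid size and rotated
    by the optimal proper rotation to the running consensus; the consensus is
    the mean of the aligned configurations, renormalized, and the loop stops
    when it moves less than ``tol``.
    """
    configs = list(configs)
    if len(configs) < 2:
        raise ValueError("GPA needs at least two configurations")
    labels = configs[0].labels
    for c in configs:
        if c.labels != labels:
            raise ValueError("all configurations must share one ordered label list")
    X, sizes = [], []
    for c in configs:
        centered = c.coords - c.coords.mean(axis=0)
        size = np.sqrt(np.sum(centered**2))
        if size < 1e-12:
            raise DegenerateConfigurationError(f"{c.subject_id}: all landmarks coincide")
        x = centered / size
        if np.linalg.svd(x, compute_uv=False)[-1] < 1e-10:
            raise DegenerateConfigurationError(f"{c.subject_id}: configuration has rank < 3")
        X.append(x)
        sizes.append(size)
    X = np.array(X)
    consensus = X[0].copy()
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        aligned = np.array([x @ _proper_rotation(x, consensus) for x in X])
        new_consensus = aligned.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        new_consensus /= np.sqrt(np.sum(new_consensus**2))
        delta = float(np.linalg.norm(new_consensus - consensus))
        consensus = new_consensus
        if delta < tol:
            break
    else:
        raise GPAConvergenceError(f"consensus not stable after {max_iter} iterations")
    aligned = np.array([x @ _proper_rotation(x, consensus) for x in X])
    rot = _canonical_rotation(consensus)
    consensus = consensus @ rot
    aligned = aligned @ rot
    logger.info("GPA converged in %d iterations (k=%d, n=%d)", n_iter, len(labels), len(configs))
    return ShapeSpace(
        labels=labels,
        subject_ids=[c.subject_id for c in configs],
        ages=np.array([c.age_months for c in configs], dtype=float),
        consensus=consensus,
        aligned=aligned,
        centroid_sizes=np.array(sizes),
        n_iterations=n_iter,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Root summed squared deviation between two unit-size centered configs
    after the optimal proper rotation."""
    r = _proper_rotation(a, b)
    return float(np.linalg.norm(a @ r - b))


def pca_shapes(space: ShapeSpace):
    """PCA of mean-centered flattened Procrustes coordinates.

    Returns ``(loadings, scores, variance_fractions)`` and stores them on the
    shape space.  Scores reproduce the data exactly (mean + scores @ loadings)
    and each component's largest-magnitude loading element is positive.
    """
    n = space.aligned.shape[0]
    if n < 3:
        raise ValueError("PCA needs at least three subjects")
    flat = space.aligned.reshape(n, -1)
    mean = flat.mean(axis=0)
    centered = flat - mean
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    scores = u * s
    loadings = vt
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    total = np.sum(s**2)
    fractions = (s**2) / total if total > 0 else np.zeros_like(s)
    space.loadings = loadings
    space.scores = scores
    space.variance_fractions = fractions
    return loadings, scores, fractions


def regress_scores_on_age(scores, ages) -> CorrelationResult:
    """Pearson correlation (with two-tailed t-test p) of PC scores vs age."""
    return pearson_with_p(np.asarray(ages, float), np.asarray(scores, float))
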