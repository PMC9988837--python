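"""Symmetrization and generalized Procrustes alignment of landmark cohorts.

Configurations are symmetrized by averaging each face with its relabelled
mirror image (X negated, landmarks re-indexed by the template's bilateral
pairing), then superimposed by generalized Procrustes analysis (GPA) with
scaling so that only shape differences remain. Centroid sizes are recorded
before scaling so they can enter the covariate model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import CohortShapes
from .synthetic_cohort import Template

__all__ = [
    "AlignedCohort",
    "centroid_size",
    "reflect_and_pair",
    "symmetrize",
    "symmetrize_cohort",
    "gpa",
    "procrustes_distance",
]


@dataclass
class AlignedCohort:
    """GPA output: aligned shapes, their mean, and pre-scaling sizes."""

    shapes: CohortShapes
    mean_shape: np.ndarray
    centroid_sizes: np.ndarray
    iterations_used: int
    converged: bool


def centroid_size(config: np.ndarray) -> float:
    """Square root of the summed squared landmark distances to the centroid
    — the standard geometric-morphometrics size measure."""
    config = np.asarray(config, dtype=float)
    if config.ndim != 2 or config.shape[0] < 3:
        raise ValueError("configuration must be (L>=3, d)")
    if not np.isfinite(config).all():
        raise ValueError("configuration contains non-finite coordinates")
    centred = config - config.mean(axis=0)
    size = float(np.sqrt((centred ** 2).sum()))
    if size == 0.0:
        warnings.warn("all landmarks coincident: centroid size is 0")
    return size


def reflect_and_pair(config: np.ndarray, template: Template) -> np.ndarray:
    """Mirror a configuration: negate X, then re-index landmarks by the
    bilateral pairing so index i again denotes the same anatomical point."""
    config = np.asarray(config, dtype=float)
    if config.shape != (template.n_landmarks, 3):
        raise ValueError(
            f"configuration shape {config.shape} does not match template "
            f"({template.n_landmarks}, 3)")
    reflected = config.copy()
    reflected[:, 0] *= -1
    return reflected[template.symmetry_pairing]


def symmetrize(config: np.ndarray, template: Template) -> np.ndarray:
    """Average a configuration with its relabelled reflection.

    The result is an exact fixed point of :func:`reflect_and_pair` and the
    operation is idempotent.
    """
    return 0.5 * (np.asarray(config, dtype=float) + reflect_and_pair(config, template))


def symmetrize_cohort(cohort: CohortShapes, template: Template) -> CohortShapes:
    out = np.empty_like(cohort.coords)
    for i in range(cohort.n):
        out[i] = symmetrize(cohort.coords[i], template)
    return CohortShapes(list(cohort.ids), out)


def _optimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimizing ||a @ R - b||_F."""
    u, s, vt = np.linalg.svd(a.T @ b)
    if np.linalg.det(u @ vt) < 0:
        u[:, -1] *= -1
    return u @ vt


def gpa(cohort: CohortShapes, scale: bool = True, tol: float = 1e-8,
        max_iter: int = 100) -> AlignedCohort:
    """Generalized Procrustes analysis with optional scaling.

    Iterative scheme: centre every configuration and (if ``scale``) scale to
    unit centroid size; rotate each configuration onto the current mean
    (optimal orthogonal rotation, reflections disallowed); recompute the
    mean; rescale it to unit size and rotate it onto the anchor
    configuration's initial orientation so the output frame is reproducible.
    The anchor is the configuration with the lexicographically smallest id,
    making the result invariant to input row order.
    Stops when the RMS change of the mean drops below ``tol``.
    """
    X = np.array(cohort.coords, dtype=float)
    n, L, _ = X.shape
    if n < 2:
        raise ValueError("GPA needs at least 2 configurations")
    if L < 3:
        raise ValueError("GPA needs at least 3 landmarks")

    sizes = np.empty(n)
    for i in range(n):
        X[i] -= X[i].mean(axis=0)
        if np.linalg.matrix_rank(X[i]) < 3:
            raise ValueError(
                f"configuration {cohort.ids[i]!r} is degenerate (rank < 3)")
        sizes[i] = np.sqrt((X[i] ** 2).sum())
        if sizes[i] == 0:
            raise ValueError(f"configuration {cohort.ids[i]!r} has zero size")
        if scale:
            X[i] /= sizes[i]

    anchor = X[min(range(n), key=lambda i: str(cohort.ids[i]))].copy()
    mean = anchor / np.sqrt((anchor ** 2).sum())
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            X[i] = X[i] @ _optimal_rotation(X[i], mean)
        new_mean = X.mean(axis=0)
        new_mean /= np.sqrt((new_mean ** 2).sum())
        new_mean = new_mean @ _optimal_rotation(new_mean, anchor)
        delta = np.sqrt(((new_mean - mean) ** 2).mean())
        mean = new_mean
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"GPA did not converge in {max_iter} iterations")
    # final pass so every configuration faces the converged mean
    for i in range(n):
        X[i] = X[i] @ _optimal_rotation(X[i], mean)

    return AlignedCohort(
        shapes=CohortShapes(list(cohort.ids), X),
        mean_shape=X.mean(axis=0),
        centroid_sizes=sizes,
        iterations_used=iterations,
        converged=converged,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Full Procrustes distance between two configurations (centred, unit
    centroid size, optimally rotated)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    a /= np.sqrt((a ** 2).sum())
    b /= np.sqrt((b ** 2).sum())
    rot = _optimal_rotation(a, b)
    return float(np.sqrt(((a @ rot - b) ** 2).sum()))
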