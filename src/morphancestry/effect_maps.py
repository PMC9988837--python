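"""Per-landmark summaries of shape differences.

Three summaries describe how a face changes under ancestry correction:

* **normal displacement** — the signed component of each landmark's
  displacement along the local surface normal (positive = outward), the
  magnitude-of-change map;
* **angle difference** — the angle in degrees between two displacement
  vectors at the same landmark, the direction-of-change comparison between
  two effects;
* **maximum ancestry shift** — per landmark, the largest pre- vs
  post-correction Euclidean distance over all individuals.

Normals are computed on the base (pre-effect) face as area-weighted averages
of incident triangle normals; the synthetic template's winding makes +z the
outward direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import CohortShapes

__all__ = [
    "EffectMap",
    "vertex_normals",
    "normal_displacement",
    "angle_difference",
    "max_ancestry_shift",
    "compare_correction_methods",
]


@dataclass
class EffectMap:
    """Displacement vectors with their derived scalar maps."""

    displacement_vectors: np.ndarray        # (L, 3)
    normal_displacement: np.ndarray         # (L,), signed
    reference_face: np.ndarray              # (L, 3)
    normals: np.ndarray                     # (L, 3), unit
    angle_difference: np.ndarray | None = None  # (L,), degrees, vs another effect

    def summary(self) -> dict:
        out = {
            "normal_displacement_min": float(self.normal_displacement.min()),
            "normal_displacement_max": float(self.normal_displacement.max()),
            "normal_displacement_rms": float(
                np.sqrt((self.normal_displacement ** 2).mean())),
        }
        if self.angle_difference is not None:
            out["angle_mean_deg"] = float(self.angle_difference.mean())
            out["angle_max_deg"] = float(self.angle_difference.max())
        return out


def vertex_normals(face: np.ndarray, triangulation: np.ndarray) -> np.ndarray:
    """Unit vertex normals as area-weighted averages of incident triangle
    normals. Every vertex must belong to at least one triangle; zero-area
    triangles are skipped with a warning."""
    face = np.asarray(face, dtype=float)
    tris = np.asarray(triangulation, dtype=int)
    L = len(face)
    covered = np.zeros(L, dtype=bool)
    covered[tris.ravel()] = True
    if not covered.all():
        missing = np.flatnonzero(~covered)
        raise ValueError(f"isolated vertices (no incident triangle): "
                         f"{missing[:10].tolist()}")
    a, b, c = face[tris[:, 0]], face[tris[:, 1]], face[tris[:, 2]]
    cross = np.cross(b - a, c - a)          # magnitude = 2 * area
    areas = np.linalg.norm(cross, axis=1)
    zero = areas == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-area triangles skipped")
    normals = np.zeros((L, 3))
    for k in range(3):
        np.add.at(normals, tris[:, k], cross)
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    if (norms == 0).any():
        raise ValueError("degenerate normal (all incident triangles zero-area)")
    return normals / norms


def normal_displacement(face_a: np.ndarray, face_b: np.ndarray,
                        normals: np.ndarray) -> np.ndarray:
    """Signed per-landmark displacement of ``face_b`` relative to ``face_a``
    along ``normals`` (positive = outward)."""
    face_a = np.asarray(face_a, dtype=float)
    face_b = np.asarray(face_b, dtype=float)
    normals = np.asarray(normals, dtype=float)
    if face_a.shape != face_b.shape or face_a.shape != normals.shape:
        raise ValueError("face_a, face_b and normals must share shape (L, 3)")
    lengths = np.linalg.norm(normals, axis=1)
    if np.abs(lengths - 1).max() > 1e-6:
        raise ValueError("normals must be unit length")
    return ((face_b - face_a) * normals).sum(axis=1)


def angle_difference(effect_a: np.ndarray, effect_b: np.ndarray,
                     eps: float = 1e-9) -> np.ndarray:
    """Per-landmark angle (degrees, in [0, 180]) between two displacement
    fields; 0 where either vector is shorter than ``eps``."""
    effect_a = np.asarray(effect_a, dtype=float)
    effect_b = np.asarray(effect_b, dtype=float)
    if effect_a.shape != effect_b.shape:
        raise ValueError("effect fields must share shape")
    if eps < 0:
        raise ValueError("eps must be >= 0")
    na = np.linalg.norm(effect_a, axis=1)
    nb = np.linalg.norm(effect_b, axis=1)
    small = (na < eps) | (nb < eps)
    denom = np.where(small, 1.0, na * nb)
    cosine = (effect_a * effect_b).sum(axis=1) / denom
    angles = np.degrees(np.arccos(np.clip(cosine, -1.0, 1.0)))
    angles[small] = 0.0
    return angles


def max_ancestry_shift(before: CohortShapes, after: CohortShapes) -> np.ndarray:
    """Per landmark, the maximum over individuals of the Euclidean distance
    between the pre- and post-correction landmark positions."""
    if before.ids != after.ids or before.coords.shape != after.coords.shape:
        raise ValueError("before/after cohorts do not match")
    dist = np.linalg.norm(before.coords - after.coords, axis=2)  # (n, L)
    return dist.max(axis=0)


def compare_correction_methods(pc_faces: dict[str, np.ndarray],
                               consensus_faces: dict[str, np.ndarray],
                               base_face: np.ndarray,
                               triangulation: np.ndarray
                               ) -> dict[str, EffectMap]:
    """Compare the genetic-PC and consensus descriptions of each region.

    Both regional faces are expressed relative to the shared base face;
    per region, the returned map carries the displacement between the two
    method outputs, its component along the base-face normals, and the angle
    between the two effects (consensus minus base vs PC minus base).
    """
    if set(pc_faces) != set(consensus_faces):
        raise ValueError(
            f"region sets differ: {sorted(pc_faces)} vs {sorted(consensus_faces)}")
    base_face = np.asarray(base_face, dtype=float)
    normals = vertex_normals(base_face, triangulation)
    out = {}
    for region in pc_faces:
        pc_face = np.asarray(pc_faces[region], dtype=float)
        cons_face = np.asarray(consensus_faces[region], dtype=float)
        out[region] = EffectMap(
            displacement_vectors=cons_face - pc_face,
            normal_displacement=normal_displacement(pc_face, cons_face, normals),
            reference_face=base_face,
            normals=normals,
            angle_difference=angle_difference(cons_face - base_face,
                                              pc_face - base_face),
        )
    return out
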