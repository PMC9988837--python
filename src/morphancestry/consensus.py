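"""Regional consensus faces and consensus-based ancestry correction.

A consensus face is the mean landmark configuration of a regional group
after covariate correction and Procrustes alignment — a phenotypic (rather
than genetic) description of regional facial ancestry. Correcting an
individual subtracts its region's consensus and adds back the cohort grand
mean; the admixture-weighted variant subtracts a Q-weighted mixture of
consensus faces instead, which reduces to the plain correction when Q is an
indicator row.

Consensus stores serialize to JSON so they can be shared across research
groups: a consensus face describes no individual.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import CohortShapes, GeneticPCs
from .shape_align import gpa
from .perm_test import subgroup_tests

__all__ = [
    "ConsensusFace",
    "ConsensusStore",
    "build_consensus",
    "consensus_correct",
    "weighted_consensus_correct",
    "apply_consensus_correction",
    "retest_after_consensus",
    "MIN_ADVISABLE_MEMBERS",
]

#: Below this group size a consensus average is considered unreliable.
MIN_ADVISABLE_MEMBERS = 30


@dataclass
class ConsensusFace:
    region: str
    mean_shape: np.ndarray      # (L, 3)
    n_members: int


@dataclass
class ConsensusStore:
    faces: dict[str, ConsensusFace]
    grand_mean: np.ndarray      # (L, 3)
    aligned_shapes: CohortShapes  # full corrected cohort in the store frame

    @property
    def regions(self) -> list[str]:
        return list(self.faces)

    def consensus(self, region: str) -> np.ndarray:
        if region not in self.faces:
            raise KeyError(f"no consensus face for region {region!r}; "
                           f"store has {self.regions}")
        return self.faces[region].mean_shape

    def save(self, directory: str | Path) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        manifest = {"regions": {}, "n_landmarks": int(self.grand_mean.shape[0])}
        for region, face in self.faces.items():
            path = directory / f"consensus_{region}.json"
            path.write_text(json.dumps({
                "region": region,
                "n_members": face.n_members,
                "mean_shape": face.mean_shape.tolist(),
            }))
            manifest["regions"][region] = {
                "file": path.name, "n_members": face.n_members}
            written.append(path)
        gm = directory / "grand_mean.json"
        gm.write_text(json.dumps({"mean_shape": self.grand_mean.tolist()}))
        written.append(gm)
        mf = directory / "manifest.json"
        mf.write_text(json.dumps(manifest, indent=1))
        written.append(mf)
        return written


def build_consensus(corrected_shapes: CohortShapes, labels,
                    run_gpa: bool = True) -> ConsensusStore:
    """Average the covariate-corrected faces per region.

    The full corrected cohort is first re-aligned by GPA (all faces must
    share one frame for consensus subtraction to be meaningful); per-region
    arithmetic means and the cohort grand mean are then taken in that frame.
    """
    labels = np.asarray(labels)
    if len(labels) != corrected_shapes.n:
        raise ValueError("labels length does not match cohort")
    regions = list(dict.fromkeys(labels.tolist()))
    for region in regions:
        n_r = int((labels == region).sum())
        if n_r < 2:
            raise ValueError(f"region {region!r} has {n_r} member(s); need >= 2")
        if n_r < MIN_ADVISABLE_MEMBERS:
            warnings.warn(
                f"region {region!r} has only {n_r} members; consensus faces "
                f"are considered robust from ~{MIN_ADVISABLE_MEMBERS}")
    shapes = gpa(corrected_shapes).shapes if run_gpa else corrected_shapes
    faces = {}
    for region in regions:
        mask = labels == region
        faces[region] = ConsensusFace(
            region=region,
            mean_shape=shapes.coords[mask].mean(axis=0),
            n_members=int(mask.sum()),
        )
    return ConsensusStore(
        faces=faces,
        grand_mean=shapes.coords.mean(axis=0),
        aligned_shapes=shapes,
    )


def consensus_correct(face: np.ndarray, region: str,
                      store: ConsensusStore) -> np.ndarray:
    """``corrected = face - consensus(region) + grand_mean``."""
    face = np.asarray(face, dtype=float)
    return face - store.consensus(region) + store.grand_mean


def weighted_consensus_correct(face: np.ndarray, q_row: np.ndarray,
                               store: ConsensusStore) -> np.ndarray:
    """Admixture-weighted correction: subtract the Q-weighted mixture of
    consensus faces. Reduces to :func:`consensus_correct` when ``q_row`` is
    an indicator."""
    face = np.asarray(face, dtype=float)
    q_row = np.asarray(q_row, dtype=float)
    if len(q_row) != len(store.faces):
        raise ValueError("one weight per stored region required")
    if abs(q_row.sum() - 1.0) > 1e-6:
        raise ValueError(f"admixture weights sum to {q_row.sum():.6g}, not 1")
    mixture = np.tensordot(
        q_row, np.stack([f.mean_shape for f in store.faces.values()]), axes=1)
    return face - mixture + store.grand_mean


def apply_consensus_correction(store: ConsensusStore, labels=None,
                               q: np.ndarray | None = None) -> CohortShapes:
    """Correct every individual in the store's aligned cohort, by region
    label (indicator mode) or by admixture proportions (weighted mode)."""
    shapes = store.aligned_shapes
    out = np.empty_like(shapes.coords)
    if q is not None:
        q = np.asarray(q, dtype=float)
        for i in range(shapes.n):
            out[i] = weighted_consensus_correct(shapes.coords[i], q[i], store)
    elif labels is not None:
        labels = np.asarray(labels)
        for i in range(shapes.n):
            out[i] = consensus_correct(shapes.coords[i], labels[i], store)
    else:
        raise ValueError("supply labels (indicator mode) or q (weighted mode)")
    return CohortShapes(list(shapes.ids), out)


def retest_after_consensus(store: ConsensusStore, pcs: GeneticPCs, labels,
                           groups=None, pc_list=None, combos=None,
                           var_threshold: float = 0.96, B: int = 10_000,
                           seed: int | None = None,
                           q: np.ndarray | None = None) -> pd.DataFrame:
    """Re-run the genetic-PC permutation tests after consensus correction.

    Returns the test table on the pre-correction cohort merged with the
    post-correction one (columns ``p_before``/``p_after``), so the collapse
    of region-aligned PCs to non-significance can be read off directly.
    """
    labels = np.asarray(labels)
    before = subgroup_tests(pcs.scores, store.aligned_shapes, labels,
                            groups=groups, pc_list=pc_list, combos=combos,
                            var_threshold=var_threshold, B=B, seed=seed)
    corrected = apply_consensus_correction(store, labels=labels, q=q)
    after = subgroup_tests(pcs.scores, corrected, labels,
                           groups=groups, pc_list=pc_list, combos=combos,
                           var_threshold=var_threshold, B=B, seed=seed)
    merged = before.merge(
        after, on=["group", "predictor_set", "n"],
        suffixes=("_before", "_after"))
    return merged
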