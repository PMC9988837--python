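"""PLSR shape regression: covariate correction, genetic-ancestry correction
and per-PC / per-region facial ancestry effects.

The cohort's aligned landmark matrix (n x 3L) is regressed onto predictors
with partial least squares regression (PLS2). Corrected faces are the
regression residuals with the mean shape added back, so correction preserves
the grand mean exactly. With ``n_components`` equal to the number of
predictors and a full-rank design, the PLSR fit coincides with multivariate
ordinary least squares — the default, which makes the correction
deterministic and oracle-checkable.

The "genetic facial ancestry effect" of an individual is the displacement
between its face before and after regressing out genetic ancestry PCs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .io_formats import CohortShapes, GeneticPCs

__all__ = [
    "PLSRModel",
    "CorrectedCohort",
    "AncestryEffect",
    "fit_plsr",
    "correct",
    "ancestry_correct",
    "single_pc_effect",
    "exaggerate",
]

#: Covariates entering the initial (non-ancestry) correction, in order.
STANDARD_COVARIATES = ("sex", "age", "age_squared", "height", "weight",
                       "centroid_size", "camera")


@dataclass
class PLSRModel:
    """A fitted PLS2 regression of flattened shapes on predictors.

    Predictors are standardized (unit variance) and shapes centred
    internally; ``coefficients`` maps standardized predictors to centred
    responses, so ``predict`` handles the de/re-normalization.
    """

    predictor_names: list[str]
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    coefficients: np.ndarray        # (p, 3L)
    n_components: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xs = (X - self.x_mean) / self.x_scale
        return Xs @ self.coefficients + self.y_mean


@dataclass
class CorrectedCohort:
    """Shapes with predictor effects regressed out; grand mean preserved."""

    shapes: CohortShapes
    model: PLSRModel
    grand_mean: np.ndarray          # (L, 3)


@dataclass
class AncestryEffect:
    """Per-individual and per-region displacement fields (before minus
    after ancestry correction)."""

    per_individual: np.ndarray      # (n, L, 3)
    per_region: dict[str, np.ndarray]  # region -> (L, 3)


def fit_plsr(X: np.ndarray, Y: np.ndarray, n_components: int | None = None,
             predictor_names: list[str] | None = None) -> PLSRModel:
    """Fit PLS2 of responses ``Y`` (n x q) on predictors ``X`` (n x p).

    ``n_components`` defaults to p. Constant (zero-variance) predictors are
    rejected; rank-deficient designs reduce the component count with a
    warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("X and Y row counts differ")
    if n <= p:
        raise ValueError(f"need n > p predictors (n={n}, p={p})")

    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=1)
    zero_var = x_scale <= 0
    if zero_var.any():
        names = predictor_names or [f"x{i}" for i in range(p)]
        bad = [names[i] for i in np.flatnonzero(zero_var)]
        raise ValueError(f"constant (zero-variance) predictors: {bad}")
    Xs = (X - x_mean) / x_scale

    if n_components is None:
        n_components = p
    if not 1 <= n_components <= min(p, n - 1):
        raise ValueError(
            f"n_components={n_components} outside [1, min(p, n-1)={min(p, n - 1)}]")
    rank = np.linalg.matrix_rank(Xs)
    if n_components > rank:
        warnings.warn(
            f"design rank {rank} < requested {n_components} components; reducing")
        n_components = rank

    y_mean = Y.mean(axis=0)
    pls = PLSRegression(n_components=n_components, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn may warn on tiny residual blocks
        pls.fit(Xs, Y - y_mean)
    coefficients = np.asarray(pls.coef_).T  # sklearn stores (q, p)

    return PLSRModel(
        predictor_names=list(predictor_names) if predictor_names else
        [f"x{i}" for i in range(p)],
        x_mean=x_mean, x_scale=x_scale, y_mean=y_mean,
        coefficients=coefficients, n_components=n_components,
    )


def correct(cohort: CohortShapes, X: np.ndarray,
            n_components: int | None = None,
            predictor_names: list[str] | None = None) -> CorrectedCohort:
    """Regress shapes on ``X`` and return residuals + mean shape.

    ``corrected_i = y_i - predicted_i + y_mean``: predictor effects are
    removed while the grand mean is preserved exactly.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != cohort.n:
        raise ValueError("predictor rows do not match cohort size")
    n, L = cohort.n, cohort.n_landmarks
    Y = cohort.coords.reshape(n, 3 * L)
    model = fit_plsr(X, Y, n_components, predictor_names)
    corrected = Y - model.predict(X) + model.y_mean
    return CorrectedCohort(
        shapes=CohortShapes(list(cohort.ids), corrected.reshape(n, L, 3)),
        model=model,
        grand_mean=model.y_mean.reshape(L, 3),
    )


def ancestry_correct(corrected: CorrectedCohort, pcs: GeneticPCs, k: int = 4,
                     labels=None) -> tuple[CorrectedCohort, AncestryEffect]:
    """Regress covariate-corrected shapes on the first ``k`` genetic PCs.

    Returns the ancestry-corrected cohort and the facial ancestry effect:
    per-individual ``before - after`` displacement fields, averaged per
    region when ``labels`` are given.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > pcs.n_pcs:
        raise ValueError(f"k={k} exceeds available PCs ({pcs.n_pcs})")
    if pcs.ids != corrected.shapes.ids:
        raise ValueError("PC ids do not align with cohort ids")
    X = pcs.scores[:, :k]
    names = [f"PC{j+1}" for j in range(k)]
    variable = X.std(axis=0, ddof=1) > 0
    if not variable.all():
        dropped = [names[j] for j in np.flatnonzero(~variable)]
        warnings.warn(f"constant ancestry PCs carry no effect, dropped: {dropped}")
        X, names = X[:, variable], [n_ for n_, v in zip(names, variable) if v]
    if X.shape[1] == 0:
        # nothing to regress out: identity correction, zero effect
        out = CorrectedCohort(
            shapes=CohortShapes(list(corrected.shapes.ids),
                                corrected.shapes.coords.copy()),
            model=corrected.model,
            grand_mean=corrected.shapes.coords.mean(axis=0))
    else:
        out = correct(corrected.shapes, X, predictor_names=names)
    effect = corrected.shapes.coords - out.shapes.coords

    per_region: dict[str, np.ndarray] = {}
    if labels is not None:
        labels = np.asarray(labels)
        for region in dict.fromkeys(labels.tolist()):
            per_region[region] = effect[labels == region].mean(axis=0)
    return out, AncestryEffect(per_individual=effect, per_region=per_region)


def single_pc_effect(corrected: CorrectedCohort, pcs: GeneticPCs,
                     exclude: int, k: int = 4
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Facial effect attributable to one ancestry PC.

    The leave-one-out contrast: correct with all ``k`` PCs versus with
    ``k - 1`` (PC ``exclude``, 1-based, left out); the per-individual
    difference between the reduced-model face and the full-model face is the
    displacement the excluded PC removes — its facial effect, signed like
    the total ancestry effect (before minus after).

    Returns (per-individual (n, L, 3) fields, cohort-mean (L, 3) field).
    The cohort mean vanishes by construction for centred predictors; the
    informative averages are per region (pass the per-individual fields
    through a label mask, as the pipeline does).
    """
    if not 1 <= exclude <= k:
        raise ValueError(f"exclude={exclude} outside 1..{k}")
    full, _ = ancestry_correct(corrected, pcs, k=k)
    keep = [j for j in range(k) if j != exclude - 1]
    reduced = correct(corrected.shapes, pcs.scores[:, keep],
                      predictor_names=[f"PC{j+1}" for j in keep])
    per_indiv = reduced.shapes.coords - full.shapes.coords
    return per_indiv, per_indiv.mean(axis=0)


def exaggerate(base_face: np.ndarray, effect: np.ndarray,
               factor: float) -> np.ndarray:
    """Add an effect field onto a base face amplified for visualization
    (statistics never use exaggerated faces)."""
    base_face = np.asarray(base_face, dtype=float)
    effect = np.asarray(effect, dtype=float)
    if not (np.isfinite(base_face).all() and np.isfinite(effect).all()):
        raise ValueError("non-finite inputs")
    return base_face + factor * effect
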