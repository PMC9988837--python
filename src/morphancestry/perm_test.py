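"""Permutation tests of the shape variance explained by predictor sets.

Shape variation is first reduced by PCA of the landmark coordinates,
retaining the components that cumulatively explain a target fraction of
variance (96% by default) and normalizing their scores to unit variance.
Predictor sets (single genetic PCs or combinations) are then evaluated by
the total R² of a full-component PLSR of the retained scores on the
predictors, with a permutation null built by re-randomizing the
predictor-to-individual assignment.

Two R² weightings are exposed: "eigenvalue" weights each shape component by
its variance (the headline "% of facial variation explained") and "unit"
weights components equally (matching the unit-variance normalized scores).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CohortShapes

__all__ = [
    "ShapePCA",
    "PermutationResult",
    "shape_pca",
    "total_r2",
    "permutation_test",
    "exact_permutation_test",
    "subgroup_tests",
    "DEFAULT_GROUPS",
]


@dataclass
class ShapePCA:
    """PCA reduction of a landmark cohort.

    ``scores`` are unit-variance normalized; ``eigenvalues`` keep the
    original component variances for back-weighting.
    """

    loadings: np.ndarray        # (3L, m)
    eigenvalues: np.ndarray     # (m,)
    scores: np.ndarray          # (n, m), unit variance
    mean: np.ndarray            # (3L,)
    var_threshold: float
    m_retained: int
    total_variance: float       # summed variance over ALL components

    @property
    def retained_fraction(self) -> float:
        return float(self.eigenvalues.sum() / self.total_variance)


@dataclass
class PermutationResult:
    r2_observed: float
    p_value: float
    n_permutations: int
    seed: int | None
    r2_null: np.ndarray | None = field(default=None, repr=False)


def shape_pca(shapes: CohortShapes | np.ndarray,
              var_threshold: float = 0.96) -> ShapePCA:
    """PCA of the centred landmark-coordinate matrix, keeping the smallest
    number of components whose cumulative variance fraction reaches
    ``var_threshold``."""
    if not 0 < var_threshold <= 1:
        raise ValueError("var_threshold must lie in (0, 1]")
    coords = shapes.coords if isinstance(shapes, CohortShapes) else np.asarray(shapes)
    n = coords.shape[0]
    if n < 3:
        raise ValueError("need at least 3 individuals for shape PCA")
    flat = coords.reshape(n, -1)
    mean = flat.mean(axis=0)
    u, s, vt = np.linalg.svd(flat - mean, full_matrices=False)
    eigenvalues = s ** 2 / (n - 1)
    total = float(eigenvalues.sum())
    cum = np.cumsum(eigenvalues) / total
    m = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    m = min(m, len(eigenvalues))
    raw_scores = u[:, :m] * s[:m]
    sd = raw_scores.std(axis=0, ddof=1)
    return ShapePCA(
        loadings=vt[:m].T,
        eigenvalues=eigenvalues[:m],
        scores=raw_scores / sd,
        mean=mean,
        var_threshold=var_threshold,
        m_retained=m,
        total_variance=total,
    )


def _r2_per_component(X: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Per-component R² of a full-component PLSR (= OLS) of scores on X."""
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Yc = scores - scores.mean(axis=0)
    if Xc.shape[1] == 1:
        # single predictor: R2_j is the squared correlation
        x = Xc[:, 0]
        xx = float(x @ x)
        if xx == 0:
            raise ValueError("predictor has zero variance")
        ess = (x @ Yc) ** 2 / xx
    else:
        q, _ = np.linalg.qr(Xc)
        proj = q.T @ Yc
        ess = (proj ** 2).sum(axis=0)
    tss = (Yc ** 2).sum(axis=0)
    tss = np.where(tss == 0, 1.0, tss)
    return ess / tss


def total_r2(X: np.ndarray, pca: ShapePCA,
             weighting: str = "eigenvalue") -> float:
    """Total fraction of retained shape variance explained by ``X``.

    "eigenvalue" weights component R²s by component variance; "unit"
    averages them equally.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim == 2 and X.shape[0] == 1 and pca.scores.shape[0] != 1:
        X = X.T
    n, q = X.shape
    if n != pca.scores.shape[0]:
        raise ValueError("predictor rows do not match PCA scores")
    if q >= n:
        raise ValueError(f"need fewer predictors than individuals (q={q}, n={n})")
    if X.std(axis=0).min() == 0:
        raise ValueError("predictor with zero variance")
    r2 = _r2_per_component(X, pca.scores)
    if weighting == "eigenvalue":
        w = pca.eigenvalues
    elif weighting == "unit":
        w = np.ones_like(pca.eigenvalues)
    else:
        raise ValueError("weighting must be 'eigenvalue' or 'unit'")
    return float((w * r2).sum() / w.sum())


def permutation_test(X: np.ndarray, pca: ShapePCA, B: int = 10_000,
                     seed: int | None = None, weighting: str = "eigenvalue",
                     scheme: str = "rows", keep_null: bool = False
                     ) -> PermutationResult:
    """Permutation test of the shape variance explained by ``X``.

    The null re-randomizes the predictor-to-individual assignment B times
    (``scheme="rows"``); ``scheme="residual"`` permutes the centred shape
    scores instead (a Freedman–Lane-style residual permutation — for this
    global test the two schemes are exchangeable-equivalent). The p-value
    uses the add-one rule, so it can never be 0.
    """
    if B < 1:
        raise ValueError("need at least one permutation")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and pca.scores.shape[0] != 1:
        X = X.T
    n = X.shape[0]
    if n < 5:
        warnings.warn("permutation null has poor resolution for n < 5")
    if scheme not in ("rows", "residual"):
        raise ValueError("scheme must be 'rows' or 'residual'")
    rng = np.random.default_rng(seed)
    observed = total_r2(X, pca, weighting)

    w = pca.eigenvalues if weighting == "eigenvalue" else np.ones_like(pca.eigenvalues)
    w = w / w.sum()
    Yc = pca.scores - pca.scores.mean(axis=0)
    tss = (Yc ** 2).sum(axis=0)
    tss = np.where(tss == 0, 1.0, tss)

    null = np.empty(B)
    if X.shape[1] == 1:
        # vectorized: B permuted copies of the single predictor at once
        x = X[:, 0] - X[:, 0].mean()
        xx = float(x @ x)
        perms = np.empty((B, n), dtype=np.intp)
        for b in range(B):
            perms[b] = rng.permutation(n)
        xp = x[perms]                      # (B, n)
        if scheme == "residual":
            # permuting scores rows jointly == permuting x rows here
            pass
        ess = (xp @ Yc) ** 2 / xx          # (B, m)
        null[:] = (ess / tss * w).sum(axis=1)
    else:
        for b in range(B):
            perm = rng.permutation(n)
            Xb = X[perm] if scheme == "rows" else X
            Yb = Yc if scheme == "rows" else Yc[perm]
            null[b] = float((w * _r2_per_component(Xb, Yb)).sum())
    p = (1 + int((null >= observed - 1e-15).sum())) / (B + 1)
    return PermutationResult(
        r2_observed=observed, p_value=p, n_permutations=B, seed=seed,
        r2_null=null if keep_null else None,
    )


def exact_permutation_test(X: np.ndarray, pca: ShapePCA,
                           weighting: str = "eigenvalue") -> float:
    """Exact p-value by enumerating all n! row permutations (tiny n only)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and pca.scores.shape[0] != 1:
        X = X.T
    n = X.shape[0]
    if n > 8:
        raise ValueError("full enumeration is limited to n <= 8")
    observed = total_r2(X, pca, weighting)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r2 = total_r2(X[list(perm)], pca, weighting)
        count += r2 >= observed - 1e-15
        total += 1
    return count / total


DEFAULT_GROUPS = ("ALL",
                  "North-East", "South-East", "East-West", "North-South",
                  "North-West", "South-West",
                  "North", "South", "East", "West")


def groups_from_regions(regions: tuple[str, ...]) -> list[tuple[str, ...]]:
    """ALL, every pair, every single region — the standard test layout."""
    groups: list[tuple[str, ...]] = [tuple(regions)]
    groups += [tuple(p) for p in itertools.combinations(regions, 2)]
    groups += [(r,) for r in regions]
    return groups


def subgroup_tests(pc_scores: np.ndarray, shapes: CohortShapes,
                   labels, groups: list[tuple[str, ...]] | None = None,
                   pc_list: list[int] | None = None,
                   combos: list[list[int]] | None = None,
                   var_threshold: float = 0.96, B: int = 10_000,
                   seed: int | None = None,
                   weighting: str = "eigenvalue") -> pd.DataFrame:
    """Run the permutation test per predictor set per regional group.

    The shape PCA is recomputed inside each group. Returns a tidy frame
    with columns (group, predictor_set, n, m_retained, r2, p); pivoting
    predictor_set x group reproduces the familiar p-value matrix (rows =
    genetic PCs, columns = ALL / pairwise / single-region groups).
    """
    labels = np.asarray(labels)
    if groups is None:
        regions = tuple(dict.fromkeys(labels.tolist()))
        groups = groups_from_regions(regions)
    if not groups:
        raise ValueError("no groups supplied")
    pc_scores = np.asarray(pc_scores, dtype=float)
    if pc_list is None:
        pc_list = list(range(1, pc_scores.shape[1] + 1))

    rng = np.random.default_rng(seed)
    rows = []
    for group in groups:
        name = "ALL" if set(group) == set(dict.fromkeys(labels.tolist())) \
            else "-".join(group)
        mask = np.isin(labels, group)
        n_g = int(mask.sum())
        if n_g < 5:
            rows.append({"group": name, "predictor_set": "(all)", "n": n_g,
                         "m_retained": np.nan, "r2": np.nan, "p": np.nan,
                         "flag": "too-few"})
            continue
        pca_g = shape_pca(shapes.subset(mask), var_threshold)
        X_g = pc_scores[mask]
        sets: list[tuple[str, list[int]]] = [(f"PC{j}", [j]) for j in pc_list]
        if combos:
            sets += [("PC" + "+".join(map(str, c)), list(c)) for c in combos]
        for set_name, pcs_idx in sets:
            cols = [j - 1 for j in pcs_idx]
            res = permutation_test(
                X_g[:, cols], pca_g, B=B,
                seed=int(rng.integers(2 ** 31)), weighting=weighting)
            rows.append({"group": name, "predictor_set": set_name, "n": n_g,
                         "m_retained": pca_g.m_retained,
                         "r2": res.r2_observed, "p": res.p_value, "flag": ""})
    return pd.DataFrame(rows)
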